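"""Two-stage LP: max secretion, weighted flux minimisation, demand variants."""

import numpy as np
import pytest

from tamboor.demand import find_secretable, run_condition, solve_demand
from tamboor.gpr import WeightVector
from tamboor.lp import LpError
from tamboor.model import MediumSpec, apply_medium, make_irreversible
from tamboor.synth import ToySpec, make_toy_model

from conftest import chain_model, unit_weights
from oracles import best_routing


def _target(irr, met, targets=None):
    targets = find_secretable(irr) if targets is None else targets
    return next(t for t in targets if t.metabolite_id == met)


class TestFindSecretable:
    def test_chain_v_max_is_uptake_bound(self):
        irr = make_irreversible(chain_model(3, uptake=10))
        t = _target(irr, "M")
        assert t.v_max == pytest.approx(10.0)

    def test_blocked_path_not_secretable(self):
        m = chain_model(3)
        m.reaction("R2").upper_bound = 0.0
        irr = make_irreversible(m)
        assert "M" not in {t.metabolite_id for t in find_secretable(irr)}

    def test_v_max_matches_cobra_on_branched_net(self):
        cobra = pytest.importorskip("cobra")
        spec = ToySpec(path_lengths=(2, 3), n_decoy_sinks=1, uptake_rate=6.0)
        model = make_toy_model(spec)
        irr = make_irreversible(model)
        ours = {t.metabolite_id: t.v_max for t in find_secretable(irr)}

        cm = cobra.Model("toy")
        cmets = {x.id: cobra.Metabolite(x.id) for x in model.metabolites}
        for r in model.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            cm.add_reactions([cr])
            cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        for met, ex in [("M", "EX_M"), ("D1", "EX_D1")]:
            cm.objective = ex
            assert ours[met] == pytest.approx(cm.optimize().objective_value, abs=1e-6)

    def test_infeasible_base_model_raises(self):
        m = chain_model(2)
        m.reactions[0].name = "biomass"
        # biomass demanded but no substrate allowed in
        m = apply_medium(m, MediumSpec({}, biomass_min=1.0))
        with pytest.raises(LpError, match="infeasible"):
            find_secretable(make_irreversible(m))


class TestSolveDemand:
    def test_three_step_path_demands(self):
        """v_max 10 at fraction 0.9 pushes 9 units through 3 unit reactions:
        weighted demand 27, flux sum 27, 3 active internal reactions."""
        irr = make_irreversible(chain_model(3, uptake=10))
        w = WeightVector("disease-sim", unit_weights(irr))
        rec = solve_demand(irr, _target(irr, "M"), w, secretion_fraction=0.9)
        assert rec.status == "optimal"
        assert rec.demand_weighted == pytest.approx(27.0, abs=1e-6)
        assert rec.demand_fluxsum == pytest.approx(27.0, abs=1e-6)
        assert rec.demand_count == 3

    def test_parallel_paths_route_through_cheaper(self):
        spec = ToySpec(path_lengths=(2, 4), uptake_rate=10.0)
        irr = make_irreversible(make_toy_model(spec))
        w = WeightVector("disease-sim", unit_weights(irr))
        rec = solve_demand(irr, _target(irr, "M"), w)
        assert rec.demand_count == 2
        assert rec.demand_weighted == pytest.approx(18.0, abs=1e-6)

    def test_weight_dependent_rerouting(self):
        """Making the short path 3x as expensive flips the optimum to the long path."""
        spec = ToySpec(path_lengths=(2, 4), uptake_rate=10.0)
        irr = make_irreversible(make_toy_model(spec))
        weights = unit_weights(irr)
        for r in weights:
            if r.startswith("P1_"):
                weights[r] = 3.0
        rec = solve_demand(irr, _target(irr, "M"), WeightVector("disease-sim", weights))
        assert rec.demand_count == 4

    def test_uniform_weight_scaling(self):
        irr = make_irreversible(chain_model(3, uptake=10))
        base = solve_demand(irr, _target(irr, "M"), WeightVector("x", unit_weights(irr)))
        doubled = solve_demand(
            irr, _target(irr, "M"),
            WeightVector("x", {r: 2.0 for r in irr.reaction_ids}),
        )
        assert doubled.demand_weighted == pytest.approx(2 * base.demand_weighted, abs=1e-6)
        assert doubled.demand_fluxsum == pytest.approx(base.demand_fluxsum, abs=1e-6)
        assert doubled.demand_count == base.demand_count

    def test_lower_fraction_never_costs_more(self):
        irr = make_irreversible(chain_model(4, uptake=10))
        w = WeightVector("x", unit_weights(irr))
        t = _target(irr, "M")
        demands = [
            solve_demand(irr, t, w, secretion_fraction=f).demand_weighted
            for f in (0.3, 0.6, 0.9, 1.0)
        ]
        assert demands == sorted(demands)

    def test_infeasible_secretion_recorded_not_fatal(self):
        irr = make_irreversible(chain_model(2, uptake=10))
        t = _target(irr, "M")
        # a target claiming more than the network can deliver
        from tamboor.demand import SecretionTarget

        bogus = SecretionTarget(t.metabolite_id, t.exchange_id, 1e6)
        rec = solve_demand(irr, bogus, WeightVector("x", unit_weights(irr)))
        assert rec.status == "infeasible"
        assert rec.demand_weighted is None


class TestRunCondition:
    def test_one_record_per_target_sorted(self):
        spec = ToySpec(path_lengths=(2,), n_decoy_sinks=2)
        irr = make_irreversible(make_toy_model(spec))
        targets = find_secretable(irr)
        recs = run_condition(irr, targets, WeightVector("x", unit_weights(irr)))
        assert [r.metabolite_id for r in recs] == sorted(r.metabolite_id for r in recs)
        assert len(recs) == len(targets)

    def test_empty_target_list(self):
        irr = make_irreversible(chain_model(2))
        assert run_condition(irr, [], WeightVector("x", unit_weights(irr))) == []

    def test_rerun_determinism(self):
        spec = ToySpec(path_lengths=(2, 3), n_decoy_sinks=1)
        irr = make_irreversible(make_toy_model(spec))
        targets = find_secretable(irr)
        w = WeightVector("x", {r: 1.0 + 0.1 * i for i, r in enumerate(irr.reaction_ids)})
        a = run_condition(irr, targets, w)
        b = run_condition(irr, targets, w)
        assert a == b


class TestOracleEquivalence:
    def _random_case(self, rng):
        n_paths = rng.integers(1, 4)
        lengths = tuple(int(rng.integers(1, 5)) for _ in range(n_paths))
        spec = ToySpec(path_lengths=lengths, uptake_rate=float(rng.uniform(1, 20)))
        model = make_toy_model(spec)
        if sum(lengths) + 2 > 12:  # keep the enumeration honest to the size bound
            return None
        irr = make_irreversible(model)
        weights = {r: float(rng.uniform(0.1, 10.0)) for r in irr.reaction_ids}
        for r in irr.base.reactions:
            if r.is_exchange:
                weights[r.id] = 1.0
        return model, irr, weights, spec

    def test_lp_matches_exhaustive_routing_enumeration(self):
        rng = np.random.default_rng(424242)
        checked = 0
        while checked < 50:
            case = self._random_case(rng)
            if case is None:
                continue
            model, irr, weights, spec = case
            t = _target(irr, "M")
            rec = solve_demand(irr, t, WeightVector("x", weights))
            flux = 0.9 * t.v_max
            best_cost, best_len = best_routing(model, "M", weights, flux)
            assert rec.demand_weighted == pytest.approx(best_cost, abs=1e-6)
            assert rec.demand_count == best_len
            checked += 1

    def test_count_at_least_bfs_shortest_path(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lengths = tuple(int(rng.integers(1, 5)) for _ in range(int(rng.integers(1, 4))))
            spec = ToySpec(path_lengths=lengths)
            model = make_toy_model(spec)
            irr = make_irreversible(model)
            weights = {r: float(rng.uniform(0.5, 2.0)) for r in irr.reaction_ids}
            rec = solve_demand(irr, _target(irr, "M"), WeightVector("x", weights))
            assert rec.demand_count >= min(lengths)

    def test_equal_weights_give_parsimonious_solution(self):
        """With all weights equal the optimum is the minimum-total-flux routing."""
        spec = ToySpec(path_lengths=(3, 5))
        model = make_toy_model(spec)
        irr = make_irreversible(model)
        t = _target(irr, "M")
        rec = solve_demand(irr, t, WeightVector("x", unit_weights(irr)))
        flux = 0.9 * t.v_max
        best_cost, best_len = best_routing(model, "M", unit_weights(irr), flux)
        assert best_len == 3
        assert rec.demand_fluxsum == pytest.approx(best_cost, abs=1e-6)
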