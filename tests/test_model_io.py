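"""Model container, JSON/SBML I/O, medium constraints, irreversible conversion."""

import json

import pytest

from tamboor.model import (
    ConfigurationError,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_medium,
    default_medium,
    make_irreversible,
    read_model,
    write_model,
)

from conftest import chain_model


class TestJsonDialect:
    def test_round_trip_preserves_everything(self, tmp_path):
        model = chain_model(3)
        model.reactions[0].gpr = "(gA and gB) or gC"
        model.genes = sorted(set(model.genes) | {"gA", "gB", "gC"})
        path = tmp_path / "m.json"
        write_model(model, path)
        back = read_model(path)
        assert [m.id for m in back.metabolites] == [m.id for m in model.metabolites]
        for a, b in zip(model.reactions, back.reactions):
            assert (a.id, a.stoichiometry, a.lower_bound, a.upper_bound, a.gpr) == (
                b.id, b.stoichiometry, b.lower_bound, b.upper_bound, b.gpr
            )

    def test_undeclared_metabolite_rejected(self, tmp_path):
        doc = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "R", "stoichiometry": {"A": -1, "GHOST": 1}}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="GHOST"):
            read_model(path)

    def test_unknown_format_is_configuration_error(self, tmp_path):
        path = tmp_path / "m.dat"
        path.write_text("{}")
        with pytest.raises(ConfigurationError):
            read_model(path)

    def test_bounds_default_when_omitted(self, tmp_path):
        doc = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "EX_A", "stoichiometry": {"A": -1}}],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        r = read_model(path).reactions[0]
        assert (r.lower_bound, r.upper_bound) == (0.0, 1000.0)


class TestInvariants:
    def test_inverted_bounds_rejected(self):
        m = chain_model(1)
        m.reactions[0].lower_bound, m.reactions[0].upper_bound = 5, -5
        with pytest.raises(ModelValidationError, match="lower bound"):
            m.validate()

    def test_gpr_gene_must_be_declared(self):
        m = chain_model(1)
        m.reactions[0].gpr = "mystery_gene"
        m.genes = ["g1"]
        with pytest.raises(ModelValidationError, match="mystery_gene"):
            m.validate()

    def test_exchange_detection(self):
        m = chain_model(2)
        assert {r.id for r in m.exchanges()} == {"EX_S", "EX_M"}


class TestApplyMedium:
    def test_only_medium_uptake_open(self):
        m = chain_model(2)
        out = apply_medium(m, MediumSpec({"S": 0.32}))
        assert out.reaction("EX_S").lower_bound == -0.32
        assert out.reaction("EX_M").lower_bound == 0.0

    def test_biomass_minimum_applied(self):
        m = chain_model(2)
        m.reactions[0].name = "biomass assembly"
        out = apply_medium(m, MediumSpec({"S": 0.32}, biomass_min=1e-4))
        assert out.reaction("R1").lower_bound == pytest.approx(1e-4)

    def test_empty_medium_blocks_everything(self):
        from tamboor.demand import find_secretable
        from tamboor.lp import maximize_flux

        m = apply_medium(chain_model(2), MediumSpec({}))
        irr = make_irreversible(m)
        assert find_secretable(irr) == []

    def test_idempotent(self):
        m = chain_model(2)
        medium = MediumSpec({"S": 0.32})
        once = apply_medium(m, medium)
        twice = apply_medium(once, medium)
        assert [(r.lower_bound, r.upper_bound) for r in once.reactions] == [
            (r.lower_bound, r.upper_bound) for r in twice.reactions
        ]

    def test_medium_metabolite_without_exchange_rejected(self):
        with pytest.raises(ConfigurationError, match="unobtainium"):
            apply_medium(chain_model(2), MediumSpec({"unobtainium": 1.0}))


class TestDefaultMedium:
    def test_amino_acid_rates_are_tenth_of_glucose(self):
        med = default_medium(0.32)
        assert med.allowed_uptakes["glucose"] == pytest.approx(0.32)
        assert med.allowed_uptakes["oxygen"] == pytest.approx(1.76)
        for aa in ["histidine", "leucine", "taurine", "ornithine", "NH3"]:
            assert med.allowed_uptakes[aa] == pytest.approx(0.032)
        assert med.biomass_min == pytest.approx(1e-4)

    def test_scaling(self):
        assert default_medium(1.0).allowed_uptakes["valine"] == pytest.approx(0.1)

    def test_full_composition_present(self):
        # Ham's 44 + taurine/ornithine/NH3
        assert len(default_medium(0.32).allowed_uptakes) == 47

    def test_zero_glucose_rejected(self):
        with pytest.raises(ConfigurationError):
            default_medium(0.0)

    def test_id_map_renames(self):
        med = default_medium(0.32, id_map={"glucose": "MAM01965e"})
        assert "MAM01965e" in med.allowed_uptakes
        assert "glucose" not in med.allowed_uptakes


class TestIrreversible:
    def test_split_bounds(self):
        m = chain_model(1)
        m.reactions[0].lower_bound = -5.0
        irr = make_irreversible(m)
        fwd, bwd = irr.split_map["R1"]
        assert irr.base.reaction(fwd).lower_bound == 0.0
        assert irr.base.reaction(fwd).upper_bound == 1000.0
        assert irr.base.reaction(bwd).lower_bound == 0.0
        assert irr.base.reaction(bwd).upper_bound == 5.0
        assert irr.base.reaction(bwd).stoichiometry == {"S": 1.0, "M": -1.0}
        assert irr.base.reaction(bwd).gpr == m.reactions[0].gpr

    def test_irreversible_reaction_untouched(self):
        irr = make_irreversible(chain_model(1))
        assert irr.split_map["R1"] == ("R1", None)

    def test_split_map_covers_all_reactions(self):
        m = chain_model(3)
        irr = make_irreversible(m)
        assert set(irr.split_map) == {r.id for r in m.reactions}
        assert all(v >= 0 for r in irr.base.reactions for v in [r.lower_bound])

    def test_fba_optimum_preserved_against_cobra(self):
        """Max secretion agrees with an independent cobra/GLPK solve on the
        original (reversible) model."""
        cobra = pytest.importorskip("cobra")
        from tamboor.lp import maximize_flux

        m = chain_model(3, uptake=7.0)
        for r in m.reactions[:2]:
            r.lower_bound = -3.0  # make part of the chain reversible
        irr = make_irreversible(m)
        ours = maximize_flux(irr, "EX_M").objective

        cm = cobra.Model("chain")
        cmets = {x.id: cobra.Metabolite(x.id) for x in m.metabolites}
        for r in m.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            cm.add_reactions([cr])
            cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        cm.objective = "EX_M"
        ref = cm.optimize().objective_value
        assert ours == pytest.approx(ref, abs=1e-6)
        assert ours == pytest.approx(7.0, abs=1e-6)


class TestSbml:
    def test_sbml_written_by_cobra_reads_back(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("mini")
        a = cobra.Metabolite("A", compartment="c")
        r1 = cobra.Reaction("R1", lower_bound=-4, upper_bound=9)
        ex = cobra.Reaction("EX_A", lower_bound=-1, upper_bound=1000)
        b = cobra.Metabolite("B", compartment="c")
        cm.add_reactions([r1, ex])
        r1.add_metabolites({a: -1, b: 1})
        ex.add_metabolites({a: -1})
        r1.gene_reaction_rule = "gX or gY"
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cm, str(path))

        m = read_model(path)
        r = m.reaction("R1")
        assert (r.lower_bound, r.upper_bound) == (-4, 9)
        assert sorted(r.stoichiometry.items()) == [("A", -1.0), ("B", 1.0)]
        assert set(m.genes) == {"gX", "gY"}
        assert m.reaction("EX_A").is_exchange
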