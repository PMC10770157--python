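"""Network demand: the two-stage LP behind the TIMBR family.

Stage one finds, per exchange metabolite, the maximum achievable secretion
flux under the medium. Stage two pins secretion at a fraction of that
maximum (default 90%) and minimises the expression-weighted flux sum over
the irreversible model. From the single optimal flux vector, three network
demands are read off:

* weighted demand  — Σ w·v over internal reactions (original TIMBR),
* flux-sum demand  — Σ v over internal reactions (modified TIMBR),
* active count     — number of internal reactions with v above the
  activity threshold (TAMBOOR).

Exchange reactions participate in the LP (at weight 1) but are plumbing
common to every solution and are excluded from the reported demands; split
halves of reversible reactions are counted separately (at a canonical
optimum at most one half carries flux).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .gpr import WeightVector
from .lp import LpError, maximize_flux, minimize_weighted_flux
from .model import IrreversibleModel

__all__ = [
    "SecretionTarget",
    "DemandRecord",
    "find_secretable",
    "solve_demand",
    "run_condition",
    "write_demands_tsv",
]

log = logging.getLogger(__name__)

#: flux above which a reaction counts as "on"
ACTIVITY_EPS = 1e-5
#: fraction of the maximum secretion rate enforced during demand minimisation
SECRETION_FRACTION = 0.9


@dataclass(frozen=True)
class SecretionTarget:
    metabolite_id: str
    exchange_id: str  # forward (secretion) half in the irreversible model
    v_max: float


@dataclass
class DemandRecord:
    metabolite_id: str
    condition: str
    demand_weighted: float | None
    demand_fluxsum: float | None
    demand_count: int | None
    status: str  # "optimal" | "infeasible" | "not-secretable"
    v_max: float = 0.0


def _secretion_exchanges(irr: IrreversibleModel) -> list[tuple[str, str]]:
    """(metabolite, secretion-exchange id) pairs, ordered by metabolite id.

    In the irreversible model the secretion direction of an exchange is the
    half that consumes its metabolite (coefficient < 0) — the forward half
    under the standard orientation, or the reversed half if the exchange was
    written in uptake orientation.
    """
    pairs: dict[str, str] = {}
    for rxn in irr.base.reactions:
        if rxn.is_exchange and rxn.upper_bound > 0:
            (met,) = rxn.stoichiometry
            if rxn.stoichiometry[met] < 0 and met not in pairs:
                pairs[met] = rxn.id
    return sorted(pairs.items())


def find_secretable(
    irr: IrreversibleModel, activity_eps: float = ACTIVITY_EPS
) -> list[SecretionTarget]:
    """Maximise each exchange's secretion flux; keep metabolites with v_max above threshold.

    Raises LpError if the base model is infeasible (medium and biomass
    minimum inconsistent).
    """
    base = minimize_weighted_flux(irr, {r: 1.0 for r in irr.reaction_ids}, canonicalize=False)
    if base.status != "optimal":
        raise LpError("base model infeasible: medium and biomass constraints are inconsistent")
    targets = []
    for met, ex in _secretion_exchanges(irr):
        res = maximize_flux(irr, ex)
        if res.status == "optimal" and res.objective > activity_eps:
            targets.append(SecretionTarget(met, ex, float(res.objective)))
        else:
            log.debug("metabolite %s not secretable", met)
    return targets


def solve_demand(
    irr: IrreversibleModel,
    target: SecretionTarget,
    weights: WeightVector,
    secretion_fraction: float = SECRETION_FRACTION,
    activity_eps: float = ACTIVITY_EPS,
    canonicalize: bool = True,
) -> DemandRecord:
    """Pin secretion at ``secretion_fraction``·v_max and minimise the weighted flux sum.

    All three demand variants are computed from the same optimal vector.
    """
    if not 0 < secretion_fraction <= 1:
        raise ValueError("secretion_fraction must be in (0, 1]")
    if target.v_max <= 0:
        return DemandRecord(target.metabolite_id, weights.case, None, None, None, "not-secretable")
    res = minimize_weighted_flux(
        irr,
        weights.weights,
        bound_overrides={target.exchange_id: (secretion_fraction * target.v_max, None)},
        canonicalize=canonicalize,
    )
    if res.status != "optimal":
        return DemandRecord(
            target.metabolite_id, weights.case, None, None, None, "infeasible", target.v_max
        )
    w = weights.weights
    internal = irr.internal_mask
    dw = sum(w[r] * v for r, v in res.fluxes.items() if internal[r])
    fs = sum(v for r, v in res.fluxes.items() if internal[r])
    cnt = sum(1 for r, v in res.fluxes.items() if internal[r] and v > activity_eps)
    return DemandRecord(
        metabolite_id=target.metabolite_id,
        condition=weights.case,
        demand_weighted=dw,
        demand_fluxsum=fs,
        demand_count=cnt,
        status="optimal",
        v_max=target.v_max,
    )


def run_condition(
    irr: IrreversibleModel,
    targets: Iterable[SecretionTarget],
    weights: WeightVector,
    secretion_fraction: float = SECRETION_FRACTION,
    activity_eps: float = ACTIVITY_EPS,
    canonicalize: bool = True,
) -> list[DemandRecord]:
    """One DemandRecord per target, ordered by metabolite id."""
    records = []
    for t in sorted(targets, key=lambda t: t.metabolite_id):
        rec = solve_demand(irr, t, weights, secretion_fraction, activity_eps, canonicalize)
        log.debug("%s/%s: %s", t.metabolite_id, weights.case, rec.status)
        records.append(rec)
    n_ok = sum(1 for r in records if r.status == "optimal")
    log.info("condition %s: %d/%d targets optimal", weights.case, n_ok, len(records))
    return records


def write_demands_tsv(records: Sequence[DemandRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "metabolite_id": r.metabolite_id,
                "condition": r.condition,
                "demand_weighted": r.demand_weighted,
                "demand_fluxsum": r.demand_fluxsum,
                "demand_count": r.demand_count,
                "status": r.status,
                "v_max": r.v_max,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
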