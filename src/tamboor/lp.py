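"""Linear-programming layer over the irreversible model (scipy HiGHS).

All solves share the steady-state constraint S·v = 0 with per-reaction
bounds 0 ≤ lb ≤ v ≤ ub. Two entry points: maximise a single flux, and
minimise a weighted flux sum with an optional canonicalisation step that
re-minimises total flux at the fixed optimum to pick a reproducible vertex
when the weighted optimum is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model import IrreversibleModel

__all__ = ["LpResult", "LpError", "maximize_flux", "minimize_weighted_flux"]

# requested solver feasibility/optimality tolerance
SOLVER_TOL = 1e-9


class LpError(RuntimeError):
    pass


@dataclass
class LpResult:
    status: str  # "optimal" | "infeasible"
    objective: float | None
    fluxes: dict[str, float] | None


def _problem(irr: IrreversibleModel, bound_overrides: Mapping[str, tuple] | None = None):
    rxns = irr.base.reactions
    met_index = {m.id: i for i, m in enumerate(irr.base.metabolites)}
    rows, cols, vals = [], [], []
    bounds = []
    for j, r in enumerate(rxns):
        lo, hi = r.lower_bound, r.upper_bound
        if bound_overrides and r.id in bound_overrides:
            olo, ohi = bound_overrides[r.id]
            lo = lo if olo is None else olo
            hi = hi if ohi is None else ohi
        bounds.append((lo, hi))
        for met, coef in r.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    A = csr_matrix((vals, (rows, cols)), shape=(len(met_index), len(rxns)))
    return A, bounds


def _solve(irr, c, bound_overrides=None, extra_ub=None):
    A, bounds = _problem(irr, bound_overrides)
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    res = linprog(
        c,
        A_eq=A,
        b_eq=np.zeros(A.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def _as_flux_dict(irr, x) -> dict[str, float]:
    return {r.id: float(v) for r, v in zip(irr.base.reactions, x)}


def maximize_flux(
    irr: IrreversibleModel,
    reaction_id: str,
    bound_overrides: Mapping[str, tuple] | None = None,
) -> LpResult:
    """Maximise one reaction's flux subject to steady state and bounds."""
    ids = irr.reaction_ids
    if reaction_id not in ids:
        raise KeyError(reaction_id)
    c = np.zeros(len(ids))
    c[ids.index(reaction_id)] = -1.0
    res = _solve(irr, c, bound_overrides)
    if res.status != 0:
        return LpResult("infeasible", None, None)
    return LpResult("optimal", -res.fun, _as_flux_dict(irr, res.x))


def minimize_weighted_flux(
    irr: IrreversibleModel,
    weights: Mapping[str, float],
    bound_overrides: Mapping[str, tuple] | None = None,
    canonicalize: bool = True,
) -> LpResult:
    """Minimise Σ w_j v_j; optionally canonicalise by re-minimising Σ v at the optimum.

    The canonicalisation adds the constraint w·v ≤ z* (plus a tolerance slack
    scaled to z*) and minimises total flux, which removes cost-free futile
    cycles and yields a solver-independent vertex among degenerate optima.
    """
    ids = irr.reaction_ids
    missing = [r for r in ids if r not in weights]
    if missing:
        raise ValueError(f"weights missing for reactions: {missing[:5]}")
    c = np.array([weights[r] for r in ids])
    res = _solve(irr, c, bound_overrides)
    if res.status != 0:
        return LpResult("infeasible", None, None)
    z = float(res.fun)
    x = res.x
    if canonicalize:
        slack = SOLVER_TOL * max(1.0, abs(z))
        res2 = _solve(
            irr,
            np.ones(len(ids)),
            bound_overrides,
            extra_ub=(c.reshape(1, -1), np.array([z + slack])),
        )
        if res2.status == 0:
            x = res2.x
            z = float(c @ x)
    return LpResult("optimal", z, _as_flux_dict(irr, x))
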