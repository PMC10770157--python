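"""GPR rules: parsing, expression mapping, and LP weight vectors.

A GPR (gene-protein-reaction) rule is a boolean expression over gene ids
with AND meaning an enzyme complex (all subunits required) and OR meaning
isoenzymes (any suffices). Mapping expression onto a reaction follows the
standard min/max semantics: AND → minimum of the subunit expressions,
OR → maximum over isoenzymes; a single-gene rule passes the value through.

Weights for the flux-minimisation objective are expression fold changes of
these reaction scores between the two states: control/disease for the
disease-case simulation and the reciprocal for the control-case simulation,
so that reactions down-regulated in the simulated case become expensive and
carry less flux.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .model import IrreversibleModel, MetabolicModel, REV_SUFFIX

__all__ = [
    "GprParseError",
    "parse_gpr",
    "genes_of",
    "evaluate_tree",
    "ExpressionProfile",
    "ReactionScoreVector",
    "WeightVector",
    "score_reactions",
    "compute_weights",
    "load_expression_tsv",
    "collapse_conditions",
]

# epsilon guarding fold-change division; cap bounding weights away from 0/inf
EPSILON = 1e-8
WEIGHT_CAP = 100.0


class GprParseError(ValueError):
    pass


# GPR tree: gene leaves are strings; internal nodes are ("and"|"or", [children]).
GprNode = Union[str, tuple]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and": "and", "or": "or", "&": "and", "&&": "and", "|": "or", "||": "or"}


def parse_gpr(gpr: str) -> GprNode | None:
    """Parse a GPR string into a tree; AND binds tighter than OR. Empty → None."""
    if gpr is None or not gpr.strip():
        return None
    tokens = [(m.group(0), m.start()) for m in _TOKEN.finditer(gpr)]
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def kind(tok):
        return _KEYWORDS.get(tok.lower()) if tok is not None else None

    def err(msg):
        at = tokens[pos][1] if pos < len(tokens) else len(gpr)
        raise GprParseError(f"{msg} at position {at} in {gpr!r}")

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while kind(peek()) == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while kind(peek()) == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            err("unexpected end of expression")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                err("expected ')'")
            pos += 1
            return node
        if tok == ")" or kind(tok) is not None:
            err(f"unexpected token {tok!r}")
        pos += 1
        return tok

    tree = parse_or()
    if pos != len(tokens):
        err(f"trailing token {peek()!r}")
    return tree


def genes_of(gpr: str | GprNode | None) -> set[str]:
    node = parse_gpr(gpr) if isinstance(gpr, str) or gpr is None else gpr
    out: set[str] = set()

    def walk(n):
        if n is None:
            return
        if isinstance(n, str):
            out.add(n)
        else:
            for c in n[1]:
                walk(c)

    walk(node)
    return out


def evaluate_tree(node: GprNode | None, values: Mapping[str, float]) -> float | None:
    """Numeric min/max evaluation of a GPR tree.

    Unmeasured genes yield None leaves; AND is undefined if any subunit is
    undefined, OR takes the max over its measured branches (undefined only if
    all are). Empty tree → None.
    """
    if node is None:
        return None
    if isinstance(node, str):
        return values.get(node)
    op, children = node
    vals = [evaluate_tree(c, values) for c in children]
    if op == "and":
        if any(v is None for v in vals):
            return None
        return min(vals)
    defined = [v for v in vals if v is not None]
    return max(defined) if defined else None


# ---------------------------------------------------------------------------
# expression profiles and reaction scores
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Per-condition gene expression summary (normalized, unitless, ≥ 0)."""

    condition: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ValueError(f"negative/non-finite expression values: {list(bad)[:5]}")


@dataclass
class ReactionScoreVector:
    """Per-reaction expression scores for one condition.

    ``provenance`` records which mapping rule produced each reaction's score:
    single | isozyme-max | complex-min for scored reactions, no-gpr for
    reactions without a rule, unmeasured when every informative gene is
    absent from the data.
    """

    condition: str
    scores: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)


def _rule_name(node: GprNode) -> str:
    if isinstance(node, str):
        return "single"
    return "isozyme-max" if node[0] == "or" else "complex-min"


def score_reactions(model: MetabolicModel, expr: ExpressionProfile) -> ReactionScoreVector:
    """Map gene expression onto reaction scores via min/max GPR evaluation."""
    if not expr.values:
        raise ValueError("expression profile is empty")
    scores: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for r in model.reactions:
        tree = parse_gpr(r.gpr)
        if tree is None:
            provenance[r.id] = "no-gpr"
            continue
        val = evaluate_tree(tree, expr.values)
        if val is None:
            provenance[r.id] = "unmeasured"
            continue
        scores[r.id] = float(val)
        provenance[r.id] = _rule_name(tree)
    return ReactionScoreVector(condition=expr.condition, scores=scores, provenance=provenance)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    """Objective coefficients for one simulated case over the irreversible model."""

    case: str  # "control-sim" | "disease-sim"
    weights: dict[str, float]

    def __post_init__(self) -> None:
        bad = {r: w for r, w in self.weights.items() if w <= 0 or not math.isfinite(w)}
        if bad:
            raise ValueError(f"non-positive/non-finite weights: {list(bad)[:5]}")


def compute_weights(
    ctrl: ReactionScoreVector,
    dis: ReactionScoreVector,
    irr: IrreversibleModel,
    case: str = "disease-sim",
    epsilon: float = EPSILON,
    cap: float = WEIGHT_CAP,
    normalize: bool = False,
) -> WeightVector:
    """Fold-change weights for one simulated case.

    disease-sim: w = (S_control + ε) / (S_disease + ε); control-sim is the
    reciprocal. Weights are clipped to [1/cap, cap]. Reactions without a GPR,
    with unmeasured genes, and exchange reactions get weight 1. Both halves
    of a split reversible reaction share the original reaction's weight.
    ``normalize=True`` rescales the vector to mean 1 (for parity with
    log-weight TIMBR variants).
    """
    if case not in ("control-sim", "disease-sim"):
        raise ValueError(f"unknown case {case!r}")
    if set(ctrl.provenance) != set(dis.provenance):
        raise ValueError("control and disease scores computed on different reaction sets")
    weights: dict[str, float] = {}
    for orig, (fwd, bwd) in irr.split_map.items():
        sc, sd = ctrl.scores.get(orig), dis.scores.get(orig)
        exchange = not irr.internal_mask.get(fwd, True)
        if sc is None or sd is None or exchange:
            w = 1.0
        else:
            ratio = (sc + epsilon) / (sd + epsilon)
            w = ratio if case == "disease-sim" else 1.0 / ratio
            w = min(max(w, 1.0 / cap), cap)
        weights[fwd] = w
        if bwd is not None:
            weights[bwd] = w
    if normalize:
        mean = sum(weights.values()) / len(weights)
        weights = {r: w / mean for r, w in weights.items()}
    return WeightVector(case=case, weights=weights)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def load_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix TSV: first column ``gene_id``, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {df.columns[0]!r}")
    return df.set_index("gene_id")


def collapse_conditions(
    matrix: pd.DataFrame, condition_map: Mapping[str, str]
) -> dict[str, ExpressionProfile]:
    """Collapse a sample-level matrix to one profile per condition (arithmetic mean)."""
    unknown = sorted(set(condition_map) - set(matrix.columns))
    if unknown:
        raise ValueError(f"condition map names samples absent from the matrix: {unknown}")
    out: dict[str, ExpressionProfile] = {}
    for cond in sorted(set(condition_map.values())):
        samples = [s for s, c in condition_map.items() if c == cond]
        means = matrix[samples].mean(axis=1)
        out[cond] = ExpressionProfile(condition=cond, values=means.to_dict())
    return out


def load_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"], comment="#")
    return dict(zip(df["sample_id"].astype(str), df["condition"].astype(str)))


def write_scores_tsv(vec: ReactionScoreVector, path: str | Path) -> None:
    rows = [
        {"reaction_id": r, "score": vec.scores.get(r, float("nan")), "rule": rule}
        for r, rule in sorted(vec.provenance.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_weights_tsv(vec: WeightVector, path: str | Path) -> None:
    rows = [{"reaction_id": r, "weight": w} for r, w in sorted(vec.weights.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_weights_tsv(path: str | Path, case: str = "disease-sim") -> WeightVector:
    df = pd.read_csv(path, sep="\t")
    return WeightVector(case=case, weights=dict(zip(df["reaction_id"], df["weight"].astype(float))))
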