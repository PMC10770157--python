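"""Production scores, percentile candidate calling, meta-analysis, evaluation.

The production score contrasts the network demand of a metabolite between
the two simulated states,

    score = (X_control − X_disease) / (X_control + X_disease),

bounded in [−1, 1] for non-negative demands. A high score means the demand
for sustaining high secretion is lower in disease, i.e. increased
production potential in disease; a low score means the opposite. Per
comparison, the top and bottom percentile tails of the score ranking are
called candidates; across comparisons, metabolites called in the same
direction in at least ``min_support`` comparisons become biomarker
candidates. Evaluation against a directional gold list uses precision and
recall with direction-aware matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .demand import DemandRecord

__all__ = [
    "ProductionScoreTable",
    "Call",
    "BiomarkerCallTable",
    "EvaluationReport",
    "ALGORITHMS",
    "production_scores",
    "call_candidates",
    "meta_analysis",
    "evaluate",
    "precision_recall_from_counts",
    "load_gold_markers",
    "load_reported_counts",
]

log = logging.getLogger(__name__)

#: demand field backing each algorithm
ALGORITHMS = {
    "timbr": "demand_weighted",
    "modified-timbr": "demand_fluxsum",
    "tamboor": "demand_count",
}

PERCENTILE = 0.25
MIN_SUPPORT = 7


@dataclass
class ProductionScoreTable:
    comparison: str
    algorithm: str
    scores: dict[str, float]
    dropped: dict[str, str] = field(default_factory=dict)


def production_scores(
    ctrl: Sequence[DemandRecord],
    dis: Sequence[DemandRecord],
    algorithm: str,
    comparison: str = "comparison",
) -> ProductionScoreTable:
    """Pair control/disease demand records by metabolite and apply the score formula.

    Metabolites with non-optimal status in either condition, or with a zero
    demand sum, are dropped with a logged reason.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {sorted(ALGORITHMS)}")
    fld = ALGORITHMS[algorithm]
    cmap = {r.metabolite_id: r for r in ctrl}
    dmap = {r.metabolite_id: r for r in dis}
    scores: dict[str, float] = {}
    dropped: dict[str, str] = {}
    for met in sorted(set(cmap) | set(dmap)):
        rc, rd = cmap.get(met), dmap.get(met)
        if rc is None or rd is None:
            dropped[met] = "missing-in-one-condition"
        elif rc.status != "optimal" or rd.status != "optimal":
            dropped[met] = f"status:{rc.status}/{rd.status}"
        else:
            xc, xd = getattr(rc, fld), getattr(rd, fld)
            if xc + xd == 0:
                dropped[met] = "zero-demand-sum"
            else:
                scores[met] = (xc - xd) / (xc + xd)
    for met, why in dropped.items():
        log.debug("dropped %s: %s", met, why)
    return ProductionScoreTable(comparison=comparison, algorithm=algorithm, scores=scores, dropped=dropped)


@dataclass(frozen=True)
class Call:
    metabolite_id: str
    comparison: str
    direction: str  # "increased" | "decreased"  (in disease)
    score: float
    rank: int


def call_candidates(table: ProductionScoreTable, percentile: float = PERCENTILE) -> list[Call]:
    """Call the top tail increased-in-disease and the bottom tail decreased-in-disease.

    Each tail holds ⌈percentile·n⌉ metabolites; ties at a cut are resolved
    by metabolite-id lexicographic order, so calls are deterministic. When
    the two tails would overlap (tiny n), the bottom tail is drawn from
    metabolites not already called increased, keeping directions mutually
    exclusive.
    """
    if not table.scores:
        raise ValueError("empty production score table")
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must be in (0, 0.5)")
    n = len(table.scores)
    k = math.ceil(percentile * n)
    desc = sorted(table.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    calls = [
        Call(met, table.comparison, "increased", s, i + 1)
        for i, (met, s) in enumerate(desc[:k])
    ]
    taken = {c.metabolite_id for c in calls}
    asc = [kv for kv in sorted(table.scores.items(), key=lambda kv: (kv[1], kv[0])) if kv[0] not in taken]
    calls += [
        Call(met, table.comparison, "decreased", s, n - i)
        for i, (met, s) in enumerate(asc[:k])
    ]
    return calls


@dataclass
class BiomarkerCallTable:
    """Per-metabolite direction counts across comparisons, with candidate flags."""

    algorithm: str
    n_comparisons: int
    min_support: int
    counts: pd.DataFrame  # index metabolite_id; n_increased, n_decreased, candidate

    def candidates(self) -> dict[str, str]:
        sel = self.counts[self.counts["candidate"].isin(["increased", "decreased"])]
        return dict(zip(sel.index, sel["candidate"]))


def meta_analysis(
    calls_by_comparison: Mapping[str, Sequence[Call]],
    min_support: int = MIN_SUPPORT,
    algorithm: str = "tamboor",
) -> BiomarkerCallTable:
    """Count per-direction calls across comparisons and flag candidates.

    A metabolite is a candidate in a direction when called that way in at
    least ``min_support`` comparisons; metabolites reaching the threshold in
    both directions are flagged contradictory and excluded. Comparisons over
    different metabolite universes are unioned, absences counting as
    no-call.
    """
    if not calls_by_comparison:
        raise ValueError("no comparisons given")
    n_comparisons = len(calls_by_comparison)
    if min_support > n_comparisons:
        raise ValueError("min_support exceeds the number of comparisons")
    universes = [
        {c.metabolite_id for c in calls} for calls in calls_by_comparison.values()
    ]
    if len(set(map(frozenset, universes))) > 1:
        log.warning("comparisons cover different metabolite sets; taking the union")
    rows: dict[str, dict[str, int]] = {}
    for calls in calls_by_comparison.values():
        for c in calls:
            row = rows.setdefault(c.metabolite_id, {"n_increased": 0, "n_decreased": 0})
            row["n_" + c.direction] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "metabolite_id"

    def flag(row):
        inc, dec = row["n_increased"] >= min_support, row["n_decreased"] >= min_support
        if inc and dec:
            return "contradictory"
        return "increased" if inc else "decreased" if dec else "none"

    df["candidate"] = df.apply(flag, axis=1)
    return BiomarkerCallTable(
        algorithm=algorithm, n_comparisons=n_comparisons, min_support=min_support, counts=df
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when no predictions were made
    recall: float
    matches: pd.DataFrame  # metabolite_id, predicted, gold, outcome

    def summary(self) -> str:
        p = "n/a" if self.precision is None else f"{self.precision:.3f}"
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn} "
            f"precision={p} recall={self.recall:.3f}"
        )


def evaluate(table: BiomarkerCallTable, gold: pd.DataFrame) -> EvaluationReport:
    """Direction-aware precision/recall of candidates against a gold marker list.

    ``gold`` needs columns ``metabolite_id`` and ``direction``. A candidate
    called in the wrong direction counts as a false positive and leaves the
    gold entry a false negative.
    """
    need = {"metabolite_id", "direction"}
    if not need <= set(gold.columns):
        raise ValueError(f"gold list must have columns {sorted(need)}")
    predicted = table.candidates()
    gold_dir = dict(zip(gold["metabolite_id"], gold["direction"]))
    rows = []
    tp = fp = fn = 0
    for met, direction in sorted(predicted.items()):
        if met in gold_dir and gold_dir[met] == direction:
            tp += 1
            rows.append((met, direction, gold_dir[met], "TP"))
        else:
            fp += 1
            rows.append((met, direction, gold_dir.get(met), "FP"))
    matched = {m for m, d in predicted.items() if gold_dir.get(m) == d}
    for met, direction in sorted(gold_dir.items()):
        if met not in matched:
            fn += 1
            rows.append((met, predicted.get(met), direction, "FN"))
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    matches = pd.DataFrame(rows, columns=["metabolite_id", "predicted", "gold", "outcome"])
    return EvaluationReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, matches=matches)


def precision_recall_from_counts(tp: int, n_predictions: int, n_gold: int) -> tuple[float, float]:
    """Precision = TP/(TP+FP) with TP+FP = n_predictions; recall = TP/(TP+FN) with TP+FN = n_gold."""
    if tp < 0 or n_predictions < tp or n_gold < tp:
        raise ValueError("inconsistent counts")
    return tp / n_predictions, tp / n_gold


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _packaged(name: str):
    return resources.files("tamboor.data").joinpath(name)


def load_gold_markers(path: str | Path | None = None) -> pd.DataFrame:
    """Curated directional marker list (high-confidence + well-known entries).

    Columns: metabolite_id, direction, source (high_confidence | well_known),
    detected_by (which algorithm(s) recovered it in the reference analysis;
    'none' if none did).
    """
    src = _packaged("gold_markers.tsv") if path is None else Path(path)
    return pd.read_csv(src, sep="\t", comment="#")


def load_reported_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Reference per-algorithm prediction counts used for evaluation arithmetic.

    Columns: algorithm, n_increased, n_decreased, n_total_reported,
    n_high_confidence_detected, n_well_known_detected.
    """
    src = _packaged("reported_counts.tsv") if path is None else Path(path)
    return pd.read_csv(src, sep="\t", comment="#").set_index("algorithm")
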