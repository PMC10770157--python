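"""Pathway over-representation analysis for candidate metabolite sets.

One-sided hypergeometric test per pathway: given a universe of U annotated
metabolites, a pathway with K members and a candidate set of n metabolites
overlapping k of them, p = P(X ≥ k) for X ~ Hypergeom(U, K, n).
Benjamini–Hochberg controls the FDR across the tested pathways (default
significance cut FDR < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .model import ConfigurationError

__all__ = ["PathwayAnnotation", "enrich", "load_annotations_tsv", "FDR_CUTOFF"]

FDR_CUTOFF = 0.05


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    name: str
    members: frozenset[str]


def load_annotations_tsv(path: str | Path) -> list[PathwayAnnotation]:
    """Long-format TSV: pathway_id, pathway_name, metabolite_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for (pid, pname), grp in df.groupby(["pathway_id", "pathway_name"], sort=True):
        out.append(PathwayAnnotation(pid, pname, frozenset(grp["metabolite_id"])))
    return out


def enrich(
    candidates: Iterable[str],
    annotations: Sequence[PathwayAnnotation],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric ORA of ``candidates`` against each pathway, BH-adjusted.

    Pathway membership is intersected with the universe before testing.
    Returns a frame sorted by p with columns pathway_id, pathway_name,
    overlap, set_size, pathway_size, universe, p, q.
    """
    universe = set(universe)
    if not universe:
        raise ConfigurationError("empty universe")
    candidates = set(candidates)
    stray = candidates - universe
    if stray:
        raise ConfigurationError(f"candidates outside the universe: {sorted(stray)[:5]}")
    rows = []
    for ann in annotations:
        members = ann.members & universe
        if not members:
            continue
        k = len(candidates & members)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(candidates)))
        rows.append(
            {
                "pathway_id": ann.pathway_id,
                "pathway_name": ann.name,
                "overlap": k,
                "set_size": len(candidates),
                "pathway_size": len(members),
                "universe": len(universe),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        return df
    df["q"] = false_discovery_control(df["p"], method="bh")
    return df.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)
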