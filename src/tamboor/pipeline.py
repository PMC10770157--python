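"""End-to-end pipeline: model + medium + expression comparisons → biomarker candidates.

Each comparison (one expression matrix with a control/disease condition
map) is processed independently: reaction scores for both conditions,
fold-change weight vectors for the control-case and disease-case
simulations, demand records per secretable metabolite, production scores
and percentile calls per algorithm. Calls are then meta-analysed across
comparisons; optional evaluation against a gold list and pathway
enrichment close the run. Every stage writes a TSV into the run directory
and a JSON manifest records parameters and output hashes, so reruns on
identical inputs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import calling, enrichment as enrichment_mod
from .calling import ALGORITHMS, BiomarkerCallTable, Call
from .demand import (
    ACTIVITY_EPS,
    SECRETION_FRACTION,
    find_secretable,
    run_condition,
    write_demands_tsv,
)
from .gpr import (
    EPSILON,
    WEIGHT_CAP,
    collapse_conditions,
    compute_weights,
    load_condition_map,
    load_expression_tsv,
    score_reactions,
    write_scores_tsv,
    write_weights_tsv,
)
from .model import ConfigurationError, MediumSpec, apply_medium, make_irreversible, read_model

log = logging.getLogger(__name__)

__all__ = ["Comparison", "RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class Comparison:
    name: str
    expression_path: Path
    condition_map_path: Path


@dataclass
class RunConfig:
    model_path: Path
    medium: MediumSpec | None  # None: use the model's own bounds unchanged
    comparisons: Sequence[Comparison]
    out_dir: Path
    algorithms: tuple[str, ...] = tuple(ALGORITHMS)
    percentile: float = calling.PERCENTILE
    min_support: int = calling.MIN_SUPPORT
    epsilon: float = EPSILON
    cap: float = WEIGHT_CAP
    secretion_fraction: float = SECRETION_FRACTION
    activity_eps: float = ACTIVITY_EPS
    canonicalize: bool = True
    normalize_weights: bool = False
    control_label: str = "control"
    disease_label: str = "disease"
    gold_path: Path | None = None
    annotations_path: Path | None = None
    model_format: str | None = None

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.model_path]
            + [c.expression_path for c in self.comparisons]
            + [c.condition_map_path for c in self.comparisons]
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")
        bad = sorted(set(self.algorithms) - set(ALGORITHMS))
        if bad:
            raise ConfigurationError(f"unknown algorithms: {bad}")
        if not self.comparisons:
            raise ConfigurationError("at least one comparison is required")
        if not 0 < self.percentile < 0.5:
            raise ConfigurationError("percentile must be in (0, 0.5)")
        if self.min_support > len(self.comparisons):
            raise ConfigurationError("min_support exceeds the number of comparisons")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to the run directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    model = read_model(config.model_path, config.model_format)
    if config.medium is not None:
        model = apply_medium(model, config.medium)
    irr = make_irreversible(model)
    targets = find_secretable(irr, config.activity_eps)
    log.info("%d secretable metabolites", len(targets))
    pd.DataFrame(
        [{"metabolite_id": t.metabolite_id, "exchange_id": t.exchange_id, "v_max": t.v_max} for t in targets]
    ).to_csv(out / "secretable.tsv", sep="\t", index=False)
    outputs["secretable"] = out / "secretable.tsv"

    calls: dict[str, dict[str, list[Call]]] = {a: {} for a in config.algorithms}
    all_scores: list[dict] = []
    for comp in config.comparisons:
        matrix = load_expression_tsv(comp.expression_path)
        cond_map = load_condition_map(comp.condition_map_path)
        profiles = collapse_conditions(matrix, cond_map)
        for label in (config.control_label, config.disease_label):
            if label not in profiles:
                raise ConfigurationError(
                    f"comparison {comp.name!r}: condition {label!r} absent from {sorted(profiles)}"
                )
        sc = score_reactions(model, profiles[config.control_label])
        sd = score_reactions(model, profiles[config.disease_label])
        write_scores_tsv(sc, out / f"{comp.name}.scores.control.tsv")
        write_scores_tsv(sd, out / f"{comp.name}.scores.disease.tsv")
        outputs[f"{comp.name}.scores.control"] = out / f"{comp.name}.scores.control.tsv"
        outputs[f"{comp.name}.scores.disease"] = out / f"{comp.name}.scores.disease.tsv"

        records = {}
        for case in ("control-sim", "disease-sim"):
            w = compute_weights(
                sc, sd, irr, case=case,
                epsilon=config.epsilon, cap=config.cap, normalize=config.normalize_weights,
            )
            write_weights_tsv(w, out / f"{comp.name}.weights.{case}.tsv")
            outputs[f"{comp.name}.weights.{case}"] = out / f"{comp.name}.weights.{case}.tsv"
            records[case] = run_condition(
                irr, targets, w,
                secretion_fraction=config.secretion_fraction,
                activity_eps=config.activity_eps,
                canonicalize=config.canonicalize,
            )
            write_demands_tsv(records[case], out / f"{comp.name}.demands.{case}.tsv")
            outputs[f"{comp.name}.demands.{case}"] = out / f"{comp.name}.demands.{case}.tsv"

        for algo in config.algorithms:
            table = calling.production_scores(
                records["control-sim"], records["disease-sim"], algo, comparison=comp.name
            )
            comp_calls = calling.call_candidates(table, config.percentile)
            calls[algo][comp.name] = comp_calls
            all_scores += [
                {"metabolite_id": c.metabolite_id, "comparison": comp.name,
                 "algorithm": algo, "direction": c.direction, "score": c.score, "rank": c.rank}
                for c in comp_calls
            ]

    pd.DataFrame(all_scores).to_csv(out / "calls.tsv", sep="\t", index=False)
    outputs["calls"] = out / "calls.tsv"

    meta_tables: dict[str, BiomarkerCallTable] = {}
    for algo in config.algorithms:
        meta = calling.meta_analysis(calls[algo], config.min_support, algorithm=algo)
        meta_tables[algo] = meta
        path = out / f"meta.{algo}.tsv"
        meta.counts.to_csv(path, sep="\t")
        outputs[f"meta.{algo}"] = path

    if config.gold_path is not None:
        gold = calling.load_gold_markers(config.gold_path)
        rows = []
        for algo, meta in meta_tables.items():
            rep = calling.evaluate(meta, gold)
            rows.append({"algorithm": algo, "tp": rep.tp, "fp": rep.fp, "fn": rep.fn,
                         "precision": rep.precision, "recall": rep.recall})
            log.info("%s: %s", algo, rep.summary())
        pd.DataFrame(rows).to_csv(out / "evaluation.tsv", sep="\t", index=False)
        outputs["evaluation"] = out / "evaluation.tsv"

    if config.annotations_path is not None:
        annotations = enrichment_mod.load_annotations_tsv(config.annotations_path)
        universe = {m for a in annotations for m in a.members} & {
            t.metabolite_id for t in targets
        }
        for algo, meta in meta_tables.items():
            cand = set(meta.candidates()) & universe
            res = enrichment_mod.enrich(cand, annotations, universe)
            path = out / f"enrichment.{algo}.tsv"
            res.to_csv(path, sep="\t", index=False)
            outputs[f"enrichment.{algo}"] = path

    manifest = {
        "parameters": {
            "model": str(config.model_path),
            "algorithms": list(config.algorithms),
            "percentile": config.percentile,
            "min_support": config.min_support,
            "epsilon": config.epsilon,
            "cap": config.cap,
            "secretion_fraction": config.secretion_fraction,
            "activity_eps": config.activity_eps,
            "canonicalize": config.canonicalize,
            "normalize_weights": config.normalize_weights,
            "n_comparisons": len(config.comparisons),
        },
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
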