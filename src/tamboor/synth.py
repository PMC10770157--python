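"""Synthetic toy models and paired expression profiles with planted regulation.

The generator builds small mass-balanced networks of the kind used to
illustrate the weighted-minimisation idea: a single substrate taken up
through an exchange, one sink metabolite reachable through several parallel
linear paths of configurable lengths, plus optional single-path decoy sinks
that share the substrate. Every internal reaction carries its own gene(s),
so a regulation pattern "planted" on a path shows up as a clean expression
fold change between the control and disease profiles and should be
recovered by the calling pipeline as a directional candidate for the sink.

Baseline expression is log-normal (median 10, σ_log 0.5) — a generic
right-skewed expression-like distribution; the disease profile multiplies
the genes of planted reactions by the planted fold change. No sample-level
noise or probe effects are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gpr import ExpressionProfile
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["ToySpec", "make_toy_model", "make_expression_pair", "planted_truth"]

#: baseline expression distribution: exp(N(log 10, 0.5))
BASELINE_LOG_MEAN = math.log(10.0)
BASELINE_LOG_SIGMA = 0.5


@dataclass(frozen=True)
class ToySpec:
    """Blueprint for one toy network and its paired expression profiles.

    ``planted`` maps a reaction id — or a path prefix such as ``"P2"``,
    which expands to every reaction of that path — to the expression fold
    change its genes get in the disease profile (fold < 1 is
    down-regulation). ``shared_intermediates=True`` makes all paths to the
    sink pass through a common first intermediate.
    """

    path_lengths: tuple[int, ...] = (2, 4)
    n_decoy_sinks: int = 0
    decoy_path_length: int = 2
    genes_per_reaction: int = 1
    gene_pattern: str = "single"  # single | or | and
    shared_intermediates: bool = False
    planted: Mapping[str, float] = field(default_factory=dict)
    uptake_rate: float = 10.0
    seed: int = 0
    baseline_log_mean: float = BASELINE_LOG_MEAN
    baseline_log_sigma: float = BASELINE_LOG_SIGMA

    def __post_init__(self) -> None:
        if not self.path_lengths or any(l < 1 for l in self.path_lengths):
            raise ValueError("path lengths must be >= 1")
        if any(f <= 0 for f in self.planted.values()):
            raise ValueError("planted fold changes must be > 0")
        if self.gene_pattern not in ("single", "or", "and"):
            raise ValueError(f"unknown gene pattern {self.gene_pattern!r}")


def _gpr_for(rid: str, spec: ToySpec) -> tuple[str, list[str]]:
    n = spec.genes_per_reaction if spec.gene_pattern != "single" else 1
    genes = [f"{rid}_g{i + 1}" for i in range(n)]
    joiner = {"single": " ", "or": " or ", "and": " and "}[spec.gene_pattern]
    return joiner.join(genes), genes


def make_toy_model(spec: ToySpec) -> MetabolicModel:
    """Deterministically build the toy network described by ``spec``."""
    mets = [Metabolite("S", "substrate", "c")]
    rxns: list[Reaction] = []
    genes: list[str] = []

    def chain(prefix: str, length: int, source: str, sink_met: str):
        prev = source
        for step in range(1, length + 1):
            rid = f"{prefix}_R{step}"
            product = sink_met if step == length else f"{prefix}_I{step}"
            if product != sink_met:
                mets.append(Metabolite(product, "", "c"))
            gpr, gs = _gpr_for(rid, spec)
            genes.extend(gs)
            rxns.append(
                Reaction(id=rid, stoichiometry={prev: -1.0, product: 1.0}, gpr=gpr)
            )
            prev = product

    source = "S"
    if spec.shared_intermediates:
        mets.append(Metabolite("H", "shared hub", "c"))
        gpr, gs = _gpr_for("HUB_R1", spec)
        genes.extend(gs)
        rxns.append(Reaction(id="HUB_R1", stoichiometry={"S": -1.0, "H": 1.0}, gpr=gpr))
        source = "H"

    mets.append(Metabolite("M", "target", "c"))
    for p, length in enumerate(spec.path_lengths, start=1):
        chain(f"P{p}", length, source, "M")
    for d in range(1, spec.n_decoy_sinks + 1):
        met = f"D{d}"
        mets.append(Metabolite(met, f"decoy {d}", "c"))
        chain(met, spec.decoy_path_length, "S", met)

    rxns.append(Reaction(id="EX_S", stoichiometry={"S": -1.0}, lower_bound=-spec.uptake_rate))
    rxns.append(Reaction(id="EX_M", stoichiometry={"M": -1.0}))
    for d in range(1, spec.n_decoy_sinks + 1):
        rxns.append(Reaction(id=f"EX_D{d}", stoichiometry={f"D{d}": -1.0}))

    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=genes, id=f"toy_seed{spec.seed}")
    model.validate()
    return model


def _fold_for_reaction(rid: str, planted: Mapping[str, float]) -> float:
    for key, fold in planted.items():
        if rid == key or rid.startswith(key + "_"):
            return fold
    return 1.0


def make_expression_pair(
    spec: ToySpec, model: MetabolicModel | None = None
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Seeded (control, disease) profiles; disease applies the planted fold changes."""
    if model is None:
        model = make_toy_model(spec)
    rng = np.random.default_rng(spec.seed)
    ctrl: dict[str, float] = {}
    dis: dict[str, float] = {}
    for r in model.reactions:
        fold = _fold_for_reaction(r.id, spec.planted)
        from .gpr import genes_of

        for g in sorted(genes_of(r.gpr)):
            base = float(rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sigma))
            ctrl[g] = base
            dis[g] = base * fold
    return ExpressionProfile("control", ctrl), ExpressionProfile("disease", dis)


def planted_truth(spec: ToySpec) -> pd.DataFrame:
    """Expected candidate direction per sink metabolite implied by the planted folds.

    A fold < 1 on a path to the sink makes that path expensive in the
    disease simulation; if the disease state is forced onto a longer/
    costlier alternative the sink's production score goes negative
    (decreased in disease), and symmetrically for fold > 1. Decoys are
    unregulated (expected score 0). Only the primary sink is annotated; the
    direction reported here is the planted *regulation* direction of its
    cheapest control path.
    """
    direction = "none"
    folds = {
        f"P{p}": _fold_for_reaction(f"P{p}_R1", spec.planted)
        for p in range(1, len(spec.path_lengths) + 1)
    }
    regulated = {k: f for k, f in folds.items() if f != 1.0}
    if regulated:
        fold = next(iter(regulated.values()))
        direction = "decreased" if fold < 1 else "increased"
    rows = [{"metabolite_id": "M", "direction": direction}]
    rows += [
        {"metabolite_id": f"D{d}", "direction": "none"}
        for d in range(1, spec.n_decoy_sinks + 1)
    ]
    return pd.DataFrame(rows)


def write_fixture(spec: ToySpec, out_dir: str | Path) -> dict[str, Path]:
    """Write model JSON, expression TSV (two single-sample conditions), map and truth."""
    from .model import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = make_toy_model(spec)
    ctrl, dis = make_expression_pair(spec, model)
    paths = {
        "model": out / "model.json",
        "expression": out / "expression.tsv",
        "condition_map": out / "condition_map.tsv",
        "truth": out / "truth.tsv",
    }
    write_model(model, paths["model"])
    df = pd.DataFrame({"gene_id": sorted(ctrl.values)})
    df["control_1"] = [ctrl.values[g] for g in df["gene_id"]]
    df["disease_1"] = [dis.values[g] for g in df["gene_id"]]
    df.to_csv(paths["expression"], sep="\t", index=False)
    paths["condition_map"].write_text("control_1\tcontrol\ndisease_1\tdisease\n")
    planted_truth(spec).to_csv(paths["truth"], sep="\t", index=False)
    return paths
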