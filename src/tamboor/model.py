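"""Metabolic model container, I/O, medium constraints and irreversible conversion.

The in-memory model is a plain stoichiometric container: metabolites,
reactions with flux bounds (μmol/g/min) and GPR strings, and a gene list.
It can be read from SBML (Level 3 + FBC, via cobrapy) or from a simple JSON
dialect that mirrors the container field-for-field, so toy fixtures need no
SBML toolchain.

Exchange reactions are recognised structurally: a reaction touching exactly
one metabolite. Sign convention is the standard one — negative flux is
uptake, positive flux is secretion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "IrreversibleModel",
    "ModelValidationError",
    "ConfigurationError",
    "read_model",
    "write_model",
    "apply_medium",
    "default_medium",
    "load_medium_yaml",
    "make_irreversible",
]

#: default bounds used when a format omits them (de-facto GEM convention)
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ConfigurationError(ValueError):
    """User-supplied configuration is inconsistent with the model."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def reversed_copy(self, new_id: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            lower_bound=max(-self.upper_bound, 0.0),
            upper_bound=-self.lower_bound,
            gpr=self.gpr,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = sorted(_genes_in_gprs(self.reactions))

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        for r in self.reactions:
            if r.is_exchange and metabolite_id in r.stoichiometry:
                return r
        return None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            genes=list(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        met_ids = set(self.metabolite_ids)
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        genes = set(self.genes)
        from .gpr import genes_of  # deferred: gpr imports nothing from here

        for r in self.reactions:
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(missing)}"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            unknown = genes_of(r.gpr) - genes
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses undeclared genes: {sorted(unknown)}"
                )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def resolve_biomass(self) -> str | None:
        """Biomass reaction id: explicit id, else unique case-insensitive name match on 'biomass'."""
        if self.biomass_reaction_id is not None:
            return self.biomass_reaction_id
        hits = [r.id for r in self.reactions if "biomass" in (r.name + " " + r.id).lower()]
        if len(hits) > 1:
            raise ConfigurationError(f"ambiguous biomass reaction: {hits}")
        return hits[0] if hits else None


def _genes_in_gprs(reactions) -> set[str]:
    from .gpr import genes_of

    out: set[str] = set()
    for r in reactions:
        out |= genes_of(r.gpr)
    return out


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------

@dataclass
class MediumSpec:
    """Permitted uptakes (metabolite id → max uptake rate, μmol/g/min) and minimum biomass flux."""

    allowed_uptakes: dict[str, float]
    biomass_min: float = 0.0
    biomass_reaction: str | None = None

    def __post_init__(self) -> None:
        bad = {m: r for m, r in self.allowed_uptakes.items() if r < 0 or not math.isfinite(r)}
        if bad:
            raise ConfigurationError(f"negative/non-finite uptake rates: {bad}")
        if self.biomass_min < 0:
            raise ConfigurationError("biomass_min must be >= 0")


#: oxygen uptake for resting-state brain metabolism, μmol/g/min
OXYGEN_RATE = 1.76
#: default minimum biomass flux keeping macromolecule synthesis active, μmol/g/min
BIOMASS_MIN = 1e-4
#: uptake bound applied to medium components without a stated rate
FREE_RATE = DEFAULT_BOUND


def default_medium(
    glucose_rate: float = 0.32,
    table_path: str | Path | None = None,
    id_map: Mapping[str, str] | None = None,
    biomass_min: float = BIOMASS_MIN,
) -> MediumSpec:
    """Build the brain-simulation medium: Ham's medium plus taurine, ornithine and NH3.

    Glucose is taken up at ``glucose_rate`` (default 0.32 μmol/g/min), oxygen
    at 1.76; the fourteen constrained amino acids, NH3 and the other organic
    carbon sources at 1/10 of the glucose rate; inorganic components are left
    effectively unconstrained. The packaged composition table is an
    approximate transcription of Ham's F-12 (44 metabolites) and can be
    replaced via ``table_path``; ``id_map`` renames metabolite ids into the
    target model's namespace.
    """
    if glucose_rate <= 0:
        raise ConfigurationError("glucose_rate must be > 0")
    if table_path is None:
        table = resources.files("tamboor.data").joinpath("ham_medium.tsv").read_text()
    else:
        table = Path(table_path).read_text()
    rates = {
        "glucose": glucose_rate,
        "oxygen": OXYGEN_RATE,
        "tenth_glucose": glucose_rate / 10.0,
        "free": FREE_RATE,
    }
    uptakes: dict[str, float] = {}
    for line in table.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("metabolite_id\t"):
            continue
        met, _name, rule = line.split("\t")
        if rule not in rates:
            raise ConfigurationError(f"unknown rate rule {rule!r} for {met!r}")
        if id_map:
            met = id_map.get(met, met)
        uptakes[met] = rates[rule]
    return MediumSpec(allowed_uptakes=uptakes, biomass_min=biomass_min)


def load_medium_yaml(path: str | Path) -> MediumSpec:
    """Read a medium spec: ``uptakes: {met_id: rate}``, ``biomass_min``, ``biomass_reaction``."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    return MediumSpec(
        allowed_uptakes={str(k): float(v) for k, v in (doc.get("uptakes") or {}).items()},
        biomass_min=float(doc.get("biomass_min", 0.0)),
        biomass_reaction=doc.get("biomass_reaction"),
    )


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with uptake bounds set from the medium and all other uptakes blocked.

    Exchange lower bounds become −rate for medium metabolites and 0 otherwise;
    the secretion direction (upper bound) of every exchange is left open. The
    biomass lower bound is raised to ``medium.biomass_min``. Idempotent.
    """
    out = model.copy()
    exchange_of: dict[str, Reaction] = {}
    for r in out.reactions:
        if r.is_exchange:
            (met,) = r.stoichiometry
            exchange_of[met] = r
    missing = sorted(set(medium.allowed_uptakes) - set(exchange_of))
    if missing:
        raise ConfigurationError(f"medium metabolites without exchange reactions: {missing}")
    for met, rxn in exchange_of.items():
        rate = medium.allowed_uptakes.get(met, 0.0)
        rxn.lower_bound = -rate
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    if medium.biomass_min > 0:
        biomass = medium.biomass_reaction or out.resolve_biomass()
        if biomass is None:
            raise ConfigurationError("biomass_min > 0 but no biomass reaction identified")
        rxn = out.reaction(biomass)
        rxn.lower_bound = max(rxn.lower_bound, medium.biomass_min)
        out.biomass_reaction_id = biomass
    return out


# ---------------------------------------------------------------------------
# irreversible conversion
# ---------------------------------------------------------------------------

@dataclass
class IrreversibleModel:
    """A model whose every flux is non-negative.

    Reversible reactions are split into a forward copy (original
    stoichiometry) and a ``<id>_rev`` backward copy (negated stoichiometry);
    both halves inherit the GPR. ``split_map`` sends each original reaction
    id to its (forward, backward-or-None) pair; ``internal_mask`` flags
    non-exchange reactions of the split model.
    """

    base: MetabolicModel
    split_map: dict[str, tuple[str, str | None]]
    internal_mask: dict[str, bool]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.base.reactions]

    def net_fluxes(self, fluxes: Mapping[str, float]) -> dict[str, float]:
        """Map a split-model flux vector back to net fluxes of the original reactions."""
        out = {}
        for orig, (fwd, bwd) in self.split_map.items():
            out[orig] = fluxes.get(fwd, 0.0) - (fluxes.get(bwd, 0.0) if bwd else 0.0)
        return out


REV_SUFFIX = "_rev"


def make_irreversible(model: MetabolicModel) -> IrreversibleModel:
    """Split reversible reactions so every bound is ≥ 0, preserving the feasible set.

    A reaction with bounds [−a, b] (a > 0) becomes forward [0, max(b, 0)] and
    backward [max(−b, 0), a]; any feasible net flux v of the original equals
    v_fwd − v_bwd of the split model and vice versa.
    """
    reactions: list[Reaction] = []
    split_map: dict[str, tuple[str, str | None]] = {}
    for r in model.reactions:
        fwd = replace(
            r,
            stoichiometry=dict(r.stoichiometry),
            lower_bound=max(r.lower_bound, 0.0),
            upper_bound=max(r.upper_bound, 0.0),
        )
        if r.lower_bound < 0:
            bwd = r.reversed_copy(r.id + REV_SUFFIX)
            reactions.extend([fwd, bwd])
            split_map[r.id] = (fwd.id, bwd.id)
        else:
            reactions.append(fwd)
            split_map[r.id] = (fwd.id, None)
    base = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=reactions,
        genes=list(model.genes),
        biomass_reaction_id=model.biomass_reaction_id,
        id=model.id,
    )
    internal_mask = {r.id: not r.is_exchange for r in reactions}
    return IrreversibleModel(base=base, split_map=split_map, internal_mask=internal_mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML (L3+FBC, '.xml'/'.sbml') or the JSON dialect ('.json')."""
    path = Path(path)
    if format is None:
        format = {"xml": "sbml", "sbml": "sbml", "json": "json"}.get(
            path.suffix.lstrip(".").lower(), ""
        )
    if format == "json":
        model = _from_json(json.loads(path.read_text()))
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ConfigurationError(f"unknown model format {format!r} for {path}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the JSON dialect (lossless for this container)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
            }
            for r in model.reactions
        ],
        "genes": model.genes,
        "biomass_reaction_id": model.biomass_reaction_id,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _from_json(doc: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={str(k): float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""),
                name=r.get("name", ""),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelValidationError(f"malformed JSON model: {exc!r}") from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=[str(g) for g in doc.get("genes", [])],
        biomass_reaction_id=doc.get("biomass_reaction_id"),
        id=doc.get("id", "model"),
    )


def _read_sbml(path: Path) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("SBML input requires the 'cobra' extra") from exc
    cm = cobra.io.read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.name or "", m.compartment or "") for m in cm.metabolites]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
            name=r.name or "",
        )
        for r in cm.reactions
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cm.genes],
        id=cm.id or path.stem,
    )
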