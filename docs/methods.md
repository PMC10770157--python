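# Methods

## Model and scope

The package operates on stoichiometric metabolic models under the
standard steady-state assumption S·v = 0 with per-reaction flux bounds in
μmol/g/min. Models arrive as SBML L3+FBC (parsed through cobrapy) or as a
JSON dialect mirroring the in-memory container; reactions without
explicit bounds default to [−1000, 1000] if reversible and [0, 1000]
otherwise, the de-facto GEM convention. Exchange reactions are recognised
structurally (exactly one metabolite in the stoichiometry) with negative
flux meaning uptake. All demand computations run on the irreversible
form: each reversible reaction is split into a forward copy and a
`_rev` copy with negated stoichiometry, bounds mapped so the feasible set
is preserved; both halves inherit the GPR and, later, the reaction's
weight.

The biomass reaction is taken from an explicit id when configured,
otherwise by a unique case-insensitive name/id match on "biomass";
ambiguity is an error rather than a guess.

## Medium

The packaged brain-simulation medium emulates Ham's medium plus taurine,
ornithine and NH₃: glucose uptake 0.32 μmol/g/min, oxygen 1.76, the
fourteen constrained amino acids (including taurine and ornithine), NH₃
and all other organic carbon sources at 1/10 of the glucose rate, and
inorganic components effectively unconstrained; biomass production is
held at ≥ 10⁻⁴ μmol/g/min so macromolecule synthesis stays active. The
composition table is an approximate transcription of the Ham's F-12
formulation under generic name ids — authoritative model-specific medium
definitions (and id namespaces) vary, so the table and an id map are both
user-overridable. Applying a medium blocks every uptake not listed,
leaves all secretion directions open, and is idempotent.

## Expression mapping and weights

Per-condition expression is the arithmetic mean of the normalized
sample-level values for that condition (the data are assumed normalized
and gene-level upstream; no normalization is performed here). GPR
evaluation is numeric min/max: AND → min (complexes need every subunit),
OR → max (any isoenzyme suffices); AND binds tighter than OR,
keywords are case-insensitive, `&`/`|` are accepted. Genes present in
the model but absent from the data make an AND undefined, are skipped
inside an OR, and a reaction whose whole rule is undefined is left
unscored.

Weights for the simulated case c are fold changes of reaction scores,

    w_j = (S_ctrl,j + ε) / (S_dis,j + ε)   (disease case; reciprocal for control),

with ε = 10⁻⁸ guarding division by zero and a clip to [1/100, 100]
bounding weights produced by near-zero scores. Unscored reactions and
exchanges get weight 1, so the objective is indifferent to them beyond
their flux itself. Raw fold-change weights are the default; a
`normalize_weights` switch rescales a weight vector to mean 1 for parity
experiments with log-weight implementations of the original algorithm —
the two differ only by a global objective scaling when the clip is
inactive.

## The two-stage LP and the three demands

Stage one maximises each exchange's secretion flux; metabolites whose
maximum exceeds the activity threshold are "secretable" and become
targets. Because the weights never enter this stage (it is bounds-only),
V_max is computed once per model+medium and shared by both conditions.
Stage two sets the target's secretion lower bound to 0.9·V_max (the
fraction is configurable in (0, 1]) and minimises Σ w_j v_j over the
irreversible model with scipy's HiGHS solver (requested feasibility /
optimality tolerances 10⁻⁹).

Weighted LPs can have degenerate optimal faces, which would make the
flux-sum and active-count demands solution- and solver-dependent. After
the weighted solve, the objective is therefore fixed at its optimum
(inequality with a relative slack of 10⁻⁹) and total flux is minimised as
a secondary objective, selecting a reproducible parsimonious vertex; the
canonicalisation can be disabled. All three demands are read from this
single vector:

* weighted demand: Σ w_j v_j over internal (non-exchange) reactions;
* flux-sum demand: Σ v_j over internal reactions;
* active count: internal reactions with v_j > 10⁻⁵.

Exchanges are excluded from all three reported demands: they are plumbing
common to every solution, and the count variant is meant to track the
number of pathway enzymes. Split halves are counted separately, which is
harmless at a canonical optimum (at most one half carries flux).
Transporters between compartments count as internal reactions — the
flux-sum variant's known weakness on compartmentalised models, where
transport fluxes can dominate the sum, is a property of the method, not
filtered away here.

## Calling, meta-analysis, evaluation

Production scores (X_ctrl − X_dis)/(X_ctrl + X_dis) are computed only for
metabolites with optimal status in both conditions; zero demand sums are
dropped (the score is undefined — typically a medium metabolite secreted
straight back out with no internal flux). Percentile calling takes
⌈p·n⌉ metabolites per tail (default p = 0.25), ranking descending for the
increased tail and ascending for the decreased tail with lexicographic
tie-breaks, so calls are fully deterministic; when the two tails would
overlap at very small n, the decreased tail is drawn from metabolites not
already called increased, keeping directions mutually exclusive.

Meta-analysis counts per-direction calls across comparisons and flags a
candidate at ≥ min_support comparisons (default 7, mirroring a
14-comparison design); a metabolite reaching the threshold in both
directions is flagged contradictory and excluded from candidates.
Evaluation against a directional gold list is direction-aware: a
candidate with the wrong direction is a false positive and leaves the
gold entry unmatched. Precision is reported as undefined (not 0) when no
predictions exist. The packaged gold list carries 25 high-confidence
directional marker entries plus 5 well-known disease alterations, with
per-entry flags recording which reference algorithm(s) recovered them; a
packaged count table carries the reference per-algorithm prediction
totals so the published precision/recall arithmetic can be recomputed
without the (non-redistributable) expression datasets. One cell pair of
that reference table is internally inconsistent (a printed total of 273
against tail counts summing to 274, and a recall of 0.484 where the
printed counts imply 0.500); the table preserves the printed values and
the self-consistent cells are the ones asserted in tests.

## Enrichment

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) for k of n candidates falling in a pathway of size K within a
universe of U annotated metabolites, with Benjamini–Hochberg adjustment
across tested pathways and FDR < 0.05 as the default significance cut.
The default universe is the annotated subset of the model's secretable
metabolites, overridable — enrichment services differ mainly in this
background choice, so it is explicit here. Pathway membership is
intersected with the universe before testing.

## Synthetic benchmark

The generator builds unit-stoichiometry networks: one substrate exchange,
a sink metabolite fed by parallel linear paths of configurable lengths,
optional single-path decoy sinks sharing the substrate, one gene per
reaction by default (AND/OR patterns available). Baseline expression is
log-normal (median 10, σ_log = 0.5 — a generic right-skewed
expression-like scale); the disease profile multiplies the genes of
planted reactions by the planted fold change. The default benchmark is a
2-vs-4-reaction path pair with a 4-fold down-regulation of the short path
and three decoys, substrate uptake 10 μmol/g/min.

What this emulates — and does not: regulation appears as exact fold
changes on single-gene reactions with no sample-level noise, no probe
effects, no correlated co-regulation and no compartments. Passing the
planted-recovery benchmark therefore demonstrates the machinery
(scoring → weights → LP → calling) propagates directional signal
correctly; it says nothing about robustness to the noise structure of
real microarray/RNA-seq cohorts or to the degeneracy of genome-scale
networks.

## Problem sizes and numerics

Tests and the acceptance script run on toy networks (≤ 12 reactions, 50
randomized instances for the LP-vs-enumeration check; 20 seeded
replicates of the benchmark), where exhaustive routing enumeration is an
exact independent oracle; these sizes make the whole suite run in
seconds while exercising every code path. Genome-scale runs use the same
code paths through sparse matrices and are bounded by one LP pair per
secretable metabolite per condition. Reported quantities are rounded only
at presentation; comparisons in tests use absolute tolerances of 10⁻⁶
against enumeration (the canonicalisation slack is an order of magnitude
below this at toy scale) and exact equality for integer bookkeeping.

## Known limitations

* Activity is assumed proportional to enzyme transcript level; the
  fold-change weights inherit every caveat of that assumption.
* The flux-sum variant is sensitive to transport-reaction inflation on
  compartmentalised models (see above).
* Alternate optima are resolved by a total-flux tiebreak, which is a
  modelling choice; other canonical solutions (e.g. random vertices of
  the optimal face) would shift count-based demands.
* The secretion fraction (0.9), activity threshold (10⁻⁵), percentile
  (0.25) and support threshold (7/14) are the reference defaults and are
  all exposed; their sensitivity is not characterised here.
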