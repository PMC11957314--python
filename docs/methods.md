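# Methods

This note documents the models, defaults, and design choices behind
myoscreen: what the synthetic generator emulates and deliberately omits,
the exact semantics of each analysis stage, and the numerical conventions
that make runs reproducible to the byte.

## The synthetic screen

The generator produces the inputs a plate-based Cell Painting cytotoxicity
screen would yield after image analysis: a single-cell feature table, plate
metadata, and one luminescence read per well. The default geometry is
30 compounds × 8 concentrations (10 nM to 30 µM, half-log spacing) ×
4 technical-replicate wells × 3 plate replicates, i.e. 96 observations per
compound, plus 35 vehicle wells per plate; 300 features; ~250 cells per
well at baseline. All outputs are pure functions of `(config, seed)`.

### Effect structure

Each compound belongs to one of 5 mechanism groups and carries a maximal
cell-count loss `emax_count` cycled through the ladder
(0, 0.5, 0.65, 0.8, 0.9, 1.0) — one inert compound and a spread of
severities per group. Dose dependence is the Hill curve
`e(c) = emax · c^h / (c^h + EC50^h)` with per-compound EC50 (log-uniform in
30 nM–3 µM) and slope (uniform in 1–2.5). The ATP curve uses the same slope
with an EC50 1–2× higher, reflecting count effects typically preceding ATP
loss.

A cell's feature vector is

    baseline + plate_offset + s · e(c) · d_compound + ε

with shift scale `s = 15` (units of the cell-level feature SD), and
`ε` block-correlated unit-variance noise (blocks of 20 features at ρ = 0.5,
standing in for the strong channel-wise inter-correlation of real
morphology features — the reason a |r| > 0.9 pruning step exists at all).

Effect directions `d` are unit vectors supported on a random "informative"
third of features. Their components are heavy-tailed (Student-t, df = 3),
and each compound's direction mixes a **shared cytotoxicity axis** (weight
0.6) with its mechanism's own direction (weight √(1−0.6²)) plus a small
per-compound jitter (0.15). Both choices mirror what real screens show:
importance of viability models concentrates on a handful of features, and
dying cells share a universal stress signature before mechanism-specific
differences appear. Within-mechanism profile correlation is ≈0.99 versus
≈0.36 between mechanisms, so the within > between invariant holds with a
wide margin.

### Counts, luminescence, decoupling

Per well, a lognormal biological factor (σ = 0.1) scales the expected
count `baseline · (1 − e_count(c))`, realized as a Poisson draw; wells can
reach zero cells at fully lethal doses (they then have no profile row but
still enter count statistics). Luminescence is
`baseline biomass · (1 − e_atp(c))` with 5% multiplicative noise and a
per-plate gain (σ = 0.1) that only vehicle-relative normalization removes.
Luminescence deliberately tracks the ATP curve rather than the realized
segmented count: for the one planted "decoupled" compound
(`emax_count = 0.9`, `emax_atp = 0`) cells fuse or deform out of
segmentability while remaining metabolically alive, so its count collapses
at toxic doses while viability stays at 100% — the colchicine-like regime
the decoupling report is built to detect. Plate offsets on features
(σ = 0.05) make per-plate control normalization load-bearing.

### What the generator does not emulate

No images, no segmentation error, no myotube-specific shape models, no
plate-edge or drift artifacts, no compound-specific feature kinetics beyond
the Hill family. Passing tests therefore demonstrate that the analysis
recovers the structure it assumes, at realistic noise — not that it is
robust to every pathology of real imaging data.

## Profiling

Wells are aggregated by the per-feature median over their cells (cells with
any missing feature are dropped first, with a logged count). Normalization
operates on aggregated well profiles — single-cell normalization is the
other defensible order; this one is recorded in the matrix flags.
Robust MAD normalization includes the 1.4826 consistency constant so a kept
feature has unit robust scale in controls; features whose control MAD (or
SD / range, for the z-score and min-max variants) is zero on any plate are
dropped rather than epsilon-inflated, since an invariant control feature
carries no calibrated deviation scale. Z-score uses ddof = 1.

Feature filtering runs SD-cap first (SD > 2000, a guard against
normalization blow-ups), then greedy correlation pruning in column order:
a feature is dropped iff it correlates beyond 0.9 with an already-kept
feature. Column order makes the rule deterministic and idempotent.

Treatment aggregation takes medians across a condition's wells over all
plates; the treatment-level cell count is the median over the *full* well
layout, so zero-cell wells pull it down even though they contribute no
profile.

## Induction and clustering

Induction is `100 · |{i : |z_i| > 3}| / n_features` with a strict
inequality; the filter keeps profiles with induction strictly above 20%.
Both boundaries are exclusive by design. Clustering uses
`scipy.cluster.hierarchy` on the condensed dissimilarity; Pearson
dissimilarity is `1 − r` (not `1 − |r|`): anti-correlated phenotypes are
maximally distant because the direction of a morphological change is
meaningful. Average linkage is the default; complete linkage is available
by config. A fully aggregated vehicle profile can be exactly constant (its
per-plate control medians are 0 by construction), which is why clustering
always follows induction filtering. Display clipping to ±8 is export-only
and never feeds back into induction or clustering.

## Forest models

All forests are 200 trees, bootstrapped, unlimited depth, `n_jobs=1`,
seeded; the split and forest seeds are derived from one spec seed via
`SeedSequence`. The 80/20 split is uniform over wells (test size is the
ceiling of 0.2·n, minimum 1 — 96 wells give 76/20), not stratified by
concentration. Per-compound models refit the feature filter inside their
own 96-well slice; the global model uses the panel-wide filtered matrix.
Vehicle wells are excluded from both. Reports whose target's SD is below
0.15·|mean| carry a `low_variance` flag: a model on an inert compound is
mostly fitting noise and its R² should not be read as signal. R² on a
zero-variance test target is reported as NaN rather than a number.

The importance matrix ranks features by their median rank of importance
across per-compound models (absent features rank last), keeps the top 30,
and clusters rows and columns with single linkage on Pearson
dissimilarity.

## SMOGN

Implemented from scratch; the documented rules are authoritative rather
than any particular package's behavior. The relevance function is built
from boxplot control points — for rare-low targets, relevance 1 at
`max(Q1 − rel_coef·IQR, min(y))`, 0 at the median and above — joined by a
shape-preserving monotone cubic (PCHIP), clamped to [0, 1], flat outside
the control range. Cases with relevance ≥ `rel_thres` (0.8) are rare;
contiguous runs along the sorted target form bins. Under `balance`, every
bin is resized to the mean original bin size: rare bins grow by synthesis,
normal bins shrink by seeded random removal (disable with
`undersample: false`); `extreme` inverts bin frequencies and rescales to
preserve the total. Synthesis from a seed case uses its k = 5 nearest
rare-bin neighbours (Euclidean, on the filtered normalized features): if
the chosen neighbour is closer than half the median neighbour distance,
SMOTE-style interpolation with the target as the inverse-distance-weighted
mean of the parents; otherwise Gaussian perturbation with per-feature SD
`0.02 · sd(feature)`, target clipped to the observed range. Augmentation
only ever sees training rows; the caller guarantees test isolation and the
model API enforces it by splitting before augmenting.

## Dose response

Viability is `(luminescence / same-plate vehicle median) · 100`, computed
divide-first so the median control well is exactly 100.0. The screen is a
two-sided Welch t-test per condition and endpoint against the vehicle wells
of the plates carrying that condition (Welch because n is small and
variances are unequal by design); no multiple-testing correction by
default, matching common screening practice — Benjamini–Hochberg is
available by config. Identical degenerate samples return p = 1.

Potency is a 4-parameter log-logistic least-squares fit
`f(log c) = floor + (ceiling − floor) / (1 + 10^{slope·(log c − log mid)})`,
initialized at (max, min, geometric-mean dose, 1) with the midpoint bounded
within 100× the tested range; responses spanning < 10 percentage points or
failed fits are reported not-determined, and midpoints outside the tested
range are flagged extrapolated. The decoupling report flags conditions with
`p_count < 0.05`, `p_viability ≥ 0.05`, and a median count drop of ≥ 20%
of the vehicle median.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the default geometry once and
share it; the null-generator calibration uses 5 replicate null screens with
2 features (the Welch screen consumes only counts and luminescence, so
feature count is pure problem-size scaling), giving 2400 null condition
tests; the byte-determinism check runs the full pipeline twice on a reduced
screen (8 compounds, 2 plates, 60 features) whose structure matches the
default. Cell-level features are float32 for memory; profiles and all
statistics are float64. CSVs are read with round-trip float parsing so
write-then-read reproduces values exactly. Every stochastic component takes
a seed derived from one master seed via `SeedSequence`.

## Known limitations

Hill-family effects only; no cross-feature effect heterogeneity within a
compound (one direction per compound scales with dose); the viability model
of the decoupled compound is unpredictable by construction (its morphology
says "toxic", its ATP says "fine" — exactly why such compounds are
interesting); boxplot relevance degenerates on targets whose IQR is 0 and
is rejected rather than patched; and the significance screen's calibration
is demonstrated under the generator's noise model, not under real plate
artifacts such as edge effects or batch drift.
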