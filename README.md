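# myoscreen

Downstream analysis for Cell Painting cytotoxicity screens in muscle cells
(C2C12 myoblasts/myotubes or comparable adherent lines): from single-cell
morphology tables and ATP-luminescence viability reads to normalized
phenotypic profiles, phenotype clustering, random-forest viability
prediction, and dose-response summaries. It is written for screening and
computational-toxicology groups who already have Harmony- or
CellProfiler-style feature exports and want a tested, deterministic
pipeline for everything that happens *after* image analysis.

Because raw imaging data of this kind is rarely shareable, the package
ships a first-class synthetic plate generator that reproduces the
statistical structure such a screen assumes — mechanism-shared dose-dependent
morphology shifts, Hill-curve cell-count decline, plate effects, and
compounds whose cell count collapses while ATP content does not — with full
ground truth, so every stage is testable end to end.

## What it computes

**Profiles.** Single cells are median-aggregated per well, then each plate
is normalized against its own vehicle (DMSO) wells. The default is robust
MAD normalization:

    z = (x − median_ctrl) / (1.4826 · MAD_ctrl)

so that each feature has median 0 and unit robust scale in controls.
Features with SD > 2000 are discarded, then correlated features are pruned
at |r| > 0.9 (earlier column wins).

**Induction.** A treatment profile's induction is the percentage of
features with |z| > 3. Profiles with induction ≤ 20% are set aside before
clustering; the rest are clustered with average linkage on the Pearson
dissimilarity d = 1 − r (complete linkage and Euclidean distance are
available).

**Prediction.** Random-forest regressors (200 trees, bootstrap, unlimited
depth, fixed seed, 80/20 well split) predict per-well viability (% of
vehicle luminescence) and cell count — one model per compound (96 wells
each under the default geometry) plus one global model across the panel.
Importances are mean decrease in impurity.

**SMOGN.** Low-viability profiles are rare in a screen where most doses do
nothing. A from-scratch SMOGN implementation (boxplot relevance function,
rare/normal bins along the sorted target, SMOTE-style interpolation near
neighbours, Gaussian perturbation otherwise, `balance` resampling) grows
the rare bins on the training split only.

**Dose response.** Per-condition Welch t-tests against vehicle controls
(tiers \*, \*\*, \*\*\* at p < 0.05/0.01/0.001), a decoupling report for
conditions where count drops but viability does not, and 4-parameter
log-logistic fits giving IC50 (viability) and LC50 (count).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic screen (30 compounds × 8 concentrations from 10 nM to 30 µM ×
4 wells × 3 plates, seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate_and_profile.py
python analysis/02_normalize_and_filter.py
python analysis/03_induction_and_clustering.py
python analysis/04_viability_models.py
python analysis/05_smogn_augmentation.py
python analysis/06_dose_response.py
```

which prints, among other things:

```
simulated 490068 cells across 2985 wells
induction filter: 108 of 240 profiles above 20% (max 79.6%)
mechanism recovery at k=5: ARI = 1.000
global viability model: test R^2 = 0.892, MSE = 137.1 (train R^2 = 0.985)
per-compound viability R^2 range [-0.304, 0.966]; Spearman vs true effect size = 0.754
unaugmented test R^2 = 0.892; SMOGN-augmented test R^2 = 0.864
top-10 importance Jaccard (augmented vs plain): 0.54
26 of 30 compounds show a significant cell-count decrease at >= 1 dose
```

Reading: clustering the induction-filtered profiles recovers the five
planted mechanism groups exactly (ARI 1.0); morphology predicts held-out
viability well (R² 0.89); models are better on more cytotoxic compounds
(Spearman 0.75 against the true effect sizes), with the inert compounds'
models flagged as noise-dominated; SMOGN barely moves the test R² while
preserving what the model considers important; and the one planted
colchicine-like compound (C021) is flagged at every dose where its count
collapses while viability stays flat.

The same stages are available as a CLI over YAML configs:

```bash
myoscreen all --config configs/small_screen.yaml --seed 42 --outdir out
```

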