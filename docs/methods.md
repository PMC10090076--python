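# Methods

This note describes the model implemented by `drcbridge`, its
assumptions, the parameter defaults and the reasons behind them, what the
synthetic data generator does and does not emulate, the numerical
choices, and the limitations. All quantitative statements here are
computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from external experiments.

## 1. Problem setting

A drug-combination screen measures, for a pair of drugs on a cell line,
a sensitivity score (CSS) and several synergy scores (S, Bliss, HSA,
Loewe, ZIP), alongside the monotherapy dose–response curve of each drug
on that cell line. The supervised task is to predict a chosen score from
features of the pair, and the interesting regime is *cross-study
transfer*: train on one study, predict on another whose experimental
design differs. The central obstacle addressed here is that monotherapy
curves are sampled at study-specific dose counts (2–10) and ranges, so a
naive curve feature encodes the design, which does not transfer.

## 2. Curve encodings

**Baseline encoding (`drc_baseline`).** Raw doses and responses are each
right-padded with the sentinel −1 to length 10 and concatenated (length
20 per curve; 40 per combination). This preserves every measured value
but ties the feature layout to the dose design.

**Imputation encoding (`drc_imputation`).** Each curve is interpolated
onto its own 10-point equally spaced grid in log10-dose, from its
smallest to largest usable dose, by three operators, and the three
10-vectors are concatenated (length 30 per curve):

- *linear*: piecewise-linear in log10-dose (`numpy.interp`); reproduces
  every knot; queries outside the knot range clamp to endpoint values;
- *Lagrange*: the unique degree-(n−1) polynomial through all n knots,
  evaluated by the explicit basis-product formula. High-degree
  polynomials oscillate between knots (Runge phenomenon), so the output
  is clipped to the observed response range extended by 50% of its span
  on each side;
- *anchored LL4*: y = b + (c − b)/(1 + exp(a·(x − log10 d))) with
  a = (y_n − y_1)/(x_n − x_1), b = max response, c = min response,
  d = IC50. The parameters are anchored from curve endpoints and the
  IC50 — not fitted — which is cheap, deterministic, and exact at the
  midpoint: y(log10 d) = (b + c)/2 identically. When no IC50 exists
  (the curve never crosses half its maximum), d falls back to the
  geometric mean of the dose range and is flagged.

Doses themselves are not part of the imputation encoding; that is what
makes it independent of the design. Degenerate curves (fewer than two
usable positive doses) yield a sentinel-filled vector rather than
failing the record.

**Zero doses.** Log-dose space cannot hold a zero (control) dose. The
default policy replaces it with a pseudo-dose of 0.1 × the smallest
positive dose on the curve, keeping the control response on the curve;
a `drop` policy is available. The factor 0.1 places the control one
decade below the measured range — far enough to act as a baseline,
close enough not to distort the grid.

## 3. Monotherapy metrics

- **IC50**: the dose at the first piecewise-linear crossing of half the
  curve's maximal response, found in log10-dose coordinates and
  exponentiated back. Curves that never reach half-max have no IC50;
  downstream features carry an explicit defined/undefined indicator and
  the sentinel −1. An `absolute_midpoint` switch uses 50% inhibition
  instead of half the curve's own maximum.
- **RI (relative inhibition)**: trapezoidal area under the response vs
  log10-dose curve, divided by (log-dose span × 100); a dose-range
  standardized efficacy in [0, 1] for responses in [0, 100].

## 4. Features (registry M1–M20)

Feature specs are named M1–M20 and stored in a packaged YAML registry;
each spec is a set of blocks:

- `drug_categorical`, `cell_line_categorical`: integer codes from a
  vocabulary fitted on training data; unseen test-time categories map to
  a reserved unknown code. Passed to LightGBM as categorical features.
- `chemical_structure`: 166 MACCS + 1024 Morgan (radius 2) + 2048 RDKit
  fingerprint bits per drug (3238 total), computed with RDKit.
- `cancer_gene_expression`: 273 cancer-gene expression values for the
  cell line, quantile-normalized across cell lines (every column is
  mapped onto the mean sorted profile by rank).
- `monotherapy_ic50` (+ defined indicator), `monotherapy_ri`: per drug.
- `drc_baseline`, `drc_imputation`: as in §2, per drug.

Anchored specs include M5 (imputation only), M12 (all monotherapy-curve
blocks), M13 (categoricals only — the reference model), M14 (M13 +
structure + expression), M15 (M14 + efficacy metrics), M16 (M15 + raw
curves) and M20 (M15 + imputed curves). Registry entries whose block
composition is not fully pinned down are flagged `uncertain` in the YAML.

## 5. Training and validation

LightGBM gradient boosting (gbdt, regression objective, 20 leaves, max
depth 8, learning rate 0.05, L1 regularization 2.0, column-wise
histograms, 500 boosting rounds by default with a 1000-round ceiling).
Validation is grouped 5-fold cross-validation where the group is the
(unordered drug pair, cell line) key, so the same biological experiment
can never sit on both sides of a split; the leakage invariant is tested
over 20 seeded runs. Because a combination (A, B) equals (B, A), every
training fold is symmetrized — each row is duplicated with the
drug-A/drug-B column blocks swapped — *after* fold assignment and only
on training rows, so augmentation cannot leak across folds. Transfer to
an unseen study uses the average of the five fold models; 3-vs-1 pooled
training is also provided.

`EXPERIMENT_ROUNDS = 120` is the boosting budget used by the desk-scale
experiment driver: the directional contrast between feature specs is
stable well before 500 rounds, and 120 keeps the multi-spec, multi-seed
experiment a few minutes on one CPU. This is a package-scale choice, not
an empirical claim about any external dataset.

## 6. Evaluation

- **Pearson r** in the covariance/product-of-sums form, undefined
  (returns `None`) for constant vectors or fewer than 3 pairs; NaN pairs
  are dropped pairwise.
- **Bootstrap CI**: 100 subsamples of 80% drawn without replacement,
  percentile 2.5/97.5 interval; deterministic given a seed.
- **Paired t-test**: t = Σd / √((nΣd² − (Σd)²)/(n − 1)) with n−1 degrees
  of freedom; a zero-variance difference vector is flagged rather than
  divided by zero. Cross-checked against `scipy.stats.ttest_rel`.
- **Performance ratio (PR)**: ratio of two models' mean correlations;
  satisfies PR(a,b)·PR(b,a) = 1.
- **Replicate replicability**: Pearson r over all ordered pairs of
  replicate measurements sharing a (drug pair, cell line) key — the
  empirical ceiling for model performance on that label.
- **Grouped importance**: per-feature mean |TreeSHAP| contributions from
  LightGBM's native `pred_contrib`, summed within feature blocks
  (falls back to gain-based importance if contributions are
  unavailable). Block scores partition the total attribution.

## 7. Synthetic data generator

The generator exists so that every pipeline claim can be verified
against a known ground truth. Per (drug, cell line) it draws one Hill
curve — Emax ~ U(30, 100)% inhibition, log10 EC50 ~ U(−2, 1), slope
~ U(0.5, 3) — shared by *all* studies; studies differ only in how they
measure it. Defaults (these ARE the study conditions for experiments and
acceptance):

| parameter | default | rationale |
|---|---|---|
| study designs | STUDY_A: 5 doses, 0.01–10 µM; STUDY_B: 3 doses, 0.03–3 µM | the two axes of real design heterogeneity: dose count and dose range |
| combinations per study | 1500 | large enough for stable correlations, minutes-scale training |
| drugs / cell lines per study | 30 / 15 | desk-scale panel |
| drug / cell-line overlap | 0.2 / 0.5 | partial overlap, as across real screens |
| response noise sd | 5 (% inhibition) | typical replicate scatter scale |
| assay calibration | gain ~ N(1, 0.1), offset ~ N(0, 3) per study | labs never read out % inhibition on the same scale |
| latent synergy sd | 10 | synergy is a minority component of CSS |
| label batch effects | CSS sd 2, synergy sd 5 per (key, study) | inter-study replicability below intra-study |
| label replicate noise | CSS sd 3, synergy sd 8 | synergy labels are noisier than sensitivity, so synergy is less replicable |
| expression | 273 genes from 3 latent cell factors, noise sd 1 | low-rank cell-line structure |

Labels: CSS = 50·(RI_a + RI_b) + 0.5·synergy (+ batch effect + noise);
each synergy score = latent synergy (+ batch effect + noise). True RI is
computed by integrating the noiseless Hill curve over a fixed reference
dose range (0.01–10 µM, 201 points), independent of any study's design.

A closed-form **attenuation oracle** gives the expected replicate
correlation var(signal)/(var(signal) + noise²) per score, which the
Monte-Carlo replicability estimate must match within 3 standard errors
(tested at 10,000 ordered pairs).

**What the generator emulates:** shared pharmacology measured under
heterogeneous dose designs; assay calibration differences; per-study
batch effects on labels; replicate noise with synergy noisier than
sensitivity; partially overlapping drug and cell panels; low-rank
expression structure. **What it does not emulate:** real chemistry
(SMILES are a fixed panel of valid drug-like molecules assigned
arbitrarily, so structure features carry identity information only, not
mechanism); dose–dose interaction surfaces (synergy is a latent scalar,
not derived from a combination response matrix); plate/position
artifacts; tissue-specific biology linking expression to drug response;
missing-data patterns of real repositories.

## 8. Numerical choices

- All interpolation happens in log10-dose coordinates; the LL4 logistic
  is evaluated via `scipy.special.expit`, which saturates to the
  asymptotes instead of overflowing for large |a·Δ|.
- The LL4 slope anchor and exponent share the log10 coordinate system so
  the midpoint identity holds exactly; a switch converts to natural-log
  slope conventions.
- Lagrange evaluation uses the explicit basis-product form (numerically
  adequate for ≤ 10 knots) with range clipping as the Runge guard.
- RI uses the composite trapezoid rule; IC50 uses exact linear inversion
  on the first crossing segment.
- Quantile normalization averages ranks against the mean sorted
  reference profile with linear interpolation for ties/length.
- Fold assignment sorts group keys, permutes them with a seeded
  generator, and splits into 5 near-equal parts — deterministic given a
  seed and independent of input row order.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are kept below 2³¹.

## 9. Limitations

- LL4 parameters are anchored, not least-squares fitted; on noisy or
  non-sigmoidal curves the anchored curve can sit far from the data
  between its anchor points.
- The IC50 is the *first* half-max crossing; non-monotone curves with
  multiple crossings are summarized by the earliest one.
- Synthetic transfer results validate the pipeline's directional
  behavior (harmonized features transfer better than raw or categorical
  features under design heterogeneity); they are not estimates of
  performance on any real screening repository.
- The feature registry pins the anchored specs; entries flagged
  `uncertain` are best-effort reconstructions of intermediate specs.
- Bootstrap intervals use subsampling without replacement at a fixed
  80% rate; they are percentile intervals, not studentized.
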