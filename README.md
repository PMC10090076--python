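# drcbridge

Cross-study transferable prediction of drug-combination response via
dose–response curve harmonization.

## The problem

High-throughput screens measure how pairs of drugs inhibit cancer cell
lines, summarized as a sensitivity score (CSS) and several synergy scores
(S, Bliss, HSA, Loewe, ZIP). Models trained on one screen often collapse
when applied to another, and a major, fixable reason is that each study
measures its monotherapy dose–response curves under a different design:
different numbers of doses (2–10) and different concentration ranges. A
feature built by concatenating raw doses and responses therefore encodes
the *study design* as much as the *pharmacology*, and a gradient-boosting
model happily learns the design.

`drcbridge` implements the harmonization remedy: interpolate every
monotherapy curve onto a common 10-point log10-dose grid using three
operators — piecewise linear, Lagrange polynomial, and an anchored
four-parameter log-logistic (LL4) curve — and feed the concatenated
interpolated responses to the model instead of (or alongside) the raw
values. The package contains the full pipeline:

- **data model** — typed dose–response curves, combination records,
  study datasets, gene-expression tables, robust text I/O;
- **curve harmonization** — baseline (pad-to-ten) and imputation
  (interpolate-to-ten) encodings;
- **monotherapy metrics** — IC50 (first half-maximal crossing in
  log-dose space) and RI (normalized area under the log10-dose curve);
- **feature assembly** — a registry of feature specifications M1–M20
  combining categorical drug/cell encodings, MACCS + Morgan + RDKit
  fingerprints (3238 bits per drug), quantile-normalized expression of
  273 cancer genes, monotherapy efficacy metrics, and the two curve
  encodings;
- **model training** — LightGBM with grouped 5-fold cross-validation by
  (unordered drug pair, cell line), drug-order symmetrization of training
  rows, and 5-model averaged ensembles for cross-study transfer;
- **evaluation** — Pearson r with subsample bootstrap CIs, paired
  t-tests, performance ratios, replicate replicability, and grouped
  TreeSHAP feature-block importance;
- **synthetic data** — a generator of multi-study screens with shared
  ground-truth pharmacology, heterogeneous dose designs, assay
  calibration differences, batch effects and replicate noise, so every
  claim in the test suite is checked against a known truth.

## Worked example

The reference five-dose example curve (drug MK-5108 on the ES2 cell
line), harmonized (`examples/01_harmonize_a_curve.py`):

```python
from drcbridge import (DoseResponseCurve, encode_drc_baseline,
                       encode_drc_imputation, estimate_ic50, compute_ri)

curve = DoseResponseCurve(
    drug_id="MK-5108", cell_line_id="ES2", study_id="DEMO",
    doses=(0.0, 0.075, 0.225, 0.675, 2.0),
    responses=(0.0, -0.48, -0.47, 4.32, 20.72),
)
print(encode_drc_baseline(curve))
print(estimate_ic50(curve), compute_ri(curve))
```

Actual output:

```
baseline encoding (doses + responses, right-padded with -1):
[ 0.     0.075  0.225  0.675  2.    -1.    -1.    -1.    -1.    -1.
  0.    -0.48  -0.47   4.32  20.72  -1.    -1.    -1.    -1.    -1.   ]

common log10-dose grid (zero dose -> pseudo-dose):
[-2.125 -1.855 -1.586 -1.316 -1.047 -0.777 -0.508 -0.238  0.031  0.301]

imputation encoding (linear | lagrange | ll4, 10 points each):
  linear   [ 0.    -0.129 -0.259 -0.388 -0.478 -0.473  0.937  3.644 11.349 20.72 ]
  lagrange [ 0.     0.097  0.092 -0.182 -0.594 -0.717  0.179  3.118  9.424 20.72 ]
  ll4      [-0.48  -0.48  -0.48  -0.48  -0.477 -0.453 -0.213  1.918 11.401 19.178]

IC50 = 1.007 uM (first crossing of half the maximal response)
RI   = 0.0262 (normalized area under the log10-dose curve)
```

And the headline experiment at a reduced size
(`examples/03_train_and_transfer.py`): train on a 5-dose study, transfer
to an unseen 3-dose study, for the categorical baseline (M13), the
raw-curve model (M16) and the interpolation model (M20). Actual output:

```
M13: intra r = 0.906   inter r = 0.506 [0.469, 0.540]
M16: intra r = 0.905   inter r = 0.922 [0.914, 0.928]
M20: intra r = 0.909   inter r = 0.938 [0.932, 0.942]
```

Within the training study all three models look similar; on the unseen
study the categorical baseline collapses and the harmonized-curve model
transfers best.

## Command line

A thin CLI wraps the same pipeline for file-based use:

```bash
drcbridge simulate --seed 0 --out data/
drcbridge featurize --dataset data/STUDY_A.csv --spec M20 --out features.csv
drcbridge train --dataset data/STUDY_A.csv --spec M13 --score CSS --out model/
drcbridge evaluate --train-dataset data/STUDY_A.csv \
    --test-dataset data/STUDY_B.csv --spec M13 --out eval.json
```

## Reproduction

`scripts/acceptance.py` re-runs the package's main computations end to
end — the two-study transfer experiment over five derived seeds, the
M20-vs-M13 performance ratio and paired t-test, the replicate
replicability of sensitivity and synergy labels against the closed-form
attenuation, and the worked-example quantities — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry is `{"name": {"value": ..., "n": ...}}` where `n` is the
sample size behind the value (seeds, curve points, or replicate pairs).
The run takes a few minutes on one CPU and is fully deterministic given
`--seed`.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and the design of the synthetic generator.
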