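"""Evaluation statistics for cross-study prediction experiments.

Pearson's r is the headline metric (the score distributions differ too
much across studies for RMSE to rank models meaningfully; RMSE is kept
as a secondary diagnostic). Model pairs are compared with two-sided
paired t-tests across evaluation scenarios and with the performance
ratio PR = x̄₁/x̄₂ of their mean correlations. Replicate measurements
sharing a treatment–cell-line key provide the empirical ceiling for
model performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import StudyDataset

logger = logging.getLogger(__name__)


@dataclass
class EvalPair:
    """Aligned gold-standard / prediction vectors, pairwise-complete."""

    gold: np.ndarray
    pred: np.ndarray

    def __init__(self, gold, pred):
        gold = np.asarray(gold, dtype=float)
        pred = np.asarray(pred, dtype=float)
        if gold.shape != pred.shape:
            raise ValueError("gold and prediction vectors differ in length")
        mask = ~(np.isnan(gold) | np.isnan(pred))
        self.gold = gold[mask]
        self.pred = pred[mask]

    def __len__(self) -> int:
        return len(self.gold)


def pearson_r(pair: EvalPair) -> float | None:
    """Pearson correlation Σ(x−x̄)(y−ȳ) / √(Σ(x−x̄)² Σ(y−ȳ)²).

    Returns None (undefined) when either vector is constant or fewer than
    3 complete pairs remain.
    """
    x, y = pair.gold, pair.pred
    if len(x) < 3:
        return None
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        return None
    return float((dx * dy).sum() / denom)


def rmse(pair: EvalPair) -> float:
    """Root-mean-square error, emitted as a secondary diagnostic only."""
    return float(np.sqrt(np.mean((pair.gold - pair.pred) ** 2)))


def bootstrap_ci(
    pair: EvalPair,
    resamples: int = 100,
    level: float = 0.95,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Percentile confidence interval for Pearson's r from repeated
    without-replacement subsampling (default 100 draws of 80% of the
    pairs).

    Degenerate draws (constant subsample) are discarded; if more than
    half are degenerate the interval is undefined (None).
    """
    n = len(pair)
    size = max(3, int(round(subsample_fraction * n)))
    if size > n:
        raise ValueError("subsample larger than the pair set")
    rng = np.random.default_rng(seed)
    draws = []
    n_degenerate = 0
    for _ in range(resamples):
        idx = rng.choice(n, size=size, replace=False)
        r = pearson_r(EvalPair(pair.gold[idx], pair.pred[idx]))
        if r is None:
            n_degenerate += 1
        else:
            draws.append(r)
    if n_degenerate > resamples / 2:
        logger.warning("bootstrap CI undefined: %d/%d degenerate draws",
                       n_degenerate, resamples)
        return None
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class PairedComparison:
    """Aligned per-scenario performances of two models."""

    perf_model1: np.ndarray
    perf_model2: np.ndarray

    def __init__(self, perf_model1, perf_model2):
        a = np.asarray(perf_model1, dtype=float)
        b = np.asarray(perf_model2, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("performance lists must be 1-D and aligned")
        mask = ~(np.isnan(a) | np.isnan(b))
        if mask.sum() < len(a):
            logger.info("excluded %d scenarios with undefined performance",
                        len(a) - int(mask.sum()))
        self.perf_model1 = a[mask]
        self.perf_model2 = b[mask]
        if len(self.perf_model1) < 2:
            raise ValueError("need at least 2 scenarios for a paired comparison")

    @property
    def d(self) -> np.ndarray:
        return self.perf_model1 - self.perf_model2

    @property
    def n(self) -> int:
        return len(self.perf_model1)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    zero_variance: bool = False


def paired_t(cmp: PairedComparison) -> TTestResult:
    """Two-sided paired t-test, t = Σd / √((nΣd² − (Σd)²)/(n − 1)).

    All-identical differences give zero within-pair variance: the result
    carries ``zero_variance=True`` with p reported as 0 (or t = 0, p = 1
    when every difference is exactly zero).
    """
    d = cmp.d
    n = cmp.n
    sum_d = d.sum()
    denom_sq = (n * (d ** 2).sum() - sum_d ** 2) / (n - 1)
    if denom_sq <= 0:
        if np.allclose(d, 0):
            return TTestResult(t=0.0, p=1.0, zero_variance=True)
        return TTestResult(t=float(np.inf) * np.sign(sum_d), p=0.0,
                           zero_variance=True)
    t = float(sum_d / np.sqrt(denom_sq))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p=p)


def performance_ratio(cmp: PairedComparison) -> float | None:
    """PR = mean(model-1 performances) / mean(model-2 performances).

    Reported as a plain ratio (multiply by 100 for the percentage form).
    Undefined (None) when the denominator mean is zero.
    """
    mean2 = cmp.perf_model2.mean()
    if mean2 == 0:
        return None
    return float(cmp.perf_model1.mean() / mean2)


@dataclass(frozen=True)
class ReplicabilityResult:
    r: float | None
    n_pairs: int
    n_keys: int


def replicate_replicability(
    datasets: StudyDataset | tuple[StudyDataset, StudyDataset],
    score: str,
) -> ReplicabilityResult:
    """Pearson's r over all ordered pairs of replicate labels sharing a
    treatment–cell-line key.

    One dataset: intra-study replicability over keys with ≥ 2 replicates
    (a key with k replicates contributes k·(k−1) ordered pairs). A pair
    of datasets: inter-study replicability over shared keys, pairing each
    replicate of one study with each of the other in both orders.
    """
    if isinstance(datasets, StudyDataset):
        by_key: dict = {}
        for rec in datasets.combinations:
            by_key.setdefault(rec.group_key, []).append(rec.labels[score])
        xs, ys = [], []
        n_keys = 0
        for values in by_key.values():
            values = [v for v in values if not np.isnan(v)]
            if len(values) < 2:
                continue
            n_keys += 1
            for i, vi in enumerate(values):
                for j, vj in enumerate(values):
                    if i != j:
                        xs.append(vi)
                        ys.append(vj)
    else:
        ds1, ds2 = datasets
        keys1: dict = {}
        keys2: dict = {}
        for rec in ds1.combinations:
            keys1.setdefault(rec.group_key, []).append(rec.labels[score])
        for rec in ds2.combinations:
            keys2.setdefault(rec.group_key, []).append(rec.labels[score])
        xs, ys = [], []
        n_keys = 0
        for key in keys1.keys() & keys2.keys():
            v1 = [v for v in keys1[key] if not np.isnan(v)]
            v2 = [v for v in keys2[key] if not np.isnan(v)]
            if not v1 or not v2:
                continue
            n_keys += 1
            for a in v1:
                for b in v2:
                    xs.extend([a, b])
                    ys.extend([b, a])
    if n_keys < 3:
        logger.warning("replicability undefined: only %d usable keys", n_keys)
        return ReplicabilityResult(r=None, n_pairs=len(xs), n_keys=n_keys)
    r = pearson_r(EvalPair(xs, ys))
    return ReplicabilityResult(r=r, n_pairs=len(xs), n_keys=n_keys)


@dataclass
class GroupedImportance:
    """Per-block feature attributions from an averaged fold ensemble.

    ``backend`` is "treeshap" for exact additive Shapley attributions from
    the tree models, or "gain" when the attribution backend is
    unavailable and split-gain importances are used instead.
    """

    block_scores: pd.Series  # mean |attribution| summed within block, ranked
    per_feature: pd.Series  # full per-feature detail
    backend: str

    def top_block(self) -> str:
        return str(self.block_scores.index[0])


def grouped_importance(bundle, matrix, n_sample: int = 200,
                       seed: int = 0) -> GroupedImportance:
    """Additive feature attributions summed within feature blocks.

    Attributions are computed on a row sample with the tree models' exact
    TreeSHAP path (additive Shapley values), averaged over the five fold
    models; the per-feature mean |attribution| is summed within each
    block. Per-feature detail is retained so the imputation block can be
    inspected position-by-position along the curve.
    """
    rng = np.random.default_rng(seed)
    n = matrix.values.shape[0]
    idx = rng.choice(n, size=min(n_sample, n), replace=False)
    X = matrix.values[idx]
    try:
        contribs = np.mean(
            [m.predict(X, pred_contrib=True) for m in bundle.fold_models], axis=0
        )
        per_feature_vals = np.abs(contribs[:, :-1]).mean(axis=0)  # drop bias column
        backend = "treeshap"
    except Exception as exc:  # pragma: no cover - backend fallback
        logger.warning("TreeSHAP attribution failed (%s); using gain", exc)
        per_feature_vals = np.mean(
            [m.feature_importance(importance_type="gain")
             for m in bundle.fold_models], axis=0)
        backend = "gain"
    per_feature = pd.Series(per_feature_vals, index=matrix.column_names)
    blocks = pd.Series(matrix.column_blocks, index=matrix.column_names)
    block_scores = per_feature.groupby(blocks).sum().sort_values(ascending=False)
    return GroupedImportance(block_scores=block_scores, per_feature=per_feature,
                             backend=backend)
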