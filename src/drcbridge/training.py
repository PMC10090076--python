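"""Gradient-boosted tree training with grouped cross-validation.

The unit of splitting is the unordered (drug pair, cell line) group, so a
held-out fold never contains a combination whose pair — in either drug
order — was seen in training. Drug-order symmetrization (the swapped-twin
augmentation) is applied to training rows only, after fold assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd

from .data_model import CombinationRecord, ExpressionTable, StudyDataset
from .features import (
    FeatureSpec,
    VocabularySet,
    assemble,
    label_vector,
)
from .harmonize import HarmonizationConfig

logger = logging.getLogger(__name__)

N_FOLDS = 5


@dataclass(frozen=True)
class GBMConfig:
    """LightGBM regressor settings.

    Defaults follow the fixed hyperparameter block used throughout:
    gbdt boosting, regression objective, 20 leaves, depth 8, learning
    rate 0.05, L1 regularization 2.0, column-wise histogram construction.
    ``boosting_rounds`` (500) governs the trees actually built;
    ``n_estimators`` (1000) is retained as a ceiling.
    """

    objective: str = "regression"
    num_leaves: int = 20
    max_depth: int = 8
    learning_rate: float = 0.05
    n_estimators: int = 1000
    boosting_rounds: int = 500
    l1_regularization: float = 2.0
    column_wise_forced: bool = True
    seed: int = 0

    def lgb_params(self, seed: int | None = None) -> dict:
        return {
            "boosting_type": "gbdt",
            "objective": self.objective,
            "num_leaves": self.num_leaves,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "force_col_wise": self.column_wise_forced,
            "reg_alpha": self.l1_regularization,
            "seed": self.seed if seed is None else seed,
            "verbose": -1,
        }

    @property
    def rounds(self) -> int:
        return min(self.boosting_rounds, self.n_estimators)


@dataclass
class ModelBundle:
    """Five fold-models from one grouped-CV training run.

    Used directly for intra-study out-of-fold evaluation and, averaged,
    as the transfer ensemble for predicting other studies.
    """

    score_name: str
    spec: FeatureSpec
    fold_models: list
    fold_assignments: dict  # group_key -> fold index
    training_study_ids: tuple[str, ...]
    vocab: VocabularySet
    harmonization: HarmonizationConfig
    gbm: GBMConfig
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fold_models) != N_FOLDS:
            raise ValueError(f"expected {N_FOLDS} fold models")


def assign_folds(records: list[CombinationRecord], seed: int,
                 n_folds: int = N_FOLDS) -> dict:
    """Partition unordered (drug pair, cell line) groups into folds.

    Deterministic given the seed; every group lands in exactly one fold.
    """
    groups = sorted({r.group_key for r in records},
                    key=lambda g: (tuple(sorted(g[0])), g[1]))
    if len(groups) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct treatment-cell-line groups, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        for gi in chunk:
            assignment[groups[gi]] = fold
    return assignment


def _drop_missing(records: list[CombinationRecord], score: str):
    kept = [r for r in records if not np.isnan(r.labels[score])]
    n_missing = len(records) - len(kept)
    if n_missing:
        logger.info("excluded %d records with missing %s label", n_missing, score)
    return kept


def _fit_fold(X_train, y_train, swap_order, categorical_idx, params, rounds):
    X_aug = np.vstack([X_train, X_train[:, swap_order]])
    y_aug = np.concatenate([y_train, y_train])
    dataset = lgb.Dataset(
        X_aug, label=y_aug,
        categorical_feature=categorical_idx or "auto",
        free_raw_data=True,
        params={"verbose": -1},
    )
    return lgb.train(params, dataset, num_boost_round=rounds)


def _train_grouped(records, spec, score, gbm, seed, expression, harmonization,
                   study_ids):
    records = _drop_missing(records, score)
    assignment = assign_folds(records, seed)
    vocab = VocabularySet.fit(records)
    matrix = assemble(records, spec, expression, harmonization, vocab)
    kept_records = [records[i] for i in matrix.kept_indices]
    y = label_vector(kept_records, score)
    folds = np.array([assignment[r.group_key] for r in kept_records])
    swap_order = matrix.swap_column_order()
    categorical_idx = matrix.categorical_indices
    params = gbm.lgb_params(seed=seed)

    models = []
    oof_pred = np.full(len(kept_records), np.nan)
    for fold in range(N_FOLDS):
        train_mask = folds != fold
        model = _fit_fold(matrix.values[train_mask], y[train_mask], swap_order,
                          categorical_idx, params, gbm.rounds)
        models.append(model)
        test_mask = ~train_mask
        if test_mask.any():
            oof_pred[test_mask] = model.predict(matrix.values[test_mask])

    bundle = ModelBundle(
        score_name=score,
        spec=spec,
        fold_models=models,
        fold_assignments=assignment,
        training_study_ids=tuple(study_ids),
        vocab=vocab,
        harmonization=spec.harmonization(harmonization),
        gbm=gbm,
        seed=seed,
        feature_names=matrix.column_names,
    )
    oof = pd.DataFrame({
        "drug_a_id": [r.drug_a_id for r in kept_records],
        "drug_b_id": [r.drug_b_id for r in kept_records],
        "cell_line_id": [r.cell_line_id for r in kept_records],
        "fold": folds,
        "y_true": y,
        "y_pred": oof_pred,
    })
    return bundle, oof


def train_intra(
    dataset: StudyDataset,
    spec: FeatureSpec,
    score: str,
    gbm: GBMConfig | None = None,
    seed: int = 0,
    expression: ExpressionTable | None = None,
    harmonization: HarmonizationConfig | None = None,
):
    """Intra-study grouped 5-fold training.

    Returns (ModelBundle, out-of-fold prediction table). Records missing
    the target score are excluded; each remaining group is held out in
    exactly one fold, and that fold's model never saw the group in either
    drug order.
    """
    gbm = gbm or GBMConfig()
    return _train_grouped(dataset.combinations, spec, score, gbm, seed,
                          expression, harmonization, (dataset.study_id,))


def train_3v1(
    datasets: list[StudyDataset],
    spec: FeatureSpec,
    score: str,
    gbm: GBMConfig | None = None,
    seed: int = 0,
    expression: ExpressionTable | None = None,
    harmonization: HarmonizationConfig | None = None,
):
    """Pool several studies into one training set (the 3-vs-1 protocol).

    The pooled records go through the same grouped 5-fold procedure as
    intra-study training; the bundle records the contributing study ids.
    """
    if len(datasets) < 2:
        raise ValueError("pooled training expects at least 2 studies")
    gbm = gbm or GBMConfig()
    pooled = [r for ds in datasets for r in ds.combinations]
    ids = tuple(ds.study_id for ds in datasets)
    return _train_grouped(pooled, spec, score, gbm, seed, expression,
                          harmonization, ids)


def predict_ensemble(
    bundle: ModelBundle,
    records: list[CombinationRecord],
    expression: ExpressionTable | None = None,
) -> np.ndarray:
    """Averaged prediction of the five fold models, aligned to ``records``.

    Records that cannot be featurized under the bundle's spec yield NaN.
    Drug and cell-line identifiers unseen at training time are encoded
    with the reserved unknown code, mirroring true cross-study transfer.
    """
    matrix = assemble(records, bundle.spec, expression, bundle.harmonization,
                      bundle.vocab)
    if matrix.column_names != bundle.feature_names:
        missing = set(bundle.feature_names) - set(matrix.column_names)
        raise ValueError(
            f"feature schema mismatch; missing columns: {sorted(missing)[:5]}"
        )
    preds = np.mean([m.predict(matrix.values) for m in bundle.fold_models], axis=0)
    out = np.full(len(records), np.nan)
    out[matrix.kept_indices] = preds
    return out


def save_bundle(bundle: ModelBundle, directory) -> None:
    """Serialize a bundle (five model files + a JSON manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, model in enumerate(bundle.fold_models):
        model.save_model(str(directory / f"fold_{i}.txt"))
    manifest = {
        "score_name": bundle.score_name,
        "spec": bundle.spec.name,
        "training_study_ids": list(bundle.training_study_ids),
        "seed": bundle.seed,
        "boosting_rounds": bundle.gbm.rounds,
        "feature_names": bundle.feature_names,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
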