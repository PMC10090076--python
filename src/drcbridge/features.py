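"""Feature-block assembly for combination records.

A feature spec names an ordered set of blocks; `assemble` realizes them
into one numeric matrix per record list. Per-drug blocks (fingerprints,
efficacy summaries, curve encodings) appear twice — a drug-A copy and a
drug-B copy — which `symmetrize` exploits to augment training sets with
order-swapped twins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .data_model import CombinationRecord, ExpressionTable, normalize_cell_line
from .harmonize import (
    HarmonizationConfig,
    encode_drc_baseline,
    encode_drc_imputation,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

BLOCK_NAMES = (
    "drug_categorical",
    "cell_line_categorical",
    "chemical_structure",
    "cancer_gene_expression",
    "monotherapy_ic50",
    "monotherapy_ri",
    "drc_baseline",
    "drc_imputation",
)

#: Blocks computed once per drug and emitted twice (drug A copy, drug B copy).
PER_DRUG_BLOCKS = (
    "chemical_structure",
    "monotherapy_ic50",
    "monotherapy_ri",
    "drc_baseline",
    "drc_imputation",
)

#: Sentinel for an undefined IC50 (curve never reached half-maximal response).
IC50_SENTINEL = -1.0

MACCS_BITS = 166
MORGAN_BITS = 1024
RDKIT_BITS = 2048
FINGERPRINT_BITS = MACCS_BITS + MORGAN_BITS + RDKIT_BITS


class UnparseableSmilesError(ValueError):
    """SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class FeatureSpec:
    """Named composition of feature blocks (one row of the M registry)."""

    name: str
    blocks: tuple[str, ...]
    imputation_methods: tuple[str, ...] | None = None
    uncertain: bool = False

    def __post_init__(self) -> None:
        if len(set(self.blocks)) != len(self.blocks):
            raise ValueError("duplicate block names in spec")
        unknown = set(self.blocks) - set(BLOCK_NAMES)
        if unknown:
            raise ValueError(f"unknown block(s): {sorted(unknown)}")

    def harmonization(self, base: HarmonizationConfig | None = None) -> HarmonizationConfig:
        base = base or HarmonizationConfig()
        if self.imputation_methods:
            return HarmonizationConfig(
                target_length=base.target_length,
                pad_value=base.pad_value,
                pad_cap=base.pad_cap,
                methods=tuple(self.imputation_methods),
                zero_dose_policy=base.zero_dose_policy,
                pseudo_dose_factor=base.pseudo_dose_factor,
                ll4_natural_log=base.ll4_natural_log,
            )
        return base


@lru_cache(maxsize=1)
def load_registry() -> dict[str, FeatureSpec]:
    """Load the packaged M1-M20 feature-spec registry."""
    text = resources.files("drcbridge.data").joinpath("feature_specs.yaml").read_text()
    raw = yaml.safe_load(text)
    registry = {}
    for name, entry in raw.items():
        registry[name] = FeatureSpec(
            name=name,
            blocks=tuple(entry["blocks"]),
            imputation_methods=tuple(entry["imputation_methods"])
            if "imputation_methods" in entry
            else None,
            uncertain=bool(entry.get("uncertain", False)),
        )
    return registry


def get_spec(name: str) -> FeatureSpec:
    registry = load_registry()
    if name not in registry:
        raise KeyError(f"unknown feature spec {name!r}; known: {sorted(registry)}")
    return registry[name]


class Vocabulary:
    """String → integer-code map for categorical tree features.

    Codes are assigned in sorted order at fit time; values unseen at fit
    time map to a reserved code (``len(known)``), so a model trained on one
    study sees every drug/cell line of another study as "unknown".
    """

    def __init__(self, values=()):
        self._codes = {v: i for i, v in enumerate(sorted(set(values)))}

    @property
    def unknown_code(self) -> int:
        return len(self._codes)

    def encode(self, value: str) -> int:
        return self._codes.get(value, self.unknown_code)

    def __len__(self) -> int:
        return len(self._codes)


@dataclass
class VocabularySet:
    drugs: Vocabulary
    cell_lines: Vocabulary

    @classmethod
    def fit(cls, records: list[CombinationRecord]) -> "VocabularySet":
        drugs = [r.drug_a_id for r in records] + [r.drug_b_id for r in records]
        cells = [r.cell_line_id for r in records]
        return cls(drugs=Vocabulary(drugs), cell_lines=Vocabulary(cells))


@dataclass
class FeatureMatrix:
    """Realized numeric matrix with per-column provenance.

    ``column_blocks`` names the source block of each column and
    ``column_roles`` marks it as a drug-A copy, drug-B copy, or shared.
    ``kept_indices`` maps matrix rows back to the input record list
    (records whose blocks could not be computed are dropped and counted).
    """

    spec: FeatureSpec
    column_names: list[str]
    column_blocks: list[str]
    column_roles: list[str]  # "drug_a" | "drug_b" | "shared"
    values: np.ndarray
    categorical_mask: np.ndarray
    kept_indices: np.ndarray
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def categorical_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.categorical_mask) if c]

    def swap_column_order(self) -> np.ndarray:
        """Column permutation exchanging drug-A and drug-B copies blockwise."""
        order = np.arange(len(self.column_names))
        for block in set(self.column_blocks):
            a_idx = [i for i in order
                     if self.column_blocks[i] == block and self.column_roles[i] == "drug_a"]
            b_idx = [i for i in order
                     if self.column_blocks[i] == block and self.column_roles[i] == "drug_b"]
            if a_idx and len(a_idx) == len(b_idx):
                order[a_idx], order[b_idx] = order[b_idx].copy(), order[a_idx].copy()
        return order


@lru_cache(maxsize=4096)
def fingerprint(smiles: str) -> np.ndarray:
    """Concatenated MACCS(166) ++ Morgan(1024, radius 2) ++ RDKit(2048)
    binary fingerprint of one molecule: 3,238 bits total.

    MACCS is emitted as 166 informative bits (the conventional 167-bit
    layout's unused index 0 is dropped).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparseableSmilesError(smiles)
    maccs = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64)[1:]
    morgan_gen = _morgan_generator()
    rdk_gen = _rdkit_generator()
    morgan = np.array(morgan_gen.GetFingerprint(mol), dtype=np.float64)
    rdk = np.array(rdk_gen.GetFingerprint(mol), dtype=np.float64)
    out = np.concatenate([maccs, morgan, rdk])
    assert out.shape == (FINGERPRINT_BITS,)
    return out


@lru_cache(maxsize=1)
def _morgan_generator():
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=MORGAN_BITS)


@lru_cache(maxsize=1)
def _rdkit_generator():
    return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=RDKIT_BITS)


def quantile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Force every cell line onto the same (mean) expression distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties receive the average of the reference values at
    their tied ranks. A single-cell-line table is returned unchanged.
    """
    frame = table.values
    if frame.shape[1] < 2:
        logger.warning("quantile normalization skipped: fewer than 2 cell lines")
        return table
    arr = frame.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = frame.rank(axis=0, method="average").to_numpy()  # 1-based, ties averaged
    normalized = np.interp(ranks, np.arange(1, arr.shape[0] + 1), reference)
    return ExpressionTable(
        values=pd.DataFrame(normalized, index=frame.index, columns=frame.columns)
    )


def _block_columns(block, spec, records, expression, harmonization, vocab):
    """Yield (names, roles, categorical, matrix) for one block across records."""
    if block == "drug_categorical":
        values = np.array(
            [[vocab.drugs.encode(r.drug_a_id), vocab.drugs.encode(r.drug_b_id)]
             for r in records], dtype=float)
        return (["drug_a_code", "drug_b_code"], ["drug_a", "drug_b"], [True, True], values)
    if block == "cell_line_categorical":
        values = np.array([[vocab.cell_lines.encode(r.cell_line_id)] for r in records],
                          dtype=float)
        return (["cell_line_code"], ["shared"], [True], values)
    if block == "chemical_structure":
        fps = np.array(
            [np.concatenate([fingerprint(r.smiles_a), fingerprint(r.smiles_b)])
             for r in records])
        names = [f"fp_a_{i:04d}" for i in range(FINGERPRINT_BITS)] + [
            f"fp_b_{i:04d}" for i in range(FINGERPRINT_BITS)]
        roles = ["drug_a"] * FINGERPRINT_BITS + ["drug_b"] * FINGERPRINT_BITS
        return (names, roles, [False] * 2 * FINGERPRINT_BITS, fps)
    if block == "cancer_gene_expression":
        if expression is None:
            raise ValueError("spec requires cancer_gene_expression but no table given")
        values = np.array([expression.vector(r.cell_line_id) for r in records])
        names = [f"expr_{g}" for g in expression.gene_ids]
        return (names, ["shared"] * len(names), [False] * len(names), values)
    if block == "monotherapy_ic50":
        def enc(summary):
            if summary.ic50 is None:
                return [IC50_SENTINEL, 0.0]
            return [summary.ic50, 1.0]
        values = np.array([enc(r.summary_a) + enc(r.summary_b) for r in records])
        names = ["ic50_a", "ic50_a_defined", "ic50_b", "ic50_b_defined"]
        roles = ["drug_a", "drug_a", "drug_b", "drug_b"]
        return (names, roles, [False] * 4, values)
    if block == "monotherapy_ri":
        values = np.array([[r.summary_a.ri, r.summary_b.ri] for r in records])
        return (["ri_a", "ri_b"], ["drug_a", "drug_b"], [False, False], values)
    if block == "drc_baseline":
        values = np.array(
            [np.concatenate([encode_drc_baseline(r.curve_a, harmonization),
                             encode_drc_baseline(r.curve_b, harmonization)])
             for r in records])
        width = 2 * harmonization.pad_cap
        names = [f"drc_base_a_{i:02d}" for i in range(width)] + [
            f"drc_base_b_{i:02d}" for i in range(width)]
        roles = ["drug_a"] * width + ["drug_b"] * width
        return (names, roles, [False] * 2 * width, values)
    if block == "drc_imputation":
        values = np.array(
            [np.concatenate([
                encode_drc_imputation(r.curve_a, r.summary_a, harmonization),
                encode_drc_imputation(r.curve_b, r.summary_b, harmonization)])
             for r in records])
        width = len(harmonization.methods) * harmonization.target_length
        names = []
        for who in ("a", "b"):
            for method in harmonization.methods:
                names += [f"drc_imp_{who}_{method}_{i:02d}"
                          for i in range(harmonization.target_length)]
        roles = ["drug_a"] * width + ["drug_b"] * width
        return (names, roles, [False] * 2 * width, values)
    raise ValueError(f"unknown block {block!r}")  # pragma: no cover


def assemble(
    records: list[CombinationRecord],
    spec: FeatureSpec,
    expression: ExpressionTable | None = None,
    harmonization: HarmonizationConfig | None = None,
    vocab: VocabularySet | None = None,
) -> FeatureMatrix:
    """Realize a feature spec into a numeric matrix, one row per record.

    Column order is deterministic: blocks in spec order, drug-A copy before
    drug-B copy inside each per-drug block. Records whose blocks cannot be
    computed (unknown cell line in the expression table, unparseable SMILES)
    are dropped and counted in ``n_dropped``.
    """
    harmonization = spec.harmonization(harmonization)
    vocab = vocab or VocabularySet.fit(records)

    usable: list[int] = []
    for i, rec in enumerate(records):
        try:
            if "chemical_structure" in spec.blocks:
                fingerprint(rec.smiles_a)
                fingerprint(rec.smiles_b)
            if "cancer_gene_expression" in spec.blocks and expression is not None:
                expression.vector(rec.cell_line_id)
            usable.append(i)
        except (UnparseableSmilesError, KeyError) as exc:
            logger.warning("dropping record %d: %s", i, exc)
    kept = [records[i] for i in usable]
    if not kept:
        raise ValueError("no records featurizable under this spec")

    names: list[str] = []
    blocks_meta: list[str] = []
    roles: list[str] = []
    cats: list[bool] = []
    pieces: list[np.ndarray] = []
    for block in spec.blocks:
        bn, br, bc, bv = _block_columns(block, spec, kept, expression, harmonization, vocab)
        names += bn
        blocks_meta += [block] * len(bn)
        roles += br
        cats += bc
        pieces.append(bv)
    values = np.hstack(pieces)
    return FeatureMatrix(
        spec=spec,
        column_names=names,
        column_blocks=blocks_meta,
        column_roles=roles,
        values=values,
        categorical_mask=np.array(cats, dtype=bool),
        kept_indices=np.array(usable, dtype=int),
        n_dropped=len(records) - len(kept),
    )


def symmetrize(matrix: FeatureMatrix, labels: np.ndarray):
    """Augment a training matrix with drug-order-swapped twins.

    Returns (values with 2n rows, labels with 2n entries): for every row,
    a twin with the drug-A and drug-B column copies exchanged and the same
    label. Intended for training folds only — applying it before fold
    assignment would leak pair identity across folds.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != matrix.n_rows:
        raise ValueError("labels misaligned with matrix rows")
    order = matrix.swap_column_order()
    if np.array_equal(order, np.arange(len(order))):
        logger.warning("spec has no per-drug blocks; symmetrize is a no-op")
        return matrix.values, labels
    twin = matrix.values[:, order]
    return np.vstack([matrix.values, twin]), np.concatenate([labels, labels])


def label_vector(records: list[CombinationRecord], score: str) -> np.ndarray:
    """Extract one score's labels aligned to a record list (NaN = missing)."""
    return np.array([r.labels[score] for r in records], dtype=float)
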