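"""Domain types and I/O for DrugComb-style combination-screening tables.

The on-disk dialect is a flat CSV with one combination experiment per row.
Monotherapy dose/response series are serialized as bracketed number lists
inside single cells (the way DrugComb exports ship them); six combination
response labels (CSS, S, Bliss, HSA, Loewe, ZIP) are plain numeric columns,
empty when missing.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six combination-response scores consumed as labels.
SCORE_NAMES = ("CSS", "S", "Bliss", "HSA", "Loewe", "ZIP")

_SCORE_COLUMNS = {name: name.lower() for name in SCORE_NAMES}

_MANDATORY_COLUMNS = (
    "study_id",
    "drug_a_id",
    "drug_b_id",
    "smiles_a",
    "smiles_b",
    "cell_line_id",
    "doses_a",
    "responses_a",
    "doses_b",
    "responses_b",
) + tuple(_SCORE_COLUMNS.values())

_OPTIONAL_COLUMNS = ("replicate_id", "ic50_a", "ri_a", "ic50_b", "ri_b")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """One monotherapy's measured doses and responses on one cell line.

    Doses are in µM, strictly increasing, with at most one zero dose (the
    untreated control) in first position. Responses are % inhibition.
    """

    drug_id: str
    cell_line_id: str
    study_id: str
    doses: tuple[float, ...]
    responses: tuple[float, ...]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if len(self.doses) != len(self.responses):
            raise ValueError(
                f"doses ({len(self.doses)}) and responses ({len(self.responses)}) "
                "differ in length"
            )
        if not 2 <= len(self.doses) <= 10:
            raise ValueError(f"curve must have 2-10 knots, got {len(self.doses)}")
        diffs = np.diff(self.doses)
        if np.any(diffs <= 0):
            raise ValueError("doses must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        # strict increase already forbids a second zero anywhere but first

    @property
    def n_doses(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class MonotherapySummary:
    """Efficacy summary of one monotherapy curve.

    ``ic50`` is None when the curve never reaches half of its maximal
    response. ``ri`` is the relative inhibition: the normalized area under
    the log10-dose response curve.
    """

    ic50: float | None
    ri: float
    stat_max: float
    stat_min: float
    stat_mean: float
    stat_median: float

    def __post_init__(self) -> None:
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValueError("ic50 must be positive when defined")
        if not (self.stat_min - 1e-9 <= self.stat_median <= self.stat_max + 1e-9):
            raise ValueError("median outside [min, max]")
        if not (self.stat_min - 1e-9 <= self.stat_mean <= self.stat_max + 1e-9):
            raise ValueError("mean outside [min, max]")

    @property
    def ic50_defined(self) -> bool:
        return self.ic50 is not None


@dataclass
class CombinationRecord:
    """A drug-pair × cell-line experiment with six response labels."""

    drug_a_id: str
    drug_b_id: str
    smiles_a: str
    smiles_b: str
    cell_line_id: str
    study_id: str
    labels: dict[str, float]
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve
    summary_a: MonotherapySummary
    summary_b: MonotherapySummary
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.drug_a_id == self.drug_b_id:
            raise ValueError("a combination requires two distinct drugs")
        missing = set(SCORE_NAMES) - set(self.labels)
        if missing:
            raise ValueError(f"labels missing score keys: {sorted(missing)}")
        for curve in (self.curve_a, self.curve_b):
            if curve.cell_line_id != self.cell_line_id:
                raise ValueError(
                    "monotherapy curve cell line does not match the combination"
                )

    @property
    def group_key(self) -> tuple[frozenset[str], str]:
        """Unordered treatment–cell-line key used for grouped CV splits."""
        return (frozenset((self.drug_a_id, self.drug_b_id)), self.cell_line_id)


@dataclass
class ExpressionTable:
    """Gene-expression matrix for a panel of cell lines (genes × cell lines)."""

    values: pd.DataFrame  # index: gene symbols, columns: cell line ids

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, cell_line_id: str) -> np.ndarray:
        key = normalize_cell_line(cell_line_id)
        lookup = {normalize_cell_line(c): c for c in self.values.columns}
        if key not in lookup:
            raise KeyError(f"cell line {cell_line_id!r} not in expression table")
        return self.values[lookup[key]].to_numpy(dtype=float)


@dataclass
class ParseReport:
    """Per-file account of rows that could not be parsed."""

    n_rows: int = 0
    n_accepted: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.errors)


@dataclass
class StudyDataset:
    """All combination records from one screening study."""

    study_id: str
    combinations: list[CombinationRecord]
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        for rec in self.combinations:
            if rec.study_id != self.study_id:
                raise ValueError(
                    f"record from study {rec.study_id!r} in dataset {self.study_id!r}"
                )

    def __len__(self) -> int:
        return len(self.combinations)

    @property
    def dose_design_summary(self) -> dict[str, int]:
        """Histogram of dose-matrix shapes, e.g. {'5x5': 120, '5x3': 4}."""
        counts: dict[str, int] = {}
        for rec in self.combinations:
            key = f"{rec.curve_a.n_doses}x{rec.curve_b.n_doses}"
            counts[key] = counts.get(key, 0) + 1
        return counts


def normalize_cell_line(name: str) -> str:
    """Canonical cell-line key: uppercase, non-alphanumerics stripped."""
    return re.sub(r"[^A-Z0-9]", "", name.upper())


_LIST_SPLIT = re.compile(r"[,\s;]+")


def parse_number_list(text: str) -> list[float]:
    """Parse a bracketed number list; commas or semicolons both accepted."""
    if not isinstance(text, str):
        raise ValueError(f"expected a serialized list, got {text!r}")
    stripped = text.strip().strip("[]()")
    if not stripped:
        raise ValueError("empty dose/response list")
    parts = [p for p in _LIST_SPLIT.split(stripped) if p]
    try:
        return [float(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"unparseable number list {text!r}") from exc


def _sorted_curve(doses: Sequence[float], responses: Sequence[float]):
    if len(doses) != len(responses):
        raise ValueError(
            f"doses ({len(doses)}) and responses ({len(responses)}) differ in length"
        )
    order = np.argsort(doses)
    return [doses[i] for i in order], [responses[i] for i in order]


def _maybe_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def summarize_curve(
    curve: DoseResponseCurve,
    ic50: float | None = None,
    ri: float | None = None,
) -> MonotherapySummary:
    """Build a MonotherapySummary, preferring table-provided IC50/RI values.

    When the input table does not carry IC50/RI, reference implementations
    from :mod:`drcbridge.monotherapy` are used.
    """
    from . import monotherapy  # local import: monotherapy depends on this module

    stats = monotherapy.curve_statistics(curve)
    if ic50 is None:
        ic50 = monotherapy.estimate_ic50(curve)
    if ri is None:
        ri = monotherapy.compute_ri(curve)
    return MonotherapySummary(
        ic50=ic50,
        ri=ri if ri is not None else float("nan"),
        stat_max=stats["max"],
        stat_min=stats["min"],
        stat_mean=stats["mean"],
        stat_median=stats["median"],
    )


def _record_from_row(row: pd.Series) -> CombinationRecord:
    doses_a, resp_a = _sorted_curve(
        parse_number_list(row["doses_a"]), parse_number_list(row["responses_a"])
    )
    doses_b, resp_b = _sorted_curve(
        parse_number_list(row["doses_b"]), parse_number_list(row["responses_b"])
    )
    replicate = int(row["replicate_id"]) if _maybe_float(row.get("replicate_id")) is not None else 0
    curve_a = DoseResponseCurve(
        drug_id=str(row["drug_a_id"]),
        cell_line_id=str(row["cell_line_id"]),
        study_id=str(row["study_id"]),
        doses=doses_a,
        responses=resp_a,
        replicate_id=replicate,
    )
    curve_b = DoseResponseCurve(
        drug_id=str(row["drug_b_id"]),
        cell_line_id=str(row["cell_line_id"]),
        study_id=str(row["study_id"]),
        doses=doses_b,
        responses=resp_b,
        replicate_id=replicate,
    )
    labels = {
        name: (
            v if (v := _maybe_float(row.get(col))) is not None else float("nan")
        )
        for name, col in _SCORE_COLUMNS.items()
    }
    return CombinationRecord(
        drug_a_id=str(row["drug_a_id"]),
        drug_b_id=str(row["drug_b_id"]),
        smiles_a=str(row["smiles_a"]),
        smiles_b=str(row["smiles_b"]),
        cell_line_id=str(row["cell_line_id"]),
        study_id=str(row["study_id"]),
        labels=labels,
        curve_a=curve_a,
        curve_b=curve_b,
        summary_a=summarize_curve(
            curve_a, _maybe_float(row.get("ic50_a")), _maybe_float(row.get("ri_a"))
        ),
        summary_b=summarize_curve(
            curve_b, _maybe_float(row.get("ic50_b")), _maybe_float(row.get("ri_b"))
        ),
        replicate_id=replicate,
    )


def read_combination_table(path, dialect: str = "drugcomb-csv") -> StudyDataset:
    """Read one study's combination-screening table.

    Malformed rows (bad number lists, mismatched curve lengths, invariant
    violations) are skipped; the count and per-row messages are collected in
    ``dataset.parse_report`` and logged.
    """
    if dialect not in ("drugcomb-csv", "drugcomb-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect.endswith("tsv") else ","
    frame = pd.read_csv(path, sep=sep, dtype={"doses_a": str, "responses_a": str,
                                              "doses_b": str, "responses_b": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ParseReport(n_rows=len(frame))
    records: list[CombinationRecord] = []
    for idx, row in frame.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            report.errors.append((int(idx), str(exc)))
    report.n_accepted = len(records)
    if report.n_skipped:
        logger.warning("skipped %d of %d rows in %s", report.n_skipped, report.n_rows, path)

    study_ids = {rec.study_id for rec in records}
    if len(study_ids) > 1:
        raise ValueError(f"file mixes multiple studies: {sorted(study_ids)}")
    if records:
        study_id = records[0].study_id
    else:
        study_id = str(frame["study_id"].iloc[0]) if len(frame) else "empty"
    return StudyDataset(study_id=study_id, combinations=records, parse_report=report)


def _serialize_list(values: Iterable[float]) -> str:
    return json.dumps([float(v) for v in values])


def write_combination_table(dataset: StudyDataset, path) -> None:
    """Write a StudyDataset in the dialect ``read_combination_table`` reads.

    ``read_combination_table(write_combination_table(ds))`` reproduces the
    dataset field-for-field; missing labels round-trip as empty cells.
    """
    rows = []
    for rec in dataset.combinations:
        row = {
            "study_id": rec.study_id,
            "drug_a_id": rec.drug_a_id,
            "drug_b_id": rec.drug_b_id,
            "smiles_a": rec.smiles_a,
            "smiles_b": rec.smiles_b,
            "cell_line_id": rec.cell_line_id,
            "replicate_id": rec.replicate_id,
            "doses_a": _serialize_list(rec.curve_a.doses),
            "responses_a": _serialize_list(rec.curve_a.responses),
            "doses_b": _serialize_list(rec.curve_b.doses),
            "responses_b": _serialize_list(rec.curve_b.responses),
            "ic50_a": rec.summary_a.ic50,
            "ri_a": rec.summary_a.ri,
            "ic50_b": rec.summary_b.ic50,
            "ri_b": rec.summary_b.ri,
        }
        for name, col in _SCORE_COLUMNS.items():
            value = rec.labels[name]
            row[col] = "" if (value is None or math.isnan(value)) else value
        rows.append(row)
    columns = list(_MANDATORY_COLUMNS[:6]) + ["replicate_id"] + [
        "doses_a", "responses_a", "doses_b", "responses_b",
        "ic50_a", "ri_a", "ic50_b", "ri_b",
    ] + list(_SCORE_COLUMNS.values())
    frame = pd.DataFrame(rows, columns=columns)
    if not rows:  # header-only file for an empty dataset
        frame = pd.DataFrame(columns=columns)
    frame.to_csv(path, index=False)


def read_expression_table(path, gene_list: Sequence[str]) -> ExpressionTable:
    """Read a genes × cell-lines expression matrix restricted to ``gene_list``.

    Orientation is auto-detected by matching ``gene_list`` against the row
    index and the columns; the table is transposed if genes arrive as
    columns. Genes absent from the file are dropped (the intersection is
    logged); fewer than 50% found is a warning, zero found an error.
    """
    frame = pd.read_csv(path, index_col=0)
    genes = set(gene_list)
    hit_rows = len(genes & set(frame.index.astype(str)))
    hit_cols = len(genes & set(frame.columns.astype(str)))
    if hit_cols > hit_rows:
        frame = frame.T
    found = [g for g in gene_list if g in frame.index]
    if not found:
        raise ValueError("none of the requested genes found in expression file")
    if len(found) < 0.5 * len(gene_list):
        logger.warning(
            "only %d of %d requested genes found in %s", len(found), len(gene_list), path
        )
    else:
        logger.info("expression intersection: %d of %d genes", len(found), len(gene_list))
    sub = frame.loc[found].astype(float)
    if sub.isna().any().any():
        n_before = len(sub)
        sub = sub.dropna(axis=0)
        logger.warning("dropped %d genes with missing values", n_before - len(sub))
    return ExpressionTable(values=sub)
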