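"""Domain types for coded patient data plus CSV readers/writers.

The package's substrate is the per-patient count of coded clinical events
(diagnoses, procedures, medications...) aggregated over the whole record.
Everything downstream — polar labeling, feature extraction, evaluation —
consumes the types defined here.

Interchange formats are plain RFC-4180 CSV:

* count tables, long layout (canonical): ``patient_id,concept,count``
* count tables, wide layout: ``patient_id,<concept>,...``
* gold labels: ``patient_id,label`` with label in {Y,N,P,U}
* silver standard: ``patient_id,silver_label,disease_count,log_count,pole``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "ConceptCountTable",
    "DiseaseCountVector",
    "GoldStandard",
    "SilverStandard",
    "read_count_table",
    "write_count_table",
    "read_gold_labels",
    "write_gold_labels",
    "read_silver_standard",
    "write_silver_standard",
]

GOLD_LABELS = frozenset("YNPU")


@dataclass(frozen=True)
class ConceptCountTable:
    """Patient x concept matrix of non-negative integer event counts.

    Wraps a dense :class:`pandas.DataFrame` whose index is the ordered list
    of unique patient identifiers and whose columns are the ordered list of
    unique concept codes (e.g. ``DX_COPD``, ``PRC_ERVisit``). A (patient,
    concept) pair absent from the source data has count 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate patient identifiers in count table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate concept codes in count table")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise FormatError("count table values must be integers")
        if (df.to_numpy() < 0).any():
            raise FormatError("count table contains negative counts")

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def concepts(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data.index)

    def count(self, patient: str, concept: str) -> int:
        return int(self.data.at[patient, concept])

    def disease_counts(self, target_concept: str | Iterable[str]) -> "DiseaseCountVector":
        """Select the target disease's diagnostic-code counts for every patient.

        ``target_concept`` may be a single concept code or an iterable of
        codes whose counts are summed (diseases coded under several codes).
        """
        if isinstance(target_concept, str):
            concepts = [target_concept]
            name = target_concept
        else:
            concepts = list(target_concept)
            name = "+".join(concepts)
        missing = [c for c in concepts if c not in self.data.columns]
        if missing:
            raise KeyError(f"concept(s) not in table: {missing}")
        counts = self.data[concepts].sum(axis=1).astype(np.int64)
        return DiseaseCountVector(counts=counts, target_concept=name)

    def subset(self, patients: Iterable[str]) -> "ConceptCountTable":
        return ConceptCountTable(self.data.loc[list(patients)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptCountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class DiseaseCountVector:
    """Per-patient count of the target disease's diagnostic codes."""

    counts: pd.Series  # index: patient_id, values: non-negative int
    target_concept: str

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise FormatError("disease counts must be non-negative")

    @property
    def patients(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class GoldStandard:
    """Chart-review labels, one of Y (present), N (absent), P (possible),
    U (unknown/can't say), per patient."""

    labels: pd.Series  # index: patient_id, values in {Y,N,P,U}

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - GOLD_LABELS
        if bad:
            raise FormatError(f"gold labels outside Y/N/P/U: {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise FormatError("duplicate patient identifiers in gold standard")

    @property
    def patients(self) -> list[str]:
        return list(self.labels.index)

    def certain(self) -> "GoldStandard":
        """Restrict to the Y/N patients (the labels used for training and
        evaluation; P and U are discarded for lack of certainty)."""
        return GoldStandard(self.labels[self.labels.isin(["Y", "N"])])

    def binary(self) -> pd.Series:
        """Y/N labels as 1/0 integers. Call on a ``certain()`` view."""
        certain = self.labels[self.labels.isin(["Y", "N"])]
        return (certain == "Y").astype(np.int64)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SilverStandard:
    """Automatically generated binary labels with per-patient provenance.

    ``records`` holds one row per labeled patient with columns
    ``silver_label`` (1/0), ``disease_count``, ``log_count`` and ``pole``
    ("high"/"low"). ``cutoffs_used`` and ``seed_used`` record how the set
    was produced; ``clamped`` is set when a non-strict train-size request
    exceeded the balanced set and the full set was returned instead.
    """

    records: pd.DataFrame
    cutoffs_used: object = None  # PoleCutoffs; kept loose to avoid an import cycle
    seed_used: int | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        required = {"silver_label", "disease_count", "log_count", "pole"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"silver standard missing columns: {sorted(missing)}")
        if not set(self.records["silver_label"].unique()) <= {0, 1}:
            raise FormatError("silver labels must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.records.index)

    @property
    def labels(self) -> pd.Series:
        return self.records["silver_label"]

    @property
    def positives(self) -> list[str]:
        return list(self.records.index[self.records["silver_label"] == 1])

    @property
    def negatives(self) -> list[str]:
        return list(self.records.index[self.records["silver_label"] == 0])

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_csv(source: str | IO[str]) -> pd.DataFrame:
    try:
        return pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty input: no header row") from exc


def _parse_count_column(values: pd.Series, context: str) -> np.ndarray:
    """Parse strings to non-negative integers, naming the offending row."""
    out = np.empty(len(values), dtype=np.int64)
    for i, raw in enumerate(values):
        try:
            as_float = float(raw)
        except ValueError:
            raise FormatError(f"{context}: row {i + 1}: non-numeric count {raw!r}") from None
        if not float(as_float).is_integer():
            raise FormatError(f"{context}: row {i + 1}: non-integer count {raw!r}")
        if as_float < 0:
            raise FormatError(f"{context}: row {i + 1}: negative count {raw!r}")
        out[i] = int(as_float)
    return out


def read_count_table(source: str | IO[str], layout: str = "long") -> ConceptCountTable:
    """Read a concept count table from CSV.

    Long layout (canonical) has columns ``patient_id,concept,count``;
    duplicate (patient, concept) rows are summed and missing cells are 0.
    Wide layout has ``patient_id`` followed by one column per concept;
    duplicate patient rows are a format error.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    df = _read_csv(source)
    if layout == "long":
        expected = ["patient_id", "concept", "count"]
        if list(df.columns) != expected:
            raise FormatError(f"long layout requires header {expected}, got {list(df.columns)}")
        if df.empty:
            return ConceptCountTable(pd.DataFrame(dtype=np.int64))
        counts = _parse_count_column(df["count"], "count table")
        long = pd.DataFrame(
            {"patient_id": df["patient_id"], "concept": df["concept"], "count": counts}
        )
        wide = long.pivot_table(
            index="patient_id", columns="concept", values="count", aggfunc="sum", fill_value=0
        ).astype(np.int64)
        # preserve first-appearance order rather than pivot's lexicographic order
        patient_order = list(dict.fromkeys(long["patient_id"]))
        concept_order = list(dict.fromkeys(long["concept"]))
        wide = wide.loc[patient_order, concept_order]
        wide.index.name = None
        wide.columns.name = None
        return ConceptCountTable(wide)
    # wide
    if len(df.columns) < 1 or df.columns[0] != "patient_id":
        raise FormatError("wide layout requires first header column 'patient_id'")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate patient row in wide layout: {dup!r}")
    wide = df.set_index("patient_id")
    wide.index.name = None
    parsed = {}
    for col in wide.columns:
        parsed[col] = _parse_count_column(wide[col], f"count table column {col!r}")
    out = pd.DataFrame(parsed, index=wide.index, dtype=np.int64)
    return ConceptCountTable(out)


def write_count_table(table: ConceptCountTable, sink: str | IO[str], layout: str = "long") -> None:
    """Write a count table as CSV in long (zero cells omitted) or wide layout."""
    if layout == "long":
        stacked = table.data.stack()
        stacked = stacked[stacked > 0]
        long = stacked.rename_axis(["patient_id", "concept"]).rename("count").reset_index()
        long.to_csv(sink, index=False)
    elif layout == "wide":
        out = table.data.rename_axis("patient_id")
        out.to_csv(sink)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_gold_labels(source: str | IO[str]) -> GoldStandard:
    """Read chart-review labels from ``patient_id,label`` CSV.

    Labels parse case-insensitively into {Y,N,P,U}; anything else is a
    format error naming the row.
    """
    df = _read_csv(source)
    expected = ["patient_id", "label"]
    if list(df.columns) != expected:
        raise FormatError(f"gold labels require header {expected}, got {list(df.columns)}")
    labels = []
    for i, raw in enumerate(df["label"]):
        sym = str(raw).strip().upper()
        if sym not in GOLD_LABELS:
            raise FormatError(f"gold labels: row {i + 1}: unknown label {raw!r}")
        labels.append(sym)
    return GoldStandard(pd.Series(labels, index=list(df["patient_id"]), dtype=object))


def write_gold_labels(gold: GoldStandard, sink: str | IO[str]) -> None:
    out = gold.labels.rename_axis("patient_id").rename("label")
    out.to_csv(sink)


def write_silver_standard(silver: SilverStandard, sink: str | IO[str]) -> None:
    """Emit the silver standard with provenance columns.

    Log counts are written at 12 significant digits so a write/read cycle
    is lossless to well past 10 significant digits.
    """
    out = silver.records.copy()
    out = out[["silver_label", "disease_count", "log_count", "pole"]]
    out = out.rename_axis("patient_id")
    out.to_csv(sink, float_format="%.12g")


def read_silver_standard(source: str | IO[str]) -> SilverStandard:
    df = _read_csv(source)
    expected = ["patient_id", "silver_label", "disease_count", "log_count", "pole"]
    if list(df.columns) != expected:
        raise FormatError(f"silver standard requires header {expected}, got {list(df.columns)}")
    records = pd.DataFrame(
        {
            "silver_label": _parse_count_column(df["silver_label"], "silver_label"),
            "disease_count": _parse_count_column(df["disease_count"], "disease_count"),
            "log_count": pd.to_numeric(df["log_count"]).to_numpy(),
            "pole": df["pole"].to_numpy(),
        },
        index=list(df["patient_id"]),
    )
    return SilverStandard(records=records)
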