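"""Tabular artifact I/O for the MRM urine-proteomics pipeline.

Reads and writes the plain-CSV artifacts the pipeline exchanges:

* transition lists (protein, proteotypic peptide, Q1/Q3 masses, retention time),
* transition-level peak-area reports with light/heavy label annotation,
* clinical tables (diagnosis group, eGFR, 24-h proteinuria, steroid resistance),
* sample x protein abundance matrices with explicit missing cells.

Dialect: comma-separated UTF-8 with a mandatory header row and "." decimal
separator.  Missing values are the empty string or "NaN" on read and "NaN"
on write — the convention of Skyline-style exports.  Missing is always
distinct from zero: a zero area or concentration is a real measurement.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "VALID_GROUPS",
    "FSGS_UNRESOLVED",
    "TransitionListEntry",
    "TransitionMeasurement",
    "ClinicalRecord",
    "AbundanceMatrix",
    "read_transition_list",
    "read_transition_report",
    "write_transition_report",
    "read_clinical_table",
    "write_clinical_table",
    "read_abundance_matrix",
    "write_abundance_matrix",
]

#: Diagnosis groups of the study cohort.  "FSGS" is the unresolved label used
#: before the severity index splits FSGS patients into mild/severe subgroups.
VALID_GROUPS = ("control", "MCD", "mFSGS", "sFSGS", "MN")
FSGS_UNRESOLVED = "FSGS"
_ALL_GROUP_LABELS = VALID_GROUPS + (FSGS_UNRESOLVED,)

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
_LABELS = ("light", "heavy")


class FormatError(ValueError):
    """A tabular artifact violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionListEntry:
    """One scheduled MRM transition: peptide surrogate of one protein."""

    protein_id: str
    peptide_sequence: str
    precursor_mz: float  # Q1, Da
    product_mz: float  # Q3, Da
    expected_rt: float  # minutes

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise FormatError(
                f"transition {self.protein_id}/{self.peptide_sequence}: "
                "Q1/Q3 masses must be positive"
            )
        if not self.peptide_sequence or not set(self.peptide_sequence) <= _AMINO_ACIDS:
            raise FormatError(
                f"peptide sequence {self.peptide_sequence!r} is not an "
                "uppercase amino-acid string"
            )


@dataclass(frozen=True)
class TransitionMeasurement:
    """Integrated peak area of one transition in one injection.

    ``below_lod`` marks signals under the limit of detection; their area is
    treated as missing (never zero) by all downstream quantification.
    """

    sample_id: str
    replicate: int
    protein_id: str
    peptide_sequence: str
    label: str  # "light" (endogenous) or "heavy" (SIS standard)
    area: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise FormatError(f"label must be one of {_LABELS}, got {self.label!r}")
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")
        if not self.below_lod and (np.isnan(self.area) or self.area < 0):
            raise FormatError(
                f"area must be a non-negative number, got {self.area!r} "
                f"({self.sample_id}/{self.peptide_sequence})"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates used by the severity index.

    ``steroid_resistant`` is True/False when assessed and None when unknown
    (e.g. not determined for a diagnosis group).
    """

    sample_id: str
    group: str
    egfr: float  # mL/min/1.73 m^2 (CKD-EPI)
    proteinuria: float  # g/24 h
    steroid_resistant: bool | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in _ALL_GROUP_LABELS:
            raise FormatError(
                f"unknown group {self.group!r}; allowed: {_ALL_GROUP_LABELS}"
            )
        if not np.isfinite(self.egfr) or self.egfr <= 0:
            raise FormatError(f"egfr must be > 0, got {self.egfr} ({self.sample_id})")
        if not np.isfinite(self.proteinuria) or self.proteinuria < 0:
            raise FormatError(
                f"proteinuria must be >= 0, got {self.proteinuria} ({self.sample_id})"
            )


@dataclass
class AbundanceMatrix:
    """Samples x proteins quantitative table with explicit missingness.

    ``values`` is a DataFrame indexed by sample_id with protein_id columns;
    missing cells are NaN.  ``scale_tag`` records the transform state
    ("raw", "ln1p" or "zscore").  ``groups`` maps sample_id -> diagnosis
    group and may be empty when labels are unknown (e.g. fresh output of
    quantification).
    """

    values: pd.DataFrame
    scale_tag: str = "raw"
    groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    SCALE_TAGS = ("raw", "ln1p", "zscore")

    def __post_init__(self) -> None:
        if self.scale_tag not in self.SCALE_TAGS:
            raise FormatError(f"scale_tag must be one of {self.SCALE_TAGS}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate protein ids")
        if len(self.groups):
            missing = self.values.index.difference(self.groups.index)
            if len(missing):
                raise FormatError(f"samples without group label: {list(missing)[:5]}")
            self.groups = self.groups.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.scale_tag, self.groups.copy())

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.scale_tag == other.scale_tag
            and self.values.equals(other.values)
            and self.groups.equals(other.groups)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def read_transition_list(path) -> list[TransitionListEntry]:
    """Read a transition list CSV (protein_id,peptide,precursor_mz,product_mz,rt_min)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df, ["protein_id", "peptide", "precursor_mz", "product_mz", "rt_min"],
        "transition list",
    )
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                TransitionListEntry(
                    protein_id=row["protein_id"],
                    peptide_sequence=row["peptide"],
                    precursor_mz=float(row["precursor_mz"]),
                    product_mz=float(row["product_mz"]),
                    expected_rt=float(row["rt_min"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"transition list row {i + 2}: {exc}") from exc
    return entries


_MISSING_TOKENS = ("", "nan", "na")


def _parse_area(token: str, row_no: int) -> tuple[float, bool]:
    """Parse an area cell; empty/NaN means below-LOD (missing)."""
    if token.strip().lower() in _MISSING_TOKENS:
        return np.nan, True
    try:
        return float(token), False
    except ValueError as exc:
        raise FormatError(f"row {row_no}: non-numeric area {token!r}") from exc


def read_transition_report(
    path, transition_list=None
) -> list[TransitionMeasurement]:
    """Read a Skyline-style transition report CSV.

    Columns: sample_id,replicate,protein_id,peptide,label,area and an
    optional below_lod flag.  When a transition list is supplied (path or
    parsed entries), report peptides absent from it are flagged with a
    warning but still parsed: rows are never silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df, ["sample_id", "replicate", "protein_id", "peptide", "label", "area"],
        "transition report",
    )
    known_peptides = None
    if transition_list is not None:
        entries = (
            transition_list
            if not isinstance(transition_list, (str, bytes, io.IOBase))
            and isinstance(transition_list, (list, tuple))
            else read_transition_list(transition_list)
        )
        known_peptides = {e.peptide_sequence for e in entries}

    measurements: list[TransitionMeasurement] = []
    unknown: set[str] = set()
    for i, row in df.iterrows():
        row_no = i + 2  # header is line 1
        area, missing = _parse_area(row["area"], row_no)
        below = missing or row.get("below_lod", "").strip().lower() in ("1", "true", "yes")
        try:
            m = TransitionMeasurement(
                sample_id=row["sample_id"],
                replicate=int(row["replicate"]),
                protein_id=row["protein_id"],
                peptide_sequence=row["peptide"],
                label=row["label"],
                area=area if not below else np.nan,
                below_lod=below,
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"transition report row {row_no}: {exc}") from exc
        if known_peptides is not None and m.peptide_sequence not in known_peptides:
            unknown.add(m.peptide_sequence)
        measurements.append(m)
    if unknown:
        warnings.warn(
            f"{len(unknown)} peptide(s) in report absent from transition list: "
            f"{sorted(unknown)[:5]}",
            stacklevel=2,
        )
    return measurements


def write_transition_report(measurements: Iterable[TransitionMeasurement], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "replicate": m.replicate,
            "protein_id": m.protein_id,
            "peptide": m.peptide_sequence,
            "label": m.label,
            "area": "NaN" if m.below_lod or np.isnan(m.area) else repr(float(m.area)),
            "below_lod": str(bool(m.below_lod)).lower(),
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


_BOOL_TOKENS = {"true": True, "1": True, "yes": True,
                "false": False, "0": False, "no": False}


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read the clinical table CSV; validates groups, eGFR and proteinuria."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        warnings.warn("clinical table is empty", stacklevel=2)
        return []
    _require_columns(
        df, ["sample_id", "group", "egfr", "proteinuria", "steroid_resistant"],
        "clinical table",
    )
    if df.empty:
        warnings.warn("clinical table has a header but no rows", stacklevel=2)
        return []
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dups}")
    records = []
    for i, row in df.iterrows():
        token = row["steroid_resistant"].strip().lower()
        if token in _MISSING_TOKENS or token == "unknown":
            steroid = None
        elif token in _BOOL_TOKENS:
            steroid = _BOOL_TOKENS[token]
        else:
            raise FormatError(
                f"clinical row {i + 2}: steroid_resistant must be boolean or "
                f"unknown, got {row['steroid_resistant']!r}"
            )
        try:
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    egfr=float(row["egfr"]),
                    proteinuria=float(row["proteinuria"]),
                    steroid_resistant=steroid,
                    sex=row.get("sex") or None,
                    age=float(row["age"]) if row.get("age", "") not in ("", "NaN") else None,
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"clinical row {i + 2}: {exc}") from exc
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "egfr": r.egfr,
                "proteinuria": r.proteinuria,
                "steroid_resistant": "unknown"
                if r.steroid_resistant is None
                else str(r.steroid_resistant).lower(),
                "sex": r.sex or "",
                "age": "" if r.age is None else r.age,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NaN")


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    """Write an abundance matrix CSV with a scale-tag header comment.

    Layout: one ``# scale=<tag>`` comment line, then a header
    ``sample_id,group,<protein...>`` and one row per sample.  Missing cells
    are written as "NaN".
    """
    df = matrix.values.copy()
    df.insert(0, "group", matrix.groups.reindex(df.index).fillna("") if len(matrix.groups) else "")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scale={matrix.scale_tag}\n")
        df.to_csv(fh, index=True, index_label="sample_id", na_rep="NaN")


def read_abundance_matrix(path) -> AbundanceMatrix:
    """Read an abundance matrix CSV written by :func:`write_abundance_matrix`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        scale_tag = "raw"
        if first.startswith("#"):
            kv = first.lstrip("#").strip()
            if "=" in kv:
                key, _, val = kv.partition("=")
                if key.strip() == "scale":
                    scale_tag = val.strip()
        else:
            fh.seek(0)
        header = fh.readline().rstrip("\n").split(",")
        if len(set(header)) != len(header):
            dup = sorted({c for c in header if header.count(c) > 1})
            raise FormatError(f"duplicated column(s) in abundance matrix: {dup}")
        fh.seek(0)
        df = pd.read_csv(
            fh, comment="#", na_values=["NaN", ""], keep_default_na=False,
            float_precision="round_trip",
        )
    _require_columns(df, ["sample_id", "group"], "abundance matrix")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    groups = df.pop("group")
    groups.name = None
    groups = groups.astype(object).where(groups.notna(), None)
    if groups.isna().all() or (groups == "").all():
        groups = pd.Series(dtype=object)
    values = df.astype(float)
    return AbundanceMatrix(values=values, scale_tag=scale_tag, groups=groups)


def matrix_from_arrays(
    values: np.ndarray,
    sample_ids: Sequence[str],
    protein_ids: Sequence[str],
    scale_tag: str = "raw",
    group_of: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Convenience constructor from a plain array plus id sequences."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(sample_ids),
                      columns=list(protein_ids))
    groups = pd.Series(dict(group_of)) if group_of else pd.Series(dtype=object)
    return AbundanceMatrix(values=df, scale_tag=scale_tag, groups=groups)
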