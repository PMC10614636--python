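"""Delimited-text I/O for participants, ROI volume tables and labeled matrices.

All tabular artifacts of the pipeline are plain TSV/CSV.  The delimiter is
auto-detected from the file extension (``.tsv`` -> tab, ``.csv`` -> comma) and
can be overridden.  Validation is fail-fast but exhaustive: every violation
found is reported, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ParticipantTable",
    "ROIVolumeTable",
    "read_participants",
    "write_participants",
    "read_roi_volumes",
    "write_roi_volumes",
    "read_matrix",
    "write_matrix",
]

#: canonical column names of a participants table
PARTICIPANT_COLUMNS = ("subject_id", "group", "age", "sex")

_SEX_CODES = {"m": 0, "f": 1, "0": 0, "1": 1}


def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    """Resolve the field delimiter from an explicit override or the extension."""
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


@dataclass(frozen=True)
class ParticipantTable:
    """Per-subject metadata: id, diagnostic group, age (years) and sex (0/1).

    Sex is normalised internally to ``0`` (male) / ``1`` (female); readers
    accept case-insensitive M/F or 0/1 codes.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate_participants(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.data["group"]))

    def group_indices(self, group: str) -> np.ndarray:
        """Positional row indices of one group's subjects."""
        idx = np.flatnonzero((self.data["group"] == group).to_numpy())
        if idx.size == 0:
            raise ValidationError(f"unknown group label: {group!r}")
        return idx

    def covariates(self, columns: Sequence[str] = ("age", "sex")) -> np.ndarray:
        """n x c covariate matrix (float) for the requested metadata columns."""
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise FormatError(f"covariate column(s) not present: {missing}")
        return self.data[list(columns)].to_numpy(dtype=float)


def _validate_participants(df: pd.DataFrame, min_group_size: int = 0) -> None:
    errors: list[str] = []
    dup = df["subject_id"][df["subject_id"].duplicated()].unique()
    if dup.size:
        errors.append(f"duplicate subject_id: {sorted(dup)}")
    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = df["subject_id"][~np.isfinite(age) | (age <= 0)]
    if len(bad_age):
        errors.append(f"non-positive or non-numeric age for subjects: {sorted(bad_age)}")
    if not set(np.unique(df["sex"])) <= {0, 1}:
        errors.append(f"sex codes not in {{0,1}} after normalisation: {sorted(set(df['sex']))}")
    if min_group_size:
        small = {g: n for g, n in df["group"].value_counts().items() if n < min_group_size}
        if small:
            errors.append(f"groups below the size floor of {min_group_size}: {small}")
    if errors:
        raise ValidationError(errors)


def read_participants(
    path: str | Path,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
    min_group_size: int = 5,
) -> ParticipantTable:
    """Read and validate a participants table.

    Parameters
    ----------
    path:
        TSV/CSV file with at least the subject id, group, age and sex columns.
    delimiter:
        Field delimiter; default auto-detected from the extension.
    columns:
        Optional mapping from canonical name (``subject_id``, ``group``,
        ``age``, ``sex``) to the column name used in the file.
    min_group_size:
        Every group must have at least this many subjects (a correlation over
        fewer is meaningless downstream).  Set to 0 to disable.
    """
    sep = detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    colmap = {c: c for c in PARTICIPANT_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [f"{canon} (column {colmap[canon]!r})" for canon in PARTICIPANT_COLUMNS if colmap[canon] not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = pd.DataFrame(
        {
            "subject_id": raw[colmap["subject_id"]].astype(str),
            "group": raw[colmap["group"]].astype(str),
            "age": pd.to_numeric(raw[colmap["age"]], errors="coerce"),
            "sex": raw[colmap["sex"]].astype(str).str.strip().str.lower().map(_SEX_CODES),
        }
    )
    errors: list[str] = []
    if df["sex"].isna().any():
        bad = sorted(set(raw[colmap["sex"]][df["sex"].isna()]))
        errors.append(f"unrecognised sex codes {bad}; accepted: M/F or 0/1 (case-insensitive)")
    else:
        df["sex"] = df["sex"].astype(int)
    if df["age"].isna().any():
        errors.append(f"non-numeric age for subjects: {sorted(df['subject_id'][df['age'].isna()])}")
    if errors:
        raise ValidationError(errors)
    _validate_participants(df, min_group_size=min_group_size)
    return ParticipantTable(df.reset_index(drop=True))


def write_participants(table: ParticipantTable, path: str | Path, delimiter: str | None = None) -> None:
    table.data.to_csv(path, sep=detect_delimiter(path, delimiter), index=False)


@dataclass(frozen=True)
class ROIVolumeTable:
    """Subjects x regions gray-matter volumes, row-aligned to a ParticipantTable."""

    data: pd.DataFrame = field(repr=False)  # index: subject_id, columns: region names

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def roi_volume_table(
    values: np.ndarray, subject_ids: Sequence[str], region_names: Sequence[str]
) -> ROIVolumeTable:
    """Assemble and validate an ROIVolumeTable from arrays."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(subject_ids), columns=list(region_names))
    _validate_volumes(df)
    return ROIVolumeTable(df)


def _validate_volumes(df: pd.DataFrame) -> None:
    errors: list[str] = []
    if df.shape[1] < 3:
        errors.append(f"need at least 3 regions, got {df.shape[1]}")
    dup_regions = df.columns[df.columns.duplicated()].unique()
    if len(dup_regions):
        errors.append(f"duplicate region names: {sorted(dup_regions)}")
    if df.isna().any().any():
        bad = sorted(df.index[df.isna().any(axis=1)])
        errors.append(f"missing/non-numeric cells for subjects: {bad}")
    if errors:
        raise ValidationError(errors)


def read_roi_volumes(
    path: str | Path,
    participants: ParticipantTable,
    delimiter: str | None = None,
) -> ROIVolumeTable:
    """Read a volumes table and align its rows to the participant order.

    The first column must be the subject id; remaining columns are atlas
    region names.  Subject id sets must match the participants table exactly;
    rows may appear in any order in the file.
    """
    sep = detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a subject-id column plus region columns")
    raw = raw.rename(columns={raw.columns[0]: "subject_id"})
    raw["subject_id"] = raw["subject_id"].astype(str)
    dup = raw["subject_id"][raw["subject_id"].duplicated()].unique()
    if dup.size:
        raise ValidationError(f"duplicate subject rows in volumes file: {sorted(dup)}")
    file_ids = set(raw["subject_id"])
    want_ids = set(participants.subject_ids)
    errors = []
    if file_ids - want_ids:
        errors.append(f"subjects in volumes but not in participants: {sorted(file_ids - want_ids)}")
    if want_ids - file_ids:
        errors.append(f"subjects in participants but missing from volumes: {sorted(want_ids - file_ids)}")
    if errors:
        raise ValidationError(errors)
    df = raw.set_index("subject_id").loc[participants.subject_ids]
    df = df.apply(pd.to_numeric, errors="coerce")
    _validate_volumes(df)
    return ROIVolumeTable(df)


def write_roi_volumes(
    table: ROIVolumeTable, path: str | Path, delimiter: str | None = None, sig_digits: int = 6
) -> None:
    """Write a volumes table; values at ``sig_digits`` significant digits."""
    table.data.to_csv(
        path,
        sep=detect_delimiter(path, delimiter),
        index_label="subject_id",
        float_format=f"%.{sig_digits}g",
    )


def write_matrix(
    matrix: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    path: str | Path,
    delimiter: str | None = None,
    precision: int = 4,
    corner: str = "",
) -> None:
    """Write a labeled real matrix as delimited text (default 4 decimals)."""
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if m.size == 0:
        m = m.reshape(len(row_labels), len(col_labels))
    if m.shape != (len(row_labels), len(col_labels)):
        raise ValidationError(
            f"label/shape mismatch: matrix {m.shape}, {len(row_labels)} row labels, {len(col_labels)} column labels"
        )
    sep = detect_delimiter(path, delimiter)
    with open(path, "w") as fh:
        fh.write(sep.join([corner, *map(str, col_labels)]) + "\n")
        for label, row in zip(row_labels, m):
            fh.write(sep.join([str(label), *(f"{v:.{precision}f}" for v in row)]) + "\n")


def read_matrix(path: str | Path, delimiter: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled matrix written by :func:`write_matrix`.

    Returns ``(values, row_labels, col_labels)``; a header-only file yields a
    0 x n matrix.
    """
    sep = detect_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        col_labels = header.split(sep)[1:]
        rows, row_labels = [], []
        for line in fh:
            parts = line.rstrip("\n").split(sep)
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(col_labels)))
    return values, row_labels, col_labels
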