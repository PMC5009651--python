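"""Delimited-text readers and writers for matrices and design tables.

File conventions
----------------
Matrix file: header row of sample IDs, first column of feature IDs,
remaining cells finite numbers.  Design file: columns ``sample``,
``batch``, ``treatment``.  Delimiter is inferred from the extension
(``.tsv`` -> tab, ``.csv`` -> comma) unless given explicitly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import ExperimentDesign, ExpressionMatrix
from .errors import ParseError, ValidationError


def detect_delimiter(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_matrix(
    path: str | os.PathLike, delimiter: str | None = None
) -> ExpressionMatrix:
    """Read a feature-by-sample matrix from delimited text.

    Non-numeric or missing cells are rejected with the offending feature
    and sample named; the method has no missing-data mechanism, so
    imputation is deliberately not offered.
    """
    delimiter = delimiter or detect_delimiter(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except OSError as exc:
        raise ParseError(f"cannot read matrix file {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (wrong delimiter?)")
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric or missing value {frame.iat[r, c]!r} at "
            f"feature {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return ExpressionMatrix(values, list(frame.index.astype(str)), list(frame.columns.astype(str)))


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | os.PathLike, delimiter: str | None = None
) -> None:
    """Write a matrix so that :func:`read_expression_matrix` round-trips it.

    Values are printed with ``repr`` precision (17 significant digits),
    which reproduces IEEE doubles exactly on re-read.
    """
    delimiter = delimiter or detect_delimiter(path)
    frame = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.sample_ids)
    frame.index.name = "feature"
    try:
        frame.to_csv(path, sep=delimiter, float_format="%.17g")
    except OSError as exc:
        raise ParseError(f"cannot write matrix file {path}: {exc}") from exc


def read_design(path: str | os.PathLike, delimiter: str | None = None) -> ExperimentDesign:
    """Read a sample/batch/treatment table.

    Raises
    ------
    ParseError
        Missing required column.
    ValidationError
        Duplicated sample rows or fewer than two batches.
    """
    delimiter = delimiter or detect_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"sample", "batch", "treatment"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: design file lacks columns {sorted(missing)}")
    if frame["sample"].duplicated().any():
        dupes = sorted(frame.loc[frame["sample"].duplicated(), "sample"].unique())
        raise ValidationError(f"{path}: samples listed more than once: {dupes}")
    if frame[["sample", "batch", "treatment"]].isna().any().any():
        raise ParseError(f"{path}: empty cells in sample/batch/treatment columns")
    samples = list(frame["sample"])
    return ExperimentDesign(
        samples,
        dict(zip(samples, frame["batch"])),
        dict(zip(samples, frame["treatment"])),
    )


def write_design(design: ExperimentDesign, path: str | os.PathLike, delimiter: str | None = None) -> None:
    delimiter = delimiter or detect_delimiter(path)
    frame = pd.DataFrame(
        {
            "sample": design.sample_ids,
            "batch": [design.batch_of[s] for s in design.sample_ids],
            "treatment": [design.treatment_of[s] for s in design.sample_ids],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)
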