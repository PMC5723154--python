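"""CSV formats: long-format observations and square dissimilarity matrices.

The canonical input is a long table with header ``subject,time,value``;
irregular sampling is the native representation, so a missing
observation is simply an absent row (no NA sentinel).  A wide
panel (subjects x time points, NaN for missing) can be converted with
:func:`subjects_from_wide`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dissim import DissimilarityMatrix
from .exceptions import ValidationError
from .spline import Subject

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "subjects_from_wide",
    "write_dissimilarity_csv",
    "read_dissimilarity_csv",
]

_HEADER = ["subject", "time", "value"]
_MIN_OBS = 4


def read_long_csv(path, strict: bool = False) -> list[Subject]:
    """Read subjects from a long-format CSV.

    Times are sorted ascending per subject.  Subjects with fewer than
    four observations cannot be smoothed; they are dropped with a
    warning, or rejected outright when ``strict`` is true.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    if list(df.columns) != _HEADER:
        raise ValidationError(
            f"{path}: header must be exactly 'subject,time,value', got {list(df.columns)}"
        )
    for col in ("time", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise ValidationError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise ValidationError(f"{path}: missing {col!r} at line {row + 2}")
        df[col] = parsed.astype(float)
    dup = df.duplicated(subset=["subject", "time"], keep=False)
    if dup.any():
        s, t = df.loc[dup.idxmax(), ["subject", "time"]]
        raise ValidationError(f"{path}: duplicate (subject, time) record ({s!r}, {t})")

    subjects: list[Subject] = []
    small: list[str] = []
    for sid, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values("time")
        if len(grp) < _MIN_OBS:
            small.append(str(sid))
            continue
        subjects.append(
            Subject(id=str(sid), times=grp["time"].to_numpy(), values=grp["value"].to_numpy())
        )
    if small:
        msg = f"{path}: subjects with fewer than {_MIN_OBS} observations rejected: {small}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    if not subjects:
        raise ValidationError(f"{path}: no usable subjects")
    return subjects


def write_long_csv(subjects: list[Subject], path) -> None:
    """Write subjects in the long-format dialect read by :func:`read_long_csv`."""
    frames = [
        pd.DataFrame({"subject": s.id, "time": s.times, "value": s.values})
        for s in subjects
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def subjects_from_wide(df: pd.DataFrame) -> list[Subject]:
    """Convert a wide panel (index = subject, columns = times) by dropping NAs."""
    subjects = []
    times = np.asarray([float(c) for c in df.columns])
    for sid, row in df.iterrows():
        mask = row.notna().to_numpy()
        subjects.append(Subject(id=str(sid), times=times[mask], values=row.to_numpy(float)[mask]))
    return subjects


def write_dissimilarity_csv(D: DissimilarityMatrix, path) -> None:
    """Square CSV with subject ids as both header row and first column."""
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(path, float_format="%.17g")


def read_dissimilarity_csv(path) -> DissimilarityMatrix:
    """Read a square dissimilarity CSV, re-validating all matrix invariants."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: row and column ids differ")
    values = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(values - values.T))) if len(ids) else 0.0
    scale = max(1.0, float(np.max(np.abs(values)))) if len(ids) else 1.0
    if asym > 1e-12 * scale:
        raise ValidationError(f"{path}: matrix not symmetric, max |D - D'| = {asym:g}")
    try:
        return DissimilarityMatrix(ids=ids, values=values)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
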