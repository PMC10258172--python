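"""Delimited-text I/O for subject records, curves and result tables.

Subject records are comma-delimited with a header; recognised columns
are ``id``, ``entry`` (optional; missing means no delayed entry),
``time``, ``status`` and any number of covariate columns (``z1``,
``z2``, ... or arbitrary names).  Output files carry a ``#``-prefixed
metadata block (package version, seed, command line) so that any result
can be reproduced from its own header.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd

from .core import Sample, make_sample

__all__ = [
    "frame_to_sample",
    "sample_to_frame",
    "read_records",
    "write_records",
    "write_results",
]

RESERVED = ("id", "entry", "time", "status")


def frame_to_sample(df: pd.DataFrame, covariates=None, d=None) -> Sample:
    """Build a :class:`Sample` from a records DataFrame.

    ``covariates`` selects covariate columns; by default every column
    not in ``{id, entry, time, status}`` (and not a previously appended
    ``pseudo``/``weight`` column) is used, in order.
    """
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "status" not in cols:
        raise ValueError("records need 'time' and 'status' columns")
    if covariates is None:
        covariates = [c for c in df.columns
                      if c.lower() not in RESERVED + ("pseudo", "weight")]
    entry = df[cols["entry"]].to_numpy(float) if "entry" in cols else None
    Z = df[list(covariates)].to_numpy(float) if covariates else None
    return make_sample(
        time=df[cols["time"]].to_numpy(float),
        status=df[cols["status"]].to_numpy(),
        entry=entry,
        covariates=Z,
        d=d,
    )


def sample_to_frame(sample: Sample, ids=None, covariate_names=None) -> pd.DataFrame:
    k = sample.covariates.shape[1]
    if covariate_names is None:
        covariate_names = [f"z{j + 1}" for j in range(k)]
    data = {
        "id": np.arange(sample.n) if ids is None else ids,
        "entry": sample.entry,
        "time": sample.time,
        "status": sample.status,
    }
    for j, name in enumerate(covariate_names):
        data[name] = sample.covariates[:, j]
    return pd.DataFrame(data)


def read_records(path) -> tuple[Sample, pd.DataFrame]:
    """Read a subject-record file; returns (sample, raw DataFrame).

    Non-numeric fields and duplicate ids raise descriptive errors with
    row numbers; a missing ``entry`` column means all entries are zero.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip() for c in df.columns]
    cols = [c.lower() for c in df.columns]
    if "time" not in cols or "status" not in cols:
        raise ValueError(f"{path}: header must contain 'time' and 'status'")
    if "id" in cols:
        ids = df[df.columns[cols.index("id")]]
        dup = ids.duplicated()
        if dup.any():
            raise ValueError(
                f"{path}: duplicate id {ids[dup].iloc[0]!r} at row "
                f"{int(np.flatnonzero(dup)[0])}"
            )
    for c in df.columns:
        if c.lower() == "id":
            continue
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad = df[c].apply(lambda v: not _is_number(v))
            row = int(np.flatnonzero(bad)[0]) if bad.any() else 0
            raise ValueError(f"{path}: non-numeric value in column {c!r}, row {row}")
    return frame_to_sample(df), df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (ValueError, TypeError):
        return False


def write_records(sample: Sample, path, ids=None, extra: dict = None,
                  meta: dict = None) -> None:
    """Write subject records, optionally with appended columns (pseudo, weight)."""
    df = sample_to_frame(sample, ids=ids)
    for name, col in (extra or {}).items():
        df[name] = col
    _write_with_header(df, path, meta)


def write_results(table: pd.DataFrame, path, meta: dict = None) -> None:
    """Write a result table as delimited text with a '#' metadata block."""
    _write_with_header(table, path, meta)


def _write_with_header(df: pd.DataFrame, path, meta: dict = None) -> None:
    from . import __version__

    lines = [f"# ijpseudo {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(f"# command: {' '.join(sys.argv)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
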