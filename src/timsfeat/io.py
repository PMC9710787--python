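"""Tabular readers and writers for point clouds, feature tables and windows.

All formats are plain delimited text (comma separated, one header row) so runs
are diffable and portable.  Conversion from vendor raw formats is external to
the package: any converter that emits ``frame_id,rt,scan,inv_k0,mz,intensity``
rows (RT in seconds) produces a valid input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Feature, ParseError, PointCloud, SchemaError, POINT_COLUMNS

logger = logging.getLogger(__name__)

#: Stable column order of the feature table.
FEATURE_COLUMNS = [
    "mono_mz",
    "charge",
    "intensity",
    "rt_apex",
    "rt_lo",
    "rt_hi",
    "scan_apex",
    "scan_lo",
    "scan_hi",
    "num_isotopes",
    "deconvolution_score",
    "coelution_coefficient",
    "mobility_coefficient",
    "identifiability_score",
]

WINDOW_COLUMNS = ["mz_lo", "mz_hi", "scan_lo", "scan_hi", "rt_lo", "rt_hi"]

_INT_POINT_COLS = {"frame_id", "scan"}


def _load_table(path: str | Path, fmt: str) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "parquet":
        return pd.read_parquet(path)
    raise ValueError(f"unsupported format: {fmt!r}")


def read_point_cloud(
    path: str | Path, fmt: str = "csv", on_bad: str = "error"
) -> PointCloud:
    """Read a tabular point cloud.

    Parameters
    ----------
    path
        File with columns ``frame_id, rt, scan, inv_k0, mz, intensity``.
    fmt
        ``"csv"`` (default) or ``"parquet"``.
    on_bad
        ``"error"`` raises :class:`ParseError` naming the first offending row;
        ``"drop"`` rejects malformed rows, logging how many and why, so that
        accepted + rejected always equals the input row count.
    """
    if on_bad not in ("error", "drop"):
        raise ValueError("on_bad must be 'error' or 'drop'")
    raw = _load_table(path, fmt)
    missing = [c for c in POINT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    raw = raw.loc[:, POINT_COLUMNS]

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1).to_numpy()
    invalid = np.zeros(len(raw), dtype=bool)
    ok = ~bad_rows
    sub = numeric.loc[ok]
    invalid[ok] = (
        (sub["intensity"] < 0)
        | (sub["mz"] <= 0)
        | (sub["rt"] < 0)
        | (sub["scan"] < 0)
    ).to_numpy()
    reject = bad_rows | invalid

    if reject.any():
        first = int(np.flatnonzero(reject)[0])
        reason = (
            "non-numeric or missing cell"
            if bool(bad_rows[first])
            else "field out of valid range"
        )
        if on_bad == "error":
            raise ParseError(f"row {first}: {reason}")
        logger.warning(
            "rejected %d of %d rows (%d malformed, %d out-of-range); "
            "first bad row %d: %s",
            int(reject.sum()), len(raw), int(bad_rows.sum()),
            int(invalid.sum()), first, reason,
        )
    accepted = numeric[~reject].astype({c: np.int64 for c in _INT_POINT_COLS})
    logger.info("read %d points from %s (%d rejected)", len(accepted), path,
                int(reject.sum()))
    return PointCloud(accepted)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    cloud.df.to_csv(path, index=False)


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    """Write one row per feature in the stable column order.

    An unset identifiability score is written as an empty cell.
    """
    rows = []
    for f in features:
        rows.append({c: getattr(f, c) for c in FEATURE_COLUMNS})
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> list[Feature]:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    out: list[Feature] = []
    for _, r in df.iterrows():
        score = r["identifiability_score"]
        out.append(
            Feature(
                mono_mz=float(r["mono_mz"]),
                charge=int(r["charge"]),
                intensity=float(r["intensity"]),
                rt_apex=float(r["rt_apex"]),
                rt_lo=float(r["rt_lo"]),
                rt_hi=float(r["rt_hi"]),
                scan_apex=int(r["scan_apex"]),
                scan_lo=int(r["scan_lo"]),
                scan_hi=int(r["scan_hi"]),
                num_isotopes=int(r["num_isotopes"]),
                deconvolution_score=float(r["deconvolution_score"]),
                coelution_coefficient=float(r["coelution_coefficient"]),
                mobility_coefficient=float(r["mobility_coefficient"]),
                identifiability_score=None if pd.isna(score) else float(score),
            )
        )
    return out


def read_windows(path: str | Path) -> pd.DataFrame:
    """Read an isolation-window table ``mz_lo,mz_hi,scan_lo,scan_hi,rt_lo,rt_hi``."""
    df = pd.read_csv(path)
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return df.loc[:, WINDOW_COLUMNS]


def read_labelled_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read classifier training data.

    Expects ``deconvolution_score,coelution_coefficient,mobility_coefficient,
    num_isotopes,label`` with label in {identified, not_identified} or {1, 0}.
    Returns ``(X, y)`` with X of shape (n, 4) and y in {0, 1}.
    """
    df = pd.read_csv(path)
    cols = [
        "deconvolution_score",
        "coelution_coefficient",
        "mobility_coefficient",
        "num_isotopes",
    ]
    missing = [c for c in cols + ["label"] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    X = df[cols].to_numpy(float)
    lab = df["label"]
    if lab.dtype == object:
        mapping = {"identified": 1, "not_identified": 0}
        unknown = set(lab) - set(mapping)
        if unknown:
            raise ParseError(f"unknown label value(s): {sorted(unknown)}")
        y = lab.map(mapping).to_numpy(np.int64)
    else:
        y = lab.to_numpy(np.int64)
    return X, y
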