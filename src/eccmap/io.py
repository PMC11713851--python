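"""Readers/writers for the interchange tables.

All tables are UTF-8, tab-separated, '.' decimal, with '#'-prefixed header
comment lines carrying the schema version and the resolved-config hash.
Floats are serialized at full precision so write -> read round-trips are
value-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: required columns of the vertex fit table (extra columns are preserved)
FITS_COLUMNS = ("vertex_id", "x", "y", "sigma", "n", "gain", "r2", "rmse",
                "ecc", "angle")
FIXATION_COLUMNS = ("participant", "clip", "time_s", "gx_px", "gy_px")


def write_table(df: pd.DataFrame, path: str | Path,
                config_hash: str = "unconfigured") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(f"# config_hash={config_hash}\n")
        # default float formatting is shortest-round-trip, i.e. exact
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


def write_fits(df: pd.DataFrame, path: str | Path,
               config_hash: str = "unconfigured") -> Path:
    missing = [c for c in FITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fit table missing columns: {', '.join(missing)}")
    return write_table(df, path, config_hash)


def read_fits(path: str | Path) -> pd.DataFrame:
    """Read a vertex fit table; unknown extra columns are preserved.

    Rows with non-finite r2 are kept but flagged (``valid`` = False); the
    downstream variance-explained threshold excludes them anyway.
    """
    df = read_table(path)
    missing = [c for c in FITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fit table missing columns: {', '.join(missing)}")
    for col in FITS_COLUMNS:
        if col != "vertex_id":
            df[col] = df[col].astype(float)
    df["valid"] = np.isfinite(df["r2"])
    return df


def read_fixations(path: str | Path) -> pd.DataFrame:
    """Read a fixation log; invalid/out-of-range samples flagged, not dropped.

    The ``valid`` column is honored when present and combined with a range
    check (gaze coordinates must be finite and non-negative).
    """
    path = Path(path)
    df = read_table(path)
    if df.empty:
        raise ValueError(f"{path}: empty fixation log")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation log missing columns: {', '.join(missing)}")
    for col in ("time_s", "gx_px", "gy_px"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.values)[0]) + 4  # 2 comments + header
            raise ValueError(f"{path}: unparseable value in column "
                             f"{col!r} at line {line}") from None
    in_range = (np.isfinite(df["gx_px"]) & np.isfinite(df["gy_px"])
                & (df["gx_px"] >= 0) & (df["gy_px"] >= 0))
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool) & in_range
    else:
        df["valid"] = in_range
    return df


def write_masks(frames, out_dir: str | Path) -> Path:
    """Write label masks as indexed PNGs (palette 0 other, 1 face, 2 body)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:04d}.png", frame.mask)
    return out_dir


def read_masks(in_dir: str | Path, frame_index: pd.DataFrame | None = None):
    import imageio.v3 as iio

    from .gaze import LabeledFrame

    in_dir = Path(in_dir)
    frames = []
    for i, p in enumerate(sorted(in_dir.glob("frame_*.png"))):
        mask = np.asarray(iio.imread(p))
        t, clip = 0.0, 0
        if frame_index is not None and i < len(frame_index):
            clip = int(frame_index.iloc[i]["clip"])
            t = float(frame_index.iloc[i]["time_s"])
        frames.append(LabeledFrame(mask=mask, frame_time=t, clip_id=clip))
    return frames
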