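"""Category-selective ROI definition and random-effects pRF comparisons.

ROIs are defined from a block-design localizer: an ordinary-least-squares
GLM with HRF-convolved boxcar regressors yields a per-vertex t statistic for
a contrast (category of interest > all other categories), thresholded at
t > 3 (strictly) within an anatomical mask. pRF properties are then
summarized per participant per ROI over vertices passing the variance-
explained filter (R^2 > 0.1), and compared across ROIs with paired,
two-tailed t tests — random-effects discipline: one number per participant
per ROI enters every group statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze import PairedTestResult, paired_ttest
from .prf import HRFSpec, convolve_hrf

#: pRF properties a ParticipantSummary row carries
SUMMARY_PROPS = ("ecc", "sigma", "y", "lower_field_pct", "r2")


@dataclass
class ROILabel:
    """Named vertex set (e.g., OTS-limb, pFus-face, CoS-place) in one hemisphere."""

    name: str
    hemisphere: str
    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.unique(np.asarray(self.vertices, dtype=int))

    @property
    def empty(self) -> bool:
        return len(self.vertices) == 0


def write_label(label: ROILabel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {label.name}\t{label.hemisphere}\n")
        for v in label.vertices:
            fh.write(f"{v}\n")


def read_label(path: str | Path) -> ROILabel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        name, hemi = header[0], (header[1] if len(header) > 1 else "rh")
        verts = [int(line.split()[0]) for line in fh if line.strip()]
    return ROILabel(name=name, hemisphere=hemi, vertices=np.array(verts, dtype=int))


def build_block_design(onsets: dict, n_timepoints: int, tr: float,
                       hrf: HRFSpec = HRFSpec()) -> tuple[np.ndarray, list]:
    """HRF-convolved boxcar design matrix with a trailing intercept column.

    ``onsets`` maps condition name -> list of (onset_s, duration_s).
    """
    if len(onsets) < 2:
        raise ValueError("need at least 2 conditions")
    kernel = hrf.kernel(tr)
    names = sorted(onsets)
    cols = []
    t = np.arange(n_timepoints) * tr
    for name in names:
        box = np.zeros(n_timepoints)
        for onset, dur in onsets[name]:
            box[(t >= onset) & (t < onset + dur)] = 1.0
        cols.append(convolve_hrf(box, kernel))
    X = np.column_stack(cols + [np.ones(n_timepoints)])
    return X, names


def glm_contrast(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
                 t_cap: float = 1e6) -> np.ndarray:
    """Per-vertex contrast t statistics from an OLS fit of design X.

    Y is (T, V); contrast is a weight vector over the columns of X
    (typically zero on the intercept). Noiseless vertices would have an
    infinite t; those are capped at ``t_cap`` with the sign of the contrast.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design/series length mismatch")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = Y.shape[0] - X.shape[1]
    mse = np.einsum("tv,tv->v", resid, resid) / df
    var_c = float(c @ xtx_inv @ c)
    eff = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(mse * var_c)
    t = np.where(np.isfinite(t), t, np.sign(eff) * t_cap)
    return np.clip(t, -t_cap, t_cap)


def define_roi(tmap: np.ndarray, threshold: float, anatomical_mask: np.ndarray,
               name: str, hemisphere: str = "rh") -> ROILabel:
    """Vertices in the mask with t strictly above threshold."""
    mask = np.asarray(anatomical_mask, dtype=int)
    if len(mask) == 0:
        raise ValueError("anatomical mask is empty")
    keep = mask[np.asarray(tmap)[mask] > threshold]
    if len(keep) == 0:
        warnings.warn(f"ROI {name} is empty at t > {threshold}", stacklevel=2)
    return ROILabel(name=name, hemisphere=hemisphere, vertices=keep)


def summarize_roi(fits: pd.DataFrame, roi: ROILabel,
                  r2_min: float = 0.1) -> dict:
    """One ParticipantSummary row: mean ecc/sigma/y, lower-field %, counts.

    Only vertices with r2 > r2_min (strict) contribute. Returns NaNs (a
    missing-value row) when no vertex survives; callers drop such rows from
    paired comparisons.
    """
    if roi.empty:
        raise ValueError("ROI is empty")
    sub = fits[fits["vertex_id"].isin(roi.vertices)]
    sub = sub[np.isfinite(sub["r2"]) & (sub["r2"] > r2_min)]
    if len(sub) == 0:
        return {"roi": roi.name, "n_vertices": 0, "ecc": np.nan,
                "sigma": np.nan, "y": np.nan, "lower_field_pct": np.nan,
                "r2": np.nan}
    return {
        "roi": roi.name,
        "n_vertices": int(len(sub)),
        "ecc": float(sub["ecc"].mean()),
        "sigma": float(sub["sigma"].mean()),
        "y": float(sub["y"].mean()),
        "lower_field_pct": float(100.0 * (sub["y"] < 0).mean()),
        "r2": float(sub["r2"].mean()),
    }


def summarize_participants(fits: pd.DataFrame, rois_by_participant: dict,
                           r2_min: float = 0.1) -> pd.DataFrame:
    """ParticipantSummary table: one row per (participant, ROI).

    ``rois_by_participant`` maps participant id -> list of ROILabel (vertex
    ids are per-participant). ``fits`` must carry a ``participant`` column.
    """
    rows = []
    for pid, rois in sorted(rois_by_participant.items()):
        pf = fits[fits["participant"] == pid]
        for roi in rois:
            if roi.empty:
                continue
            row = summarize_roi(pf, roi, r2_min=r2_min)
            row["participant"] = pid
            rows.append(row)
    if not rows:
        raise ValueError("no ROI summaries produced")
    return pd.DataFrame(rows)


def paired_compare(summaries: pd.DataFrame, roi_a: str, roi_b: str,
                   prop: str = "ecc") -> PairedTestResult:
    """Paired two-tailed t test of a pRF property between two ROIs.

    Participants lacking either ROI (missing row or NaN property after
    thresholding) are excluded; at least 3 complete pairs are required.
    """
    if prop not in SUMMARY_PROPS:
        raise ValueError(f"unknown property {prop!r}")
    wide = summaries.pivot_table(index="participant", columns="roi",
                                 values=prop, aggfunc="first")
    if roi_a not in wide.columns or roi_b not in wide.columns:
        raise ValueError("fewer than 3 complete pairs")
    pair = wide[[roi_a, roi_b]].dropna()
    if len(pair) < 3:
        raise ValueError("fewer than 3 complete pairs")
    return paired_ttest(pair[roi_a].values, pair[roi_b].values)


def rank_rois(summaries: pd.DataFrame, prop: str = "ecc") -> pd.DataFrame:
    """ROIs sorted ascending by group-mean property; ties broken by name."""
    if prop not in SUMMARY_PROPS:
        raise ValueError(f"unknown property {prop!r}")
    g = (summaries.groupby("roi")[prop].agg(["mean", "count"])
         .reset_index().rename(columns={"mean": f"{prop}_mean",
                                        "count": "n_participants"}))
    return (g.sort_values([f"{prop}_mean", "roi"], kind="mergesort")
            .reset_index(drop=True))
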