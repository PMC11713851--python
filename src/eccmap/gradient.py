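"""Eccentricity gradients across seven ordered anatomical ROIs.

The headline analysis: mean pRF eccentricity per participant in seven
anatomically defined ROIs ordered along the medial-to-lateral axis
(CoS, FG-medial, FG-lateral, OTS, ITG, ITS, MTG; positions coded 1..7),
a one-way within-subject ANOVA over positions, and a descriptive
linear-vs-quadratic model comparison. A "reversal" verdict — the U-shaped
gradient with a trough near the lateral fusiform — requires an upward
quadratic coefficient, a trough strictly inside the ROI range, and a
quadratic R^2 advantage over the linear fit above a margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

ANAT_ROI_ORDER = ("CoS", "FG-medial", "FG-lateral", "OTS", "ITG", "ITS", "MTG")

log = logging.getLogger(__name__)


@dataclass
class EccentricityMatrix:
    """participants x ordered-ROI-positions mean-eccentricity table (DVA).

    ``data`` is a DataFrame indexed by participant with one column per
    anatomical ROI in medial-to-lateral order; positions are coded 1..7.
    """

    data: pd.DataFrame
    hemisphere: str = "rh"

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.data.shape[1] + 1)

    def complete(self) -> pd.DataFrame:
        return self.data.dropna(axis=0)

    def long(self) -> pd.DataFrame:
        d = self.data.copy()
        d.columns = self.positions
        out = d.reset_index(names="participant").melt(
            id_vars="participant", var_name="position", value_name="ecc")
        return out.dropna()


@dataclass
class GradientFit:
    """Linear and quadratic OLS fits of eccentricity on ROI position."""

    linear: dict
    quadratic: dict
    trough: float
    n_points: int

    @property
    def delta_r2(self) -> float:
        return self.quadratic["r2"] - self.linear["r2"]


def build_matrix(fits: pd.DataFrame, anat_labels_by_participant: dict,
                 r2_min: float = 0.1, hemisphere: str = "rh") -> EccentricityMatrix:
    """Mean eccentricity per participant per ordered anatomical ROI.

    ``anat_labels_by_participant`` maps participant -> ordered list of
    ROILabel (medial to lateral). Cell (p, k) averages that participant's
    vertices in ROI k with r2 > r2_min; participants with no surviving
    vertex anywhere are dropped with a warning.
    """
    rows = {}
    for pid, labels in sorted(anat_labels_by_participant.items()):
        pf = fits[fits["participant"] == pid] if "participant" in fits else fits
        pf = pf[np.isfinite(pf["r2"]) & (pf["r2"] > r2_min)]
        row = {}
        for label in labels:
            sub = pf[pf["vertex_id"].isin(label.vertices)]
            row[label.name] = float(sub["ecc"].mean()) if len(sub) else np.nan
        if all(np.isnan(v) for v in row.values()):
            log.warning("participant %s has no surviving vertices; dropped", pid)
            continue
        rows[pid] = row
    if not rows:
        raise ValueError("no participants with surviving vertices")
    first = next(iter(anat_labels_by_participant.values()))
    order = [lab.name for lab in first]
    df = pd.DataFrame.from_dict(rows, orient="index")[order]
    df.index.name = "participant"
    return EccentricityMatrix(data=df, hemisphere=hemisphere)


def rm_anova(matrix: EccentricityMatrix) -> dict:
    """One-way within-subject ANOVA of eccentricity over ROI positions.

    Standard decomposition: SS_total = SS_subjects + SS_conditions +
    SS_error, F = MS_cond / MS_error with df = (k-1, (k-1)(n-1)); no
    sphericity correction. Incomplete rows are listwise-deleted (count
    logged). Identical columns yield F = 0, p = 1.
    """
    from scipy import stats as sps

    full = matrix.data
    d = matrix.complete()
    dropped = len(full) - len(d)
    if dropped:
        log.info("rm_anova: %d incomplete participants excluded", dropped)
    n, k = d.shape
    if n < 3:
        raise ValueError("need at least 3 complete participants")
    vals = d.values
    grand = vals.mean()
    ss_subj = k * np.sum((vals.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((vals.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((vals - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ss_cond <= 1e-12 * max(ss_tot, 1.0):
        return {"F": 0.0, "df_effect": df1, "df_error": df2, "p": 1.0, "n": n}
    if ms_err <= 0:
        return {"F": np.inf, "df_effect": df1, "df_error": df2, "p": 0.0, "n": n}
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return {"F": float(F), "df_effect": df1, "df_error": df2, "p": p, "n": n}


def _poly_fit(x: np.ndarray, y: np.ndarray, deg: int) -> dict:
    coef = np.polyfit(x, y, deg)
    pred = np.polyval(coef, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - pred) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / len(y)))
    return {"coef": coef, "r2": float(r2), "rmse": rmse}


def fit_gradient_models(matrix: EccentricityMatrix,
                        mode: str = "cells") -> GradientFit:
    """Linear and quadratic OLS of eccentricity on position 1..k.

    mode="cells" (default) pools every participant-ROI cell as one point;
    mode="means" fits the k group means instead. The quadratic trough is
    -b/(2c) when the quadratic coefficient c is positive, else NaN.
    """
    if mode not in ("cells", "means"):
        raise ValueError("mode must be 'cells' or 'means'")
    longd = matrix.long()
    if mode == "means":
        g = longd.groupby("position")["ecc"].mean().reset_index()
        x, y = g["position"].values.astype(float), g["ecc"].values
    else:
        x = longd["position"].values.astype(float)
        y = longd["ecc"].values
    if len(np.unique(x)) < 3:
        raise ValueError("need data at >= 3 distinct positions")
    lin = _poly_fit(x, y, 1)
    quad = _poly_fit(x, y, 2)
    # nested models: quadratic can never fit worse; clamp fp jitter
    if quad["r2"] < lin["r2"]:
        quad["r2"] = lin["r2"]
    c, b, _ = quad["coef"]
    trough = float(-b / (2 * c)) if c > 0 else np.nan
    linear = {"intercept": float(lin["coef"][1]), "slope": float(lin["coef"][0]),
              "r2": lin["r2"], "rmse": lin["rmse"]}
    quadratic = {"intercept": float(quad["coef"][2]), "b": float(quad["coef"][1]),
                 "c": float(c), "r2": quad["r2"], "rmse": quad["rmse"]}
    return GradientFit(linear=linear, quadratic=quadratic, trough=trough,
                       n_points=len(y))


def nested_f_test(fit: GradientFit) -> dict:
    """Optional F test of the quadratic term (not used for the verdict)."""
    from scipy import stats as sps

    n = fit.n_points
    ss_lin = fit.linear["rmse"] ** 2 * n
    ss_quad = fit.quadratic["rmse"] ** 2 * n
    df2 = n - 3
    if df2 <= 0 or ss_quad <= 0:
        return {"F": np.nan, "p": np.nan}
    F = (ss_lin - ss_quad) / (ss_quad / df2)
    return {"F": float(F), "p": float(sps.f.sf(F, 1, df2))}


def detect_reversal(fit: GradientFit, n_positions: int = 7,
                    margin: float = 0.02) -> dict:
    """Classify the gradient: reversal (U-shape), monotone, or inconclusive.

    Reversal requires an upward quadratic (c > 0), a trough strictly inside
    (1, n_positions), and quadratic R^2 exceeding linear R^2 by ``margin``.
    An upward quadratic whose trough falls outside the ROI range is
    monotone (the U is not expressed within the sampled ROIs); an upward
    quadratic with an in-range trough but sub-margin R^2 gain is
    inconclusive.
    """
    c = fit.quadratic["c"]
    if c <= 0:
        return {"verdict": "monotone", "trough": np.nan}
    trough = fit.trough
    if not (1 < trough < n_positions):
        return {"verdict": "monotone", "trough": trough}
    if fit.delta_r2 > margin:
        return {"verdict": "reversal", "trough": trough}
    return {"verdict": "inconclusive", "trough": trough}
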