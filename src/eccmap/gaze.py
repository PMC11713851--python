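"""Naturalistic-viewing statistics: fixations on category-labeled frames.

Frames extracted from movie clips carry a per-pixel category mask (0 =
other/scene, 1 = face, 2 = body). Combining them with eye-tracking
fixations yields (a) the fraction of frames on which each category was
fixated, (b) per-frame pixel coverage per category, and (c) the
fixation-centered "retinal image": each frame translated so the gaze point
sits at the screen center, averaged into per-category probability images
whose marginal profiles quantify where faces and bodies fall on the retina.

Screen pixel coordinates follow the image convention (y down, origin top
left); conversion to visual-field degrees (y up) happens in exactly one
place, :meth:`ScreenGeometry.pixel_to_degrees`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORIES = ("other", "face", "body")
OTHER, FACE, BODY = 0, 1, 2


def visual_angle(extent_mm: float, distance_mm: float) -> float:
    """Visual angle in degrees subtended by ``extent_mm`` at ``distance_mm``."""
    if extent_mm <= 0 or distance_mm <= 0:
        raise ValueError("extent and distance must be positive")
    return float(np.degrees(2.0 * np.arctan(extent_mm / (2.0 * distance_mm))))


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing monitor geometry; assumes square pixels.

    Defaults are the study monitor: 597 mm wide at 570 mm viewing distance,
    2,560 x 1,440 px, i.e. about 55 x 33 degrees of visual angle.
    """

    width_mm: float = 597.0
    distance_mm: float = 570.0
    res_x: int = 2560
    res_y: int = 1440

    def __post_init__(self):
        if min(self.width_mm, self.distance_mm, self.res_x, self.res_y) <= 0:
            raise ValueError("screen geometry values must be positive")

    @property
    def height_mm(self) -> float:
        return self.width_mm * self.res_y / self.res_x

    @property
    def width_deg(self) -> float:
        return visual_angle(self.width_mm, self.distance_mm)

    @property
    def height_deg(self) -> float:
        return visual_angle(self.height_mm, self.distance_mm)

    @property
    def ppd(self) -> float:
        """Pixels per degree (linear approximation across the screen)."""
        return self.res_x / self.width_deg

    @property
    def center_px(self) -> tuple[int, int]:
        """(cx, cy) pixel brought to the fovea by the centering step."""
        return self.res_x // 2, self.res_y // 2

    def pixel_to_degrees(self, px_x, px_y) -> tuple[np.ndarray, np.ndarray]:
        """Screen pixels -> visual-field DVA relative to center, y up."""
        cx, cy = self.center_px
        return ((np.asarray(px_x) - cx) / self.ppd,
                (cy - np.asarray(px_y)) / self.ppd)


@dataclass
class LabeledFrame:
    """Category mask for one extracted frame (uint8: 0 other, 1 face, 2 body)."""

    mask: np.ndarray
    frame_time: float = 0.0
    clip_id: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")


@dataclass
class FixationRecord:
    participant_id: int
    clip_id: int
    time: float
    gx: float
    gy: float
    valid: bool = True


@dataclass
class RetinalImage:
    """Fixation-centered average category-probability images.

    ``probs[cat]`` holds the probability of observing the category at each
    retinal location across contributing frames; shift padding contributes
    to no category (it is off-screen content, not scene), so the three
    images sum to coverage/n <= 1 pixelwise. ``coverage`` counts how many
    shifted frames carried actual content at each pixel. In
    padding="scene" mode padding is counted as the scene category and the
    images sum to exactly 1.
    """

    probs: dict
    coverage: np.ndarray
    n_frames: int
    geometry: ScreenGeometry


def extract_frame_times(duration: float, rate: float = 0.2) -> np.ndarray:
    """Deterministic frame-sampling times at bin midpoints (k + 0.5) / rate.

    A clip shorter than one period contributes a single mid-clip frame.
    """
    if duration <= 0:
        raise ValueError("empty clip")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(np.floor(duration * rate))
    if n == 0:
        return np.array([duration / 2.0])
    return (np.arange(n) + 0.5) / rate


def extract_frames(clip: np.ndarray, duration: float, rate: float = 0.2):
    """Sample frames from a (N, H, W) clip array at ``extract_frame_times``."""
    clip = np.asarray(clip)
    if clip.ndim != 3 or len(clip) == 0:
        raise ValueError("empty clip")
    times = extract_frame_times(duration, rate)
    src_times = (np.arange(len(clip)) + 0.5) * (duration / len(clip))
    idx = np.abs(src_times[None, :] - times[:, None]).argmin(axis=1)
    return clip[idx], times


def fixated_category(frame: LabeledFrame, fix: FixationRecord) -> str:
    """Category of the pixel under the gaze point; raises on invalid gaze."""
    h, w = frame.mask.shape
    gx, gy = int(round(fix.gx)), int(round(fix.gy))
    if not fix.valid or not (0 <= gx < w and 0 <= gy < h):
        raise ValueError("invalid or out-of-bounds fixation")
    return CATEGORIES[frame.mask[gy, gx]]


def _valid_pairs(frames, fixations):
    for frame, fix in zip(frames, fixations):
        h, w = frame.mask.shape
        gx, gy = int(round(fix.gx)), int(round(fix.gy))
        if fix.valid and 0 <= gx < w and 0 <= gy < h:
            yield frame, fix, gx, gy


def fixation_fractions(frames, fixations) -> dict:
    """Per-category fraction of valid (frame, fixation) pairs; sums to 1."""
    counts = dict.fromkeys(CATEGORIES, 0)
    total = 0
    for frame, fix, gx, gy in _valid_pairs(frames, fixations):
        counts[CATEGORIES[frame.mask[gy, gx]]] += 1
        total += 1
    if total == 0:
        raise ValueError("no valid (frame, fixation) pairs")
    return {c: counts[c] / total for c in CATEGORIES}


def pixel_coverage(frame: LabeledFrame) -> dict:
    """Fraction of frame pixels per category; sums to 1."""
    counts = np.bincount(frame.mask.ravel(), minlength=3)
    return {c: counts[i] / frame.mask.size for i, c in enumerate(CATEGORIES)}


def center_on_fixation(frame: LabeledFrame, fix: FixationRecord,
                       geometry: ScreenGeometry):
    """Translate the frame so the gaze pixel lands at the output center.

    Output has monitor dimensions. Returns (shifted mask, observed mask);
    pixels vacated by the shift are zero in the observed mask and carry no
    category information (they are padding, not scene).
    """
    h, w = geometry.res_y, geometry.res_x
    fh, fw = frame.mask.shape
    gx, gy = int(round(fix.gx)), int(round(fix.gy))
    if not fix.valid or not (0 <= gx < fw and 0 <= gy < fh):
        raise ValueError("invalid fixation")
    cx, cy = geometry.center_px
    dx, dy = cx - gx, cy - gy
    out = np.zeros((h, w), dtype=np.uint8)
    seen = np.zeros((h, w), dtype=bool)
    src_r0, src_r1 = max(0, -dy), min(fh, h - dy)
    src_c0, src_c1 = max(0, -dx), min(fw, w - dx)
    if src_r1 > src_r0 and src_c1 > src_c0:
        out[src_r0 + dy:src_r1 + dy, src_c0 + dx:src_c1 + dx] = \
            frame.mask[src_r0:src_r1, src_c0:src_c1]
        seen[src_r0 + dy:src_r1 + dy, src_c0 + dx:src_c1 + dx] = True
    return out, seen


def average_retinal_image(frames, fixations, geometry: ScreenGeometry,
                          padding: str = "missing") -> RetinalImage:
    """Average fixation-centered category indicators over (frame, fixation) pairs.

    padding="missing" (default) lets shift padding contribute to no
    category numerator (the probability of each category is unconditional,
    over all frames); padding="scene" counts padding as the scene/other
    category, matching the zero-padded averaging of the original analysis.
    The two modes differ only in the "other" image.
    """
    if padding not in ("missing", "scene"):
        raise ValueError("padding must be 'missing' or 'scene'")
    h, w = geometry.res_y, geometry.res_x
    sums = {c: np.zeros((h, w)) for c in CATEGORIES}
    coverage = np.zeros((h, w))
    n = 0
    for frame, fix, _, _ in _valid_pairs(frames, fixations):
        shifted, seen = center_on_fixation(frame, fix, geometry)
        for i, c in enumerate(CATEGORIES):
            if c == "other" and padding == "scene":
                sums[c] += (shifted == OTHER) | ~seen
            else:
                sums[c] += (shifted == i) & seen
        coverage += seen
        n += 1
    if n == 0:
        raise ValueError("no valid (frame, fixation) pairs")
    probs = {c: sums[c] / n for c in CATEGORIES}
    return RetinalImage(probs=probs, coverage=coverage, n_frames=n,
                        geometry=geometry)


def _peak_index(profile: np.ndarray, center: float) -> int:
    """Argmax with ties broken toward the center coordinate."""
    m = np.nanmax(profile)
    ties = np.flatnonzero(profile >= m - 1e-12)
    return int(ties[np.argmin(np.abs(ties - center))])


def marginal_profiles(img: RetinalImage, axis: str = "y") -> dict:
    """Per-category marginal intensity profiles, normalized to max 1.

    axis="y": average the probability image across columns, profile over
    rows, peak coordinate reported in DVA (y up). axis="x" analogously over
    columns. All-zero categories are returned with ``peak_deg`` = NaN.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    cx, cy = img.geometry.center_px
    out = {}
    for c in CATEGORIES:
        prof = (np.mean(img.probs[c], axis=1) if axis == "y"
                else np.mean(img.probs[c], axis=0))
        m = prof.max()
        if m <= 0:
            out[c] = {"profile": prof, "coords_deg": None, "peak_deg": np.nan,
                      "defined": False}
            continue
        norm = prof / m
        center = cy if axis == "y" else cx
        idx = _peak_index(norm, center)
        if axis == "y":
            _, peak = img.geometry.pixel_to_degrees(cx, idx)
            coords = img.geometry.pixel_to_degrees(cx, np.arange(len(norm)))[1]
        else:
            peak, _ = img.geometry.pixel_to_degrees(idx, cy)
            coords = img.geometry.pixel_to_degrees(np.arange(len(norm)), cy)[0]
        out[c] = {"profile": norm, "coords_deg": coords,
                  "peak_deg": float(peak), "defined": True}
    return out


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    mean_diff: float
    n: int


def paired_ttest(a, b, alpha: float = 0.05) -> PairedTestResult:
    """Two-tailed paired t test with 95% CI of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    if np.ptp(d) == 0 and d.std() == 0:
        if np.allclose(d, 0):
            return PairedTestResult(t=0.0, df=len(d) - 1, p=1.0,
                                    ci=(0.0, 0.0), mean_diff=0.0, n=len(d))
        raise ValueError("degenerate contrast")
    res = sps.ttest_rel(a, b)
    df = len(d) - 1
    se = d.std(ddof=1) / np.sqrt(len(d))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    md = float(d.mean())
    return PairedTestResult(t=float(res.statistic), df=df,
                            p=float(res.pvalue),
                            ci=(md - tcrit * se, md + tcrit * se),
                            mean_diff=md, n=len(d))


def compare_peaks(peaks_a, peaks_b) -> PairedTestResult:
    """Paired two-tailed t test on per-participant peak coordinates."""
    return paired_ttest(peaks_a, peaks_b)


def match_fixations(fixations: pd.DataFrame, clip_id: int,
                    frame_time: float) -> pd.DataFrame:
    """One gaze sample per participant: the log sample nearest the frame time."""
    sub = fixations[fixations["clip"] == clip_id]
    if sub.empty:
        return sub
    rows = []
    for pid, grp in sub.groupby("participant", sort=True):
        i = (grp["time_s"] - frame_time).abs().idxmin()
        rows.append(grp.loc[i])
    return pd.DataFrame(rows)
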