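"""Seeded generators for every input the analysis pipeline consumes.

Three generators stand in for the study's recordings:

* :func:`gen_sheet` — a simulated cortical sheet: vertices along a
  medial-to-lateral axis a in [0, 1] split into the seven anatomical ROIs,
  with ground-truth pRF parameters whose eccentricity follows a configurable
  U-shaped (default), linear, or flat profile, plus category-selective
  clusters (limb / face / place) whose eccentricity and lower-visual-field
  biases mirror the reported group values.
* :func:`gen_bold` / :func:`gen_localizer` — BOLD time series from the
  forward pRF model (and a block-design localizer) plus white Gaussian noise.
* :func:`gen_movie_dataset` — category-labeled movie frames (face above a
  stacked body silhouette) and face-biased fixation logs.

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gaze import FACE, BODY, LabeledFrame, ScreenGeometry, extract_frame_times
from .gradient import ANAT_ROI_ORDER, EccentricityMatrix
from .prf import HRFSpec, convolve_hrf
from .roi import ROILabel, build_block_design
from .stimulus import ApertureMovie

LOCALIZER_CONDITIONS = ("cars", "faces", "feet", "hands", "houses", "words")

#: category-selective cluster -> preferred localizer condition
CLUSTER_CONDITION = {"limb": "hands", "face": "faces", "place": "houses"}


@dataclass(frozen=True)
class ClusterSpec:
    """A category-selective cluster on the simulated sheet.

    ``ecc_mean`` overrides the anatomical truth for member vertices
    (selective vertices are a biased subsample of their anatomical
    neighborhood); ``lower_prob`` is the probability that a member's pRF
    center falls in the lower visual field.
    """

    name: str
    category: str            # limb | face | place
    a_lo: float
    a_hi: float
    ecc_mean: float
    ecc_sd: float = 1.0
    lower_prob: float = 0.6
    member_frac: float = 0.5

    def __post_init__(self):
        if not (0 <= self.a_lo < self.a_hi <= 1):
            raise ValueError("invalid cluster interval")


def default_clusters() -> tuple[ClusterSpec, ...]:
    # group-mean eccentricities follow the reported values:
    # limb-selective OTS 5.8 DVA, fusiform face 3.6 DVA, place peripheral
    return (
        ClusterSpec("CoS-place", "place", 0.02, 0.10, ecc_mean=6.5,
                    ecc_sd=1.5, lower_prob=0.57),
        ClusterSpec("pFus-face", "face", 0.30, 0.38, ecc_mean=3.6,
                    ecc_sd=1.0, lower_prob=0.62),
        ClusterSpec("OTS-limb", "limb", 0.45, 0.49, ecc_mean=5.8,
                    ecc_sd=1.2, lower_prob=0.75),
    )


@dataclass(frozen=True)
class SheetSpec:
    """Ground-truth cortical sheet specification.

    The default cohort mirrors the study scale: 27 participants, 7
    anatomical ROIs, 200 vertices per ROI. The U-shaped eccentricity truth
    ecc(a) = e_min + amp * (a - trough_a)^2 places its trough at the
    FG-lateral / OTS boundary (a ~ 0.4).
    """

    n_participants: int = 27
    vertices_per_roi: int = 200
    shape: str = "u"                 # u | linear | flat
    e_min: float = 3.0
    amp: float = 10.0
    trough_a: float = 0.4
    linear_slope: float = 3.0        # for shape="linear"
    flat_level: float = 4.5          # for shape="flat"
    ecc_jitter_sd: float = 1.0
    between_sd: float = 0.5
    sigma0: float = 1.5
    sigma_slope: float = 0.8
    sigma_jitter_sd: float = 0.3
    gain: float = 1.0
    exponent: float = 0.5
    lower_field_prob: float = 0.55
    clusters: tuple[ClusterSpec, ...] = field(default_factory=default_clusters)
    hemisphere: str = "rh"
    seed: int = 0

    def ecc_truth(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if self.shape == "u":
            return self.e_min + self.amp * (a - self.trough_a) ** 2
        if self.shape == "linear":
            return self.e_min + self.linear_slope * a
        if self.shape == "flat":
            return np.full_like(a, self.flat_level)
        raise ValueError(f"unknown shape {self.shape!r}")


def gen_sheet(spec: SheetSpec) -> pd.DataFrame:
    """Ground-truth vertex table for the whole cohort.

    Columns: participant, vertex_id, anat_roi, roi_pos, cluster, a,
    x_true, y_true, sigma_true, gain_true, n_true, ecc_true, angle_true.
    Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(ANAT_ROI_ORDER)
    rows = []
    for pid in range(spec.n_participants):
        offset = rng.normal(0, spec.between_sd)
        vid = 0
        for ri, roi in enumerate(ANAT_ROI_ORDER):
            a = rng.uniform(ri / k, (ri + 1) / k, size=spec.vertices_per_roi)
            ecc = spec.ecc_truth(a) + offset + rng.normal(
                0, spec.ecc_jitter_sd, size=len(a))
            cluster = np.array([""] * len(a), dtype=object)
            lower_prob = np.full(len(a), spec.lower_field_prob)
            for cl in spec.clusters:
                inside = (a >= cl.a_lo) & (a < cl.a_hi)
                member = inside & (rng.random(len(a)) < cl.member_frac)
                cluster[member] = cl.name
                lower_prob[member] = cl.lower_prob
                # cluster eccentricity means are calibrated against the
                # U-shaped truth; under the linear/flat effect dials the
                # eccentricity truth must stay exactly that shape, so
                # members keep the local truth and only angular biases apply
                if spec.shape == "u":
                    ecc[member] = cl.ecc_mean + offset + rng.normal(
                        0, cl.ecc_sd, size=int(member.sum()))
            ecc = np.clip(ecc, 0.1, None)
            lower = rng.random(len(a)) < lower_prob
            theta = np.where(lower, rng.uniform(-np.pi, 0, len(a)),
                             rng.uniform(0, np.pi, len(a)))
            sigma = np.clip(spec.sigma0 + spec.sigma_slope * ecc
                            + rng.normal(0, spec.sigma_jitter_sd, len(a)),
                            0.3, None)
            for j in range(len(a)):
                rows.append((pid, vid + j, roi, ri + 1, cluster[j], a[j],
                             ecc[j] * np.cos(theta[j]), ecc[j] * np.sin(theta[j]),
                             sigma[j], spec.gain, spec.exponent, ecc[j],
                             np.degrees(theta[j])))
            vid += len(a)
    return pd.DataFrame(rows, columns=[
        "participant", "vertex_id", "anat_roi", "roi_pos", "cluster", "a",
        "x_true", "y_true", "sigma_true", "gain_true", "n_true", "ecc_true",
        "angle_true"])


def anat_labels(sheet: pd.DataFrame, participant: int,
                hemisphere: str = "rh") -> list[ROILabel]:
    """Ordered anatomical ROILabels (medial to lateral) for one participant."""
    pf = sheet[sheet["participant"] == participant]
    return [ROILabel(name=r, hemisphere=hemisphere,
                     vertices=pf.loc[pf["anat_roi"] == r, "vertex_id"].values)
            for r in ANAT_ROI_ORDER]


def anat_masks(sheet: pd.DataFrame, participant: int) -> dict:
    """Anatomical vertex-index masks (used to constrain functional ROIs)."""
    pf = sheet[sheet["participant"] == participant]
    return {r: pf.loc[pf["anat_roi"] == r, "vertex_id"].values
            for r in ANAT_ROI_ORDER}


def _forward_predictions(pf: pd.DataFrame, movie: ApertureMovie,
                         hrf: HRFSpec) -> np.ndarray:
    """Clean forward-model predictions, (T, V) float32, chunked over vertices."""
    T = movie.n_frames
    flat = movie.frames.reshape(T, -1).astype(np.float32)
    xx, yy = movie.geometry.coords()
    xf = xx.ravel().astype(np.float32)
    yf = yy.ravel().astype(np.float32)
    kernel = hrf.kernel(movie.frame_interval)
    xs = pf["x_true"].values.astype(np.float32)
    ys = pf["y_true"].values.astype(np.float32)
    sg = pf["sigma_true"].values.astype(np.float32)
    gn = pf["gain_true"].values.astype(np.float32)
    en = pf["n_true"].values.astype(np.float32)
    out = np.empty((T, len(pf)), dtype=np.float32)
    chunk = 2048
    for i0 in range(0, len(pf), chunk):
        sl = slice(i0, min(i0 + chunk, len(pf)))
        d2 = (xf[:, None] - xs[sl]) ** 2 + (yf[:, None] - ys[sl]) ** 2
        G = np.exp(-d2 / (2.0 * sg[sl] ** 2))
        overlap = flat @ G
        drive = gn[sl] * np.clip(overlap, 0, None) ** en[sl]
        out[:, sl] = convolve_hrf(drive, kernel)
    return out


def gen_bold(sheet: pd.DataFrame, movie: ApertureMovie,
             hrf: HRFSpec = HRFSpec(), noise_sd: float = 0.5,
             seed: int = 0) -> np.ndarray:
    """Forward-model BOLD plus white Gaussian noise, (T, n_rows) float.

    ``noise_sd`` is expressed as a fraction of the cohort's reference signal
    amplitude (median peak-to-trough of the clean predictions over vertices
    with nonzero gain), so noise_sd = 1 means noise SD equal to the signal
    amplitude. Vertices with zero gain therefore carry pure noise.
    """
    clean = _forward_predictions(sheet, movie, hrf)
    driven = sheet["gain_true"].values > 0
    amp = float(np.median(np.ptp(clean[:, driven], axis=0))) if driven.any() else 1.0
    if amp == 0:
        amp = 1.0
    rng = np.random.default_rng(seed)
    noise = rng.normal(0, noise_sd * amp, size=clean.shape)
    return clean.astype(float) + noise


def localizer_design(tr: float = 2.0, block_s: float = 4.0,
                     blocks_per_condition: int = 8, seed: int = 0):
    """Randomized block order for the category localizer.

    Returns (onsets dict, n_timepoints). Six conditions in shuffled block
    order with interspersed baseline blocks, ~209 s at the defaults.
    """
    rng = np.random.default_rng(seed)
    blocks = [c for c in LOCALIZER_CONDITIONS for _ in range(blocks_per_condition)]
    order = rng.permutation(len(blocks))
    onsets = {c: [] for c in LOCALIZER_CONDITIONS}
    t = block_s  # leading baseline block
    for i in order:
        onsets[blocks[i]].append((t, block_s))
        t += block_s
        if rng.random() < 0.1:     # occasional baseline block
            t += block_s
    n_tp = int(np.ceil((t + 12.0) / tr))
    return onsets, n_tp


def gen_localizer(sheet: pd.DataFrame, participant: int,
                  hrf: HRFSpec = HRFSpec(), tr: float = 2.0,
                  noise_sd: float = 0.3, amp_pref: float = 1.0,
                  amp_other: float = 0.3, seed: int = 0):
    """Block-design localizer BOLD for one participant's vertices.

    Cluster vertices respond with ``amp_pref`` to their preferred category
    and ``amp_other`` to the rest; unselective vertices respond equally to
    everything, so contrasts are null there. Returns (Y (T, V), X, names).
    """
    pf = sheet[sheet["participant"] == participant].sort_values("vertex_id")
    onsets, n_tp = localizer_design(tr=tr, seed=seed)
    X, names = build_block_design(onsets, n_tp, tr, hrf)
    amps = np.full((len(names), len(pf)), amp_other)
    cat_of = {}
    for cl in set(pf["cluster"]) - {""}:
        cat = cl.split("-")[-1]
        cat_of[cl] = CLUSTER_CONDITION.get(cat, None)
    for j, cl in enumerate(pf["cluster"].values):
        cond = cat_of.get(cl)
        if cond is not None:
            amps[names.index(cond), j] = amp_pref
    clean = X[:, :-1] @ amps
    rng = np.random.default_rng(seed + 1)
    return clean + rng.normal(0, noise_sd, size=clean.shape), X, names


def contrast_vector(names: list, condition: str) -> np.ndarray:
    """Category-of-interest > all-other-categories weights (+ zero intercept)."""
    c = np.full(len(names) + 1, -1.0 / (len(names) - 1))
    c[names.index(condition)] = 1.0
    c[-1] = 0.0
    return c


def gen_ecc_matrix(n_participants: int = 27, shape: str = "u",
                   spec: SheetSpec | None = None, cell_noise_sd: float = 1.0,
                   seed: int = 0) -> EccentricityMatrix:
    """Matrix-level shortcut: ROI-mean eccentricities without BOLD fitting.

    Cell (participant, ROI) = eccentricity truth at the ROI's axis midpoint
    + a participant offset + N(0, cell_noise_sd). Used for ANOVA power and
    null-verdict simulations where the pRF-fitting stage is irrelevant.
    """
    spec = replace(spec or SheetSpec(), shape=shape)
    rng = np.random.default_rng(seed)
    k = len(ANAT_ROI_ORDER)
    centers = (np.arange(k) + 0.5) / k
    truth = spec.ecc_truth(centers)
    offs = rng.normal(0, spec.between_sd, size=n_participants)
    vals = truth[None, :] + offs[:, None] + rng.normal(
        0, cell_noise_sd, size=(n_participants, k))
    df = pd.DataFrame(vals, columns=list(ANAT_ROI_ORDER))
    df.index.name = "participant"
    return EccentricityMatrix(data=df, hemisphere=spec.hemisphere)


# ---------------------------------------------------------------------------
# labeled movie frames + fixation logs

@dataclass(frozen=True)
class MovieSpec:
    """Synthetic labeled-movie dataset specification.

    Frames contain a face rectangle with a stacked body silhouette below it
    (shoulders / torso / legs); the torso is widest at ``body_peak_deg``
    below the face center, so the body's marginal-profile peak identifies
    the configured offset. Pixel sizes are chosen so net coverage
    approximates the reported 11% faces / 32% bodies / 57% scenes. The
    fixation policy lands gaze on the face with probability ``p_face``
    (study value 0.66), the visible body with ``p_body``, else background.
    """

    n_clips: int = 25
    clip_duration: float = 30.0
    screen: ScreenGeometry = ScreenGeometry(597.0, 570.0, 640, 360)
    frame_rate: float = 0.2
    face_w: int = 176
    face_h: int = 144
    face_center: tuple[int, int] = (320, 80)      # (cx, cy) base position
    body_peak_deg: float = -11.6
    shoulder_h: int = 17
    torso_half_h: int = 45
    torso_peak_w: int = 460
    torso_edge_w: int = 300
    limb_w: int = 340
    leg_len: int = 96
    jitter_x: int = 16
    jitter_y: int = 4
    p_face: float = 0.66
    p_body: float = 0.174
    # within-target gaze scatter comparable to the face's half-extent:
    # humans scan features within a face rather than a fixed point, and a
    # point-like policy leaves the face's marginal profile flat-topped,
    # making its configured (zero) offset unidentifiable
    gaze_jitter_px: float = 30.0
    tremor_px: float = 2.0
    fix_rate: float = 10.0
    invalid_prob: float = 0.005
    n_participants: int = 25
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_face <= 1 and 0 <= self.p_body <= 1
                and self.p_face + self.p_body <= 1):
            raise ValueError("fixation probabilities must sum to <= 1")
        if (self.face_w > self.screen.res_x or self.face_h > self.screen.res_y
                or self.torso_peak_w > self.screen.res_x):
            raise ValueError("rectangle larger than frame")

    @property
    def p_other(self) -> float:
        return 1.0 - self.p_face - self.p_body


@dataclass
class MovieDataset:
    frames: list            # LabeledFrame per (clip, extracted frame)
    fixations: pd.DataFrame  # participant, clip, time_s, gx_px, gy_px, valid
    truth: pd.DataFrame      # per (participant, frame): intended category/target
    spec: MovieSpec

    @property
    def screen(self) -> ScreenGeometry:
        return self.spec.screen

    def frame_index(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.clip_id, f.frame_time) for f in self.frames],
            columns=["clip", "time_s"])


def _render_frame(spec: MovieSpec, rng: np.random.Generator):
    """One labeled frame plus its person geometry (face/torso anchors)."""
    s = spec.screen
    mask = np.zeros((s.res_y, s.res_x), dtype=np.uint8)
    dx = int(rng.integers(-spec.jitter_x, spec.jitter_x + 1))
    dy = int(rng.integers(-spec.jitter_y, spec.jitter_y + 1))
    fcx, fcy = spec.face_center[0] + dx, spec.face_center[1] + dy
    offset_px = int(round(abs(spec.body_peak_deg) * s.ppd))
    face_top = fcy - spec.face_h // 2
    face_bot = fcy + spec.face_h // 2
    torso_c = fcy + offset_px

    # body silhouette below the face (drawn first; face overwrites = precedence)
    r0 = face_bot
    r1 = r0 + spec.shoulder_h
    mask[max(0, r0):r1, fcx - spec.limb_w // 2: fcx + spec.limb_w // 2] = BODY
    taper = (spec.torso_peak_w - spec.torso_edge_w) / max(spec.torso_half_h, 1)
    for r in range(torso_c - spec.torso_half_h, torso_c + spec.torso_half_h + 1):
        if 0 <= r < s.res_y:
            w = int(spec.torso_peak_w - taper * abs(r - torso_c))
            mask[r, fcx - w // 2: fcx + w // 2] = BODY
    l0 = torso_c + spec.torso_half_h + 1
    mask[l0:min(l0 + spec.leg_len, s.res_y),
         fcx - spec.limb_w // 2: fcx + spec.limb_w // 2] = BODY
    mask[max(0, face_top):face_bot,
         fcx - spec.face_w // 2: fcx + spec.face_w // 2] = FACE
    return mask, (fcx, fcy, torso_c)


def gen_movie_dataset(spec: MovieSpec = MovieSpec()) -> MovieDataset:
    """Labeled frames and fixation logs for the whole eye-tracking cohort.

    The same extracted frames are shared by all participants; each
    participant's gaze for each frame bin targets the face center, the
    visible torso, or a background point per the fixation policy, with
    within-bin tremor in the 10 Hz log. Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.screen
    frames, anchors = [], []
    times = extract_frame_times(spec.clip_duration, spec.frame_rate)
    for clip in range(spec.n_clips):
        for t in times:
            mask, anchor = _render_frame(spec, rng)
            frames.append(LabeledFrame(mask=mask, frame_time=float(t),
                                       clip_id=clip))
            anchors.append(anchor)

    period = 1.0 / spec.frame_rate
    log_rows, truth_rows = [], []
    cats = ("face", "body", "other")
    probs = (spec.p_face, spec.p_body, spec.p_other)
    for pid in range(spec.n_participants):
        for fi, frame in enumerate(frames):
            fcx, fcy, torso_c = anchors[fi]
            cat = cats[rng.choice(3, p=probs)]
            if cat == "face":
                tx = fcx + rng.normal(0, spec.gaze_jitter_px)
                ty = fcy + rng.normal(0, spec.gaze_jitter_px)
                tx = np.clip(tx, fcx - spec.face_w // 2 + 2, fcx + spec.face_w // 2 - 2)
                ty = np.clip(ty, fcy - spec.face_h // 2 + 2, fcy + spec.face_h // 2 - 2)
            elif cat == "body":
                tx = fcx + rng.normal(0, spec.gaze_jitter_px)
                ty = torso_c + rng.normal(0, spec.gaze_jitter_px)
                tx = np.clip(tx, fcx - spec.torso_edge_w // 2 + 2,
                             fcx + spec.torso_edge_w // 2 - 2)
                ty = np.clip(ty, torso_c - spec.torso_half_h + 1,
                             torso_c + spec.torso_half_h - 1)
            else:
                for _ in range(100):
                    tx = rng.uniform(2, s.res_x - 2)
                    ty = rng.uniform(2, s.res_y - 2)
                    if frame.mask[int(ty), int(tx)] == 0:
                        break
                else:
                    tx, ty = 5.0, 5.0
            truth_rows.append((pid, frame.clip_id, fi, cat, tx, ty))

            bin_start = frame.frame_time - period / 2.0
            n_samp = int(round(period * spec.fix_rate))
            for si in range(n_samp):
                ts = bin_start + (si + 0.5) / spec.fix_rate
                if rng.random() < spec.invalid_prob:
                    log_rows.append((pid, frame.clip_id, ts, -1.0, -1.0, False))
                    continue
                gx = np.clip(tx + rng.normal(0, spec.tremor_px), 0, s.res_x - 1)
                gy = np.clip(ty + rng.normal(0, spec.tremor_px), 0, s.res_y - 1)
                log_rows.append((pid, frame.clip_id, ts, gx, gy, True))

    fixations = pd.DataFrame(log_rows, columns=[
        "participant", "clip", "time_s", "gx_px", "gy_px", "valid"])
    truth = pd.DataFrame(truth_rows, columns=[
        "participant", "clip", "frame_idx", "category", "target_gx", "target_gy"])
    return MovieDataset(frames=frames, fixations=fixations, truth=truth,
                        spec=spec)
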