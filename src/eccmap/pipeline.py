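"""Top-level pipeline: configuration, gaze report, and the full run.

``run_pipeline`` executes simulate -> pRF fitting -> ROI statistics ->
gradient analysis -> gaze statistics on synthetic inputs, writing every
interchange table plus the resolved configuration next to the outputs.
Identical configurations (including seeds) produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gaze as gz
from . import gradient as gr
from . import io as eio
from . import prf, roi, stimulus, synthetic

log = logging.getLogger("eccmap.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run; round-trips losslessly through YAML."""

    # stimulus / acquisition
    radius: float = 11.5
    grid_n: int = 101
    bar_width: float = 2.0
    sweep_duration: float = 30.0
    blank_duration: float = 12.0
    blank_every: int = 2
    frame_rate: float = 4.0
    tr: float = 2.0
    # model / thresholds
    hrf: prf.HRFSpec = field(default_factory=prf.HRFSpec)
    r2_min: float = 0.1
    t_threshold: float = 3.0
    reversal_margin: float = 0.02
    # synthetic cohort
    sheet: synthetic.SheetSpec = field(default_factory=synthetic.SheetSpec)
    movie: synthetic.MovieSpec = field(default_factory=synthetic.MovieSpec)
    noise_sd: float = 0.5
    loc_noise_sd: float = 0.3
    seed: int = 7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = prf.HRFSpec(**d["hrf"])
        if "sheet" in d and isinstance(d["sheet"], dict):
            sd = dict(d["sheet"])
            sd["clusters"] = tuple(
                synthetic.ClusterSpec(**c) if isinstance(c, dict) else c
                for c in sd.get("clusters", ()))
            d["sheet"] = synthetic.SheetSpec(**sd)
        if "movie" in d and isinstance(d["movie"], dict):
            md = dict(d["movie"])
            if isinstance(md.get("screen"), dict):
                md["screen"] = gz.ScreenGeometry(**md["screen"])
            if isinstance(md.get("face_center"), list):
                md["face_center"] = tuple(md["face_center"])
            d["movie"] = synthetic.MovieSpec(**md)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def preset(name: str, seed: int = 7) -> RunConfig:
    """Named configurations: 'paperlike' (study-scale) or 'fast' (smoke)."""
    if name == "paperlike":
        cfg = RunConfig(seed=seed)
    elif name == "fast":
        cfg = RunConfig(
            sheet=synthetic.SheetSpec(n_participants=8, vertices_per_roi=20),
            movie=synthetic.MovieSpec(n_clips=6, n_participants=6),
            seed=seed)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, sheet=replace(cfg.sheet, seed=seed),
                   movie=replace(cfg.movie, seed=seed))


# ---------------------------------------------------------------------------
# gaze analysis

def participant_pairs(dataset: synthetic.MovieDataset, pid: int):
    """(frame, FixationRecord) pairs: log sample nearest each frame time."""
    sub = dataset.fixations[dataset.fixations["participant"] == pid]
    groups = {c: g.sort_values("time_s").reset_index(drop=True)
              for c, g in sub.groupby("clip")}
    pairs = []
    for f in dataset.frames:
        g = groups.get(f.clip_id)
        if g is None or g.empty:
            continue
        i = (g["time_s"] - f.frame_time).abs().idxmin()
        row = g.loc[i]
        pairs.append((f, gz.FixationRecord(
            participant_id=pid, clip_id=f.clip_id, time=float(row["time_s"]),
            gx=float(row["gx_px"]), gy=float(row["gy_px"]),
            valid=bool(row["valid"]))))
    return pairs


def gaze_report(dataset: synthetic.MovieDataset,
                padding: str = "missing") -> dict:
    """Full naturalistic-viewing report for one eye-tracking cohort.

    Returns per-participant fixation fractions, per-frame pixel coverage,
    per-participant marginal-profile peak coordinates (y axis), the group
    retinal image profiles, and the paired face-vs-body peak test.
    """
    screen = dataset.screen
    pids = sorted(dataset.fixations["participant"].unique())

    frac_rows, peak_rows = [], []
    all_pairs = []
    for pid in pids:
        pairs = participant_pairs(dataset, pid)
        all_pairs.extend(pairs)
        frames = [p[0] for p in pairs]
        fixes = [p[1] for p in pairs]
        fr = gz.fixation_fractions(frames, fixes)
        fr["participant"] = pid
        frac_rows.append(fr)
        img = gz.average_retinal_image(frames, fixes, screen, padding=padding)
        prof = gz.marginal_profiles(img, axis="y")
        peak_rows.append({"participant": pid,
                          "face_peak_y": prof["face"]["peak_deg"],
                          "body_peak_y": prof["body"]["peak_deg"]})
    fractions = pd.DataFrame(frac_rows)
    peaks = pd.DataFrame(peak_rows)

    coverage = pd.DataFrame([gz.pixel_coverage(f) for f in dataset.frames])
    group_img = gz.average_retinal_image([p[0] for p in all_pairs],
                                         [p[1] for p in all_pairs],
                                         screen, padding=padding)
    profiles = gz.marginal_profiles(group_img, axis="y")
    test = gz.compare_peaks(peaks["face_peak_y"], peaks["body_peak_y"])
    return {"fractions": fractions, "coverage": coverage, "peaks": peaks,
            "group_image": group_img, "profiles_y": profiles,
            "face_vs_body_peaks": test}


# ---------------------------------------------------------------------------
# fMRI-side stages

def simulate_fmri(cfg: RunConfig):
    """Apertures, ground-truth sheet, and BOLD for the configured cohort."""
    geom = stimulus.FieldGeometry(radius=cfg.radius, grid_n=cfg.grid_n)
    movie = stimulus.make_bar_apertures(
        geom, bar_width=cfg.bar_width, sweep_duration=cfg.sweep_duration,
        blank_spec=stimulus.BlankSchedule(cfg.blank_duration, cfg.blank_every),
        frame_rate=cfg.frame_rate)
    movie_tr = stimulus.resample_to_tr(movie, cfg.tr)
    sheet = synthetic.gen_sheet(cfg.sheet)
    bold = synthetic.gen_bold(sheet, movie_tr, cfg.hrf, cfg.noise_sd,
                              seed=cfg.seed + 1000)
    return movie, movie_tr, sheet, bold


def fit_cohort(sheet: pd.DataFrame, bold: np.ndarray,
               movie_tr: stimulus.ApertureMovie, cfg: RunConfig,
               refine: bool = False) -> pd.DataFrame:
    """Batch pRF fits for every vertex, keyed by participant/vertex_id."""
    fits = prf.fit_prf_batch(bold, movie_tr, cfg.hrf, refine=refine,
                             vertex_ids=sheet["vertex_id"].values)
    fits.insert(0, "participant", sheet["participant"].values)
    return fits


def functional_rois(sheet: pd.DataFrame, cfg: RunConfig) -> dict:
    """Localizer GLM + t > threshold ROI definition per participant.

    Each cluster's functional ROI is sought within its anatomical ROI mask
    (limb in OTS, face in FG-lateral, place in CoS), mirroring the
    anatomically guided labeling of the real analysis.
    """
    cluster_anat = {"OTS-limb": "OTS", "pFus-face": "FG-lateral",
                    "CoS-place": "CoS"}
    out = {}
    for pid in sorted(sheet["participant"].unique()):
        Y, X, names = synthetic.gen_localizer(
            sheet, pid, hrf=cfg.hrf, tr=cfg.tr, noise_sd=cfg.loc_noise_sd,
            seed=cfg.seed + 2000 + int(pid))
        masks = synthetic.anat_masks(sheet, pid)
        rois = []
        for cl_name, anat in cluster_anat.items():
            cond = synthetic.CLUSTER_CONDITION[cl_name.split("-")[-1]]
            c = synthetic.contrast_vector(names, cond)
            t = roi.glm_contrast(Y, X, c)
            rois.append(roi.define_roi(t, cfg.t_threshold, masks[anat],
                                       cl_name, cfg.sheet.hemisphere))
        out[int(pid)] = rois
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write the report directory.

    Stages: simulate -> fit-prf -> roi-stats -> gradient -> gaze-stats.
    Any stage error aborts with the stage named in the raised exception.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    cfg.to_yaml(out_dir / "config_resolved.yaml")
    stage = "simulate"
    log_lines = []
    try:
        movie, movie_tr, sheet, bold = simulate_fmri(cfg)
        stimulus.write_apertures(movie_tr, out_dir / "apertures")
        eio.write_table(sheet, out_dir / "sheet_truth.tsv", h)
        log_lines.append(f"simulate: {len(sheet)} vertices, "
                         f"{movie_tr.n_frames} TRs, {movie.n_sweeps} sweeps")

        stage = "fit-prf"
        fits = fit_cohort(sheet, bold, movie_tr, cfg)
        eio.write_fits(fits, out_dir / "fits.tsv", h)
        log_lines.append(f"fit-prf: {len(fits)} fits, "
                         f"median r2 {fits['r2'].median():.3f}")

        stage = "roi-stats"
        rois = functional_rois(sheet, cfg)
        summaries = roi.summarize_participants(fits, rois, r2_min=cfg.r2_min)
        eio.write_table(summaries, out_dir / "summaries.tsv", h)
        comp_rows = []
        for prop in ("ecc", "sigma", "y", "lower_field_pct"):
            try:
                r = roi.paired_compare(summaries, "OTS-limb", "pFus-face", prop)
                comp_rows.append({"contrast": "OTS-limb_vs_pFus-face",
                                  "property": prop, "t": r.t, "df": r.df,
                                  "p": r.p, "ci_lo": r.ci[0], "ci_hi": r.ci[1],
                                  "mean_diff": r.mean_diff, "n_pairs": r.n})
            except ValueError as e:
                comp_rows.append({"contrast": "OTS-limb_vs_pFus-face",
                                  "property": prop, "t": np.nan, "df": 0,
                                  "p": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                                  "mean_diff": np.nan, "n_pairs": 0})
                log_lines.append(f"roi-stats: {prop} comparison skipped ({e})")
        eio.write_table(pd.DataFrame(comp_rows), out_dir / "comparisons.tsv", h)
        log_lines.append(f"roi-stats: {len(summaries)} summary rows")

        stage = "gradient"
        labels = {int(p): synthetic.anat_labels(sheet, p, cfg.sheet.hemisphere)
                  for p in sorted(sheet["participant"].unique())}
        matrix = gr.build_matrix(fits, labels, r2_min=cfg.r2_min,
                                 hemisphere=cfg.sheet.hemisphere)
        eio.write_table(matrix.data.reset_index(), out_dir / "ecc_matrix.tsv", h)
        anova = gr.rm_anova(matrix)
        gfit = gr.fit_gradient_models(matrix)
        verdict = gr.detect_reversal(gfit, margin=cfg.reversal_margin)
        report = pd.DataFrame([{
            "hemisphere": matrix.hemisphere,
            "anova_F": anova["F"], "anova_df_effect": anova["df_effect"],
            "anova_df_error": anova["df_error"], "anova_p": anova["p"],
            "linear_r2": gfit.linear["r2"], "linear_rmse": gfit.linear["rmse"],
            "linear_slope": gfit.linear["slope"],
            "quadratic_r2": gfit.quadratic["r2"],
            "quadratic_rmse": gfit.quadratic["rmse"],
            "quadratic_c": gfit.quadratic["c"],
            "trough_position": verdict["trough"],
            "verdict": verdict["verdict"],
        }])
        eio.write_table(report, out_dir / "gradient_report.tsv", h)
        log_lines.append(f"gradient: verdict {verdict['verdict']}, "
                         f"F={anova['F']:.2f}")

        stage = "gaze-stats"
        dataset = synthetic.gen_movie_dataset(
            replace(cfg.movie, seed=cfg.seed + 3000))
        eio.write_table(dataset.fixations, out_dir / "fixations.tsv", h)
        rep = gaze_report(dataset)
        eio.write_table(rep["fractions"], out_dir / "gaze_fractions.tsv", h)
        eio.write_table(rep["peaks"], out_dir / "gaze_peaks.tsv", h)
        t = rep["face_vs_body_peaks"]
        gsum = pd.DataFrame([{
            "face_fraction_mean": rep["fractions"]["face"].mean(),
            "body_fraction_mean": rep["fractions"]["body"].mean(),
            "other_fraction_mean": rep["fractions"]["other"].mean(),
            "face_coverage_mean": rep["coverage"]["face"].mean(),
            "body_coverage_mean": rep["coverage"]["body"].mean(),
            "other_coverage_mean": rep["coverage"]["other"].mean(),
            "face_peak_y_mean": rep["peaks"]["face_peak_y"].mean(),
            "body_peak_y_mean": rep["peaks"]["body_peak_y"].mean(),
            "peaks_t": t.t, "peaks_df": t.df, "peaks_p": t.p,
        }])
        eio.write_table(gsum, out_dir / "gaze_report.tsv", h)
        log_lines.append(f"gaze-stats: {len(rep['fractions'])} participants")
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out_dir
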