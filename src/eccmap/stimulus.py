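"""Sweeping-bar aperture movies for population receptive field mapping.

The mapping stimulus is a bar of fixed width (in degrees of visual angle,
DVA) sweeping across a circular stimulus region while the participant holds
central fixation. Only the binary aperture matters for the encoding model:
the carrier imagery inside the bar does not enter the model.

Coordinate convention (used package-wide): x positive rightward, y positive
upward (upper visual field). On the model grid, row 0 is the *top* of the
visual field, so the row index increases as y decreases. The single place
this convention is realized is :meth:`FieldGeometry.coords`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

#: sweep-axis name -> motion direction angle in degrees (bar is orthogonal)
AXIS_ANGLES = {
    "vertical": 90.0,
    "horizontal": 0.0,
    "diag45": 45.0,
    "diag135": 135.0,
}

DEFAULT_SWEEP_AXES = ("vertical", "horizontal", "diag45", "diag135")

BLANK = -1  # sweep_labels value marking blank (mean-luminance) frames


@dataclass(frozen=True)
class FieldGeometry:
    """Square model grid covering the circular stimulus region.

    Parameters
    ----------
    radius : float
        Stimulus radius in DVA (default 11.5).
    grid_n : int
        Pixels per side of the square model grid (default 101).
    """

    radius: float = 11.5
    grid_n: int = 101

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.grid_n < 16:
            raise ValueError("grid_n must be at least 16")

    @property
    def ppd(self) -> float:
        """Model-grid pixels per degree."""
        return self.grid_n / (2.0 * self.radius)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xx, yy) grid-center coordinates in DVA, row 0 = top."""
        x = np.linspace(-self.radius, self.radius, self.grid_n)
        y = np.linspace(self.radius, -self.radius, self.grid_n)
        return np.meshgrid(x, y)

    def disc_mask(self) -> np.ndarray:
        xx, yy = self.coords()
        return (xx**2 + yy**2) <= self.radius**2


@dataclass(frozen=True)
class BlankSchedule:
    """Blank (aperture-removed) segments inserted between sweeps.

    ``every=2`` inserts one blank after every second sweep; ``every=0``
    disables blanks.
    """

    duration: float = 12.0
    every: int = 2


@dataclass
class ApertureMovie:
    """Binary (or, after resampling, fractional) aperture masks over time.

    Attributes
    ----------
    frames : (T, grid_n, grid_n) float array in [0, 1]
    times : (T,) frame timestamps in seconds (bin midpoints), strictly increasing
    geometry : FieldGeometry
    sweep_labels : (T,) int array; sweep index per frame, ``BLANK`` for blanks
    """

    frames: np.ndarray
    times: np.ndarray
    geometry: FieldGeometry
    sweep_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, n, n)")
        if len(self.frames) != len(self.times):
            raise ValueError("frame count must equal len(times)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.sweep_labels is None:
            self.sweep_labels = np.full(len(self.times), BLANK, dtype=int)
        self.sweep_labels = np.asarray(self.sweep_labels, dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            return float(self.times[0]) * 2 if len(self.times) else 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Total covered duration, treating timestamps as bin midpoints."""
        return float(self.times[-1] + self.frame_interval / 2.0)

    @property
    def n_sweeps(self) -> int:
        labels = self.sweep_labels[self.sweep_labels != BLANK]
        return int(len(np.unique(labels)))

    def fingerprint(self) -> tuple:
        """Cheap content key used for prediction-grid caching."""
        import hashlib

        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.frames).tobytes())
        h.update(np.ascontiguousarray(self.times).tobytes())
        return (self.frames.shape, self.geometry, h.hexdigest())


def _bar_mask(geometry: FieldGeometry, angle_deg: float, center: float,
              bar_width: float) -> np.ndarray:
    """Binary bar orthogonal to the motion axis, clipped to the disc."""
    xx, yy = geometry.coords()
    u = np.deg2rad(angle_deg)
    proj = xx * np.cos(u) + yy * np.sin(u)
    mask = (np.abs(proj - center) <= bar_width / 2.0) & geometry.disc_mask()
    return mask.astype(float)


def make_bar_apertures(
    geometry: FieldGeometry = FieldGeometry(),
    bar_width: float = 2.0,
    sweep_axes: tuple[str, ...] = DEFAULT_SWEEP_AXES,
    directions_per_axis: int = 2,
    sweep_duration: float = 30.0,
    blank_spec: BlankSchedule = BlankSchedule(),
    frame_rate: float = 4.0,
) -> ApertureMovie:
    """Generate the sweeping-bar aperture movie.

    One contiguous sweep segment per (axis, direction) pair, in the given
    axis order with the forward direction first; the bar center advances
    linearly with time from -radius to +radius along the motion axis
    (continuous motion, sampled at ``frame_rate``). Blank segments are
    inserted per ``blank_spec``. With the defaults (4 axes x 2 directions)
    this yields the 8 sweep configurations of the mapping experiment.
    """
    if bar_width <= 0:
        raise ValueError("bar_width must be positive")
    if bar_width >= 2 * geometry.radius:
        raise ValueError("bar covers whole field")
    if not sweep_axes:
        raise ValueError("sweep_axes must be nonempty")
    if directions_per_axis < 1:
        raise ValueError("directions_per_axis must be >= 1")
    if sweep_duration <= 0:
        raise ValueError("zero-duration sweep")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    for ax in sweep_axes:
        if ax not in AXIS_ANGLES:
            raise ValueError(f"unknown sweep axis {ax!r}")

    dt = 1.0 / frame_rate
    n_per_sweep = max(1, int(round(sweep_duration * frame_rate)))
    n_blank = max(0, int(round(blank_spec.duration * frame_rate)))
    R = geometry.radius

    frames, labels = [], []
    t0 = 0.0
    times = []
    sweep_idx = 0
    zero = np.zeros((geometry.grid_n, geometry.grid_n))
    for ax in sweep_axes:
        for direction in (1, -1)[:directions_per_axis]:
            for k in range(n_per_sweep):
                frac = (k + 0.5) / n_per_sweep
                center = direction * (-R + 2 * R * frac)
                frames.append(_bar_mask(geometry, AXIS_ANGLES[ax], center, bar_width))
                times.append(t0 + (k + 0.5) * dt)
                labels.append(sweep_idx)
            t0 += n_per_sweep * dt
            sweep_idx += 1
            if blank_spec.every and sweep_idx % blank_spec.every == 0 and n_blank:
                for k in range(n_blank):
                    frames.append(zero)
                    times.append(t0 + (k + 0.5) * dt)
                    labels.append(BLANK)
                t0 += n_blank * dt
    return ApertureMovie(np.stack(frames), np.array(times), geometry,
                         np.array(labels))


def resample_to_tr(movie: ApertureMovie, tr: float) -> ApertureMovie:
    """Time-average aperture frames into TR-length bins.

    Each output frame is the mean of the source masks whose timestamps fall
    in its bin, so values lie in [0, 1]; total duration is preserved to
    within one TR. Raises if ``tr`` is shorter than the source interval.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    dt = movie.frame_interval
    if tr < dt - 1e-9:
        raise ValueError("tr shorter than source frame interval")
    if abs(tr - dt) < 1e-9:
        return replace(movie)

    n_out = int(round(movie.duration / tr))
    bins = np.minimum((movie.times // tr).astype(int), n_out - 1)
    out = np.zeros((n_out,) + movie.frames.shape[1:])
    counts = np.bincount(bins, minlength=n_out)
    np.add.at(out, bins, movie.frames)
    out /= np.maximum(counts, 1)[:, None, None]
    # output sweep label: label of the source frame nearest each bin center
    centers = (np.arange(n_out) + 0.5) * tr
    nearest = np.searchsorted(movie.times, centers)
    nearest = np.clip(nearest, 0, movie.n_frames - 1)
    left = np.clip(nearest - 1, 0, movie.n_frames - 1)
    use_left = np.abs(movie.times[left] - centers) <= np.abs(movie.times[nearest] - centers)
    nearest = np.where(use_left, left, nearest)
    labels = movie.sweep_labels[nearest]
    return ApertureMovie(out, centers, movie.geometry, labels)


def write_apertures(movie: ApertureMovie, out_dir: str | Path) -> Path:
    """Write frames as a portable array file plus a text sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "apertures.npy", movie.frames.astype(np.float32))
    sidecar = {
        "radius": float(movie.geometry.radius),
        "grid_n": int(movie.geometry.grid_n),
        "times": [float(t) for t in movie.times],
        "sweep_labels": [int(v) for v in movie.sweep_labels],
        "sweep_order": "axes in declared order, forward direction first; "
                       "blanks per schedule",
    }
    with open(out_dir / "apertures.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return out_dir


def read_apertures(in_dir: str | Path) -> ApertureMovie:
    in_dir = Path(in_dir)
    frames = np.load(in_dir / "apertures.npy").astype(float)
    with open(in_dir / "apertures.yaml") as fh:
        meta = yaml.safe_load(fh)
    geom = FieldGeometry(radius=meta["radius"], grid_n=meta["grid_n"])
    return ApertureMovie(frames, np.array(meta["times"]), geom,
                         np.array(meta["sweep_labels"]))
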