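"""Functional assay quantification: colonies, impedance (RTCA), migration.

Colony-forming assays: plate photographs are rigidly registered to a
reference carrying a hand-drawn region of interest; trypan-blue-stained
colonies are then thresholded on the b channel of CIELAB (blue means
strongly negative b) and reported as the covered area fraction.

Impedance assays (xCELLigence-style RTCA) report the unitless Cell Index

    CI(t) = (Z(t) - Z_blank(t)) / Z_nominal

normalised to 1.0 at the treatment time for comparability across wells.
The relative invasiveness of a Matrigel-coated well is its normalised CI.

Migration: per-cell speed is path length over elapsed time; the direction
distribution is summarised by a speed-weighted rose histogram and by the
summary vector — net displacement of all cells divided by total path
length, 1 for perfectly straight common motion and 0 for balanced motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.color import rgb2gray, rgb2lab
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate

__all__ = [
    "ColonyPlateImage",
    "ColonyResult",
    "RigidTransform",
    "ImpedanceSeries",
    "Track",
    "MotilitySummary",
    "RegistrationError",
    "register_to_reference",
    "colony_covered_fraction",
    "cell_index",
    "normalize_ci",
    "track_motility",
    "wound_open_fraction_stats",
    "DEFAULT_LAB_B_THRESHOLD",
]

# Single fixed Lab b-channel threshold separating blue-stained colonies from
# the plate; the midpoint between plate (b ~ +3) and stain (b ~ -74) puts the
# decision boundary at the half-coverage contour of an anti-aliased colony
# edge, keeping area fractions unbiased.  Overridable per call.
DEFAULT_LAB_B_THRESHOLD = -35.0


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Rigid misalignment of an image relative to the reference.

    `translation` is the (row, col) displacement of the image content with
    respect to the reference, measured after removing the rotation.
    """

    rotation_deg: float
    translation: tuple[float, float]  # (row, col) px
    correlation: float


@dataclass
class ColonyPlateImage:
    rgb: np.ndarray  # HxWx3 float in [0,1] or uint8
    roi: Optional[np.ndarray] = None  # bool mask (reference only)
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("expected an RGB image")
        if self.roi is not None and self.roi.shape != self.rgb.shape[:2]:
            raise ValueError("ROI must match image shape")


@dataclass
class ColonyResult:
    covered_fraction: float
    threshold: float
    transform: Optional[RigidTransform] = None


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _shift_corr(ref: np.ndarray, img: np.ndarray) -> tuple[np.ndarray, float]:
    """Best translation of img onto ref and the aligned correlation."""
    shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=10, normalization=None)
    moved = ndi.shift(img, shift, order=1, mode="nearest")
    return shift, _norm_corr(ref, moved)


def register_to_reference(
    img: ColonyPlateImage,
    ref: ColonyPlateImage,
    max_rotation: float = 10.0,
    min_correlation: float = 0.2,
) -> tuple[RigidTransform, np.ndarray]:
    """Rigid registration (rotation + translation) of a plate photo.

    The rotation is found by maximising the translation-aligned intensity
    correlation over a coarse angle grid refined by bounded scalar
    minimisation; translation per candidate comes from phase correlation.
    Returns the transform and the reference ROI resampled onto `img`.
    """
    if ref.roi is None:
        raise ValueError("reference image must carry an ROI")
    g_ref = rgb2gray(ref.rgb)
    g_img = rgb2gray(img.rgb)

    def neg_corr(angle: float) -> float:
        back = rotate(g_img, -angle, order=1, mode="edge")
        _, corr = _shift_corr(g_ref, back)
        return -corr

    coarse = np.arange(-max_rotation, max_rotation + 0.5, 1.0)
    scores = [neg_corr(a) for a in coarse]
    a0 = coarse[int(np.argmin(scores))]
    res = minimize_scalar(neg_corr, bounds=(a0 - 1.0, a0 + 1.0), method="bounded", options={"xatol": 0.01})
    angle = float(res.x)
    back = rotate(g_img, -angle, order=1, mode="edge")
    shift, corr = _shift_corr(g_ref, back)
    if corr < min_correlation:
        raise RegistrationError(f"registration correlation {corr:.3f} below {min_correlation}")
    # map the reference ROI into the image frame: forward rotate + shift
    roi_moved = ndi.shift(ref.roi.astype(float), -shift, order=0, mode="constant")
    roi_img = rotate(roi_moved, angle, order=0, mode="constant") > 0.5
    return RigidTransform(angle, (float(-shift[0]), float(-shift[1])), corr), roi_img


def colony_covered_fraction(
    rgb: np.ndarray,
    roi: np.ndarray,
    threshold: float = DEFAULT_LAB_B_THRESHOLD,
    transform: Optional[RigidTransform] = None,
) -> ColonyResult:
    """Fraction of ROI covered by blue-stained colonies (Lab b < threshold)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    lab = rgb2lab(rgb if rgb.dtype != np.uint8 else rgb / 255.0)
    colonies = lab[..., 2] < threshold
    frac = float((colonies & roi).sum() / roi.sum())
    return ColonyResult(frac, threshold, transform)


@dataclass
class ImpedanceSeries:
    times: np.ndarray  # h, strictly increasing
    impedance: np.ndarray
    blank: np.ndarray  # cell-free impedance, same grid
    nominal: float
    matrigel: bool = False
    treatment_time: Optional[float] = None
    well: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=float)
        self.blank = np.asarray(self.blank, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.nominal <= 0:
            raise ValueError("nominal impedance must be positive")
        if not (self.times.shape == self.impedance.shape == self.blank.shape):
            raise ValueError("times, impedance and blank must align")


def cell_index(series: ImpedanceSeries) -> np.ndarray:
    """CI(t) = (Z(t) - Z_blank(t)) / Z_nominal."""
    return (series.impedance - series.blank) / series.nominal


def normalize_ci(times: np.ndarray, ci: np.ndarray, t_treat: float) -> np.ndarray:
    """Normalise a CI series to 1.0 at the treatment time.

    Off-grid treatment times use linear interpolation of CI (sampling every
    15 min makes the interpolation numerically minor).
    """
    times = np.asarray(times, dtype=float)
    ci = np.asarray(ci, dtype=float)
    if not times[0] <= t_treat <= times[-1]:
        raise ValueError("t_treat outside the series")
    ref = float(np.interp(t_treat, times, ci))
    if ref == 0:
        raise ZeroDivisionError("CI at treatment time is zero; cannot normalise")
    return ci / ref


@dataclass
class Track:
    cell_id: int
    times: np.ndarray  # h
    positions: np.ndarray  # (n, 2) um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.size < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("track times must increase")
        if self.positions.shape != (self.times.size, 2):
            raise ValueError("positions must be (n, 2)")


@dataclass
class MotilitySummary:
    speeds: np.ndarray  # per-cell mean speed, um/h
    rose_bin_edges: np.ndarray  # degrees
    rose_weights: np.ndarray  # speed-weighted direction histogram
    summary_vector: tuple[float, float]

    @property
    def summary_magnitude(self) -> float:
        return float(np.hypot(*self.summary_vector))


def track_motility(
    tracks: Sequence[Track],
    n_bins: int = 12,
    per_cell_average: bool = False,
) -> MotilitySummary:
    """Speeds, speed-weighted rose histogram and directional summary vector.

    Rose bins are `n_bins` sectors with the first bin centred on +x.  The
    summary vector divides the vector sum of all displacement steps by the
    total path length (`per_cell_average=True` instead averages per-cell
    ratios), so its magnitude is 1 for straight common motion and bounded
    by 1 always.
    """
    if not tracks:
        raise ValueError("no tracks")
    speeds = []
    all_steps = []
    all_dt = []
    per_cell_vec = []
    for tr in tracks:
        dt = np.diff(tr.times)
        steps = np.diff(tr.positions, axis=0)
        lengths = np.hypot(steps[:, 0], steps[:, 1])
        elapsed = tr.times[-1] - tr.times[0]
        if elapsed <= 0:
            raise ValueError("zero elapsed time")
        speeds.append(lengths.sum() / elapsed)
        all_steps.append(steps)
        all_dt.append(dt)
        path = lengths.sum()
        per_cell_vec.append(steps.sum(axis=0) / path if path > 0 else np.zeros(2))
    steps = np.vstack(all_steps)
    dt = np.concatenate(all_dt)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    if per_cell_average:
        vec = np.mean(per_cell_vec, axis=0)
    else:
        total_path = lengths.sum()
        vec = steps.sum(axis=0) / total_path if total_path > 0 else np.zeros(2)
    # rose: first bin centred on +x, i.e. edges offset by half a bin width
    width = 360.0 / n_bins
    edges = -width / 2 + width * np.arange(n_bins + 1)
    ang = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))  # (-180, 180]
    ang = (ang + width / 2) % 360.0 - width / 2  # into [edges[0], edges[-1])
    step_speed = np.divide(lengths, dt, out=np.zeros_like(lengths), where=dt > 0)
    weights, _ = np.histogram(ang, bins=edges, weights=step_speed)
    return MotilitySummary(
        speeds=np.asarray(speeds),
        rose_bin_edges=edges,
        rose_weights=weights,
        summary_vector=(float(vec[0]), float(vec[1])),
    )


def wound_open_fraction_stats(
    fractions_t0: Sequence[float],
    fractions_t24: Sequence[float],
) -> pd.DataFrame:
    """Per-well wound closure from imported open-area percentages.

    closure = open(t0) - open(t24); negative closure (wound widening) is
    allowed and flagged.  The open-area computation itself is done by
    external wound-healing software; this only aggregates its output.
    """
    f0 = np.asarray(fractions_t0, dtype=float)
    f24 = np.asarray(fractions_t24, dtype=float)
    if f0.shape != f24.shape:
        raise ValueError("unpaired input: t0 and t24 lengths differ")
    if ((f0 < 0) | (f0 > 100) | (f24 < 0) | (f24 > 100)).any():
        raise ValueError("open-area fractions must lie in [0, 100]")
    closure = f0 - f24
    return pd.DataFrame(
        {
            "open_t0_pct": f0,
            "open_t24_pct": f24,
            "closure_pct": closure,
            "widened": closure < 0,
        }
    )
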