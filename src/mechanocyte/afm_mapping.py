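"""Stiffness-map assembly, height-image segmentation and per-cell mechanics.

A force-volume map is a grid of FD curves.  Fitting every curve yields two
images: Young's modulus E (Pa) and "setpoint height" (the piezo z at which
the commanded maximum force was reached — a topography proxy).  Cells are
segmented on the setpoint-height image by watershed, and per-cell mean
stiffness/height are extracted over the resulting masks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import pearsonr
from skimage.filters import gaussian
from skimage.morphology import h_maxima
from skimage.segmentation import watershed, relabel_sequential

from .force_spectroscopy import FitOptions, ForceCurve, TipModel, fit_hertz, NoContactError

__all__ = [
    "ForceMap",
    "StiffnessMap",
    "SegmentationMask",
    "CellMechRecord",
    "MaskEdit",
    "build_stiffness_map",
    "segment_height_map",
    "apply_mask_edits",
    "extract_cell_mechanics",
    "profile_correlation",
    "save_stiffness_map",
    "load_stiffness_map",
]

log = logging.getLogger(__name__)


@dataclass
class ForceMap:
    """Grid of force curves on a regular spatial raster."""

    curves: list[ForceCurve]
    shape: tuple[int, int]
    extent: tuple[float, float]  # physical size (um x um)

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows * cols == 0 or len(self.curves) != rows * cols:
            raise ValueError(f"expected {rows * cols} curves for shape {self.shape}, got {len(self.curves)}")

    @property
    def pixel_size(self) -> float:
        return self.extent[0] / self.shape[0]


@dataclass
class StiffnessMap:
    E_image: np.ndarray  # Pa; NaN where the fit failed
    setpoint_height_image: np.ndarray  # um
    quality_image: np.ndarray  # bool, True = converged
    pixel_size: float

    def __post_init__(self) -> None:
        if not (self.E_image.shape == self.setpoint_height_image.shape == self.quality_image.shape):
            raise ValueError("all map channels must share one shape")


@dataclass
class SegmentationMask:
    labels: np.ndarray  # 0 = background, 1..n = cells
    provenance: str = "automatic"

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


@dataclass
class CellMechRecord:
    label: int
    mean_E: float
    mean_setpoint_height: float
    area: float  # um^2
    n_valid: int
    valid: bool


def build_stiffness_map(fmap: ForceMap, tip: TipModel, options: FitOptions | None = None) -> StiffnessMap:
    """Fit every curve of the map; flag and exclude failures.

    The setpoint height of a pixel is the piezo z of the final extend
    sample (where the force reached the setpoint).
    """
    rows, cols = fmap.shape
    E = np.full((rows, cols), np.nan)
    height = np.zeros((rows, cols))
    quality = np.zeros((rows, cols), dtype=bool)
    for idx, curve in enumerate(fmap.curves):
        r, c = divmod(idx, cols)
        height[r, c] = curve.z_extend[-1]
        try:
            fit = fit_hertz(curve, tip, options)
        except NoContactError:
            continue
        if fit.converged and fit.E > 0:
            E[r, c] = fit.E
            quality[r, c] = True
    n_bad = int((~quality).sum())
    if n_bad > quality.size // 2:
        warnings.warn(f"{n_bad}/{quality.size} map pixels failed to converge", stacklevel=2)
    return StiffnessMap(E, height, quality, fmap.pixel_size)


def _background_plane(img: np.ndarray) -> tuple[np.ndarray, float]:
    """Robust substrate plane: LSQ plane through the lowest-decile pixels.

    Returns the plane image and the MAD of the residuals of those pixels.
    Substrate tilt is common in AFM maps, so a scalar background would bias
    the threshold.
    """
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    cutoff = np.quantile(img, 0.1)
    sel = img <= cutoff
    design = np.column_stack([np.ones(sel.sum()), rr[sel], cc[sel]])
    coef, *_ = np.linalg.lstsq(design, img[sel], rcond=None)
    plane = coef[0] + coef[1] * rr + coef[2] * cc
    resid = img[sel] - plane[sel]
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return plane, mad


@dataclass
class MaskEdit:
    """One replayable manual correction: merge / split / delete.

    op 'merge': labels = (a, b, ...) fused into the first.
    op 'split': label split by watershed from `seeds` ((row, col) points).
    op 'delete': label removed to background.
    """

    op: str
    labels: tuple[int, ...] = ()
    seeds: tuple[tuple[int, int], ...] = ()


def apply_mask_edits(labels: np.ndarray, edits: Sequence[MaskEdit], height: np.ndarray | None = None) -> np.ndarray:
    out = labels.copy()
    for e in edits:
        if e.op == "merge":
            keep = e.labels[0]
            for l in e.labels[1:]:
                out[out == l] = keep
        elif e.op == "delete":
            out[out == e.labels[0]] = 0
        elif e.op == "split":
            if height is None:
                raise ValueError("split edits need the height image")
            region = out == e.labels[0]
            markers = np.zeros_like(out)
            for i, (r, c) in enumerate(e.seeds, start=1):
                markers[r, c] = i
            sub = watershed(-height, markers, mask=region)
            nxt = out.max()
            for i in range(1, len(e.seeds) + 1):
                nxt += 1
                out[sub == i] = nxt
        else:
            raise ValueError(f"unknown edit op {e.op!r}")
    out, _, _ = relabel_sequential(out)
    return out


def segment_height_map(
    height: np.ndarray,
    manual_corrections: Sequence[MaskEdit] = (),
    sigma: float = 0.75,
    h_depth: float = 0.5,
    min_offset: float = 0.6,
    min_area: int = 5,
) -> SegmentationMask:
    """Watershed segmentation of a setpoint-height image.

    Smoothed height is thresholded against a robust substrate plane plus an
    offset (3x residual MAD, floored at `min_offset` um); seeds are the
    h-maxima of depth `h_depth` um; the watershed runs downhill on the
    inverted height.  Manual corrections, a replayable edit script, are
    applied last.
    """
    height = np.asarray(height, dtype=float)
    if not np.all(np.isfinite(height)):
        raise ValueError("height image must be finite")
    smooth = gaussian(height, sigma=sigma, preserve_range=True)
    plane, mad = _background_plane(smooth)
    fg = (smooth - plane) > max(3.0 * mad, min_offset)
    if not fg.any():
        return SegmentationMask(np.zeros(height.shape, dtype=np.int32))
    rel = np.where(fg, smooth - plane, 0.0)
    seeds = h_maxima(rel, h_depth)
    markers, _ = ndi.label(seeds)
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-rel, markers, mask=fg)
    # drop specks below min_area
    for l, count in zip(*np.unique(labels, return_counts=True)):
        if l != 0 and count < min_area:
            labels[labels == l] = 0
    labels, _, _ = relabel_sequential(labels)
    provenance = "automatic"
    if manual_corrections:
        labels = apply_mask_edits(labels, manual_corrections, height=smooth)
        provenance = "manually corrected"
    return SegmentationMask(labels.astype(np.int32), provenance)


def extract_cell_mechanics(smap: StiffnessMap, mask: SegmentationMask) -> list[CellMechRecord]:
    """Per-cell means of E and setpoint height over valid (converged) pixels."""
    if smap.E_image.shape != mask.labels.shape:
        raise ValueError("stiffness map and mask shapes differ")
    records = []
    for l in range(1, mask.labels.max() + 1):
        sel = mask.labels == l
        n_px = int(sel.sum())
        if n_px == 0:
            continue
        valid = sel & smap.quality_image
        n_valid = int(valid.sum())
        if n_valid == 0:
            log.warning("label %d has no valid pixels; flagged", l)
            records.append(CellMechRecord(l, np.nan, np.nan, n_px * smap.pixel_size**2, 0, False))
            continue
        records.append(
            CellMechRecord(
                label=l,
                mean_E=float(np.nanmean(smap.E_image[valid])),
                mean_setpoint_height=float(smap.setpoint_height_image[valid].mean()),
                area=n_px * smap.pixel_size**2,
                n_valid=n_valid,
                valid=True,
            )
        )
    return records


def profile_correlation(height_profile: np.ndarray, E_profile: np.ndarray) -> float:
    """Pearson correlation of pixel profiles along a user-drawn line."""
    h = np.asarray(height_profile, dtype=float)
    e = np.asarray(E_profile, dtype=float)
    if h.size != e.size or h.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.ptp(h) == 0 or np.ptp(e) == 0:
        raise ValueError("correlation undefined for zero-variance profile")
    return float(pearsonr(h, e).statistic)


# ---------------------------------------------------------------------------
# map I/O: multi-channel TIFF (E, setpoint height, quality) + JSON sidecar

def save_stiffness_map(path, smap: StiffnessMap) -> None:
    import tifffile

    stack = np.stack([smap.E_image, smap.setpoint_height_image, smap.quality_image.astype(np.float32)])
    tifffile.imwrite(path, stack.astype(np.float32))
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"pixel_size_um": smap.pixel_size, "channels": ["E_pa", "setpoint_height_um", "quality"]}, fh)


def load_stiffness_map(path) -> StiffnessMap:
    import tifffile

    stack = tifffile.imread(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return StiffnessMap(
        E_image=stack[0].astype(float),
        setpoint_height_image=stack[1].astype(float),
        quality_image=stack[2] > 0.5,
        pixel_size=float(meta["pixel_size_um"]),
    )
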