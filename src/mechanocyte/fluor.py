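"""Fluorescence morphometrics: region intensities, cell shape, stress fibres.

Works on manually segmented cell and fibre masks (the standard practice for
stress-fibre studies) together with actin/tubulin channel images.  Two
regions are analysed per cell: the whole footprint and a peripheral band of
configurable width (default 4 um) inside the cell border, where cortical
actin and docetaxel-stabilised tubulin accumulate.

Fibre orientations are axial quantities (a fibre at 170 deg is 20 deg away
from one at 10 deg).  The dispersion statistic is the circular standard
deviation sqrt(-2 ln Rbar); `mode='raw'` applies it directly to the angles,
`mode='axial'` doubles them first (period 180 deg) and halves the result,
which is the statistically correct treatment for orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.stats import circstd
from skimage.measure import regionprops
from skimage.morphology import disk, erosion

__all__ = [
    "FluorCell",
    "RegionIntensity",
    "CellShape",
    "FiberRecord",
    "circularity",
    "periphery_band",
    "region_intensity",
    "cell_shape",
    "fiber_metrics",
    "angle_dispersion",
]


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity 4*pi*A/P^2: 1 for a circle, pi/4 for a square."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


@dataclass
class FluorCell:
    mask: np.ndarray  # bool, single cell
    channels: dict[str, np.ndarray]  # e.g. {'actin': ..., 'tubulin': ...}
    pixel_size: float  # um

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, img in self.channels.items():
            if img.shape != self.mask.shape:
                raise ValueError(f"channel {name!r} shape differs from mask")


@dataclass
class RegionIntensity:
    region: str  # 'whole_cell' | 'periphery'
    channel: str
    integrated_intensity: float
    median_intensity: float


@dataclass
class CellShape:
    area: float  # um^2
    max_feret: float  # um
    roundness: float  # 4A / (pi * feret^2)
    aspect_ratio: float  # major/minor of the inertia ellipse
    circularity: float  # 4*pi*A/P^2


@dataclass
class FiberRecord:
    length: float  # um
    feret_angle: float  # degrees in [0, 180)
    integrated_intensity: float
    mean_intensity: float


def periphery_band(mask: np.ndarray, width: float = 4.0, pixel_size: float = 1.0) -> np.ndarray:
    """Peripheral band: the mask minus its erosion by a disk of radius `width`.

    If the erosion empties the mask (small cell), the whole cell is the
    band.  width 0 gives an empty band.
    """
    mask = np.asarray(mask, dtype=bool)
    if width < 0:
        raise ValueError("width must be non-negative")
    r_px = int(round(width / pixel_size))
    if r_px == 0:
        return np.zeros_like(mask)
    core = erosion(mask, disk(r_px))
    if not core.any():
        return mask.copy()
    return mask & ~core


def region_intensity(cell: FluorCell, region: np.ndarray, channel: str) -> RegionIntensity:
    """Integrated (sum) and median pixel intensity over a region mask."""
    region = np.asarray(region, dtype=bool)
    if region.shape != cell.mask.shape:
        raise ValueError("region shape differs from cell mask")
    if not region.any():
        raise ValueError("empty region")
    vals = cell.channels[channel][region]
    name = "whole_cell" if np.array_equal(region, cell.mask) else "periphery"
    return RegionIntensity(name, channel, float(vals.sum()), float(np.median(vals)))


def _max_feret(coords: np.ndarray) -> tuple[float, float]:
    """Maximum caliper length (px) and its orientation (deg, [0, 180)).

    Angle convention: image x to the right, y upward (rows count downward,
    hence the sign flip); a horizontal chord has angle 0.
    """
    pts = np.unique(coords, axis=0).astype(float)
    if len(pts) == 1:
        return 0.0, 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    dr = pts[j, 0] - pts[i, 0]
    dc = pts[j, 1] - pts[i, 1]
    angle = np.degrees(np.arctan2(-dr, dc)) % 180.0
    return float(np.sqrt(d2[i, j])), float(angle)


def cell_shape(mask: np.ndarray, pixel_size: float = 1.0) -> CellShape:
    """Area, max feret, roundness, aspect ratio and circularity of one mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    prop = regionprops(mask.astype(np.uint8))[0]
    area = prop.area * pixel_size**2
    feret = prop.feret_diameter_max * pixel_size
    roundness = 4.0 * area / (np.pi * feret**2) if feret > 0 else np.nan
    minor = prop.axis_minor_length
    aspect = prop.axis_major_length / minor if minor > 0 else np.inf
    perim = prop.perimeter_crofton * pixel_size
    circ = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
    return CellShape(float(area), float(feret), float(roundness), float(aspect), float(circ))


def fiber_metrics(
    fibres: Sequence[np.ndarray],
    channel: np.ndarray,
    pixel_size: float = 1.0,
) -> tuple[list[FiberRecord], int]:
    """Per-fibre length, feret angle and intensities; returns (records, count)."""
    records = []
    for fmask in fibres:
        fmask = np.asarray(fmask, dtype=bool)
        if not fmask.any():
            raise ValueError("empty fibre mask")
        coords = np.argwhere(fmask)
        length_px, angle = _max_feret(coords)
        vals = channel[fmask]
        records.append(
            FiberRecord(
                length=float(length_px * pixel_size),
                feret_angle=angle,
                integrated_intensity=float(vals.sum()),
                mean_intensity=float(vals.mean()),
            )
        )
    return records, len(records)


def angle_dispersion(angles: Sequence[float], mode: str = "raw") -> float:
    """Circular standard deviation (radians) of feret angles given in degrees.

    raw:   sqrt(-2 ln Rbar) on the angles as-is (period 360 deg).
    axial: angles doubled first (period 180 deg), result halved.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least 2 angles")
    if mode == "raw":
        return float(circstd(np.radians(angles)))
    if mode == "axial":
        return float(circstd(np.radians(2.0 * angles)) / 2.0)
    raise ValueError(f"unknown mode {mode!r}")
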