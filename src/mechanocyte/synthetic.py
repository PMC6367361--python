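"""Seeded synthetic data for every modality, with exact ground truth.

Each generator draws from its own named RNG substream derived from the
master seed, so adding or reordering generators never perturbs the others,
and a fixed seed reproduces identical outputs byte for byte.

The generators emulate the structure of the real assays — force-volume
maps obeying the Hertz forward model, phase fields deposited from known
per-cell dry masses, fibre images with von-Mises orientations, stained
colony plates with a known covered fraction, biased persistent random
walks, and logistic impedance growth — not their photometric realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .force_spectroscopy import AcquisitionSettings, ForceCurve, TipModel, simulate_force_curve
from .afm_mapping import ForceMap
from .assays import ColonyPlateImage, ImpedanceSeries, Track
from .qpi import PhaseImage

__all__ = [
    "substream",
    "gen_force_map",
    "gen_phase_image",
    "gen_fiber_image",
    "gen_colony_image",
    "make_misaligned_copy",
    "gen_tracks",
    "gen_impedance",
]

_STREAMS = {
    "force_map": 1,
    "phase": 2,
    "fibers": 3,
    "colony": 4,
    "tracks": 5,
    "impedance": 6,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named modality substream."""
    return np.random.default_rng([int(seed), _STREAMS[name]])


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_px: float,
    margin: float = 2.0,
    max_tries: int = 500,
) -> list[tuple[float, float]]:
    """Non-overlapping cell centres by rejection sampling."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        r = rng.uniform(radius_px + 1, shape[0] - radius_px - 1)
        c = rng.uniform(radius_px + 1, shape[1] - radius_px - 1)
        if all(np.hypot(r - r0, c - c0) >= 2 * radius_px + margin for r0, c0 in centers):
            centers.append((r, c))
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                warnings.warn("cell placement overlap; restarting layout", stacklevel=2)
                centers.clear()
                tries = 0
    return centers


def _bump(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Smooth compact bump: cos^2 profile, 1 at the centre, 0 outside radius."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    prof = np.where(d < radius_px, np.cos(np.pi * d / (2 * radius_px)) ** 2, 0.0)
    return prof


def gen_force_map(
    seed: int = 0,
    shape: tuple[int, int] = (32, 32),
    extent: tuple[float, float] = (40.0, 40.0),
    cell_E: Sequence[float] = (700.0, 1200.0),
    substrate_E: float = 10000.0,
    cell_height: float = 3.0,
    cell_radius_um: float = 8.0,
    edge_margin_um: float = 3.0,
    noise_sd: float = 0.02,
    tip: TipModel | None = None,
    settings: AcquisitionSettings | None = None,
) -> tuple[ForceMap, dict]:
    """Force-volume map of bump-shaped cells on a stiff substrate.

    Every pixel gets an FD curve from the Hertz forward model with the
    pixel's true modulus; the contact point tracks the topography (cells
    rise `cell_height` um above the substrate plane).  The cell-stiffness
    region extends `edge_margin_um` beyond the height footprint: the thin
    cell rim still covers the substrate there, so an indenting tip meets
    cell material even where the topographic signal has vanished.
    """
    rng = substream(seed, "force_map")
    tip = tip or TipModel()
    settings = settings or AcquisitionSettings(z_range=(0.0, 12.0), dz=0.02)
    rows, cols = shape
    px = extent[0] / rows
    radius_px = cell_radius_um / px
    margin_px = edge_margin_um / px
    centers = _place_cells(rng, shape, len(cell_E), radius_px + margin_px / 2)
    rr, cc = np.mgrid[:rows, :cols]
    height = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    E_true = np.full(shape, float(substrate_E))
    for i, (ctr, E) in enumerate(zip(centers, cell_E), start=1):
        d = np.hypot(rr - ctr[0], cc - ctr[1])
        bump = cell_height * np.where(d < radius_px, np.cos(np.pi * d / (2 * radius_px)) ** 2, 0.0)
        take = bump > height
        height = np.maximum(height, bump)
        labels[take & (bump > 0)] = i
        E_true[d < radius_px + margin_px] = E
    z_base = 4.0
    curves = []
    for r in range(rows):
        for c in range(cols):
            curves.append(
                simulate_force_curve(
                    E=float(E_true[r, c]),
                    tip=tip,
                    z0=z_base + float(height[r, c]),
                    noise_sd=noise_sd,
                    settings=settings,
                    seed=rng,
                )
            )
            curves[-1].position = (c * px, r * px)
    fmap = ForceMap(curves, shape, extent)
    truth = {
        "label_image": labels,
        "cell_E": {i: float(E) for i, E in enumerate(cell_E, start=1)},
        "substrate_E": float(substrate_E),
        "height_image": height,
        "z_base": z_base,
        "tip": tip,
    }
    return fmap, truth


def gen_phase_image(
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    pixel_size: float = 0.5,
    cell_masses: Sequence[float] = (300.0,),
    cell_radius_um: float = 15.0,
    wavelength: float = 0.65,
    alpha: float = 0.18,
    background_offset: float = 0.2,
    noise_sd: float = 0.01,
) -> tuple[PhaseImage, dict]:
    """Phase image deposited from known per-cell dry masses.

    Each cell is a cos^2 mass-density profile scaled so that its rasterised
    total equals the requested mass exactly; the phase is the inverse of
    the dry-mass relation, phi = 2*pi*alpha*m/lambda, plus a background
    offset and Gaussian phase noise.
    """
    rng = substream(seed, "phase")
    radius_px = cell_radius_um / pixel_size
    centers = _place_cells(rng, shape, len(cell_masses), radius_px)
    density = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i, (ctr, mass) in enumerate(zip(centers, cell_masses), start=1):
        prof = _bump(shape, ctr, radius_px)
        raster_mass = prof.sum() * pixel_size**2
        prof *= mass / raster_mass
        density += prof
        labels[prof > 0] = i
    phase_clean = 2.0 * np.pi * alpha * density / wavelength
    phase = phase_clean + background_offset
    if noise_sd > 0:
        phase = phase + rng.normal(0.0, noise_sd, size=shape)
    img = PhaseImage(phase, pixel_size, wavelength, alpha)
    truth = {
        "label_image": labels,
        "cell_mass": {i: float(m) for i, m in enumerate(cell_masses, start=1)},
        "density_image": density,
        "background_offset": background_offset,
    }
    return img, truth


def _circ_dispersion(angles_deg: np.ndarray) -> float:
    """Raw circular standard deviation, radians (reference formula)."""
    th = np.radians(angles_deg)
    rbar = np.abs(np.mean(np.exp(1j * th)))
    return float(np.sqrt(-2.0 * np.log(rbar)))


def gen_fiber_image(
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    pixel_size: float = 0.25,
    n_fibers: int = 20,
    mean_angle: float = 30.0,
    kappa: float = 4.0,
    length_um: tuple[float, float] = (8.0, 16.0),
    width_sigma_px: float = 1.0,
    intensity: float = 100.0,
    noise_sd: float = 2.0,
) -> tuple[dict, list[np.ndarray], dict]:
    """Stress-fibre image: line segments with Gaussian cross-section.

    Orientations are drawn from a von Mises distribution centred on
    `mean_angle` with concentration kappa; the truth includes the drawn
    angles and their analytic circular dispersion.
    Returns (channels, fibre_masks, truth).
    """
    rng = substream(seed, "fibers")
    angles = np.degrees(rng.vonmises(np.radians(mean_angle), kappa, size=n_fibers))
    img = np.zeros(shape)
    masks = []
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for ang in angles:
        L = rng.uniform(*length_um) / pixel_size
        r0 = rng.uniform(0.2 * shape[0], 0.8 * shape[0])
        c0 = rng.uniform(0.2 * shape[1], 0.8 * shape[1])
        # y-up convention: angle 0 is horizontal, positive CCW
        dr, dc = -np.sin(np.radians(ang)), np.cos(np.radians(ang))
        # distance from each pixel to the segment
        pr, pc = rr - r0, cc - c0
        t = np.clip(pr * dr + pc * dc, -L / 2, L / 2)
        d = np.hypot(pr - t * dr, pc - t * dc)
        profile = intensity * np.exp(-0.5 * (d / width_sigma_px) ** 2)
        img += profile
        masks.append(d < 2.0 * width_sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    channels = {"actin": img}
    truth = {
        "angles_deg": angles,
        "dispersion_raw_rad": _circ_dispersion(angles),
        "n_fibers": n_fibers,
        "mean_angle": mean_angle,
        "kappa": kappa,
    }
    return channels, masks, truth


_PLATE_RGB = np.array([0.93, 0.92, 0.90])
_COLONY_RGB = np.array([0.15, 0.2, 0.75])


def gen_colony_image(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    target_fraction: float = 0.3,
    radius_px: tuple[int, int] = (5, 12),
) -> tuple[ColonyPlateImage, dict]:
    """White plate with blue anti-aliased colony disks inside a central ROI.

    Disks are placed without overlap until the covered fraction of the ROI
    reaches the target; the last disk is sized to land on it.  Truth is the
    exact rasterised fraction of the binary colony mask.
    """
    rng = substream(seed, "colony")
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    ctr = (shape[0] / 2 - 0.5, shape[1] / 2 - 0.5)
    roi = np.hypot(rr - ctr[0], cc - ctr[1]) < 0.42 * min(shape)
    roi_px = int(roi.sum())
    colony = np.zeros(shape, dtype=bool)
    soft = np.zeros(shape)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while colony[roi].sum() / roi_px < target_fraction - 1e-9 and attempts < 20000:
        attempts += 1
        remaining = (target_fraction - colony[roi].sum() / roi_px) * roi_px
        r_max = min(radius_px[1], max(radius_px[0], int(np.sqrt(remaining / np.pi))))
        rad = float(rng.integers(radius_px[0], r_max + 1))
        pr = rng.uniform(rad, shape[0] - rad)
        pc = rng.uniform(rad, shape[1] - rad)
        if np.hypot(pr - ctr[0], pc - ctr[1]) > 0.42 * min(shape) - rad:
            continue
        if any(np.hypot(pr - qr, pc - qc) < rad + qrad + 1 for qr, qc, qrad in placed):
            continue
        d = np.hypot(rr - pr, cc - pc)
        colony |= d < rad
        soft = np.maximum(soft, np.clip(rad - d + 0.5, 0.0, 1.0))
        placed.append((pr, pc, rad))
    rgb = _PLATE_RGB[None, None, :] * (1 - soft[..., None]) + _COLONY_RGB[None, None, :] * soft[..., None]
    plate = ColonyPlateImage(rgb.astype(np.float64), roi=roi, is_reference=True)
    truth = {
        "covered_fraction": float(colony[roi].sum() / roi_px),
        "colony_mask": colony,
        "n_colonies": len(placed),
    }
    return plate, truth


def make_misaligned_copy(
    plate: ColonyPlateImage,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
) -> tuple[ColonyPlateImage, dict]:
    """Rotate-then-shift copy of a plate photo, with the true transform."""
    from scipy import ndimage as ndi
    from skimage.transform import rotate

    out = plate.rgb.copy()
    if rotation_deg != 0.0:
        out = np.stack([rotate(out[..., i], rotation_deg, order=1, mode="edge") for i in range(3)], axis=-1)
    if translation != (0.0, 0.0):
        out = np.stack(
            [ndi.shift(out[..., i], translation, order=1, mode="nearest") for i in range(3)], axis=-1
        )
    moved = ColonyPlateImage(out, roi=None, is_reference=False)
    return moved, {"rotation_deg": rotation_deg, "translation": translation}


def gen_tracks(
    seed: int = 0,
    n_cells: int = 100,
    n_steps: int = 48,
    dt: float = 0.25,
    speed: float = 20.0,
    bias: float = 0.0,
    bias_direction_deg: float = 0.0,
    persistence: float = 0.5,
) -> tuple[list[Track], dict]:
    """Biased persistent random walks.

    Headings follow a wrapped random walk whose turning spread shrinks with
    `persistence`; each step direction mixes the heading with a fixed drift
    direction by weight `bias` (0 = unbiased, 1 = perfectly straight).
    """
    rng = substream(seed, "tracks")
    drift = np.array([np.cos(np.radians(bias_direction_deg)), np.sin(np.radians(bias_direction_deg))])
    sigma_turn = (1.0 - persistence) * np.pi
    tracks = []
    realized_speed = []
    for cid in range(n_cells):
        theta = rng.uniform(0, 2 * np.pi)
        pos = np.zeros((n_steps + 1, 2))
        for k in range(n_steps):
            theta += rng.normal(0.0, sigma_turn)
            u = np.array([np.cos(theta), np.sin(theta)])
            v = (1.0 - bias) * u + bias * drift
            norm = np.hypot(*v)
            v = drift if norm == 0 else v / norm
            pos[k + 1] = pos[k] + speed * dt * v
        times = dt * np.arange(n_steps + 1)
        tracks.append(Track(cid, times, pos))
        path = np.hypot(*np.diff(pos, axis=0).T).sum()
        realized_speed.append(path / (times[-1] - times[0]))
    truth = {
        "speed": speed,
        "bias": bias,
        "bias_direction_deg": bias_direction_deg,
        "realized_speeds": np.asarray(realized_speed),
    }
    return tracks, truth


def gen_impedance(
    seed: int = 0,
    duration_h: float = 150.0,
    dt_h: float = 0.25,
    nominal: float = 15.0,
    blank_level: float = 10.0,
    ci_plateau: float = 8.0,
    growth_rate: float = 0.08,
    t_mid: float = 40.0,
    treatment_time: float = 48.0,
    rate_multiplier: float = 1.0,
    matrigel: bool = False,
    ci_noise_sd: float = 0.0,
) -> tuple[ImpedanceSeries, dict]:
    """Logistic cell-index growth inverted to an impedance record.

    CI follows a logistic curve; after the treatment time the growth rate
    is multiplied by `rate_multiplier` and the logistic continues from the
    reached value.  Impedance is reconstructed exactly through the CI
    definition, Z = CI * nominal + blank, so analysing the series recovers
    the intended CI to machine precision (sampling every 15 min over 150 h
    gives 601 points at the defaults).
    """
    rng = substream(seed, "impedance")
    times = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    ci = ci_plateau / (1.0 + np.exp(-growth_rate * (times - t_mid)))
    if rate_multiplier != 1.0:
        post = times > treatment_time
        ci_at = ci_plateau / (1.0 + np.exp(-growth_rate * (treatment_time - t_mid)))
        B = ci_plateau / ci_at - 1.0
        r2 = growth_rate * rate_multiplier
        ci[post] = ci_plateau / (1.0 + B * np.exp(-r2 * (times[post] - treatment_time)))
    if ci_noise_sd > 0:
        ci = ci + rng.normal(0.0, ci_noise_sd, size=ci.size)
    blank = np.full_like(times, blank_level)
    series = ImpedanceSeries(
        times=times,
        impedance=ci * nominal + blank,
        blank=blank,
        nominal=nominal,
        matrigel=matrigel,
        treatment_time=treatment_time,
    )
    truth = {
        "ci": ci,
        "ci_plateau": ci_plateau,
        "growth_rate": growth_rate,
        "treatment_time": treatment_time,
        "rate_multiplier": rate_multiplier,
    }
    return series, truth
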