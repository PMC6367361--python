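"""Force-distance curve modelling and Hertz-Sneddon fitting.

A force-distance (FD) curve records cantilever force (nN) against piezo
position z (um) while the tip approaches a cell.  Before contact the force
sits at an instrumental baseline; past the contact point z0 it rises
according to the Hertz-Sneddon contact model for the tip geometry.  The
indentation depth is the piezo travel past contact minus the cantilever's
own bending:

    delta = (z - z0) - F / k

with k the cantilever spring constant.  Fitting force vs indentation yields
the cell's effective Young's modulus E.

Units used throughout: z in um, force in nN, E in Pa, k in N/m
(1 nN / (1 N/m) = 1e-3 um of deflection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ForceCurve",
    "TipModel",
    "HertzFit",
    "AcquisitionSettings",
    "FitOptions",
    "NoContactError",
    "SetpointUnreachableError",
    "simulate_force_curve",
    "estimate_contact_point",
    "fit_hertz",
    "save_curves_hdf5",
    "load_curves_hdf5",
    "load_curve_txt",
]

# nN per (Pa * um^2): 1 Pa * um^2 = 1e-12 N = 1e-3 nN
_PA_UM2_TO_NN = 1e-3
# cantilever deflection in um per nN at 1 N/m
_NN_PER_NPM_TO_UM = 1e-3


class NoContactError(ValueError):
    """Raised when a curve shows no detectable tip-sample contact."""


class SetpointUnreachableError(ValueError):
    """Raised when the requested setpoint force cannot be reached in the z-range."""


@dataclass
class TipModel:
    """Indenter geometry and sample Poisson ratio.

    geometry: 'cone', 'pyramid' (four-sided) or 'sphere'.
    half_angle: opening half-angle theta in degrees (cone/pyramid).
    radius: tip radius in um (sphere).
    poisson: Poisson ratio of the sample; 0.5 = incompressible cell.
    """

    geometry: str = "pyramid"
    half_angle: float = 35.0
    radius: Optional[float] = None
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if self.geometry not in ("cone", "pyramid", "sphere"):
            raise ValueError(f"unknown tip geometry {self.geometry!r}")
        if self.geometry in ("cone", "pyramid"):
            if not 0.0 < self.half_angle < 90.0:
                raise ValueError("half_angle must lie in (0, 90) degrees")
        else:
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere geometry requires radius > 0")
        if not 0.0 < self.poisson <= 0.5:
            raise ValueError("poisson must lie in (0, 0.5]")

    @property
    def exponent(self) -> float:
        """Power of indentation depth in the force law."""
        return 1.5 if self.geometry == "sphere" else 2.0

    def prefactor(self, E: float) -> float:
        """Force-law prefactor A such that F[nN] = A * delta[um]**exponent.

        cone:    F = (2/pi) * E/(1-nu^2) * tan(theta) * delta^2
        pyramid: F = 0.7453 * E/(1-nu^2) * tan(theta) * delta^2
        sphere:  F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)
        """
        E_eff = E / (1.0 - self.poisson**2)
        if self.geometry == "cone":
            a = (2.0 / math.pi) * E_eff * math.tan(math.radians(self.half_angle))
        elif self.geometry == "pyramid":
            a = 0.7453 * E_eff * math.tan(math.radians(self.half_angle))
        else:
            a = (4.0 / 3.0) * E_eff * math.sqrt(self.radius)
        return a * _PA_UM2_TO_NN

    def modulus_from_prefactor(self, a: float) -> float:
        """Inverse of :meth:`prefactor`."""
        unit = self.prefactor(1.0)
        return a / unit


@dataclass
class AcquisitionSettings:
    """Metadata of the approach ramp.

    z_range: (start, end) of the piezo extend ramp, um.
    dz: sampling step, um (30 um/s at a 2048 Hz pixel rate ~ 15 nm).
    spring_constant: cantilever stiffness, N/m.
    setpoint: maximum commanded force, nN.
    speed: approach speed, um/s (metadata only).
    """

    z_range: tuple[float, float] = (0.0, 15.0)
    dz: float = 0.015
    spring_constant: float = 0.03
    setpoint: float = 1.0
    speed: float = 30.0


@dataclass
class ForceCurve:
    """One FD record at a map position."""

    z_extend: np.ndarray
    force_extend: np.ndarray
    spring_constant: float
    setpoint: float
    speed: float = 30.0
    position: tuple[float, float] = (0.0, 0.0)
    z_retract: Optional[np.ndarray] = None
    force_retract: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z_extend = np.asarray(self.z_extend, dtype=float)
        self.force_extend = np.asarray(self.force_extend, dtype=float)
        if self.z_extend.shape != self.force_extend.shape:
            raise ValueError("z_extend and force_extend must have equal length")
        if self.z_extend.size < 16:
            raise ValueError("extend segment needs at least 16 samples")
        dz = np.diff(self.z_extend)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_extend must be strictly monotonic")
        if self.setpoint <= 0:
            raise ValueError("setpoint must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")


@dataclass
class HertzFit:
    """Result of a joint (E, z0, baseline) Hertz-Sneddon fit."""

    E: float
    z0: float
    baseline: float
    rss: float
    n_fit: int
    converged: bool
    message: str = ""


@dataclass
class FitOptions:
    xtol: float = 1e-8
    max_iter: int = 200


def _hertz_force_selfconsistent(u: np.ndarray, a: float, p: float, k_um: float) -> np.ndarray:
    """Solve F = a * ((u - F/k_um))**p for F >= 0, elementwise.

    u is piezo travel past contact (um); k_um in nN/um.  Accounts for the
    cantilever bending that reduces true indentation.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up = u[pos]
    if p == 2.0:
        # quadratic in F: (a/k^2) F^2 - (2au/k + 1) F + a u^2 = 0, physical root F < k u
        qa = a / k_um**2
        qb = -(2.0 * a * up / k_um + 1.0)
        qc = a * up**2
        disc = qb**2 - 4.0 * qa * qc
        # smaller root via the cancellation-free form; stable as qa -> 0 (stiff lever)
        out[pos] = 2.0 * qc / (-qb + np.sqrt(disc))
    else:
        vals = np.empty_like(up)
        for i, ui in enumerate(up):
            hi = k_um * ui  # F cannot exceed full-bending limit
            f = lambda F: a * max(ui - F / k_um, 0.0) ** p - F
            vals[i] = brentq(f, 0.0, hi, xtol=1e-12)
        out[pos] = vals
    return out


def simulate_force_curve(
    E: float,
    tip: TipModel,
    z0: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    settings: AcquisitionSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> ForceCurve:
    """Forward-model an approach FD curve.

    Pre-contact force equals `baseline`; past `z0` it follows the
    Hertz-Sneddon law with indentation corrected for cantilever bending,
    solved self-consistently.  The ramp terminates at the sample where the
    noiseless force first reaches the setpoint.  Gaussian force noise with
    standard deviation `noise_sd` (nN) is added throughout.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    settings = settings or AcquisitionSettings()
    z = np.arange(settings.z_range[0], settings.z_range[1] + settings.dz / 2, settings.dz)
    if z.size < 16:
        raise ValueError("z-range too short for a valid curve")
    a = tip.prefactor(E)
    k_um = settings.spring_constant / _NN_PER_NPM_TO_UM  # nN per um
    clean = _hertz_force_selfconsistent(z - z0, a, tip.exponent, k_um)
    reached = np.nonzero(clean >= settings.setpoint)[0]
    if reached.size == 0:
        raise SetpointUnreachableError(
            f"setpoint {settings.setpoint} nN not reached within z-range {settings.z_range}"
        )
    end = reached[0] + 1
    z = z[:end]
    clean = clean[:end]
    if z.size < 16:
        raise SetpointUnreachableError("setpoint reached too early; fewer than 16 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=z.size) if noise_sd > 0 else 0.0
    force = baseline + clean + noise
    return ForceCurve(
        z_extend=z,
        force_extend=force,
        spring_constant=settings.spring_constant,
        setpoint=settings.setpoint,
        speed=settings.speed,
    )


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def estimate_contact_point(curve: ForceCurve) -> float:
    """Heuristic contact-point estimate by a ratio-of-variance scan.

    For every split index the variance of a trailing window (past the
    candidate contact) is divided by that of a leading window (baseline);
    the ratio peaks where the force starts rising out of the noise.  Used
    to initialize :func:`fit_hertz`; never reported as a final contact
    point.
    """
    f = curve.force_extend
    z = curve.z_extend
    n = f.size
    n_base = max(8, n // 4)
    noise_mad = _mad(f[:n_base])
    if float(f.max() - f.min()) <= 3.0 * noise_mad + 1e-12:
        raise NoContactError("force range below noise floor; no contact detected")
    w = max(8, n // 25)
    idx = np.arange(w, n - w)
    rov = np.empty(idx.size)
    eps = max(noise_mad**2, 1e-20)
    for j, i in enumerate(idx):
        rov[j] = np.var(f[i : i + w]) / (np.var(f[i - w : i]) + eps)
    i_peak = idx[int(np.argmax(rov))]
    # step back from the variance peak to where force last sat at baseline level
    thresh = np.median(f[:n_base]) + 3.0 * max(noise_mad, 1e-12)
    below = np.nonzero(f[: i_peak + 1] <= thresh)[0]
    i_contact = int(below[-1]) if below.size else i_peak
    # local refinement: piecewise (flat baseline | quadratic rise) least squares
    # over candidate contact samples near the scan estimate; the quadratic is
    # the leading-order contact force for any blunt indenter
    dz = float(np.median(np.abs(np.diff(z))))
    half = max(3, int(round(0.75 / dz)))
    lo, hi = max(1, i_contact - half), min(n - 4, i_contact + half)
    best_rss, best_z0 = np.inf, float(z[i_contact])
    for i in range(lo, hi + 1):
        d = np.clip(z - z[i], 0.0, None) ** 2
        design = np.column_stack([np.ones(n), d])
        coef, *_ = np.linalg.lstsq(design, f, rcond=None)
        rss = float(np.sum((design @ coef - f) ** 2))
        if rss < best_rss:
            best_rss, best_z0 = rss, float(z[i])
    return best_z0


def fit_hertz(
    curve: ForceCurve,
    tip: TipModel,
    options: FitOptions | None = None,
) -> HertzFit:
    """Jointly fit (E, z0, baseline) on the extend segment.

    The indentation uses the bending correction delta = (z - z0) -
    (F - baseline)/k with the measured force, so the model prediction is
    explicit.  Pre-contact samples constrain the baseline; post-contact
    samples constrain E and z0.  Non-convergence is reported via
    ``converged=False`` rather than a silent modulus.
    """
    options = options or FitOptions()
    z = curve.z_extend
    f = curve.force_extend
    z0_init = estimate_contact_point(curve)  # NoContactError propagates
    pre = z < z0_init
    baseline_init = float(np.median(f[pre])) if np.count_nonzero(pre) >= 4 else float(f[:8].mean())
    k_um = curve.spring_constant / _NN_PER_NPM_TO_UM
    p = tip.exponent
    unit_a = tip.prefactor(1.0)

    delta_end = (z[-1] - z0_init) - (f[-1] - baseline_init) / k_um
    if delta_end <= 0:
        delta_end = (z[-1] - z0_init) or 1e-3
    a_init = max((f[-1] - baseline_init), 1e-6) / max(delta_end, 1e-6) ** p
    E_init = max(tip.modulus_from_prefactor(a_init), 1.0)

    def residuals(params: np.ndarray) -> np.ndarray:
        logE, z0, baseline = params
        a = unit_a * math.exp(logE)
        delta = (z - z0) - (f - baseline) / k_um
        model = baseline + a * np.clip(delta, 0.0, None) ** p
        return model - f

    x0 = np.array([math.log(E_init), z0_init, baseline_init])
    span = float(z[-1] - z[0])
    res = least_squares(
        residuals,
        x0,
        bounds=([math.log(1e-3), z[0] - span, -np.inf], [math.log(1e9), z[-1] + span, np.inf]),
        xtol=options.xtol,
        ftol=options.xtol,
        gtol=None,
        max_nfev=options.max_iter * 10,
        x_scale=[1.0, max(span / 10.0, 1e-3), max(abs(baseline_init), 0.1)],
    )
    logE, z0_fit, baseline_fit = res.x
    E_fit = tip.modulus_from_prefactor(unit_a * math.exp(logE))
    delta = (z - z0_fit) - (f - baseline_fit) / k_um
    n_fit = int(np.count_nonzero(delta > 0))
    converged = bool(res.success and E_fit > 0 and z[0] - span <= z0_fit <= z[-1] + span and n_fit >= 4)
    return HertzFit(
        E=float(E_fit),
        z0=float(z0_fit),
        baseline=float(baseline_fit),
        rss=float(np.sum(res.fun**2)),
        n_fit=n_fit,
        converged=converged,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# container I/O: HDF5 with /curves/<i>/{z_extend,force_extend,...} and
# per-curve attributes, plus a minimal 2-column text reader.

def save_curves_hdf5(path, curves: list[ForceCurve]) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("curves")
        for i, c in enumerate(curves):
            g = grp.create_group(str(i))
            g.create_dataset("z_extend", data=c.z_extend)
            g.create_dataset("force_extend", data=c.force_extend)
            if c.z_retract is not None:
                g.create_dataset("z_retract", data=c.z_retract)
                g.create_dataset("force_retract", data=c.force_retract)
            g.attrs["spring_constant"] = c.spring_constant
            g.attrs["setpoint"] = c.setpoint
            g.attrs["speed"] = c.speed
            g.attrs["x"] = c.position[0]
            g.attrs["y"] = c.position[1]


def load_curves_hdf5(path) -> list[ForceCurve]:
    import h5py

    curves = []
    with h5py.File(path, "r") as h5:
        keys = sorted(h5["curves"].keys(), key=int)
        for k in keys:
            g = h5["curves"][k]
            curves.append(
                ForceCurve(
                    z_extend=g["z_extend"][()],
                    force_extend=g["force_extend"][()],
                    z_retract=g["z_retract"][()] if "z_retract" in g else None,
                    force_retract=g["force_retract"][()] if "force_retract" in g else None,
                    spring_constant=float(g.attrs["spring_constant"]),
                    setpoint=float(g.attrs["setpoint"]),
                    speed=float(g.attrs.get("speed", 30.0)),
                    position=(float(g.attrs.get("x", 0.0)), float(g.attrs.get("y", 0.0))),
                )
            )
    return curves


def load_curve_txt(path, spring_constant: float, setpoint: float, speed: float = 30.0) -> ForceCurve:
    """Read a 2-column plain-text curve: z (um), force (nN)."""
    arr = np.loadtxt(path)
    return ForceCurve(
        z_extend=arr[:, 0],
        force_extend=arr[:, 1],
        spring_constant=spring_constant,
        setpoint=setpoint,
        speed=speed,
    )
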