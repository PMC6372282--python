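"""Skull-aware acoustic modelling for low-intensity transcranial focused ultrasound.

Maps CT-like Hounsfield-unit volumes onto acoustic media (density, sound
speed, attenuation via the bone-porosity power law), estimates the focused
steady-state pressure field of a spherical-cap transducer with a discretized
Rayleigh surface integral plus ray attenuation, anchors absolute amplitude
with a free-water calibration, and computes the standard pulse intensity
metrics (I_sppa, I_spta).

The full-wave time-domain propagation used in high-fidelity dosimetry is
deliberately replaced here by the monochromatic Rayleigh integral: the
quantities of interest (steady-state peak pressure, pulse intensities) are
properties of the steady-state linear field, and the free-water calibration
rescaling anchors the absolute scale exactly as a measured-transducer
calibration would. Refraction inside heterogeneous bone is not modelled;
only the accumulated attenuation along the source-to-voxel ray is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("sonoprint")

#: conversion between decibels and nepers: 1 Np = 20/ln(10) dB.
DB_PER_NEPER = 8.6859


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumMappingParams:
    """Linear HU -> (density, speed) maps and the porosity attenuation law.

    ``alpha0`` is the attenuation prefactor in dB/cm/MHz^b; ``b`` the
    frequency exponent; ``beta`` the porosity exponent.  ``hu_ref`` is the
    Hounsfield value mapped onto compact bone (rho_max, c_max).
    """

    rho_water: float = 1000.0   # kg/m^3, also soft tissue
    c_water: float = 1500.0     # m/s
    rho_max: float = 2200.0     # kg/m^3, compact bone
    c_max: float = 3100.0       # m/s
    beta: float = 0.5
    alpha0: float = 8.0         # dB/cm/MHz^b
    b: float = 1.1
    hu_ref: float = 2000.0

    def __post_init__(self) -> None:
        if self.rho_max <= self.rho_water:
            raise ValueError("rho_max must exceed rho_water")
        if self.c_max <= self.c_water:
            raise ValueError("c_max must exceed c_water")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be non-negative")


@dataclass
class AcousticMedium:
    """Voxelized acoustic medium at a fixed carrier frequency."""

    density: np.ndarray      # kg/m^3
    speed: np.ndarray        # m/s
    attenuation: np.ndarray  # Np/m at the carrier frequency
    porosity: np.ndarray     # dimensionless in [0, 1]
    spacing: float           # mm, isotropic

    def __post_init__(self) -> None:
        if not (self.density.shape == self.speed.shape
                == self.attenuation.shape == self.porosity.shape):
            raise ValueError("medium grids must share one shape")


@dataclass(frozen=True)
class TransducerGeometry:
    """Spherical-section focused transducer.

    ``apodization_r`` is the rim-to-centre amplitude ratio of a radial
    Gaussian taper over the cap (1.0 means a uniform cap).  ``position`` is
    the cap apex in grid mm coordinates and ``axis`` the unit beam axis.
    """

    roc: float = 63.0          # mm radius of curvature
    aperture: float = 64.0     # mm active diameter
    apodization_r: float = 0.35
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.aperture > 2.0 * self.roc:
            raise ValueError("aperture cannot exceed the cap diameter 2*roc")
        if not (0.0 < self.apodization_r <= 1.0):
            raise ValueError("apodization_r must lie in (0, 1]")


@dataclass(frozen=True)
class SonicationProtocol:
    """Pulse schedule and electrical drive of one sonication train."""

    f0: float = 250e3              # Hz carrier
    burst_duration: float = 30.0   # ms on per burst
    burst_period: float = 100.0    # ms burst repetition period
    train_duration: float = 40.0   # s
    drive_voltage: float = 130.0   # V peak-to-peak
    calibration_pressure: float = 1.2e6  # Pa free-water max at calibration_voltage
    calibration_voltage: float = 130.0   # V

    def __post_init__(self) -> None:
        if self.burst_duration > self.burst_period:
            raise ValueError("burst_duration must not exceed burst_period")

    @property
    def duty_cycle(self) -> float:
        return self.burst_duration / self.burst_period

    @property
    def free_water_pressure(self) -> float:
        """Calibrated free-water maximum pressure at the drive voltage (Pa)."""
        return self.calibration_pressure * self.drive_voltage / self.calibration_voltage


@dataclass
class PressureField:
    """Steady-state peak pressure amplitude on a voxel grid."""

    peak_pressure: np.ndarray  # Pa
    spacing: float             # mm
    focus_index: tuple[int, int, int] | None = None

    @property
    def focus_value(self) -> float:
        if self.focus_index is None:
            return float(self.peak_pressure.max())
        return float(self.peak_pressure[self.focus_index])


# ---------------------------------------------------------------------------
# HU -> medium maps
# ---------------------------------------------------------------------------

def porosity(density: np.ndarray | float,
             params: MediumMappingParams = MediumMappingParams()) -> np.ndarray | float:
    """Bone porosity phi = (rho_max - rho) / (rho_max - rho_water), clipped to [0, 1].

    Water maps to 1 (fully porous), compact bone to 0.
    """
    rho = np.asarray(density, dtype=float)
    if np.any(rho < params.rho_water) or np.any(rho > params.rho_max):
        logger.warning("density outside [rho_water, rho_max]; porosity clipped")
    phi = (params.rho_max - rho) / (params.rho_max - params.rho_water)
    phi = np.clip(phi, 0.0, 1.0)
    return float(phi) if np.isscalar(density) else phi


def attenuation_power_law(phi: np.ndarray | float, f: float,
                          params: MediumMappingParams = MediumMappingParams()) -> np.ndarray | float:
    """Acoustic attenuation alpha0 * f_MHz^b * phi^beta, returned in Np/m.

    The power law is specified in dB/cm/MHz^b; converted via
    dB -> Np (divide by 8.6859) and cm^-1 -> m^-1 (multiply by 100).
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > 1):
        raise ValueError("porosity must lie in [0, 1]")
    f_mhz = f / 1e6
    alpha_db_cm = params.alpha0 * f_mhz ** params.b * phi_arr ** params.beta
    alpha_np_m = alpha_db_cm / DB_PER_NEPER * 100.0
    return float(alpha_np_m) if np.isscalar(phi) else alpha_np_m


def hu_to_medium(phantom, params: MediumMappingParams = MediumMappingParams(),
                 f: float = 250e3) -> AcousticMedium:
    """Convert a head phantom's HU volume into an :class:`AcousticMedium`.

    Density and speed are affine in HU with HU=0 -> water and
    HU=hu_ref -> (rho_max, c_max).  Soft tissue (every non-skull voxel) is
    forced to water values, so heterogeneity enters only through the skull.
    Attenuation follows the porosity power law; pure water attenuates zero.
    """
    hu = np.asarray(phantom.hu_volume, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume must be finite")

    skull = phantom.compartment_labels == phantom.SKULL

    frac = np.clip(hu / params.hu_ref, 0.0, 1.0)
    density = params.rho_water + frac * (params.rho_max - params.rho_water)
    speed = params.c_water + frac * (params.c_max - params.c_water)
    # homogeneous-soft-tissue assumption: only skull keeps its mapped values
    density = np.where(skull, density, params.rho_water)
    speed = np.where(skull, speed, params.c_water)

    phi = porosity(density, params)
    atten = attenuation_power_law(phi, f, params)
    # the porosity law applies to mineralized bone only: skull voxels at
    # HU <= 0 contain no bone and behave as water (zero attenuation)
    atten = np.where(skull & (hu > 0), atten, 0.0)
    return AcousticMedium(density=density, speed=speed, attenuation=atten,
                          porosity=np.asarray(phi), spacing=float(phantom.spacing))


# ---------------------------------------------------------------------------
# focused field
# ---------------------------------------------------------------------------

def oneil_onaxis(geom: TransducerGeometry, f0: float, source_pressure: float,
                 z_mm: np.ndarray, c: float = 1500.0) -> np.ndarray:
    """Closed-form on-axis pressure amplitude of a uniform focused spherical cap.

    Classical lossless-water solution for a concave cap of radius of
    curvature ``A`` (apex at z=0, centre of curvature at z=A) driven at
    uniform surface amplitude ``source_pressure``:

        |p(z)| = 2 p0 |A/(A - z)| |sin(k (r_e(z) - z) / 2)|

    where ``r_e(z)`` is the distance from the axial point to the cap rim; at
    the geometric focus the limit is ``p0 k A (1 - cos(theta_max))``.
    Apodization is not part of the closed form (uniform cap only).

    Parameters are in mm for ``z_mm`` and SI otherwise; returns Pa.
    """
    wavelength_mm = c / f0 * 1e3
    if geom.aperture < 5.0 * wavelength_mm:
        warnings.warn("cap aperture below ~5 wavelengths; on-axis closed form "
                      "loses accuracy", stacklevel=2)
    A = geom.roc * 1e-3
    a = geom.aperture / 2.0 * 1e-3
    z = np.asarray(z_mm, dtype=float) * 1e-3
    k = 2.0 * np.pi * f0 / c
    sin_t = a / A
    cos_t = np.sqrt(1.0 - sin_t ** 2)

    r_edge = np.sqrt(A ** 2 + (z - A) ** 2 + 2.0 * A * (z - A) * cos_t)
    dz = A - z
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * source_pressure * np.abs(A / dz) * np.abs(np.sin(0.5 * k * (r_edge - z)))
    focal = source_pressure * k * A * (1.0 - cos_t)
    p = np.where(np.abs(dz) < 1e-9, focal, p)
    return p


def _cap_sources(geom: TransducerGeometry, n_theta: int = 60,
                 n_phi: int = 120) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature points (mm, in transducer frame) and amplitude*area weights
    for the apodized spherical cap.  Apex at origin, axis +z, focus at z=roc."""
    A = geom.roc
    a = geom.aperture / 2.0
    theta_max = np.arcsin(a / A)
    # midpoint rule on (theta, phi); dS = A^2 sin(theta) dtheta dphi
    th = (np.arange(n_theta) + 0.5) * theta_max / n_theta
    ph = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    x = A * np.sin(TH) * np.cos(PH)
    y = A * np.sin(TH) * np.sin(PH)
    z = A * (1.0 - np.cos(TH))
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    dS = A ** 2 * np.sin(TH) * (theta_max / n_theta) * (2.0 * np.pi / n_phi)
    # radial Gaussian taper with rim amplitude = apodization_r of the centre
    if geom.apodization_r < 1.0:
        sigma2 = -a ** 2 / (2.0 * np.log(geom.apodization_r))
        radial2 = (A * np.sin(TH)) ** 2
        apod = np.exp(-radial2 / (2.0 * sigma2))
    else:
        apod = np.ones_like(TH)
    return pts, (dS * apod).ravel()


def _frame(geom: TransducerGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (3x3, rows) whose third row is the beam axis, and origin."""
    w = np.asarray(geom.axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w]), np.asarray(geom.position, dtype=float)


def rayleigh_points(geom: TransducerGeometry, points_mm: np.ndarray, f0: float,
                    source_pressure: float, c: float = 1500.0,
                    n_theta: int = 60, n_phi: int = 120) -> np.ndarray:
    """Steady-state pressure amplitude (Pa) at arbitrary points (mm, lab frame)
    from the discretized Rayleigh integral over the apodized cap.

    p(x) = (i k p0 / 2 pi) * sum_j w_j exp(i k r_j) / r_j  with w_j the
    apodized area weights; linear in ``source_pressure``.
    """
    basis, origin = _frame(geom)
    pts_local = (np.asarray(points_mm, dtype=float) - origin) @ basis.T  # mm
    src, w = _cap_sources(geom, n_theta, n_phi)
    k = 2.0 * np.pi * f0 / c  # rad/m
    out = np.empty(len(pts_local), dtype=float)
    src_m = src * 1e-3
    w_m2 = w * 1e-6
    ss = (src_m ** 2).sum(axis=1)
    # |p - s|^2 = |p|^2 + |s|^2 - 2 p.s via BLAS; chunk to bound memory
    chunk = max(1, int(4e7 // max(len(src), 1)))
    for i0 in range(0, len(pts_local), chunk):
        p = pts_local[i0:i0 + chunk] * 1e-3
        r2 = (p ** 2).sum(axis=1)[:, None] + ss[None, :] - 2.0 * (p @ src_m.T)
        r = np.sqrt(np.maximum(r2, 1e-12))
        contrib = (np.exp(1j * k * r) / r) @ w_m2
        out[i0:i0 + chunk] = np.abs(contrib)
    return out * (k * source_pressure / (2.0 * np.pi))


def _ray_attenuation(medium: AcousticMedium, origin_mm: np.ndarray,
                     points_mm: np.ndarray, step_mm: float) -> np.ndarray:
    """exp(-integral of alpha along the straight ray source->point), per point."""
    alpha = medium.attenuation  # Np/m
    if not np.any(alpha > 0):
        return np.ones(len(points_mm))
    vecs = points_mm - origin_mm[None, :]
    dists = np.linalg.norm(vecs, axis=1)
    n_steps = max(2, int(np.ceil(dists.max() / step_mm)))
    ts = (np.arange(n_steps) + 0.5) / n_steps
    total = np.zeros(len(points_mm))
    shape = np.array(alpha.shape)
    for t in ts:
        sample = origin_mm[None, :] + t * vecs  # mm
        idx = np.round(sample / medium.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
        vals = np.zeros(len(points_mm))
        ii = idx[inside]
        vals[inside] = alpha[ii[:, 0], ii[:, 1], ii[:, 2]]
        total += vals
    # mean alpha along ray * path length (m)
    return np.exp(-(total / n_steps) * dists * 1e-3)


def rayleigh_field(geom: TransducerGeometry, grid_shape: tuple[int, int, int],
                   spacing: float, f0: float, medium: AcousticMedium | None = None,
                   source_pressure: float = 1.0, focus_index: tuple[int, int, int] | None = None,
                   n_theta: int = 60, n_phi: int = 120) -> PressureField:
    """Pressure amplitude over a voxel grid; heterogeneous media attenuate each
    voxel by the Beer–Lambert factor along the apex-to-voxel ray."""
    idx = np.indices(grid_shape).reshape(3, -1).T
    pts_mm = idx * spacing
    amp = rayleigh_points(geom, pts_mm, f0, source_pressure,
                          c=1500.0 if medium is None else float(np.min(medium.speed)),
                          n_theta=n_theta, n_phi=n_phi)
    if medium is not None:
        origin = np.asarray(geom.position, dtype=float)
        amp = amp * _ray_attenuation(medium, origin, pts_mm, step_mm=spacing)
    field = amp.reshape(grid_shape)
    if focus_index is not None:
        fi = tuple(int(i) for i in focus_index)
        if any(i < 0 or i >= s for i, s in zip(fi, grid_shape)):
            raise ValueError("focus index outside the grid")
    return PressureField(peak_pressure=field, spacing=spacing, focus_index=focus_index)


def rescale_by_calibration(field: PressureField, protocol: SonicationProtocol,
                           free_water_max: float) -> PressureField:
    """Anchor absolute amplitude: scale the field so that the free-water
    simulation maximum equals the calibrated pressure at the drive voltage
    (linear in voltage)."""
    if free_water_max <= 0:
        raise ValueError("free-water reference maximum must be positive")
    scale = protocol.free_water_pressure / free_water_max
    return PressureField(peak_pressure=field.peak_pressure * scale,
                         spacing=field.spacing, focus_index=field.focus_index)


def pulse_intensities(p: float | np.ndarray, rho: float = 1000.0, c: float = 1500.0,
                      duty_cycle: float = 0.3) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Plane-wave pulse intensities from peak pressure amplitude.

    I_sppa = p^2 / (2 rho c) in W/cm^2; I_spta = I_sppa * duty_cycle.
    """
    if not (0.0 <= duty_cycle <= 1.0):
        raise ValueError("duty cycle must lie in [0, 1]")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("pressure amplitude must be non-negative")
    i_sppa = p_arr ** 2 / (2.0 * rho * c) / 1e4  # W/m^2 -> W/cm^2
    i_spta = i_sppa * duty_cycle
    if np.isscalar(p):
        return float(i_sppa), float(i_spta)
    return i_sppa, i_spta
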