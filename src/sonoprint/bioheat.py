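"""Pennes bioheat simulation of a sonication train.

Solves rho C dT/dt = kappa lap(T) + q(t) - w rho_b C_b (T - T_a) with an
explicit forward-Euler / central-difference scheme on an isotropic voxel
grid, over a pre-sonication / sonication / post-sonication timeline with
Dirichlet boundaries.  The perfusion sink acts only in brain tissue (it is
assumed homogeneous over the brain and absent in skull and water).  Heating
uses the time-averaged source q * duty_cycle by default; resolving the
30 ms / 100 ms burst schedule explicitly is available but changes the slow
thermal response negligibly, since the thermal time constants are three
orders of magnitude above the burst period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustics import (DB_PER_NEPER, AcousticMedium, MediumMappingParams,
                        PressureField, SonicationProtocol, porosity)
from .synthetic import BRAIN, SKULL, WATER


@dataclass
class ThermalMaterials:
    """Per-voxel thermal properties and the acoustic absorption grid."""

    kappa: np.ndarray    # W/m/K
    C: np.ndarray        # J/kg/K
    rho: np.ndarray      # kg/m^3
    alpha_abs: np.ndarray  # Np/m at carrier — absorption only, not total attenuation
    speed: np.ndarray    # m/s (for q = alpha_abs * p^2 / (2 rho c))

    KAPPA_TISSUE = 0.528
    KAPPA_SKULL = 0.4
    C_TISSUE = 3600.0
    C_SKULL = 1300.0
    ALPHA_ABS_TISSUE_DB = 0.21   # dB/cm/MHz^b

    @classmethod
    def alpha_abs_max_db(cls, params: MediumMappingParams = MediumMappingParams()) -> float:
        """Skull absorption ceiling alpha0/3 in dB/cm/MHz^b."""
        return params.alpha0 / 3.0

    @classmethod
    def from_medium(cls, medium: AcousticMedium, labels: np.ndarray,
                    f: float = 250e3,
                    params: MediumMappingParams = MediumMappingParams()) -> "ThermalMaterials":
        """Build thermal grids from an acoustic medium and compartment labels.

        Tissue absorption is 0.21 dB/cm/MHz^b; skull absorption scales
        linearly with density (via 1 - porosity) up to the ceiling alpha0/3 —
        absorption is deliberately lower than the propagation attenuation,
        which also includes scattering.
        """
        skull = labels == SKULL
        water = labels == WATER
        kappa = np.where(skull, cls.KAPPA_SKULL, cls.KAPPA_TISSUE)
        C = np.where(skull, cls.C_SKULL, cls.C_TISSUE)
        f_mhz = f / 1e6
        alpha_tis = cls.ALPHA_ABS_TISSUE_DB * f_mhz ** params.b / DB_PER_NEPER * 100.0
        alpha_sk_max = cls.alpha_abs_max_db(params) * f_mhz ** params.b / DB_PER_NEPER * 100.0
        phi = np.asarray(porosity(medium.density, params))
        alpha = np.where(skull, alpha_sk_max * (1.0 - phi), alpha_tis)
        alpha = np.where(water, 0.0, alpha)
        return cls(kappa=kappa, C=C, rho=medium.density.astype(float),
                   alpha_abs=alpha, speed=medium.speed.astype(float))

    @classmethod
    def homogeneous_tissue(cls, shape: tuple[int, int, int], f: float = 250e3,
                           b: float = 1.1) -> "ThermalMaterials":
        """Uniform soft-tissue grid (water acoustic values, tissue thermal values)."""
        f_mhz = f / 1e6
        alpha = cls.ALPHA_ABS_TISSUE_DB * f_mhz ** b / DB_PER_NEPER * 100.0
        one = np.ones(shape)
        return cls(kappa=cls.KAPPA_TISSUE * one, C=cls.C_TISSUE * one,
                   rho=1000.0 * one, alpha_abs=alpha * one, speed=1500.0 * one)


@dataclass(frozen=True)
class PerfusionParams:
    """Blood perfusion sink parameters, homogeneous over the brain."""

    w: float = 0.008       # 1/s perfusion rate
    rho_b: float = 1030.0  # kg/m^3 blood density
    C_b: float = 3620.0    # J/kg/K blood specific heat
    T_a: float = 37.0      # degC arterial temperature

    @property
    def sink_coefficient(self) -> float:
        """w * rho_b * C_b in W/m^3/K."""
        return self.w * self.rho_b * self.C_b


@dataclass(frozen=True)
class ThermalTimeline:
    """Pre / on / post phases of the simulated sonication, seconds."""

    pre: float = 60.0
    on: float = 40.0
    post: float = 300.0
    dt: float | None = None      # None -> largest stable step
    record_stride: int = 20      # solver steps per saved frame


@dataclass
class TemperatureState:
    T: np.ndarray     # degC
    time: float       # s


def initial_temperature(labels: np.ndarray, t_tissue: float = 37.0,
                        t_water: float = 24.0) -> TemperatureState:
    """37 degC in brain, skull and background tissue; 24 degC in the water cone."""
    T = np.full(labels.shape, t_tissue, dtype=float)
    T[labels == WATER] = t_water
    return TemperatureState(T=T, time=0.0)


def heat_source(field: PressureField, materials: ThermalMaterials,
                protocol: SonicationProtocol, time_averaged: bool = True) -> np.ndarray:
    """Acoustic heat deposition q = alpha_abs * P^2 / (2 rho c) in W/m^3.

    ``time_averaged`` multiplies by the duty cycle, folding the burst
    schedule into a continuous equivalent source.
    """
    p = field.peak_pressure
    if p.shape != materials.alpha_abs.shape:
        raise ValueError("pressure and material grids must be congruent")
    q = materials.alpha_abs * p ** 2 / (2.0 * materials.rho * materials.speed)
    if time_averaged:
        q = q * protocol.duty_cycle
    return q


def stability_dt(materials: ThermalMaterials, spacing_mm: float,
                 safety: float = 0.9) -> float:
    """von Neumann bound for the 3D explicit scheme: dt <= dx^2 / (6 max D)."""
    dx = spacing_mm * 1e-3
    diffusivity = materials.kappa / (materials.rho * materials.C)
    return safety * dx ** 2 / (6.0 * float(diffusivity.max()))


def solve_pennes(state0: TemperatureState, materials: ThermalMaterials,
                 perfusion: PerfusionParams, q: np.ndarray,
                 timeline: ThermalTimeline, spacing_mm: float,
                 brain_mask: np.ndarray | None = None,
                 protocol: SonicationProtocol | None = None,
                 pulsed: bool = False,
                 boundary: str = "dirichlet") -> tuple[list[TemperatureState], np.ndarray]:
    """March the bioheat equation across the pre/on/post timeline.

    ``q`` is the sonication-phase source (W/m^3); it is switched on during
    [pre, pre+on) only.  With ``pulsed`` and a protocol, the burst schedule
    is resolved explicitly (q scaled to its instantaneous value and gated at
    the burst period) instead of time-averaged.  ``brain_mask`` restricts
    the perfusion sink; default is everywhere q-independent perfusion off —
    callers pass the brain-tissue mask.  ``boundary`` is ``dirichlet``
    (edges pinned at their initial values) or ``periodic`` (validation
    mode for the perfusion-only closed form).

    Returns the recorded frames and the focal-free per-frame time vector.
    """
    dx = spacing_mm * 1e-3
    dt_max = stability_dt(materials, spacing_mm)
    dt = timeline.dt if timeline.dt is not None else dt_max
    if dt > dt_max * (1 + 1e-12):
        raise ValueError(f"dt={dt:g}s unstable; explicit bound is {dt_max:g}s")

    T = state0.T.astype(float).copy()
    if brain_mask is None:
        brain_mask = np.ones_like(T, dtype=bool)
    sink = perfusion.sink_coefficient * brain_mask  # W/m^3/K
    rhoC = materials.rho * materials.C
    kappa = materials.kappa
    total = timeline.pre + timeline.on + timeline.post
    n_steps = int(np.ceil(total / dt))

    if pulsed:
        if protocol is None:
            raise ValueError("pulsed mode needs the sonication protocol")
        q_inst = q / protocol.duty_cycle  # undo any averaging implied upstream
        period = protocol.burst_period * 1e-3
        burst = protocol.burst_duration * 1e-3

    frames: list[TemperatureState] = [TemperatureState(T=T.copy(), time=0.0)]
    times = [0.0]
    boundary_T = T.copy()

    for step in range(n_steps):
        t = step * dt
        if timeline.pre <= t < timeline.pre + timeline.on:
            if pulsed:
                phase = (t - timeline.pre) % period
                q_t = q_inst if phase < burst else 0.0
            else:
                q_t = q
        else:
            q_t = 0.0

        if boundary == "periodic":
            lap = (np.roll(T, 1, 0) + np.roll(T, -1, 0)
                   + np.roll(T, 1, 1) + np.roll(T, -1, 1)
                   + np.roll(T, 1, 2) + np.roll(T, -1, 2) - 6.0 * T) / dx ** 2
            rhs = kappa * lap + q_t - sink * (T - perfusion.T_a)
            T = T + dt * rhs / rhoC
        else:
            lap = np.zeros_like(T)
            core = (slice(1, -1),) * 3
            lap[core] = (T[2:, 1:-1, 1:-1] + T[:-2, 1:-1, 1:-1]
                         + T[1:-1, 2:, 1:-1] + T[1:-1, :-2, 1:-1]
                         + T[1:-1, 1:-1, 2:] + T[1:-1, 1:-1, :-2]
                         - 6.0 * T[core]) / dx ** 2
            rhs = kappa * lap + q_t - sink * (T - perfusion.T_a)
            T = T + dt * rhs / rhoC
            # Dirichlet: pin all faces at their initial temperatures
            for ax in range(3):
                sl0 = [slice(None)] * 3
                sl1 = [slice(None)] * 3
                sl0[ax] = 0
                sl1[ax] = -1
                T[tuple(sl0)] = boundary_T[tuple(sl0)]
                T[tuple(sl1)] = boundary_T[tuple(sl1)]

        if (step + 1) % timeline.record_stride == 0 or step == n_steps - 1:
            frames.append(TemperatureState(T=T.copy(), time=(step + 1) * dt))
            times.append((step + 1) * dt)

    return frames, np.asarray(times)


def summarize_thermal(frames: list[TemperatureState], labels: np.ndarray,
                      focus: tuple[int, int, int],
                      baseline: float = 37.0) -> dict:
    """Per-compartment maxima over space and time, plus the focal timecourse."""
    if not frames:
        raise ValueError("no recorded frames")
    report: dict = {"focal_timecourse": [], "times": []}
    masks = {"skull": labels == SKULL, "brain": labels == BRAIN,
             "water": labels == WATER}
    if not any(m.any() for m in masks.values()):
        raise ValueError("no labelled compartment voxels to summarize")
    maxima = {k: -np.inf for k in masks}
    for fr in frames:
        report["times"].append(fr.time)
        report["focal_timecourse"].append(float(fr.T[tuple(focus)]))
        for k, m in masks.items():
            if m.any():
                maxima[k] = max(maxima[k], float(fr.T[m].max()))
    for k, m in masks.items():
        if m.any():
            report[f"max_{k}_T"] = maxima[k]
            report[f"max_{k}_dT"] = maxima[k] - baseline
    report["max_focal_T"] = float(max(report["focal_timecourse"]))
    report["max_focal_dT"] = report["max_focal_T"] - baseline
    return report
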