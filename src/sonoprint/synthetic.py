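"""Synthetic head phantoms and BOLD datasets.

The phantom stands in for a CT head scan: an ellipsoidal skull shell of
elevated Hounsfield units around homogeneous brain tissue, with a cylindrical
degassed-water coupling cone seated on the shell above the focus.

The BOLD generator emulates a multi-subject, multi-run, two-condition
anaesthetized-macaque resting-state design (three runs of 800 volumes at
TR 2 s): voxel timeseries are linear mixtures of latent ROI signals whose
population correlation equals a prescribed coupling matrix, plus white
voxel noise, plus an optional shared slow component loaded most heavily on
the meningeal compartment (the non-neuronal global confound).  A stimulation
condition "sharpens" the seed region's coupling profile — within-network
coupling scaled up, coupling between the seed and out-of-network regions
scaled down — mirroring the direction of the offline-ultrasound effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# compartment codes shared across the package
BACKGROUND, BRAIN, SKULL, WATER = 0, 1, 2, 3          # phantom labels
GM, WM, MENINGEAL = 1, 2, 3                            # BOLD compartment labels


# ---------------------------------------------------------------------------
# head phantom
# ---------------------------------------------------------------------------

@dataclass
class HeadPhantom:
    """CT-like head phantom on an isotropic grid."""

    hu_volume: np.ndarray            # Hounsfield units
    spacing: float                   # mm per voxel
    compartment_labels: np.ndarray   # BACKGROUND | BRAIN | SKULL | WATER
    focus_point: tuple[int, int, int]

    BACKGROUND = BACKGROUND
    BRAIN = BRAIN
    SKULL = SKULL
    WATER = WATER


def make_head_phantom(grid_shape: tuple[int, int, int] = (64, 64, 64),
                      spacing: float = 0.5, skull_hu: float = 1800.0,
                      skull_thickness: float = 2.0, seed: int = 0) -> HeadPhantom:
    """Build an ellipsoidal skull shell with interior brain and a water cone.

    The shell axes fill ~70% of the grid; the cone is a cylinder along +z
    from the top of the shell to the grid edge, centred over the focus.  The
    focus is placed at the brain centre.  Deterministic given ``seed`` (seed
    only drives sub-HU tissue texture).
    """
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 32:
        raise ValueError("grid must be at least 32 voxels per axis")
    if skull_thickness < 2.0 * spacing:
        raise ValueError("skull thickness must be at least two voxels")

    rng = np.random.default_rng(seed)
    centre = (np.array(shape) - 1) / 2.0
    semi = 0.35 * np.array(shape) * spacing       # outer semi-axes, mm
    if np.any(semi <= skull_thickness * 2):
        raise ValueError("grid too small to contain shell and interior")

    ii = np.indices(shape).astype(float)
    d_mm = (ii - centre.reshape(3, 1, 1, 1)) * spacing
    r_out = np.sqrt(((d_mm / semi.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    semi_in = semi - skull_thickness
    r_in = np.sqrt(((d_mm / semi_in.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))

    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    labels[r_out <= 1.0] = SKULL
    labels[r_in <= 1.0] = BRAIN

    # cylindrical water coupling cone above the focus, along +z
    radius_mm = 0.2 * min(shape[0], shape[1]) * spacing
    rho_xy = np.sqrt(d_mm[0] ** 2 + d_mm[1] ** 2)
    zz = np.broadcast_to(np.arange(shape[2]).reshape(1, 1, -1), shape)
    cone = (rho_xy <= radius_mm) & (labels == BACKGROUND) & (zz > centre[2])
    labels[cone] = WATER

    hu = np.zeros(shape, dtype=float)
    hu[labels == BRAIN] = 40.0 + rng.normal(0.0, 2.0, int((labels == BRAIN).sum()))
    hu[labels == SKULL] = skull_hu
    # water cone and background stay at HU ~ 0

    focus = tuple(int(round(c)) for c in centre)
    if labels[focus] != BRAIN:
        raise RuntimeError("focus fell outside brain tissue")
    return HeadPhantom(hu_volume=hu, spacing=float(spacing),
                       compartment_labels=labels, focus_point=focus)


# ---------------------------------------------------------------------------
# BOLD data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Planted stimulation effect on the seed region's coupling profile."""

    seed_roi: str = "SMA"
    local_gain: float = 1.3
    distal_loss: float = 0.6
    global_confound_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.local_gain < 1.0:
            raise ValueError("local_gain must be >= 1")
        if not (0.0 <= self.distal_loss <= 1.0):
            raise ValueError("distal_loss must lie in [0, 1]")
        if self.global_confound_sd < 0.0:
            raise ValueError("global_confound_sd must be >= 0")


@dataclass
class RunInfo:
    subject: int
    run: int
    condition: str  # "control" | "stim"


@dataclass
class BoldDataset:
    """Multi-run BOLD data on a shared voxel grid.

    ``timeseries`` maps (subject, run) -> 4D array (x, y, z, t).
    """

    timeseries: dict[tuple[int, int], np.ndarray]
    runs: list[RunInfo]
    tr: float
    compartments: np.ndarray                 # GM | WM | MENINGEAL | 0
    motion_params: dict[tuple[int, int], np.ndarray]   # (t, 6)
    roi_voxels: dict[str, dict[str, np.ndarray]]       # name -> {"left","right"}: (n,3) int
    grid_shape: tuple[int, int, int]
    spacing: float
    rng_seed: int


def default_roi_layout(grid_shape: tuple[int, int, int] = (14, 14, 10),
                       ) -> tuple[dict[str, tuple[int, int, int]], dict[str, str]]:
    """Bilateral ROI centres (right-hemisphere voxel coords) and the
    ROI -> network partition used by the default synthetic design.

    Two networks loosely modelled on the sensorimotor vs prefrontal split:
    the seed ("SMA"-like) couples strongly within its own network and weakly
    with the other; an independent control seed ("FPC"-like) mirrors it.
    """
    nx, ny, nz = grid_shape
    if nx < 14 or ny < 14 or nz < 10:
        raise ValueError("default ROI layout needs a grid of at least 14x14x10")
    x_r = 3 * nx // 4
    z_hi, z_lo = nz - 3, nz - 6
    centres = {
        "SMA": (x_r, 3, z_hi),
        "M1": (x_r, 6, z_hi),
        "SPL": (x_r, 9, z_hi),
        "MCC": (x_r, 3, z_lo),
        "FPC": (x_r, 12, z_hi),
        "9m": (x_r, 6, z_lo),
        "PCC": (x_r, 9, z_lo),
        "aSTG": (x_r, 12, z_lo),
    }
    partition = {"SMA": "motor", "M1": "motor", "SPL": "motor", "MCC": "motor",
                 "FPC": "prefrontal", "9m": "prefrontal", "PCC": "prefrontal",
                 "aSTG": "prefrontal"}
    return centres, partition


def default_base_coupling(partition: dict[str, str], within: float = 0.6,
                          between: float = 0.15) -> tuple[np.ndarray, list[str]]:
    """Block-structured ROI coupling matrix: ``within`` inside a network,
    ``between`` across networks, unit diagonal."""
    names = list(partition)
    n = len(names)
    C = np.full((n, n), between)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if partition[a] == partition[b]:
                C[i, j] = within
    np.fill_diagonal(C, 1.0)
    return C, names


def _nearest_psd(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped projection to the PSD cone, diagonal renormalized to 1."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    w = np.clip(w, eps, None)
    M = (V * w) @ V.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


def sharpen_coupling(C: np.ndarray, names: list[str],
                     partition: dict[str, str], effect: EffectSpec) -> np.ndarray:
    """Apply the planted sharpening to the population coupling matrix.

    Off-diagonal entries within the seed's network are multiplied by
    ``local_gain`` (capped at 0.95); entries linking the seed to
    out-of-network regions are multiplied by ``distal_loss``.  The result is
    projected to the nearest unit-diagonal PSD matrix.
    """
    seed_net = partition[effect.seed_roi]
    s = names.index(effect.seed_roi)
    M = C.copy()
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            if partition[a] == seed_net and partition[b] == seed_net:
                M[i, j] = min(M[i, j] * effect.local_gain, 0.95)
            elif (i == s and partition[b] != seed_net) or (j == s and partition[a] != seed_net):
                M[i, j] = M[i, j] * effect.distal_loss
    return _nearest_psd(M)


def _roi_masks(centres: dict[str, tuple[int, int, int]],
               grid_shape: tuple[int, int, int], radius_vox: float = 1.2,
               ) -> dict[str, dict[str, np.ndarray]]:
    """Bilateral spherical ROI voxel sets; the left member mirrors the right
    across the mid-sagittal (x) plane."""
    idx = np.indices(grid_shape).reshape(3, -1).T
    nx = grid_shape[0]
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, c in centres.items():
        c = np.asarray(c, dtype=float)
        c_l = c.copy()
        c_l[0] = nx - 1 - c[0]
        right = idx[np.linalg.norm(idx - c, axis=1) <= radius_vox]
        left = idx[np.linalg.norm(idx - c_l, axis=1) <= radius_vox]
        if len(right) == 0 or len(left) == 0:
            raise ValueError(f"empty ROI {name}")
        out[name] = {"right": right, "left": left}
    return out


def _smooth_component(n: int, rng: np.random.Generator, tr: float,
                      cutoff_s: float = 30.0) -> np.ndarray:
    """Unit-variance slow component: white noise smoothed to ~cutoff_s."""
    x = rng.standard_normal(n)
    sigma = cutoff_s / tr / 2.355
    y = ndimage.gaussian_filter1d(x, sigma, mode="wrap")
    sd = y.std()
    return y / sd if sd > 0 else y


def make_bold_dataset(n_subjects: int = 3, n_runs: int = 3, n_volumes: int = 800,
                      tr: float = 2.0,
                      grid_shape: tuple[int, int, int] = (14, 14, 10),
                      spacing: float = 2.0,
                      network_partition: dict[str, str] | None = None,
                      roi_centres: dict[str, tuple[int, int, int]] | None = None,
                      base_coupling: np.ndarray | None = None,
                      effect: EffectSpec = EffectSpec(),
                      noise_sd: float = 1.0,
                      signal_sd: float = 1.0,
                      meningeal_load: float = 1.0,
                      tissue_load: float = 0.35,
                      wm_load: float = 0.05,
                      seed: int = 0) -> tuple[BoldDataset, BoldDataset]:
    """Generate matched (control, stim) BOLD datasets.

    Latent ROI signals are Gaussian with correlation exactly ``base_coupling``
    (control) or its sharpened version (stim), obtained by mixing white noise
    through the Cholesky factor.  Every voxel of an ROI carries that ROI's
    latent signal (bilaterally), scaled by ``signal_sd``, plus white noise of
    ``noise_sd``.  A shared slow global component of amplitude
    ``global_confound_sd`` is added with weight ``meningeal_load`` on
    meningeal voxels, ``tissue_load`` on grey matter and ``wm_load`` on deep
    white matter (a vascular component strongest near the pial surface and
    venous sinuses, weakest deep in WM).  Motion parameters are
    smooth low-amplitude random walks.  Reproducible given ``seed``.
    """
    if n_volumes < 100:
        raise ValueError("need at least 100 volumes per run")
    if network_partition is None or roi_centres is None:
        roi_centres, network_partition = default_roi_layout(grid_shape)
    if base_coupling is None:
        base_coupling, names = default_base_coupling(network_partition)
    else:
        names = list(network_partition)
        C = np.asarray(base_coupling, dtype=float)
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("base_coupling must be symmetric with unit diagonal")
        if np.linalg.eigvalsh((C + C.T) / 2).min() < -1e-10:
            raise ValueError("base_coupling must be positive semidefinite")
        base_coupling = C

    stim_coupling = sharpen_coupling(base_coupling, names, network_partition, effect)
    rois = _roi_masks(roi_centres, grid_shape)

    # compartments: GM on ROI voxels, WM interior slab, meningeal outer shell
    comp = np.zeros(grid_shape, dtype=np.int8)
    comp[1:-1, 1:-1, 1:-1] = WM
    shell = comp == 0
    comp[shell] = MENINGEAL
    for name in rois:
        for side in ("left", "right"):
            v = rois[name][side]
            comp[v[:, 0], v[:, 1], v[:, 2]] = GM

    n_vox = int(np.prod(grid_shape))
    flat_comp = comp.ravel()
    roi_flat = {name: {side: np.ravel_multi_index(rois[name][side].T, grid_shape)
                       for side in ("left", "right")} for name in rois}

    def _generate(condition: str, coupling: np.ndarray, base_seed: int) -> BoldDataset:
        L = np.linalg.cholesky(coupling + 1e-12 * np.eye(len(names)))
        ts: dict[tuple[int, int], np.ndarray] = {}
        motion: dict[tuple[int, int], np.ndarray] = {}
        runs: list[RunInfo] = []
        for s in range(n_subjects):
            for r in range(n_runs):
                rng = np.random.default_rng((base_seed, s, r))
                # empirically whiten the sample before mixing so the sample
                # correlation of the latents equals the coupling matrix exactly
                Z = rng.standard_normal((len(names), n_volumes))
                Z -= Z.mean(axis=1, keepdims=True)
                L_emp = np.linalg.cholesky(Z @ Z.T / n_volumes)
                latents = L @ np.linalg.solve(L_emp, Z)
                data = rng.normal(0.0, noise_sd, (n_vox, n_volumes))
                for i, name in enumerate(names):
                    for side in ("left", "right"):
                        data[roi_flat[name][side]] += signal_sd * latents[i]
                if effect.global_confound_sd > 0:
                    g = _smooth_component(n_volumes, rng, tr)
                    load = np.select(
                        [flat_comp == MENINGEAL, flat_comp == GM],
                        [meningeal_load, tissue_load], default=wm_load)
                    data += effect.global_confound_sd * load[:, None] * g[None, :]
                ts[(s, r)] = data.reshape(*grid_shape, n_volumes)
                steps = rng.normal(0.0, 0.01, (n_volumes, 6))
                motion[(s, r)] = ndimage.gaussian_filter1d(
                    np.cumsum(steps, axis=0), 5.0, axis=0)
                runs.append(RunInfo(subject=s, run=r, condition=condition))
        return BoldDataset(timeseries=ts, runs=runs, tr=tr, compartments=comp.copy(),
                           motion_params=motion, roi_voxels=rois,
                           grid_shape=grid_shape, spacing=spacing, rng_seed=base_seed)

    control = _generate("control", base_coupling, seed * 2 + 1)
    stim = _generate("stim", stim_coupling, seed * 2 + 2)
    return control, stim
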