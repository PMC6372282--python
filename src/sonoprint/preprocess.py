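"""BOLD timeseries cleaning.

The pipeline mirrors a standard anaesthetized-primate resting-state recipe:
discard initial volumes, temporal high-pass (2000 s cutoff), dynamic
band-stop notches at shared spectral noise peaks, nuisance regression of
compartment signals (mean + first five principal components of the combined
white-matter and meningeal compartments) together with a second-degree
Volterra expansion of the six motion/B0 parameters, temporal low-pass
(10 s cutoff), volumetric Gaussian smoothing (3 mm FWHM) and demeaning.

All temporal filters are zero-phase spectral projections on the DCT-II
basis (hard frequency masks): the family is a package choice — projections
are exactly idempotent, have unit passband gain and preserve the
correlation structure the downstream connectivity analysis depends on.
With a 2000 s high-pass cutoff on a ~1600 s run, a causal IIR family
cannot even represent the cutoff; the DCT projection (the standard fMRI
high-pass construction) handles it exactly.

Timeseries are handled as (n_voxels, n_volumes) matrices; volumetric
operations take the 4D (x, y, z, t) layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy import fft, ndimage

logger = logging.getLogger("sonoprint")

FWHM_TO_SIGMA = 2.3548200450309493  # 2 sqrt(2 ln 2)


@dataclass
class FilterSpec:
    highpass_cutoff: float = 2000.0  # s (period)
    lowpass_cutoff: float = 10.0     # s (period)
    notches: list[tuple[float, float]] = field(default_factory=list)  # (centre Hz, halfwidth Hz)

    def __post_init__(self) -> None:
        if self.highpass_cutoff <= self.lowpass_cutoff:
            raise ValueError("high-pass period must exceed low-pass period")


@dataclass
class ConfoundSet:
    compartment_mean: np.ndarray          # (t,)
    compartment_pcs: np.ndarray           # (t, k)
    motion_expanded: np.ndarray | None    # (t, n_terms)

    def design_matrix(self, include_compartment: bool = True) -> np.ndarray:
        cols = []
        if include_compartment:
            cols.append(self.compartment_mean[:, None])
            cols.append(self.compartment_pcs)
        if self.motion_expanded is not None:
            cols.append(self.motion_expanded)
        if not cols:
            raise ValueError("no confound columns selected")
        return np.column_stack(cols)


def drop_initial_volumes(ts: np.ndarray, n: int = 5) -> np.ndarray:
    """Discard the first ``n`` volumes (time is the last axis)."""
    if ts.shape[-1] <= n:
        raise ValueError(f"run of {ts.shape[-1]} volumes cannot drop {n}")
    return ts[..., n:]


def temporal_filter(ts: np.ndarray, spec: FilterSpec, tr: float,
                    apply_highpass: bool = True, apply_lowpass: bool = True,
                    apply_notches: bool = True) -> np.ndarray:
    """Zero-phase high-/low-pass and band-stop notches by DCT-II projection.

    The DCT bin k corresponds to frequency k / (2 N TR); bins below the
    high-pass cutoff (including DC), above the low-pass cutoff, or inside a
    notch band are zeroed and the series reconstructed.  Exactly idempotent.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    nyq = 0.5 / tr
    X = np.asarray(ts, dtype=float)
    n = X.shape[-1]
    freqs = np.arange(n) / (2.0 * n * tr)
    keep = np.ones(n, dtype=bool)
    if apply_highpass:
        fc = 1.0 / spec.highpass_cutoff
        if fc >= nyq:
            raise ValueError("high-pass cutoff beyond Nyquist")
        keep &= freqs >= fc
        keep[0] = False  # DC always removed by the high-pass
    if apply_notches:
        for centre, half in spec.notches:
            if not (0.0 < centre < nyq):
                raise ValueError(f"notch centre {centre} outside (0, Nyquist)")
            keep &= ~((freqs >= centre - half) & (freqs <= centre + half))
    if apply_lowpass:
        fc = 1.0 / spec.lowpass_cutoff
        if fc >= nyq:
            raise ValueError("low-pass cutoff beyond Nyquist")
        keep &= freqs <= fc
    coeffs = fft.dct(X, type=2, axis=-1, norm="ortho")
    coeffs[..., ~keep] = 0.0
    return fft.idct(coeffs, type=2, axis=-1, norm="ortho")


def detect_bandstop(ts: np.ndarray, tr: float, n_pcs: int = 3,
                    threshold: float = 5.0, window: int = 21,
                    halfwidth_bins: int = 2) -> list[tuple[float, float]]:
    """Find shared cyclical-noise bands from the spectra of the first PCs.

    The amplitude spectrum of each of the first ``n_pcs`` principal
    components is compared against its rolling median; bins exceeding
    ``threshold`` times the local median are flagged, adjacent flagged bins
    merged, and each band widened by ``halfwidth_bins`` frequency bins.
    Returns (centre Hz, halfwidth Hz) pairs; empty for featureless data.
    """
    X = np.asarray(ts, dtype=float)
    X = X.reshape(-1, X.shape[-1])
    if X.shape[0] < n_pcs:
        raise ValueError("need at least n_pcs voxels")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        return []
    # right singular vectors = component timecourses
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = Vt[:n_pcs]
    n_t = X.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=tr)
    df = freqs[1] - freqs[0]
    flagged = np.zeros(len(freqs), dtype=bool)
    for pc in pcs:
        amp = np.abs(np.fft.rfft(pc))
        med = ndimage.median_filter(amp, size=window, mode="nearest")
        # the rolling-median guard alone misfires at the spectrum edges;
        # a genuine shared tone also towers over the global median
        local = amp > threshold * np.maximum(med, 1e-12 * amp.max())
        global_ok = amp > 3.0 * np.median(amp)
        flagged |= local & global_ok
    flagged[0] = False  # DC is the high-pass filter's job
    bands: list[tuple[float, float]] = []
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            lo = max(i - halfwidth_bins, 1)
            hi = min(j + halfwidth_bins, len(freqs) - 1)
            centre = 0.5 * (freqs[lo] + freqs[hi])
            bands.append((float(centre), float(max(centre - freqs[lo], df))))
            i = j + 1
        else:
            i += 1
    return bands


def volterra_expand(motion: np.ndarray, degree: int = 2,
                    include_lag1: bool = False) -> np.ndarray:
    """Second-degree Volterra (polynomial) expansion of the 6 motion columns.

    Returns the 6 linear terms plus all 21 degree-2 products (including
    squares), each demeaned: 27 columns.  ``include_lag1`` appends the
    one-volume-lagged linear terms (zero-padded) for a lagged variant.
    """
    M = np.asarray(motion, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    if not np.all(np.isfinite(M)):
        raise ValueError("motion table contains missing values")
    cols = [M[:, i] for i in range(6)]
    if degree >= 2:
        for i, j in combinations_with_replacement(range(6), 2):
            cols.append(M[:, i] * M[:, j])
    if include_lag1:
        lagged = np.vstack([np.zeros((1, 6)), M[:-1]])
        cols.extend(lagged[:, i] for i in range(6))
    out = np.column_stack(cols)
    return out - out.mean(axis=0, keepdims=True)


def compartment_confounds(ts: np.ndarray, mask: np.ndarray, k: int = 5,
                          motion_expanded: np.ndarray | None = None) -> ConfoundSet:
    """Mean timecourse + first ``k`` principal-component timecourses of the
    voxels inside ``mask`` (an SVD of the demeaned voxel-by-time matrix).

    Sign convention: each component is flipped so its largest-magnitude
    sample is positive, making the decomposition deterministic.
    """
    X = np.asarray(ts, dtype=float)
    flat = X.reshape(-1, X.shape[-1])
    m = np.asarray(mask, dtype=bool).ravel()
    if not m.any():
        raise ValueError("empty compartment mask")
    comp = flat[m]
    mean_course = comp.mean(axis=0)
    Xc = comp - comp.mean(axis=1, keepdims=True)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if rank < k:
        warnings.warn(f"compartment rank {rank} < requested {k} components; truncated",
                      stacklevel=2)
    pcs = Vt[:min(k, max(rank, 0))].copy()
    for row in pcs:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1.0
    if pcs.shape[0] < k:
        pcs = np.vstack([pcs, np.zeros((k - pcs.shape[0], Xc.shape[1]))])
    return ConfoundSet(compartment_mean=mean_course, compartment_pcs=pcs.T,
                       motion_expanded=motion_expanded)


def regress_confounds(ts: np.ndarray, confounds: ConfoundSet,
                      include_compartment: bool = True) -> np.ndarray:
    """OLS nuisance regression per voxel; returns residuals.

    The design always carries an intercept; rank-deficient columns are
    dropped with a warning.  ``include_compartment=False`` reproduces the
    diagnostic variant in which only WM-derived (or motion) confounds are
    removed, leaving the meningeal global component in the data.
    """
    X = np.asarray(ts, dtype=float)
    shape = X.shape
    flat = X.reshape(-1, shape[-1])
    D = confounds.design_matrix(include_compartment)
    if D.shape[0] != shape[-1]:
        raise ValueError("confound length does not match timeseries")
    D = D - D.mean(axis=0, keepdims=True)
    D = np.column_stack([np.ones(D.shape[0]), D])
    # drop linearly dependent columns (QR diagonal test)
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        logger.warning("dropping %d rank-deficient confound columns", (~keep).sum())
        D = D[:, keep]
        q, r = np.linalg.qr(D)
    beta = np.linalg.solve(r, q.T @ flat.T)
    resid = flat.T - D @ beta
    return resid.T.reshape(shape)


def smooth_spatial(vol_ts: np.ndarray, fwhm: float = 3.0, spacing: float = 2.0) -> np.ndarray:
    """Per-volume Gaussian smoothing with FWHM given in mm."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if fwhm < spacing:
        warnings.warn("smoothing FWHM below voxel size; kernel under-resolved",
                      stacklevel=2)
    sigma_vox = fwhm / FWHM_TO_SIGMA / spacing
    return ndimage.gaussian_filter(np.asarray(vol_ts, dtype=float),
                                   sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))


def explained_variance(signals: np.ndarray, k: int = 5) -> float:
    """Fraction of compartment-signal variance in the first ``k`` eigenvalues
    of the covariance matrix (sum of first k over sum of all)."""
    X = np.asarray(signals, dtype=float)
    X = X.reshape(-1, X.shape[-1])
    Xc = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = s ** 2
    total = ev.sum()
    if total <= 0:
        return 0.0
    return float(ev[:k].sum() / total)


def clean_run(vol_ts: np.ndarray, motion: np.ndarray, compartments: np.ndarray,
              tr: float, spacing: float, spec: FilterSpec | None = None,
              n_drop: int = 5, n_pcs: int = 5,
              include_meningeal: bool = True, fwhm: float = 3.0) -> np.ndarray:
    """Full per-run cleaning pipeline in the canonical order.

    drop volumes -> high-pass -> dynamic band-stop -> confound regression
    (WM[+meningeal] mean + 5 PCs, Volterra-expanded motion) -> low-pass ->
    spatial smoothing -> demean.  ``include_meningeal=False`` extracts
    compartment confounds from WM alone, the diagnostic variant that leaves
    the meningeal global signal in place.
    """
    from .synthetic import MENINGEAL, WM

    if spec is None:
        spec = FilterSpec()
    X = drop_initial_volumes(np.asarray(vol_ts, dtype=float), n_drop)
    M = drop_initial_volumes(np.asarray(motion, dtype=float).T, n_drop).T
    X = temporal_filter(X, spec, tr, apply_lowpass=False, apply_notches=False)
    notches = detect_bandstop(X, tr)
    if notches:
        X = temporal_filter(X, FilterSpec(notches=notches), tr,
                            apply_highpass=False, apply_lowpass=False)
    if include_meningeal:
        mask = (compartments == WM) | (compartments == MENINGEAL)
    else:
        mask = compartments == WM
    conf = compartment_confounds(X, mask, k=n_pcs,
                                 motion_expanded=volterra_expand(M))
    X = regress_confounds(X, conf, include_compartment=True)
    X = temporal_filter(X, spec, tr, apply_highpass=False, apply_notches=False)
    X = smooth_spatial(X, fwhm=fwhm, spacing=spacing)
    return X - X.mean(axis=-1, keepdims=True)
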