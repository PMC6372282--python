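"""Seed-based coupling, connectional fingerprints and permutation inference.

Coupling is Pearson correlation passed through Fisher's z (atanh) and
clipped to [-2, 2] per voxel pair before any averaging.  A bilateral ROI's
seed map is the mean map of its left members and of its right members,
averaged across hemispheres.  A connectional fingerprint collects the
seed's hemisphere-averaged coupling with a fixed, ordered set of target
ROIs; two conditions are compared through the cosine similarity of their
mean fingerprints, with significance from a non-parametric permutation
test over run-level fingerprints.  For 9-vs-9 run labels the exhaustive
null has C(18,9)/2 - 1 = 24309 distinct relabellings (complementary
assignments identified, identity excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

Z_BOUND = 2.0


# ---------------------------------------------------------------------------
# data-matrix plumbing
# ---------------------------------------------------------------------------

@dataclass
class ReducedSeries:
    """Group-PCA-reduced data: k component 'volumes' spanning all voxels.

    Columns are already centred by construction, so coupling operators
    must not re-demean (cosine of the component loadings reproduces the
    Pearson correlation of the full data exactly at full rank).
    """

    data: np.ndarray  # (k, n_voxels)


def _as_matrix(ts) -> tuple[np.ndarray, bool]:
    """Return (time-by-voxel matrix, demean flag)."""
    if isinstance(ts, ReducedSeries):
        return ts.data, False
    X = np.asarray(ts, dtype=float)
    if X.ndim > 2:
        X = X.reshape(-1, X.shape[-1]).T  # (t, v)
    return X, True


def _standardize(M: np.ndarray, demean: bool) -> np.ndarray:
    if demean:
        M = M - M.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(M, axis=0)
    zero = norms == 0
    if zero.any():
        norms = np.where(zero, 1.0, norms)
    return M / norms


def bounded_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r), clipped to [-Z_BOUND, Z_BOUND]."""
    r_c = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return np.clip(np.arctanh(r_c), -Z_BOUND, Z_BOUND)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """Bilateral region of interest as voxel index arrays (n, 3)."""

    name: str
    left: np.ndarray
    right: np.ndarray

    def flat(self, grid_shape) -> dict[str, np.ndarray]:
        return {side: np.ravel_multi_index(getattr(self, side).T, grid_shape)
                for side in ("left", "right")}


def make_roi(centre_mm: tuple[float, float, float], grid_shape: tuple[int, int, int],
             spacing: float | tuple[float, float, float], radius_mm: float = 4.0,
             name: str = "roi") -> Roi:
    """Euclidean ball of ``radius_mm`` around the centre and around its
    mirror across the mid-sagittal plane (the x mid-plane of the grid).
    ``spacing`` may be a scalar or a per-axis triple (mm)."""
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    centre = np.asarray(centre_mm, dtype=float) / sp
    if np.any(centre < 0) or np.any(centre > np.array(grid_shape) - 1):
        raise ValueError("ROI centre outside the grid")
    mirror = centre.copy()
    mirror[0] = (grid_shape[0] - 1) - centre[0]
    idx = np.indices(grid_shape).reshape(3, -1).T
    right = idx[np.linalg.norm((idx - centre) * sp, axis=1) <= radius_mm]
    left = idx[np.linalg.norm((idx - mirror) * sp, axis=1) <= radius_mm]
    if len(right) == 0 or len(left) == 0:
        raise ValueError("ROI radius below half the voxel size: empty ball")
    return Roi(name=name, left=left, right=right)


# ---------------------------------------------------------------------------
# coupling maps and fingerprints
# ---------------------------------------------------------------------------

def _roi_mean_zmap(Z: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return Z[rows].mean(axis=0)


def seed_map(ts, roi: Roi, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Hemisphere-averaged bounded-z coupling of a bilateral seed ROI with
    every voxel; returns a flat (n_voxels,) map."""
    M, demean = _as_matrix(ts)
    S = _standardize(M, demean)
    flat = roi.flat(grid_shape)
    maps = []
    for side in ("left", "right"):
        rows = flat[side]
        R = S[:, rows].T @ S  # (n_roi, n_vox) correlations
        maps.append(_roi_mean_zmap(np.asarray(bounded_z(R)), np.arange(len(rows))))
    return 0.5 * (maps[0] + maps[1])


def fingerprint(ts, seed: Roi, targets: list[Roi],
                grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, list[str]]:
    """Seed's mean bounded-z coupling with each target ROI (hemisphere-averaged
    on both the seed and the target side); returns (values, target names)."""
    seed_flat = np.concatenate([seed.flat(grid_shape)[s] for s in ("left", "right")])
    smap = seed_map(ts, seed, grid_shape)
    values = []
    for t in targets:
        tf = t.flat(grid_shape)
        overlap = np.intersect1d(seed_flat, np.concatenate([tf["left"], tf["right"]]))
        if overlap.size:
            raise ValueError(f"target {t.name} overlaps the seed ROI")
        values.append(0.5 * (smap[tf["left"]].mean() + smap[tf["right"]].mean()))
    return np.asarray(values), [t.name for t in targets]


def self_coupling(ts, roi: Roi, grid_shape: tuple[int, int, int]) -> float:
    """Mean bounded-z coupling of every ROI voxel with every other ROI voxel."""
    M, demean = _as_matrix(ts)
    rows = np.concatenate([roi.flat(grid_shape)[s] for s in ("left", "right")])
    if len(rows) < 2:
        raise ValueError("self-coupling needs at least two ROI voxels")
    S = _standardize(M[:, rows], demean)
    R = S.T @ S
    Z = np.asarray(bounded_z(R))
    np.fill_diagonal(Z, 0.0)
    per_voxel = Z.sum(axis=1) / (len(rows) - 1)
    return float(per_voxel.mean())


def percentile_coupling_map(ts, q: float = 98.0, chunk: int = 512) -> np.ndarray:
    """Per voxel: bounded-z coupling with all other voxels, q-th percentile
    (linear interpolation).  Captures overall coupling inflation."""
    M, demean = _as_matrix(ts)
    S = _standardize(M, demean)
    n_vox = S.shape[1]
    out = np.empty(n_vox)
    for i0 in range(0, n_vox, chunk):
        R = S[:, i0:i0 + chunk].T @ S  # (chunk, n_vox)
        Z = np.asarray(bounded_z(R))
        for j in range(Z.shape[0]):
            row = np.delete(Z[j], i0 + j)
            out[i0 + j] = np.percentile(row, q)
    return out


def group_reduce(datasets: list[np.ndarray], k: int = 200) -> ReducedSeries:
    """Group PCA: stack run-concatenated (t, v) matrices in time, centre the
    columns, and keep the top-k singular components as k pseudo-volumes.

    Implemented as a plain SVD of the stacked matrix: at this problem scale
    it is exact, and at full rank the reduced series reproduces voxel-wise
    coupling identically.
    """
    mats = []
    for d in datasets:
        X = np.asarray(d, dtype=float)
        if X.ndim > 2:
            X = X.reshape(-1, X.shape[-1]).T
        mats.append(X)
    stack = np.vstack(mats)
    stack = stack - stack.mean(axis=0, keepdims=True)
    if stack.shape[0] < 2:
        raise ValueError("concatenated length too short for reduction")
    _, s, Vt = np.linalg.svd(stack, full_matrices=False)
    k_eff = min(k, len(s))
    comp = s[:k_eff, None] * Vt[:k_eff]
    # deterministic sign: largest-magnitude loading positive
    for row in comp:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1.0
    return ReducedSeries(data=comp)


# ---------------------------------------------------------------------------
# cosine similarity and permutation inference
# ---------------------------------------------------------------------------

def cosine_similarity(f1: np.ndarray, f2: np.ndarray) -> float:
    """dot(f1, f2) / (|f1| |f2|); scale-invariant shape comparison."""
    a = np.asarray(f1, dtype=float)
    b = np.asarray(f2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fingerprints must share target order and length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero fingerprint")
    return float(a @ b / (na * nb))


def count_exhaustive(n_total: int, group_size: int) -> int:
    """Distinct balanced relabellings up to group exchange, identity excluded:
    C(n_total, group_size) / 2 - 1."""
    if n_total != 2 * group_size:
        raise ValueError("exhaustive counting requires two equal groups")
    return comb(n_total, group_size) // 2 - 1


@dataclass
class PermutationResult:
    observed_cosine: float
    null_distribution: np.ndarray
    n_permutations: int
    p_value: float
    exhaustive: bool
    seed: int | None = None


def _group_cosines(F: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Cosine similarity between the two group-mean fingerprints for each
    boolean row mask in ``masks`` (True = group A)."""
    nA = masks.sum(axis=1, keepdims=True).astype(float)
    nB = masks.shape[1] - nA
    sums = masks.astype(float) @ F            # (m, d)
    meanA = sums / nA
    meanB = (F.sum(axis=0)[None, :] - sums) / nB
    num = (meanA * meanB).sum(axis=1)
    den = np.linalg.norm(meanA, axis=1) * np.linalg.norm(meanB, axis=1)
    return num / den


def permutation_test(fingerprints: np.ndarray, labels: list[str] | np.ndarray,
                     mode: str = "exhaustive", n_mc: int = 9999,
                     seed: int | None = None) -> PermutationResult:
    """Permutation test on the cosine similarity of condition-mean fingerprints.

    The observed statistic is the cosine similarity between the mean
    fingerprint of each condition; lower similarity means a larger
    condition difference, so the p-value is the proportion of null
    similarities at or below the observed one (one-tailed toward
    dissimilarity).  Exhaustive mode enumerates all distinct balanced
    relabellings with complements identified and the identity excluded
    (exact p as a proportion); unbalanced designs fall back to Monte Carlo
    with p = (b + 1) / (n + 1).
    """
    F = np.asarray(fingerprints, dtype=float)
    lab = np.asarray(labels)
    conds = np.unique(lab)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    isA = lab == conds[0]
    nA, nB = int(isA.sum()), int((~isA).sum())
    if nA < 2 or nB < 2:
        raise ValueError("need at least two observations per condition")
    observed = float(_group_cosines(F, isA[None, :])[0])

    n = len(lab)
    if mode == "exhaustive" and nA != nB:
        import warnings
        warnings.warn("unbalanced groups: falling back to Monte Carlo", stacklevel=2)
        mode = "monte_carlo"

    if mode == "exhaustive":
        # fix observation 0 in group A to identify complementary assignments
        others = list(range(1, n))
        masks = []
        for pick in combinations(others, nA - 1):
            m = np.zeros(n, dtype=bool)
            m[0] = True
            m[list(pick)] = True
            if np.array_equal(m, isA) or np.array_equal(m, ~isA):
                continue  # exclude the identity labelling (either orientation)
            masks.append(m)
        masks = np.asarray(masks)
        null = _group_cosines(F, masks)
        p = float((null <= observed + 1e-12).mean())
        p = max(p, 1.0 / (len(null) + 1))  # exact proportion, floored away from 0
        return PermutationResult(observed_cosine=observed, null_distribution=null,
                                 n_permutations=len(null), p_value=p, exhaustive=True)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_mc, n), dtype=bool)
    for i in range(n_mc):
        masks[i, rng.choice(n, size=nA, replace=False)] = True
    null = _group_cosines(F, masks)
    b = int((null <= observed + 1e-12).sum())
    p = (b + 1) / (n_mc + 1)
    return PermutationResult(observed_cosine=observed, null_distribution=null,
                             n_permutations=n_mc, p_value=p, exhaustive=False,
                             seed=seed)
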