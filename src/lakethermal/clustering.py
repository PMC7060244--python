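"""Thermal-region discovery: K-means on spline coefficients, gap statistic.

Lakes with similar seasonal temperature patterns have similar saturated
B-spline coefficient vectors, so K-means on the coefficient matrix groups
lakes into candidate thermal regions.  The number of groups is selected
with the gap statistic (Tibshirani et al.): the log within-cluster
dispersion of the data is compared against its expectation under B
reference datasets drawn uniformly in the principal-axes-aligned bounding
box of the data, and the smallest k satisfying the one-standard-error rule
is chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .curves import SeasonalCurve
from .synthetic import REGION_CODES, REGION_TABLE, PEAK_DOY


@dataclass
class ClusterModel:
    """K-means solution over the lakes x n_basis coefficient matrix."""

    k: int
    centroids: np.ndarray         # k x n_basis
    labels: np.ndarray            # per-lake int in 0..k-1
    within_dispersion: float      # W_k, the pooled within-cluster SS
    seed: int
    n_init: int


@dataclass
class GapResult:
    """Gap-statistic curve and the k chosen by the one-SE rule."""

    k_grid: np.ndarray
    gap: np.ndarray
    sk: np.ndarray
    chosen_k: int
    B: int
    log_wk: np.ndarray = field(default=None)


def _within_dispersion(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """W_k = sum_r sum_{i in C_r} ||x_i - mu_r||^2 (equals the pairwise form
    sum_r (1/2n_r) sum_{i,i' in C_r} ||x_i - x_i'||^2)."""
    d = x - centroids[labels]
    return float(np.einsum("ij,ij->", d, d))


def kmeans_coefficients(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
) -> ClusterModel:
    """Best-of-``n_init`` K-means (k-means++ seeding) on coefficient vectors.

    Deterministic given ``seed``; ties in nearest-centroid assignment are
    broken toward the lowest cluster index; empty clusters are re-seeded
    from the farthest points.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (lakes x n_basis)")
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite coefficient rows at indices {np.where(bad)[0].tolist()}")
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k must be in [1, {x.shape[0]}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=seed, init="k-means++").fit(x)
    # re-derive labels from centroids so the lowest-index tie-break is explicit
    d2 = ((x[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(-1) \
        if x.shape[0] * k * x.shape[1] < 5e7 else None
    labels = km.labels_.astype(int) if d2 is None else np.argmin(d2, axis=1)
    return ClusterModel(
        k=k, centroids=km.cluster_centers_, labels=labels,
        within_dispersion=_within_dispersion(x, labels, km.cluster_centers_),
        seed=seed, n_init=n_init,
    )


def _reference_sampler(x: np.ndarray, rng: np.random.Generator):
    """Uniform sampler over the SVD-aligned bounding box of the data."""
    mu = x.mean(axis=0)
    xc = x - mu
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    xp = xc @ vt.T
    lo, hi = xp.min(axis=0), xp.max(axis=0)

    def draw(n: int) -> np.ndarray:
        zp = rng.uniform(lo, hi, size=(n, lo.size))
        return zp @ vt + mu

    return draw


def gap_statistic(
    matrix: np.ndarray,
    k_max: int = 15,
    B: int = 50,
    seed: int = 0,
    n_init_data: int = 50,
    n_init_ref: int = 10,
) -> GapResult:
    """Choose the number of clusters by the gap statistic.

    Gap(k) = mean_b log W*_kb - log W_k with B reference datasets uniform
    in the principal-axes-aligned box; s_k = sd_b(log W*_kb) sqrt(1 + 1/B);
    chosen_k is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    x = np.asarray(matrix, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")
    if np.allclose(x, x[0]):
        warnings.warn("degenerate data: all rows identical; choosing k = 1")
        k_grid = np.arange(1, k_max + 1)
        z = np.zeros(k_max)
        return GapResult(k_grid, z, z, chosen_k=1, B=B, log_wk=z)

    rng = np.random.default_rng(seed)
    k_grid = np.arange(1, k_max + 1)
    log_wk = np.empty(k_max)
    for i, k in enumerate(k_grid):
        model = kmeans_coefficients(x, int(k), seed=seed, n_init=n_init_data)
        # a perfect partition (W = 0) can occur when k approaches n
        log_wk[i] = np.log(max(model.within_dispersion, 1e-300))

    draw = _reference_sampler(x, rng)
    ref_seeds = rng.integers(0, 2**31 - 1, size=B)
    log_wkb = np.empty((B, k_max))
    for b in range(B):
        z = draw(x.shape[0])
        for i, k in enumerate(k_grid):
            m = kmeans_coefficients(z, int(k), seed=int(ref_seeds[b]),
                                    n_init=n_init_ref)
            log_wkb[b, i] = np.log(m.within_dispersion)

    gap = log_wkb.mean(axis=0) - log_wk
    sk = log_wkb.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen = int(k_grid[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            chosen = int(k_grid[i])
            break
    return GapResult(k_grid, gap, sk, chosen_k=chosen, B=B, log_wk=log_wk)


def name_clusters(profiles: list[SeasonalCurve], labels: np.ndarray) -> dict[int, str]:
    """Map cluster indices to the nine region codes.

    Each cluster's mean seasonal statistics (annual mean, annual range,
    hemisphere phase of the peak) are matched to the reference region
    table.  With at most nine clusters an optimal one-to-one assignment is
    used; with more clusters each takes its nearest region (duplicates
    allowed).
    """
    labels = np.asarray(labels)
    ks = np.unique(labels)
    feats = []
    for k in ks:
        idx = np.where(labels == k)[0]
        means = [profiles[i].mean for i in idx]
        rngs = [profiles[i].range for i in idx]
        peaks = [profiles[i].peak_fraction for i in idx]
        feats.append((float(np.mean(means)), float(np.mean(rngs)),
                      float(np.median(peaks))))

    def cost(feat, code):
        mean_t, range_t = REGION_TABLE[code][1], REGION_TABLE[code][2]
        c = (feat[0] - mean_t) ** 2 + (feat[1] - range_t) ** 2
        # hemisphere phase: peak in Apr-Sep (northern summer) vs Oct-Mar
        peak_north = 0.25 <= feat[2] < 0.75
        target_north = 0.25 <= PEAK_DOY[code] / 365.0 < 0.75
        if peak_north != target_north:
            c += 1e4
        return c

    codes = list(REGION_CODES)
    cmat = np.array([[cost(f, c) for c in codes] for f in feats])
    if len(ks) <= len(codes):
        ri, ci = linear_sum_assignment(cmat)
        return {int(ks[i]): codes[j] for i, j in zip(ri, ci)}
    return {int(ks[i]): codes[int(np.argmin(cmat[i]))] for i in range(len(ks))}
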