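"""Data-driven network clustering of voxel tuning profiles.

Voxels are grouped by the similarity of their encoding-model feature
weights (or raw condition response profiles) with k-means under the
correlation distance: each profile is row-centered and unit-normalized,
so voxels with the same *relative* weighting pattern cluster together
regardless of overall response gain.  Cluster count is guided by the mean
silhouette (correlation metric) and mean pairwise centroid correlation.
Cross-set robustness is quantified by the co-assignment sensitivity index
d' = z(Hit) - z(FA) over all voxel pairs, with a shuffled-label baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from .config import DataError

EXCLUDED = 0          # reserved label for insufficient-variance voxels
VARIANCE_TOL = 1e-10  # row sd below this is "insufficient variance"


@dataclass
class ClusterSolution:
    """A k-means partition of voxel profiles.

    labels are 1..k per included voxel and 0 (EXCLUDED) for rows with
    insufficient variance; centroids are the mean normalized member
    profiles, re-normalized.
    """

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    inertia: float
    diagnostics: dict = field(default_factory=dict)
    colors: np.ndarray | None = None

    @property
    def included(self) -> np.ndarray:
        return self.labels != EXCLUDED


@dataclass
class DPrimeResult:
    """Co-assignment sensitivity between two partitions of the same voxels."""

    hit_rate: float
    fa_rate: float
    dprime: float
    clamp: float

    def __post_init__(self) -> None:
        if not (0 < self.hit_rate < 1 and 0 < self.fa_rate < 1):
            raise ValueError("rates must lie in (0, 1) after clamping")


def _normalize_rows(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center and unit-normalize; returns (normalized, included mask)."""
    P = np.asarray(P, dtype=float)
    centered = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = (P.std(axis=1) >= VARIANCE_TOL) & np.isfinite(P).all(axis=1)
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def exclude_low_variance(profiles: np.ndarray,
                         tolerance: float = VARIANCE_TOL) -> np.ndarray:
    """Boolean mask of rows whose sd falls below the tolerance."""
    P = np.asarray(profiles, dtype=float)
    return P.std(axis=1) < tolerance


def _normalize_centroids(C: np.ndarray) -> np.ndarray:
    C = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    return np.divide(C, norms, out=np.zeros_like(C), where=norms > 0)


def _lloyd(Xn: np.ndarray, k: int, max_iter: int,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    n = Xn.shape[0]
    centroids = Xn[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sims = Xn @ centroids.T            # rows unit-norm: corr similarity
        new_labels = np.argmax(sims, axis=1)
        # re-seed empty clusters at the point farthest from its centroid
        d_own = 1.0 - sims[np.arange(n), new_labels]
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d_own))
                centroids[c] = Xn[far]
                new_labels[far] = c
                d_own[far] = -np.inf
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = Xn[members].mean(axis=0)
        centroids = _normalize_centroids(centroids)
    sims = Xn @ centroids.T
    labels = np.argmax(sims, axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(n), labels]))
    return labels, centroids, inertia


def kmeans_correlation(profiles: np.ndarray, k: int, replicates: int = 10,
                       max_iter: int = 500,
                       seed: int | np.random.Generator = 0,
                       ) -> ClusterSolution:
    """k-means under the correlation distance (1 - Pearson r to centroid).

    Profiles are row-centered and unit-normalized up front; rows with
    insufficient variance are excluded and labeled 0.  The best of
    ``replicates`` random initializations by total within-cluster
    correlation distance wins.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    P = np.asarray(profiles, dtype=float)
    Xn_full, ok = _normalize_rows(P)
    n_inc = int(ok.sum())
    if k > n_inc:
        raise DataError(f"k={k} exceeds {n_inc} included voxels")
    Xn = Xn_full[ok]
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    best = None
    for _ in range(max(replicates, 1)):
        labels, centroids, inertia = _lloyd(Xn, k, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels_inc, centroids, inertia = best
    labels = np.full(P.shape[0], EXCLUDED, dtype=int)
    labels[ok] = labels_inc + 1
    return ClusterSolution(labels=labels, centroids=centroids, k=k,
                           inertia=inertia)


def cluster_responses(response_profiles: np.ndarray, k: int,
                      replicates: int = 10, max_iter: int = 500,
                      seed: int | np.random.Generator = 0) -> ClusterSolution:
    """Feature-free variant: cluster voxels by their raw per-condition
    response profiles instead of fitted feature weights; the procedure is
    otherwise identical."""
    return kmeans_correlation(response_profiles, k, replicates=replicates,
                              max_iter=max_iter, seed=seed)


def k_diagnostics(profiles: np.ndarray, k_range=range(2, 21),
                  replicates: int = 10, max_iter: int = 500,
                  seed: int = 0) -> dict:
    """Sweep k and report mean silhouette (correlation metric) and mean
    pairwise centroid correlation per k, plus each solution."""
    if min(k_range) < 2:
        raise ValueError("silhouette is undefined for k < 2; start at k=2")
    P = np.asarray(profiles, dtype=float)
    _, ok = _normalize_rows(P)
    rows, solutions = [], {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        sol = kmeans_correlation(P, k, replicates=replicates,
                                 max_iter=max_iter, seed=rng)
        sil = float(silhouette_score(P[ok], sol.labels[ok],
                                     metric="correlation"))
        C = sol.centroids
        cc = np.corrcoef(C)
        pair = cc[np.triu_indices(k, k=1)]
        cent_sim = float(pair.mean()) if pair.size else np.nan
        sol.diagnostics = {"silhouette": sil, "centroid_similarity": cent_sim}
        rows.append({"k": k, "silhouette": sil,
                     "centroid_similarity": cent_sim})
        solutions[k] = sol
    return {"table": rows, "solutions": solutions}


def choose_k(diagnostics: dict, max_centroid_corr: float = 0.8) -> int:
    """Among k whose centroids stay distinguishable (mean pairwise centroid
    correlation below the threshold), pick the k with maximal silhouette.
    Falls back to the global silhouette maximum if none qualify."""
    rows = diagnostics["table"]
    ok = [r for r in rows if r["centroid_similarity"] < max_centroid_corr]
    pool = ok if ok else rows
    return int(max(pool, key=lambda r: r["silhouette"])["k"])


def _pair_counts(a: np.ndarray, b: np.ndarray
                 ) -> tuple[float, float, float, float]:
    """Unordered-pair co-assignment counts via the contingency table."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise DataError("labelings must cover the same voxels")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    joint = np.bincount(ai * nb + bi).astype(float)
    ra = np.bincount(ai).astype(float)
    cb = np.bincount(bi).astype(float)

    def pairs(x):
        return float(np.sum(x * (x - 1) / 2))

    return pairs(joint), pairs(ra), pairs(cb), n * (n - 1) / 2.0


def coassignment_dprime(labels_a: np.ndarray,
                        labels_b: np.ndarray) -> DPrimeResult:
    """d' between two partitions from voxel-pair co-assignment.

    Hit rate: of the pairs assigned to the same cluster in A, the fraction
    also together in B.  False-alarm rate: of the pairs split in A, the
    fraction together in B.  Degenerate rates (0 or 1) are clamped to
    1/(2P) from the boundary with P the total pair count, and
    d' = z(hit) - z(fa).

    Counting uses the A-by-B contingency table, so the full voxels-squared
    pair enumeration is never materialized.
    """
    same_both, same_a, same_b, total = _pair_counts(labels_a, labels_b)
    if same_a == 0 or same_a == total:
        raise DataError("all pairs same (or all different) in labels_a: "
                        "conditioning set empty")
    hit = same_both / same_a
    fa = (same_b - same_both) / (total - same_a)
    clamp = 1.0 / (2.0 * total)
    hit = min(max(hit, clamp), 1.0 - clamp)
    fa = min(max(fa, clamp), 1.0 - clamp)
    return DPrimeResult(hit_rate=hit, fa_rate=fa,
                        dprime=float(norm.ppf(hit) - norm.ppf(fa)),
                        clamp=clamp)


def shuffled_baseline(labels_a: np.ndarray, labels_b: np.ndarray,
                      n_shuffles: int = 100, seed: int = 0) -> dict:
    """Null distribution of d' under voxel-order shuffling of labels_b.

    Independently permuting one labeling destroys any true voxel
    correspondence, so the baseline mean sits near zero.  Returns mean,
    sd and the per-shuffle values.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng(seed)
    b = np.asarray(labels_b).ravel()
    vals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        vals[i] = coassignment_dprime(labels_a, rng.permutation(b)).dprime
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
            "values": vals}


def match_centroids(solution_a: ClusterSolution, solution_b: ClusterSolution
                    ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """One-to-one centroid pairing maximizing total Pearson correlation
    (Hungarian assignment); returns the pairing and per-pair correlations."""
    if solution_a.k != solution_b.k:
        raise DataError("solutions have different k")
    k = solution_a.k
    C = np.corrcoef(solution_a.centroids, solution_b.centroids)[:k, k:]
    ri, ci = linear_sum_assignment(-C)
    return list(zip(ri.tolist(), ci.tolist())), C[ri, ci]


def _classical_mds(D: np.ndarray, ndim: int = 3) -> np.ndarray:
    """Torgerson classical MDS of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < ndim:
        coords = np.pad(coords, ((0, 0), (0, ndim - coords.shape[1])))
    return coords


def mds_colors(centroids: np.ndarray) -> np.ndarray:
    """RGB colors from a 3-D classical MDS of centroid correlation
    distances: each embedding axis is min-max rescaled to [0, 1] and used
    as a color channel, so similar tuning profiles get similar hues.
    A zero-spread axis (e.g., identical centroids) maps to 0.5."""
    C = np.asarray(centroids, dtype=float)
    if C.shape[0] < 2:
        raise DataError("need at least 2 centroids to color")
    D = 1.0 - np.corrcoef(C)
    coords = _classical_mds(D, ndim=3)
    colors = np.empty_like(coords)
    spreads = coords.max(axis=0) - coords.min(axis=0)
    # axes with negligible spread relative to the embedding scale carry
    # only numerical noise from degenerate eigenvalues
    floor = 1e-8 * max(float(spreads.max()), 1e-30)
    for j in range(3):
        lo, hi = coords[:, j].min(), coords[:, j].max()
        if hi - lo <= floor:
            warnings.warn("zero-spread MDS axis mapped to 0.5",
                          RuntimeWarning, stacklevel=2)
            colors[:, j] = 0.5
        else:
            colors[:, j] = (coords[:, j] - lo) / (hi - lo)
    return colors
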