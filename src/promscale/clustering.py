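"""Proportional-scaling clustering of promoter activity profiles.

Viewed from the origin of the m-dimensional condition space, promoters
whose activities scale proportionally across conditions lie on a common
ray.  K-means with the cosine metric (spherical k-means) therefore
partitions promoters into groups that each preserve internal ratios: the
metric d(x, y) = 1 - cos(angle between x and y) is invariant to positive
rescaling of either profile.  K is chosen as the largest number of
clusters whose centers remain mutually separated by at least ``min_sep``
in cosine distance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .scaling import fit_scale_line

logger = logging.getLogger(__name__)


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cos(angle) between two non-zero activity vectors; in [0, 2]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(x, y) / (nx * ny))


@dataclasses.dataclass
class ClusterModel:
    """A fitted spherical k-means partition.

    centers are unit-norm rows (one per cluster), sorted by descending
    cluster size so cluster 0 is the dominant (global) one; objective is
    the summed cosine distance of members to their center, minimized over
    restarts.
    """

    k: int
    assignment: np.ndarray       # promoter index -> cluster id
    centers: np.ndarray          # (k, m), unit rows
    objective: float
    restarts: int
    seed: int
    promoters: list[str] | None = None

    def assignment_series(self) -> pd.Series:
        idx = self.promoters if self.promoters is not None else np.arange(self.assignment.size)
        return pd.Series(self.assignment, index=idx, name="cluster")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("profiles with zero norm cannot be clustered")
    return x / norms[:, None]


def _spherical_kmeans_once(xu: np.ndarray, k: int, init_idx: np.ndarray,
                           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    centers = xu[init_idx].copy()
    assign = np.full(xu.shape[0], -1)
    for _ in range(max_iter):
        sims = xu @ centers.T
        new_assign = np.argmax(sims, axis=1)         # ties -> lowest index
        # re-seed empty clusters at the point farthest from all centers
        for _pass in range(k):
            empty = [j for j in range(k) if not np.any(new_assign == j)]
            if not empty:
                break
            for j in empty:
                far = int(np.argmin(sims.max(axis=1)))
                logger.debug("re-seeding empty cluster %d at point %d", j, far)
                centers[j] = xu[far]
                sims = xu @ centers.T
                new_assign = np.argmax(sims, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = xu[assign == j]
            if members.size == 0:
                continue
            mean = members.mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                centers[j] = mean / norm
    sims = xu @ centers.T
    objective = float(np.sum(1.0 - sims[np.arange(xu.shape[0]), assign]))
    return assign, centers, objective


def kmeans_cosine(x: np.ndarray, k: int, restarts: int = 100, seed: int = 0,
                  promoters: list[str] | None = None, max_iter: int = 300) -> ClusterModel:
    """Best-of-``restarts`` spherical k-means under the cosine metric.

    Each restart initializes the centers at k distinct random profiles;
    assignment goes to the nearest center (lowest index on ties), centers
    update to the normalized mean of their members' unit vectors, and the
    restart whose converged partition has the smallest summed cosine
    distance wins.  Deterministic given ``seed``.
    """
    x = np.asarray(x, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] < k:
        raise ValueError("need at least k profiles")
    xu = _unit_rows(x)
    rng = np.random.default_rng(seed)

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(max(restarts, 1)):
        init_idx = rng.choice(x.shape[0], size=k, replace=False)
        result = _spherical_kmeans_once(xu, k, init_idx, max_iter=max_iter)
        if best is None or result[2] < best[2]:
            best = result
    assign, centers, objective = best

    # relabel by descending cluster size (stable: ties keep original order)
    sizes = np.bincount(assign, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, int)
    relabel[order] = np.arange(k)
    return ClusterModel(k=k, assignment=relabel[assign], centers=centers[order],
                        objective=objective, restarts=restarts, seed=seed,
                        promoters=promoters)


def min_center_separation(model: ClusterModel) -> float:
    if model.k < 2:
        return np.inf
    sims = model.centers @ model.centers.T
    d = 1.0 - sims[np.triu_indices(model.k, 1)]
    return float(d.min())


def select_k(x: np.ndarray, k_max: int = 12, min_sep: float = 0.05,
             restarts: int = 100, seed: int = 0) -> int:
    """Largest K whose best k-means model keeps all centers >= ``min_sep`` apart.

    K-means is run for K = 2..k_max; the largest qualifying K is
    returned, or 1 if no K qualifies.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    best_k = 1
    for k in range(2, min(k_max, np.asarray(x).shape[0]) + 1):
        model = kmeans_cosine(x, k, restarts=restarts, seed=seed)
        if min_center_separation(model) >= min_sep:
            best_k = k
    return best_k


def fit_clusters(x: np.ndarray, k_max: int = 12, min_sep: float = 0.05,
                 restarts: int = 100, seed: int = 0,
                 promoters: list[str] | None = None) -> ClusterModel:
    """Select K by the separation rule and return the fitted model."""
    k = select_k(x, k_max=k_max, min_sep=min_sep, restarts=restarts, seed=seed)
    return kmeans_cosine(x, k, restarts=restarts, seed=seed, promoters=promoters)


def variance_explained_clustering(x: np.ndarray, model: ClusterModel) -> float:
    """1 - variance(d) / variance(v) with v projected on its cluster's ray.

    Each profile v(p) is projected onto the ray spanned by its cluster
    center ((v . c) c for unit c); d(p) is the residual.  Variances are
    pooled over all promoter-condition entries (mean-centered).
    """
    x = np.asarray(x, float)
    c = model.centers[model.assignment]              # (n, m)
    proj = np.sum(x * c, axis=1, keepdims=True) * c
    d = x - proj
    return 1.0 - float(np.var(d.ravel())) / float(np.var(x.ravel()))


@dataclasses.dataclass
class ClusterScalingTable:
    """Per-cluster, per-condition scaling factors.

    ``absolute`` holds s_t[c], the ray slope between the reference and
    condition c fitted over cluster t's members; ``relative`` divides by
    the global factor S[ref, c], so the dominant cluster's relative
    factors sit near 1 and values above/below 1 indicate relative
    activation/repression.  Clusters with fewer than ``min_points``
    members use the median activity ratio and are flagged ``low_n``.

    The ray fit weights members by the inverse variance of their activity
    ratio (from the error model's CVs) so that neither the brightest
    member (which would dominate an unweighted fit) nor the noisiest
    low-activity members (whose ratios are biased and wild) control the
    factor; without an error model, inverse-x^2 weights (equal leverage
    per member) are used.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame
    low_n: pd.Series


def cluster_scaling_factors(values: pd.DataFrame, model: ClusterModel,
                            global_factors: pd.Series, reference: str,
                            min_points: int = 10,
                            below_detection: pd.DataFrame | None = None,
                            error_model=None) -> ClusterScalingTable:
    conds = list(values.columns)
    if reference not in conds:
        raise ValueError(f"reference {reference!r} not among conditions")
    absolute = pd.DataFrame(index=range(model.k), columns=conds, dtype=float)
    low_n = pd.Series(False, index=range(model.k))
    vals = values.to_numpy(float)
    below = (below_detection.to_numpy() if below_detection is not None
             else np.zeros(vals.shape, bool))
    ref_col = conds.index(reference)
    for t in range(model.k):
        members = model.assignment == t
        low_n[t] = members.sum() < min_points
        for ci, c in enumerate(conds):
            # floored cells carry no ratio information and would bias the
            # inverse-x^2-weighted fit, so they are dropped per pair
            ok = members & ~below[:, ref_col] & ~below[:, ci]
            x = vals[ok, ref_col]
            y = vals[ok, ci]
            if low_n[t] or ok.sum() < min_points:
                absolute.loc[t, c] = float(np.median(y / x)) if ok.sum() else np.nan
                low_n[t] = True
            else:
                if error_model is not None:
                    cvx = np.asarray(error_model.cv_at(np.maximum(x, 1e-300)))
                    cvy = np.asarray(error_model.cv_at(np.maximum(y, 1e-300)))
                    w = 1.0 / (np.maximum(x, 1e-300) ** 2 * (cvx ** 2 + cvy ** 2))
                else:
                    w = 1.0 / np.maximum(x, 1e-300) ** 2
                absolute.loc[t, c] = fit_scale_line(
                    x, y, weights=w, min_points=min(min_points, int(ok.sum())))
    relative = absolute.div(global_factors.reindex(conds), axis=1)
    return ClusterScalingTable(absolute=absolute, relative=relative, low_n=low_n)


def cluster_stability(assign_a: pd.Series, assign_b: pd.Series) -> float:
    """Fraction of shared promoters keeping their (matched) cluster identity.

    Clusters of the two models are matched by maximal-overlap bipartite
    assignment (so a pure relabeling scores 1), then the preserved
    fraction is computed over the promoters present in both models.
    """
    shared = assign_a.index.intersection(assign_b.index)
    if len(shared) == 0:
        raise ValueError("models share no promoters")
    a = assign_a.loc[shared].to_numpy()
    b = assign_b.loc[shared].to_numpy()
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    overlap = np.zeros((ka, kb))
    np.add.at(overlap, (a, b), 1)
    rows, cols = linear_sum_assignment(-overlap)
    return float(overlap[rows, cols].sum() / len(shared))
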