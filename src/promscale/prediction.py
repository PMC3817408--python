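"""Predicting promoter activities in a new condition from few representatives.

Once promoters are clustered into proportionally scaling groups over m
measured conditions, a new condition only adds one unknown per cluster:
the cluster's scaling coordinate in that condition.  Measuring a handful
of representative promoters in the new condition identifies those
coordinates — the cluster centers are "extended" from length m to m+1 —
after which every other promoter's activity is predicted from its
projection onto its cluster's ray.

Two representative-selection schemes are provided: ``nearest`` picks the
promoters closest (cosine metric) to each cluster center with an
equal-as-possible allocation across clusters, and ``greedy`` forward-
selects the promoters whose rows best reconstruct the whole activity
matrix by least squares.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .clustering import ClusterModel, fit_clusters

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def choose_representatives_nearest(x: np.ndarray, model: ClusterModel, n: int = 10) -> np.ndarray:
    """Indices of the n promoters nearest their cluster centers.

    floor(n/K) promoters are taken from every cluster and the remaining
    slots go one each to the largest clusters; within a cluster the
    members with the smallest cosine distance to the center are chosen.
    If a cluster has fewer members than its share, the leftover slots
    cascade to the next-largest clusters.
    """
    if n < model.k:
        raise ValueError("need at least one representative per cluster (n >= K)")
    x = np.asarray(x, float)
    xu = x / np.linalg.norm(x, axis=1, keepdims=True)
    sizes = model.sizes()
    alloc = np.full(model.k, n // model.k)
    extra = n - alloc.sum()
    order = np.argsort(-sizes, kind="stable")
    for j in order[:extra]:
        alloc[j] += 1
    # cap by size, cascading surplus to larger clusters first
    surplus = 0
    for j in np.argsort(sizes, kind="stable"):
        if alloc[j] > sizes[j]:
            surplus += alloc[j] - sizes[j]
            alloc[j] = sizes[j]
    for j in order:
        if surplus <= 0:
            break
        room = sizes[j] - alloc[j]
        take = min(room, surplus)
        alloc[j] += take
        surplus -= take

    chosen: list[int] = []
    for t in range(model.k):
        members = np.flatnonzero(model.assignment == t)
        d = 1.0 - xu[members] @ model.centers[t]
        chosen.extend(members[np.argsort(d, kind="stable")[: alloc[t]]].tolist())
    return np.array(sorted(chosen), dtype=int)


def choose_representatives_greedy(x: np.ndarray, n: int) -> np.ndarray:
    """Greedy forward selection of rows that best reconstruct the matrix.

    Starting from the empty set, each step adds the promoter whose row,
    joined to the current selection, minimizes the total squared residual
    of the least-squares reconstruction of all rows as linear
    combinations of the selected rows.  Ties break toward the lower
    promoter index.
    """
    x = np.asarray(x, float)
    if n < 0:
        raise ValueError("n must be >= 0")
    selected: list[int] = []
    for _ in range(min(n, x.shape[0])):
        best_idx, best_resid = -1, np.inf
        for cand in range(x.shape[0]):
            if cand in selected:
                continue
            basis = x[selected + [cand]]
            q, _ = np.linalg.qr(basis.T)     # orthonormal basis of the row space
            resid = float(np.sum((x - (x @ q) @ q.T) ** 2))
            if resid < best_resid - 1e-15:
                best_idx, best_resid = cand, resid
        selected.append(best_idx)
        if best_resid <= 1e-24:
            # matrix already reconstructed exactly; remaining picks are
            # arbitrary, keep filling deterministically by index order
            remaining = [i for i in range(x.shape[0]) if i not in selected]
            selected.extend(remaining[: n - len(selected)])
            break
    return np.array(selected[:n], dtype=int)


# ---------------------------------------------------------------------------
# prediction via extended centers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PredictionModel:
    """A cluster model extended into a held-out condition."""

    base: ClusterModel
    representatives: np.ndarray          # indices into the training matrix
    extensions: np.ndarray               # per-cluster coordinate in the new condition
    fallback_clusters: list[int]         # clusters that inherited the global extension


def extend_centers(model: ClusterModel, x: np.ndarray, rep_idx: np.ndarray,
                   rep_values: np.ndarray) -> PredictionModel:
    """Estimate each cluster's coordinate in the new condition.

    For cluster t the extension e_t is the no-intercept least-squares
    slope regressing the representatives' measured new-condition values
    on their projection coefficients (x_rep . c_t for unit c_t); the
    extended center is (c_t, e_t) up to normalization.  A cluster with no
    representative inherits the dominant (global) cluster's extension and
    is flagged.
    """
    x = np.asarray(x, float)
    rep_idx = np.asarray(rep_idx, int)
    rep_values = np.asarray(rep_values, float)
    ext = np.full(model.k, np.nan)
    for t in range(model.k):
        in_t = model.assignment[rep_idx] == t
        if not np.any(in_t):
            continue
        alpha = x[rep_idx[in_t]] @ model.centers[t]
        denom = float(np.sum(alpha * alpha))
        if denom > 0:
            ext[t] = float(np.sum(alpha * rep_values[in_t]) / denom)
    fallback = [t for t in range(model.k) if not np.isfinite(ext[t])]
    if fallback:
        if not np.isfinite(ext[0]):
            raise ValueError("global cluster has no usable representative")
        logger.info("clusters %s have no representative; using the global extension", fallback)
        ext[fallback] = ext[0]
    return PredictionModel(base=model, representatives=rep_idx, extensions=ext,
                           fallback_clusters=fallback)


def predict_condition(model: ClusterModel, x: np.ndarray, rep_idx: np.ndarray,
                      rep_values: np.ndarray, detection: float | None = None) -> np.ndarray:
    """Predicted activities in the new condition for every promoter.

    Prediction for promoter p in cluster t is (x_p . c_t) * e_t, the
    projection coefficient on the cluster ray times the cluster's
    extension coordinate.  If ``detection`` is given, predictions are
    floored at it (matching the activity-matrix convention).
    """
    pm = extend_centers(model, x, rep_idx, rep_values)
    x = np.asarray(x, float)
    alpha = np.sum(x * pm.base.centers[pm.base.assignment], axis=1)
    pred = alpha * pm.extensions[pm.base.assignment]
    if detection is not None:
        pred = np.maximum(pred, detection)
    return pred


def predict_linear_sum(x: np.ndarray, rep_idx: np.ndarray, rep_values: np.ndarray,
                       detection: float | None = None) -> np.ndarray:
    """Predict the new condition as the best linear sum of representatives.

    Each promoter's training profile is reconstructed by least squares as
    a linear combination of the representatives' training profiles; the
    same coefficients applied to the representatives' measured
    new-condition values give the prediction.  This is the predictor the
    greedy selection criterion optimizes; it is well determined when the
    number of representatives is below the number of training conditions.
    """
    x = np.asarray(x, float)
    rep_idx = np.asarray(rep_idx, int)
    b = x[rep_idx]                                   # (n_reps, m)
    coef, *_ = np.linalg.lstsq(b.T, x.T, rcond=None)  # (n_reps, n_promoters)
    pred = coef.T @ np.asarray(rep_values, float)
    if detection is not None:
        pred = np.maximum(pred, detection)
    return pred


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(values: pd.DataFrame, n_reps: int = 10, scheme: str = "nearest",
                  k_max: int = 12, min_sep: float = 0.05, restarts: int = 100,
                  seed: int = 0, error_model=None,
                  detection: pd.Series | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-condition-out prediction benchmark.

    For every held-out condition: re-select K on the remaining
    conditions, cluster, pick ``n_reps`` representatives by ``scheme``
    (``nearest`` or ``greedy``), predict the held-out column from the
    representatives' measured values, and score.  The nearest scheme
    predicts through extended cluster centers; the greedy scheme uses
    the best-linear-sum predictor its selection criterion optimizes
    (see :func:`predict_linear_sum`).  Returns a per-condition
    summary (r2 = variance explained between predicted and measured,
    fraction of promoters with relative error within 3x their CV, K) and
    a long per-promoter table.
    """
    conds = list(values.columns)
    if len(conds) < 3:
        raise ValueError("need at least 3 conditions for cross-validation")
    summaries = []
    details = []
    for j, held in enumerate(conds):
        train_conds = [c for c in conds if c != held]
        xtrain = values[train_conds].to_numpy(float)
        usable = np.linalg.norm(xtrain, axis=1) > 0
        xtrain = xtrain[usable]
        y = values.loc[usable, held].to_numpy(float)
        promoters = values.index[usable]

        model = fit_clusters(xtrain, k_max=k_max, min_sep=min_sep,
                             restarts=restarts, seed=seed + j)
        floor = float(detection[held]) if detection is not None else None
        if scheme == "nearest":
            rep_idx = choose_representatives_nearest(xtrain, model, n=n_reps)
            pred = predict_condition(model, xtrain, rep_idx, y[rep_idx], detection=floor)
        elif scheme == "greedy":
            rep_idx = choose_representatives_greedy(xtrain, n=n_reps)
            pred = predict_linear_sum(xtrain, rep_idx, y[rep_idx], detection=floor)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

        resid = y - pred
        r2 = 1.0 - float(np.sum(resid ** 2)) / float(np.sum((y - y.mean()) ** 2))
        rel_err = np.abs(resid) / np.maximum(y, 1e-300)
        if error_model is not None:
            cv = np.asarray(error_model.cv_at(np.maximum(y, 1e-300)), float)
            within = rel_err <= 3.0 * cv
            frac_within = float(np.mean(within))
        else:
            frac_within = np.nan
        summaries.append({"condition": held, "r2": r2, "k": model.k,
                          "n_promoters": int(usable.sum()),
                          "n_representatives": len(rep_idx),
                          "frac_within_3cv": frac_within})
        details.append(pd.DataFrame({
            "promoter": promoters, "condition": held, "predicted": pred,
            "measured": y, "relative_error": rel_err,
            "is_representative": np.isin(np.arange(xtrain.shape[0]), rep_idx),
        }))
    return pd.DataFrame(summaries).set_index("condition"), pd.concat(details, ignore_index=True)
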