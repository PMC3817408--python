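"""Global scale lines between condition pairs.

For every pair of conditions (A, B) the activities of most promoters are
related by a single multiplicative constant — the global scaling factor
S[A, B], the slope of a ray through the origin in the (activity-in-A,
activity-in-B) plane.  This module fits that ray robustly, quantifies how
much of the pairwise variance it explains, attaches a permutation
p-value, and classifies each promoter as following the global trend or as
condition specific by two complementary rules:

* method A — a promoter is global if its residual from the ray is within
  three experimental standard deviations (from the error model) in either
  coordinate; applicable to the whole detected range.
* method B — restricted to promoters active above a floor (default 0.1)
  in both conditions, a promoter is global if its activity is within a
  fixed relative tolerance (default 30%) of the ray's prediction.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .activity import ActivityMatrix
from .error_model import ErrorModel

logger = logging.getLogger(__name__)

GLOBAL, SPECIFIC, EXCLUDED = "global", "specific", "excluded"


# ---------------------------------------------------------------------------
# robust ray fit
# ---------------------------------------------------------------------------

def fit_scale_line(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                   tuning: float = 4.685, max_iter: int = 100, tol: float = 1e-8,
                   min_points: int = 10) -> float:
    """Slope of the origin-anchored robust line y = a x.

    Iteratively reweighted least squares with Tukey bisquare weights on
    the residuals y - a x.  The residual scale is fixed at
    1.4826 * median |residual| of the median-ratio fit (a zero scale
    means that fit is already exact).  Because the bisquare loss at fixed
    scale can be multimodal, the IRLS iteration is started from the
    deciles of the observed ratios y/x and the converged slope with the
    lowest bisquare objective is returned.  Zero or negative inputs are
    excluded (with a logged count).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w0 = np.ones_like(x) if weights is None else np.asarray(weights, float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0) & (w0 > 0)
    if ok.sum() < x.size:
        logger.debug("fit_scale_line: excluded %d non-positive/invalid pairs", int(x.size - ok.sum()))
    x, y, w0 = x[ok], y[ok], w0[ok]
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} usable pairs, got {x.size}")

    ratios = y / x
    a0 = float(np.median(ratios))
    scale = 1.4826 * float(np.median(np.abs(y - a0 * x)))
    if scale == 0.0:
        return a0

    def irls(a: float) -> float | None:
        for _ in range(max_iter):
            u = (y - a * x) / (tuning * scale)
            w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0) * w0
            denom = float(np.sum(w * x * x))
            if denom <= 0:
                return None
            a_new = float(np.sum(w * x * y) / denom)
            if abs(a_new - a) <= tol * max(abs(a), 1e-300):
                return a_new
            a = a_new
        return a

    starts = np.unique(np.concatenate([[a0], np.quantile(ratios, np.linspace(0.1, 0.9, 9))]))
    best_a, best_obj = None, np.inf
    for a_start in starts:
        a_fit = irls(float(a_start))
        if a_fit is None or a_fit <= 0:
            continue
        obj = bisquare_objective(x, y, a_fit, scale, tuning)
        if obj < best_obj - 1e-12:
            best_a, best_obj = a_fit, obj
    if best_a is None:
        raise ValueError("all points down-weighted to zero; cannot fit")
    return best_a


def bisquare_objective(x: np.ndarray, y: np.ndarray, a: float,
                       scale: float, tuning: float = 4.685) -> float:
    """Tukey bisquare loss of the residuals y - a x at a fixed scale.

    This is the objective whose stationary point the IRLS iteration
    reaches; exposed so independent grid searches can validate the fit.
    """
    u = (y - a * x) / (tuning * scale)
    rho = np.where(np.abs(u) < 1.0, (1.0 - (1.0 - u * u) ** 3) / 6.0, 1.0 / 6.0)
    return float(np.sum(rho))


def initial_scale(x: np.ndarray, y: np.ndarray) -> float:
    """The fixed residual scale used by :func:`fit_scale_line`."""
    a0 = float(np.median(y / x))
    return 1.4826 * float(np.median(np.abs(y - a0 * x)))


# ---------------------------------------------------------------------------
# variance explained and permutation test
# ---------------------------------------------------------------------------

def _pooled_var(arr: np.ndarray) -> float:
    return float(np.var(arr.ravel()))


def variance_explained_line(x: np.ndarray, y: np.ndarray, slope: float) -> float:
    """Fraction of pooled pairwise variance captured by the ray y = slope * x.

    Each point v = (x_g, y_g) is orthogonally projected onto the ray;
    with d(g) = v - projection, the result is
    1 - variance(d) / variance(v), both variances pooled over all scalar
    components (mean-centered).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = 1.0 / np.hypot(1.0, slope)
    s = slope * c
    r = s * x - c * y                     # signed perpendicular distance
    d = np.stack([s * r, -c * r])
    v = np.stack([x, y])
    return 1.0 - _pooled_var(d) / _pooled_var(v)


def permutation_pvalue(x: np.ndarray, y: np.ndarray, slope: float,
                       n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the variance explained by the fitted ray.

    The y-condition activities are permuted across promoters and the
    variance explained by the *original* ray is recomputed for each
    permutation; p = (1 + #{VE_perm >= VE_obs}) / (n_perm + 1), so the
    attainable minimum is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    n = x.size
    c = 1.0 / np.hypot(1.0, slope)
    s = slope * c

    def pooled_var_d(r: np.ndarray) -> np.ndarray:
        # residual components are (s*r, -c*r): pooled over 2n entries
        mean_d = 0.5 * (s - c) * r.mean(axis=-1)
        return 0.5 * (r * r).mean(axis=-1) - mean_d ** 2

    var_v = _pooled_var(np.stack([x, y]))
    ve_obs = 1.0 - pooled_var_d(s * x - c * y) / var_v

    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = s * x[None, :] - c * y[perm]
    ve_perm = 1.0 - pooled_var_d(r_perm) / var_v
    return float((1 + np.sum(ve_perm >= ve_obs)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# global / specific classification
# ---------------------------------------------------------------------------

def classify_global_a(x: np.ndarray, y: np.ndarray, slope: float,
                      err: ErrorModel, n_sd: float = 3.0) -> np.ndarray:
    """Method A: global if within three experimental SDs of the ray.

    A promoter with activities (x, y) follows the global trend if
    |y - a x| < 3 s_y or |x - y/a| < 3 s_x, where s_x, s_y are the
    error-model SDs at its activity levels.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s_x = np.asarray(err.sd_at(x), float)
    s_y = np.asarray(err.sd_at(y), float)
    ok = (np.abs(y - slope * x) < n_sd * s_y) | (np.abs(x - y / slope) < n_sd * s_x)
    return np.where(ok, GLOBAL, SPECIFIC)


def classify_global_b(x: np.ndarray, y: np.ndarray, slope: float,
                      min_activity: float = 0.1, tol: float = 0.30) -> np.ndarray:
    """Method B: global if within ``tol`` of the ray, on moderately active promoters.

    Promoters with activity <= ``min_activity`` in either condition are
    labeled excluded; the rest are global iff |y / (a x) - 1| <= tol.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels = np.full(x.shape, EXCLUDED, dtype=object)
    active = (x > min_activity) & (y > min_activity)
    dev = np.abs(y[active] / (slope * x[active]) - 1.0)
    labels[active] = np.where(dev <= tol, GLOBAL, SPECIFIC)
    return labels.astype(str)


# ---------------------------------------------------------------------------
# all-pairs driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScaleFit:
    """Fitted scale line and classification for one condition pair (A -> B)."""

    cond_a: str
    cond_b: str
    slope: float
    variance_explained: float
    permutation_p: float
    labels: pd.Series            # per analyzed promoter: global/specific/excluded
    method: str
    n_fit: int

    @property
    def n_global(self) -> int:
        return int((self.labels == GLOBAL).sum())

    @property
    def n_specific(self) -> int:
        return int((self.labels == SPECIFIC).sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == EXCLUDED).sum())

    @property
    def fraction_global(self) -> float:
        n = self.n_global + self.n_specific
        return self.n_global / n if n else np.nan


@dataclasses.dataclass
class PairwiseScaling:
    """All-pairs scale fits plus the per-condition factor vector vs the reference."""

    fits: dict[tuple[str, str], ScaleFit]
    factors: pd.Series           # S[ref, c], reference = 1
    reference: str

    def get(self, cond_a: str, cond_b: str) -> ScaleFit:
        if (cond_a, cond_b) in self.fits:
            return self.fits[(cond_a, cond_b)]
        raise KeyError((cond_a, cond_b))

    def slope(self, cond_a: str, cond_b: str) -> float:
        """S[A, B] for any ordered pair (uses 1/slope for the reversed key)."""
        if cond_a == cond_b:
            return 1.0
        if (cond_a, cond_b) in self.fits:
            return self.fits[(cond_a, cond_b)].slope
        return 1.0 / self.fits[(cond_b, cond_a)].slope

    def to_table(self) -> pd.DataFrame:
        rows = [{
            "cond_a": f.cond_a, "cond_b": f.cond_b, "slope": f.slope,
            "variance_explained": f.variance_explained, "permutation_p": f.permutation_p,
            "n_global": f.n_global, "n_specific": f.n_specific,
            "n_excluded": f.n_excluded, "fraction_global": f.fraction_global,
        } for f in self.fits.values()]
        return pd.DataFrame(rows)


def fit_pair(x: pd.Series, y: pd.Series, fit_mask: np.ndarray, classify_mask: np.ndarray,
             cond_a: str, cond_b: str, err: ErrorModel | None, method: str = "A",
             n_perm: int = 1000, seed: int = 0,
             min_activity: float = 0.1, tol: float = 0.30) -> ScaleFit:
    """Fit and classify one condition pair on pre-masked data."""
    xv, yv = x.to_numpy(float), y.to_numpy(float)
    slope = fit_scale_line(xv[fit_mask], yv[fit_mask])
    ve = variance_explained_line(xv[fit_mask], yv[fit_mask], slope)
    p = permutation_pvalue(xv[fit_mask], yv[fit_mask], slope, n_perm=n_perm, seed=seed)

    labels = np.full(xv.shape, EXCLUDED, dtype=object)
    if method == "A":
        if err is None:
            raise ValueError("method A requires an error model")
        labels[classify_mask] = classify_global_a(xv[classify_mask], yv[classify_mask], slope, err)
    elif method == "B":
        labels[classify_mask] = classify_global_b(xv[classify_mask], yv[classify_mask], slope,
                                                  min_activity=min_activity, tol=tol)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScaleFit(cond_a=cond_a, cond_b=cond_b, slope=slope, variance_explained=ve,
                    permutation_p=p, labels=pd.Series(labels.astype(str), index=x.index),
                    method=method, n_fit=int(fit_mask.sum()))


def pairwise_scaling(matrix: ActivityMatrix, err: ErrorModel | None, reference: str,
                     method: str = "A", n_perm: int = 1000, seed: int = 0) -> PairwiseScaling:
    """Fit the scale line for every unordered condition pair.

    Detection-floored (or zeroed) cells are excluded from the slope fit —
    floors would bias the ray downward — but promoters above detection in
    at least one of the two conditions are retained (at their floor
    values) for classification.  The per-condition factor vector is
    S[ref, c] with the reference fixed at 1.
    """
    conds = matrix.conditions
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    if reference not in conds:
        raise ValueError(f"reference {reference!r} not among conditions")
    vals = matrix.values
    below = matrix.below_detection

    fits: dict[tuple[str, str], ScaleFit] = {}
    for i, (ca, cb) in enumerate(combinations(conds, 2)):
        fit_mask = (~below[ca] & ~below[cb] & vals[ca].gt(0) & vals[cb].gt(0)).to_numpy()
        cls_mask = (~(below[ca] & below[cb]) & vals[ca].gt(0) & vals[cb].gt(0)).to_numpy()
        fits[(ca, cb)] = fit_pair(vals[ca], vals[cb], fit_mask, cls_mask, ca, cb, err,
                                  method=method, n_perm=n_perm, seed=seed + i)

    ps = PairwiseScaling(fits=fits, factors=pd.Series(dtype=float), reference=reference)
    ps.factors = pd.Series({c: ps.slope(reference, c) for c in conds}, name="global_factor")
    return ps
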