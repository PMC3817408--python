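"""Activity-dependent measurement error learned from replicates.

The relative error of an extracted promoter activity depends strongly on
its level: replicate coefficients of variation (CV = SD/mean) are large
for barely detectable promoters and settle to a small constant for
strongly expressed ones.  The model bins promoter-condition cells by
their replicate-mean activity on a log grid, averages the per-cell CVs
within each bin, and answers CV/SD queries at arbitrary activity levels
by linear interpolation between bin centers in log-activity (clamped to
the edge values outside the binned range).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Binned CV-vs-activity curve; see :func:`fit_error_model`."""

    bin_centers: np.ndarray   # ascending activity levels
    bin_cv: np.ndarray        # mean replicate CV per bin
    n_per_bin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, float))
        object.__setattr__(self, "bin_cv", np.asarray(self.bin_cv, float))
        object.__setattr__(self, "n_per_bin", np.asarray(self.n_per_bin, int))
        if self.bin_centers.size != self.bin_cv.size or self.bin_centers.size == 0:
            raise ValueError("bin_centers and bin_cv must be non-empty and equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")

    def cv_at(self, activity) -> np.ndarray | float:
        """CV at the given activity level(s); log-linear interpolation, edge-clamped."""
        a = np.asarray(activity, float)
        if np.any(a[np.isfinite(a)] <= 0):
            raise ValueError("activity must be positive")
        out = np.interp(np.log10(a), np.log10(self.bin_centers), self.bin_cv)
        return float(out) if np.isscalar(activity) else out

    def sd_at(self, activity) -> np.ndarray | float:
        """SD = CV * activity."""
        return self.cv_at(activity) * np.asarray(activity, float) if not np.isscalar(activity) \
            else self.cv_at(activity) * float(activity)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"activity": self.bin_centers, "cv": self.bin_cv,
                             "n": self.n_per_bin})

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ErrorModel":
        n = table["n"].to_numpy() if "n" in table else np.zeros(len(table), int)
        return cls(table["activity"].to_numpy(), table["cv"].to_numpy(), n)


def fit_error_model(records: pd.DataFrame, n_bins: int = 10, min_per_bin: int = 5) -> ErrorModel:
    """Fit the binned CV curve from per-replicate activity records.

    ``records`` needs columns promoter, condition, replicate, activity.
    Promoter-condition cells with at least two replicates contribute one
    (mean, CV) point; points are binned by mean on a log grid of
    ``n_bins`` bins, bins with fewer than ``min_per_bin`` points are
    merged into their neighbor, and each surviving bin reports the mean
    CV at the geometric-mean activity of its members.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    g = records.groupby(["promoter", "condition"])["activity"]
    mean = g.mean()
    sd = g.std(ddof=1)
    n = g.size()
    usable = (n >= 2) & (mean > 0)
    if not usable.any():
        raise ValueError("no promoter with >= 2 replicates")
    mean, sd = mean[usable], sd[usable]
    cv = (sd / mean).to_numpy()
    logm = np.log10(mean.to_numpy())

    edges = np.linspace(logm.min(), logm.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(logm, edges) - 1, 0, n_bins - 1)

    # merge sparse bins rightward into the next occupied neighbor
    groups: list[np.ndarray] = []
    pending = np.zeros(0, int)
    for b in range(n_bins):
        members = np.flatnonzero(idx == b)
        pending = np.concatenate([pending, members])
        if pending.size >= min_per_bin:
            groups.append(pending)
            pending = np.zeros(0, int)
    if pending.size:
        if groups:
            groups[-1] = np.concatenate([groups[-1], pending])
        else:
            groups.append(pending)

    centers = np.array([10 ** logm[g].mean() for g in groups])
    cvs = np.array([cv[g].mean() for g in groups])
    counts = np.array([g.size for g in groups])
    if np.all(cvs == 0):
        logger.warning("all replicate CVs are zero; error model is degenerate")
    order = np.argsort(centers)
    return ErrorModel(bin_centers=centers[order], bin_cv=cvs[order], n_per_bin=counts[order])


def cv_at(model: ErrorModel, activity):
    """Functional alias for :meth:`ErrorModel.cv_at`."""
    return model.cv_at(activity)


def sd_at(model: ErrorModel, activity):
    """Functional alias for :meth:`ErrorModel.sd_at`."""
    return model.sd_at(activity)
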