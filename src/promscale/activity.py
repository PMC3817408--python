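"""Promoter-activity extraction from reporter growth curves.

Each well is reduced to a single number per condition: the reporter
production rate per OD unit per second inside a window placed at the
culture's maximal growth.  The steps are background subtraction
(media OD, autofluorescence proportional to OD), outlier smoothing
(Hampel filter), growth-window detection on the smoothed log-OD series,
doubling-time estimation, and the activity quadrature

    activity = (F(t2) - F(t1)) / integral_{t1}^{t2} OD dt

which equals the window average of (dF/dt)/OD for a constant production
rate and is robust to pointwise noise.

Two window modes are supported:

* ``yeast`` — the interval spanning exactly two OD doublings around the
  time of maximal growth; sub-detection activities are floored at the
  detection level (the 95th percentile of a normal fit to promoter-less
  control activities).
* ``ecoli`` — a 3-hour interval centered on the time of maximal growth
  (optionally restricted to after a compound-addition time);
  sub-threshold activities (below mean + 3 SD of controls) are zeroed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import WellCurve

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class NoGrowthError(ValueError):
    """Raised when no usable growth phase is found in a well."""


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BlankStats:
    """Background levels estimated from media blanks and promoter-less controls."""

    od_offset: float
    fluor_offset: dict[str, float]
    autofluor_per_od: dict[str, float]


def estimate_blank_stats(wells: list[WellCurve]) -> BlankStats:
    """Estimate background OD/fluorescence from blanks and the
    autofluorescence-vs-OD slope from promoter-less control wells.

    The slope is the through-origin least-squares regression of
    background-corrected control fluorescence on background-corrected OD,
    pooled over all control wells and time points.
    """
    blanks = [w for w in wells if w.is_blank]
    controls = [w for w in wells if w.is_control]
    if not blanks:
        raise ValueError("no media-blank wells found")
    od_offset = float(np.median(np.concatenate([w.od for w in blanks])))
    channels = sorted({c for w in wells for c in w.channels})
    fluor_offset = {c: float(np.median(np.concatenate([w.channels[c] for w in blanks if c in w.channels])))
                    for c in channels}
    auto = {}
    for c in channels:
        # reporter channels accumulate signal in promoter wells, so only
        # promoter-less controls identify the autofluorescence slope
        src = controls if controls else blanks
        x = np.concatenate([w.od - od_offset for w in src])
        y = np.concatenate([w.channels[c] - fluor_offset[c] for w in src if c in w.channels])
        denom = float(np.dot(x, x))
        auto[c] = float(np.dot(x, y) / denom) if denom > 0 else 0.0
    return BlankStats(od_offset=od_offset, fluor_offset=fluor_offset, autofluor_per_od=auto)


def subtract_background(curve: WellCurve, blank_stats: BlankStats) -> WellCurve:
    """Subtract media background and autofluorescence; clip negatives to 0.

    Clipping sets the ``background_clipped`` QC-style flag but is not a
    failure: near-zero series of blank and control wells legitimately
    fluctuate around zero.
    """
    od = curve.od - blank_stats.od_offset
    flags = set(curve.qc_flags)
    clipped = bool(np.any(od < 0))
    od = np.clip(od, 0.0, None)
    chans = {}
    for name, f in curve.channels.items():
        g = f - blank_stats.fluor_offset.get(name, 0.0) - blank_stats.autofluor_per_od.get(name, 0.0) * od
        clipped |= bool(np.any(g < 0))
        chans[name] = np.clip(g, 0.0, None)
    if clipped:
        flags.add("background_clipped")
    return curve.replace(od=od, channels=chans, qc_flags=flags)


# ---------------------------------------------------------------------------
# outlier smoothing
# ---------------------------------------------------------------------------

def _hampel(x: np.ndarray, window: int, k: float) -> tuple[np.ndarray, int]:
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    mad = (s - med).abs().rolling(window, center=True, min_periods=1).median().to_numpy()
    sigma = 1.4826 * mad
    bad = np.abs(x - med) > k * np.maximum(sigma, 1e-12)
    out = np.where(bad, med, x)
    return out, int(bad.sum())


def smooth_outliers(curve: WellCurve, hampel_window: int = 7, hampel_k: float = 3.0) -> tuple[WellCurve, int]:
    """Replace isolated spikes by the rolling median (Hampel filter).

    Points deviating from the rolling median by more than
    ``hampel_k`` times the rolling MAD-based sigma are replaced.
    Returns the smoothed curve and the number of replaced points.
    """
    if hampel_window % 2 == 0 or hampel_window < 3:
        raise ValueError("hampel_window must be odd and >= 3")
    if hampel_k <= 0:
        raise ValueError("hampel_k must be positive")
    od, n = _hampel(curve.od, hampel_window, hampel_k)
    chans = {}
    for name, f in curve.channels.items():
        chans[name], ni = _hampel(f, hampel_window, hampel_k)
        n += ni
    return curve.replace(od=od, channels=chans), n


# ---------------------------------------------------------------------------
# growth window and doubling time
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ActivityWindow:
    """Maximal-growth window [t1, t2] in seconds."""

    t1: float
    t2: float
    mode: str

    def __post_init__(self):
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")


def _rolling_slope(t: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of y vs t in sliding windows; returns (centers, slopes)."""
    n = t.size
    if n < window:
        return np.array([]), np.array([])
    slopes = np.empty(n - window + 1)
    centers = np.empty(n - window + 1)
    for i in range(n - window + 1):
        tt, yy = t[i:i + window], y[i:i + window]
        tm, ym = tt.mean(), yy.mean()
        denom = np.sum((tt - tm) ** 2)
        slopes[i] = np.sum((tt - tm) * (yy - ym)) / denom
        centers[i] = tm
    return centers, slopes


def find_growth_window(time: np.ndarray, od: np.ndarray, mode: str = "yeast",
                       od_floor: float = 0.01, slope_window: int = 5,
                       compound_time_s: float | None = None,
                       well_id: str = "?") -> ActivityWindow:
    """Locate the maximal-growth window on a background-corrected OD series.

    The time of maximal d(ln OD)/dt is found by rolling linear regression
    (``slope_window`` points) on ln OD restricted to points above
    ``od_floor``.  In ``yeast`` mode the returned interval spans exactly
    two OD doublings around that time (shifted into the measured range
    when necessary); in ``ecoli`` mode it is the 3-hour interval centered
    on that time, clipped to the run and, if given, to after
    ``compound_time_s``.
    """
    time = np.asarray(time, float)
    od = np.asarray(od, float)
    mask = np.isfinite(od) & (od > od_floor)
    if compound_time_s is not None:
        mask &= time >= compound_time_s
    if mask.sum() < 10:
        raise NoGrowthError(f"well {well_id!r}: fewer than 10 OD points above background")
    t, y = time[mask], np.log(od[mask])

    centers, slopes = _rolling_slope(t, y, slope_window)
    if centers.size == 0 or np.nanmax(slopes) <= 0:
        raise NoGrowthError(f"well {well_id!r}: no growth detected")
    t_star = float(centers[int(np.nanargmax(slopes))])

    if mode == "ecoli":
        half = 1.5 * 3600.0
        t1 = max(t_star - half, t[0])
        t2 = min(t1 + 2 * half, t[-1])
        t1 = max(t2 - 2 * half, t[0])
        return ActivityWindow(t1=t1, t2=t2, mode="ecoli")
    if mode != "yeast":
        raise ValueError(f"unknown mode {mode!r}")

    # monotone envelope of ln OD so level crossings are well defined under noise
    y_mon = np.maximum.accumulate(y)
    lo, hi = float(y_mon[0]), float(y_mon[-1])
    if hi - lo < 2 * LN2:
        raise NoGrowthError(f"well {well_id!r}: culture grew less than two doublings")
    y_star = float(np.interp(t_star, t, y_mon))
    y1 = float(np.clip(y_star - LN2, lo, hi - 2 * LN2))
    y2 = y1 + 2 * LN2
    t1 = float(np.interp(y1, y_mon, t))
    t2 = float(np.interp(y2, y_mon, t))
    return ActivityWindow(t1=t1, t2=t2, mode="yeast")


def doubling_time(time: np.ndarray, od: np.ndarray, window: ActivityWindow) -> float:
    """ln 2 over the least-squares slope of ln OD vs t inside the window."""
    time = np.asarray(time, float)
    od = np.asarray(od, float)
    sel = (time >= window.t1) & (time <= window.t2) & (od > 0) & np.isfinite(od)
    if sel.sum() < 3:
        raise NoGrowthError("fewer than 3 usable OD points in the window")
    res = stats.linregress(time[sel], np.log(od[sel]))
    if res.slope <= 0:
        raise NoGrowthError("non-positive growth rate in the window")
    return LN2 / float(res.slope)


# ---------------------------------------------------------------------------
# activity quadrature
# ---------------------------------------------------------------------------

def _interp_od(time: np.ndarray, od: np.ndarray, t: float) -> float:
    """OD at t, interpolating exponentially where the neighbors are positive."""
    i = int(np.searchsorted(time, t))
    if i == 0:
        return float(od[0])
    if i >= time.size:
        return float(od[-1])
    t0, t1 = time[i - 1], time[i]
    v0, v1 = od[i - 1], od[i]
    w = (t - t0) / (t1 - t0)
    if v0 > 0 and v1 > 0:
        return float(np.exp((1 - w) * np.log(v0) + w * np.log(v1)))
    return float((1 - w) * v0 + w * v1)


def promoter_activity(curve: WellCurve, window: ActivityWindow, channel: str = "yfp") -> float:
    """Reporter production rate per OD per second within the window.

    (F(t2) - F(t1)) / integral OD dt with trapezoidal quadrature on the
    measurement grid; fluorescence is interpolated linearly and OD
    exponentially at the fractional window boundaries.
    """
    t = curve.time
    od = curve.od
    f = curve.channels[channel]
    if window.t1 < t[0] - 1e-9 or window.t2 > t[-1] + 1e-9:
        raise ValueError("window outside the measured range")
    f1 = float(np.interp(window.t1, t, f))
    f2 = float(np.interp(window.t2, t, f))
    inner = (t > window.t1) & (t < window.t2)
    tt = np.concatenate([[window.t1], t[inner], [window.t2]])
    oo = np.concatenate([[_interp_od(t, od, window.t1)], od[inner], [_interp_od(t, od, window.t2)]])
    int_od = float(np.trapezoid(oo, tt))
    if int_od <= 0:
        raise ValueError("non-positive OD integral in the window")
    return (f2 - f1) / int_od


# ---------------------------------------------------------------------------
# detection level
# ---------------------------------------------------------------------------

def detection_level(control_activities: np.ndarray, mode: str = "yeast",
                    min_controls: int = 30) -> float:
    """Detection threshold from promoter-less control activities.

    ``yeast``: the 95th percentile of a normal distribution fitted to the
    control activities (mu + 1.6449 sigma).  ``ecoli``: mu + 3 sigma.
    """
    a = np.asarray(control_activities, float)
    a = a[np.isfinite(a)]
    if a.size < min_controls:
        raise ValueError(f"need >= {min_controls} control activities, got {a.size}")
    mu, sigma = float(np.mean(a)), float(np.std(a, ddof=1))
    if mode == "yeast":
        return float(stats.norm.ppf(0.95, loc=mu, scale=sigma)) if sigma > 0 else mu
    if mode == "ecoli":
        return mu + 3.0 * sigma
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# activity matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ActivityMatrix:
    """Promoters x conditions activity estimates with uncertainties.

    values[g, c] is the replicate-mean activity (floored at the detection
    level in yeast mode, zeroed below threshold in ecoli mode), sd the
    replicate SD (or an error-model SD when only one replicate exists),
    n_replicates the replicate count, below_detection the floor/zero flag
    and detection_level the per-condition threshold.
    """

    values: pd.DataFrame
    sd: pd.DataFrame
    n_replicates: pd.DataFrame
    below_detection: pd.DataFrame
    detection_level: pd.Series
    mode: str = "yeast"

    @property
    def promoters(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def to_table(self) -> pd.DataFrame:
        """Long-format interchange table (promoter, condition, activity, sd, n, flag)."""
        out = self.values.stack().rename("activity").reset_index()
        out.columns = ["promoter", "condition", "activity"]
        idx = out.set_index(["promoter", "condition"]).index
        out["sd"] = self.sd.stack().reindex(idx).to_numpy()
        out["n"] = self.n_replicates.stack().reindex(idx).to_numpy()
        out["below_detection"] = self.below_detection.stack().reindex(idx).to_numpy()
        return out

    @classmethod
    def from_table(cls, table: pd.DataFrame, detection: pd.Series, mode: str = "yeast") -> "ActivityMatrix":
        piv = lambda col: table.pivot(index="promoter", columns="condition", values=col)
        return cls(values=piv("activity"), sd=piv("sd"), n_replicates=piv("n"),
                   below_detection=piv("below_detection").astype(bool),
                   detection_level=detection, mode=mode)


def build_activity_matrix(records: pd.DataFrame, detection: pd.Series, mode: str = "yeast",
                          error_model=None) -> ActivityMatrix:
    """Average per-replicate activities into an :class:`ActivityMatrix`.

    ``records`` must have columns promoter, condition, replicate,
    activity (QC-passing replicates only).  In yeast mode sub-detection
    means are set to the detection level and flagged; in ecoli mode they
    are set to zero.  Cells with a single replicate take their SD from
    ``error_model`` (see :mod:`promscale.error_model`) when provided.
    """
    grouped = records.groupby(["promoter", "condition"])["activity"]
    mean = grouped.mean().unstack("condition")
    sd = grouped.std(ddof=1).unstack("condition")
    n = grouped.size().unstack("condition").fillna(0).astype(int)

    detection = detection.reindex(mean.columns)
    if detection.isna().any():
        raise ValueError("detection level missing for some conditions")

    below = mean.lt(detection, axis=1)
    values = mean.copy()
    if mode == "yeast":
        floor = pd.DataFrame(np.broadcast_to(detection.to_numpy(), values.shape),
                             index=values.index, columns=values.columns)
        values = values.where(~below, floor)
    elif mode == "ecoli":
        values = values.where(~below, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if error_model is not None:
        single = (n == 1) & mean.notna() & (mean > 0)
        if single.to_numpy().any():
            safe = mean.where(mean > 0, 1.0)
            est = pd.DataFrame(error_model.sd_at(safe.to_numpy()),
                               index=mean.index, columns=mean.columns)
            sd = sd.where(~single, est)

    return ActivityMatrix(values=values, sd=sd, n_replicates=n, below_detection=below,
                          detection_level=detection, mode=mode)


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def extract_activities(wells: list[WellCurve], mode: str = "yeast", channel: str = "yfp",
                       hampel_window: int = 7, hampel_k: float = 3.0,
                       od_floor: float = 0.01,
                       compound_time_s: float | None = None,
                       ) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Run the per-well pipeline over a set of wells.

    QC-flagged wells are skipped.  Returns

    * per-replicate activity records (promoter, condition, replicate, activity),
    * per-condition detection level,
    * per-condition doubling time in seconds (median over usable wells),
    * per-condition control-activity records (for error diagnostics).
    """
    blank_stats = estimate_blank_stats(wells)

    records: list[dict] = []
    controls: list[dict] = []
    taus: dict[str, list[float]] = {}
    n_failed = 0
    for w in wells:
        if w.is_blank or w.qc_flags:
            continue
        corrected = subtract_background(w, blank_stats)
        smoothed, _ = smooth_outliers(corrected, hampel_window, hampel_k)
        try:
            win = find_growth_window(smoothed.time, smoothed.od, mode=mode,
                                     od_floor=od_floor, compound_time_s=compound_time_s,
                                     well_id=w.well_id)
            act = promoter_activity(smoothed, win, channel=channel)
            tau = doubling_time(smoothed.time, smoothed.od, win)
        except (NoGrowthError, ValueError) as exc:
            n_failed += 1
            logger.debug("well %s failed extraction: %s", w.well_id, exc)
            continue
        taus.setdefault(w.condition, []).append(tau)
        row = {"promoter": w.promoter, "condition": w.condition,
               "replicate": w.replicate, "activity": act}
        (controls if w.is_control else records).append(row)
    if n_failed:
        logger.info("extraction skipped %d well(s) with no usable growth", n_failed)

    rec = pd.DataFrame(records)
    ctl = pd.DataFrame(controls)
    if ctl.empty:
        raise ValueError("no promoter-less control wells available for detection level")
    detection = ctl.groupby("condition")["activity"].apply(
        lambda a: detection_level(a.to_numpy(), mode=mode))
    tau_s = pd.Series({c: float(np.median(v)) for c, v in taus.items()}, name="tau_s")
    return rec, detection, tau_s, ctl
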