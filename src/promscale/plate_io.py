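"""Reading, writing and quality control of plate-reader growth curves.

A plate-reader run yields, per well, a time series of optical density (OD)
and one or more fluorescence channels (a promoter-driven reporter such as
YFP and, optionally, a constitutive second reporter such as RFP/mCherry
used to spot aberrant strains).  This module parses delimited-text exports
of such runs into :class:`WellCurve` objects and applies strain-level QC.

QC follows a flag-don't-drop policy: failing wells are marked with failure
codes but never deleted, so downstream stages decide what to exclude and
the full audit trail is preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: failure codes set by :func:`qc_filter`
QC_NO_GROWTH = "no_growth"
QC_GAPS = "gaps"
QC_CONSTITUTIVE_OUTLIER = "constitutive_outlier"
_QC_CODES = (QC_NO_GROWTH, QC_GAPS, QC_CONSTITUTIVE_OUTLIER)


@dataclasses.dataclass
class WellCurve:
    """One well's time series.

    Parameters
    ----------
    well_id : str
        Unique well identifier.
    promoter : str
        Promoter/strain identifier.  The reserved names ``__control__``
        (promoter-less reporter strain) and ``__blank__`` (media only)
        mark wells used for background and detection-level estimation.
    condition : str
        Growth-condition name.
    replicate : int
        Replicate index within (promoter, condition).
    time : ndarray
        Measurement times in seconds, strictly increasing.
    od : ndarray
        Optical density readings.
    channels : dict of str -> ndarray
        Fluorescence series keyed by channel name (e.g. ``"yfp"``,
        ``"rfp"``); all the same length as ``time``.
    qc_flags : set of str
        Failure codes; empty for a clean well.
    """

    well_id: str
    promoter: str
    condition: str
    replicate: int
    time: np.ndarray
    od: np.ndarray
    channels: dict[str, np.ndarray]
    qc_flags: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = self.time.size
        if self.od.size != n or any(v.size != n for v in self.channels.values()):
            raise ValueError(f"well {self.well_id!r}: series lengths differ")
        dt = np.diff(self.time)
        if n > 1 and not np.all(dt[np.isfinite(dt)] > 0):
            raise ValueError(f"well {self.well_id!r}: time is not strictly increasing")

    @property
    def is_control(self) -> bool:
        return self.promoter == "__control__"

    @property
    def is_blank(self) -> bool:
        return self.promoter == "__blank__"

    def replace(self, **kwargs) -> "WellCurve":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["well", "promoter", "condition", "replicate", "time_s", "od"]


def write_plate_table(wells: list[WellCurve], path, dialect: str = "long", sep: str = "\t") -> None:
    """Write wells as delimited text.

    ``long`` dialect has one row per (well, time point) with columns
    ``well, promoter, condition, replicate, time_s, od, <channel...>``.
    ``wide`` dialect has one ``time_s`` column followed by one column per
    (well, series) named ``<well>|od`` and ``<well>|<channel>``; it
    requires all wells to share the same time grid.
    """
    if dialect == "long":
        frames = []
        for w in wells:
            df = pd.DataFrame({
                "well": w.well_id,
                "promoter": w.promoter,
                "condition": w.condition,
                "replicate": w.replicate,
                "time_s": w.time,
                "od": w.od,
            })
            for name, series in w.channels.items():
                df[name] = series
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False, float_format="%.17g")
    elif dialect == "wide":
        t0 = wells[0].time
        for w in wells:
            if w.time.shape != t0.shape or not np.allclose(w.time, t0):
                raise ValueError("wide dialect requires a shared time grid")
        data = {"time_s": t0}
        for w in wells:
            data[f"{w.well_id}|od"] = w.od
            for name, series in w.channels.items():
                data[f"{w.well_id}|{name}"] = series
        pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_plate_table(path, dialect: str = "long", sep: str = "\t",
                     column_map: dict[str, str] | None = None) -> list[WellCurve]:
    """Read a delimited plate table into :class:`WellCurve` objects.

    ``column_map`` renames file columns onto the canonical names of the
    long dialect.  Rows with non-numeric time/OD entries are reported
    with their line numbers (via the module logger) and skipped; a
    non-monotone time series is a hard error naming the well.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)

    if dialect == "wide":
        return _read_wide(df)
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    channel_cols = [c for c in df.columns if c not in LONG_COLUMNS]

    numeric_cols = ["time_s", "od"] + channel_cols
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced[["time_s", "od"]].isna().any(axis=1) & df[["time_s", "od"]].notna().any(axis=1)
    bad |= df[["time_s", "od"]].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        logger.warning("%s: skipped %d malformed row(s) at line(s) %s", path, len(lines), lines)
    df = df.loc[~bad].copy()
    df[numeric_cols] = coerced.loc[~bad]

    wells = []
    for well_id, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {well_id!r}: non-monotone time series")
        wells.append(WellCurve(
            well_id=str(well_id),
            promoter=str(grp["promoter"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            replicate=int(grp["replicate"].iloc[0]),
            time=t,
            od=grp["od"].to_numpy(float),
            channels={c: grp[c].to_numpy(float) for c in channel_cols},
        ))
    return wells


def _read_wide(df: pd.DataFrame) -> list[WellCurve]:
    if "time_s" not in df.columns:
        raise ValueError("wide table must contain a 'time_s' column")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValueError("wide table: non-monotone or non-numeric time column")
    per_well: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        if "|" not in col:
            raise ValueError(f"wide column {col!r} must be named '<well>|<series>'")
        well, series = col.rsplit("|", 1)
        per_well.setdefault(well, {})[series] = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
    wells = []
    for well_id, series in per_well.items():
        if "od" not in series:
            raise ValueError(f"well {well_id!r}: wide table lacks an od column")
        parts = well_id.split(":")
        promoter, condition, replicate = (parts + ["", "0"])[:3] if len(parts) == 3 else (well_id, "", 0)
        if len(parts) == 3:
            condition, promoter, replicate = parts
        wells.append(WellCurve(
            well_id=well_id, promoter=str(promoter), condition=str(condition),
            replicate=int(replicate), time=t, od=series.pop("od"), channels=series,
        ))
    return wells


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class QCRules:
    """Thresholds for strain-level quality control.

    min_od_gain
        Minimal raw OD gain (max minus initial) a growing culture must
        show; wells below it are flagged ``no_growth``.
    max_gaps
        Maximal tolerated count of missing/non-finite points per well.
    constitutive_channel
        Name of the constitutive reporter channel, or None to skip the
        cross-strain consistency check.
    max_constitutive_z
        Bound on the robust z-score of the constitutive-channel yield
        (fluorescence gain per OD gain) across wells of one condition.
    """

    min_od_gain: float = 0.1
    max_gaps: int = 2
    constitutive_channel: str | None = "rfp"
    max_constitutive_z: float = 3.0


def qc_filter(wells: list[WellCurve], rules: QCRules = QCRules()) -> dict[str, int]:
    """Apply QC rules in place, setting ``qc_flags`` on failing wells.

    Blank (media-only) wells are exempt.  Returns a summary count per
    failure code.  Idempotent: flags owned by QC are recomputed from
    scratch on every call.
    """
    for w in wells:
        w.qc_flags.difference_update(_QC_CODES)

    summary = {code: 0 for code in _QC_CODES}
    candidates = [w for w in wells if not w.is_blank]

    for w in candidates:
        n_bad = int(np.sum(~np.isfinite(w.od)) + sum(np.sum(~np.isfinite(v)) for v in w.channels.values()))
        if n_bad > rules.max_gaps:
            w.qc_flags.add(QC_GAPS)
            summary[QC_GAPS] += 1
        od = w.od[np.isfinite(w.od)]
        gain = float(od.max() - od[0]) if od.size else 0.0
        if gain < rules.min_od_gain:
            w.qc_flags.add(QC_NO_GROWTH)
            summary[QC_NO_GROWTH] += 1

    ch = rules.constitutive_channel
    if ch is not None:
        by_condition: dict[str, list[WellCurve]] = {}
        for w in candidates:
            if ch in w.channels:
                by_condition.setdefault(w.condition, []).append(w)
        for cond_wells in by_condition.values():
            yields = np.array([_constitutive_yield(w, ch) for w in cond_wells])
            ok = np.isfinite(yields)
            if ok.sum() < 3:
                continue
            med = np.median(yields[ok])
            mad = np.median(np.abs(yields[ok] - med)) * 1.4826
            if mad == 0:
                continue
            z = (yields - med) / mad
            for w, zi in zip(cond_wells, z):
                if np.isfinite(zi) and abs(zi) > rules.max_constitutive_z:
                    w.qc_flags.add(QC_CONSTITUTIVE_OUTLIER)
                    summary[QC_CONSTITUTIVE_OUTLIER] += 1

    logger.info("QC summary: %s", summary)
    return summary


def _constitutive_yield(w: WellCurve, channel: str) -> float:
    """Constitutive fluorescence gain per OD gain; NaN if the well did not grow."""
    od = w.od
    f = w.channels[channel]
    ok = np.isfinite(od) & np.isfinite(f)
    if ok.sum() < 2:
        return np.nan
    od, f = od[ok], f[ok]
    d_od = od.max() - od[0]
    if d_od <= 1e-6:
        return np.nan
    return (f.max() - f[0]) / d_od
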