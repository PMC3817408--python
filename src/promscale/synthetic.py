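"""Synthetic reporter-library data with a planted scaling structure.

The generator plants the structure this package is built to recover: most
promoters (one dominant cluster) change between growth conditions by a
single global scaling factor, while a few small clusters additionally
carry condition-specific multipliers.  Global factors are generated
self-consistently from a conservation law — the summed promoter activity
times the doubling time is the same fixed resource in every condition —
so the downstream resource-allocation model is exact on noise-free truth.

On top of the ground-truth activity matrix the generator emits realistic
plate-reader wells: logistic OD growth, cumulative reporter fluorescence
driven by a constant per-OD production rate, autofluorescence
proportional to OD, additive media background, and multiplicative
log-normal well-to-well noise whose coefficient of variation depends on
activity (large at very low activity, small at high activity, matching
replicate variability of fluorescent-reporter assays).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .plate_io import WellCurve

MIN_PER_S = 60.0


@dataclasses.dataclass(frozen=True)
class Condition:
    """A growth condition and its culture doubling time (minutes)."""

    name: str
    doubling_time_min: float

    @property
    def tau_s(self) -> float:
        return self.doubling_time_min * MIN_PER_S


#: Default panel: a reference rich-carbon condition plus alternative carbon
#: sources and stresses, with doubling times in the range typical of
#: budding-yeast plate cultures.
DEFAULT_CONDITIONS = (
    Condition("glucose", 90.0),
    Condition("galactose", 140.0),
    Condition("glycerol", 180.0),
    Condition("ethanol", 220.0),
    Condition("osmotic", 160.0),
    Condition("heat", 120.0),
)

#: Default condition-specific multipliers r_t[c] for clusters 2..6 (row per
#: cluster, column per condition in DEFAULT_CONDITIONS order).  Cluster 1 is
#: the global cluster (r identically 1, not listed).  The signatures mimic a
#: respiration group, an osmotic-stress group, a galactose-utilization
#: group, a heat-shock group and a group repressed on poor carbon; each
#: differs from the global direction in at least two conditions so the
#: planted geometry survives leaving any one condition out.
DEFAULT_SPECIFIC_FACTORS = (
    (1.0, 3.0, 8.0, 12.0, 1.0, 1.0),
    (1.0, 1.0, 1.0, 1.0, 10.0, 3.0),
    (1.0, 12.0, 3.5, 1.0, 1.0, 1.0),
    (1.0, 1.0, 2.5, 2.5, 1.0, 10.0),
    (1.0, 0.15, 0.08, 0.06, 0.3, 0.45),
)

#: Activity-dependent replicate CV: ~0.36 at very low activities falling to
#: a constant 0.05 for activities above 0.1 (log-linear in between).
DEFAULT_CV_CURVE = ((0.003, 0.36), (0.01, 0.20), (0.03, 0.10), (0.1, 0.05), (10.0, 0.05))


@dataclasses.dataclass(frozen=True)
class TruthConfig:
    """Configuration of the planted ground truth.

    cluster_fractions must sum to 1; the first entry is the dominant
    global cluster.  relative_specific_factors has one row per cluster
    t >= 2 and one positive multiplier per condition (the global cluster's
    multipliers are implicitly 1).  baseline_dispersion is the SD of
    ln(baseline activity); total_budget is the conserved
    activity x doubling-time resource (its value only sets the overall
    scale and cancels once the reference factor is normalized to 1).
    """

    n_promoters: int = 500
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    n_clusters: int = 6
    cluster_fractions: tuple[float, ...] = (0.77, 0.05, 0.05, 0.05, 0.04, 0.04)
    relative_specific_factors: tuple[tuple[float, ...], ...] = DEFAULT_SPECIFIC_FACTORS
    baseline_dispersion: float = 1.5
    total_budget: float = 1.0
    reference: str = "glucose"
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be positive")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if any(c.doubling_time_min <= 0 for c in self.conditions):
            raise ValueError("all doubling times must be positive")
        if len(self.cluster_fractions) != self.n_clusters:
            raise ValueError("cluster_fractions length must equal n_clusters")
        if not np.isclose(sum(self.cluster_fractions), 1.0):
            raise ValueError("cluster_fractions must sum to 1")
        r = self.specific_matrix()
        if r.shape != (self.n_clusters, len(self.conditions)):
            raise ValueError("relative_specific_factors must have one row per cluster >= 2 "
                             "and one column per condition")
        if np.any(r <= 0):
            raise ValueError("specific factors must be positive")
        if self.reference not in [c.name for c in self.conditions]:
            raise ValueError(f"reference condition {self.reference!r} not in conditions")
        if self.total_budget <= 0:
            raise ValueError("total_budget must be positive")

    def specific_matrix(self) -> np.ndarray:
        """Full (n_clusters x n_conditions) multiplier matrix; row 0 is all ones."""
        rows = [np.ones(len(self.conditions))]
        rows += [np.asarray(r, dtype=float) for r in self.relative_specific_factors]
        return np.vstack(rows) if self.n_clusters > 1 else np.asarray(rows[:1])

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    @property
    def tau_s(self) -> np.ndarray:
        return np.array([c.tau_s for c in self.conditions])

    @property
    def reference_index(self) -> int:
        return self.condition_names.index(self.reference)


@dataclasses.dataclass
class GroundTruth:
    """Planted activities, factors and labels."""

    config: TruthConfig
    promoters: list[str]
    true_activity: pd.DataFrame          # promoters x conditions, positive
    true_global_factors: pd.Series       # per condition, reference == 1
    cluster_of: pd.Series                # promoter -> cluster id (0-based, 0 = global)
    is_specific: pd.DataFrame            # promoters x conditions bool (r differs from ref)
    baselines: pd.Series

    @property
    def conditions(self) -> list[str]:
        return list(self.true_activity.columns)


def solve_self_consistent_factors(cfg: TruthConfig, baselines: np.ndarray,
                                  cluster_of: np.ndarray) -> np.ndarray:
    """Global factors under the fixed-resource-per-doubling-time law.

    With activities P[g,c] = baseline_g * S[c] * r_{t(g)}[c], requiring
    tau_c * sum_g P[g,c] == total_budget in every condition gives

        S[c] = total_budget / (tau_c * sum_g baseline_g * r_{t(g)}[c])

    after which S is rescaled so the reference condition equals 1.
    """
    cfg.validate()
    baselines = np.asarray(baselines, dtype=float)
    cluster_of = np.asarray(cluster_of, dtype=int)
    if baselines.size == 0:
        raise ValueError("empty promoter set")
    if np.any(baselines <= 0):
        raise ValueError("baselines must be positive")
    r = cfg.specific_matrix()                      # (K, m)
    denom = cfg.tau_s * (baselines @ r[cluster_of])  # per condition
    s = cfg.total_budget / denom
    return s / s[cfg.reference_index]


def simulate_truth(cfg: TruthConfig) -> GroundTruth:
    """Draw baselines and cluster memberships; build the exact activity matrix.

    Deterministic given ``cfg.seed``.  RNG consumption order (part of the
    reproducibility contract): cluster memberships first, then baselines.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cluster_of = rng.choice(cfg.n_clusters, size=cfg.n_promoters, p=cfg.cluster_fractions)
    baselines = np.exp(rng.normal(0.0, cfg.baseline_dispersion, size=cfg.n_promoters))

    s = solve_self_consistent_factors(cfg, baselines, cluster_of)
    r = cfg.specific_matrix()
    activity = baselines[:, None] * s[None, :] * r[cluster_of]

    promoters = [f"p{i:04d}" for i in range(cfg.n_promoters)]
    names = cfg.condition_names
    ref = cfg.reference_index
    specific = r[cluster_of] != r[cluster_of][:, [ref]]
    return GroundTruth(
        config=cfg,
        promoters=promoters,
        true_activity=pd.DataFrame(activity, index=promoters, columns=names),
        true_global_factors=pd.Series(s, index=names),
        cluster_of=pd.Series(cluster_of, index=promoters),
        is_specific=pd.DataFrame(specific, index=promoters, columns=names),
        baselines=pd.Series(baselines, index=promoters),
    )


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PlateConfig:
    """Plate-reader simulation settings.

    Time grid: readings every ``interval_s`` seconds for ``duration_s``.
    Growth is logistic, OD(t) = K od0 e^{mu t} / (K + od0 (e^{mu t} - 1))
    with mu = ln 2 / tau_c, so the early phase is exponential.  Measured
    OD adds the media background plus Gaussian read noise; measured
    fluorescence is background + autofluorescence proportional to OD +
    the accumulated reporter signal + read noise.  Reporter accumulation
    uses one multiplicative log-normal factor per well whose CV comes
    from ``noise_cv_curve`` (this is what sets replicate variability of
    the extracted activity) plus small per-increment jitter.
    """

    interval_s: float = 1200.0
    duration_s: float = 72000.0
    od_init: float = 0.005
    carrying_capacity: float = 1.4
    od_background: float = 0.04
    od_noise_sd: float = 0.002
    fluor_background: float = 50.0
    autofluorescence_per_od: float = 20.0
    fluor_read_noise_sd: float = 2.0
    fluor_increment_cv: float = 0.01
    noise_cv_curve: tuple[tuple[float, float], ...] = DEFAULT_CV_CURVE
    n_replicates: int = 3
    n_controls: int = 36
    n_blanks: int = 6
    abnormal_fraction: float = 0.0
    seed: int = 1

    def noiseless(self) -> "PlateConfig":
        """Copy with every noise source switched off (for oracle tests)."""
        return dataclasses.replace(
            self, od_noise_sd=0.0, fluor_read_noise_sd=0.0, fluor_increment_cv=0.0,
            noise_cv_curve=((1e-12, 0.0), (1e12, 0.0)), abnormal_fraction=0.0)

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.interval_s, self.interval_s)


def cv_of_activity(curve: tuple[tuple[float, float], ...], activity) -> np.ndarray:
    """Log-linear interpolation of the CV curve, clamped at the edges."""
    pts = np.asarray(curve, dtype=float)
    a = np.maximum(np.asarray(activity, dtype=float), 1e-300)
    return np.interp(np.log10(a), np.log10(pts[:, 0]), pts[:, 1])


@dataclasses.dataclass
class PlateSet:
    """Simulated wells plus the identities of planted abnormal wells."""

    wells: list[WellCurve]
    abnormal_wells: set[str]


def _logistic_od(t: np.ndarray, mu: float, od0: float, k: float) -> np.ndarray:
    e = np.exp(mu * t)
    return k * od0 * e / (k + od0 * (e - 1.0))


def simulate_plates(truth: GroundTruth, plate_cfg: PlateConfig = PlateConfig()) -> PlateSet:
    """Simulate reporter wells, promoter-less control wells and media blanks.

    Per condition, every promoter is measured in ``n_replicates`` wells,
    plus ``n_controls`` wells of the promoter-less (RFP-only) strain and
    ``n_blanks`` media-only wells.  A fraction ``abnormal_fraction`` of
    the promoter wells is planted with flat (non-growing) OD for QC
    testing.  Deterministic given ``plate_cfg.seed``.
    """
    cfg = plate_cfg
    t = cfg.time_grid()
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time grid")
    rng = np.random.default_rng(cfg.seed)
    tcfg = truth.config
    # constitutive reporter: identical baseline in every strain, scaling globally
    rfp_rate = 2.0

    wells: list[WellCurve] = []
    abnormal: set[str] = set()
    activity = truth.true_activity.to_numpy()

    for ci, cond in enumerate(tcfg.conditions):
        mu = np.log(2.0) / cond.tau_s
        od_true = _logistic_od(t, mu, cfg.od_init, cfg.carrying_capacity)
        od_flat = np.full_like(t, cfg.od_init)
        # per-interval integral of true OD (trapezoid), reused by all wells
        inc = 0.5 * (od_true[1:] + od_true[:-1]) * np.diff(t)
        inc_flat = 0.5 * (od_flat[1:] + od_flat[:-1]) * np.diff(t)
        s_rfp = rfp_rate * truth.true_global_factors.iloc[ci]

        def make_well(well_id, promoter, rep, p_level, grows=True):
            od_base = od_true if grows else od_flat
            inc_base = inc if grows else inc_flat
            od = od_base + cfg.od_background
            if cfg.od_noise_sd > 0:
                od = od + rng.normal(0.0, cfg.od_noise_sd, size=t.size)
            chans = {}
            for name, rate in (("yfp", p_level), ("rfp", s_rfp)):
                if rate > 0:
                    cv = float(cv_of_activity(cfg.noise_cv_curve, rate))
                    sig = np.sqrt(np.log1p(cv * cv))
                    well_factor = np.exp(rng.normal(-0.5 * sig * sig, sig)) if sig > 0 else 1.0
                    d = rate * well_factor * inc_base
                    if cfg.fluor_increment_cv > 0:
                        s2 = np.sqrt(np.log1p(cfg.fluor_increment_cv ** 2))
                        d = d * np.exp(rng.normal(-0.5 * s2 * s2, s2, size=d.size))
                    f = np.concatenate([[0.0], np.cumsum(d)])
                else:
                    f = np.zeros_like(t)
                f = f + cfg.fluor_background + cfg.autofluorescence_per_od * od_base
                if cfg.fluor_read_noise_sd > 0:
                    f = f + rng.normal(0.0, cfg.fluor_read_noise_sd, size=t.size)
                chans[name] = f
            return WellCurve(well_id=well_id, promoter=promoter, condition=cond.name,
                             replicate=rep, time=t.copy(), od=od, channels=chans)

        n_wells = tcfg.n_promoters * cfg.n_replicates
        n_abn = int(round(cfg.abnormal_fraction * n_wells))
        abn_idx = set(rng.choice(n_wells, size=n_abn, replace=False).tolist()) if n_abn else set()

        widx = 0
        for gi, promoter in enumerate(truth.promoters):
            for rep in range(cfg.n_replicates):
                wid = f"{cond.name}:{promoter}:{rep}"
                grows = widx not in abn_idx
                wells.append(make_well(wid, promoter, rep, activity[gi, ci], grows=grows))
                if not grows:
                    abnormal.add(wid)
                widx += 1
        for rep in range(cfg.n_controls):
            wells.append(make_well(f"{cond.name}:__control__:{rep}", "__control__", rep, 0.0))
        for rep in range(cfg.n_blanks):
            od = np.full_like(t, cfg.od_background)
            f = np.full_like(t, cfg.fluor_background)
            if cfg.od_noise_sd > 0:
                od = od + rng.normal(0.0, cfg.od_noise_sd, size=t.size)
            chans = {}
            for name in ("yfp", "rfp"):
                fn = f.copy()
                if cfg.fluor_read_noise_sd > 0:
                    fn = fn + rng.normal(0.0, cfg.fluor_read_noise_sd, size=t.size)
                chans[name] = fn
            wells.append(WellCurve(well_id=f"{cond.name}:__blank__:{rep}", promoter="__blank__",
                                   condition=cond.name, replicate=rep, time=t.copy(),
                                   od=od, channels=chans))

    return PlateSet(wells=wells, abnormal_wells=abnormal)


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def truth_tables(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format ground-truth table and a per-condition factor table."""
    rows = truth.true_activity.stack().rename("true_activity").reset_index()
    rows.columns = ["promoter", "condition", "true_activity"]
    rows["cluster"] = truth.cluster_of.loc[rows["promoter"]].to_numpy()
    flags = truth.is_specific.stack().reindex(
        rows.set_index(["promoter", "condition"]).index)
    rows["specific_flag"] = flags.to_numpy()
    factors = truth.true_global_factors.rename("true_global_factor").reset_index()
    factors.columns = ["condition", "true_global_factor"]
    factors["doubling_time_min"] = [c.doubling_time_min for c in truth.config.conditions]
    return rows, factors
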