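"""Parameter-free models of the global scaling factors.

Two cellular invariants, each with no free parameters, predict the global
scaling factor S[A, B] between conditions A and B:

* growth-rate model — unregulated promoters preserve their activity per
  doubling time, so concentration is preserved and

      S[A, B] = tau[A] / tau[B]

  with tau the culture doubling times.

* passive resource-allocation model — the *total* promoter activity per
  doubling time is a fixed resource, differentially partitioned between
  the condition-specific promoters G_spe and the globally responding
  promoters G_glo.  With f_glo[X] the fraction of the summed activity in
  condition X carried by G_glo,

      S[A, B] = (tau[A] / tau[B]) * (f_glo[B] / f_glo[A]).

  This follows algebraically from the conservation law plus
  proportionality of the G_glo promoters; it reduces to the growth-rate
  model when the specific response vanishes (f_glo = 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .scaling import GLOBAL, SPECIFIC


@dataclasses.dataclass(frozen=True)
class ConditionMeta:
    """Doubling times and the reference condition."""

    tau_s: pd.Series                     # per condition, seconds
    reference: str

    def __post_init__(self):
        if (self.tau_s <= 0).any():
            raise ValueError("all doubling times must be positive")
        if self.reference not in self.tau_s.index:
            raise ValueError(f"reference {self.reference!r} has no doubling time")

    @property
    def conditions(self) -> list[str]:
        return list(self.tau_s.index)


def growth_rate_model(meta: ConditionMeta) -> pd.Series:
    """Predicted S[ref, c] = tau[ref] / tau[c] for every condition."""
    tau = meta.tau_s.astype(float)
    return (tau[meta.reference] / tau).rename("predicted_factor")


def resource_allocation_model(values: pd.DataFrame,
                              labels_by_condition: dict[str, pd.Series],
                              meta: ConditionMeta) -> pd.Series:
    """Predicted S[ref, c] under fixed total activity per doubling time.

    ``labels_by_condition[c]`` carries the per-promoter global/specific
    labels of the (reference, c) pairwise comparison (promoters labeled
    excluded are dropped from both sums).  For each condition,
    f_glo[X] = sum_{g in G_glo} P[g, X] / sum_{g in G_glo u G_spe} P[g, X]
    and S[ref, c] = (tau[ref] / tau[c]) * (f_glo[c] / f_glo[ref]).
    """
    ref = meta.reference
    tau = meta.tau_s.astype(float)
    out = {}
    for c in values.columns:
        if c == ref:
            out[c] = 1.0
            continue
        labels = labels_by_condition[c]
        glo = labels.index[labels == GLOBAL]
        spe = labels.index[labels == SPECIFIC]
        if len(glo) == 0:
            raise ValueError(f"no globally responding promoters for condition {c!r}")
        analyzed = glo.union(spe)
        f_ref = values.loc[glo, ref].sum() / values.loc[analyzed, ref].sum()
        f_c = values.loc[glo, c].sum() / values.loc[analyzed, c].sum()
        out[c] = float(tau[ref] / tau[c] * (f_c / f_ref))
    return pd.Series(out, name="predicted_factor").reindex(values.columns)


def predicted_factor(predictions: pd.Series, cond_a: str, cond_b: str) -> float:
    """Model prediction for an arbitrary ordered pair, S[A, B] = S[ref,B] / S[ref,A].

    Defining pairwise predictions through the per-condition vector makes
    reciprocity (S[A,B] S[B,A] = 1) and transitivity
    (S[A,C] = S[A,B] S[B,C]) exact by construction for both models.
    """
    return float(predictions[cond_b] / predictions[cond_a])


@dataclasses.dataclass
class ModelScore:
    """Per-condition relative deviations of predicted vs measured factors.

    The reference condition (deviation identically zero) is excluded from
    the summary statistics; ``within 15%`` is boundary-inclusive.
    """

    table: pd.DataFrame                  # condition, predicted, measured, relative_deviation
    mean_deviation: float
    sd_deviation: float
    n_within_15pct: int
    n_conditions: int


def model_deviation(predicted: pd.Series, measured: pd.Series,
                    reference: str | None = None) -> ModelScore:
    """Relative deviations |predicted - measured| / measured per condition."""
    conds = predicted.index.intersection(measured.index)
    if len(conds) == 0:
        raise ValueError("no shared conditions")
    pred = predicted.loc[conds].astype(float)
    meas = measured.loc[conds].astype(float)
    dev = (pred - meas).abs() / meas
    table = pd.DataFrame({"predicted": pred, "measured": meas, "relative_deviation": dev})
    scored = dev.drop(index=reference) if reference in dev.index else dev
    return ModelScore(
        table=table,
        mean_deviation=float(scored.mean()),
        sd_deviation=float(scored.std(ddof=1)) if len(scored) > 1 else 0.0,
        n_within_15pct=int((scored <= 0.15).sum()),
        n_conditions=int(len(scored)),
    )


def total_activity_cv(values: pd.DataFrame, meta: ConditionMeta) -> float:
    """CV across conditions of the conserved quantity tau_c * sum_g P[g, c]."""
    tau = meta.tau_s.reindex(values.columns).astype(float)
    totals = values.sum(axis=0).to_numpy() * tau.to_numpy()
    return float(np.std(totals) / np.mean(totals))
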