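"""End-to-end orchestration: simulate -> extract -> decompose -> cluster -> predict.

Used by the ``promscale demo`` command and the reproduction script; every
stage writes its table into the artifact directory together with a config
snapshot so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .activity import build_activity_matrix, extract_activities
from .clustering import cluster_scaling_factors, fit_clusters, variance_explained_clustering
from .error_model import fit_error_model
from .global_models import (ConditionMeta, growth_rate_model, model_deviation,
                            resource_allocation_model, total_activity_cv)
from .plate_io import QCRules, qc_filter
from .prediction import crossvalidate
from .scaling import pairwise_scaling

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles of everything the pipeline computed."""

    truth: synthetic.GroundTruth
    matrix: "pd.DataFrame | None"
    activity: object
    error_model: object
    scaling: object
    cluster_model: object
    cluster_variance_explained: float
    cv_summary: pd.DataFrame
    growth_score: object
    resource_score: object
    total_cv: float
    tau_s: pd.Series


def run_pipeline(seed: int = 0, out_dir: str | Path | None = None,
                 truth_cfg: synthetic.TruthConfig | None = None,
                 plate_cfg: synthetic.PlateConfig | None = None,
                 n_perm: int = 1000, n_reps: int = 10, restarts: int = 100,
                 cv_restarts: int | None = None) -> PipelineResult:
    """Run every stage on synthetic data; optionally write an artifact directory."""
    truth_cfg = truth_cfg or synthetic.TruthConfig(seed=seed)
    plate_cfg = plate_cfg or synthetic.PlateConfig(seed=seed + 1)
    reference = truth_cfg.reference

    logger.info("simulating truth (%d promoters, %d conditions)",
                truth_cfg.n_promoters, len(truth_cfg.conditions))
    truth = synthetic.simulate_truth(truth_cfg)
    plates = synthetic.simulate_plates(truth, plate_cfg)

    qc_summary = qc_filter(plates.wells, QCRules())
    logger.info("QC flagged wells: %s", qc_summary)

    records, detection, tau_s, _ = extract_activities(plates.wells, mode="yeast")
    err = fit_error_model(records)
    matrix = build_activity_matrix(records, detection, mode="yeast", error_model=err)

    scaling = pairwise_scaling(matrix, err, reference=reference, n_perm=n_perm, seed=seed)

    vals = matrix.values
    usable = (~matrix.below_detection.all(axis=1)) & (vals > 0).all(axis=1)
    x = vals.loc[usable].to_numpy(float)
    model = fit_clusters(x, restarts=restarts, seed=seed, promoters=list(vals.index[usable]))
    cluster_ve = variance_explained_clustering(x, model)
    factors_table = cluster_scaling_factors(vals.loc[usable], model, scaling.factors, reference,
                                            below_detection=matrix.below_detection.loc[usable],
                                            error_model=err)

    cv_summary, _ = crossvalidate(vals.loc[usable], n_reps=n_reps, scheme="nearest",
                                  restarts=cv_restarts or restarts, seed=seed,
                                  error_model=err, detection=matrix.detection_level)

    meta = ConditionMeta(tau_s=tau_s.reindex(vals.columns), reference=reference)
    labels = {c: scaling.get(*(sorted([reference, c], key=list(vals.columns).index))).labels
              for c in vals.columns if c != reference}
    growth = model_deviation(growth_rate_model(meta), scaling.factors, reference)
    resource = model_deviation(resource_allocation_model(vals, labels, meta),
                               scaling.factors, reference)
    total_cv = total_activity_cv(vals, meta)

    result = PipelineResult(
        truth=truth, matrix=vals, activity=matrix, error_model=err, scaling=scaling,
        cluster_model=model, cluster_variance_explained=cluster_ve, cv_summary=cv_summary,
        growth_score=growth, resource_score=resource, total_cv=total_cv, tau_s=tau_s,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth_rows, truth_factors = synthetic.truth_tables(truth)
        truth_rows.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        truth_factors.to_csv(out / "true_factors.tsv", sep="\t", index=False)
        matrix.to_table().to_csv(out / "activity_matrix.tsv", sep="\t", index=False)
        err.to_table().to_csv(out / "error_model.tsv", sep="\t", index=False)
        scaling.to_table().to_csv(out / "scale_fits.tsv", sep="\t", index=False)
        model.assignment_series().to_csv(out / "clusters.tsv", sep="\t")
        pd.DataFrame(model.centers, columns=vals.columns).to_csv(out / "centers.tsv", sep="\t")
        factors_table.relative.to_csv(out / "cluster_scaling_relative.tsv", sep="\t")
        cv_summary.to_csv(out / "prediction_crossvalidation.tsv", sep="\t")
        growth.table.to_csv(out / "model_growth_rate.tsv", sep="\t")
        resource.table.to_csv(out / "model_resource_allocation.tsv", sep="\t")
        snapshot = {
            "seed": seed,
            "truth_config": dataclasses.asdict(truth_cfg),
            "plate_config": dataclasses.asdict(plate_cfg),
            "n_perm": n_perm, "n_reps": n_reps, "restarts": restarts,
            "selected_k": model.k,
            "cluster_variance_explained": cluster_ve,
            "total_activity_cv": total_cv,
        }
        (out / "run_config.json").write_text(json.dumps(snapshot, indent=2, default=str))
        logger.info("artifact directory written to %s", out)

    return result
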