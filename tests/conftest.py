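"""Shared fixtures: a paper-like synthetic study computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from promscale import synthetic
from promscale.activity import build_activity_matrix, extract_activities
from promscale.error_model import fit_error_model
from promscale.plate_io import QCRules, qc_filter
from promscale.scaling import pairwise_scaling


@dataclasses.dataclass
class Study:
    """Everything downstream stages need from one simulated study."""

    truth: synthetic.GroundTruth
    plates: synthetic.PlateSet
    records: object
    detection: object
    tau_s: object
    error_model: object
    matrix: object
    scaling: object


def run_study(n_promoters: int = 500, seed: int = 0, n_perm: int = 1000,
              plate_overrides: dict | None = None) -> Study:
    cfg = synthetic.TruthConfig(n_promoters=n_promoters, seed=seed)
    truth = synthetic.simulate_truth(cfg)
    pcfg = synthetic.PlateConfig(seed=seed + 1, **(plate_overrides or {}))
    plates = synthetic.simulate_plates(truth, pcfg)
    qc_filter(plates.wells, QCRules())
    records, detection, tau_s, _ = extract_activities(plates.wells, mode="yeast")
    err = fit_error_model(records)
    matrix = build_activity_matrix(records, detection, mode="yeast", error_model=err)
    ps = pairwise_scaling(matrix, err, reference=cfg.reference, n_perm=n_perm, seed=seed)
    return Study(truth=truth, plates=plates, records=records, detection=detection,
                 tau_s=tau_s, error_model=err, matrix=matrix, scaling=ps)


@pytest.fixture(scope="session")
def paperlike() -> Study:
    """500 promoters x 6 conditions at the study's default noise and structure."""
    return run_study(n_promoters=500, seed=0)


@pytest.fixture(scope="session")
def small_study() -> Study:
    """A fast 80-promoter study for unit-level checks."""
    return run_study(n_promoters=80, seed=3, n_perm=200)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130)
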