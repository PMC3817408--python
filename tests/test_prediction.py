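"""Few-promoter prediction: representative selection and extended centers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promscale.clustering import ClusterModel, kmeans_cosine
from promscale.prediction import (choose_representatives_greedy,
                                  choose_representatives_nearest,
                                  crossvalidate, predict_condition)


def rank_structured(rng, dirs, sizes):
    """Noise-free profiles: each cluster exactly rank-1."""
    rows, labels = [], []
    for t, (d, n) in enumerate(zip(dirs, sizes)):
        for _ in range(n):
            rows.append(np.asarray(d, float) * np.exp(rng.normal(0, 1)))
            labels.append(t)
    return np.asarray(rows), np.asarray(labels)


class TestNearestSelection:
    def test_equal_split_two_clusters(self, rng):
        x, _ = rank_structured(rng, [(1, 0.1, 0.1), (0.1, 1, 0.1)], [8, 8])
        model = kmeans_cosine(x, 2, restarts=20, seed=0)
        reps = choose_representatives_nearest(x, model, n=4)
        assert len(reps) == 4
        assert np.bincount(model.assignment[reps], minlength=2).tolist() == [2, 2]

    def test_ten_from_six_clusters_allocates_extras_to_largest(self, rng):
        dirs = np.eye(6) * 0.9 + 0.1
        sizes = [30, 20, 10, 8, 6, 6]
        x, _ = rank_structured(rng, dirs, sizes)
        model = kmeans_cosine(x, 6, restarts=40, seed=1)
        reps = choose_representatives_nearest(x, model, n=10)
        counts = np.bincount(model.assignment[reps], minlength=6)
        # clusters sorted by size descending: (2,2,2,2,1,1)
        assert sorted(counts.tolist(), reverse=True) == [2, 2, 2, 2, 1, 1]
        assert counts[0] == 2 and counts[5] == 1

    def test_matches_brute_force_minimal_distance_selection(self, rng):
        x, _ = rank_structured(rng, [(1, 0.2), (0.2, 1)], [7, 5])
        model = kmeans_cosine(x, 2, restarts=20, seed=2)
        reps = set(choose_representatives_nearest(x, model, n=4).tolist())
        xu = x / np.linalg.norm(x, axis=1, keepdims=True)
        expected = set()
        for t in range(2):
            members = np.flatnonzero(model.assignment == t)
            d = 1.0 - xu[members] @ model.centers[t]
            expected.update(members[np.argsort(d, kind="stable")[:2]].tolist())
        assert reps == expected

    def test_fewer_slots_than_clusters_rejected(self, rng):
        x, _ = rank_structured(rng, [(1, 0.1), (0.1, 1)], [5, 5])
        model = kmeans_cosine(x, 2, restarts=10, seed=0)
        with pytest.raises(ValueError):
            choose_representatives_nearest(x, model, n=1)


class TestGreedySelection:
    def test_rank_one_matrix_solved_by_first_pick(self, rng):
        base = np.array([1.0, 0.5, 0.25, 2.0])
        x = np.outer(np.exp(rng.normal(0, 1, 12)), base)
        reps = choose_representatives_greedy(x, 3)
        q, _ = np.linalg.qr(x[reps[:1]].T)
        resid = np.sum((x - (x @ q) @ q.T) ** 2)
        assert resid == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_archetypes_match_best_subset_oracle(self, rng):
        # 20 promoters built from 3 orthogonal archetypes: greedy residual
        # must equal the best subset's at each of the first 3 steps
        arch = np.eye(3)
        weights = rng.integers(0, 2, size=(20, 3)) + 0.5 * rng.random((20, 3))
        x = weights @ arch * np.exp(rng.normal(0, 0.5, (20, 1)))
        reps = choose_representatives_greedy(x, 3)

        def subset_resid(idx):
            q, _ = np.linalg.qr(x[list(idx)].T)
            return float(np.sum((x - (x @ q) @ q.T) ** 2))

        chosen = []
        for step in range(3):
            best = min(subset_resid(chosen + [c]) for c in range(20) if c not in chosen)
            chosen.append(reps[step])
            assert subset_resid(chosen) == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_n_zero_returns_empty(self):
        assert choose_representatives_greedy(np.ones((5, 3)), 0).size == 0


class TestPredictCondition:
    def test_exact_on_noise_free_rank_structured_data(self, rng):
        dirs = [(1, 0.3, 0.2), (0.2, 1, 0.4), (0.3, 0.2, 1)]
        x, labels = rank_structured(rng, dirs, [12, 10, 8])
        model = kmeans_cosine(x, 3, restarts=30, seed=3)
        # held-out condition: each cluster scales by its own planted factor
        factor = np.array([0.5, 2.0, 1.3])
        y = np.array([np.linalg.norm(x[i]) * factor[labels[i]] for i in range(len(labels))])
        # proportional within cluster: y = ||x|| * factor works because each
        # cluster is exactly rank-1 (projection coefficient == norm)
        reps = choose_representatives_nearest(x, model, n=6)
        pred = predict_condition(model, x, reps, y[reps])
        np.testing.assert_allclose(pred, y, rtol=1e-9)

    def test_single_cluster_reduces_to_common_ratio(self, rng):
        base = np.array([2.0, 1.0, 0.5])
        scale = np.exp(rng.normal(0, 1, 15))
        x = np.outer(scale, base)
        model = kmeans_cosine(x, 1, restarts=5, seed=0)
        y = 3.0 * np.linalg.norm(x, axis=1)
        pred = predict_condition(model, x, np.array([0, 1]), y[[0, 1]])
        np.testing.assert_allclose(pred, y, rtol=1e-9)

    def test_cluster_without_representative_uses_global_extension(self, rng):
        x, labels = rank_structured(rng, [(1, 0.1), (0.1, 1)], [10, 4])
        model = kmeans_cosine(x, 2, restarts=20, seed=1)
        y = np.linalg.norm(x, axis=1)
        reps = np.flatnonzero(model.assignment == 0)[:3]
        pred = predict_condition(model, x, reps, y[reps])
        assert np.all(np.isfinite(pred))

    def test_equivariant_to_rescaling_non_representative_profile(self, rng):
        x, _ = rank_structured(rng, [(1, 0.3), (0.3, 1)], [8, 8])
        model = kmeans_cosine(x, 2, restarts=20, seed=2)
        y = 1.7 * np.linalg.norm(x, axis=1)
        reps = choose_representatives_nearest(x, model, n=4)
        target = [i for i in range(16) if i not in reps][0]
        pred1 = predict_condition(model, x, reps, y[reps])
        x2 = x.copy()
        x2[target] *= 5.0
        model2 = kmeans_cosine(x2, 2, restarts=20, seed=2)
        np.testing.assert_array_equal(model.assignment, model2.assignment)
        pred2 = predict_condition(model2, x2, reps, y[reps])
        assert pred2[target] == pytest.approx(5.0 * pred1[target], rel=1e-9)
        others = [i for i in range(16) if i != target]
        np.testing.assert_allclose(pred2[others], pred1[others], rtol=1e-9)


class TestCrossvalidate:
    def test_duplicated_condition_is_predicted_perfectly(self, rng):
        base, labels = rank_structured(rng, [(1, 0.3, 0.2), (0.2, 1, 0.3)], [15, 10])
        vals = pd.DataFrame(base, columns=["a", "b", "c"])
        vals["c2"] = vals["c"]
        summary, _ = crossvalidate(vals, n_reps=4, restarts=20, seed=0, k_max=4)
        assert summary.loc["c2", "r2"] >= 0.999

    def test_more_representatives_do_not_hurt_on_average(self, paperlike):
        # Monte-Carlo trend over seeds, not per-draw
        vals = paperlike.matrix.values
        sub = vals.iloc[:200]
        mses = {n: [] for n in (6, 12)}
        for seed in range(3):
            for n in (6, 12):
                summary, details = crossvalidate(sub, n_reps=n, restarts=20,
                                                 seed=seed, k_max=8)
                err = (details["predicted"] - details["measured"]) ** 2
                mses[n].append(float(err.mean()))
        assert np.mean(mses[12]) <= np.mean(mses[6]) * 1.05

    def test_greedy_scheme_with_five_reps_close_to_nearest(self):
        # bacteria-like panel: nine growth conditions, fewer and milder
        # specific programs; a handful (five) of greedily chosen
        # representatives with the best-linear-sum predictor should score
        # within 0.05 of the nearest-to-center scheme at its full allocation
        from promscale import synthetic as syn
        from promscale.activity import build_activity_matrix, extract_activities
        from promscale.error_model import fit_error_model
        from promscale.plate_io import qc_filter

        conds = tuple(syn.Condition(n, t) for n, t in [
            ("glucose", 60), ("galactose", 95), ("glycerol", 120), ("acetate", 160),
            ("osmotic", 110), ("heat", 80), ("fructose", 65), ("lowN", 140),
            ("succinate", 130)])
        cfg = syn.TruthConfig(
            n_promoters=200, conditions=conds, n_clusters=4,
            cluster_fractions=(0.76, 0.08, 0.08, 0.08),
            relative_specific_factors=((1, 3, 8, 12, 1, 1, 1, 1.5, 6),
                                       (1, 1, 1, 1, 10, 4, 1, 2, 1),
                                       (1, 12, 4, 1, 1, 3, 1, 1, 1)),
            seed=31)
        truth = syn.simulate_truth(cfg)
        plates = syn.simulate_plates(truth, syn.PlateConfig(seed=32))
        qc_filter(plates.wells)
        rec, det, _, _ = extract_activities(plates.wells)
        err = fit_error_model(rec)
        m = build_activity_matrix(rec, det, error_model=err)
        vals = m.values[(m.values > 0).all(axis=1)]
        near, _ = crossvalidate(vals, n_reps=10, scheme="nearest", restarts=30, seed=1, k_max=8)
        greedy, _ = crossvalidate(vals, n_reps=5, scheme="greedy", restarts=30, seed=1, k_max=8)
        assert float((near["r2"] - greedy["r2"]).max()) <= 0.05
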