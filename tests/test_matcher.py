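"""Matching objective, Frank-Wolfe relaxation, rounding and the matcher."""

import itertools

import numpy as np
import pytest

from mmalign.features import FeatureMatrix, LandmarkSet
from mmalign.linmap import compute_Z
from mmalign.matcher import (
    Correspondence,
    MatchConfig,
    cardinality_penalty,
    distance_penalty,
    frank_wolfe,
    match_features,
    match_landmarks,
    objective_gradient,
    round_correspondence,
    total_objective,
    write_matches_tsv,
)
from mmalign.synthetic import make_matching_problem


def small_instance(rng, m=4, n=5, k=3, l=3):
    theta = FeatureMatrix(rng.standard_normal((k, m)))
    phi = FeatureMatrix(rng.standard_normal((l, n)))
    lm_i = LandmarkSet(rng.random((m, 2)), np.ones(m))
    lm_j = LandmarkSet(rng.random((n, 2)), np.ones(n))
    return theta, phi, lm_i, lm_j, compute_Z(phi, 0.6)


class TestPenalties:
    def test_cardinality_zero_matrix(self):
        assert cardinality_penalty(np.zeros((2, 2)), 1.5) == pytest.approx(9.0)

    def test_cardinality_exact_target_is_zero(self):
        e = np.full((3, 3), 0.5)  # all row and column sums equal 1.5
        assert cardinality_penalty(e, 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_cardinality_hand_computed(self):
        assert cardinality_penalty(np.ones((2, 3)), 1.5) == pytest.approx(5.25)

    def test_distance_zero_for_coincident_points(self, rng):
        pts = rng.random((4, 2))
        lm = LandmarkSet(pts, np.ones(4))
        # all landmark pairs coincident -> zero for any E
        same = LandmarkSet(pts.copy(), np.ones(4))
        assert distance_penalty(np.eye(4), lm, same) == pytest.approx(0.0)
        one_point = LandmarkSet(np.tile(pts[:1], (4, 1)), np.ones(4))
        assert distance_penalty(rng.random((4, 4)), one_point, one_point) == pytest.approx(0.0)
        assert distance_penalty(np.zeros((4, 4)), lm, lm) == pytest.approx(0.0)

    def test_distance_single_pair(self):
        lm1 = LandmarkSet(np.array([[0.0, 0.0]]), np.ones(1))
        lm2 = LandmarkSet(np.array([[0.3, 0.4]]), np.ones(1))
        assert distance_penalty(np.array([[1.0]]), lm1, lm2) == pytest.approx(0.25)

    def test_distance_linear_in_e(self, rng):
        lm1 = LandmarkSet(rng.random((3, 2)), np.ones(3))
        lm2 = LandmarkSet(rng.random((4, 2)), np.ones(4))
        e1, e2 = rng.random((3, 4)), rng.random((3, 4))
        lhs = distance_penalty(e1 + e2, lm1, lm2)
        rhs = distance_penalty(e1, lm1, lm2) + distance_penalty(e2, lm1, lm2)
        assert lhs == pytest.approx(rhs)


class TestTotalObjective:
    def test_degenerate_weights_reduce_to_data_term(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        cfg = MatchConfig(w_card=0.0, w_dist=0.0)
        e = rng.random((4, 5))
        from mmalign.linmap import data_objective

        assert total_objective(e, theta, z, lm_i, lm_j, cfg) == pytest.approx(
            data_objective(theta, e, z)
        )

    def test_zero_e_leaves_only_cardinality(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        cfg = MatchConfig()
        val = total_objective(np.zeros((4, 5)), theta, z, lm_i, lm_j, cfg)
        assert val == pytest.approx(cfg.w_card * (4 + 5) * cfg.target_degree**2)

    def test_equals_sum_of_components(self, rng):
        from mmalign.linmap import data_objective

        theta, phi, lm_i, lm_j, z = small_instance(rng)
        cfg = MatchConfig()
        e = rng.random((4, 5))
        expect = (
            data_objective(theta, e, z)
            + cfg.w_card * cardinality_penalty(e, cfg.target_degree)
            + cfg.w_dist * distance_penalty(e, lm_i, lm_j)
        )
        assert total_objective(e, theta, z, lm_i, lm_j, cfg) == pytest.approx(expect, abs=1e-10)


class TestGradient:
    def test_matches_central_differences(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        cfg = MatchConfig()
        e = rng.random((4, 5))
        grad = objective_gradient(e, theta, z, lm_i, lm_j, cfg)
        num = np.zeros_like(e)
        h = 1e-6
        for idx in np.ndindex(*e.shape):
            ep, em = e.copy(), e.copy()
            ep[idx] += h
            em[idx] -= h
            num[idx] = (
                total_objective(ep, theta, z, lm_i, lm_j, cfg)
                - total_objective(em, theta, z, lm_i, lm_j, cfg)
            ) / (2 * h)
        assert np.max(np.abs(grad - num)) < 1e-5

    def test_zero_e_without_priors_gives_zero_gradient(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        cfg = MatchConfig(w_card=0.0, w_dist=0.0)
        grad = objective_gradient(np.zeros((4, 5)), theta, z, lm_i, lm_j, cfg)
        np.testing.assert_allclose(grad, 0, atol=1e-14)

    def test_zero_theta_leaves_distance_term(self, rng):
        _, phi, lm_i, lm_j, z = small_instance(rng)
        theta = FeatureMatrix(np.zeros((3, 4)))
        cfg = MatchConfig(w_card=0.0, w_dist=0.7)
        from mmalign.matcher import squared_distance_matrix

        grad = objective_gradient(np.ones((4, 5)), theta, z, lm_i, lm_j, cfg)
        np.testing.assert_allclose(grad, 0.7 * squared_distance_matrix(lm_i, lm_j), atol=1e-12)


class TestFrankWolfe:
    def test_scalar_problem_converges_to_target(self):
        cfg = MatchConfig(w_card=1.0, w_dist=0.0, target_degree=0.5, seed=3)
        z = compute_Z(FeatureMatrix(np.ones((2, 1))), 0.6)
        rel = frank_wolfe(FeatureMatrix(np.zeros((2, 1))), z, None, None, cfg)
        np.testing.assert_allclose(rel.values, [[0.5]], atol=1e-3)

    def test_objective_monotone_nonincreasing(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        rel = frank_wolfe(theta, z, lm_i, lm_j, MatchConfig(seed=1))
        hist = np.asarray(rel.meta["objective"])
        assert np.all(np.diff(hist) <= 1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_relaxed_optimum_below_binary_minimum(self, seed):
        """Relaxation bound: box optimum <= best of all 512 binary 3x3 E."""
        rng = np.random.default_rng(seed)
        theta = FeatureMatrix(rng.standard_normal((3, 3)))
        phi = FeatureMatrix(rng.standard_normal((3, 3)))
        lm_i = LandmarkSet(rng.random((3, 2)), np.ones(3))
        lm_j = LandmarkSet(rng.random((3, 2)), np.ones(3))
        z = compute_Z(phi, 0.6)
        cfg = MatchConfig(seed=seed, max_iter=2000, tol=1e-8)
        rel = frank_wolfe(theta, z, lm_i, lm_j, cfg)
        relaxed_val = total_objective(rel, theta, z, lm_i, lm_j, cfg)
        binary_best = min(
            total_objective(np.array(bits, dtype=float).reshape(3, 3), theta, z, lm_i, lm_j, cfg)
            for bits in itertools.product([0, 1], repeat=9)
        )
        assert relaxed_val <= binary_best + 1e-6

    def test_convexity_seed_independence(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng, m=5, n=5)
        vals = []
        for seed in (0, 99):
            cfg = MatchConfig(seed=seed, max_iter=5000, tol=1e-9)
            rel = frank_wolfe(theta, z, lm_i, lm_j, cfg)
            vals.append(total_objective(rel, theta, z, lm_i, lm_j, cfg))
        assert abs(vals[0] - vals[1]) < 1e-4

    def test_duality_gap_reported(self, rng):
        theta, phi, lm_i, lm_j, z = small_instance(rng)
        rel = frank_wolfe(theta, z, lm_i, lm_j, MatchConfig(seed=0))
        assert rel.meta["gap"] >= 0


class TestRounding:
    def test_binary_permutation_unchanged(self):
        e = np.eye(3)[:, [1, 0, 2]]
        out = round_correspondence(Correspondence(e, relaxed=True))
        np.testing.assert_array_equal(out.values, e)

    def test_two_by_two_worked_example(self):
        out = round_correspondence(
            Correspondence(np.array([[0.9, 0.8], [0.85, 0.1]]), relaxed=True)
        )
        assert {(i, j) for i, j, _ in out.pairs} == {(0, 1), (1, 0)}

    def test_all_below_half_gives_no_matches(self, rng):
        out = round_correspondence(Correspondence(rng.random((4, 4)) * 0.49, relaxed=True))
        assert out.n_matches == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_one_to_one_invariant(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 8, size=2)
        out = round_correspondence(Correspondence(rng.random((m, n)), relaxed=True))
        assert out.values.sum(axis=0).max(initial=0) <= 1
        assert out.values.sum(axis=1).max(initial=0) <= 1
        # pairs consistent with the matrix and sorted by confidence
        assert len(out.pairs) == out.n_matches
        confs = [c for _, _, c in out.pairs]
        assert confs == sorted(confs, reverse=True)

    def test_pairs_have_confidences_from_input(self):
        e = np.array([[0.95, 0.0], [0.0, 0.7]])
        out = round_correspondence(Correspondence(e, relaxed=True))
        assert out.pairs == ((0, 0, 0.95), (1, 1, 0.7))


class TestMatchLandmarks:
    def test_identical_images_self_match(self, small_scene):
        res = match_landmarks(small_scene, small_scene, MatchConfig(seed=0), max_points=40)
        assert res.correspondence.n_matches >= 0.8 * res.lm_I.count
        assert all(i == j for i, j, _ in res.correspondence.pairs)

    def test_permutation_recovery_on_synthetic_features(self):
        hits = 0
        for seed in range(10):
            theta, phi, t0, pi = make_matching_problem(8, 6, 6, 0.02, seed)
            res = match_features(
                FeatureMatrix(theta), FeatureMatrix(phi), None, None,
                MatchConfig(w_dist=0.0, seed=seed),
            )
            pairs = {(i, j) for i, j, _ in res.correspondence.pairs}
            hits += pairs == {(i, int(pi[i])) for i in range(8)}
        assert hits >= 9

    def test_zero_overlap_with_large_distance_weight_gives_empty(self, rng):
        lm_a = LandmarkSet(rng.uniform(0.0, 0.15, (6, 2)), np.ones(6))
        lm_b = LandmarkSet(rng.uniform(0.85, 1.0, (6, 2)), np.ones(6))
        theta = FeatureMatrix(rng.standard_normal((10, 6)))
        phi = FeatureMatrix(rng.standard_normal((10, 6)))
        res = match_features(theta, phi, lm_a, lm_b, MatchConfig(w_dist=50.0, seed=0))
        assert res.correspondence.n_matches == 0

    def test_too_few_landmarks_raises(self):
        from mmalign.errors import TooFewLandmarksError

        flat = np.full((64, 64), 0.5)
        with pytest.raises(TooFewLandmarksError):
            match_landmarks(flat, flat)

    def test_translation_equivariance_of_matching(self, small_scene):
        """Translating both images identically leaves the match set unchanged."""
        shifted = np.roll(small_scene, (7, 7), axis=(0, 1))
        res0 = match_landmarks(small_scene, small_scene, MatchConfig(seed=0), max_points=30)
        res1 = match_landmarks(shifted, shifted, MatchConfig(seed=0), max_points=30)
        pairs0 = {(i, j) for i, j, _ in res0.correspondence.pairs}
        pairs1 = {(i, j) for i, j, _ in res1.correspondence.pairs}
        # identical landmark ordering up to border effects of the roll
        assert len(pairs0 & pairs1) >= 0.7 * max(len(pairs0), 1)

    def test_matches_tsv(self, tmp_path, small_scene):
        import pandas as pd

        res = match_landmarks(small_scene, small_scene, MatchConfig(seed=0), max_points=20)
        path = tmp_path / "matches.tsv"
        write_matches_tsv(path, res)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["i", "j", "x_i", "y_i", "x_j", "y_j", "confidence"]
        assert (df["confidence"].diff().dropna() <= 1e-12).all()


class TestValidation:
    def test_relaxed_entries_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            Correspondence(np.array([[1.5]]), relaxed=True)

    def test_binary_must_be_one_to_one(self):
        with pytest.raises(ValueError):
            Correspondence(np.ones((2, 2)), relaxed=False)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(ridge=0.0)
        with pytest.raises(ValueError):
            MatchConfig(target_degree=-1.0)
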