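import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from psfpercept import mds, synth
from psfpercept import procrustes as pr


def metric_dissimilarity(rng, n, ndim):
    X = rng.normal(size=(n, ndim))
    return X, squareform(pdist(X))


class TestToDissimilarity:
    def test_reverse_scaling_endpoints(self):
        s = np.array([[10.0, 1.0], [1.0, 10.0]])
        d = mds.to_dissimilarity(s)
        # min 1, max 10: s = 10 -> d = 1 (not 0), s = 1 -> d = 10
        assert d.d[0, 0] == 1.0
        assert d.d[0, 1] == 10.0
        assert d.scale_min == 1.0 and d.scale_max == 10.0

    def test_transform_is_involution(self, rng):
        s = rng.uniform(1, 10, size=(8, 8))
        s = (s + s.T) / 2
        once = mds.to_dissimilarity(s)
        twice = mds.to_dissimilarity(once.d)
        assert np.allclose(twice.d, s)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            mds.to_dissimilarity(np.array([[0.0, np.inf], [np.inf, 0.0]]))


class TestPAVA:
    def test_matches_sklearn_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 21))
            y = rng.normal(size=n)
            expected = IsotonicRegression().fit_transform(np.arange(n), y)
            assert np.allclose(mds.pava(y), expected, atol=1e-12)

    def test_matches_sklearn_oracle_weighted(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 21))
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 3.0, size=n)
            expected = IsotonicRegression().fit_transform(
                np.arange(n), y, sample_weight=w
            )
            assert np.allclose(mds.pava(y, w), expected, atol=1e-12)

    def test_already_monotone_unchanged(self):
        y = np.array([1.0, 2.0, 3.5, 3.5, 7.0])
        assert np.array_equal(mds.pava(y), y)

    def test_output_always_nondecreasing(self, rng):
        for _ in range(20):
            out = mds.pava(rng.normal(size=15))
            assert np.all(np.diff(out) >= -1e-12)


class TestSmacof:
    def test_perfect_metric_recovery(self, rng):
        X, d = metric_dissimilarity(rng, 5, 2)
        cfg = mds.smacof_nonmetric(d, 2)
        assert cfg.stress1 < 1e-6
        res = pr.procrustes_align(X, cfg.coords)
        assert res.residual < 1e-6

    def test_planted_3d_with_monotone_distortion(self, rng):
        X, d = metric_dissimilarity(rng, 15, 3)
        cfg = mds.best_fit(d**2, 3, n_restarts=5, seed=0)
        assert cfg.stress1 < 0.01
        assert pr.congruence_coefficient(X, cfg.coords) > 0.99

    def test_four_item_multistart_oracle(self, rng):
        d = squareform(rng.uniform(1, 10, size=6))
        cfg = mds.best_fit(d, 2, n_restarts=10, seed=0)
        # reference: best of 200 random restarts
        best = np.inf
        for seed in range(200):
            ref = mds.smacof_nonmetric(d, 2, init="random", seed=seed)
            best = min(best, ref.stress1)
        assert cfg.stress1 <= best + 1e-4

    def test_stress_history_nonincreasing(self, rng):
        _, d = metric_dissimilarity(rng, 12, 3)
        cfg = mds.smacof_nonmetric(d + rng.uniform(0, 0.5, size=d.shape).mean(), 2)
        diffs = np.diff(cfg.stress_history)
        assert np.all(diffs <= 1e-8)

    def test_disparities_monotone_in_dissimilarity_order(self, rng):
        _, d = metric_dissimilarity(rng, 10, 2)
        noisy = d + squareform(rng.uniform(0, 0.3, size=45))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        cfg = mds.smacof_nonmetric(noisy, 2)
        diss = squareform(noisy, checks=False)
        order = np.argsort(diss, kind="stable")
        assert np.all(np.diff(cfg.disparities[order]) >= -1e-9)

    def test_coords_centered(self, rng):
        _, d = metric_dissimilarity(rng, 8, 2)
        cfg = mds.smacof_nonmetric(d, 2)
        assert np.allclose(cfg.coords.mean(axis=0), 0.0, atol=1e-10)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds.smacof_nonmetric(d, 2)

    def test_too_few_items_rejected(self, rng):
        _, d = metric_dissimilarity(rng, 3, 2)
        with pytest.raises(ValueError):
            mds.smacof_nonmetric(d, 3)

    def test_stress_scale_invariance(self, rng):
        _, d = metric_dissimilarity(rng, 10, 3)
        noisy = d + squareform(rng.uniform(0, 0.4, size=45))
        noisy = (noisy + noisy.T) / 2.0
        np.fill_diagonal(noisy, 0)
        a = mds.smacof_nonmetric(noisy, 2)
        b = mds.smacof_nonmetric(noisy * 7.3, 2)
        assert a.stress1 == pytest.approx(b.stress1, abs=1e-8)


class TestDimensionScan:
    def test_stress_nonincreasing_in_dimension(self, rng):
        d = squareform(rng.uniform(1, 10, size=45))
        scan = mds.stress_dimension_scan(d, [1, 2, 3, 4], n_restarts=3, seed=0)
        assert np.all(np.diff(scan["stress1"]) <= 1e-12)

    def test_perfect_2d_metric_excellent_at_2_and_3(self, rng):
        _, d = metric_dissimilarity(rng, 8, 2)
        scan = mds.stress_dimension_scan(d, [2, 3], n_restarts=2, seed=0)
        assert np.all(scan["stress1"] < 1e-6)
        assert list(scan["fit_band"]) == ["excellent", "excellent"]

    def test_descending_list_rejected(self, rng):
        _, d = metric_dissimilarity(rng, 8, 2)
        with pytest.raises(ValueError):
            mds.stress_dimension_scan(d, [3, 2])

    def test_planted_3d_crosses_excellent_at_3(self):
        cfg = synth.SimulationConfig(seed=11)
        bundle = synth.generate_study(cfg, include_optics=False)
        mean = mds.mean_rating_matrix(bundle.similarity, "D2D")
        diss = mds.to_dissimilarity(mean.matrix)
        scan = mds.stress_dimension_scan(diss, [1, 2, 3], n_restarts=3, seed=0)
        assert scan.loc[scan["ndim"] == 3, "stress1"].iloc[0] < 0.10


class TestShepard:
    def test_stress_recomputation_matches(self, rng):
        _, d = metric_dissimilarity(rng, 10, 3)
        noisy = d + squareform(rng.uniform(0, 0.5, size=45))
        noisy = (noisy + noisy.T) / 2.0
        np.fill_diagonal(noisy, 0)
        cfg = mds.smacof_nonmetric(noisy, 2)
        shep = mds.shepard_data(noisy, cfg)
        assert shep.stress1() == pytest.approx(cfg.stress1, abs=1e-10)

    def test_perfect_fit_points_on_monotone_line(self, rng):
        _, d = metric_dissimilarity(rng, 6, 2)
        cfg = mds.smacof_nonmetric(d, 2)
        shep = mds.shepard_data(d, cfg)
        assert np.allclose(shep.disparity, shep.distance, atol=1e-5)

    def test_disparity_step_function_monotone(self, rng):
        d = squareform(rng.uniform(1, 10, size=45))
        cfg = mds.smacof_nonmetric(d, 3)
        shep = mds.shepard_data(d, cfg)
        assert np.all(np.diff(shep.disparity) >= -1e-9)

    def test_size_mismatch_rejected(self, rng):
        _, d = metric_dissimilarity(rng, 8, 2)
        cfg = mds.smacof_nonmetric(d, 2)
        with pytest.raises(ValueError):
            mds.shepard_data(d[:6, :6], cfg)


class TestPermutationTest:
    def test_planted_structure_minimum_p(self, rng):
        X, d = metric_dissimilarity(rng, 12, 2)
        result = mds.permutation_test(d, 2, n_perm=99, seed=0, n_restarts=0)
        assert result["p_value"] == pytest.approx(1 / 100)

    def test_p_within_bounds_and_null_size(self, rng):
        d = squareform(rng.uniform(1, 10, size=15))
        result = mds.permutation_test(d, 2, n_perm=19, seed=1, n_restarts=0)
        assert 1 / 20 <= result["p_value"] <= 1.0
        assert len(result["null_stress"]) == 19

    def test_small_n_perm_rejected(self, rng):
        _, d = metric_dissimilarity(rng, 6, 2)
        with pytest.raises(ValueError):
            mds.permutation_test(d, 2, n_perm=10)

    def test_null_calibration_p_roughly_uniform(self):
        # when the observed matrix is itself a permutation draw, p should be
        # roughly uniform over replicates
        master = np.random.default_rng(42)
        ps = []
        for _ in range(60):
            d = squareform(master.uniform(1, 10, size=21))  # 7 items
            result = mds.permutation_test(
                d, 2, n_perm=19, seed=int(master.integers(2**31)), n_restarts=0
            )
            ps.append(result["p_value"])
        assert 0.25 < np.mean(ps) < 0.75


class TestMeanRatingMatrix:
    def test_constant_ten_everywhere(self):
        rows = []
        for rater in ("a", "b"):
            for i in range(3):
                for j in range(i, 3):
                    rows.append(
                        {"rater_id": rater, "image_a": i, "image_b": j,
                         "block": "D2D", "rating": 10}
                    )
        study = mds.SimilarityStudy(pd.DataFrame(rows))
        result = mds.mean_rating_matrix(study, "D2D")
        assert np.all(result.matrix.to_numpy() == 10.0)
        assert result.diagonal_summary["sd"] == 0.0

    def test_two_raters_average(self):
        rows = []
        for rater, rating in (("a", 4), ("b", 6)):
            for i in range(3):
                for j in range(i, 3):
                    rows.append(
                        {"rater_id": rater, "image_a": i, "image_b": j,
                         "block": "G2G", "rating": rating}
                    )
        study = mds.SimilarityStudy(pd.DataFrame(rows))
        result = mds.mean_rating_matrix(study, "G2G")
        assert np.all(result.matrix.to_numpy() == 5.0)

    def test_missing_pair_named(self):
        rows = [
            {"rater_id": r, "image_a": 0, "image_b": 0, "block": "D2D", "rating": 9}
            for r in ("a", "b")
        ]
        rows += [
            {"rater_id": r, "image_a": 1, "image_b": 1, "block": "D2D", "rating": 9}
            for r in ("a", "b")
        ]
        study = mds.SimilarityStudy(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="no ratings"):
            mds.mean_rating_matrix(study, "D2D")

    def test_single_rater_rejected(self):
        rows = [
            {"rater_id": "a", "image_a": i, "image_b": j, "block": "D2D", "rating": 5}
            for i in range(3)
            for j in range(i, 3)
        ]
        with pytest.raises(ValueError, match="2 raters"):
            mds.mean_rating_matrix(mds.SimilarityStudy(pd.DataFrame(rows)), "D2D")

    def test_synthetic_diagonal_above_off_diagonal(self):
        bundle = synth.generate_study(
            synth.SimulationConfig(seed=2), include_optics=False
        )
        result = mds.mean_rating_matrix(bundle.similarity, "D2D")
        assert (
            result.diagonal_summary["mean"] > result.off_diagonal_summary["mean"]
        )


class TestBootstrapRegions:
    def _study(self, noise, seed=0, n_raters=6, n_images=8):
        cfg = synth.SimulationConfig(
            seed=seed, n_images=n_images, n_raters=n_raters,
            similarity_noise_sd=noise,
        )
        return synth.generate_study(cfg, include_optics=False)

    def test_zero_noise_tiny_regions(self):
        bundle = self._study(0.0)
        result = mds.bootstrap_regions(
            bundle.similarity, "D2D", 2, n_boot=20, seed=0
        )
        for region in result["regions"].values():
            assert np.all(region["semi_axes"] < 1e-6)

    def test_more_noise_bigger_regions(self):
        small = mds.bootstrap_regions(
            self._study(0.5).similarity, "D2D", 2, n_boot=25, seed=0
        )
        big = mds.bootstrap_regions(
            self._study(1.5).similarity, "D2D", 2, n_boot=25, seed=0
        )
        def mean_size(res):
            return np.mean(
                [r["semi_axes"].sum() for r in res["regions"].values()]
            )
        assert mean_size(big) > mean_size(small)

    def test_alignment_centers_near_reference(self):
        bundle = self._study(0.4)
        result = mds.bootstrap_regions(
            bundle.similarity, "D2D", 2, n_boot=25, seed=0
        )
        ref = result["reference"].coords
        scale = np.abs(ref).max()
        for i, item in enumerate(sorted(result["regions"])):
            center = result["regions"][item]["center"]
            assert np.linalg.norm(center - ref[i]) < 0.5 * scale

    def test_too_few_raters_rejected(self):
        bundle = self._study(0.5, n_raters=4)
        with pytest.raises(ValueError, match="5 raters"):
            mds.bootstrap_regions(bundle.similarity, "D2D", 2, n_boot=5, seed=0)


class TestRandomStartStudy:
    def test_perfect_metric_starts_reach_zero_stress(self, rng):
        # random starts can land in local minima even on perfect-metric
        # input (that is why multistart exists); the best start and the
        # median start must still reach the zero-stress solution
        _, d = metric_dissimilarity(rng, 7, 2)
        result = mds.random_start_study(d, 2, n_starts=10, seed=0, tol=1e-12,
                                        max_iter=2000)
        assert result["best"] < 1e-8
        assert result["median"] < 1e-6

    def test_best_never_worse_than_classical(self, rng):
        d = squareform(rng.uniform(1, 10, size=45))
        result = mds.random_start_study(d, 2, n_starts=10, seed=0)
        assert result["best"] <= result["classical_stress"] + 1e-8
        assert result["best"] <= result["median"] <= result["worst"]

    def test_fixed_seed_reproducible(self, rng):
        d = squareform(rng.uniform(1, 10, size=28))
        a = mds.random_start_study(d, 2, n_starts=8, seed=123)
        b = mds.random_start_study(d, 2, n_starts=8, seed=123)
        assert np.array_equal(a["stresses"], b["stresses"])
        assert np.array_equal(
            a["best_config"].coords, b["best_config"].coords
        )
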