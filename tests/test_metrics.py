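import math

import numpy as np
import pytest

from spotae.metrics import (
    ari,
    evaluate,
    frobenius_distance,
    gearys_c,
    jsd_per_spot,
    morans_i,
    pcc_per_celltype,
    purity,
    rasterize,
    rmse,
    ssim_per_celltype,
)
from spotae.spatial_graph import build_spatial_graph


def simplex_rows(rng, n, k):
    return rng.dirichlet(np.ones(k), size=n)


class TestPCC:
    def test_identical_nonconstant_columns_score_one(self):
        rng = np.random.default_rng(0)
        P = simplex_rows(rng, 10, 3)
        pcc, mean, sd = pcc_per_celltype(P, P)
        np.testing.assert_allclose(pcc, 1.0, atol=1e-12)
        assert mean == pytest.approx(1.0)

    def test_negated_column_scores_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        flipped = 2 * x.mean() - x
        pcc, *_ = pcc_per_celltype(flipped[:, None], x[:, None])
        assert pcc[0] == pytest.approx(-1.0)

    def test_textbook_covariance_formula_oracle(self):
        rng = np.random.default_rng(2)
        A, B = rng.uniform(size=(2, 20, 3))
        pcc, mean, sd = pcc_per_celltype(A, B)
        for t in range(3):
            a, b = A[:, t], B[:, t]
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            expected = cov / (a.std() * b.std())
            assert pcc[t] == pytest.approx(expected, rel=1e-10)
        assert mean == pytest.approx(pcc.mean())
        assert sd == pytest.approx(pcc.std(ddof=1))

    def test_zero_variance_column_scores_zero_with_warning(self):
        P = np.column_stack([np.full(5, 0.5), np.linspace(0, 1, 5)])
        Q = np.column_stack([np.linspace(0, 1, 5), np.linspace(0, 1, 5)])
        with pytest.warns(UserWarning, match="zero-variance"):
            pcc, *_ = pcc_per_celltype(P, Q)
        assert pcc[0] == 0.0
        assert pcc[1] == pytest.approx(1.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            pcc_per_celltype(np.ones((3, 2)), np.ones((4, 2)))


class TestErrorMetrics:
    def test_identical_inputs_give_zero(self):
        P = np.random.default_rng(0).uniform(size=(6, 4))
        assert rmse(P, P) == 0.0
        assert frobenius_distance(P, P) == 0.0

    def test_single_entry_difference_arithmetic(self):
        A = np.zeros((2, 2))
        B = np.zeros((2, 2))
        B[0, 0] = 0.5
        assert frobenius_distance(A, B) == pytest.approx(0.5)
        assert rmse(A, B) == pytest.approx(0.25)

    def test_frobenius_rmse_identity(self):
        rng = np.random.default_rng(3)
        A, B = rng.uniform(size=(2, 17, 5))
        ns, k = A.shape
        assert frobenius_distance(A, B) == pytest.approx(rmse(A, B) * math.sqrt(ns * k), rel=1e-10)


class TestJSD:
    def test_identical_rows_give_zero(self):
        rng = np.random.default_rng(4)
        P = simplex_rows(rng, 8, 3)
        vec, mean = jsd_per_spot(P, P)
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_disjoint_supports_reach_ln2(self):
        vec, mean = jsd_per_spot(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        assert vec[0] == pytest.approx(math.log(2))

    def test_hand_expansion(self):
        # p=(0.5,0.5), q=(1,0), m=(0.75,0.25)
        expected = 0.5 * (
            0.5 * math.log(0.5 / 0.75) + 0.5 * math.log(0.5 / 0.25)
        ) + 0.5 * (1.0 * math.log(1.0 / 0.75))
        vec, _ = jsd_per_spot(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        assert vec[0] == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_ln2(self):
        rng = np.random.default_rng(5)
        P, Q = simplex_rows(rng, 50, 4), simplex_rows(rng, 50, 4)
        vec, _ = jsd_per_spot(P, Q)
        assert vec.max() <= math.log(2) + 1e-12
        assert vec.min() >= 0

    def test_log2_base_rescales(self):
        rng = np.random.default_rng(6)
        P, Q = simplex_rows(rng, 5, 3), simplex_rows(rng, 5, 3)
        nat, _ = jsd_per_spot(P, Q)
        two, _ = jsd_per_spot(P, Q, base="2")
        np.testing.assert_allclose(two, nat / math.log(2), rtol=1e-12)

    def test_off_simplex_rows_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalized"):
            vec, _ = jsd_per_spot(np.array([[2.0, 2.0]]), np.array([[0.5, 0.5]]))
        assert vec[0] == pytest.approx(0.0, abs=1e-12)


class TestSSIM:
    def grid_coords(self, n):
        return np.array([(i, j) for i in range(n) for j in range(n)], dtype=float)

    def test_identical_fields_score_one(self):
        rng = np.random.default_rng(7)
        coords = self.grid_coords(6)
        P = simplex_rows(rng, 36, 3)
        np.testing.assert_allclose(ssim_per_celltype(P, P, coords), 1.0, atol=1e-12)

    def test_constant_fields_score_one(self):
        coords = self.grid_coords(4)
        P = np.full((16, 2), 0.5)
        np.testing.assert_allclose(ssim_per_celltype(P, P, coords), 1.0, atol=1e-12)

    def test_matches_reference_ssim_on_shifted_square(self):
        from skimage.metrics import structural_similarity

        a = np.zeros((12, 12))
        b = np.zeros((12, 12))
        a[3:7, 3:7] = 1.0
        b[5:9, 5:9] = 1.0
        expected = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False, data_range=1.0
        )
        coords = self.grid_coords(12)
        got = ssim_per_celltype(a.ravel()[:, None], b.ravel()[:, None], coords)
        assert got[0] == pytest.approx(expected, rel=1e-7)

    def test_collapsing_spots_error(self):
        coords = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0]])
        P = np.full((3, 1), 0.5)
        with pytest.raises(ValueError, match="raster"):
            ssim_per_celltype(P, P, coords)

    def test_rasterize_places_values_on_lattice(self):
        coords = np.array([[10.0, 20.0], [11.0, 20.0], [10.0, 21.0]])
        img = rasterize(np.array([1.0, 2.0, 3.0]), coords)
        assert img.shape == (2, 2)
        assert img[0, 0] == 1.0 and img[1, 0] == 2.0 and img[0, 1] == 3.0


class TestClusteringAgreement:
    def test_identical_labelings(self):
        labels = ["a", "a", "b", "b", "c"]
        assert ari(labels, labels) == pytest.approx(1.0)
        assert purity(labels, labels) == pytest.approx(1.0)

    def test_single_cluster_purity_is_majority_fraction(self):
        assert purity([0, 0, 0, 0], ["x", "x", "y", "y"]) == pytest.approx(0.5)

    def test_ari_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 3, size=30)
        n = len(a)
        same_a = a[:, None] == a[None, :]
        same_b = b[:, None] == b[None, :]
        iu = np.triu_indices(n, 1)
        n11 = np.sum(same_a[iu] & same_b[iu])
        n00 = np.sum(~same_a[iu] & ~same_b[iu])
        n10 = np.sum(same_a[iu] & ~same_b[iu])
        n01 = np.sum(~same_a[iu] & same_b[iu])
        total = n * (n - 1) / 2
        index = n11
        expected_index = (n11 + n10) * (n11 + n01) / total
        max_index = ((n11 + n10) + (n11 + n01)) / 2
        expected = (index - expected_index) / (max_index - expected_index)
        assert ari(a, b) == pytest.approx(expected, rel=1e-10)

    def test_ari_symmetric_and_permutation_invariant(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [1, 1, 0, 0, 2, 2]
        assert ari(a, b) == ari(b, a)
        relabeled = [{0: "x", 1: "y", 2: "z"}[v] for v in a]
        assert ari(relabeled, b) == pytest.approx(ari(a, b))

    def test_purity_invariant_to_cluster_id_permutation(self):
        clusters = [0, 0, 1, 1, 2]
        truth = ["a", "a", "b", "a", "c"]
        relabeled = [{0: 7, 1: 3, 2: 9}[c] for c in clusters]
        assert purity(relabeled, truth) == purity(clusters, truth)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ari([1, 2], [1])
        with pytest.raises(ValueError):
            purity([], [])


class TestSpatialAutocorrelation:
    def path_graph(self, n):
        coords = np.column_stack([np.arange(float(n)), np.zeros(n)])
        return build_spatial_graph(coords, k_neighbors=1)

    def test_smooth_field_positive_autocorrelation(self):
        g = self.path_graph(10)
        values = np.arange(10.0)
        assert morans_i(values, g) > 0
        assert gearys_c(values, g) < 1

    def test_alternating_ring_negative_autocorrelation(self):
        n = 12
        theta = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(theta), np.sin(theta)])
        g = build_spatial_graph(coords, k_neighbors=2)
        values = np.array([1.0, -1.0] * (n // 2))
        assert morans_i(values, g) < 0

    def test_double_loop_formula_oracle(self):
        rng = np.random.default_rng(9)
        coords = np.array([(i, j) for i in range(6) for j in range(6)], dtype=float)
        g = build_spatial_graph(coords, k_neighbors=4)
        x = rng.normal(size=36)
        W = g.W.toarray()
        n = 36
        z = x - x.mean()
        S0 = W.sum()
        num_i = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        num_c = sum(W[i, j] * (x[i] - x[j]) ** 2 for i in range(n) for j in range(n))
        expected_i = (n / S0) * num_i / (z @ z)
        expected_c = ((n - 1) / (2 * S0)) * num_c / (z @ z)
        assert morans_i(x, g) == pytest.approx(expected_i, rel=1e-10)
        assert gearys_c(x, g) == pytest.approx(expected_c, rel=1e-10)

    def test_constant_field_errors(self):
        g = self.path_graph(5)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(5), g)
        with pytest.raises(ValueError, match="constant"):
            gearys_c(np.ones(5), g)


class TestDirectionConventions:
    def test_noise_degrades_all_metrics_in_expectation(self):
        """Higher-is-better metrics fall and lower-is-better metrics rise
        as noise is mixed into the prediction (averaged over 20 seeds)."""
        rng = np.random.default_rng(10)
        coords = np.array([(i, j) for i in range(6) for j in range(6)], dtype=float)
        # smooth spatially structured truth
        base = np.column_stack([coords[:, 0], 5 - coords[:, 0], coords[:, 1]]) + 1.0
        P_true = base / base.sum(axis=1, keepdims=True)
        deltas = {"pcc": [], "ssim": [], "jsd": [], "rmse": []}
        for s in range(20):
            noise_rng = np.random.default_rng(100 + s)
            noise = noise_rng.dirichlet(np.ones(3), size=36)
            P_noisy = 0.5 * P_true + 0.5 * noise
            clean = evaluate(P_true, P_true, coords=coords)
            noisy = evaluate(P_noisy, P_true, coords=coords)
            deltas["pcc"].append(noisy.pcc_mean - clean.pcc_mean)
            deltas["ssim"].append(
                np.mean(noisy.ssim_per_type) - np.mean(clean.ssim_per_type)
            )
            deltas["jsd"].append(noisy.jsd_mean - clean.jsd_mean)
            deltas["rmse"].append(noisy.rmse - clean.rmse)
        assert np.mean(deltas["pcc"]) < 0
        assert np.mean(deltas["ssim"]) < 0
        assert np.mean(deltas["jsd"]) > 0
        assert np.mean(deltas["rmse"]) > 0


class TestEvaluateBundle:
    def test_report_contains_all_metrics(self):
        rng = np.random.default_rng(11)
        coords = np.array([(i, j) for i in range(5) for j in range(5)], dtype=float)
        P = simplex_rows(rng, 25, 3)
        Q = simplex_rows(rng, 25, 3)
        score = evaluate(P, Q, coords=coords, type_names=["a", "b", "c"])
        d = score.to_dict()
        for key in ("pcc_mean", "pcc_sd", "jsd_mean", "rmse", "frobenius", "ssim_mean"):
            assert key in d
        tidy = score.to_tidy()
        assert set(tidy.columns) == {"metric", "cell_type", "value"}
        assert (tidy.metric == "pcc").sum() == 3
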