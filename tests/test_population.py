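"""Uncentered PCA, angles, classification, mixtures and soma-axon logic."""

import numpy as np
import pandas as pd
import pytest

import photoline as pl
from photoline.population import (DegenerateMatrixError, PairedRecording,
                                  angle_difference_deg, angle_group_test,
                                  build_feature_table, circular_mean_deg,
                                  dat_mixture, fit_mixture_weight,
                                  fit_pca_uncentered, kmeans_classify,
                                  linearize_angles, mixture_fit_quality,
                                  pairwise_distance_similarity, pc_angle,
                                  peak_group_test, soma_axon_xcorr, timing_lag)


class TestUncenteredPCA:
    def test_identical_rows_pc1_explains_everything(self):
        X = np.tile(np.sin(np.linspace(0, 3, 201)), (5, 1))
        d = fit_pca_uncentered(X)
        assert d.variance_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_two_component_split_matches_eigendecomposition_oracle(self, rng):
        # rows = a*u + b*v with orthonormal u, v and E[a^2]/E[b^2] = 4
        lags = 201
        u = np.zeros(lags)
        u[:100] = 1.0 / 10.0
        v = np.zeros(lags)
        v[100:200] = 1.0 / 10.0
        a = rng.normal(0, 2.0, 60)
        b = rng.normal(0, 1.0, 60)
        X = np.outer(a, u) + np.outer(b, v)
        d = fit_pca_uncentered(X)
        # oracle: eigenvalues of X'X, no centering
        evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        expect = 100.0 * evals / evals.sum()
        np.testing.assert_allclose(d.variance_explained[:2], expect[:2],
                                   atol=1e-8)
        assert 70.0 < d.variance_explained[0] < 90.0
        assert d.variance_explained[:2].sum() > 95.0

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(12, 30))
        d = fit_pca_uncentered(X)
        rel = (np.linalg.norm(X - d.scores @ d.loadings)
               / np.linalg.norm(X))
        assert rel < 1e-8

    def test_heldout_projection_uses_fitted_loadings(self, rng):
        X = rng.normal(size=(10, 50))
        d = fit_pca_uncentered(X)
        held = rng.normal(size=(4, 50))
        np.testing.assert_allclose(d.transform(held), held @ d.loadings.T)

    def test_sign_convention_largest_loading_element_positive(self, rng):
        X = rng.normal(size=(15, 40))
        d = fit_pca_uncentered(X)
        for row in d.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            fit_pca_uncentered(np.zeros((5, 10)))
        with pytest.raises(DegenerateMatrixError):
            fit_pca_uncentered(np.ones((2, 10)))


class TestAngles:
    @pytest.mark.parametrize("xy,expected", [
        ((1.0, 0.0), 0.0), ((0.0, 1.0), 90.0),
        ((1.0, 1.0), 45.0), ((-1.0, -1.0), 225.0),
    ])
    def test_angle_convention(self, xy, expected):
        assert pc_angle(*xy) == pytest.approx(expected)

    def test_zero_scores_flagged_nan(self):
        assert np.isnan(pc_angle(0.0, 0.0))

    def test_scale_invariance(self, rng):
        x, y = rng.normal(size=2)
        assert pc_angle(3.7 * x, 3.7 * y) == pytest.approx(pc_angle(x, y))

    def test_circular_difference_wraps(self):
        assert angle_difference_deg(10.0, 350.0) == pytest.approx(20.0)
        assert angle_difference_deg(0.0, 180.0) == pytest.approx(180.0)

    def test_linearization_opens_at_45(self):
        out = linearize_angles([44.0, 46.0, 300.0])
        np.testing.assert_allclose(out, [404.0, 46.0, 300.0])

    def test_circular_mean(self):
        assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)


class TestAngleGroupTest:
    def test_identical_groups_p_capped_at_one(self):
        angles = np.array([100.0, 120.0, 140.0] * 2)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        p = angle_group_test(angles, labels)
        assert p[("a", "b")] == 1.0

    def test_separated_groups_significant(self, rng):
        a = 135.0 + rng.normal(0, 5.0, 10)
        b = 225.0 + rng.normal(0, 5.0, 10)
        p = angle_group_test(np.concatenate([a, b]),
                             np.array(["a"] * 10 + ["b"] * 10),
                             bonferroni=3)
        assert p[("a", "b")] < 0.001

    def test_three_groups_three_pvalues(self, rng):
        angles = rng.uniform(0, 360, 15)
        labels = np.repeat(["a", "b", "c"], 5)
        assert len(angle_group_test(angles, labels)) == 3

    def test_small_group_dropped(self, rng):
        angles = rng.uniform(0, 360, 7)
        labels = np.array(["a"] * 5 + ["b"] * 1 + ["c"] * 1)
        assert angle_group_test(angles, labels) == {}


class TestTimingLag:
    def test_symmetric_trough_located(self):
        lags = np.arange(-100, 101) / 100.0
        values = -np.exp(-((lags - 0.3) ** 2) / 0.02)
        r = timing_lag(values, lags, "xcorr_min")
        assert r.lag == pytest.approx(0.3)
        assert not r.boundary_flag

    def test_monotone_trace_flags_boundary(self):
        lags = np.arange(-100, 101) / 100.0
        r = timing_lag(lags.copy(), lags, "xcorr_min")
        assert r.boundary_flag
        assert r.lag == 0.0

    def test_accel_modes_report_positive_magnitude(self):
        lags = np.arange(-100, 101) / 100.0
        values = -np.exp(-((lags + 0.4) ** 2) / 0.02)
        r = timing_lag(values, lags, "accel_min")
        assert r.lag == pytest.approx(0.4)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            timing_lag(np.zeros(201), np.linspace(-1, 1, 201), "argmax")


def cloud_features(rng, centers, n=20, sd=0.05):
    rows = []
    for label, c in centers.items():
        for _ in range(n):
            f = np.asarray(c) + rng.normal(0, sd, 4)
            rows.append({"reward_response": f[0], "airpuff_response": f[1],
                         "pc1_score": f[2], "pc2_score": f[3],
                         "subtype_label": label})
    return build_feature_table(rows)


CENTERS = {"Vglut2": (8.0, 16.0, -1.0, 1.0),
           "Calb1": (12.0, 5.0, -1.0, -1.0),
           "Anxa1": (0.0, -4.0, 1.5, -0.5)}


class TestKMeans:
    def test_separable_clouds_perfect_accuracy(self, rng):
        features = cloud_features(rng, CENTERS)
        res = kmeans_classify(features, seed=0)
        assert res.overall_accuracy == 100.0
        assert set(res.matching.values()) == set(CENTERS)

    def test_permuted_labels_near_chance(self, rng):
        features = cloud_features(rng, CENTERS, n=30)
        perm = features["subtype_label"].sample(frac=1.0, random_state=1)
        features["subtype_label"] = perm.to_numpy()
        res = kmeans_classify(features, seed=0)
        assert 100.0 / 3.0 - 1e-9 <= res.overall_accuracy < 60.0

    def test_invariance_to_column_rescaling_and_order(self, rng):
        features = cloud_features(rng, CENTERS)
        res0 = kmeans_classify(features, seed=3)
        rescaled = features.copy()
        rescaled["airpuff_response"] = rescaled["airpuff_response"] * 50.0 + 7.0
        res1 = kmeans_classify(rescaled, seed=3)
        reordered = features[["pc2_score", "subtype_label", "reward_response",
                              "airpuff_response", "pc1_score"]]
        res2 = kmeans_classify(reordered, seed=3)
        assert res0.overall_accuracy == res1.overall_accuracy
        assert res0.overall_accuracy == res2.overall_accuracy

    def test_k_larger_than_n_rejected(self, rng):
        features = cloud_features(rng, CENTERS, n=1)
        with pytest.raises(ValueError):
            kmeans_classify(features, k=10)

    def test_matching_is_bijection(self, rng):
        features = cloud_features(rng, CENTERS, n=8, sd=3.0)
        res = kmeans_classify(features, seed=1)
        assert len(set(res.matching)) == 3
        assert len(set(res.matching.values())) == 3


class TestDistanceSimilarity:
    def test_euclidean_distance_345(self):
        angles = np.array([0.0, 20.0])
        labels = np.array(["Vglut2", "Vglut2"])
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]])
        out = pairwise_distance_similarity(angles, labels, coords)
        assert out["pairs"].distance_mm.iloc[0] == pytest.approx(3.0)
        assert out["pairs"].angle_diff_deg.iloc[0] == pytest.approx(20.0)

    def test_groups_enumerated(self, rng):
        labels = np.array(["Vglut2"] * 3 + ["Calb1"] * 3 + ["DAT"] * 3
                          + ["Aldh1a1"] * 2)
        n = labels.size
        angles = rng.uniform(0, 360, n)
        coords = rng.normal(0, 1, (n, 3))
        out = pairwise_distance_similarity(angles, labels, coords)
        counts = out["pairs"].group.value_counts()
        assert counts["within-Vglut2"] == 3
        assert counts["within-Calb1"] == 3
        assert counts["DAT"] == 3
        assert counts["mismatched"] == 9
        assert "Aldh1a1" not in " ".join(out["pairs"].group.unique())

    def test_missing_coords_pair_dropped(self):
        angles = np.array([0.0, 10.0, 20.0])
        labels = np.array(["Vglut2"] * 3)
        coords = np.array([[0, 0, 0], [np.nan, 0, 0], [1, 1, 1.0]])
        out = pairwise_distance_similarity(angles, labels, coords)
        assert len(out["pairs"]) == 1


class TestDATMixture:
    def test_pure_weights_return_templates(self, rng):
        calb1 = rng.normal(size=201)
        anxa1 = rng.normal(size=201)
        np.testing.assert_allclose(dat_mixture(calb1, anxa1, [1.0])[0], anxa1)
        np.testing.assert_allclose(dat_mixture(calb1, anxa1, [0.0])[0], calb1)

    def test_half_weight_is_elementwise_mean(self, rng):
        calb1 = rng.normal(size=201)
        anxa1 = rng.normal(size=201)
        np.testing.assert_allclose(dat_mixture(calb1, anxa1, [0.5])[0],
                                   (calb1 + anxa1) / 2.0)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            dat_mixture(np.zeros(10), np.ones(10), [1.2])

    def test_weight_recovery_from_constructed_mixtures(self, rng):
        calb1 = np.sin(np.linspace(0, 3, 201))
        anxa1 = -np.cos(np.linspace(0, 3, 201))
        for w in (0.0, 0.25, 0.6, 1.0):
            obs = w * anxa1 + (1 - w) * calb1 + rng.normal(0, 0.02, 201)
            w_hat = fit_mixture_weight(obs, calb1, anxa1)
            assert w_hat == pytest.approx(w, abs=0.05)
            pred = dat_mixture(calb1, anxa1, [w_hat])[0]
            assert mixture_fit_quality(obs, pred) > 0.98


def make_pair(rng, n=100_000, shared=None, soma=None):
    soma_sig = rng.normal(size=n) if soma is None else soma
    axon_sig = rng.normal(size=n)
    s405 = rng.normal(size=n)
    a405 = rng.normal(size=n)
    if shared is not None:
        soma_sig = soma_sig + shared
        axon_sig = axon_sig + shared
        s405 = s405 + shared
        a405 = a405 + shared
    return PairedRecording(soma_dff=soma_sig, axon_dff=axon_sig,
                           soma_dff405=s405, axon_dff405=a405)


class TestSomaAxon:
    def test_identical_traces_peak_one_at_zero_lag(self, rng):
        x = rng.normal(size=20000)
        pair = PairedRecording(soma_dff=x, axon_dff=x.copy(),
                               soma_dff405=rng.normal(size=20000),
                               axon_dff405=rng.normal(size=20000))
        pair = soma_axon_xcorr(pair)
        assert pair.peak == pytest.approx(1.0)
        i0 = np.argmax(pair.xcorr.values)
        assert pair.xcorr.lags[i0] == pytest.approx(0.0)
        assert not pair.excluded

    def test_independent_noise_peak_small(self):
        rng = np.random.default_rng(42)
        pair = soma_axon_xcorr(make_pair(rng))
        assert pair.peak < 0.05

    def test_shared_artifact_trips_control_exclusion(self):
        rng = np.random.default_rng(43)
        shared = np.zeros(100_000)
        for b in range(500, 100_000 - 200, 700):
            shared[b:b + 30] = 8.0
        pair = soma_axon_xcorr(make_pair(rng, shared=shared))
        assert pair.control_peak > 0.12
        assert pair.excluded

    def test_clock_mismatch_is_structural_error(self, rng):
        pair = PairedRecording(soma_dff=rng.normal(size=1000),
                               axon_dff=rng.normal(size=900),
                               soma_dff405=rng.normal(size=1000),
                               axon_dff405=rng.normal(size=900))
        with pytest.raises(ValueError, match="clock"):
            soma_axon_xcorr(pair)

    def test_peak_group_test_detects_shift(self, rng):
        groups = {"DAT": rng.normal(0.37, 0.05, 30),
                  "Vglut2": rng.normal(0.65, 0.05, 12)}
        p = peak_group_test(groups, bonferroni=3)
        assert p["Vglut2"] < 0.01


class TestFeatureTable:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_feature_table([{"reward_response": 1.0}])
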