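"""Mixture-density composite: GMM fits, closed-form L2 distance vs
quadrature, classical MDS against the double-centering oracle."""

import numpy as np
import pytest

from gpsmobility.composite import (MixtureDensityModel, build_distance_matrix,
                                   classical_mds, cohort_mds1, fit_daily_gmm,
                                   gmm_l2_distance)


def gaussian_model(means, covs, weights=None, pid="m"):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, p = means.shape
    covs = np.asarray(covs, dtype=float).reshape(k, p, p)
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights)
    return MixtureDensityModel(pid, w, means, covs, [f"f{i}" for i in range(p)], k)


def mixture_pdf_1d(model, x):
    from scipy.stats import norm
    out = np.zeros_like(x)
    for w, mu, cov in zip(model.weights, model.means, model.covariances):
        out += w * norm.pdf(x, mu[0], np.sqrt(cov[0, 0, 0] if cov.ndim == 3
                                              else cov[0, 0]))
    return out


def l2_by_quadrature(m1, m2, lo=-60.0, hi=60.0, n=200001):
    x = np.linspace(lo, hi, n)
    f = mixture_pdf_1d(m1, x)
    g = mixture_pdf_1d(m2, x)
    return np.trapezoid((f - g) ** 2, x)


class TestGmmFit:
    def test_identical_seed_identical_parameters(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 3))
        a = fit_daily_gmm(X, k=3, seed=7)
        b = fit_daily_gmm(X, k=3, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.means, b.means)

    def test_k1_recovers_sample_mle(self):
        rng = np.random.default_rng(1)
        X = rng.normal([1.0, -2.0], [1.0, 0.5], (200, 2))
        m = fit_daily_gmm(X, k=1, seed=0)
        np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(m.covariances[0],
                                   np.cov(X.T, bias=True), atol=1e-5)

    def test_pooled_mean_recovers_single_gaussian_truth(self):
        rng = np.random.default_rng(2)
        mu_true = np.array([2.0, -1.0])
        X = rng.normal(mu_true, 1.0, (60, 2))
        m = fit_daily_gmm(X, k=3, seed=0)
        pooled = (m.weights[:, None] * m.means).sum(axis=0)
        se = 1.0 / np.sqrt(len(X))
        assert np.all(np.abs(pooled - mu_true) < 3 * se + 0.2)

    def test_k_reduced_for_short_records(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (7, 2))
        with pytest.warns(UserWarning, match="reduced"):
            m = fit_daily_gmm(X, k=3, seed=0)
        assert m.k == 2  # 7 // 3

    def test_degenerate_identical_rows(self):
        X = np.zeros((12, 2))
        m = fit_daily_gmm(X, k=3, seed=0)
        assert np.allclose(m.means, 0.0, atol=1e-8)


class TestL2Distance:
    def test_identical_models_distance_zero(self):
        m = gaussian_model([[0.0]], [[[1.0]]])
        assert gmm_l2_distance(m, m) == 0.0

    def test_unit_gaussians_two_apart_closed_form(self):
        m1 = gaussian_model([[0.0]], [[[1.0]]])
        m2 = gaussian_model([[2.0]], [[[1.0]]])
        expected = (1.0 / np.sqrt(4 * np.pi)) * 2.0 * (1.0 - np.exp(-1.0))
        d2 = gmm_l2_distance(m1, m2)
        assert d2 == pytest.approx(expected, abs=1e-12)
        assert d2 == pytest.approx(0.3566, abs=2e-4)
        assert d2 == pytest.approx(l2_by_quadrature(m1, m2), abs=1e-9)

    def test_closed_form_matches_quadrature_on_random_mixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k1, k2 = rng.integers(1, 4, 2)
            m1 = gaussian_model(rng.normal(0, 3, (k1, 1)),
                                rng.uniform(0.3, 2.0, (k1, 1, 1)),
                                rng.dirichlet(np.ones(k1)))
            m2 = gaussian_model(rng.normal(0, 3, (k2, 1)),
                                rng.uniform(0.3, 2.0, (k2, 1, 1)),
                                rng.dirichlet(np.ones(k2)))
            assert gmm_l2_distance(m1, m2) == pytest.approx(
                l2_by_quadrature(m1, m2), abs=1e-6)

    def test_dimension_mismatch_raises(self):
        m1 = gaussian_model([[0.0]], [[[1.0]]])
        m2 = gaussian_model([[0.0, 0.0]], [np.eye(2)])
        with pytest.raises(ValueError, match="feature spaces"):
            gmm_l2_distance(m1, m2)

    def test_interpolating_toward_a_model_shrinks_distance(self):
        rng = np.random.default_rng(4)
        XA = rng.normal(0.0, 1.0, (40, 2))
        shift = np.array([4.0, -3.0])
        mB = fit_daily_gmm(XA + shift, k=1, seed=0)
        d_prev = np.inf
        for alpha in (0.0, 0.33, 0.66, 1.0):
            m = fit_daily_gmm(XA + alpha * shift, k=1, seed=0)
            d = gmm_l2_distance(m, mB)
            assert d < d_prev + 1e-12
            d_prev = d
        assert d_prev == pytest.approx(0.0, abs=1e-10)


class TestDistanceMatrix:
    def models(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        return [gaussian_model(rng.normal(0, 2, (2, 1)),
                               rng.uniform(0.5, 1.5, (2, 1, 1)),
                               rng.dirichlet([1, 1]), pid=f"P{i}")
                for i in range(n)]

    def test_identical_models_zero_matrix(self):
        m = gaussian_model([[1.0]], [[[1.0]]])
        _, M = build_distance_matrix([m, m])
        np.testing.assert_allclose(M, 0.0, atol=1e-12)

    def test_entries_match_pairwise_calls(self):
        models = self.models()
        ids, M = build_distance_matrix(models)
        for i in range(5):
            for j in range(5):
                expect = gmm_l2_distance(models[i], models[j]) if i != j else 0.0
                assert M[i, j] == pytest.approx(expect, abs=1e-12)
        assert (M == M.T).all() and np.all(np.diag(M) == 0)

    def test_permutation_equivariance(self):
        models = self.models()
        _, M = build_distance_matrix(models)
        perm = [3, 1, 4, 0, 2]
        _, Mp = build_distance_matrix([models[i] for i in perm])
        np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)], atol=1e-12)

    def test_sqrt_distances_satisfy_triangle_inequality(self):
        _, M = build_distance_matrix(self.models(6, seed=9))
        d = np.sqrt(M)
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestClassicalMds:
    def test_collinear_coordinates_recovered(self):
        coords = np.array([0.0, 1.0, 3.0])
        D2 = (coords[:, None] - coords[None, :]) ** 2
        scores, evals, varfrac = classical_mds(D2)
        expected = coords - coords.mean()  # {-4/3, -1/3, 5/3}
        sign = np.sign(scores[np.argmax(np.abs(expected))]
                       * expected[np.argmax(np.abs(expected))])
        np.testing.assert_allclose(sign * scores, expected, atol=1e-9)
        assert varfrac == pytest.approx(1.0)
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_distances_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            classical_mds(np.zeros((4, 4)))

    def test_orientation_follows_reference_vector(self):
        coords = np.array([0.0, 1.0, 3.0, 7.0])
        D2 = (coords[:, None] - coords[None, :]) ** 2
        s1, _, _ = classical_mds(D2, orient=coords)
        assert np.corrcoef(s1, coords)[0, 1] > 0
        s2, _, _ = classical_mds(D2, orient=-coords)
        assert np.corrcoef(s2, coords)[0, 1] < 0

    def test_planted_two_cluster_structure_separates(self):
        rng = np.random.default_rng(6)
        models = []
        for i in range(8):
            center = 0.0 if i < 4 else 6.0
            models.append(gaussian_model(
                [[center + rng.normal(0, 0.2)]], [[[1.0]]], pid=f"P{i}"))
        _, M = build_distance_matrix(models)
        scores, _, _ = classical_mds(M)
        a, b = scores[:4], scores[4:]
        gap = abs(a.mean() - b.mean())
        spread = max(a.std(), b.std())
        assert gap > 3 * spread

    def test_identical_daily_matrices_get_identical_mds1(self):
        import pandas as pd
        from gpsmobility.features import FEATURE_COLUMNS
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, (12, len(FEATURE_COLUMNS)))
        rows = []
        for pid in ("A", "B", "C"):
            X = base if pid in ("A", "B") else base + 3.0
            for i, row in enumerate(X):
                r = {"participant_id": pid, "date": f"d{i}", "excluded": False}
                r.update(dict(zip(FEATURE_COLUMNS, np.abs(row))))
                rows.append(r)
        daily = pd.DataFrame(rows)
        scores, _, _ = cohort_mds1(daily, k=1, seed=0)
        sa = scores.loc[scores["participant_id"] == "A", "mds1"].iloc[0]
        sb = scores.loc[scores["participant_id"] == "B", "mds1"].iloc[0]
        sc = scores.loc[scores["participant_id"] == "C", "mds1"].iloc[0]
        assert sa == pytest.approx(sb, abs=1e-6)
        assert abs(sc - sa) > 1e-3
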