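import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from conftest import make_links
from featrack.features import FeatureTable
from featrack.model import (LOG2_6PIE, DisplacementModel,
                            InsufficientTrainingError, adaptive_threshold,
                            build_trackability_report, compute_displacements,
                            expected_spurious, fit_displacement_model,
                            normalize_displacement, running_median,
                            select_training_links, trackability)


def _random_spd(rng, n):
    a = rng.normal(size=(n, n))
    return a @ a.T + n * np.eye(n)


def _model(mu, sigma_delta, sigma_x=None, n_o=10, n_train=100):
    mu = np.asarray(mu, dtype=float)
    sigma_x = sigma_delta if sigma_x is None else sigma_x
    return DisplacementModel((0, 1), mu, np.atleast_2d(sigma_delta),
                             np.atleast_2d(sigma_x), n_o, n_train)


class TestComputeDisplacements:
    def test_identical_vectors_give_zero(self, open_spec):
        X = np.array([[1.0, 2.0, 0.5], [5.0, 6.0, 1.5]])
        t0 = FeatureTable(0, [0, 1], X)
        t1 = FeatureTable(1, [0, 1], X)
        d = compute_displacements(t0, t1, make_links(0, [0, 1], [0, 1]), open_spec)
        assert np.allclose(d, 0)

    def test_matches_elementwise_oracle(self, linear_spec, rng):
        n = 100
        t0 = FeatureTable(0, np.arange(n), rng.uniform(0, 100, (n, 4)))
        t1 = FeatureTable(1, np.arange(n), rng.uniform(0, 100, (n, 4)))
        perm = rng.permutation(n)
        links = make_links(0, np.arange(n), perm)
        d = compute_displacements(t0, t1, links, linear_spec)
        # brute-force per-feature subtraction and wrap
        for k in range(n):
            row0 = t0.X[k]
            row1 = t1.X[perm[k]]
            for j in range(4):
                raw = row1[j] - row0[j]
                if j < 2:  # periodic position
                    period = 100.0
                    while raw > period / 2:
                        raw -= period
                    while raw <= -period / 2:
                        raw += period
                assert d[k, j] == pytest.approx(raw, abs=1e-9)

    def test_missing_id_identifies_link(self, open_spec):
        t0 = FeatureTable(0, [0], [[0.0, 0.0, 0.0]])
        t1 = FeatureTable(1, [5], [[0.0, 0.0, 0.0]])
        with pytest.raises(KeyError, match="id 3"):
            compute_displacements(t0, t1, make_links(0, [0], [3]), open_spec)


class TestSelectTrainingLinks:
    def test_half_keeps_five_smallest(self, rng):
        links = make_links(0, np.arange(10), np.arange(10),
                           scores=np.arange(10)[::-1].astype(float))
        kept = select_training_links(links, 0.5)
        assert sorted(kept.df["score"]) == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_full_fraction_is_identity(self, rng):
        links = make_links(0, np.arange(10), np.arange(10),
                           scores=rng.uniform(size=10))
        assert select_training_links(links, 1.0).keys() == links.keys()

    def test_matches_full_sort_oracle(self, rng):
        n = 1000
        scores = rng.uniform(size=n)
        links = make_links(0, np.arange(n), np.arange(n), scores=scores)
        kept = select_training_links(links, 0.3)
        expected = set(np.argsort(scores, kind="stable")[:300])
        assert set(kept.df["id_from"]) == expected

    def test_empty_is_an_error(self):
        from featrack.tracker import LinkSet
        with pytest.raises(InsufficientTrainingError):
            select_training_links(LinkSet.empty(), 0.5)


class TestFitDisplacementModel:
    def test_constant_displacements_reduce_to_ridge(self):
        d = np.tile([1.0, 2.0], (20, 1))
        table = FeatureTable(1, np.arange(20), np.random.default_rng(0)
                             .normal(size=(20, 2)))
        m = fit_displacement_model(d, table, n_o=20)
        assert np.allclose(m.mu, [1.0, 2.0])
        assert np.allclose(m.sigma_delta, np.diag([1e-12, 1e-12]))

    def test_monte_carlo_recovery(self, rng):
        mu = np.array([1.0, -2.0, 0.5])
        cov = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.3], [0.0, 0.3, 1.5]])
        n = 10_000
        d = rng.multivariate_normal(mu, cov, size=n)
        table = FeatureTable(1, np.arange(100),
                             rng.multivariate_normal(np.zeros(3), 4 * cov, size=100))
        m = fit_displacement_model(d, table, n_o=100)
        se_mu = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(m.mu - mu) < 3 * se_mu)
        # covariance elements converge at ~sqrt(2/n) relative scale
        assert np.linalg.norm(m.sigma_delta - cov) < 3 * np.sqrt(2 / n) * np.linalg.norm(cov) * 3

    def test_sigma_x_recovers_frame_covariance(self, rng):
        cov = np.array([[3.0, 1.0], [1.0, 2.0]])
        X = rng.multivariate_normal(np.zeros(2), cov, size=5000)
        m = fit_displacement_model(rng.normal(size=(100, 2)),
                                   FeatureTable(1, np.arange(5000), X), n_o=5000)
        assert np.linalg.norm(m.sigma_x - cov) / np.linalg.norm(cov) < 0.1

    def test_too_few_links_raise(self):
        with pytest.raises(InsufficientTrainingError, match="insufficient"):
            fit_displacement_model(np.zeros((2, 3)),
                                   FeatureTable(1, [0], np.zeros((1, 3))), 1)


class TestTrackability:
    def test_single_feature_single_object_constant(self):
        r = trackability(np.eye(1), np.eye(1), 1)
        assert r == pytest.approx(0.5 * LOG2_6PIE, abs=1e-12)

    def test_two_feature_arithmetic(self):
        # variance ratio 16 per feature and 16 objects: the first and third
        # terms cancel to leave exactly log2(6*pi*e)
        r = trackability(np.diag([16.0, 16.0]), np.eye(2), 16)
        assert r == pytest.approx(LOG2_6PIE, abs=1e-12)

    def test_single_feature_formula_equivalence(self, rng):
        # the general determinant form collapses to the scalar
        # variance-ratio formula for one feature and one object
        for _ in range(20):
            vx, vd = rng.uniform(0.01, 100, 2)
            r = trackability(np.array([[vx]]), np.array([[vd]]), 1)
            expected = 0.5 * math.log2(vx / vd) + 0.5 * LOG2_6PIE
            assert r == pytest.approx(expected, rel=1e-12)

    def test_matches_eigenvalue_product_oracle(self, rng):
        for n in (2, 3, 5):
            sx, sd = _random_spd(rng, n), _random_spd(rng, n)
            det_x = np.prod(np.linalg.eigvalsh(sx))
            det_d = np.prod(np.linalg.eigvalsh(sd))
            expected = (0.5 * math.log2(det_x / det_d)
                        + 0.5 * n * LOG2_6PIE - math.log2(7))
            assert trackability(sx, sd, 7) == pytest.approx(expected, rel=1e-10)

    def test_block_additivity(self, rng):
        sx1, sd1 = _random_spd(rng, 2), _random_spd(rng, 2)
        sx2, sd2 = _random_spd(rng, 3), _random_spd(rng, 3)
        from scipy.linalg import block_diag
        whole = trackability(block_diag(sx1, sx2), block_diag(sd1, sd2), 16)
        part1 = trackability(sx1, sd1, 1) - 0.5 * 2 * LOG2_6PIE
        part2 = trackability(sx2, sd2, 1) - 0.5 * 3 * LOG2_6PIE
        expected = part1 + part2 + 0.5 * 5 * LOG2_6PIE - math.log2(16)
        assert whole == pytest.approx(expected, rel=1e-10)

    def test_doubling_cloud_adds_n_bits(self, rng):
        for n in (1, 2, 4):
            sx, sd = _random_spd(rng, n), _random_spd(rng, n)
            assert trackability(4 * sx, sd, 5) - trackability(sx, sd, 5) == \
                pytest.approx(n, abs=1e-10)

    def test_doubling_objects_costs_one_bit(self, rng):
        sx, sd = _random_spd(rng, 3), _random_spd(rng, 3)
        assert trackability(sx, sd, 10) - trackability(sx, sd, 20) == \
            pytest.approx(1.0, abs=1e-12)

    def test_noisier_feature_reduces_trackability(self, rng):
        sx, sd = _random_spd(rng, 3), _random_spd(rng, 3)
        w, v = np.linalg.eigh(sd)
        for k in range(3):
            w2 = w.copy()
            w2[k] *= 1.5
            noisier = v @ np.diag(w2) @ v.T
            assert trackability(sx, noisier, 5) < trackability(sx, sd, 5)

    def test_rejects_non_spd(self):
        with pytest.raises(ValueError):
            trackability(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2), 1)


class TestNormalizeDisplacement:
    def test_mean_maps_to_origin(self):
        m = _model([3.0, -1.0], np.diag([4.0, 1.0]))
        w, norm = normalize_displacement(np.array([3.0, -1.0]), m)
        assert np.allclose(w, 0) and norm == 0

    def test_diagonal_closed_form(self):
        m = _model([0.0, 0.0], np.diag([4.0, 1.0]))
        w, norm = normalize_displacement(np.array([2.0, 1.0]), m)
        assert np.allclose(w, [1.0, 1.0])
        assert norm == pytest.approx(math.sqrt(2))

    def test_whitened_training_set_is_isotropic(self, rng):
        cov = np.array([[2.0, 0.8, -0.3], [0.8, 1.5, 0.4], [-0.3, 0.4, 1.0]])
        d = rng.multivariate_normal([1.0, 2.0, 3.0], cov, size=10_000)
        m = fit_displacement_model(d, FeatureTable(1, np.arange(10),
                                                   rng.normal(size=(10, 3))), 10)
        w, _ = normalize_displacement(d, m)
        assert np.linalg.norm(w.mean(axis=0)) < 0.02
        assert np.linalg.norm(np.cov(w, rowvar=False) - np.eye(3)) < 0.05


class TestAdaptiveThreshold:
    def test_more_objects_means_stricter(self):
        sx = np.diag([100.0, 100.0])
        m1 = _model([0, 0], np.eye(2), sx, n_o=10)
        m2 = _model([0, 0], np.eye(2), sx, n_o=20)
        assert adaptive_threshold(m2, 0.05) < adaptive_threshold(m1, 0.05)

    def test_increasing_in_p_until_cap(self):
        m = _model([0, 0], np.eye(2), np.diag([50.0, 50.0]), n_o=100)
        betas = [adaptive_threshold(m, p) for p in np.geomspace(1e-4, 10, 12)]
        assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))
        assert betas[0] < betas[-1]

    def test_matches_bisection_oracle(self, rng):
        for _ in range(10):
            sx = _random_spd(rng, 2) * 50
            m = _model([0, 0], _random_spd(rng, 2), sx, n_o=rng.integers(5, 500))
            P = float(rng.uniform(0.001, 0.5))
            beta = adaptive_threshold(m, P)
            root = brentq(lambda b: expected_spurious(m, b) - P, 1e-9, 1e6)
            from scipy.stats import chi2
            cap = math.sqrt(chi2.ppf(0.999, 2))
            assert beta == pytest.approx(min(root, cap), rel=1e-9)

    def test_nonpositive_p_rejected(self):
        m = _model([0.0], [[1.0]])
        with pytest.raises(ValueError):
            adaptive_threshold(m, 0.0)


class TestTrackabilityReport:
    def _models(self, r_values):
        out = []
        for i, r in enumerate(r_values):
            m = _model([0.0], [[1.0]], n_o=5)
            m.frame_pair = (i, i + 1)
            m.r = float(r)
            m.beta = 1.0
            out.append(m)
        return out

    def test_constant_series_unflagged(self):
        rep = build_trackability_report(self._models([5.0] * 30))
        assert len(rep.flags) == 0

    def test_single_deep_dip_flagged(self):
        r = [5.0] * 30
        r[17] = 0.0
        rep = build_trackability_report(self._models(r))
        assert list(rep.flags) == [17]

    def test_matches_sliding_median_oracle(self, rng):
        r = rng.normal(10, 0.2, size=80)
        for i in rng.choice(80, size=6, replace=False):
            r[i] -= rng.uniform(2, 6)
        rep = build_trackability_report(self._models(r), drop_bits=1.0, window=21)
        flags = []
        for i in range(80):
            lo, hi = max(0, i - 10), min(80, i + 11)
            if r[i] < np.median(r[lo:hi]) - 1.0:
                flags.append(i)
        assert list(rep.flags) == flags

    @given(st.integers(3, 31).filter(lambda w: w % 2 == 1))
    def test_running_median_matches_brute_force(self, window):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        med = running_median(x, window)
        half = window // 2
        for i in range(50):
            assert med[i] == np.median(x[max(0, i - half):min(50, i + half + 1)])
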