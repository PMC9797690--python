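"""Parametric empirical Bayes, Bayesian model reduction, thresholding."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ecdcm.exceptions import ArgumentError, ConfigError
from ecdcm.peb import (PEB, ConnectionProbabilities, GaussianDensity,
                       PEBConfig, bmr_reduce, threshold_network)


def _gauss(x, m, v):
    return np.exp(-(x - m) ** 2 / (2 * v)) / np.sqrt(2 * np.pi * v)


class TestBmrReduce:
    def test_identity_reduction_changes_nothing(self):
        prior = GaussianDensity(np.zeros(3), np.eye(3))
        post = GaussianDensity(np.array([0.3, -0.2, 0.1]), 0.5 * np.eye(3))
        dF, red = bmr_reduce(prior, post, GaussianDensity(np.zeros(3),
                                                          np.eye(3)))
        assert dF == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(red.mean, post.mean)
        assert np.allclose(red.cov, post.cov)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_1d_quadrature_evidence(self, case):
        g = np.random.default_rng(case)
        m0, v0 = g.normal(0, 1), g.uniform(0.5, 2.0)
        mu, s = g.normal(0, 1), g.uniform(0.1, 0.4)
        mr, vr = g.normal(0, 0.5), g.uniform(1e-6, 0.5)
        # implied likelihood kernel: posterior / prior
        num = quad(lambda t: _gauss(t, mu, s) * _gauss(t, mr, vr)
                   / _gauss(t, m0, v0), -25, 25, limit=500)[0]
        dF, _ = bmr_reduce(GaussianDensity([m0], [[v0]]),
                           GaussianDensity([mu], [[s]]),
                           GaussianDensity([mr], [[vr]]))
        assert dF == pytest.approx(np.log(num), abs=1e-6)

    def test_switching_off_pins_posterior_to_zero(self):
        prior = GaussianDensity(np.zeros(2), np.eye(2) / 16)
        post = GaussianDensity(np.array([0.2, -0.1]), np.eye(2) * 0.002)
        reduced = GaussianDensity(np.zeros(2), np.diag([1e-10, 1.0 / 16]))
        _, red = bmr_reduce(prior, post, reduced)
        assert abs(red.mean[0]) < 1e-4
        assert red.mean[1] == pytest.approx(-0.1, abs=1e-3)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            bmr_reduce(GaussianDensity([0.0], [[1.0]]),
                       GaussianDensity([0.0, 0.0], np.eye(2)),
                       GaussianDensity([0.0], [[1.0]]))


class TestPebFit:
    def test_single_subject_without_shrinkage_returns_posterior_mean(self):
        mu = np.array([0.5, -0.3])
        cov = np.array([[0.04, 0.01], [0.01, 0.05]])
        res = PEB([(mu, cov)], config=PEBConfig(beta_prior_var=None)).fit()
        assert np.allclose(res.beta_mean.ravel(), mu, atol=1e-10)

    def test_matches_conjugate_gaussian_oracle_at_fixed_precision(self):
        # known between-subject variance: compare with direct matrix algebra
        g = np.random.default_rng(1)
        p, n_sub = 3, 12
        sig_b = 0.05 ** 2
        mus = [g.normal(0, 0.3, p) for _ in range(n_sub)]
        covs = [np.diag(g.uniform(0.001, 0.003, p)) for _ in range(n_sub)]
        prior_v = 1.0
        gamma = -np.log(sig_b)
        cfg = PEBConfig(beta_prior_var=prior_v,
                        gamma_bounds=(gamma, gamma + 1e-9))
        res = PEB(list(zip(mus, covs)), config=cfg).fit()
        # oracle: precision-weighted normal equations on the stacked system
        P = np.eye(p) / prior_v
        r = np.zeros(p)
        for m, c in zip(mus, covs):
            Ci = np.linalg.inv(c + sig_b * np.eye(p))
            P += Ci
            r += Ci @ m
        expect = np.linalg.solve(P, r)
        assert np.allclose(res.beta_mean.ravel(), expect, atol=1e-6)

    def test_identity_design_equal_covariances_gives_plain_average(self):
        g = np.random.default_rng(2)
        mus = [g.normal(0, 0.2, 4) for _ in range(8)]
        cov = 0.01 * np.eye(4)
        cfg = PEBConfig(beta_prior_var=None,
                        gamma_bounds=(5.0, 5.0 + 1e-9))
        res = PEB([(m, cov) for m in mus], config=cfg).fit()
        assert np.allclose(res.beta_mean.ravel(), np.mean(mus, axis=0),
                           atol=1e-8)

    def test_groupwise_fits_produce_four_matrices(self, base4):
        from ecdcm.cohort import CohortConfig, generate_cohort
        from ecdcm.inversion import InversionConfig, fit_cohort
        from ecdcm.spectra import SpectralConfig
        cfg = CohortConfig(base_A=base4,
                           node_labels=("L-PCC", "R-PCC", "L-dlPFC", "mPFC"),
                           group_sizes={g: 2 for g in
                                        ("CN", "EMCI", "LMCI", "AD")},
                           n_volumes=140, seed=11)
        records = generate_cohort(cfg)
        posts = fit_cohort(records, config=InversionConfig(max_iter=6),
                           spectral_config=SpectralConfig(
                               nperseg=64, smooth=3, fmin=0.008, fmax=0.1,
                               n_freq=6))
        mats = {}
        for g in ("CN", "EMCI", "LMCI", "AD"):
            ps = [p for p, r in zip(posts, records) if r.group == g]
            cp = PEB(ps).fit().search(max_exhaustive=4)
            mats[g] = cp.strength_mean
            assert cp.strength_mean.shape == (4, 4)
            assert np.all((cp.prob >= 0) & (cp.prob <= 1))
            assert np.all(cp.strength_var >= 0)
        assert len(mats) == 4

    def test_empty_subject_list_rejected(self):
        with pytest.raises(ConfigError):
            PEB([])

    def test_rank_deficient_design_rejected(self):
        mu, cov = np.zeros(2), np.eye(2)
        X = np.ones((3, 2))           # duplicated column
        with pytest.raises(ConfigError):
            PEB([(mu, cov)] * 3, design_matrix=X)


@pytest.fixture(scope="module")
def toy_fit():
    g = np.random.default_rng(2)
    true = np.array([0.3, -0.25, 0.0, 0.0])
    subs = []
    for _ in range(25):
        th = true + 0.05 * g.standard_normal(4)
        subs.append((th + 0.03 * g.standard_normal(4),
                     0.03 ** 2 * np.eye(4)))
    return PEB(subs, config=PEBConfig(beta_prior_var=1 / 16)).fit()


class TestSearch:
    def test_strong_effects_on_null_effects_off(self, toy_fit):
        cp = toy_fit.search()
        assert np.all(cp.param_prob[:2] > 0.99)
        assert np.all(cp.param_prob[2:] < 0.5)

    def test_greedy_pruning_equals_exhaustive_enumeration(self, toy_fit):
        exhaustive = toy_fit.search(max_exhaustive=4)   # scores all 2^4
        greedy = toy_fit.search(max_exhaustive=2)       # forces pruning
        assert np.allclose(greedy.param_prob, exhaustive.param_prob,
                           atol=0.05)
        # and the model-averaged strengths agree
        assert np.allclose(greedy.param_mean, exhaustive.param_mean,
                           atol=0.01)

    def test_probabilities_invariant_to_parameter_ordering(self):
        g = np.random.default_rng(5)
        true = np.array([0.25, 0.0, -0.2, 0.05])
        subs = [(true + 0.04 * g.standard_normal(4), 0.002 * np.eye(4))
                for _ in range(15)]
        perm = np.array([2, 0, 3, 1])
        probs = PEB(subs).fit().search().param_prob
        subs_p = [(m[perm], c[np.ix_(perm, perm)]) for m, c in subs]
        probs_p = PEB(subs_p).fit().search().param_prob
        assert np.allclose(probs[perm], probs_p, atol=1e-6)


class TestBmrProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_identity_reduction_is_exact_for_random_gaussians(self, seed):
        g = np.random.default_rng(seed)
        p = int(g.integers(1, 4))
        L = g.normal(0, 1, (p, p))
        prior_cov = L @ L.T + np.eye(p)
        Lp = g.normal(0, 0.3, (p, p))
        post_cov = Lp @ Lp.T + 0.1 * np.eye(p)
        prior = GaussianDensity(g.normal(0, 1, p), prior_cov)
        post = GaussianDensity(g.normal(0, 1, p), post_cov)
        dF, red = bmr_reduce(prior, post,
                             GaussianDensity(prior.mean.copy(),
                                             prior_cov.copy()))
        assert abs(dF) < 1e-8
        assert np.allclose(red.mean, post.mean, atol=1e-8)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_threshold_nesting_for_arbitrary_probabilities(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(2, 6))
        cp = ConnectionProbabilities(prob=g.random((n, n)),
                                     strength_mean=g.normal(0, 1, (n, n)),
                                     strength_var=g.random((n, n)))
        prev = None
        for level in (0.0, 0.5, 0.75, 0.95, 0.99):
            adj, _ = threshold_network(cp, level)
            if prev is not None:
                assert np.all(adj <= prev)
            prev = adj


class TestThresholdNetwork:
    @pytest.fixture
    def cp(self):
        prob = np.array([[1.0, 0.6, 0.2], [0.97, 1.0, 0.0],
                         [0.995, 0.8, 0.55]])
        s = np.arange(9, dtype=float).reshape(3, 3) / 10 + 0.1
        return ConnectionProbabilities(prob=prob, strength_mean=s,
                                       strength_var=np.zeros((3, 3)))

    def test_no_threshold_keeps_all_nonzero_probability_edges(self, cp):
        adj, s = threshold_network(cp, 0.0)
        assert adj.sum() == 8          # one edge has probability exactly 0
        assert np.all(s[~adj] == 0)

    def test_levels_produce_nested_edge_sets(self, cp):
        prev = None
        for level in (0.0, 0.5, 0.75, 0.95, 0.99):
            adj, _ = threshold_network(cp, level)
            if prev is not None:
                assert np.all(adj <= prev)   # nested: edges only disappear
            prev = adj

    def test_strengths_carried_unchanged(self, cp):
        adj, s = threshold_network(cp, 0.5)
        assert np.all(s[adj] == cp.strength_mean[adj])

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_level_rejected(self, cp, bad):
        with pytest.raises(ArgumentError):
            threshold_network(cp, bad)

    def test_edge_list_layout(self, cp):
        cp.node_labels = ("a", "b", "c")
        df = cp.edge_list()
        assert list(df.columns) == ["from_label", "to_label", "strength",
                                    "variance", "probability"]
        assert len(df) == 9
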