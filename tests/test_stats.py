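"""Noise/signal correlations and factor analysis of shared variability."""

import numpy as np
import pytest

from v4popcode.stats import factor_fit, noise_correlations, signal_vs_noise
from v4popcode.synthetic import (
    RingModelParams,
    expected_rank1_correlation,
    gen_ring_responses,
)
from v4popcode.trialmatrix import TrialMatrix


def _tm(counts, theta=0.5):
    counts = np.asarray(counts, dtype=float)
    return TrialMatrix(counts=counts,
                       theta=np.full(counts.shape[0], theta))


class TestNoiseCorrelations:
    def test_duplicated_unit_pair_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, size=(100, 1)).astype(float)
        tm = _tm(np.hstack([x, x, rng.poisson(5, (100, 1))]))
        res = noise_correlations(tm)
        pair_01 = np.where((res.pair_index == [0, 1]).all(axis=1))[0][0]
        assert res.pairwise_noise_corr[pair_01] == pytest.approx(1.0)

    def test_independent_units_near_zero(self):
        rs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            tm = _tm(rng.poisson(8, size=(80, 10)))
            rs.append(noise_correlations(tm).mean_rsc)
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 3 * rs.std(ddof=1) / np.sqrt(rs.size)

    def test_zero_variance_unit_excluded_and_reported(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(50, 4)).astype(float)
        counts[:, 2] = 7.0
        res = noise_correlations(_tm(counts))
        assert res.excluded_units == [2]
        bad = (res.pair_index == 2).any(axis=1)
        assert np.isnan(res.pairwise_noise_corr[bad]).all()

    def test_rank1_model_matches_analytic_mean(self):
        p = RingModelParams(n_units=50, radial_noise_sd=0.25,
                            private_noise_sd=2.0)
        tm = gen_ring_responses(p, [0.5], 5000, seed=2)
        pred = expected_rank1_correlation(p, 0.5)
        iu = np.triu_indices(50, 1)
        assert noise_correlations(tm).mean_rsc == pytest.approx(
            pred[iu].mean(), rel=0.15)

    def test_requires_single_condition(self):
        tm = TrialMatrix(counts=np.ones((6, 2)), theta=np.r_[0, 0, 0, .5, .5, .5])
        with pytest.raises(ValueError, match="single stimulus"):
            noise_correlations(tm)


class TestSignalVsNoise:
    def test_shared_gain_links_signal_and_noise_correlations(self):
        p = RingModelParams(n_units=40, radial_noise_sd=0.3,
                            private_noise_sd=2.0)
        tm = gen_ring_responses(p, np.arange(10) / 10, 200, seed=0)
        assert signal_vs_noise(tm).noise_vs_signal_r > 0.2

    def test_attention_weakens_the_relationship(self):
        vals = {}
        for level in (0.0, 1.0):
            p = RingModelParams(n_units=40, radial_noise_sd=0.3,
                                private_noise_sd=2.0, attention_level=level)
            tm = gen_ring_responses(p, np.arange(10) / 10, 250, seed=1)
            vals[level] = signal_vs_noise(tm).noise_vs_signal_r
        assert vals[1.0] < vals[0.0]

    def test_private_noise_only_gives_no_relationship(self):
        p = RingModelParams(n_units=30, radial_noise_sd=0.0,
                            private_noise_sd=2.0)
        tm = gen_ring_responses(p, np.arange(8) / 8, 150, seed=2)
        assert abs(signal_vs_noise(tm).noise_vs_signal_r) < 0.1

    def test_needs_five_orientations(self):
        p = RingModelParams(n_units=10)
        tm = gen_ring_responses(p, [0.1, 0.3, 0.6], 10, seed=0)
        with pytest.raises(ValueError, match=">= 5 orientations"):
            signal_vs_noise(tm)


class TestFactorAnalysis:
    def test_recovers_planted_rank1_eigenvalue(self):
        rng = np.random.default_rng(0)
        n_units, n_trials = 30, 2000
        load = rng.normal(0, 1, n_units)
        lam1 = float(load @ load)
        psi = rng.uniform(0.5, 1.5, n_units)
        z = rng.normal(size=(n_trials, 1))
        x = 10 + z * load + rng.normal(0, np.sqrt(psi), (n_trials, n_units))
        fit = factor_fit(x, n_factors=5)
        assert fit.shared_eigenvalues[0] == pytest.approx(lam1, rel=0.10)
        assert fit.shared_eigenvalues[1] < 0.1 * lam1

    def test_independent_noise_gives_tiny_lambda1(self):
        # many trials per unit so the finite-sample noise floor of the
        # maximum-likelihood fit sits below 5% of the private variance
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, size=(30000, 6))
        fit = factor_fit(x, n_factors=2)
        assert fit.shared_eigenvalues[0] < 0.05 * 4.0  # 5% of private var

    def test_eigenvalues_descending_nonnegative_and_m_long(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(6, size=(400, 15)).astype(float)
        fit = factor_fit(x)  # default m = 5
        ev = fit.shared_eigenvalues
        assert ev.shape == (5,)
        assert np.all(np.diff(ev) <= 1e-9)
        assert np.all(ev >= -1e-12)
        assert np.all(fit.private_variances > 0)

    def test_log_likelihood_nondecreasing(self):
        rng = np.random.default_rng(3)
        load = rng.normal(0, 1, (12, 2))
        z = rng.normal(size=(600, 2))
        x = z @ load.T + rng.normal(0, 1, (600, 12))
        fit = factor_fit(x, n_factors=3, tol=1e-6)
        assert fit.converged
        ll = fit.log_likelihoods
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_too_many_factors_rejected(self):
        with pytest.raises(ValueError):
            factor_fit(np.random.default_rng(0).normal(size=(50, 4)),
                       n_factors=4)
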