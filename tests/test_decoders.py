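"""Specific/general decoders, Fisher information estimators, classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v4popcode import decoders as dec
from v4popcode.synthetic import (
    RingModelParams,
    gen_gaussian_population,
    gen_ring_responses,
)
from v4popcode.trialmatrix import TrialMatrix


def ring_data(n_theta=200, noise=0.0, seed=0, reps=1):
    """2-unit cosine/sine ring responses, optionally with isotropic noise."""
    th = np.tile(np.arange(n_theta) / n_theta, reps)
    f = np.column_stack([np.cos(2 * np.pi * th), np.sin(2 * np.pi * th)])
    if noise > 0:
        f = f + np.random.default_rng(seed).normal(0, noise, f.shape)
    return TrialMatrix(counts=f, theta=th)


class TestSpecificDecoder:
    def test_isotropic_weights_proportional_to_fprime(self):
        fp = np.array([1.0, 3.0, -2.0])
        d = dec.specific_weights(0.01 * fp, -0.01 * fp, np.eye(3), 0.01)
        fprime = fp  # (f+ - f-)/(2 dtheta) with dtheta = 0.01
        assert d.weights @ fprime == pytest.approx(1.0)
        np.testing.assert_allclose(np.cross(d.weights, fprime), 0, atol=1e-12)

    def test_variance_identity_on_random_covariances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 8)
            a = rng.normal(size=(n, n))
            cov = a @ a.T + 0.5 * np.eye(n)
            fp = rng.normal(size=n)
            d = dec.specific_weights(0.01 * fp, -0.01 * fp, cov, 0.01)
            # Var(theta_hat) = w' Sigma w = 1 / (f' Sigma^-1 f')
            lhs = d.weights @ cov @ d.weights
            rhs = 1.0 / (fp @ np.linalg.solve(cov, fp))
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_estimator_locally_unbiased(self):
        fp = np.array([2.0, 1.0])
        cov = np.array([[1.0, 0.3], [0.3, 2.0]])
        d = dec.specific_weights(0.5 + 0.01 * fp, 0.5 - 0.01 * fp, cov, 0.01,
                                 theta0=0.5)
        # decoding the exact condition means returns theta0 +- dtheta
        hi = d.estimate(0.5 + 0.01 * fp)
        lo = d.estimate(0.5 - 0.01 * fp)
        assert hi[0] == pytest.approx(0.51)
        assert lo[0] == pytest.approx(0.49)

    def test_singular_covariance_uses_pseudoinverse_with_warning(self):
        cov = np.outer([1.0, 1.0], [1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            d = dec.specific_weights(np.array([0.01, 0.01]),
                                     np.array([-0.01, -0.01]), cov, 0.01)
        assert d.used_pseudoinverse


class TestFisherBiasCorrection:
    COV = np.array([[1.0, 0.5], [0.5, 1.0]])

    def _sample(self, seed, dtheta=0.2, ntr=200):
        return gen_gaussian_population(
            dtheta / 2 * np.ones(2), -dtheta / 2 * np.ones(2), self.COV,
            ntr, seed=seed)

    def test_mean_matches_analytic_value(self):
        """f'=(1,1), Sigma=[[1,.5],[.5,1]] has Fisher information 4/3."""
        vals = [dec.fisher_info_bc(self._sample(s), 0.2).value
                for s in range(1000)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 4.0 / 3.0) < 3 * se

    def test_plugin_exceeds_corrected(self):
        for s in range(20):
            d = self._sample(s)
            assert dec.fisher_info_naive(d, 0.2).value \
                > dec.fisher_info_bc(d, 0.2).value

    def test_zero_information_centered_on_zero(self):
        vals = []
        for s in range(300):
            d = gen_gaussian_population(np.zeros(2), np.zeros(2), self.COV,
                                        100, seed=s)
            vals.append(dec.fisher_info_bc(d, 0.1).value)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_correction_validity_bound_enforced(self):
        d = gen_gaussian_population(np.zeros(8), np.zeros(8), np.eye(8), 5,
                                    seed=0)
        with pytest.raises(ValueError, match="2\\*Ntr > N \\+ 3"):
            dec.fisher_info_bc(d, 0.1)

    def test_monotone_in_mean_separation(self):
        means = []
        for gap in (0.05, 0.1, 0.2):
            vals = [dec.fisher_info_bc(
                gen_gaussian_population(gap / 2 * np.ones(2),
                                        -gap / 2 * np.ones(2),
                                        self.COV, 300, seed=s), 0.1).value
                for s in range(60)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGeneralDecoder:
    def test_noiseless_two_unit_ring_weights_are_one_and_i(self):
        tm = ring_data()
        g = dec.general_weights(tm)
        np.testing.assert_allclose(g.weights, [1.0, 1.0j], atol=1e-9)
        z = dec.decode_general(g, tm.counts)
        np.testing.assert_allclose(dec.phase_to_theta(z), tm.theta, atol=1e-9)

    def test_isotropic_noise_halves_weights(self):
        # Sigma = I/2 gives <Sigma + f f^T> = I, so w = (1/2, i/2)
        th = np.arange(100) / 100
        f = np.column_stack([np.cos(2 * np.pi * th), np.sin(2 * np.pi * th)])
        rng = np.random.default_rng(0)
        counts = np.vstack([f + rng.normal(0, np.sqrt(0.5), f.shape)
                            for _ in range(400)])
        tm = TrialMatrix(counts=counts, theta=np.tile(th, 400))
        g = dec.general_weights(tm)
        np.testing.assert_allclose(g.weights, [0.5, 0.5j], atol=0.02)
        # printed MSE expression: E = 1 - c* M^-1 c = 1 - 1/2 = 1/2
        assert g.expected_mse == pytest.approx(0.5, abs=0.02)

    def test_closed_form_beats_random_perturbations(self, ring_params):
        thetas = np.arange(40) / 40
        tm = gen_ring_responses(ring_params, thetas, 30, seed=1)
        g = dec.general_weights(tm)
        z_target = dec.ring_phase(tm.theta)

        def mse(w):
            return np.mean(np.abs(tm.counts @ w - z_target) ** 2)

        base = mse(g.weights)
        rng = np.random.default_rng(2)
        scale = np.abs(g.weights).mean()
        for _ in range(200):
            delta = (rng.normal(size=g.weights.size)
                     + 1j * rng.normal(size=g.weights.size)) * 0.05 * scale
            assert mse(g.weights + delta) >= base

    def test_noiseless_info_is_unbounded_sentinel(self):
        tm = ring_data()
        g = dec.general_weights(tm)
        est = dec.general_info(tm, g)
        assert est.unbounded
        assert np.isinf(est.value)

    def test_info_requires_enough_trials(self):
        tm = ring_data(n_theta=10)  # 10 trials, 2 units -> fine
        sub = TrialMatrix(counts=tm.counts[:4], theta=tm.theta[:4])
        with pytest.raises(ValueError, match="Ntr > N \\+ 2"):
            dec.general_info(sub, dec.general_weights(tm))

    def test_info_matches_holdout_variance(self, ring_params):
        """Corrected information tracks 1/Var(theta_hat) on a big holdout."""
        thetas = np.arange(50) / 50
        train = gen_ring_responses(ring_params, thetas, 60, seed=3)
        hold = gen_ring_responses(ring_params, thetas, 600, seed=4)
        g = dec.general_weights(train)
        est = dec.general_info(train, g)
        resid = dec.wrap_theta(
            dec.phase_to_theta(dec.decode_general(g, hold.counts))
            - hold.theta)
        assert est.value == pytest.approx(1.0 / np.var(resid), rel=0.10)


class TestPairDiscrimination:
    def test_same_distribution_is_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for s in range(15):
            counts = rng.normal(5, 1, size=(200, 6))  # one distribution
            tm = TrialMatrix(counts=counts,
                             theta=np.repeat([0.3, 0.7], 100))
            accs.append(dec.pair_discrimination(tm, 0.3, 0.7, seed=s))
        # within 3 SE of binomial chance on 200-trial folds
        assert abs(np.mean(accs) - 0.5) < 3 * 0.5 / np.sqrt(200 * 15)

    def test_separable_distributions_are_perfect(self):
        counts = np.vstack([np.zeros((20, 2)), np.ones((20, 2)) * 10])
        tm = TrialMatrix(counts=counts,
                         theta=np.repeat([0.3, 0.7], 20))
        assert dec.pair_discrimination(tm, 0.3, 0.7) == 1.0

    def test_general_mode_uses_all_orientation_weights(self, ring_params):
        thetas = np.arange(25) / 25
        tm = gen_ring_responses(ring_params, thetas, 40, seed=5)
        acc = dec.pair_discrimination(tm, 0.4, 0.44, mode="general", seed=0)
        assert 0.5 <= acc <= 1.0


class TestLOOCV:
    def test_separable_labels_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] > 0).astype(int)
        x[:, 0] += np.where(y == 1, 5.0, -5.0)
        assert dec.loocv_linear_performance(x, y) == 1.0

    def test_uninformative_counts_near_chance(self):
        accs = []
        for s in range(25):
            rng = np.random.default_rng(s)
            x = rng.normal(size=(60, 5))
            y = rng.integers(0, 2, 60)
            if np.unique(y).size < 2:
                continue
            accs.append(dec.loocv_linear_performance(x, y))
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_choice_trained_stimulus_scored_below_stimulus_trained(self):
        """With noisy choices, the choice-trained readout identifies the
        stimulus worse than the stimulus-trained readout, but above chance."""
        rng = np.random.default_rng(1)
        diffs, monk = [], []
        for rep in range(25):
            n = 120
            stim = rng.integers(0, 2, n)
            x = rng.normal(size=(n, 8)) + np.outer(stim, np.r_[2, np.zeros(7)])
            noisy = x[:, 0] + rng.normal(0, 2.5, n)
            choice = (noisy > 1).astype(int)
            if np.unique(choice).size < 2:
                continue
            p_stim = dec.loocv_linear_performance(x, stim)
            p_monk = dec.loocv_linear_performance(x, choice,
                                                  eval_labels=stim)
            diffs.append(p_stim - p_monk)
            monk.append(p_monk)
        assert np.mean(monk) > 0.6          # above chance
        assert np.mean(diffs) > 0           # below the stimulus decoder


@settings(max_examples=25, deadline=None)
@given(x=st.floats(-5, 5))
def test_theta_wrapping_bounds(x):
    w = dec.wrap_theta(x)
    assert -0.5 < w <= 0.5
    assert (x - w) % 1.0 == pytest.approx(0, abs=1e-9) \
        or (x - w) % 1.0 == pytest.approx(1, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(theta=st.floats(0, 0.999999))
def test_ring_phase_roundtrip(theta):
    assert dec.phase_to_theta(dec.ring_phase(theta)) == pytest.approx(
        theta, abs=1e-9)
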