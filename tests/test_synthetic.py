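"""Generators: ring model, Gaussian oracle populations, sessions, shuffling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v4popcode.stats import noise_correlations
from v4popcode.synthetic import (
    RingModelParams,
    SessionConfig,
    expected_rank1_correlation,
    gen_gaussian_population,
    gen_ring_responses,
    gen_session,
    ring_tuning,
    shuffle_trials,
)


class TestRingModel:
    def test_noiseless_counts_equal_tuning_curve(self):
        p = RingModelParams(n_units=20, radial_noise_sd=0.0,
                            private_noise_sd=0.0)
        tm = gen_ring_responses(p, [0.1, 0.6], 3, seed=0)
        for th in (0.1, 0.6):
            np.testing.assert_allclose(tm.condition(theta=th).counts,
                                       np.tile(ring_tuning(p, th), (3, 1)))

    def test_rank1_noise_correlation_matches_closed_form(self, ring_params):
        tm = gen_ring_responses(ring_params, [0.5], 4000, seed=1)
        emp = noise_correlations(tm)
        pred = expected_rank1_correlation(ring_params, 0.5)
        iu = np.triu_indices(ring_params.n_units, 1)
        # Monte-Carlo agreement of mean pairwise correlation
        assert emp.mean_rsc == pytest.approx(pred[iu].mean(), rel=0.15)
        assert emp.mean_rsc > 0

    def test_noise_correlation_increases_with_radial_sd(self):
        means = []
        for sd in (0.05, 0.15, 0.30):
            p = RingModelParams(n_units=40, radial_noise_sd=sd)
            tm = gen_ring_responses(p, [0.5], 1500, seed=2)
            means.append(noise_correlations(tm).mean_rsc)
        assert means[0] < means[1] < means[2]

    def test_attention_decreases_mean_rsc(self):
        out = {}
        for level in (0.0, 1.0):
            p = RingModelParams(n_units=40, radial_noise_sd=0.3,
                                attention_level=level)
            tm = gen_ring_responses(p, [0.5], 2000, seed=3)
            out[level] = noise_correlations(tm).mean_rsc
        assert out[1.0] < out[0.0]

    def test_seeded_determinism(self, ring_params):
        a = gen_ring_responses(ring_params, [0.2, 0.8], 10, seed=7)
        b = gen_ring_responses(ring_params, [0.2, 0.8], 10, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    @pytest.mark.parametrize("bad", [
        dict(n_units=1),
        dict(radial_noise_sd=-0.1),
        dict(attention_level=1.5),
        dict(tuning_amplitude=float("nan")),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            RingModelParams(**bad)

    def test_ring_coverage_required(self):
        # all preferences bunched on a half-ring leave a gap >= 0.5
        with pytest.raises(ValueError, match="cover the ring"):
            RingModelParams(n_units=4,
                            preferred_orientations=np.array(
                                [0.0, 0.1, 0.2, 0.3]))

    def test_signal_and_noise_correlations_positively_related(self, ring_params):
        from v4popcode.stats import signal_vs_noise
        thetas = np.arange(8) / 8
        tm = gen_ring_responses(ring_params, thetas, 300, seed=5)
        res = signal_vs_noise(tm)
        assert res.noise_vs_signal_r > 0


class TestGaussianPopulation:
    def test_sample_covariance_converges(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        tm = gen_gaussian_population(np.array([1.0, 2.0]),
                                     np.array([0.0, 0.0]), cov, 20000, seed=0)
        lo = tm.condition(theta=0.49)
        np.testing.assert_allclose(np.cov(lo.counts, rowvar=False), cov,
                                   atol=0.04)

    def test_non_positive_definite_covariance_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        with pytest.raises(ValueError, match="eigenvalue"):
            gen_gaussian_population(np.zeros(2), np.zeros(2), cov, 10, seed=0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gen_gaussian_population(np.zeros(3), np.zeros(2), np.eye(2), 10,
                                    seed=0)


class TestShuffleTrials:
    def test_per_unit_marginals_preserved(self, ring_params):
        tm = gen_ring_responses(ring_params, [0.2, 0.7], 50, seed=1)
        sh = shuffle_trials(tm, seed=2)
        for th in (0.2, 0.7):
            a = np.sort(tm.condition(theta=th).counts, axis=0)
            b = np.sort(sh.condition(theta=th).counts, axis=0)
            np.testing.assert_array_equal(a, b)

    def test_shuffle_removes_noise_correlations(self):
        rs = []
        for rep in range(30):
            p = RingModelParams(n_units=30, radial_noise_sd=0.3)
            tm = gen_ring_responses(p, [0.5], 300, seed=100 + rep)
            sh = shuffle_trials(tm, seed=rep)
            rs.append(noise_correlations(sh).mean_rsc)
        rs = np.asarray(rs)
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) < 3 * se + 1e-3


class TestSession:
    def test_block_composition(self, small_session_config):
        sess = gen_session(small_session_config, seed=0)
        df = sess.presentations
        cfg = small_session_config
        # uncued block: median and largest changes only, scaled counts
        unc = df[(df["cued"] == 0) & (df["change_amount"] > 0)]
        counts = unc["change_amount"].value_counts().to_dict()
        assert set(counts) <= {3, 5}
        assert counts[3] == cfg.n_uncued_median
        assert counts[5] == cfg.n_uncued_largest
        # cued block: all five amounts present
        cued = df[(df["cued"] == 1) & (df["change_amount"] > 0)]
        assert set(cued["change_amount"]) == {1, 2, 3, 4, 5}
        # each block has the configured number of RF or away change trials
        n_trials = df.groupby("block")["trial"].nunique()
        assert (n_trials == cfg.change_trials_per_block).all()

    def test_paper_scale_block_counts(self):
        cfg = SessionConfig()  # 125 change trials per block
        assert cfg.n_uncued_median == 20
        assert cfg.n_uncued_largest == 5

    def test_first_flash_flagged(self, small_session_config):
        sess = gen_session(small_session_config, seed=1)
        df = sess.presentations
        assert (df.loc[df["flash"] == 0, "first_flash"] == 1).all()
        assert (df.loc[df["flash"] > 0, "first_flash"] == 0).all()

    def test_hit_rate_monotone_in_change_amount(self, small_session_config):
        """Threshold choice model: larger changes are detected more often."""
        hits = np.zeros(5)
        tot = np.zeros(5)
        for seed in range(40):
            sess = gen_session(small_session_config, seed=seed)
            df = sess.presentations
            ch = df[df["change_amount"] > 0]
            for k in range(1, 6):
                g = ch[ch["change_amount"] == k]
                hits[k - 1] += g["choice"].sum()
                tot[k - 1] += len(g)
        rate = hits / tot
        assert np.all(np.diff(rate) >= -0.02)  # nondecreasing up to MC noise
        assert rate[-1] > rate[0] + 0.2

    def test_noiseless_choices_follow_planted_axis_exactly(self):
        cfg = SessionConfig(psychometric_noise=0.0, n_blocks=2,
                            change_trials_per_block=30)
        sess = gen_session(cfg, seed=3)
        df = sess.presentations
        ch = df[df["change_amount"] > 0]
        d = sess.counts[ch.index] @ sess.planted_axis
        expect = (d > sess.params["threshold"]).astype(int)
        np.testing.assert_array_equal(ch["choice"].to_numpy(), expect)

    def test_csv_roundtrip(self, small_session_config, tmp_path):
        sess = gen_session(small_session_config, seed=4)
        sess.to_csv(tmp_path / "s.csv", tmp_path / "s.json")
        from v4popcode.synthetic import SyntheticSession
        back = SyntheticSession.from_csv(tmp_path / "s.csv",
                                         tmp_path / "s.json")
        np.testing.assert_allclose(back.counts, sess.counts)
        np.testing.assert_allclose(back.planted_axis, sess.planted_axis)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2 ** 20), n_units=st.integers(3, 12),
       sd=st.floats(0, 0.4))
def test_ring_generator_reproducible_and_nonnegative(seed, n_units, sd):
    p = RingModelParams(n_units=n_units, radial_noise_sd=sd)
    a = gen_ring_responses(p, [0.0, 0.5], 4, seed=seed)
    b = gen_ring_responses(p, [0.0, 0.5], 4, seed=seed)
    np.testing.assert_array_equal(a.counts, b.counts)
    assert np.all(a.counts >= 0)
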