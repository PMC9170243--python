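"""Orientation map, Gabor/OU front end, and the spiking network."""

import warnings

import numpy as np
import pytest

from v4popcode.circuit import (
    GaborFilterBank,
    GaborStimulusParams,
    NetworkConfig,
    OUNoise,
    ProtocolConfig,
    attention_params,
    build_and_simulate,
    gabor_image,
    make_orientation_map,
    paper_parameters,
    prepare_network,
    simulate_l4,
)
from v4popcode.circuit.network import RecurrentLayerParams


def tiny_config(total_ms=2000.0, **kw) -> NetworkConfig:
    """A miniature network for fast structural tests."""
    return NetworkConfig(l4_side=12, e_side=8, i_side=4,
                         protocol=ProtocolConfig(total_ms=total_ms), **kw)


class TestOrientationMap:
    def test_range_and_determinism(self):
        a = make_orientation_map(0.2, grid_side=16, seed=3)
        b = make_orientation_map(0.2, grid_side=16, seed=3)
        assert np.all((a.preferred_orientation >= 0)
                      & (a.preferred_orientation < 1))
        np.testing.assert_array_equal(a.preferred_orientation,
                                      b.preferred_orientation)
        c = make_orientation_map(0.2, grid_side=16, seed=4)
        assert not np.array_equal(a.preferred_orientation,
                                  c.preferred_orientation)

    def test_power_spectrum_peaks_at_column_frequency(self):
        m = make_orientation_map(0.2, grid_side=30, seed=0)
        p = np.abs(np.fft.fft2(m.field())) ** 2
        p[0, 0] = 0.0
        freqs = np.fft.fftfreq(30, d=1.0 / 30)
        fx, fy = np.meshgrid(freqs, freqs, indexing="ij")
        r = np.sqrt(fx ** 2 + fy ** 2).ravel()
        bins = np.arange(0, 16)
        prof = [p.ravel()[(r >= b - 0.5) & (r < b + 0.5)].sum() for b in bins]
        peak = bins[int(np.argmax(prof))]
        assert abs(peak - 1.0 / 0.2) <= 1.0  # within one frequency bin

    def test_column_spacing_must_fit_domain(self):
        with pytest.raises(ValueError, match="columns"):
            make_orientation_map(1.5, grid_side=16, seed=0)


class TestOUNoise:
    def test_zero_amplitude_is_identity(self):
        ou = OUNoise((5, 5), tau_ms=40.0, sigma=0.0, seed=0)
        before = ou.state.copy()
        ou.step(1.0)
        np.testing.assert_array_equal(ou.state, before)

    def test_stationary_variance_matches_sde(self):
        # tau dEta = -Eta dt + sigma dW  =>  Var = sigma^2 / (2 tau)
        ou = OUNoise((2000,), tau_ms=40.0, sigma=3.5, seed=1)
        samples = ou.sample_trajectory(400, 5.0)
        assert samples.var() == pytest.approx(3.5 ** 2 / (2 * 40.0), rel=0.05)

    def test_autocorrelation_decays_exponentially(self):
        ou = OUNoise((1,), tau_ms=40.0, sigma=3.5, seed=2)
        x = ou.sample_trajectory(10000, 1.0).ravel()  # 10 s trace
        x = x - x.mean()
        ac = np.correlate(x, x, "full")[x.size - 1:]
        ac /= ac[0]
        for lag in (20, 40, 80):
            assert ac[lag] == pytest.approx(np.exp(-lag / 40.0), abs=0.08)


class TestGaborFrontEnd:
    def test_image_matches_stimulus_parameters(self):
        img = gabor_image(0.0)
        assert img.shape == (25, 25)
        assert np.abs(img).max() <= 1.0
        # orientation rotates the carrier: images differ
        assert not np.allclose(img, gabor_image(0.25))

    def test_calibrated_on_rate_and_off_rate(self):
        m = make_orientation_map(0.2, grid_side=12, seed=0)
        bank = GaborFilterBank(m)
        bank.calibrate(target_hz=10.0, n_orientations=20, seed=0)
        proto = ProtocolConfig(total_ms=5000.0)
        thetas = np.arange(proto.n_intervals) / proto.n_intervals
        counts, _ = simulate_l4(bank, proto, thetas, seed=1)
        on = np.zeros(counts.shape[1], bool)
        for a, b in proto.on_windows():
            on[int(a): int(b)] = True
        on_rate = counts[:, on].sum() / (bank.n_units * on.sum() / 1000.0)
        off_rate = counts[:, ~on].sum() / (bank.n_units * (~on).sum() / 1000.0)
        assert on_rate == pytest.approx(10.0, abs=1.0)
        assert off_rate == pytest.approx(5.0, abs=0.5)

    def test_uncalibrated_bank_refuses_rates(self):
        m = make_orientation_map(0.2, grid_side=12, seed=0)
        with pytest.raises(RuntimeError, match="calibrate"):
            GaborFilterBank(m).rates(0.5)


class TestAttentionParams:
    def test_printed_endpoints(self):
        assert attention_params(0.0) == (20.0, 0.0)
        assert attention_params(1.0) == (23.0, 0.5)

    def test_linear_midpoint(self):
        gamma, mu = attention_params(0.5)
        assert gamma == pytest.approx(21.5)
        assert mu == pytest.approx(0.25)

    def test_monotone_in_level(self):
        levels = np.linspace(0, 1, 7)
        gammas, mus = zip(*(attention_params(v) for v in levels))
        assert np.all(np.diff(gammas) >= 0)
        assert np.all(np.diff(mus) >= 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.01, 2.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            attention_params(bad)


class TestNetworkSimulation:
    def test_seeded_determinism(self):
        cfg = tiny_config()
        omap = make_orientation_map(0.2, grid_side=cfg.l4_side, seed=0)
        bank, conn = prepare_network(cfg, omap)
        thetas = np.full(cfg.protocol.n_intervals, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra, ta = build_and_simulate(cfg, omap, 0.5, thetas, seed=9,
                                        bank=bank, conn=conn)
            rb, tb = build_and_simulate(cfg, omap, 0.5, thetas, seed=9,
                                        bank=bank, conn=conn)
        np.testing.assert_array_equal(ta.counts, tb.counts)
        np.testing.assert_array_equal(ra.layers["V4"][0], rb.layers["V4"][0])

    def test_first_interval_dropped_and_labels_match(self):
        cfg = tiny_config()
        omap = make_orientation_map(0.2, grid_side=cfg.l4_side, seed=0)
        bank, conn = prepare_network(cfg, omap)
        n_on = cfg.protocol.n_intervals
        thetas = np.arange(n_on) / n_on
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, tm = build_and_simulate(cfg, omap, 0.0, thetas, seed=1,
                                       bank=bank, conn=conn)
        assert tm.n_trials == n_on - 1
        np.testing.assert_allclose(tm.theta, thetas[1:])
        assert tm.n_units == cfg.n_e

    def test_zero_feedforward_removes_orientation_information(self):
        cfg = tiny_config(total_ms=4000.0, gamma_unattended=0.0,
                          gamma_attended=0.0)
        omap = make_orientation_map(0.2, grid_side=cfg.l4_side, seed=0)
        bank, conn = prepare_network(cfg, omap)
        n_on = cfg.protocol.n_intervals
        thetas = np.tile([0.2, 0.7], n_on // 2 + 1)[:n_on]
        parts = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(6):
                _, tm = build_and_simulate(cfg, omap, 0.0, thetas, seed=s,
                                           bank=bank, conn=conn)
                parts.append(tm)
        from v4popcode.trialmatrix import TrialMatrix
        data = TrialMatrix.concat(parts)
        a = data.condition(theta=0.2).counts
        b = data.condition(theta=0.7).counts
        # per-unit two-sample t statistics stay at chance level
        pooled = np.sqrt(a.var(0) / a.shape[0] + b.var(0) / b.shape[0]) + 1e-9
        t = (a.mean(0) - b.mean(0)) / pooled
        assert np.mean(np.abs(t) > 2) < 0.15

    def test_paper_parameter_record_is_complete(self):
        rec = paper_parameters()
        assert rec["orientation_map"]["column_spacing"] == 0.2
        assert rec["stimulus"]["ou_tau_ms"] == 40.0
        assert rec["network"]["gamma_range_mv"] == [20.0, 23.0]
        assert rec["network"]["dt_ms"] == 0.01
        assert rec["specific_decoder"]["dtheta"] == 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(dt_ms=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(alpha_ffwd3=-1.0)
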