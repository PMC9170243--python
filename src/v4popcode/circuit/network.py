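"""Recurrent EIF network layers and the three-stage attention model.

The model stacks a Poisson L4 front end (see :mod:`.gabor`) and two
recurrently coupled excitatory/inhibitory layers of exponential
integrate-and-fire neurons — V1 L2/3 and V4 — on spatial grids covering the
periodic unit square Γ.  Connection probability decays with wrapped-Gaussian
distance.  Attention acts only on V4: the feedforward strength from V1
scales as [J_eF3, J_iF3] = γ·[1, 0.4] with γ interpolating 20→23 mV from the
most unattended to the most attended state, and a depolarizing current
μ_i interpolating 0→0.5 mV/ms is injected into V4 inhibitory neurons.

Single-neuron and recurrent-coupling constants are adopted companion-model
defaults (the published description defers them to its reference network);
all are overridable through :class:`NetworkConfig`, and the printed
parameter set is recorded in ``configs/paper.json``.  The default layer
sizes and integration step are scaled down for desk-scale runs; paper-scale
values remain reachable via config.

Synaptic weights are specified in mV and divided by sqrt(presynaptic-layer
size), so jump amplitudes grow as layers shrink — the usual
fluctuation-driven scaling that keeps the scaled network in an
asynchronous, balanced-like regime.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from numba import njit

from ..trialmatrix import CountingWindow, TrialMatrix
from .gabor import GaborFilterBank, GaborStimulusParams, ProtocolConfig, simulate_l4
from .orientation_map import OrientationMap, square_grid

__all__ = [
    "EIFParams",
    "NetworkConfig",
    "SpikeRaster",
    "Connectivity",
    "attention_params",
    "build_connectivity",
    "prepare_network",
    "build_and_simulate",
    "paper_parameters",
]


@dataclass(frozen=True)
class EIFParams:
    """Exponential integrate-and-fire and synaptic constants (adopted defaults)."""

    tau_m_e: float = 15.0      # ms
    tau_m_i: float = 10.0
    e_leak: float = -60.0      # mV
    v_t: float = -50.0         # soft threshold
    v_spike: float = -10.0     # hard spike cutoff
    v_reset: float = -65.0
    delta_t_e: float = 2.0     # spike-initiation sharpness, mV
    delta_t_i: float = 0.5
    tau_ref_e: float = 1.5     # ms
    tau_ref_i: float = 0.5
    tau_syn_ffwd: float = 5.0  # feedforward PSC decay, ms


@dataclass(frozen=True)
class RecurrentLayerParams:
    """Recurrent coupling of one E/I layer (adopted, overridable defaults).

    Weights are in mV (divided by sqrt(layer size) at build time); in-degree
    fractions are of the presynaptic population.  The V4 defaults sit closer
    to the rate instability, with slower inhibitory synapses, so the layer
    generates slow low-dimensional rate fluctuations that depolarization of
    its inhibitory population can quench — the scaled-down analog of the
    correlated-variability state of the full-size model.
    """

    j_ee: float = 25.0
    j_ei: float = -150.0
    j_ie: float = 112.5
    j_ii: float = -250.0
    tau_syn_e: float = 5.0     # excitatory PSC decay, ms
    tau_syn_i: float = 8.0     # inhibitory PSC decay, ms
    alpha_rec: float = 0.10    # wrapped-Gaussian connection width on Γ
    alpha_rec_i: float | None = None   # width of I projections (defaults to
                                       # alpha_rec; narrow = local tracking)
    p_from_e: float = 0.10     # in-degree fraction from the E population
    p_from_i: float = 0.30
    mu_bg_e: float = 0.0       # static background currents, mV/ms
    mu_bg_i: float = 0.0
    het_mu_sd: float = 0.0     # SD of fixed per-neuron background jitter,
                               # mV/ms (quenched heterogeneity; desynchronizes)
    frac_slow_ee: float = 0.0  # fraction of E->E charge through a slow
                               # (NMDA-like) synapse
    tau_syn_slow: float = 100.0  # slow E->E decay, ms
    # shared slow modulatory current into the E population (OU process),
    # standing in for the internally generated low-dimensional variability
    # of the full-size network, which needs cluster-scale N to emerge;
    # its amplitude is attention-independent — attention acts on it only
    # through the inhibitory operating point
    shared_noise_sd: float = 0.0    # stationary SD, mV/ms
    shared_noise_tau: float = 150.0  # OU timescale, ms


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of the three-stage model (scaled defaults)."""

    l4_side: int = 30
    e_side: int = 20           # E grid side per recurrent layer
    i_side: int = 10           # I grid side per recurrent layer
    dt_ms: float = 0.05
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    stimulus: GaborStimulusParams = field(default_factory=GaborStimulusParams)
    eif: EIFParams = field(default_factory=EIFParams)

    # connection-probability widths on Γ (wrapped Gaussian SD)
    alpha_ffwd2: float = 0.05   # L4 -> V1 L2/3
    alpha_ffwd3: float = 0.05   # V1 L2/3 -> V4 (printed value)

    # in-degree fractions of the presynaptic population
    p_ffwd2: float = 0.10
    p_ffwd3: float = 0.50
    p_ffwd3_i: float | None = 0.30   # V1->V4 in-degree for I targets
                                     # (None: same as p_ffwd3)

    # recurrent coupling per layer
    v1: RecurrentLayerParams = field(default_factory=RecurrentLayerParams)
    v4: RecurrentLayerParams = field(default_factory=lambda:
                                     RecurrentLayerParams(
                                         j_ee=12.0, j_ei=-180.0, j_ie=250.0,
                                         j_ii=-100.0, alpha_rec=0.5,
                                         p_from_e=0.2, p_from_i=0.5,
                                         mu_bg_i=-2.5,
                                         shared_noise_sd=0.6,
                                         shared_noise_tau=150.0))

    # feedforward strengths, mV (divided by sqrt(presynaptic layer size))
    j_e_ffwd2: float = 140.0
    j_i_ffwd2: float = 100.0
    ffwd3_i_ratio: float = 0.4          # [JeF3, JiF3] = gamma * [1, ratio]
    ffwd3_scale: float = 2.2            # scaled-down compensation so the
                                        # feedforward current keeps its
                                        # full-size O(sqrt(N)) dominance

    # attention endpoints (printed values)
    gamma_unattended: float = 20.0      # mV
    gamma_attended: float = 23.0
    mu_i_unattended: float = 0.0        # mV/ms, V4 inhibitory depolarization
    mu_i_attended: float = 0.5

    rate_ceiling_hz: float = 200.0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        for name in ("alpha_ffwd2", "alpha_ffwd3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for layer in (self.v1, self.v4):
            if layer.alpha_rec <= 0:
                raise ValueError("alpha_rec must be > 0")

    @property
    def n_e(self) -> int:
        return self.e_side ** 2

    @property
    def n_i(self) -> int:
        return self.i_side ** 2

    @property
    def n_l4(self) -> int:
        return self.l4_side ** 2


def attention_params(level: float,
                     gamma_range: tuple[float, float] = (20.0, 23.0),
                     mu_i_range: tuple[float, float] = (0.0, 0.5),
                     ) -> tuple[float, float]:
    """Map an attentional modulation level in [0, 1] to (γ mV, μ_i mV/ms).

    Linear interpolation between the unattended (level 0) and attended
    (level 1) endpoints: γ 20→23 mV, μ_i 0→0.5 mV/ms by default.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"attention level must be in [0, 1], got {level}")
    gamma = gamma_range[0] + level * (gamma_range[1] - gamma_range[0])
    mu_i = mu_i_range[0] + level * (mu_i_range[1] - mu_i_range[0])
    return gamma, mu_i


@dataclass
class SpikeRaster:
    """Spike times (ms) per layer plus ON/OFF protocol markers."""

    layers: dict                       # name -> (times_ms, neuron_ids)
    on_windows: list                   # [(start_ms, stop_ms), ...]

    def to_frame(self):
        import pandas as pd
        parts = []
        for name, (t, ids) in self.layers.items():
            parts.append(pd.DataFrame(
                {"neuron": ids, "time_ms": t, "layer": name}))
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------- connectivity

def _wrapped_sq_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared torus distance between rows of a (n,2) and b (m,2): (n, m)."""
    d = np.abs(a[:, None, :] - b[None, :, :])
    d = np.minimum(d, 1.0 - d)
    return (d ** 2).sum(axis=-1)


def _sample_projection(pre_pos: np.ndarray, post_pos: np.ndarray, k_in: int,
                       alpha: float, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sample k_in presynaptic partners per postsynaptic neuron.

    Returns the projection inverted to presynaptic CSR form
    (offsets of length n_pre+1, concatenated target indices) for fast
    spike propagation.
    """
    n_pre = pre_pos.shape[0]
    n_post = post_pos.shape[0]
    k_in = min(k_in, n_pre)
    prob = np.exp(-_wrapped_sq_dist(post_pos, pre_pos) / (2 * alpha ** 2))
    prob /= prob.sum(axis=1, keepdims=True)
    pre_lists = [[] for _ in range(n_pre)]
    for j in range(n_post):
        chosen = rng.choice(n_pre, size=k_in, replace=False, p=prob[j])
        for c in chosen:
            pre_lists[c].append(j)
    offsets = np.zeros(n_pre + 1, dtype=np.int64)
    for i, lst in enumerate(pre_lists):
        offsets[i + 1] = offsets[i] + len(lst)
    idx = np.empty(offsets[-1], dtype=np.int32)
    for i, lst in enumerate(pre_lists):
        idx[offsets[i]: offsets[i + 1]] = lst
    return offsets, idx


@dataclass
class Connectivity:
    """All projections of one configuration, fixed across simulations."""

    # feedforward, presynaptic CSR; targets indexed into [E | I] of the layer
    l4_to_v1: tuple
    v1e_to_v4: tuple
    # recurrent per layer: (offsets, idx, weights) over n_e + n_i neurons
    v1_rec: tuple
    v4_rec: tuple
    # per-edge feedforward weights are built at simulation time from gamma
    l4_weights: np.ndarray    # per-edge weights for l4_to_v1
    v4_ffwd_unit: np.ndarray  # per-edge weight for gamma = 1
    # quenched per-neuron background-current jitter (fixed per configuration)
    mu_het_v1: np.ndarray | None = None
    mu_het_v4: np.ndarray | None = None


def _build_recurrent(cfg: NetworkConfig, lp: RecurrentLayerParams,
                     e_pos, i_pos, rng):
    n_e, n_i = cfg.n_e, cfg.n_i
    norm = np.sqrt(n_e + n_i)
    k_e = int(round(lp.p_from_e * n_e))
    k_i = int(round(lp.p_from_i * n_i))
    alpha_i = lp.alpha_rec_i if lp.alpha_rec_i is not None else lp.alpha_rec
    pieces = []  # (pre_offset, csr, global targets, fast weight, slow weight)
    for pre_pos, pre_off, k, w_to_e, w_to_i, alpha in [
            (e_pos, 0, k_e, lp.j_ee, lp.j_ie, lp.alpha_rec),
            (i_pos, n_e, k_i, lp.j_ei, lp.j_ii, alpha_i)]:
        for post_pos, post_off, w in [(e_pos, 0, w_to_e),
                                      (i_pos, n_e, w_to_i)]:
            off, idx = _sample_projection(pre_pos, post_pos, k, alpha, rng)
            slow = 0.0
            if pre_off == 0 and post_off == 0 and lp.frac_slow_ee > 0:
                slow = w * lp.frac_slow_ee / norm
                w = w * (1.0 - lp.frac_slow_ee)
            pieces.append((pre_off, off, idx + post_off, w / norm, slow))
    n = n_e + n_i
    per_pre = [[] for _ in range(n)]
    for pre_off, off, idx, w, ws in pieces:
        n_pre = off.size - 1
        for i in range(n_pre):
            for e in range(off[i], off[i + 1]):
                per_pre[pre_off + i].append((idx[e], w, ws))
    offsets = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        offsets[i + 1] = offsets[i] + len(per_pre[i])
    ridx = np.empty(offsets[-1], dtype=np.int32)
    rw = np.empty(offsets[-1])
    rws = np.empty(offsets[-1])
    for i in range(n):
        for j, (k, w, ws) in enumerate(per_pre[i]):
            ridx[offsets[i] + j] = k
            rw[offsets[i] + j] = w
            rws[offsets[i] + j] = ws
    return offsets, ridx, rw, rws


def _build_ffwd(cfg, pre_pos, e_pos, i_pos, k_in, alpha, w_e, w_i, rng,
                k_in_i: int | None = None):
    """Feedforward projection to a layer; returns CSR + per-edge weights."""
    n_e = e_pos.shape[0]
    off_e, idx_e = _sample_projection(pre_pos, e_pos, k_in, alpha, rng)
    off_i, idx_i = _sample_projection(pre_pos, i_pos,
                                      k_in if k_in_i is None else k_in_i,
                                      alpha, rng)
    n_pre = pre_pos.shape[0]
    offsets = np.zeros(n_pre + 1, dtype=np.int64)
    for i in range(n_pre):
        offsets[i + 1] = (offsets[i] + (off_e[i + 1] - off_e[i])
                          + (off_i[i + 1] - off_i[i]))
    idx = np.empty(offsets[-1], dtype=np.int32)
    w = np.empty(offsets[-1])
    for i in range(n_pre):
        a = offsets[i]
        ne = off_e[i + 1] - off_e[i]
        ni = off_i[i + 1] - off_i[i]
        idx[a: a + ne] = idx_e[off_e[i]: off_e[i + 1]]
        w[a: a + ne] = w_e
        idx[a + ne: a + ne + ni] = idx_i[off_i[i]: off_i[i + 1]] + n_e
        w[a + ne: a + ne + ni] = w_i
    return (offsets, idx), w


def build_connectivity(cfg: NetworkConfig, seed: int = 0) -> Connectivity:
    """Draw all connection matrices once for a configuration."""
    rng = np.random.default_rng(seed)
    l4_pos = square_grid(cfg.l4_side)
    e_pos = square_grid(cfg.e_side)
    i_pos = square_grid(cfg.i_side)
    norm4 = np.sqrt(cfg.n_l4)
    k_f2 = int(round(cfg.p_ffwd2 * cfg.n_l4))
    l4_to_v1, l4_w = _build_ffwd(cfg, l4_pos, e_pos, i_pos, k_f2,
                                 cfg.alpha_ffwd2, cfg.j_e_ffwd2 / norm4,
                                 cfg.j_i_ffwd2 / norm4, rng)
    v1_rec = _build_recurrent(cfg, cfg.v1, e_pos, i_pos, rng)
    norm_v1e = np.sqrt(cfg.n_e)
    k_f3 = int(round(cfg.p_ffwd3 * cfg.n_e))
    k_f3_i = None if cfg.p_ffwd3_i is None \
        else int(round(cfg.p_ffwd3_i * cfg.n_e))
    v1e_to_v4, v4_w_unit = _build_ffwd(
        cfg, e_pos, e_pos, i_pos, k_f3, cfg.alpha_ffwd3,
        cfg.ffwd3_scale / norm_v1e,
        cfg.ffwd3_scale * cfg.ffwd3_i_ratio / norm_v1e, rng, k_in_i=k_f3_i)
    v4_rec = _build_recurrent(cfg, cfg.v4, e_pos, i_pos, rng)
    if l4_to_v1[0][-1] == 0 or v1e_to_v4[0][-1] == 0:
        warnings.warn("network has no feedforward connections",
                      RuntimeWarning, stacklevel=2)
    n = cfg.n_e + cfg.n_i
    het = [lp.het_mu_sd * rng.standard_normal(n) if lp.het_mu_sd > 0
           else np.zeros(n) for lp in (cfg.v1, cfg.v4)]
    return Connectivity(l4_to_v1=l4_to_v1, v1e_to_v4=v1e_to_v4,
                        v1_rec=v1_rec, v4_rec=v4_rec,
                        l4_weights=l4_w, v4_ffwd_unit=v4_w_unit,
                        mu_het_v1=het[0], mu_het_v4=het[1])


# ------------------------------------------------------------------ kernel

@njit(cache=True)
def _sim_layer(n_e, n, dt, n_steps, steps_per_ms,
               v, tau_m, delta_t, ref_steps, mu_ext,
               e_leak, v_t, v_spike, v_reset,
               dec_e, dec_i, dec_f, dec_s,
               inv_tau_e, inv_tau_i, inv_tau_f, inv_tau_s,
               rec_off, rec_idx, rec_w, rec_ws,
               ff_counts, ff_off, ff_idx, ff_w,
               sh_series, sh_gain,
               max_spikes):
    x_e = np.zeros(n)
    x_i = np.zeros(n)
    x_f = np.zeros(n)
    x_s = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    spk_step = np.empty(max_spikes, dtype=np.int64)
    spk_id = np.empty(max_spikes, dtype=np.int32)
    ns = 0
    blowup = -1
    n_in = ff_counts.shape[0]
    sh_now = 0.0
    for step in range(n_steps):
        if step % steps_per_ms == 0:
            ms = step // steps_per_ms
            sh_now = sh_series[ms]
            for j in range(n_in):
                c = ff_counts[j, ms]
                if c > 0:
                    for e in range(ff_off[j], ff_off[j + 1]):
                        x_f[ff_idx[e]] += c * ff_w[e] * inv_tau_f
        for i in range(n):
            x_e[i] *= dec_e
            x_i[i] *= dec_i
            x_f[i] *= dec_f
            x_s[i] *= dec_s
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                continue
            arg = (v[i] - v_t) / delta_t[i]
            if arg > 20.0:
                arg = 20.0
            dv = ((-(v[i] - e_leak) + delta_t[i] * np.exp(arg)) / tau_m[i]
                  + x_e[i] + x_i[i] + x_f[i] + x_s[i] + mu_ext[i]
                  + sh_gain[i] * sh_now)
            v[i] += dt * dv
            if v[i] >= v_spike:
                if ns < max_spikes:
                    spk_step[ns] = step
                    spk_id[ns] = i
                ns += 1
                v[i] = v_reset
                refr[i] = ref_steps[i]
                for e in range(rec_off[i], rec_off[i + 1]):
                    k = rec_idx[e]
                    w = rec_w[e]
                    if w >= 0.0:
                        x_e[k] += w * inv_tau_e
                    else:
                        x_i[k] += w * inv_tau_i
                    ws = rec_ws[e]
                    if ws > 0.0:
                        x_s[k] += ws * inv_tau_s
        if (step & 8191) == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    blowup = step
                    break
            if blowup >= 0:
                break
    m = ns if ns < max_spikes else max_spikes
    return spk_step[:m], spk_id[:m], ns, blowup


def _run_layer(cfg: NetworkConfig, lp: RecurrentLayerParams, rec, ff, ff_w,
               ff_counts, mu_e: float, mu_i: float,
               rng: np.random.Generator, mu_het: np.ndarray | None = None):
    """Simulate one E/I layer for the whole protocol; spikes as (steps, ids)."""
    eif = cfg.eif
    n_e, n_i = cfg.n_e, cfg.n_i
    n = n_e + n_i
    dt = cfg.dt_ms
    steps_per_ms = int(round(1.0 / dt))
    n_steps = int(round(cfg.protocol.total_ms)) * steps_per_ms
    tau_m = np.where(np.arange(n) < n_e, eif.tau_m_e, eif.tau_m_i)
    delta_t = np.where(np.arange(n) < n_e, eif.delta_t_e, eif.delta_t_i)
    ref_steps = np.where(np.arange(n) < n_e,
                         int(round(eif.tau_ref_e / dt)),
                         int(round(eif.tau_ref_i / dt))).astype(np.int64)
    mu_ext = np.where(np.arange(n) < n_e, mu_e, mu_i)
    if mu_het is not None:
        mu_ext = mu_ext + mu_het
    v0 = rng.uniform(eif.v_reset, eif.v_t, size=n)
    n_ms = int(round(cfg.protocol.total_ms))
    if lp.shared_noise_sd > 0:
        a = np.exp(-1.0 / lp.shared_noise_tau)
        incr = rng.standard_normal(n_ms) * lp.shared_noise_sd * np.sqrt(1 - a * a)
        sh_series = np.empty(n_ms)
        x = rng.standard_normal() * lp.shared_noise_sd
        for t in range(n_ms):
            x = a * x + incr[t]
            sh_series[t] = x
    else:
        sh_series = np.zeros(n_ms)
    sh_gain = np.where(np.arange(n) < n_e, 1.0, 0.0)
    max_spikes = int(n * cfg.protocol.total_ms / 1000.0
                     * max(cfg.rate_ceiling_hz * 2.5, 500.0))
    spk_step, spk_id, ns, blowup = _sim_layer(
        n_e, n, dt, n_steps, steps_per_ms,
        v0, tau_m, delta_t, ref_steps, mu_ext,
        eif.e_leak, eif.v_t, eif.v_spike, eif.v_reset,
        np.exp(-dt / lp.tau_syn_e), np.exp(-dt / lp.tau_syn_i),
        np.exp(-dt / eif.tau_syn_ffwd), np.exp(-dt / lp.tau_syn_slow),
        1.0 / lp.tau_syn_e, 1.0 / lp.tau_syn_i, 1.0 / eif.tau_syn_ffwd,
        1.0 / lp.tau_syn_slow,
        rec[0], rec[1], rec[2], rec[3],
        ff_counts, ff[0], ff[1], ff_w,
        sh_series, sh_gain,
        max_spikes)
    if blowup >= 0:
        raise RuntimeError(
            f"membrane potential became non-finite at step {blowup} "
            f"(t = {blowup * dt:.2f} ms)")
    if ns > spk_step.size:
        raise RuntimeError(
            f"spike buffer overflow ({ns} spikes): network is in a "
            "pathological high-rate regime")
    return spk_step, spk_id


def _bin_spikes_ms(spk_step, spk_id, n_units, total_ms, steps_per_ms,
                   unit_slice) -> np.ndarray:
    """Bin a subset of units' spikes into 1-ms bins (units x ms)."""
    sel = (spk_id >= unit_slice.start) & (spk_id < unit_slice.stop)
    ids = spk_id[sel] - unit_slice.start
    ms = (spk_step[sel] // steps_per_ms).astype(np.int64)
    counts = np.zeros((unit_slice.stop - unit_slice.start, int(total_ms)),
                      dtype=np.int32)
    np.add.at(counts, (ids, ms), 1)
    return counts


def prepare_network(cfg: NetworkConfig, omap: OrientationMap,
                    conn_seed: int = 0, calibration_seed: int = 0,
                    target_hz: float = 10.0
                    ) -> tuple[GaborFilterBank, Connectivity]:
    """Build and calibrate the filter bank and draw the fixed connectivity."""
    bank = GaborFilterBank(omap, cfg.stimulus)
    bank.calibrate(target_hz=target_hz, seed=calibration_seed)
    conn = build_connectivity(cfg, seed=conn_seed)
    return bank, conn


def build_and_simulate(cfg: NetworkConfig, omap: OrientationMap,
                       attention_level: float,
                       orientation_sequence: np.ndarray, seed: int,
                       bank: GaborFilterBank | None = None,
                       conn: Connectivity | None = None,
                       record_v1: bool = False
                       ) -> tuple[SpikeRaster, TrialMatrix]:
    """Run one full protocol simulation and return ON-interval spike counts.

    Connectivity is fixed per configuration (pass ``conn`` to reuse it across
    simulations); membrane potentials and all spiking noise are randomized
    per simulation via ``seed``.  The returned TrialMatrix holds V4
    excitatory spike counts per ON interval with the first interval dropped,
    labelled by the interval's orientation and the attention level.
    """
    gamma, mu_i_att = attention_params(
        attention_level,
        gamma_range=(cfg.gamma_unattended, cfg.gamma_attended),
        mu_i_range=(cfg.mu_i_unattended, cfg.mu_i_attended))
    if bank is None or conn is None:
        b2, c2 = prepare_network(cfg, omap)
        bank = bank or b2
        conn = conn or c2
    rng = np.random.default_rng(seed)
    steps_per_ms = int(round(1.0 / cfg.dt_ms))
    total_ms = int(round(cfg.protocol.total_ms))

    l4_counts, thetas = simulate_l4(bank, cfg.protocol, orientation_sequence,
                                    seed=int(rng.integers(2 ** 31)))
    v1_steps, v1_ids = _run_layer(cfg, cfg.v1, conn.v1_rec, conn.l4_to_v1,
                                  conn.l4_weights, l4_counts,
                                  cfg.v1.mu_bg_e, cfg.v1.mu_bg_i, rng,
                                  mu_het=conn.mu_het_v1)
    v1e_counts = _bin_spikes_ms(v1_steps, v1_ids, cfg.n_e, total_ms,
                                steps_per_ms, slice(0, cfg.n_e))
    v4_steps, v4_ids = _run_layer(cfg, cfg.v4, conn.v4_rec, conn.v1e_to_v4,
                                  gamma * conn.v4_ffwd_unit, v1e_counts,
                                  cfg.v4.mu_bg_e, cfg.v4.mu_bg_i + mu_i_att,
                                  rng, mu_het=conn.mu_het_v4)

    on_windows = cfg.protocol.on_windows()
    v4e_ms = _bin_spikes_ms(v4_steps, v4_ids, cfg.n_e, total_ms,
                            steps_per_ms, slice(0, cfg.n_e))
    counts = np.stack([
        v4e_ms[:, int(t0): int(t1)].sum(axis=1)
        for (t0, t1) in on_windows], axis=0).astype(float)
    # the first spike count of each simulation is excluded
    tm = TrialMatrix(
        counts=counts[1:],
        theta=np.asarray(thetas[1: len(on_windows)]) % 1.0,
        attention=np.full(len(on_windows) - 1, attention_level),
        window=CountingWindow(0.0, cfg.protocol.on_ms, "on-interval"),
    )
    rates = counts.sum(axis=0) / (len(on_windows) * cfg.protocol.on_ms / 1000.0)
    if np.any(rates > cfg.rate_ceiling_hz):
        k = int((rates > cfg.rate_ceiling_hz).sum())
        warnings.warn(
            f"{k} V4 E neurons exceed the {cfg.rate_ceiling_hz:.0f} Hz "
            "rate ceiling during ON intervals", RuntimeWarning, stacklevel=2)
    layers = {"V4": (v4_steps * cfg.dt_ms, v4_ids)}
    if record_v1:
        layers["V1"] = (v1_steps * cfg.dt_ms, v1_ids)
        l4_ids, l4_ms = np.nonzero(l4_counts)
        layers["L4"] = (l4_ms.astype(float), l4_ids.astype(np.int32))
    raster = SpikeRaster(layers=layers, on_windows=on_windows)
    return raster, tm


def paper_parameters() -> dict:
    """The printed parameter record bundled with the package."""
    with resources.files("v4popcode.configs").joinpath(
            "paper.json").open() as fh:
        return json.load(fh)
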