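"""Synthetic inputs for the decoding and correlated-variability analyses.

Three generators:

* a parametric *ring model* of an orientation-tuned population whose shared
  ("radial") variability is a rank-1 multiplicative gain fluctuation, scaled
  down by attention — a fast surrogate for the spiking circuit model;
* multivariate-Gaussian two-condition populations with known linear Fisher
  information, used as analytic oracles for the bias-corrected estimator;
* full behavioral sessions emulating a cued orientation-change-detection
  experiment, with choices generated from a planted linear readout axis.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trialmatrix import CountingWindow, TrialMatrix

__all__ = [
    "RingModelParams",
    "SessionConfig",
    "SyntheticSession",
    "ring_tuning",
    "ring_tuning_derivative",
    "gen_ring_responses",
    "expected_rank1_correlation",
    "gen_gaussian_population",
    "gen_session",
    "shuffle_trials",
]


# --------------------------------------------------------------------- ring

def circ_dist(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """Circular distance on the normalized ring [0, 1); result in [0, 0.5]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 1.0
    return np.minimum(d, 1.0 - d)


@dataclass(frozen=True)
class RingModelParams:
    """Parameters of the rank-1 gain ring model.

    The mean response of unit *i* to orientation θ is a wrapped-Gaussian bump

        f_i(θ) = baseline + tuning_amplitude * exp(-d(θ, φ_i)^2 / (2 w^2))

    with d the circular distance and φ_i the unit's preferred orientation.
    On each trial every unit's mean is multiplied by (1 + g) with a single
    shared Gaussian gain g of standard deviation
    ``radial_noise_sd * (1 - attention_gain_factor * attention_level)``,
    so the shared fluctuation points along the "radial" direction f(θ) of
    the population ring, and attention shrinks it.  Independent Gaussian
    noise of SD ``private_noise_sd`` is added per unit, and counts are
    truncated at zero (a deliberate departure from exact Gaussianity,
    negligible at the default operating point).
    """

    n_units: int = 100
    preferred_orientations: np.ndarray | None = None
    tuning_amplitude: float = 10.0
    tuning_width: float = 0.12
    baseline: float = 4.0
    radial_noise_sd: float = 0.25
    private_noise_sd: float = 2.0
    attention_level: float = 0.0
    attention_gain_factor: float = 0.5  # "c": shared SD shrinks by c per unit level

    def __post_init__(self):
        for name in ("tuning_amplitude", "tuning_width", "baseline",
                     "radial_noise_sd", "private_noise_sd",
                     "attention_level", "attention_gain_factor"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"RingModelParams.{name} is not finite")
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.radial_noise_sd < 0 or self.private_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.attention_level <= 1.0:
            raise ValueError("attention_level must be in [0, 1]")
        if self.preferred_orientations is not None:
            pref = np.asarray(self.preferred_orientations, dtype=float)
            if pref.shape != (self.n_units,):
                raise ValueError("preferred_orientations must have length n_units")
            if np.any((pref < 0) | (pref >= 1)):
                raise ValueError("preferred orientations must lie in [0, 1)")
            gaps = np.diff(np.concatenate([np.sort(pref), [np.sort(pref)[0] + 1]]))
            if gaps.max() >= 0.5:
                raise ValueError("preferred orientations must cover the ring "
                                 "(largest gap >= 0.5)")
            object.__setattr__(self, "preferred_orientations", pref)

    def prefs(self) -> np.ndarray:
        if self.preferred_orientations is not None:
            return self.preferred_orientations
        return np.arange(self.n_units) / self.n_units

    @property
    def effective_radial_sd(self) -> float:
        return self.radial_noise_sd * (
            1.0 - self.attention_gain_factor * self.attention_level)


def ring_tuning(params: RingModelParams, theta) -> np.ndarray:
    """Mean response vector(s) f(θ); shape (..., n_units)."""
    theta = np.asarray(theta, dtype=float)
    d = circ_dist(theta[..., None], params.prefs())
    return params.baseline + params.tuning_amplitude * np.exp(
        -(d ** 2) / (2.0 * params.tuning_width ** 2))


def ring_tuning_derivative(params: RingModelParams, theta,
                           dtheta: float = 1e-4) -> np.ndarray:
    """Central-difference tuning derivative f'(θ)."""
    return (ring_tuning(params, np.asarray(theta) + dtheta)
            - ring_tuning(params, np.asarray(theta) - dtheta)) / (2 * dtheta)


def gen_ring_responses(params: RingModelParams, thetas: Sequence[float],
                       trials_per_theta: int, seed: int) -> TrialMatrix:
    """Sample trials from the rank-1 gain ring model.

    Counts are ``f(θ) * (1 + g_t) + ε`` truncated at zero, with g_t shared
    across units within a trial.  Trials are grouped by orientation in the
    order given.
    """
    if trials_per_theta < 2:
        raise ValueError("trials_per_theta must be >= 2")
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    sd_g = params.effective_radial_sd
    blocks, labels = [], []
    for th in thetas:
        f = ring_tuning(params, th)
        g = rng.normal(0.0, sd_g, size=(trials_per_theta, 1)) if sd_g > 0 \
            else np.zeros((trials_per_theta, 1))
        eps = rng.normal(0.0, params.private_noise_sd,
                         size=(trials_per_theta, params.n_units)) \
            if params.private_noise_sd > 0 else 0.0
        counts = np.maximum(f[None, :] * (1.0 + g) + eps, 0.0)
        blocks.append(counts)
        labels.append(np.full(trials_per_theta, th % 1.0))
    return TrialMatrix(
        counts=np.vstack(blocks),
        theta=np.concatenate(labels),
        attention=np.full(len(thetas) * trials_per_theta, params.attention_level),
    )


def expected_rank1_correlation(params: RingModelParams, theta: float) -> np.ndarray:
    """Analytic noise-correlation matrix of the (untruncated) rank-1 model.

    Cov = sd_g^2 f f^T + sd_p^2 I, hence
    ρ_ij = sd_g^2 f_i f_j / sqrt((sd_g^2 f_i^2 + sd_p^2)(sd_g^2 f_j^2 + sd_p^2)).
    """
    f = ring_tuning(params, theta)
    v = params.effective_radial_sd ** 2 * np.outer(f, f)
    s = np.sqrt(np.diag(v) + params.private_noise_sd ** 2)
    rho = v / np.outer(s, s)
    np.fill_diagonal(rho, 1.0)
    return rho


# ----------------------------------------------------------------- gaussian

def gen_gaussian_population(f_plus: np.ndarray, f_minus: np.ndarray,
                            covariance: np.ndarray, trials_per_condition: int,
                            seed: int,
                            theta_pair: tuple[float, float] = (0.49, 0.51),
                            ) -> TrialMatrix:
    """Two equal-size multivariate-normal condition blocks (Fisher oracle input).

    The condition with mean ``f_minus`` is labelled ``theta_pair[0]`` and the
    one with ``f_plus`` is labelled ``theta_pair[1]``.
    """
    f_plus = np.asarray(f_plus, dtype=float)
    f_minus = np.asarray(f_minus, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    n = f_plus.size
    if f_minus.shape != (n,) or covariance.shape != (n, n):
        raise ValueError("dimension mismatch between means and covariance")
    if not np.allclose(covariance, covariance.T):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(covariance)
    if evals[0] <= 0:
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue "
            f"{evals[0]:.3g})")
    rng = np.random.default_rng(seed)
    lo = rng.multivariate_normal(f_minus, covariance, size=trials_per_condition,
                                 method="cholesky")
    hi = rng.multivariate_normal(f_plus, covariance, size=trials_per_condition,
                                 method="cholesky")
    return TrialMatrix(
        counts=np.vstack([lo, hi]),
        theta=np.concatenate([np.full(trials_per_condition, theta_pair[0]),
                              np.full(trials_per_condition, theta_pair[1])]),
    )


# ------------------------------------------------------------------ shuffle

def shuffle_trials(data: TrialMatrix, seed: int) -> TrialMatrix:
    """Independently permute each unit's counts within each condition.

    Destroys trial-to-trial correlations between units while preserving every
    unit's marginal count distribution per (orientation, attention) condition
    — the control used to show that correlated variability, not single-unit
    statistics, drives the decoder effects.
    """
    rng = np.random.default_rng(seed)
    counts = data.counts.copy()
    keys = list(zip(np.round(data.theta, 9), data.attention))
    df = pd.DataFrame({"k": pd.Categorical([str(k) for k in keys])})
    for _, idx in df.groupby("k", observed=True).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError("need >= 2 trials per condition to shuffle")
        for j in range(data.n_units):
            counts[idx, j] = counts[rng.permutation(idx), j]
    return TrialMatrix(counts=counts, theta=data.theta.copy(),
                       attention=data.attention.copy(),
                       choice=None if data.choice is None else data.choice.copy(),
                       block=None if data.block is None else data.block.copy(),
                       window=data.window)


# ------------------------------------------------------------------ session

@dataclass(frozen=True)
class SessionConfig:
    """Parameters of a synthetic cued change-detection session.

    A session is a sequence of blocks; the cue alternates between the
    recorded (RF) location and the opposite location.  Each block contains
    ``change_trials_per_block`` orientation-change trials, 80% of them at
    the cued location.  When the RF location is uncued, the changes it does
    receive are restricted to the median (20/block) and largest (5/block)
    amounts.  Choices are generated by thresholding a planted linear readout
    of the population response plus Gaussian noise.
    """

    ring: RingModelParams = field(default_factory=lambda: RingModelParams(
        n_units=24, tuning_amplitude=10.0, tuning_width=0.10, baseline=4.0,
        radial_noise_sd=0.20, private_noise_sd=2.0))
    start_theta: float = 0.30
    change_amounts: tuple[float, ...] = (0.03, 0.06, 0.10, 0.15, 0.21)
    n_blocks: int = 4              # a recording day: two cue-block pairs
    change_trials_per_block: int = 125
    cued_fraction: float = 0.8
    # None: scale with block size as in the real design (20 and 5 at 125
    # change trials), keeping cued and uncued median-change counts equal
    uncued_median_per_block: int | None = None
    uncued_largest_per_block: int | None = None
    max_presentations: int = 12
    presentation_continue_prob: float = 0.65
    psychometric_noise: float = 0.5   # SD of choice noise, in units of the
                                      # median-change signal along the axis
    planted_radial_mix: float = 0.35  # weight of the radial (gain) direction
                                      # in the default planted axis
    planted_axis: np.ndarray | None = None

    def __post_init__(self):
        ca = np.asarray(self.change_amounts, dtype=float)
        if ca.size != 5 or np.any(np.diff(ca) <= 0):
            raise ValueError("need exactly 5 strictly increasing change amounts")

    @property
    def n_uncued_median(self) -> int:
        if self.uncued_median_per_block is not None:
            return self.uncued_median_per_block
        return max(2, int(round(self.cued_fraction
                                * self.change_trials_per_block / 5)))

    @property
    def n_uncued_largest(self) -> int:
        if self.uncued_largest_per_block is not None:
            return self.uncued_largest_per_block
        return max(1, int(round(self.n_uncued_median / 4)))

    def resolved_axis(self) -> np.ndarray:
        """Planted readout axis (unit norm)."""
        if self.planted_axis is not None:
            a = np.asarray(self.planted_axis, dtype=float)
            return a / np.linalg.norm(a)
        ring = self.ring
        f0 = ring_tuning(ring, self.start_theta)
        fmed = ring_tuning(ring, self.start_theta + self.change_amounts[2])
        disc = fmed - f0
        disc = disc / np.linalg.norm(disc)
        rad = f0 / np.linalg.norm(f0)
        a = (1 - self.planted_radial_mix) * disc + self.planted_radial_mix * rad
        return a / np.linalg.norm(a)


@dataclass
class SyntheticSession:
    """One synthetic recording day: presentations, counts, and ground truth.

    ``presentations`` has one row per stimulus flash with columns
    ``block, trial, flash, theta, change_amount (0 = starting orientation,
    1..5 = change index), cued (RF cued in this block), choice (1 = saccade),
    correct, first_flash``.  ``counts`` is the matched (flashes x units)
    spike-count matrix.  ``params`` records the generative configuration,
    including the planted readout axis.
    """

    presentations: pd.DataFrame
    counts: np.ndarray
    params: dict
    #: per-trial pre-first-flash baseline counts (100 ms window), trials x units
    baseline_counts: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def planted_axis(self) -> np.ndarray:
        return np.asarray(self.params["planted_axis"], dtype=float)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = self.presentations.copy()
        for i in range(self.n_units):
            df[f"unit_{i}"] = self.counts[:, i]
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.params, fh, indent=1)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "SyntheticSession":
        df = pd.read_csv(path)
        unit_cols = sorted((c for c in df.columns if c.startswith("unit_")),
                           key=lambda c: int(c.split("_")[1]))
        counts = df[unit_cols].to_numpy(dtype=float)
        with open(sidecar_path) as fh:
            params = json.load(fh)
        return cls(df.drop(columns=unit_cols), counts, params)


def _block_change_schedule(cfg: SessionConfig, cued_at_rf: bool,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-trial change-amount index at the RF location (0 = change away)."""
    n = cfg.change_trials_per_block
    n_cued = int(round(cfg.cued_fraction * n))
    if cued_at_rf:
        # cued changes at RF spread evenly over the five amounts
        per = n_cued // 5
        amounts = np.concatenate([np.full(per, k + 1) for k in range(5)])
        extra = n_cued - amounts.size
        amounts = np.concatenate([amounts, rng.integers(1, 6, size=extra)])
        sched = np.concatenate([amounts, np.zeros(n - n_cued, dtype=int)])
    else:
        n_med, n_large = cfg.n_uncued_median, cfg.n_uncued_largest
        sched = np.concatenate([
            np.full(n_med, 3),
            np.full(n_large, 5),
            np.zeros(n - n_med - n_large, dtype=int)])
    rng.shuffle(sched)
    return sched


def gen_session(config: SessionConfig, seed: int) -> SyntheticSession:
    """Generate one synthetic session (see :class:`SessionConfig`).

    The hit rate rises with change amount because the planted-axis signal
    grows with the orientation change while the choice-noise SD is fixed.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    axis = cfg.resolved_axis()

    f0 = ring_tuning(cfg.ring, cfg.start_theta)
    s_med = axis @ (ring_tuning(cfg.ring, cfg.start_theta + cfg.change_amounts[2])
                    - f0)
    if s_med <= 0:
        raise ValueError("planted axis does not separate the median change "
                         "from the starting orientation")
    threshold = axis @ f0 + 0.5 * s_med
    noise_sd = cfg.psychometric_noise * s_med

    rows, count_rows, baseline_rows = [], [], []
    for b in range(cfg.n_blocks):
        cued_at_rf = (b % 2 == 0)
        att = 1.0 if cued_at_rf else 0.0
        ring = RingModelParams(**{
            **cfg.ring.__dict__, "attention_level": att,
            "preferred_orientations": cfg.ring.preferred_orientations})
        sched = _block_change_schedule(cfg, cued_at_rf, rng)
        for t, amount in enumerate(sched):
            # 100 ms pre-first-flash baseline window (half the count window)
            baseline_rows.append(rng.poisson(0.5 * cfg.ring.baseline,
                                             size=cfg.ring.n_units))
            # number of starting-orientation flashes before the change
            n_start = 1 + rng.geometric(1 - cfg.presentation_continue_prob)
            n_start = min(n_start, cfg.max_presentations - 1)
            thetas = [cfg.start_theta] * n_start
            if amount > 0:
                thetas.append((cfg.start_theta
                               + cfg.change_amounts[amount - 1]) % 1.0)
            tm = gen_ring_responses(ring, thetas, 2,
                                    seed=int(rng.integers(2 ** 31)))
            # gen_ring_responses needs >= 2 trials/θ; keep the first of each pair
            counts = tm.counts[::2]
            for flash, th in enumerate(thetas):
                r = counts[flash]
                is_change = amount > 0 and flash == len(thetas) - 1
                if is_change:
                    d = axis @ r + rng.normal(0.0, noise_sd) if noise_sd > 0 \
                        else axis @ r
                    choice = int(d > threshold)
                    correct = choice
                else:
                    choice, correct = 0, 1
                rows.append(dict(block=b, trial=t, flash=flash, theta=th,
                                 change_amount=int(amount) if is_change else 0,
                                 cued=int(cued_at_rf), choice=choice,
                                 correct=correct, first_flash=int(flash == 0)))
                count_rows.append(r)
    params = dict(
        planted_axis=axis.tolist(),
        start_theta=cfg.start_theta,
        change_amounts=list(cfg.change_amounts),
        psychometric_noise=cfg.psychometric_noise,
        threshold=float(threshold),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return SyntheticSession(pd.DataFrame(rows), np.asarray(count_rows), params,
                            baseline_counts=np.asarray(baseline_rows, float))
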