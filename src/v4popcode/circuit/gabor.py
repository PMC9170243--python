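"""Gabor stimulus, Ornstein-Uhlenbeck pixel noise, and the Poisson L4 front end.

The stimulus is a 25x25-pixel Gabor image on Γ, corrupted by independent
per-pixel OU noise η with timescale τn and SDE amplitude σn
(τn dη = -η dt + σn dW, stationary SD σn/sqrt(2 τn)).  Each V1 layer-4 unit
is a Gabor filter sharing the image's envelope width, wavelength, and phase,
centered on the unit's grid position with its map-preferred orientation; its
firing rate is the rectified filter response scaled by a normalization
constant calibrated so the grand-mean ON-interval rate is 10 Hz.  L4 spikes
are inhomogeneous Poisson during ON intervals and homogeneous Poisson at
r_X = 5 Hz during OFF intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation_map import OrientationMap

__all__ = [
    "GaborStimulusParams",
    "OUNoise",
    "gabor_image",
    "GaborFilterBank",
    "ProtocolConfig",
    "simulate_l4",
]


@dataclass(frozen=True)
class GaborStimulusParams:
    """Static Gabor image parameters (Γ units)."""

    n_pixels: int = 25
    envelope_sigma: float = 0.2
    wavelength: float = 0.6
    phase: float = 0.0
    ou_tau_ms: float = 40.0
    ou_sigma: float = 3.5

    def __post_init__(self):
        if self.envelope_sigma <= 0 or self.wavelength <= 0:
            raise ValueError("envelope sigma and wavelength must be > 0")

    @property
    def ou_stationary_sd(self) -> float:
        """Stationary SD of η implied by τn dη = -η dt + σn dW."""
        return self.ou_sigma / np.sqrt(2.0 * self.ou_tau_ms)


def _pixel_grid(n_pixels: int) -> tuple[np.ndarray, np.ndarray]:
    u = (np.arange(n_pixels) + 0.5) / n_pixels - 0.5
    return np.meshgrid(u, u, indexing="ij")


def _gabor(xx, yy, x0, y0, theta_norm, p: GaborStimulusParams) -> np.ndarray:
    """Gabor patch centered at (x0, y0); θ normalized in [0,1) -> angle πθ."""
    ang = np.pi * theta_norm
    dx, dy = xx - x0, yy - y0
    carrier = np.cos(2 * np.pi * (dx * np.cos(ang) + dy * np.sin(ang))
                     / p.wavelength + p.phase)
    envelope = np.exp(-(dx ** 2 + dy ** 2) / (2 * p.envelope_sigma ** 2))
    return envelope * carrier


def gabor_image(theta: float, params: GaborStimulusParams | None = None
                ) -> np.ndarray:
    """Static (noise-free) Gabor image I(θ), shape (n_pixels, n_pixels)."""
    p = params or GaborStimulusParams()
    xx, yy = _pixel_grid(p.n_pixels)
    return _gabor(xx, yy, 0.0, 0.0, theta, p)


class OUNoise:
    """Exactly discretized Ornstein-Uhlenbeck process, one state per pixel.

    The update over a step of dt ms is
    η <- η e^{-dt/τ} + σ_st sqrt(1 - e^{-2dt/τ}) ξ,  ξ ~ N(0, I),
    which preserves the stationary variance exactly for any dt.
    """

    def __init__(self, shape, tau_ms: float, sigma: float, seed: int,
                 start_stationary: bool = True):
        self.tau_ms = tau_ms
        self.sigma = sigma
        self.stationary_sd = sigma / np.sqrt(2.0 * tau_ms)
        self.rng = np.random.default_rng(seed)
        self.state = (self.rng.normal(0.0, self.stationary_sd, size=shape)
                      if start_stationary and sigma > 0
                      else np.zeros(shape))

    def step(self, dt_ms: float) -> np.ndarray:
        if self.sigma == 0:
            return self.state
        a = np.exp(-dt_ms / self.tau_ms)
        self.state = (a * self.state
                      + self.stationary_sd * np.sqrt(1.0 - a * a)
                      * self.rng.normal(size=self.state.shape))
        return self.state

    def sample_trajectory(self, n_steps: int, dt_ms: float) -> np.ndarray:
        """(n_steps, *shape) trajectory, advancing the internal state."""
        out = np.empty((n_steps,) + self.state.shape)
        for t in range(n_steps):
            out[t] = self.step(dt_ms)
        return out


class GaborFilterBank:
    """One Gabor filter per L4 unit, matched to the stimulus parameters.

    ``rate_scale`` converts rectified filter responses to firing rates (Hz);
    it is set by :meth:`calibrate` so that the mean ON-interval rate over
    units and uniformly spaced orientations hits ``target_hz``.
    """

    def __init__(self, omap: OrientationMap,
                 params: GaborStimulusParams | None = None,
                 rate_scale: float | None = None):
        self.params = params or GaborStimulusParams()
        self.omap = omap
        xx, yy = _pixel_grid(self.params.n_pixels)
        filters = np.empty((omap.grid.shape[0], xx.size))
        for i, ((x0, y0), th) in enumerate(
                zip(omap.grid, omap.preferred_orientation)):
            filters[i] = _gabor(xx, yy, x0, y0, th, self.params).ravel()
        # normalize pixel sums by pixel area so responses are resolution-free
        self.filters = filters / xx.size
        self.rate_scale = rate_scale

    @property
    def n_units(self) -> int:
        return self.filters.shape[0]

    def static_response(self, theta: float) -> np.ndarray:
        """Noise-free filter responses F_i x I(θ) (before rectification)."""
        img = gabor_image(theta, self.params).ravel()
        return self.filters @ img

    def rates(self, theta: float, noise_frames: np.ndarray | None = None
              ) -> np.ndarray:
        """Rectified, calibrated rates in Hz.

        ``noise_frames`` is an optional (T, n_pix, n_pix) OU-noise stack;
        output is (n_units,) without noise or (n_units, T) with it.
        """
        if self.rate_scale is None:
            raise RuntimeError("filter bank is not calibrated; call calibrate()")
        s = self.static_response(theta)
        if noise_frames is None:
            drive = s
        else:
            frames = noise_frames.reshape(noise_frames.shape[0], -1).T
            drive = s[:, None] + self.filters @ frames
        return np.maximum(drive, 0.0) * self.rate_scale

    def calibrate(self, target_hz: float = 10.0, n_orientations: int = 50,
                  n_noise_frames: int = 200, seed: int = 0) -> float:
        """Set ``rate_scale`` so the grand-mean rectified response = target.

        The expectation is over units, ``n_orientations`` uniform
        orientations, and Monte-Carlo OU noise frames at the stationary
        distribution.
        """
        rng_seed = seed
        thetas = np.arange(n_orientations) / n_orientations
        ou = OUNoise((self.params.n_pixels, self.params.n_pixels),
                     self.params.ou_tau_ms, self.params.ou_sigma, rng_seed)
        frames = ou.rng.normal(
            0.0, ou.stationary_sd,
            size=(n_noise_frames, self.params.n_pixels ** 2))
        acc = 0.0
        for th in thetas:
            s = self.static_response(th)
            drive = s[:, None] + self.filters @ frames.T
            acc += np.maximum(drive, 0.0).mean()
        mean_rect = acc / n_orientations
        if mean_rect <= 0:
            raise ValueError("rectified responses are identically zero; "
                             "cannot calibrate")
        self.rate_scale = target_hz / mean_rect
        return self.rate_scale


@dataclass(frozen=True)
class ProtocolConfig:
    """Alternating OFF/ON stimulus protocol."""

    off_ms: float = 300.0
    on_ms: float = 200.0
    total_ms: float = 20000.0
    off_rate_hz: float = 5.0   # r_X: L4 rate during OFF intervals

    @property
    def n_intervals(self) -> int:
        return int(self.total_ms // (self.off_ms + self.on_ms))

    def on_windows(self) -> list[tuple[float, float]]:
        period = self.off_ms + self.on_ms
        return [(k * period + self.off_ms, (k + 1) * period)
                for k in range(self.n_intervals)]


def simulate_l4(bank: GaborFilterBank, protocol: ProtocolConfig,
                orientation_sequence: np.ndarray, seed: int,
                bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Poisson L4 spike counts in ``bin_ms`` bins over the whole protocol.

    Returns ``(counts, theta_per_on)`` where counts has shape
    (n_units, n_bins).  During OFF intervals every unit fires at the
    protocol's r_X; during the k-th ON interval, rates follow the rectified
    filter response to a Gabor at ``orientation_sequence[k]`` with OU pixel
    noise advanced continuously through the interval.
    """
    orientation_sequence = np.asarray(orientation_sequence, dtype=float)
    if orientation_sequence.size < protocol.n_intervals:
        raise ValueError("orientation sequence shorter than protocol")
    rng = np.random.default_rng(seed)
    ou = OUNoise((bank.params.n_pixels, bank.params.n_pixels),
                 bank.params.ou_tau_ms, bank.params.ou_sigma,
                 seed=int(rng.integers(2 ** 31)))
    n_bins = int(round(protocol.total_ms / bin_ms))
    rates = np.full((bank.n_units, n_bins), protocol.off_rate_hz)
    for k, (t0, t1) in enumerate(protocol.on_windows()):
        b0, b1 = int(round(t0 / bin_ms)), int(round(t1 / bin_ms))
        ou.step(protocol.off_ms)  # advance through the OFF gap in one exact step
        frames = ou.sample_trajectory(b1 - b0, bin_ms)
        rates[:, b0:b1] = bank.rates(orientation_sequence[k], frames)
    counts = rng.poisson(rates * (bin_ms / 1000.0))
    return counts.astype(np.int32), orientation_sequence[: protocol.n_intervals]
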