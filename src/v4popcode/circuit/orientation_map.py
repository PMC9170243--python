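"""Columnar orientation-preference map on the periodic unit square.

The map is a superposition of n randomly phased plane waves whose wavevectors
all have magnitude ~1/Λ (Λ = average column spacing); the preferred
orientation at position x is the argument of the resulting complex field,
normalized to [0, 1).  To keep the map exactly periodic on Γ = [-0.5, 0.5]²,
wavevectors are drawn from the integer lattice points whose norm is closest
to 1/Λ, so the radially averaged power spectrum of e^{i2πθ(x)} peaks at
spatial frequency 1/Λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrientationMap", "make_orientation_map"]


@dataclass(frozen=True)
class OrientationMap:
    """Grid positions on Γ with a preferred orientation per grid point."""

    grid: np.ndarray                  # (n, 2) positions in [-0.5, 0.5)
    preferred_orientation: np.ndarray  # (n,) values in [0, 1)
    column_spacing: float
    grid_side: int

    def field(self) -> np.ndarray:
        """Complex unit field e^{i2πθ} reshaped to (side, side)."""
        return np.exp(2j * np.pi * self.preferred_orientation).reshape(
            self.grid_side, self.grid_side)


def square_grid(side: int) -> np.ndarray:
    """Uniform (side², 2) grid on Γ = [-0.5, 0.5)², row-major."""
    u = (np.arange(side) + 0.5) / side - 0.5
    xx, yy = np.meshgrid(u, u, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _lattice_wavevectors(target_norm: float) -> np.ndarray:
    """Integer lattice points with norm closest to ``target_norm``."""
    r = int(np.ceil(target_norm)) + 2
    mm = np.array([(i, j) for i in range(-r, r + 1) for j in range(-r, r + 1)
                   if (i, j) != (0, 0)])
    norms = np.linalg.norm(mm, axis=1)
    best = np.min(np.abs(norms - target_norm))
    return mm[np.abs(norms - target_norm) <= best + 1e-9]


def make_orientation_map(column_spacing: float = 0.2, grid_side: int = 30,
                         seed: int = 0, n_waves: int = 30) -> OrientationMap:
    """Build a plane-wave-superposition orientation map.

    Parameters
    ----------
    column_spacing
        Λ, the average orientation-column spacing in Γ units (default 0.2).
    grid_side
        Number of grid points per side (>= 8).
    n_waves
        Number of randomly phased plane waves summed (default 30).
    """
    if column_spacing <= 0:
        raise ValueError("column_spacing must be > 0")
    if column_spacing >= 1.0:
        raise ValueError("column spacing >= domain size: no orientation "
                         "columns are representable on Γ")
    if grid_side < 8:
        raise ValueError("grid_side must be >= 8")
    rng = np.random.default_rng(seed)
    grid = square_grid(grid_side)
    candidates = _lattice_wavevectors(1.0 / column_spacing)
    kvecs = candidates[rng.integers(candidates.shape[0], size=n_waves)]
    phases = rng.uniform(0.0, 2 * np.pi, size=n_waves)
    z = np.zeros(grid.shape[0], dtype=complex)
    for k, ph in zip(kvecs, phases):
        z += np.exp(1j * (2 * np.pi * (grid @ k) + ph))
    theta = (np.angle(z) / (2 * np.pi)) % 1.0
    return OrientationMap(grid=grid, preferred_orientation=theta,
                          column_spacing=column_spacing, grid_side=grid_side)
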