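"""Trial-by-unit spike-count container shared by all analyses.

A :class:`TrialMatrix` holds a ``(n_trials, n_units)`` matrix of spike counts
together with per-trial labels: stimulus orientation ``theta`` on the
normalized ring [0, 1), an attention-condition label, and (optionally) a
behavioral choice and a block id.  It is the lingua franca between the
synthetic generators, the spiking circuit model, the decoders, and the
session pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["TrialMatrix", "CountingWindow"]


@dataclass(frozen=True)
class CountingWindow:
    """Descriptor of the spike-counting window, in ms after stimulus onset."""

    start_ms: float = 0.0
    stop_ms: float = 200.0
    label: str = "full"

    @property
    def length_ms(self) -> float:
        return self.stop_ms - self.start_ms


@dataclass
class TrialMatrix:
    """Spike counts (trials x units) with per-trial condition labels.

    Parameters
    ----------
    counts
        ``(n_trials, n_units)`` nonnegative float array.
    theta
        Per-trial orientation on the normalized ring [0, 1).
    attention
        Per-trial attention label (any hashable; typically 0/1 or a float
        attention level).
    choice
        Optional per-trial binary choice (1 = saccade / change reported).
    block
        Optional per-trial block id.
    window
        Counting-window descriptor for bookkeeping assertions downstream.
    """

    counts: np.ndarray
    theta: np.ndarray
    attention: np.ndarray | None = None
    choice: np.ndarray | None = None
    block: np.ndarray | None = None
    window: CountingWindow = field(default_factory=CountingWindow)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (trials x units)")
        n = self.counts.shape[0]
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (n,):
            raise ValueError(
                f"theta has length {self.theta.shape}, expected ({n},)"
            )
        if self.attention is None:
            self.attention = np.zeros(n)
        self.attention = np.asarray(self.attention)
        if self.attention.shape != (n,):
            raise ValueError("attention labels must match number of trials")
        for name in ("choice", "block"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValueError(f"{name} labels must match number of trials")
                setattr(self, name, v)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def select(self, mask: np.ndarray) -> "TrialMatrix":
        """Return a new TrialMatrix restricted to trials where ``mask``."""
        mask = np.asarray(mask)
        return TrialMatrix(
            counts=self.counts[mask],
            theta=self.theta[mask],
            attention=self.attention[mask],
            choice=None if self.choice is None else self.choice[mask],
            block=None if self.block is None else self.block[mask],
            window=self.window,
        )

    def select_units(self, unit_idx: Iterable[int]) -> "TrialMatrix":
        idx = np.asarray(list(unit_idx), dtype=int)
        return replace(self, counts=self.counts[:, idx])

    def condition(self, theta: float | None = None,
                  attention=None, atol: float = 1e-9) -> "TrialMatrix":
        """Restrict to one (orientation, attention) condition."""
        mask = np.ones(self.n_trials, dtype=bool)
        if theta is not None:
            d = np.abs(self.theta - theta)
            mask &= np.minimum(d, 1.0 - d) <= atol
        if attention is not None:
            mask &= np.asarray(self.attention == attention)
        return self.select(mask)

    def unique_thetas(self, decimals: int = 9) -> np.ndarray:
        return np.unique(np.round(self.theta, decimals))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        cols = {f"unit_{i}": self.counts[:, i] for i in range(self.n_units)}
        cols["theta"] = self.theta
        cols["attention"] = self.attention
        if self.choice is not None:
            cols["choice"] = self.choice
        if self.block is not None:
            cols["block"] = self.block
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   window: CountingWindow | None = None) -> "TrialMatrix":
        unit_cols = [c for c in df.columns if c.startswith("unit_")]
        unit_cols.sort(key=lambda c: int(c.split("_")[1]))
        return cls(
            counts=df[unit_cols].to_numpy(dtype=float),
            theta=df["theta"].to_numpy(dtype=float),
            attention=df["attention"].to_numpy() if "attention" in df else None,
            choice=df["choice"].to_numpy() if "choice" in df else None,
            block=df["block"].to_numpy() if "block" in df else None,
            window=window or CountingWindow(),
        )

    @classmethod
    def from_csv(cls, path, window: CountingWindow | None = None) -> "TrialMatrix":
        return cls.from_frame(pd.read_csv(path), window=window)

    @staticmethod
    def concat(parts: Iterable["TrialMatrix"]) -> "TrialMatrix":
        parts = list(parts)
        if not parts:
            raise ValueError("nothing to concatenate")
        has_choice = all(p.choice is not None for p in parts)
        has_block = all(p.block is not None for p in parts)
        return TrialMatrix(
            counts=np.vstack([p.counts for p in parts]),
            theta=np.concatenate([p.theta for p in parts]),
            attention=np.concatenate([p.attention for p in parts]),
            choice=np.concatenate([p.choice for p in parts]) if has_choice else None,
            block=np.concatenate([p.block for p in parts]) if has_block else None,
            window=parts[0].window,
        )
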