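"""Shared-variability statistics: pairwise correlations and factor analysis.

Noise (spike-count) correlation r_SC is the Pearson correlation between two
units' counts over repeated presentations of an identical stimulus; signal
correlation is the correlation of the units' mean tuning across stimuli.
Factor analysis models counts as x ~ N(μ, LLᵀ + Ψ) and the eigenvalues of
LLᵀ summarize the low-dimensional shared variability; attention's quenching
of shared fluctuations appears as a drop of the leading eigenvalue λ1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trialmatrix import TrialMatrix

__all__ = [
    "CorrelationSummary",
    "FactorFit",
    "noise_correlations",
    "signal_vs_noise",
    "factor_fit",
]


@dataclass
class CorrelationSummary:
    """Pairwise correlation vectors over a fixed unit-pair ordering."""

    pair_index: np.ndarray            # (n_pairs, 2) unit indices i<j
    pairwise_noise_corr: np.ndarray | None = None
    mean_rsc: float | None = None
    pairwise_signal_corr: np.ndarray | None = None
    noise_vs_signal_r: float | None = None
    excluded_units: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "mean_rsc": self.mean_rsc,
            "noise_vs_signal_r": self.noise_vs_signal_r,
            "n_pairs": int(self.pair_index.shape[0]),
            "excluded_units": [int(u) for u in self.excluded_units],
        }

    def to_csv(self, path) -> None:
        """Write one row per unit pair: unit_i, unit_j, r_noise[, r_signal]."""
        import pandas as pd
        cols = {"unit_i": self.pair_index[:, 0],
                "unit_j": self.pair_index[:, 1]}
        if self.pairwise_noise_corr is not None:
            cols["r_noise"] = self.pairwise_noise_corr
        if self.pairwise_signal_corr is not None:
            cols["r_signal"] = self.pairwise_signal_corr
        pd.DataFrame(cols).to_csv(path, index=False)


def _pair_index(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def _pairwise_from_corrmat(c: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(c.shape[0], k=1)
    return c[iu]


def noise_correlations(data: TrialMatrix) -> CorrelationSummary:
    """Pairwise spike-count correlations within one stimulus condition.

    All trials must share one orientation; pairs involving a zero-variance
    unit are excluded (the unit is listed in ``excluded_units``).
    """
    if data.n_trials < 3:
        raise ValueError("need at least 3 trials for noise correlations")
    if data.unique_thetas().size != 1:
        raise ValueError("noise correlations require a single stimulus "
                         "condition; restrict the TrialMatrix first")
    n = data.n_units
    var = data.counts.var(axis=0)
    good = var > 0
    excluded = list(np.where(~good)[0])
    pairs = _pair_index(n)
    rho = np.full(pairs.shape[0], np.nan)
    if good.sum() >= 2:
        c = np.corrcoef(data.counts[:, good], rowvar=False)
        sub = _pairwise_from_corrmat(c)
        keep = good[pairs[:, 0]] & good[pairs[:, 1]]
        rho[keep] = sub
    valid = ~np.isnan(rho)
    return CorrelationSummary(
        pair_index=pairs,
        pairwise_noise_corr=rho,
        mean_rsc=float(np.mean(rho[valid])) if valid.any() else np.nan,
        excluded_units=excluded,
    )


def signal_vs_noise(data: TrialMatrix) -> CorrelationSummary:
    """Signal correlations and their relation to noise correlations.

    Signal correlation per pair: Pearson correlation of the two units' mean
    responses across the orientations present in ``data``.  Noise
    correlations are computed within each orientation and averaged over
    orientations, pairwise.  ``noise_vs_signal_r`` is the across-pairs
    correlation of the two vectors; pairs touching an excluded (flat-tuned
    or zero-variance) unit are dropped listwise from both vectors.
    """
    ths = data.unique_thetas()
    if ths.size < 5:
        raise ValueError("need >= 5 orientations for signal correlations")
    n = data.n_units
    pairs = _pair_index(n)

    tuning = np.vstack([data.condition(theta=t).counts.mean(axis=0)
                        for t in ths])          # (n_theta, n_units)
    flat = tuning.var(axis=0) == 0
    noise_acc = np.zeros(pairs.shape[0])
    noise_cnt = np.zeros(pairs.shape[0])
    zero_var = np.zeros(n, dtype=bool)
    for t in ths:
        cond = data.condition(theta=t)
        if cond.n_trials < 3:
            continue
        ns = noise_correlations(cond)
        v = ~np.isnan(ns.pairwise_noise_corr)
        noise_acc[v] += ns.pairwise_noise_corr[v]
        noise_cnt[v] += 1
        zero_var[ns.excluded_units] = True

    good_unit = ~(flat | zero_var)
    excluded = list(np.where(~good_unit)[0])
    keep = (good_unit[pairs[:, 0]] & good_unit[pairs[:, 1]]
            & (noise_cnt > 0))
    noise = np.full(pairs.shape[0], np.nan)
    noise[noise_cnt > 0] = noise_acc[noise_cnt > 0] / noise_cnt[noise_cnt > 0]

    sig = np.full(pairs.shape[0], np.nan)
    c = np.corrcoef(tuning[:, good_unit], rowvar=False)
    sig_keep = good_unit[pairs[:, 0]] & good_unit[pairs[:, 1]]
    sig[sig_keep] = _pairwise_from_corrmat(c)

    both = keep & ~np.isnan(noise) & ~np.isnan(sig)
    if both.sum() >= 3 and np.std(noise[both]) > 0 and np.std(sig[both]) > 0:
        r = float(np.corrcoef(noise[both], sig[both])[0, 1])
    else:
        r = np.nan
    return CorrelationSummary(
        pair_index=pairs,
        pairwise_noise_corr=noise,
        mean_rsc=float(np.nanmean(noise[keep])) if keep.any() else np.nan,
        pairwise_signal_corr=sig,
        noise_vs_signal_r=r,
        excluded_units=excluded,
    )


# ------------------------------------------------------------------ FA

@dataclass
class FactorFit:
    """Maximum-likelihood factor-analysis fit of one condition's counts."""

    mean: np.ndarray
    loadings: np.ndarray            # (units, m)
    private_variances: np.ndarray   # diagonal of Ψ
    shared_eigenvalues: np.ndarray  # λ1 >= ... >= λm, eigenvalues of LLᵀ
    n_factors: int
    converged: bool
    log_likelihoods: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "shared_eigenvalues": self.shared_eigenvalues.tolist(),
            "converged": bool(self.converged),
        }


_PSI_FLOOR = 1e-6


def _fa_loglik(s: np.ndarray, load: np.ndarray, psi: np.ndarray,
               n_units: int) -> float:
    """Average Gaussian log-likelihood per trial (up to the 2π constant)."""
    sigma = load @ load.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    return -0.5 * (logdet + np.trace(np.linalg.solve(sigma, s))
                   + n_units * np.log(2 * np.pi))


def _fa_em(s: np.ndarray, load: np.ndarray, psi: np.ndarray,
           max_iter: int, tol: float):
    """Closed-form EM for the factor model, on the sample covariance."""
    m = load.shape[1]
    lls = []
    converged = False
    for _ in range(max_iter):
        lls.append(_fa_loglik(s, load, psi, s.shape[0]))
        psi_inv_l = load / psi[:, None]
        g = np.linalg.inv(np.eye(m) + load.T @ psi_inv_l)
        beta = g @ psi_inv_l.T               # (m, units)
        s_bt = s @ beta.T                    # (units, m)
        load = s_bt @ np.linalg.inv(g + beta @ s_bt)
        psi = np.maximum(np.diag(s - load @ (beta @ s)), _PSI_FLOOR)
        if len(lls) > 1:
            if lls[-1] - lls[-2] < tol * max(abs(lls[-2]), 1.0):
                converged = True
                break
    return load, psi, np.asarray(lls), converged


def factor_fit(counts: np.ndarray, n_factors: int = 5, max_iter: int = 2000,
               tol: float = 1e-8, n_restarts: int = 10,
               seed: int = 0) -> FactorFit:
    """Fit x ~ N(μ, LLᵀ + Ψ) by maximum likelihood (EM) and rank LLᵀ's spectrum.

    The fit uses closed-form EM on the sample covariance, started from a
    principal-component solution (loadings = top eigenvectors scaled by the
    excess of their eigenvalues over the residual variance); on
    non-convergence up to ``n_restarts`` jittered restarts are tried and the
    best-likelihood fit is returned with ``converged=False`` if none
    converged.  ``tol`` is the relative log-likelihood change per EM step.

    ``shared_eigenvalues`` are the descending eigenvalues of LLᵀ (the squared
    singular values of L), of length ``n_factors``; λ1 quantifies the
    dominant shared-variability mode.  The per-iteration log-likelihood
    trace is retained so EM monotonicity can be asserted.
    """
    counts = np.asarray(counts, dtype=float)
    n_trials, n_units = counts.shape
    if n_factors >= n_units:
        raise ValueError("n_factors must be smaller than the number of units")
    if n_trials <= n_units:
        warnings.warn(
            f"factor analysis with {n_trials} trials <= {n_units} units: "
            "fit may be unstable", RuntimeWarning, stacklevel=2)
    mean = counts.mean(axis=0)
    resid = counts - mean
    s = resid.T @ resid / max(n_trials - 1, 1)

    evals, evecs = np.linalg.eigh(s)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    resid_var = max(evals[n_factors:].mean(), _PSI_FLOOR) \
        if n_factors < n_units else _PSI_FLOOR
    load0 = evecs[:, :n_factors] * np.sqrt(
        np.maximum(evals[:n_factors] - resid_var, _PSI_FLOOR))
    psi0 = np.maximum(np.diag(s) - (load0 ** 2).sum(axis=1), _PSI_FLOOR)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            l_init, p_init = load0, psi0
        else:  # jittered restart
            l_init = load0 * (1 + 0.3 * rng.standard_normal(load0.shape))
            p_init = psi0 * rng.uniform(0.5, 1.5, size=psi0.shape)
        load, psi, lls, converged = _fa_em(s, l_init.copy(), p_init.copy(),
                                           max_iter, tol)
        if best is None or lls[-1] > best[2][-1]:
            best = (load, psi, lls, converged)
        if converged:
            break
    load, psi, lls, converged = best

    sv = np.linalg.svd(load, compute_uv=False)
    lam = np.zeros(n_factors)
    lam[: sv.size] = sv ** 2
    return FactorFit(
        mean=mean,
        loadings=load,
        private_variances=psi,
        shared_eigenvalues=np.sort(lam)[::-1],
        n_factors=n_factors,
        converged=converged,
        log_likelihoods=lls,
    )
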