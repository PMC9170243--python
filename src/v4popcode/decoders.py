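"""Population decoders of orientation and their information estimators.

Implements the two readout families compared throughout the package:

* the **specific decoder**, an optimal local linear estimator for a fine
  discrimination between two nearby orientations θ0 ± dθ, whose inverse
  variance is the linear Fisher information f'ᵀ Σ⁻¹ f', estimated from data
  with the bias-corrected quadratic-form estimator;
* the **general decoder**, a single complex-valued linear readout
  ẑ = wᵀ r mapping population activity to a point on the stimulus ring for
  *all* orientations at once, with its information measured as the inverse
  variance of the decoded angle;

plus the cross-validated classifiers used for the session-style analyses:
a two-fold SVM pairwise discrimination (run either on the full population or
on the general decoder's 2-D projection) and leave-one-out cross-validated
linear classification with separate training and evaluation label sets.

Conventions
-----------
Orientation θ lives on the normalized ring [0, 1).  It is embedded in the
complex plane as z = e^{i 2π θ} (see :func:`ring_phase`); decoded angles are
mapped back with :func:`phase_to_theta` and angular residuals are wrapped to
(-0.5, 0.5] in θ units, so all information values are in 1/θ-units².

The bias-corrected Fisher estimator divides the empirical mean difference by
``dθ`` exactly as in its printed form, while the training orientations are
θ0 ± dθ; this convention is kept literally and cancels in every attended /
unattended ratio the package reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .trialmatrix import TrialMatrix

__all__ = [
    "SpecificDecoder",
    "GeneralDecoder",
    "FisherEstimate",
    "ring_phase",
    "phase_to_theta",
    "wrap_theta",
    "specific_weights",
    "fisher_info_bc",
    "fisher_info_naive",
    "general_weights",
    "decode_general",
    "general_info",
    "pair_discrimination",
    "loocv_linear_performance",
    "fit_linear_readout",
]


# ----------------------------------------------------------------- ring map

def ring_phase(theta) -> np.ndarray:
    """Embed θ ∈ [0,1) on the unit circle: z = e^{i 2π θ}."""
    return np.exp(2j * np.pi * np.asarray(theta, dtype=float))


def phase_to_theta(z) -> np.ndarray:
    """Inverse of :func:`ring_phase`: θ̂ = arg(z)/2π mod 1."""
    return (np.angle(z) / (2 * np.pi)) % 1.0


def wrap_theta(d) -> np.ndarray:
    """Wrap an orientation difference to (-0.5, 0.5]."""
    return -((-np.asarray(d, dtype=float) + 0.5) % 1.0 - 0.5)


# ------------------------------------------------------------------- types

@dataclass
class SpecificDecoder:
    """Optimal local linear estimator around a reference orientation."""

    weights: np.ndarray
    reference_orientation: float
    half_offset: float
    trained_conditions: tuple[float, float]
    midpoint: np.ndarray
    used_pseudoinverse: bool = False

    def estimate(self, counts: np.ndarray) -> np.ndarray:
        """θ̂ = θ0 + wᵀ(r - (f(θ+)+f(θ-))/2) per trial."""
        counts = np.atleast_2d(counts)
        return self.reference_orientation + (counts - self.midpoint) @ self.weights

    def to_json_dict(self) -> dict:
        return {
            "kind": "specific",
            "weights": self.weights.tolist(),
            "reference_orientation": self.reference_orientation,
            "half_offset": self.half_offset,
            "trained_conditions": list(self.trained_conditions),
            "used_pseudoinverse": self.used_pseudoinverse,
        }


@dataclass
class GeneralDecoder:
    """Complex linear readout ẑ = wᵀ r, fixed across all orientations."""

    weights: np.ndarray  # complex, one entry per unit
    expected_mse: float | None = None
    ridge: float = 0.0

    def to_json_dict(self) -> dict:
        return {
            "kind": "general",
            "weights_real": self.weights.real.tolist(),
            "weights_imag": self.weights.imag.tolist(),
            "expected_mse": self.expected_mse,
            "ridge": self.ridge,
        }


@dataclass
class FisherEstimate:
    """An information value in 1/θ-units², with its estimation context."""

    value: float
    n_units: int
    trials_per_condition: int
    half_offset: float | None = None
    corrected: bool = True
    unbounded: bool = False


# -------------------------------------------------------- specific decoder

def specific_weights(f_plus: np.ndarray, f_minus: np.ndarray,
                     covariance: np.ndarray, dtheta: float,
                     theta0: float = 0.5) -> SpecificDecoder:
    """Optimal specific-decoder weights w = Σ⁻¹f' / (f'ᵀΣ⁻¹f').

    ``f_plus``/``f_minus`` are the mean responses at θ0 ± dθ and
    f' = (f₊ - f₋)/(2 dθ).  With exact inputs the estimator
    θ̂ = θ0 + wᵀ(r - (f₊+f₋)/2) is locally unbiased (wᵀf' = 1) and its
    variance wᵀΣw equals 1/(f'ᵀΣ⁻¹f').
    """
    if dtheta <= 0:
        raise ValueError("dtheta must be > 0")
    f_plus = np.asarray(f_plus, dtype=float)
    f_minus = np.asarray(f_minus, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    fprime = (f_plus - f_minus) / (2.0 * dtheta)
    used_pinv = False
    try:
        sol = np.linalg.solve(covariance, fprime)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: using pseudo-inverse for the "
                      "specific decoder", RuntimeWarning, stacklevel=2)
        sol = np.linalg.pinv(covariance) @ fprime
        used_pinv = True
    denom = fprime @ sol
    if denom == 0:
        raise ValueError("f' is in the null space of the covariance; no "
                         "informative direction")
    return SpecificDecoder(
        weights=sol / denom,
        reference_orientation=theta0,
        half_offset=dtheta,
        trained_conditions=(theta0 + dtheta, theta0 - dtheta),
        midpoint=0.5 * (f_plus + f_minus),
        used_pseudoinverse=used_pinv,
    )


def trim_equal_trials(data: TrialMatrix) -> TrialMatrix:
    """Trim each orientation condition to the smallest condition's size.

    The bias-corrected two-condition estimator assumes equal trial counts;
    trailing trials of the larger conditions are dropped deterministically.
    """
    ths = data.unique_thetas()
    n_min = min(data.condition(theta=t).n_trials for t in ths)
    keep = np.zeros(data.n_trials, dtype=bool)
    for t in ths:
        d = np.abs(data.theta - t)
        idx = np.where(np.minimum(d, 1 - d) <= 1e-9)[0][:n_min]
        keep[idx] = True
    return data.select(keep)


def _two_condition_moments(data: TrialMatrix):
    ths = data.unique_thetas()
    if ths.size != 2:
        raise ValueError(f"need exactly 2 orientation conditions, got {ths.size}")
    lo, hi = (data.condition(theta=t) for t in ths)
    if lo.n_trials != hi.n_trials:
        raise ValueError("conditions must have equal trial counts "
                         f"({lo.n_trials} vs {hi.n_trials})")
    return ths, lo, hi


def fisher_info_bc(data: TrialMatrix, dtheta: float) -> FisherEstimate:
    """Bias-corrected linear Fisher information from two-condition data.

    Î = (Δf̂/dθ)ᵀ Σ̂⁻¹ (Δf̂/dθ) · (2Ntr - N - 3)/(2Ntr - 2) - 2N/(Ntr dθ²)

    with Δf̂ the empirical mean difference, Σ̂ the average of the two
    empirical condition covariances, N the number of units and Ntr the
    trials per condition.  The estimate is mean-unbiased for f'ᵀΣ⁻¹f' on
    Gaussian data; negative values are possible near zero information and
    are reported as-is.  Requires 2Ntr > N + 3 for the correction factor to
    be valid.
    """
    ths, lo, hi = _two_condition_moments(data)
    n_tr, n_units = lo.n_trials, lo.n_units
    if 2 * n_tr <= n_units + 3:
        raise ValueError(
            f"bias correction requires 2*Ntr > N + 3 (got Ntr={n_tr}, "
            f"N={n_units})")
    df = (hi.counts.mean(axis=0) - lo.counts.mean(axis=0)) / dtheta
    sigma = 0.5 * (np.cov(lo.counts, rowvar=False)
                   + np.cov(hi.counts, rowvar=False))
    quad = df @ np.linalg.solve(sigma, df)
    value = (quad * (2 * n_tr - n_units - 3) / (2 * n_tr - 2)
             - 2 * n_units / (n_tr * dtheta ** 2))
    return FisherEstimate(value=float(value), n_units=n_units,
                          trials_per_condition=n_tr, half_offset=dtheta,
                          corrected=True)


def fisher_info_naive(data: TrialMatrix, dtheta: float) -> FisherEstimate:
    """Plug-in (uncorrected) Fisher estimator; upward-biased in finite samples."""
    _, lo, hi = _two_condition_moments(data)
    df = (hi.counts.mean(axis=0) - lo.counts.mean(axis=0)) / dtheta
    sigma = 0.5 * (np.cov(lo.counts, rowvar=False)
                   + np.cov(hi.counts, rowvar=False))
    quad = df @ np.linalg.solve(sigma, df)
    return FisherEstimate(value=float(quad), n_units=lo.n_units,
                          trials_per_condition=lo.n_trials,
                          half_offset=dtheta, corrected=False)


# --------------------------------------------------------- general decoder

_COND_BOUND = 1e12


def general_weights(data: TrialMatrix) -> GeneralDecoder:
    """Optimal complex weights w = ⟨Σ(θ) + f fᵀ⟩θ⁻¹ ⟨f e^{i2πθ}⟩θ.

    Moments are empirical per orientation and averaged over the orientation
    grid (which should be approximately uniform on [0, 1)).  The attained
    mean squared error of ẑ is 1 - c* M⁻¹ c with c = ⟨f e^{i2πθ}⟩θ and is
    returned as ``expected_mse``.  A singular second-moment matrix triggers
    a ridge fallback: the smallest power of ten whose addition brings the
    condition number below 1e12, recorded on the result.
    """
    ths = data.unique_thetas()
    if ths.size < 2:
        raise ValueError("general decoder needs data spanning the ring")
    n = data.n_units
    m = np.zeros((n, n))
    c = np.zeros(n, dtype=complex)
    for th in ths:
        cond = data.condition(theta=th)
        f = cond.counts.mean(axis=0)
        # ddof=0: <Sigma + f f^T> is the empirical second moment E[r r^T],
        # which makes the closed form the exact empirical-MSE minimizer
        sig = np.cov(cond.counts, rowvar=False, ddof=0) \
            if cond.n_trials > 1 else np.zeros((n, n))
        m += sig + np.outer(f, f)
        c += f * ring_phase(th)
    m /= ths.size
    c /= ths.size
    ridge = 0.0
    condno = np.linalg.cond(m)
    if not np.isfinite(condno) or condno > _COND_BOUND:
        scale = np.trace(m) / n
        ridge = 10.0 ** np.floor(np.log10(scale) - 12)
        while np.linalg.cond(m + ridge * np.eye(n)) > _COND_BOUND:
            ridge *= 10.0
        warnings.warn(f"singular second-moment matrix: ridge {ridge:g} added",
                      RuntimeWarning, stacklevel=2)
        m = m + ridge * np.eye(n)
    w = np.linalg.solve(m, c)
    mse = float(1.0 - np.real(np.conj(c) @ np.linalg.solve(m, c)))
    return GeneralDecoder(weights=w, expected_mse=mse, ridge=ridge)


def decode_general(decoder: GeneralDecoder, counts: np.ndarray) -> np.ndarray:
    """Complex readout ẑ = wᵀ r per trial."""
    return np.atleast_2d(counts) @ decoder.weights


def general_info(data: TrialMatrix, decoder: GeneralDecoder) -> FisherEstimate:
    """General-decoder information Îᵍ = [1/Var(θ̂ - θ)] · (Ntr-N-2)/(Ntr-1).

    θ̂ = arg(ẑ)/2π and residuals are wrapped to (-0.5, 0.5] before taking
    the (linear) variance, so the value is in 1/θ-units², directly
    comparable with the specific decoder's Fisher information.  ``Ntr`` is
    the total trial count over all orientations.  Zero residual variance
    (noiseless data) yields an explicit unbounded sentinel.
    """
    n_tr, n_units = data.n_trials, data.n_units
    if n_tr <= n_units + 2:
        raise ValueError(
            f"information correction requires Ntr > N + 2 (got Ntr={n_tr}, "
            f"N={n_units})")
    theta_hat = phase_to_theta(decode_general(decoder, data.counts))
    resid = wrap_theta(theta_hat - data.theta)
    var = float(np.var(resid, ddof=1))
    if var <= 1e-18:  # zero up to floating-point round-off: noiseless data
        return FisherEstimate(value=np.inf, n_units=n_units,
                              trials_per_condition=n_tr, corrected=True,
                              unbounded=True)
    value = (1.0 / var) * (n_tr - n_units - 2) / (n_tr - 1)
    return FisherEstimate(value=float(value), n_units=n_units,
                          trials_per_condition=n_tr, corrected=True)


# ----------------------------------------------------------- classifiers

class _FastLDA:
    """Minimal regularized linear discriminant (Ledoit-Wolf shrinkage).

    Equivalent to LDA with a shrunk pooled covariance, implemented without
    estimator-framework overhead so leave-one-out loops stay cheap.
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        c0, c1 = self.classes_
        x0, x1 = x[y == c0], x[y == c1]
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        n = x.shape[0]
        resid = np.vstack([x0 - mu0, x1 - mu1])
        cov = resid.T @ resid / max(n - 2, 1)
        cov = _ledoit_wolf_shrink(resid, cov)
        w = np.linalg.solve(cov, mu1 - mu0)
        self.coef_ = w[None, :]
        prior_term = np.log(x1.shape[0] / x0.shape[0])
        self.intercept_ = np.array(
            [-0.5 * (mu1 + mu0) @ w + prior_term])
        return self

    def decision_function(self, x):
        return np.asarray(x, dtype=float) @ self.coef_.ravel() \
            + self.intercept_[0]

    def predict(self, x):
        return np.where(self.decision_function(x) > 0,
                        self.classes_[1], self.classes_[0])


def _ledoit_wolf_shrink(resid: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage of a pooled covariance toward a scaled identity."""
    n, p = resid.shape
    mu = np.trace(cov) / p
    delta2 = ((cov - mu * np.eye(p)) ** 2).sum() / p
    x2 = resid ** 2
    beta2 = (x2.T @ x2 / n - cov ** 2).sum() / (n * p)
    beta2 = min(beta2, delta2)
    rho = beta2 / delta2 if delta2 > 0 else 1.0
    return (1 - rho) * cov + rho * mu * np.eye(p)


def _make_classifier(classifier: str, seed: int | None = None):
    if classifier == "lda":
        return _FastLDA()
    if classifier == "sklearn-lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if classifier == "svm":
        return SVC(kernel="linear", C=1.0)
    if classifier == "logistic":
        return LogisticRegression(max_iter=2000)
    raise ValueError(f"unknown classifier {classifier!r}")


def pair_discrimination(data: TrialMatrix, theta1: float, theta2: float,
                        mode: str = "specific", folds: int = 2,
                        seed: int = 0) -> float:
    """Two-fold cross-validated linear discrimination of two orientations.

    ``mode="specific"`` trains a linear SVM on the full N-dimensional
    response space of the θ1/θ2 trials.  ``mode="general"`` first computes
    the optimal general decoder from *all* orientations in ``data``
    (excluding no trials), projects the θ1/θ2 trials to the 2-D plane
    (Re ẑ, Im ẑ), and trains the SVM there.  Folding is stratified so each
    fold contains both classes.
    """
    d1 = data.condition(theta=theta1)
    d2 = data.condition(theta=theta2)
    if d1.n_trials == 0 or d2.n_trials == 0:
        raise ValueError("both orientations must be present in the data")
    x = np.vstack([d1.counts, d2.counts])
    y = np.concatenate([np.zeros(d1.n_trials), np.ones(d2.n_trials)])
    if mode == "general":
        dec = general_weights(data)
        z = x @ dec.weights
        x = np.column_stack([z.real, z.imag])
    elif mode != "specific":
        raise ValueError("mode must be 'specific' or 'general'")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(x, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(x[train], y[train])
        correct += int(np.sum(clf.predict(x[test]) == y[test]))
    return correct / y.size


def fit_linear_readout(counts: np.ndarray, labels: np.ndarray,
                       classifier: str = "lda"):
    """Fit a linear classifier and return (weights, intercept, model)."""
    clf = _make_classifier(classifier)
    clf.fit(counts, labels)
    return clf.coef_.ravel().copy(), float(np.ravel(clf.intercept_)[0]), clf


def loocv_linear_performance(counts: np.ndarray, train_labels: np.ndarray,
                             eval_labels: np.ndarray | None = None,
                             classifier: str = "lda") -> float:
    """Leave-one-out cross-validated proportion correct.

    For each left-out trial a linear classifier is fit on the remaining
    trials' ``train_labels`` and its prediction for the left-out trial is
    scored against that trial's ``eval_label``.  With
    ``eval_labels = train_labels`` this is ordinary LOOCV accuracy (the
    stimulus decoders); with choice training labels and stimulus evaluation
    labels it is the subject's-decoder performance.  A fold whose training
    set contains a single class scores the trial by that majority class.
    """
    counts = np.asarray(counts, dtype=float)
    train_labels = np.asarray(train_labels)
    if eval_labels is None:
        eval_labels = train_labels
    eval_labels = np.asarray(eval_labels)
    n = counts.shape[0]
    if train_labels.shape != (n,) or eval_labels.shape != (n,):
        raise ValueError("labels must have one entry per trial")
    if np.unique(train_labels).size < 2:
        raise ValueError("training labels must contain both classes")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        y = train_labels[rest]
        if np.unique(y).size < 2:
            pred = y[0]  # degenerate fold: majority (only) class
        else:
            clf = _make_classifier(classifier)
            clf.fit(counts[rest], y)
            pred = clf.predict(counts[i][None, :])[0]
        correct += int(pred == eval_labels[i])
    return correct / n
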