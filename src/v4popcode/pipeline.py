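"""Session-level analysis of cued change-detection recordings.

Runs, end to end on a (synthetic) session: unit inclusion by stimulus
responsiveness, counting-window bookkeeping (rates from a 60-260 ms window,
decoders from an abbreviated 60-130 ms window), the stimulus-trained
*specific* decoder and the choice-trained *subject's* ("monkey's") decoder
with leave-one-out cross-validation against stimulus identity, population
size curves with evoked-response ranking, mean noise correlation per
attention condition, the generality ladder (decoders trained on k of the
four non-median change amounts and evaluated across amounts and on choice
prediction), performance-versus-r_SC correlations with Tukey outlier
exclusion, and Williams' procedure for comparing dependent correlations.

Synthetic sessions carry one spike count per stimulus flash, standing for
the full 200 ms response; the abbreviated decoder window is emulated by
binomial thinning with p = 70/200, which preserves Poisson-like statistics
while honoring the rule that decoders never see counts outside their
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoders import _make_classifier, fit_linear_readout, loocv_linear_performance
from .stats import noise_correlations
from .synthetic import SyntheticSession
from .trialmatrix import CountingWindow, TrialMatrix

__all__ = [
    "RATE_WINDOW",
    "DECODER_WINDOW",
    "WilliamsResult",
    "SessionAnalysis",
    "include_units",
    "thin_counts",
    "evoked_ranking",
    "specific_and_monkeys_decoders",
    "generality_ladder",
    "analyze_session",
    "performance_vs_rsc",
    "williams_test",
]

RATE_WINDOW = CountingWindow(60.0, 260.0, "rates")
DECODER_WINDOW = CountingWindow(60.0, 130.0, "decoders")

#: change-amount indices available to the generality ladder (median=3 is
#: reserved for the subject's decoder to avoid the inherent relationship)
LADDER_AMOUNTS = (1, 2, 4, 5)


# ------------------------------------------------------------- inclusion

def include_units(stim_rates: np.ndarray, baseline_rates: np.ndarray,
                  min_rate_hz: float = 10.0, alpha: float = 1e-10
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Responsiveness-based unit inclusion.

    A unit is kept iff its mean stimulus-driven rate exceeds ``min_rate_hz``
    and is significantly higher than its baseline rate (two-sided Wilcoxon
    signed-rank test on the paired per-trial rates, p < ``alpha``).  Units
    with fewer than 6 paired trials are excluded with reason
    ``"insufficient trials"``.

    Parameters are (n_trials, n_units) arrays of rates in Hz.
    """
    stim_rates = np.atleast_2d(np.asarray(stim_rates, dtype=float))
    baseline_rates = np.atleast_2d(np.asarray(baseline_rates, dtype=float))
    if stim_rates.shape != baseline_rates.shape:
        raise ValueError("stimulus and baseline rate arrays must be paired")
    n_trials, n_units = stim_rates.shape
    rows = []
    mask = np.zeros(n_units, dtype=bool)
    for u in range(n_units):
        mean_rate = stim_rates[:, u].mean()
        if n_trials < 6:
            rows.append(dict(unit=u, mean_rate_hz=mean_rate, p=np.nan,
                             included=False, reason="insufficient trials"))
            continue
        diff = stim_rates[:, u] - baseline_rates[:, u]
        if np.all(diff == 0):
            p = 1.0
        else:
            p = sps.wilcoxon(stim_rates[:, u], baseline_rates[:, u],
                             zero_method="wilcox").pvalue
        higher = mean_rate > baseline_rates[:, u].mean()
        ok = (mean_rate > min_rate_hz) and higher and (p < alpha)
        reason = "included" if ok else (
            "rate below threshold" if mean_rate <= min_rate_hz
            else "not significantly above baseline")
        mask[u] = ok
        rows.append(dict(unit=u, mean_rate_hz=mean_rate, p=p, included=ok,
                         reason=reason))
    return mask, pd.DataFrame(rows)


def thin_counts(counts: np.ndarray, p: float, seed: int) -> np.ndarray:
    """Binomial thinning of spike counts to a shorter counting window."""
    rng = np.random.default_rng(seed)
    ints = np.maximum(np.round(counts), 0).astype(np.int64)
    return rng.binomial(ints, p).astype(float)


def evoked_ranking(stim_counts: np.ndarray, baseline_counts: np.ndarray,
                   stim_window_ms: float, baseline_window_ms: float
                   ) -> np.ndarray:
    """Units ordered by evoked response (stimulus rate minus baseline rate)."""
    ev = (stim_counts.mean(axis=0) / (stim_window_ms / 1000.0)
          - baseline_counts.mean(axis=0) / (baseline_window_ms / 1000.0))
    return np.argsort(-ev, kind="stable")


# --------------------------------------------------- session data access

def _session_frames(session: SyntheticSession) -> pd.DataFrame:
    df = session.presentations.copy()
    df["row"] = np.arange(len(df))
    return df


def _median_change_set(session: SyntheticSession, cued: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows, stimulus labels, and choice labels of the median-change
    presentations and the starting presentation immediately before each
    (first flashes excluded everywhere)."""
    df = _session_frames(session)
    df = df[df["cued"] == cued]
    rows, stim, choice = [], [], []
    for (_, _), trial in df.groupby(["block", "trial"]):
        ch = trial[trial["change_amount"] == 3]
        if ch.empty:
            continue
        ch = ch.iloc[0]
        prev = trial[(trial["flash"] == ch["flash"] - 1)
                     & (trial["first_flash"] == 0)]
        rows.append(int(ch["row"]))
        stim.append(1)
        choice.append(int(ch["choice"]))
        if not prev.empty:
            rows.append(int(prev.iloc[0]["row"]))
            stim.append(0)
            choice.append(0)
    return np.asarray(rows, int), np.asarray(stim, int), np.asarray(choice, int)


def _start_rows(session: SyntheticSession, cued: int) -> np.ndarray:
    """Non-first starting-orientation presentations (rate-window analyses)."""
    df = _session_frames(session)
    sel = (df["cued"] == cued) & (df["change_amount"] == 0) \
        & (df["first_flash"] == 0)
    return df.loc[sel, "row"].to_numpy()


def _change_rows(session: SyntheticSession, cued: int, amount: int
                 ) -> np.ndarray:
    df = _session_frames(session)
    sel = (df["cued"] == cued) & (df["change_amount"] == amount)
    return df.loc[sel, "row"].to_numpy()


# ----------------------------------------------------------- decoders

def _loocv_transfer(train_counts, train_labels, eval_counts, eval_labels,
                    eval_in_train: np.ndarray | None = None,
                    classifier: str = "lda",
                    clf_cache: dict | None = None) -> float:
    """LOOCV where evaluation trials may or may not be part of training.

    ``eval_in_train[i]`` gives the training-set index of evaluation trial i
    (or -1 if it is not a training trial, in which case the full training
    set is used).  ``clf_cache`` memoizes the per-left-out-index classifiers
    so repeated evaluations against the same training set stay cheap.
    """
    n_eval = eval_counts.shape[0]
    if eval_in_train is None:
        eval_in_train = np.full(n_eval, -1)
    if clf_cache is None:
        clf_cache = {}
    correct = 0
    for i in range(n_eval):
        j = int(eval_in_train[i])
        if j not in clf_cache:
            if j < 0:
                clf = _make_classifier(classifier)
                clf.fit(train_counts, train_labels)
            else:
                keep = np.arange(train_counts.shape[0]) != j
                y = train_labels[keep]
                if np.unique(y).size < 2:
                    clf = y[0]  # degenerate fold: majority class sentinel
                else:
                    clf = _make_classifier(classifier)
                    clf.fit(train_counts[keep], y)
            clf_cache[j] = clf
        clf = clf_cache[j]
        pred = clf if np.isscalar(clf) else clf.predict(
            eval_counts[i][None, :])[0]
        correct += int(pred == eval_labels[i])
    return correct / n_eval


@dataclass
class SessionAnalysis:
    """Results of one session's full analysis."""

    included_units: np.ndarray
    inclusion_report: pd.DataFrame
    rate_window: CountingWindow
    decoder_window: CountingWindow
    decoder_performances: pd.DataFrame   # decoder, condition, pop_size, perf
    mean_rsc: dict                       # condition -> mean r_SC
    monkey_axis: np.ndarray | None = None
    axis_cosine: float | None = None
    ladder_results: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)


def specific_and_monkeys_decoders(session: SyntheticSession, cued: int,
                                  pop_sizes, ranking: np.ndarray,
                                  decoder_counts: np.ndarray,
                                  classifier: str = "lda",
                                  min_presentations: int = 10):
    """Specific and subject's decoder performance for one attention condition.

    Both decoders are trained on the same presentations (median changed
    orientation and the starting presentation immediately before it, decoder
    window): the specific decoder on stimulus labels, the subject's decoder
    on saccade/no-saccade choice labels.  Both are evaluated by LOOCV
    against stimulus identity, per population size over the most responsive
    units.  Returns (rows, axis_weights) where axis_weights is the subject's
    decoder axis fit on the full included population.
    """
    rows_idx, stim, choice = _median_change_set(session, cued)
    out = []
    if rows_idx.size < min_presentations:
        return out, None, f"condition cued={cued}: only {rows_idx.size} usable presentations"
    x_all = decoder_counts[rows_idx]
    axis = None
    if np.unique(choice).size >= 2:
        axis, _, _ = fit_linear_readout(x_all, choice, classifier)
    for ps in pop_sizes:
        # a day with fewer included units than requested uses all of them,
        # keeping the requested population-size label
        units = ranking[: min(int(ps), ranking.size)]
        x = x_all[:, units]
        perf_spec = loocv_linear_performance(x, stim, classifier=classifier)
        if np.unique(choice).size < 2:
            perf_monk = np.nan
        else:
            perf_monk = loocv_linear_performance(x, choice, eval_labels=stim,
                                                 classifier=classifier)
        out.append(dict(decoder="specific", cued=cued, pop_size=int(ps),
                        performance=perf_spec))
        out.append(dict(decoder="monkeys", cued=cued, pop_size=int(ps),
                        performance=perf_monk))
    return out, axis, None


def generality_ladder(session: SyntheticSession, decoder_counts: np.ndarray,
                      units: np.ndarray, levels=(1, 2, 3, 4),
                      classifier: str = "lda") -> pd.DataFrame:
    """Decoders of increasing generality (cued condition only).

    For each level k, every k-subset of the non-median change amounts
    {1, 2, 4, 5} trains a linear classifier (changed orientations vs.
    starting orientation, decoder window).  Each decoder is evaluated (i)
    by LOOCV on identifying each of the four non-median changed orientations
    vs. the start, and (ii) by its accuracy predicting the subject's choice
    on the median-change presentations (which never enter training).
    """
    cued = 1
    start = _start_rows(session, cued)
    per_amount = {a: _change_rows(session, cued, a) for a in LADDER_AMOUNTS}
    med_rows, med_stim, med_choice = _median_change_set(session, cued)
    recs = []
    for k in levels:
        for subset in combinations(LADDER_AMOUNTS, k):
            train_rows = np.concatenate(
                [start] + [per_amount[a] for a in subset])
            if any(per_amount[a].size == 0 for a in subset):
                recs.append(dict(k=k, subset=str(subset), eval_amount=None,
                                 performance=np.nan, choice_pred=np.nan,
                                 status="missing change amount"))
                continue
            train_y = np.concatenate(
                [np.zeros(start.size, int)]
                + [np.ones(per_amount[a].size, int) for a in subset])
            xt = decoder_counts[np.asarray(train_rows)][:, units]
            cache: dict = {}
            # (ii) choice prediction on median-change presentations
            if med_rows.size and np.unique(med_choice).size >= 1:
                choice_pred = _loocv_transfer(
                    xt, train_y, decoder_counts[med_rows][:, units],
                    med_choice, classifier=classifier, clf_cache=cache)
            else:
                choice_pred = np.nan
            for a in LADDER_AMOUNTS:
                ev_rows = per_amount[a]
                if ev_rows.size == 0:
                    recs.append(dict(k=k, subset=str(subset), eval_amount=a,
                                     performance=np.nan,
                                     choice_pred=choice_pred,
                                     status="evaluation orientation never shown"))
                    continue
                ev_all = np.concatenate([start, ev_rows])
                ev_y = np.concatenate([np.zeros(start.size, int),
                                       np.ones(ev_rows.size, int)])
                # map evaluation rows back into the training set when shared
                pos_in_train = {r: i for i, r in enumerate(train_rows)}
                eit = np.array([pos_in_train.get(r, -1) for r in ev_all])
                perf = _loocv_transfer(xt, train_y,
                                       decoder_counts[ev_all][:, units],
                                       ev_y, eval_in_train=eit,
                                       classifier=classifier,
                                       clf_cache=cache)
                recs.append(dict(k=k, subset=str(subset), eval_amount=a,
                                 performance=perf, choice_pred=choice_pred,
                                 status="ok"))
    return pd.DataFrame(recs)


def analyze_session(session: SyntheticSession, pop_sizes=(5, 10, 20),
                    seed: int = 0, classifier: str = "lda",
                    run_ladder: bool = True,
                    baseline_window_ms: float = 100.0) -> SessionAnalysis:
    """Full single-session analysis (see module docstring)."""
    rng = np.random.default_rng(seed)
    rate_counts = session.counts                       # 60-260 ms window
    frac = DECODER_WINDOW.length_ms / RATE_WINDOW.length_ms
    assert DECODER_WINDOW.stop_ms <= RATE_WINDOW.stop_ms
    decoder_counts = thin_counts(rate_counts, frac,
                                 seed=int(rng.integers(2 ** 31)))

    # inclusion from starting presentations vs. the per-trial baseline
    start_all = np.concatenate([_start_rows(session, c) for c in (0, 1)])
    stim_rates = rate_counts[start_all] / (RATE_WINDOW.length_ms / 1000.0)
    base = getattr(session, "baseline_counts", None)
    if base is not None:
        reps = int(np.ceil(start_all.size / base.shape[0]))
        base_rates = np.tile(base / (baseline_window_ms / 1000.0),
                             (reps, 1))[: start_all.size]
    else:
        base_rates = np.zeros_like(stim_rates)
    included, report = include_units(stim_rates, base_rates)
    if not included.any():
        included = np.ones(session.n_units, dtype=bool)
        report = report.assign(reason="inclusion fallback: all units kept")
    unit_idx = np.where(included)[0]

    if base is not None:
        ranking_local = evoked_ranking(
            rate_counts[start_all][:, unit_idx], base[:, unit_idx],
            RATE_WINDOW.length_ms, baseline_window_ms)
    else:
        ev = rate_counts[start_all][:, unit_idx].mean(axis=0)
        ranking_local = np.argsort(-ev, kind="stable")
    ranking = unit_idx[ranking_local]

    rows, skipped = [], []
    axis = None
    for cued in (1, 0):
        out, _, skip = specific_and_monkeys_decoders(
            session, cued, pop_sizes,
            ranking, decoder_counts, classifier=classifier)
        rows.extend(out)
        if skip:
            skipped.append(skip)
        if cued == 1:
            # axis-recovery diagnostic: fit the choice readout on the full
            # counting window the generative choice model actually used
            ridx, _, ch = _median_change_set(session, 1)
            if ridx.size and np.unique(ch).size >= 2:
                axis, _, _ = fit_linear_readout(rate_counts[ridx], ch,
                                                classifier)
    perf = pd.DataFrame(rows)

    mean_rsc = {}
    for cued in (0, 1):
        sr = _start_rows(session, cued)
        if sr.size >= 3:
            tm = TrialMatrix(counts=rate_counts[sr][:, unit_idx],
                             theta=np.full(sr.size, 0.0),
                             window=RATE_WINDOW)
            mean_rsc[cued] = noise_correlations(tm).mean_rsc
        else:
            mean_rsc[cued] = np.nan

    cosine = None
    if axis is not None and "planted_axis" in session.params:
        a = session.planted_axis
        cosine = float(axis @ a / (np.linalg.norm(axis) * np.linalg.norm(a)))

    ladder = None
    if run_ladder:
        ladder = generality_ladder(session, decoder_counts, unit_idx,
                                   classifier=classifier)
    return SessionAnalysis(
        included_units=included, inclusion_report=report,
        rate_window=RATE_WINDOW, decoder_window=DECODER_WINDOW,
        decoder_performances=perf, mean_rsc=mean_rsc,
        monkey_axis=axis, axis_cosine=cosine,
        ladder_results=ladder, skipped=skipped)


# -------------------------------------------------- cross-day statistics

def performance_vs_rsc(day_results: pd.DataFrame,
                       rsc_cut: str = "tukey") -> pd.DataFrame:
    """Correlate decoder performance with mean r_SC across day-conditions.

    ``day_results`` needs columns ``decoder, performance, mean_rsc`` (one
    row per day x attention condition x decoder).  Outlying mean-r_SC points
    beyond the Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR, computed on the
    pooled r_SC values) are excluded; both the included-only and
    all-points correlations are reported per decoder.
    """
    df = day_results.dropna(subset=["performance", "mean_rsc"])
    if df.groupby("decoder").size().min() < 5:
        raise ValueError("need >= 5 day-condition points per decoder")
    rsc = df["mean_rsc"].to_numpy()
    q1, q3 = np.percentile(rsc, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (df["mean_rsc"] >= lo) & (df["mean_rsc"] <= hi)
    rows = []
    for dec, g in df.groupby("decoder"):
        for label, gg in [("tukey", g[keep.loc[g.index]]), ("all", g)]:
            x = gg["mean_rsc"].to_numpy()
            y = gg["performance"].to_numpy()
            if np.std(y) == 0 or np.std(x) == 0 or x.size < 3:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
            rows.append(dict(decoder=dec, subset=label, r=r, p=p,
                             n=int(x.size),
                             excluded=int((~keep.loc[g.index]).sum())))
    return pd.DataFrame(rows)


# ----------------------------------------------------------- Williams' t

@dataclass(frozen=True)
class WilliamsResult:
    """Williams/Steiger test of two dependent correlations sharing a variable."""

    t_statistic: float
    p_value: float
    df: int
    inputs: tuple


def williams_test(r_jk: float, r_jh: float, r_kh: float, n: int
                  ) -> WilliamsResult:
    """Compare r_jk with r_jh (both involving variable j), given r_kh.

    Uses the Williams t2 statistic with n - 3 degrees of freedom; the
    two-sided p-value comes from the t distribution.  The statistic is
    antisymmetric under swapping the two compared correlations.
    """
    for name, r in [("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)]:
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    det = (1 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2
           + 2 * r_jk * r_jh * r_kh)
    if det <= 0:
        raise ValueError(
            "correlation triple is not consistent with a positive-definite "
            f"correlation matrix (determinant {det:.3g})")
    rbar = 0.5 * (r_jk + r_jh)
    denom = (2 * det * (n - 1) / (n - 3)
             + rbar ** 2 * (1 - r_kh) ** 3)
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1 + r_kh) / denom)
    df = n - 3
    p = 2 * sps.t.sf(abs(t), df)
    return WilliamsResult(t_statistic=float(t), p_value=float(min(p, 1.0)),
                          df=df, inputs=(r_jk, r_jh, r_kh, n))
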