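"""Canonical experiments: the model-side attention sweep and synthetic days.

Two entry points orchestrate everything the library computes:

* :func:`run_model_experiment` — for each attention level, produce population
  responses (spiking network or fast ring surrogate), then rates, noise
  correlations, factor-analysis eigenvalues, specific (bias-corrected
  Fisher) and general (complex-readout) information across population sizes,
  and the trial-shuffle control;
* :func:`run_session_experiment` — generate many synthetic recording days,
  run the full session pipeline on each, and summarize across days:
  performance-versus-r_SC correlations with Williams' comparison, and the
  generality-ladder trends.

Both are deterministic given the config seed and write CSV tables plus a
JSON manifest embedding the config hash and seed set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import decoders as dec
from .circuit import (
    NetworkConfig,
    build_and_simulate,
    make_orientation_map,
    prepare_network,
)
from .pipeline import analyze_session, performance_vs_rsc, williams_test
from .stats import factor_fit, noise_correlations
from .synthetic import (
    RingModelParams,
    SessionConfig,
    gen_ring_responses,
    gen_session,
    shuffle_trials,
)
from .trialmatrix import TrialMatrix

log = logging.getLogger("v4popcode")

#: day-count presets matching the two recorded subjects
MONKEY1_DAYS = 46
MONKEY2_DAYS = 28

__all__ = [
    "ExperimentConfig",
    "ring_information_sweep",
    "network_attention_comparison",
    "run_model_experiment",
    "session_day_table",
    "ladder_day_summary",
    "run_session_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the two canonical experiments."""

    name: str = "experiment"
    seed: int = 0
    scale: float = 1.0             # multiplies trial counts
    backend: str = "ring"          # "ring" or "network"
    out_dir: str | None = None

    # model-side sweep
    attention_levels: tuple = (0.0, 1.0)
    pop_sizes: tuple = (50, 100, 200)
    theta0: float = 0.5
    dtheta: float = 0.01
    ntr_specific: int = 2000
    n_thetas: int = 50
    trials_per_theta: int = 100
    ring: RingModelParams = field(default_factory=lambda: RingModelParams(
        n_units=200))
    network: NetworkConfig = field(default_factory=NetworkConfig)
    network_sims_per_level: int = 8

    # session experiment
    n_days: int = MONKEY1_DAYS     # MONKEY2_DAYS = 28 is the other preset
    session: SessionConfig = field(default_factory=SessionConfig)
    day_pop_size: int = 20
    day_radial_sd_range: tuple = (0.05, 0.30)
    day_private_sd_range: tuple | None = (1.0, 5.0)
    run_ladder: bool = True
    ladder_days: int | None = None   # run the ladder on this many days only
                                     # (None: all days)

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)
                        if f.name != "out_dir"}  # hash the science, not paths
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(records: list, name: str, t0: float, **params) -> None:
    elapsed = time.perf_counter() - t0
    rec = dict(stage=name, elapsed_s=round(elapsed, 3), **params)
    log.info("stage %s done in %.2fs %s", name, elapsed, params)
    records.append(rec)


def _subset_indices(n_total: int, n_sub: int) -> np.ndarray:
    """Evenly spaced unit subset preserving ring coverage."""
    return np.unique(np.round(np.linspace(0, n_total - 1, n_sub)).astype(int))


# ------------------------------------------------------------- model side

def ring_information_sweep(ring: RingModelParams, attention_levels,
                           pop_sizes, seed: int, theta0: float = 0.5,
                           dtheta: float = 0.01, ntr_specific: int = 2000,
                           n_thetas: int = 50, trials_per_theta: int = 100,
                           shuffle: bool = False) -> pd.DataFrame:
    """Specific and general information vs. population size and attention.

    For each attention level the ring model generates (a) a two-condition
    set at θ0 ± dθ for the bias-corrected Fisher estimator and (b) a
    whole-ring set (``n_thetas`` uniform orientations) for the general
    decoder.  Population sizes are evenly spaced unit subsets of the same
    draws, so curves differ only in the readout dimension.  With
    ``shuffle=True`` both sets are trial-shuffled within condition first.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for level in attention_levels:
        params = replace(ring, attention_level=float(level))
        s_pair = int(rng.integers(2 ** 31))
        s_ring = int(rng.integers(2 ** 31))
        pair = gen_ring_responses(params, [theta0 - dtheta, theta0 + dtheta],
                                  ntr_specific, seed=s_pair)
        grid = np.arange(n_thetas) / n_thetas
        ring_data = gen_ring_responses(params, grid, trials_per_theta,
                                       seed=s_ring)
        if shuffle:
            pair = shuffle_trials(pair, seed=s_pair + 1)
            ring_data = shuffle_trials(ring_data, seed=s_ring + 1)
        for n_sub in pop_sizes:
            idx = _subset_indices(ring.n_units, n_sub)
            i_spec = dec.fisher_info_bc(pair.select_units(idx), dtheta)
            sub = ring_data.select_units(idx)
            gdec = dec.general_weights(sub)
            i_gen = dec.general_info(sub, gdec)
            rows.append(dict(attention=float(level), n_units=int(idx.size),
                             shuffled=shuffle,
                             specific_info=i_spec.value,
                             general_info=i_gen.value))
    return pd.DataFrame(rows)


def information_ratios(sweep: pd.DataFrame) -> pd.DataFrame:
    """Attended/unattended information ratios per population size."""
    lo = sweep["attention"].min()
    hi = sweep["attention"].max()
    out = []
    for n, g in sweep.groupby("n_units"):
        ga = g.set_index("attention")
        out.append(dict(
            n_units=int(n),
            ratio_specific=float(ga.loc[hi, "specific_info"]
                                 / ga.loc[lo, "specific_info"]),
            ratio_general=float(ga.loc[hi, "general_info"]
                                / ga.loc[lo, "general_info"])))
    return pd.DataFrame(out)


def _paired_onesided_p(diff: np.ndarray, rng: np.random.Generator,
                       n_flips: int = 2000) -> float:
    """Sign-flip permutation p for mean(diff) > 0."""
    obs = diff.mean()
    flips = rng.choice([-1.0, 1.0], size=(n_flips, diff.size))
    null = (flips * np.abs(diff)).mean(axis=1)
    return float((1 + np.sum(null >= obs)) / (n_flips + 1))


def network_attention_comparison(cfg: NetworkConfig, attention_levels=(0.0, 1.0),
                                 n_sims: int = 8, seed: int = 0,
                                 n_subsets: int = 30, subset_size: int = 50,
                                 theta: float = 0.5, map_seed: int = 0,
                                 n_factors: int = 5) -> dict:
    """Attention endpoint comparison on the spiking network.

    Runs ``n_sims`` protocol simulations per attention level with a fixed
    stimulus orientation, pools ON-interval V4 spike counts, then compares
    the two levels on ``n_subsets`` random samples of ``subset_size``
    excitatory units: mean rate, mean pairwise r_SC, and the leading
    factor-analysis eigenvalue λ1.  The two levels share simulation seeds
    (common random numbers: identical stimulus-noise, L4 and V1
    realizations), so the comparison isolates the attention manipulation.
    One-sided p-values come from a sign-flip permutation test over the
    paired subset differences.
    """
    omap = make_orientation_map(grid_side=cfg.l4_side, seed=map_seed)
    bank, conn = prepare_network(cfg, omap, conn_seed=map_seed)
    n_on = cfg.protocol.n_intervals
    orientations = np.full(n_on, theta)
    data = {}
    for level in attention_levels:
        parts = []
        for s in range(n_sims):
            _, tm = build_and_simulate(
                cfg, omap, level, orientations,
                seed=seed + 137 * s,
                bank=bank, conn=conn)
            parts.append(tm)
        data[level] = TrialMatrix.concat(parts)

    rng = np.random.default_rng(seed)
    lo, hi = min(attention_levels), max(attention_levels)
    window_s = cfg.protocol.on_ms / 1000.0
    recs = []
    for rep in range(n_subsets):
        units = rng.choice(cfg.n_e, size=subset_size, replace=False)
        row = dict(rep=rep)
        for name, level in [("unatt", lo), ("att", hi)]:
            sub = data[level].select_units(units)
            row[f"rate_{name}"] = sub.counts.mean() / window_s
            row[f"rsc_{name}"] = noise_correlations(sub).mean_rsc
            row[f"lambda1_{name}"] = factor_fit(
                sub.counts, n_factors=n_factors).shared_eigenvalues[0]
        recs.append(row)
    df = pd.DataFrame(recs)
    p_rng = np.random.default_rng(seed + 7)
    pvals = dict(
        rate_increase=_paired_onesided_p(
            (df["rate_att"] - df["rate_unatt"]).to_numpy(), p_rng),
        rsc_decrease=_paired_onesided_p(
            (df["rsc_unatt"] - df["rsc_att"]).to_numpy(), p_rng),
        lambda1_decrease=_paired_onesided_p(
            (df["lambda1_unatt"] - df["lambda1_att"]).to_numpy(), p_rng),
    )
    return dict(subsets=df, p_values=pvals, data=data)


def run_model_experiment(config: ExperimentConfig) -> dict:
    """Full model-side bundle: information curves, ratios, shuffle control,
    and (network backend) the attention comparison of rates/r_SC/λ1."""
    records: list = []
    bundle: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "stages": records, "partial": False}
    try:
        t0 = time.perf_counter()
        sweep = ring_information_sweep(
            config.ring, config.attention_levels, config.pop_sizes,
            seed=config.seed, theta0=config.theta0, dtheta=config.dtheta,
            ntr_specific=max(16, int(config.ntr_specific * config.scale)),
            n_thetas=config.n_thetas,
            trials_per_theta=max(8, int(config.trials_per_theta * config.scale)))
        bundle["info_curves"] = sweep
        bundle["info_ratios"] = information_ratios(sweep)
        _stage(records, "ring_information", t0, backend="ring")

        t0 = time.perf_counter()
        shuffled = ring_information_sweep(
            config.ring, config.attention_levels, config.pop_sizes,
            seed=config.seed, theta0=config.theta0, dtheta=config.dtheta,
            ntr_specific=max(16, int(config.ntr_specific * config.scale)),
            n_thetas=config.n_thetas,
            trials_per_theta=max(8, int(config.trials_per_theta * config.scale)),
            shuffle=True)
        bundle["info_curves_shuffled"] = shuffled
        bundle["info_ratios_shuffled"] = information_ratios(shuffled)
        _stage(records, "shuffle_control", t0)

        if config.backend == "network":
            t0 = time.perf_counter()
            comp = network_attention_comparison(
                config.network,
                attention_levels=(min(config.attention_levels),
                                  max(config.attention_levels)),
                n_sims=config.network_sims_per_level, seed=config.seed)
            bundle["network_subsets"] = comp["subsets"]
            bundle["network_p_values"] = comp["p_values"]
            _stage(records, "network_comparison", t0,
                   n_sims=config.network_sims_per_level)
    except Exception as exc:  # preserve prior stages, mark bundle partial
        bundle["partial"] = True
        bundle["error"] = repr(exc)
        log.exception("model experiment stage failed")
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


# ----------------------------------------------------------- session side

def session_day_table(config: ExperimentConfig) -> tuple[pd.DataFrame, list]:
    """Generate and analyze ``n_days`` synthetic days.

    Day-to-day variation in shared-noise amplitude (radial SD drawn
    uniformly from ``day_radial_sd_range``) drives variation in both mean
    r_SC and subject's-decoder performance, as in real across-day data.
    Returns the day table (one row per day x condition x decoder) and the
    per-day analyses.
    """
    rng = np.random.default_rng(config.seed)
    rows, analyses = [], []
    for day in range(config.n_days):
        sd = rng.uniform(*config.day_radial_sd_range)
        kw = {"radial_noise_sd": float(sd)}
        if config.day_private_sd_range is not None:
            kw["private_noise_sd"] = float(
                rng.uniform(*config.day_private_sd_range))
        ring = replace(config.session.ring, **kw)
        scfg = replace(config.session, ring=ring)
        sess = gen_session(scfg, seed=int(rng.integers(2 ** 31)))
        with_ladder = config.run_ladder and (
            config.ladder_days is None or day < config.ladder_days)
        res = analyze_session(sess, pop_sizes=(config.day_pop_size,),
                              seed=int(rng.integers(2 ** 31)),
                              run_ladder=with_ladder)
        analyses.append(res)
        for _, r in res.decoder_performances.iterrows():
            rows.append(dict(day=day, decoder=r["decoder"], cued=r["cued"],
                             pop_size=r["pop_size"],
                             performance=r["performance"],
                             mean_rsc=res.mean_rsc[r["cued"]],
                             axis_cosine=res.axis_cosine,
                             radial_sd=sd))
    return pd.DataFrame(rows), analyses


def ladder_day_summary(analyses: list) -> pd.DataFrame:
    """Across-days generality-ladder summary.

    For every ladder decoder (k, subset, eval amount): the across-days
    Pearson correlation between its performance and the subject's-decoder
    performance, and its mean choice-prediction accuracy; aggregated per
    generality level k.
    """
    perf_frames, monkey = [], []
    for day, res in enumerate(analyses):
        if res.ladder_results is None:
            continue
        lf = res.ladder_results.assign(day=day)
        perf_frames.append(lf)
        dp = res.decoder_performances
        m = dp[(dp["decoder"] == "monkeys") & (dp["cued"] == 1)]
        monkey.append(dict(day=day,
                           monkey_perf=m["performance"].mean()))
    if not perf_frames:
        return pd.DataFrame()
    ladder = pd.concat(perf_frames, ignore_index=True)
    monkey = pd.DataFrame(monkey)
    ladder = ladder.merge(monkey, on="day")
    rows = []
    for (k, subset, amt), g in ladder[ladder["status"] == "ok"].groupby(
            ["k", "subset", "eval_amount"]):
        if g["performance"].std() == 0 or g["monkey_perf"].std() == 0 \
                or len(g) < 3:
            r = np.nan
        else:
            r = sps.pearsonr(g["performance"], g["monkey_perf"])[0]
        rows.append(dict(k=int(k), subset=subset, eval_amount=amt,
                         corr_with_monkey=r,
                         choice_pred=g["choice_pred"].mean()))
    return pd.DataFrame(rows)


def ladder_trends(summary: pd.DataFrame, per_level: bool = True) -> dict:
    """Spearman trend of ladder statistics against generality level k.

    With ``per_level=True`` (default) the trend is computed on the per-k
    aggregate values — the k-level statistic as a function of k — which
    isolates the generality effect from the large within-level dispersion
    across subsets and evaluation amounts.  ``per_level=False`` pools all
    decoder rows instead.
    """
    out = {}
    for col in ("corr_with_monkey", "choice_pred"):
        g = summary.dropna(subset=[col])
        if g.empty or g["k"].nunique() < 2:
            out[col] = dict(rho=np.nan, p=np.nan)
            continue
        if per_level:
            g = g.groupby("k", as_index=False)[col].mean()
        rho, p = sps.spearmanr(g["k"], g[col])
        out[col] = dict(rho=float(rho), p=float(p))
    return out


def run_session_experiment(config: ExperimentConfig) -> dict:
    """Cross-day bundle: day table, r_SC correlations, Williams test, ladder."""
    records: list = []
    bundle: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "stages": records, "partial": False}
    try:
        t0 = time.perf_counter()
        days, analyses = session_day_table(config)
        bundle["day_table"] = days
        _stage(records, "sessions", t0, n_days=config.n_days)

        t0 = time.perf_counter()
        day_points = days[days["pop_size"] == config.day_pop_size]
        corr = performance_vs_rsc(day_points)
        bundle["performance_vs_rsc"] = corr

        tuk = corr[corr["subset"] == "tukey"].set_index("decoder")
        pts = day_points.pivot_table(index=["day", "cued"], columns="decoder",
                                     values="performance").dropna()
        rsc = day_points.pivot_table(index=["day", "cued"],
                                     values="mean_rsc").loc[pts.index]
        r_mm = float(tuk.loc["monkeys", "r"])
        r_ss = float(tuk.loc["specific", "r"])
        r_ms = float(np.corrcoef(pts["monkeys"], pts["specific"])[0, 1])
        bundle["williams"] = williams_test(r_mm, r_ss, r_ms,
                                           n=int(len(pts)))
        _stage(records, "rsc_correlations", t0)

        if config.run_ladder:
            t0 = time.perf_counter()
            summary = ladder_day_summary(analyses)
            bundle["ladder_summary"] = summary
            bundle["ladder_trends"] = ladder_trends(summary)
            bundle["ladder_trends_pooled"] = ladder_trends(summary,
                                                           per_level=False)
            per_k = summary.groupby("k")[["corr_with_monkey",
                                          "choice_pred"]].mean()
            bundle["ladder_per_k"] = per_k.reset_index()
            _stage(records, "ladder", t0)
    except Exception as exc:
        bundle["partial"] = True
        bundle["error"] = repr(exc)
        log.exception("session experiment stage failed")
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


# ------------------------------------------------------------------ output

def _write_bundle(bundle: dict, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={bundle['config_hash']} seed={bundle['seed']}\n"
    manifest = {"name": config.name, "config_hash": bundle["config_hash"],
                "seed": bundle["seed"], "partial": bundle["partial"],
                "stages": bundle["stages"], "tables": []}
    for key, val in list(bundle.items()):
        if isinstance(val, pd.DataFrame):
            path = out / f"{config.name}_{key}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                val.to_csv(fh, index=False)
            manifest["tables"].append(path.name)
        elif key in ("network_p_values", "ladder_trends"):
            manifest[key] = val
    if "williams" in bundle:
        w = bundle["williams"]
        manifest["williams"] = dict(t=w.t_statistic, p=w.p_value, df=w.df)
    with open(out / f"{config.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
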