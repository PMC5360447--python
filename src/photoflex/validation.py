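"""Simulation-based validation suite.

Each function runs one property study of the pipeline on synthetic data
with known ground truth - artifact-correction recovery, null behavior on
activity-insensitive (YFP-like) sessions, exponential time-constant
recovery, slow-vs-fast learning-rate ordering, inclusion-criteria
calibration, and the anticipatory-licking value ordering - and returns
the measured quantities.  The studies use single sessions of 140 trials
(the low end of the observed per-session range) so the whole suite runs
in minutes; docs/methods.md discusses the problem sizes.
"""

from __future__ import annotations

import dataclasses
import tempfile

import numpy as np

from . import behavior as beh
from . import dynamics as dyn
from . import preprocess as pp
from . import responses as resp
from .config import RunConfig, SimConfig, US_IDENTITIES
from .pipeline import run_pipeline
from .synthetic import (
    generate_licking,
    generate_session,
    generate_trial_schedule,
    simulate_response_course,
)

STUDY_TRIALS = 140  # per-session trial count used by the batch studies


def _single_session_config(seed: int, **kwargs) -> SimConfig:
    return SimConfig(
        n_sessions=1,
        trials_per_session=STUDY_TRIALS,
        reversal_session=0,
        reversal_trial=STUDY_TRIALS // 2,
        seed=int(seed),
        **kwargs,
    )


def yfp_config(config: SimConfig) -> SimConfig:
    """Zero-neural variant: an activity-insensitive fluorophore in the
    signal channel."""
    neural = dataclasses.replace(
        config.neural,
        cs_amplitude={k: 0.0 for k in US_IDENTITIES},
        us_gain=0.0,
        airpuff_us_amplitude=0.0,
    )
    return dataclasses.replace(config, neural=neural)


def artifact_recovery_study(seeds=range(1, 11), slope=0.8, offset=0.02) -> dict:
    """Slope recovery and corrected-vs-clean RMSE over seeded sessions.

    Each session is generated with coupling ``slope`` (a*) and dF/F
    offset ``offset`` (b*), processed by the full mixture + regression
    correction, and compared against the ground-truth clean signal
    pushed through the identical smoothing/baselining.
    """
    slope_errors, rmse_ratios = [], []
    for seed in seeds:
        cfg = _single_session_config(seed)
        cfg = dataclasses.replace(
            cfg, artifact=dataclasses.replace(cfg.artifact, slope=slope, offset=offset)
        )
        bundle = generate_session(cfg)
        sess = pp.process_session(bundle)
        ref = pp.clean_reference_session(bundle)
        corr = np.concatenate(
            [t.corrected[t.valid_mask] for t in sess.trials if t.valid]
        )
        unc = np.concatenate([t.green[t.valid_mask] for t in sess.trials if t.valid])
        clean = np.concatenate([t.green[t.valid_mask] for t in ref.trials if t.valid])
        slope_errors.append(abs(sess.model.slope - slope) / slope)
        rmse_ratios.append(
            float(np.sqrt(np.mean((corr - clean) ** 2))
                  / np.sqrt(np.mean((unc - clean) ** 2)))
        )
    return {
        "slope_rel_errors": np.asarray(slope_errors),
        "rmse_ratios": np.asarray(rmse_ratios),
        "n_within_5pct": int(np.sum(np.asarray(slope_errors) <= 0.05)),
        "n_sessions": len(slope_errors),
    }


def yfp_null_study(n_sessions: int = 100, base_seed: int = 1) -> dict:
    """Event-window null check on zero-neural sessions.

    For each session, every CS and US identity's trial-averaged corrected
    response must satisfy |mean| < 3 x its standard error; returns the
    fraction of sessions where all windows pass.
    """
    passes, max_ts = [], []
    for i in range(n_sessions):
        cfg = yfp_config(_single_session_config(base_seed + i))
        sess = pp.process_session(generate_session(cfg))
        tab = resp.build_response_table(sess)
        ts = [
            abs(sub["amplitude"].mean()) / sub["amplitude"].sem()
            for _, sub in tab[tab["valid"]].groupby(["event_class", "identity"])
        ]
        passes.append(max(ts) < 3.0)
        max_ts.append(max(ts))
    return {
        "pass_fraction": float(np.mean(passes)),
        "n_sessions": n_sessions,
        "max_t": float(np.max(max_ts)),
        "median_t": float(np.median(max_ts)),
    }


def tau_recovery_study(
    taus=(10.0, 50.0, 150.0),
    n_reps: int = 50,
    noise_scale: float = 0.3,
    n_pre: int = 100,
    n_post: int = 400,
    seed: int = 42,
) -> dict:
    """Recovery of (A, B, tau) from noisy exponential courses.

    Courses relax from 2 to 1 (so A=1, |B|=1) with additive noise of SD
    ``noise_scale * |B|``; fits use the full post-reversal course with
    the 225-trial tau cap.  Errors are relative to the true values.
    """
    rng = np.random.default_rng(seed)
    out = {"per_tau": {}, "A_errors": [], "B_errors": []}
    for tau in taus:
        tau_errors = []
        for _ in range(n_reps):
            vals = simulate_response_course(n_pre, n_post, 2.0, 1.0, tau, noise_scale, rng)
            fit = dyn.fit_reversal(
                dyn.build_trial_course(vals, n_pre, -1, 1),
                post_window=n_post,
                tau_cap=225.0,
            )
            tau_errors.append(abs(fit.tau - tau) / tau)
            out["A_errors"].append(abs(fit.A - 1.0))
            out["B_errors"].append(abs(fit.B - 1.0))
        out["per_tau"][tau] = {
            "median_rel_error": float(np.median(tau_errors)),
            "n": n_reps,
        }
    out["A_median_error"] = float(np.median(out.pop("A_errors")))
    out["B_median_error"] = float(np.median(out.pop("B_errors")))
    return out


def opponent_ordering_study(
    n_cohorts: int = 100,
    n_slow: int = 8,
    n_fast: int = 3,
    tau_fast: float = 20.0,
    noise_scale: float = 0.3,
    seed: int = 7,
) -> dict:
    """Slow (tau = 4k) vs fast (tau = k) cohorts: how often the estimated
    mean time constants preserve the true ordering."""
    rng = np.random.default_rng(seed)

    def fitted_tau(tau):
        vals = simulate_response_course(100, 200, 2.0, 1.0, tau, noise_scale, rng)
        return dyn.fit_reversal(dyn.build_trial_course(vals, 100, -1, 1)).tau

    wins = 0
    for _ in range(n_cohorts):
        slow = [fitted_tau(4.0 * tau_fast) for _ in range(n_slow)]
        fast = [fitted_tau(tau_fast) for _ in range(n_fast)]
        wins += float(np.mean(slow)) > float(np.mean(fast))
    return {"ordering_fraction": wins / n_cohorts, "n_cohorts": n_cohorts}


def inclusion_calibration_study(
    n_null: int = 1000, n_constructed: int = 50, alpha: float = 0.05, seed: int = 3
) -> dict:
    """Calibration of the inclusion criteria.

    Null courses (no reversal effect) should be excluded by the pre/post
    t-test at ~(1 - alpha); constructed wrong-trend and tau <= 1 courses
    must be excluded with exactly those reasons.
    """
    rng = np.random.default_rng(seed)
    null_reasons = []
    for _ in range(n_null):
        vals = rng.normal(1.0, 0.3, 300)
        fit = dyn.evaluate_course(dyn.build_trial_course(vals, 100, -1, 1), alpha=alpha)
        null_reasons.append(fit.exclusion_reason)
    wrong_trend_ok = 0
    for _ in range(n_constructed):
        vals = np.concatenate([rng.normal(0.0, 0.1, 100), rng.normal(1.0, 0.1, 200)])
        fit = dyn.evaluate_course(dyn.build_trial_course(vals, 100, -1, 1), alpha=alpha)
        wrong_trend_ok += fit.exclusion_reason == "wrong_trend"
    small_tau_ok = 0
    k = np.arange(1, 201)
    for _ in range(n_constructed):
        post = np.exp(-k / 0.5) + rng.normal(0, 0.005, 200)
        vals = np.concatenate([rng.normal(1.0, 0.05, 100), post])
        fit = dyn.evaluate_course(dyn.build_trial_course(vals, 100, -1, 1), alpha=alpha)
        small_tau_ok += fit.exclusion_reason == "tau_not_gt_1"
    return {
        "null_exclusion_rate": float(
            np.mean([r == "no_pre_post_difference" for r in null_reasons])
        ),
        "n_null": n_null,
        "wrong_trend_fraction": wrong_trend_ok / n_constructed,
        "small_tau_fraction": small_tau_ok / n_constructed,
        "n_constructed": n_constructed,
    }


def anticipatory_ordering_study(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Expert-stage sessions: fraction of seeds in which mean anticipatory
    licking orders the cues as large > small > (neutral ~ air puff)."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_sessions=2,
            trials_per_session=STUDY_TRIALS,
            reversal_session=1,
            reversal_trial=STUDY_TRIALS // 2,
            seed=base_seed + i,
        )
        rng = np.random.default_rng(cfg.seed)
        ev = generate_trial_schedule(cfg, rng, session_index=0)  # expert day (-1)
        licks = generate_licking(ev, cfg, rng)
        trace = beh.lick_rate(licks, float(ev["trial_end"].max()))
        tab = beh.anticipatory_table(ev, trace)
        m = tab[tab["cued"]].groupby("us_id")["anticipatory_lick"].mean()
        wins += m["large"] > m["small"] > max(m["neutral"], m["airpuff"])
    return {"ordering_fraction": wins / n_seeds, "n_seeds": n_seeds}


def end_to_end_demo(seed: int = 0, out_dir=None) -> dict:
    """Full pipeline on one simulated animal (5 sessions around the
    reversal, default generator): returns the fitted reversal time
    constants for licking and cue responses and, when enough mouse-odor
    pairs pass the inclusion criteria, the neural-vs-behavioral tau
    regression."""
    import pandas as pd

    sim = SimConfig(seed=int(seed))
    with tempfile.TemporaryDirectory() as tmp:
        cfg = RunConfig(out_dir=out_dir or tmp, sim=sim)
        report = run_pipeline(cfg)
        fits = pd.read_csv(f"{cfg.out_dir}/fits.tsv", sep="\t")
    out = {"n_courses": len(fits)}
    for kind in ("neural", "licking"):
        sub = fits[(fits["kind"] == kind) & (fits["included"] == True)]  # noqa: E712
        out[f"{kind}_included"] = int(len(sub))
        out[f"{kind}_mean_tau"] = float(sub["tau"].mean()) if len(sub) else float("nan")
    pairs = fits.pivot_table(index="cs_id", columns="kind", values="tau")
    included = fits.pivot_table(index="cs_id", columns="kind", values="included")
    usable = included.all(axis=1)
    if usable.sum() >= 3:
        reg = dyn.regress_tau(
            pairs.loc[usable, "neural"], pairs.loc[usable, "licking"]
        )
        out["tau_regression_slope"] = reg["slope"]
        out["tau_regression_r_squared"] = reg["r_squared"]
        out["n_pairs_above_identity"] = reg["n_above_identity"]
    return out
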