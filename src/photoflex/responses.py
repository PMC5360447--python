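"""Event-aligned response amplitudes and their summaries.

A CS response is the mean artifact-corrected dF/F over the 1.5 s after
odor onset (the per-trial dF/F is already referenced to the pre-odor
second, so no further baseline is removed); a US response is the mean
over the 1.5 s after outcome delivery minus the mean over the 1 s before
it.  Two z-scoring conventions are provided: within the expert
(pre-reversal) phase pooling all CS and US responses per animal, and
across days per animal and event identity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DffSession, DffTrial

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroVarianceError",
    "extract_cs_response",
    "extract_us_response",
    "build_response_table",
    "zscore_group",
    "with_zscores",
    "day_summary",
    "pool_cued_uncued",
]


class ZeroVarianceError(RuntimeError):
    pass


def _window_mean(trial: DffTrial, start: float, end: float) -> float:
    """Mean corrected dF/F over the half-open window [start, end) in
    trial-relative seconds; NaN when the window is not fully inside the
    trial."""
    if trial.corrected is None:
        raise ValueError("trial has no corrected trace; apply the artifact correction first")
    fs = 1.0  # windows expressed on the trial's own time axis
    t = trial.t
    if t.size == 0 or start < t[0] or end > t[-1] + (t[1] - t[0] if t.size > 1 else 0):
        return float("nan")
    mask = (t >= start) & (t < end)
    if not mask.any():
        return float("nan")
    return float(trial.corrected[mask].mean())


def extract_cs_response(trial: DffTrial, window: float = 1.5) -> float:
    """Mean corrected dF/F over [odor onset, odor onset + window)."""
    if not trial.valid or not trial.cued:
        return float("nan")
    return _window_mean(trial, 0.0, window)


def extract_us_response(
    trial: DffTrial, window: float = 1.5, baseline: float = 1.0
) -> float:
    """Mean corrected dF/F over [US, US + window) minus the mean over
    [US - baseline, US).

    A slow CS transient still decaying through the pre-US baseline pushes
    a response-free US window negative - an expected signature, not an
    error.
    """
    if not trial.valid:
        return float("nan")
    u = trial.us_time_rel
    resp = _window_mean(trial, u, u + window)
    base = _window_mean(trial, u - baseline, u)
    return resp - base


def build_response_table(
    session: DffSession,
    animal: str = "sim",
    window: float = 1.5,
    us_baseline: float = 1.0,
) -> pd.DataFrame:
    """Tidy table with one row per trial-event (CS rows for cued trials,
    US rows for all trials)."""
    rows = []
    for tr, ev in zip(session.trials, session.events.itertuples()):
        common = {
            "animal": animal,
            "trial_index": tr.trial_index,
            "global_trial": int(ev.global_trial),
            "session_day": tr.session_day,
            "trials_since_reversal": int(ev.trials_since_reversal),
            "cs_id": ev.cs_id,
            "us_id": ev.us_id,
            "cued": tr.cued,
        }
        if tr.cued:
            amp = extract_cs_response(tr, window)
            rows.append(
                {**common, "event_class": "CS", "identity": f"CS{int(ev.cs_id)}",
                 "amplitude": amp, "valid": bool(np.isfinite(amp))}
            )
        amp = extract_us_response(tr, window, us_baseline)
        rows.append(
            {**common, "event_class": "US", "identity": ev.us_id,
             "amplitude": amp, "valid": bool(np.isfinite(amp))}
        )
    return pd.DataFrame(rows)


def zscore_group(
    df: pd.DataFrame, value_col: str = "amplitude", group_cols=("animal",)
) -> pd.Series:
    """Within-group z-scores, (x - mean) / sd with the n-1 denominator.

    Raises :class:`ZeroVarianceError` naming the first group with fewer
    than two values or zero variance.
    """
    group_cols = list(group_cols)

    def _z(s: pd.Series) -> pd.Series:
        vals = s.dropna()
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            raise ZeroVarianceError(f"group {s.name!r} has <2 values or zero variance")
        return (s - vals.mean()) / vals.std(ddof=1)

    if not group_cols:
        return _z(df[value_col])
    return df.groupby(group_cols, dropna=False, group_keys=False)[value_col].apply(_z)


def with_zscores(df: pd.DataFrame, expert_days=(-2, -1)) -> pd.DataFrame:
    """Add the two z-scoring conventions as columns.

    ``z_expert``: per animal, mean/SD estimated from all valid CS and US
    responses on the expert (pre-reversal) days and applied to every row,
    so the amplitudes of responses to different events are comparable.
    ``z_across_days``: per animal and event identity, z-scored across all
    days.
    """
    out = df.copy()
    out["z_expert"] = np.nan
    for animal, sub in out.groupby("animal"):
        expert = sub[sub["session_day"].isin(expert_days) & sub["valid"]]
        vals = expert["amplitude"].dropna()
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            raise ZeroVarianceError(f"animal {animal!r} has no usable expert-phase responses")
        out.loc[sub.index, "z_expert"] = (sub["amplitude"] - vals.mean()) / vals.std(ddof=1)
    out["z_across_days"] = zscore_group(
        out, "amplitude", ["animal", "event_class", "identity"]
    )
    return out


def day_summary(
    df: pd.DataFrame,
    value_col: str = "z_across_days",
    baseline_days=(-2, -1),
) -> pd.DataFrame:
    """Day x identity means with comparisons to the pre-reversal baseline.

    Returns per (event_class, identity, day): mean, SEM (n-1 SD), n, and
    a Welch two-sample t statistic/p-value against the pooled responses
    of the baseline days.  When the baseline days are absent the
    comparisons are NaN (logged), not an error.
    """
    if df["session_day"].nunique() < 2:
        raise ValueError("need at least two days of data")
    valid = df[df["valid"]]
    rows = []
    for (cls, ident), sub in valid.groupby(["event_class", "identity"]):
        base = sub[sub["session_day"].isin(baseline_days)][value_col].dropna()
        if base.empty:
            logger.warning("no baseline-day responses for %s %s; comparisons skipped", cls, ident)
        for day, day_sub in sub.groupby("session_day"):
            vals = day_sub[value_col].dropna()
            t = p = np.nan
            if len(base) >= 2 and len(vals) >= 2:
                if vals.var(ddof=1) == 0 and base.var(ddof=1) == 0:
                    # degenerate but well-defined: identical constants differ by 0
                    t, p = (0.0, 1.0) if vals.mean() == base.mean() else (np.inf, 0.0)
                else:
                    t, p = stats.ttest_ind(vals, base, equal_var=False)
            rows.append(
                {
                    "event_class": cls,
                    "identity": ident,
                    "session_day": day,
                    "mean": vals.mean(),
                    "sem": vals.sem(ddof=1) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                    "t_vs_baseline": t,
                    "p_vs_baseline": p,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["event_class", "identity", "session_day"]
    ).reset_index(drop=True)


def pool_cued_uncued(df: pd.DataFrame, value_col: str = "amplitude") -> pd.DataFrame:
    """Predicted-vs-unpredicted US summary over pooled sessions.

    Per US identity, mean +/- SEM of the US responses split by the cued
    flag.  Raises when no uncued trials are present.
    """
    us = df[(df["event_class"] == "US") & df["valid"]]
    if not (~us["cued"]).any():
        raise ValueError("no uncued trials in the pooled responses")
    rows = []
    for (ident, cued), sub in us.groupby(["us_id", "cued"]):
        vals = sub[value_col].dropna()
        rows.append(
            {
                "us_id": ident,
                "cued": cued,
                "mean": vals.mean(),
                "sem": vals.sem(ddof=1) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows).sort_values(["us_id", "cued"]).reset_index(drop=True)
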