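"""Licking and eye-movement metrics.

Lick rate is the 1 kHz lick indicator convolved with a unit-area
Gaussian of 50 ms SD (scaled to Hz); anticipatory licking is the mean
rate 500-2800 ms after odor onset minus the mean over -500..500 ms
around onset; bouts are runs of licks separated by no more than 315 ms;
the blink/eye-movement metric is the first difference of the per-frame
mean pixel intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import gaussian_smooth

__all__ = [
    "LickRateTrace",
    "lick_rate",
    "anticipatory_lick",
    "anticipatory_table",
    "segment_lick_bouts",
    "blink_metric",
    "detect_blink_events",
]


@dataclass
class LickRateTrace:
    """Smoothed instantaneous lick rate in Hz on a uniform time grid."""

    time: np.ndarray
    rate: np.ndarray
    sample_rate: float

    def window_mean(self, start: float, end: float) -> float:
        """Mean rate over the half-open window [start, end); NaN when the
        window is clipped by the session edges."""
        i0 = int(round(start * self.sample_rate))
        i1 = int(round(end * self.sample_rate))
        if i0 < 0 or i1 > self.rate.size or i1 <= i0:
            return float("nan")
        return float(self.rate[i0:i1].mean())


def lick_rate(
    lick_times: np.ndarray,
    session_duration: float,
    sample_rate: float = 1000.0,
    sd_ms: float = 50.0,
) -> LickRateTrace:
    """Smoothed lick-rate trace.

    The binary lick indicator (counts per sample) is convolved with a
    unit-sum Gaussian kernel and multiplied by the sample rate, so a
    single lick integrates to 1 and a steady train at r Hz reads r Hz.
    """
    lick_times = np.asarray(lick_times, dtype=float)
    if lick_times.size and (lick_times.min() < 0 or lick_times.max() > session_duration):
        raise ValueError("lick times must lie within [0, session_duration]")
    n = int(round(session_duration * sample_rate))
    indicator = np.zeros(n)
    if lick_times.size:
        idx = np.clip(np.round(lick_times * sample_rate).astype(int), 0, n - 1)
        np.add.at(indicator, idx, 1.0)
    rate = gaussian_smooth(indicator, sd_ms, sample_rate) * sample_rate
    t = np.arange(n) / sample_rate
    return LickRateTrace(time=t, rate=rate, sample_rate=sample_rate)


def anticipatory_lick(
    trace: LickRateTrace,
    odor_onset: float,
    window: tuple = (0.5, 2.8),
    baseline: tuple = (-0.5, 0.5),
) -> float:
    """Anticipatory-licking metric for one trial (Hz).

    Mean rate over ``odor_onset + window`` minus the mean over
    ``odor_onset + baseline``; NaN when either window is clipped by the
    recording edge (the trial should then be flagged invalid).
    """
    resp = trace.window_mean(odor_onset + window[0], odor_onset + window[1])
    base = trace.window_mean(odor_onset + baseline[0], odor_onset + baseline[1])
    return resp - base


def anticipatory_table(
    events: pd.DataFrame,
    trace: LickRateTrace,
    window: tuple = (0.5, 2.8),
    baseline: tuple = (-0.5, 0.5),
    max_ili: float = 0.315,
    lick_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-trial behavior table: anticipatory lick metric for every cued
    trial (NaN for uncued trials) plus bout counts per trial window."""
    bouts = None
    if lick_times is not None:
        bouts = segment_lick_bouts(lick_times, max_ili)
    rows = []
    for row in events.itertuples():
        if bool(row.cued):
            val = anticipatory_lick(trace, row.odor_onset, window, baseline)
        else:
            val = np.nan
        n_bouts = 0
        if bouts is not None and len(bouts):
            in_trial = (bouts["start"] >= row.trial_start) & (bouts["start"] < row.trial_end)
            n_bouts = int(in_trial.sum())
        rows.append(
            {
                "trial_index": int(row.trial_index),
                "global_trial": int(row.global_trial),
                "session_day": int(row.session_day),
                "trials_since_reversal": int(row.trials_since_reversal),
                "cs_id": row.cs_id,
                "us_id": row.us_id,
                "cued": bool(row.cued),
                "anticipatory_lick": val,
                "n_bouts": n_bouts,
                "valid": bool(np.isfinite(val)) if bool(row.cued) else False,
            }
        )
    return pd.DataFrame(rows)


def segment_lick_bouts(lick_times: np.ndarray, max_ili: float = 0.315) -> pd.DataFrame:
    """Greedy chaining of licks into bouts.

    Licks separated by at most ``max_ili`` (strictly greater gaps split)
    belong to the same bout; single licks are kept with ``is_single``
    set.  Columns: start, end, n_licks, is_single.
    """
    t = np.asarray(lick_times, dtype=float)
    cols = {"start": float, "end": float, "n_licks": int, "is_single": bool}
    if t.size == 0:
        return pd.DataFrame({k: pd.Series(dtype=v) for k, v in cols.items()})
    if np.any(np.diff(t) < 0):
        raise ValueError("lick times must be sorted")
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps > max_ili)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    n = ends - starts + 1
    return pd.DataFrame(
        {
            "start": t[starts],
            "end": t[ends],
            "n_licks": n.astype(int),
            "is_single": n == 1,
        }
    )


def blink_metric(frame_means: np.ndarray) -> np.ndarray:
    """Frame-to-frame change of the mean eye-region pixel intensity.

    Element ``k`` is ``frame_means[k+1] - frame_means[k]``; blink starts
    and ends appear as sudden positive and negative deflections.
    """
    x = np.asarray(frame_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two frames")
    return np.diff(x)


def detect_blink_events(movement: np.ndarray, threshold: float) -> pd.DataFrame:
    """Threshold the movement series into candidate blink starts/ends.

    A start is a frame-difference above ``+threshold``, an end one below
    ``-threshold``.  The threshold is in the units of the frame-mean
    series and should be calibrated per recording (e.g. a multiple of the
    series' robust SD); no default is imposed.
    """
    m = np.asarray(movement, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    starts = np.flatnonzero(m > threshold)
    ends = np.flatnonzero(m < -threshold)
    kind = ["start"] * starts.size + ["end"] * ends.size
    frames = np.concatenate([starts, ends]) if starts.size + ends.size else np.empty(0, int)
    out = pd.DataFrame({"frame": frames.astype(int), "kind": kind})
    return out.sort_values("frame", kind="stable").reset_index(drop=True)
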