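"""Synthetic dual-color photometry sessions with known ground truth.

Generates trial-structured classical-conditioning sessions: a schedule of
four odor cues mapped to large reward / small reward / neutral / air puff
(reversed mid-experiment), lick bouts with value-scaled anticipatory
licking that relaxes exponentially after the reversal, and two 1 kHz
fluorescence channels that share sparse movement artifacts, so every
downstream analysis stage can be validated without any recorded data.

All randomness flows through explicitly threaded ``numpy`` generators;
an identical :class:`~photoflex.config.SimConfig` (including its seed)
reproduces a bit-identical experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import segment_lick_bouts
from .config import SimConfig, US_IDENTITIES, US_VALUE

__all__ = [
    "SessionBundle",
    "relaxation",
    "generate_trial_schedule",
    "generate_licking",
    "generate_fluorescence",
    "generate_session",
    "generate_experiment",
    "simulate_response_course",
]

EVENT_COLUMNS = [
    "trial_index",
    "global_trial",
    "session_day",
    "cs_id",
    "cued",
    "us_id",
    "odor_onset",
    "us_onset",
    "trial_start",
    "trial_end",
    "foreperiod",
    "post_reversal",
    "trials_since_reversal",
]


@dataclass
class SessionBundle:
    """One session's raw traces, lick times, event table and (for
    synthetic sessions) the generative ground truth."""

    green_raw: np.ndarray
    red_raw: np.ndarray
    lick_times: np.ndarray
    events: pd.DataFrame
    sample_rate: float
    session_index: int = 0
    ground_truth: Optional[dict] = None

    def validate(self) -> None:
        if self.green_raw.shape != self.red_raw.shape:
            raise ValueError("channel traces must have equal length")
        if self.lick_times.size and np.any(np.diff(self.lick_times) <= 0):
            raise ValueError("lick times must be strictly increasing")
        duration = self.green_raw.size / self.sample_rate
        if (self.events["trial_end"] > duration + 1e-9).any():
            raise ValueError("event times exceed the trace duration")


def relaxation(old: float, new: float, k, tau: float):
    """Exponential relaxation of a learned quantity after the reversal.

    ``k`` counts trials since the reversal (k >= 1 on the first
    post-reversal trial; k <= 0 returns ``old``).  ``tau <= 0`` switches
    in a single trial.
    """
    k = np.asarray(k, dtype=float)
    if tau <= 0:
        frac = (k > 0).astype(float)
    else:
        frac = np.where(k > 0, 1.0 - np.exp(-k / tau), 0.0)
    out = old + (new - old) * frac
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# trial schedule


def generate_trial_schedule(
    config: SimConfig,
    rng: np.random.Generator,
    session_index: int = 0,
    n_trials: Optional[int] = None,
    global_trial_start: int = 0,
    global_reversal_trial: Optional[int] = None,
) -> pd.DataFrame:
    """Event table for one session.

    Per cued trial the CS is uniform over 1-4 and the US follows the
    pre- or post-reversal map; uncued trials occur with probability
    ``uncued_fraction`` and deliver a uniformly drawn US at the scheduled
    cue time.  Timing draws: foreperiod U(3,4) s, odor 1 s, trace 2 s
    (so US onset - odor onset = 3 s on cued trials), ITI U(4,8) s.
    """
    tm = config.timing
    day = session_index - config.reversal_session
    if n_trials is None:
        n_trials = config.trials_per_session
    if n_trials is None:
        n_trials = int(np.clip(round(rng.normal(223.0, 30.0)), 140, 346))
    if day == 0 and config.reversal_trial >= n_trials:
        raise ValueError(
            f"reversal_trial ({config.reversal_trial}) must be smaller than the "
            f"number of trials in the reversal session ({n_trials})"
        )
    if global_reversal_trial is None:
        if day == 0:
            global_reversal_trial = global_trial_start + config.reversal_trial
        elif day < 0:
            global_reversal_trial = np.iinfo(np.int64).max  # never reached
        else:
            global_reversal_trial = global_trial_start - 10**6  # long since reversed

    rows = []
    cursor = 0.0
    for i in range(n_trials):
        g = global_trial_start + i
        post = g >= global_reversal_trial
        k = int(g - global_reversal_trial + 1) if post else 0
        foreperiod = rng.uniform(*tm.foreperiod_range)
        iti = rng.uniform(*tm.iti_range)
        cued = bool(rng.random() >= config.uncued_fraction)
        trial_start = cursor
        if cued:
            cs = int(rng.integers(1, 5))
            us = (config.cs_us_map_post if post else config.cs_us_map_pre)[cs]
            odor_onset = trial_start + foreperiod
            us_onset = odor_onset + tm.odor_duration + tm.trace_duration
        else:
            cs = pd.NA
            us = US_IDENTITIES[int(rng.integers(0, 4))]
            odor_onset = np.nan
            us_onset = trial_start + foreperiod
        trial_end = us_onset + tm.us_window + iti
        cursor = trial_end
        rows.append(
            (i, g, day, cs, cued, us, odor_onset, us_onset, trial_start, trial_end,
             foreperiod, post, k)
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["cs_id"] = events["cs_id"].astype("Int64")
    return events


# ---------------------------------------------------------------------------
# licking


def _dead_time_poisson(rate, t0, t1, refractory, rng) -> np.ndarray:
    """Poisson events on [t0, t1) with a dead time.

    The driving intensity is compensated (lambda = r / (1 - r*tau)) so
    the realized rate equals ``rate`` in expectation.
    """
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    lam = rate / (1.0 - rate * refractory)
    n = rng.poisson(lam * (t1 - t0))
    if n == 0:
        return np.empty(0)
    t = np.sort(rng.uniform(t0, t1, n))
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] > refractory:
            keep.append(x)
    return np.asarray(keep)


def generate_licking(
    events: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Lick timestamps (s, 1 ms resolution) for one session.

    Baseline licking is emitted as spontaneous bouts (geometric size,
    ~140 ms intra-bout intervals) whose overall rate equals the
    configured baseline.  On cued trials an anticipatory term is added
    between odor onset + 0.5 s and US delivery, at the value-scaled rate
    that relaxes from the pre- toward the post-reversal association; a
    consummatory term follows reward delivery.
    """
    b = config.behavior
    duration = float(events["trial_end"].max())
    chunks = []

    # spontaneous bouts over the whole session
    seed_rate = b.baseline_rate / b.bout_size_mean
    n_seeds = rng.poisson(seed_rate * duration)
    seeds = np.sort(rng.uniform(0, duration, n_seeds))
    for s in seeds:
        n = int(rng.geometric(1.0 / b.bout_size_mean))
        ilis = np.clip(
            rng.normal(b.intra_bout_ili, 0.02, n - 1),
            b.refractory + 0.01,
            0.31,
        )
        chunks.append(s + np.concatenate([[0.0], np.cumsum(ilis)]))

    for row in events.itertuples():
        k = row.trials_since_reversal
        if row.cued:
            cs = int(row.cs_id)
            r_old = b.anticipatory_rate[config.cs_us_map_pre[cs]]
            r_new = b.anticipatory_rate[config.cs_us_map_post[cs]]
            r = relaxation(r_old, r_new, k, b.lick_adaptation_tau)
            if r < 0:
                raise ValueError("anticipatory lick rate became negative")
            chunks.append(
                _dead_time_poisson(r, row.odor_onset + 0.5, row.us_onset, b.refractory, rng)
            )
        r_cons = b.consummatory_rate[row.us_id]
        chunks.append(
            _dead_time_poisson(
                r_cons, row.us_onset, row.us_onset + b.consummatory_duration, b.refractory, rng
            )
        )

    licks = np.concatenate(chunks) if chunks else np.empty(0)
    licks = np.unique(np.round(licks[(licks >= 0) & (licks <= duration)], 3))
    return licks


# ---------------------------------------------------------------------------
# fluorescence


def _double_exp_kernel(rise: float, decay: float, fs: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials transient kernel."""
    t = np.arange(0.0, rise + 6.0 * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel rise must be shorter than decay")
    return k / peak


def _plateau_kernel(duration: float, edge_sd: float, fs: float) -> np.ndarray:
    """Peak-normalized sustained-epoch kernel: a boxcar with Gaussian
    edges (movement epochs shift the fluorescence for their whole
    duration, giving the control channel a shifted second mode)."""
    from .preprocess import gaussian_smooth

    pad = int(round(4 * edge_sd * fs))
    box = np.zeros(int(round(duration * fs)) + 2 * pad)
    box[pad:-pad] = 1.0
    k = gaussian_smooth(box, edge_sd * 1000.0, fs)
    return k / k.max()


def _per_trial_amplitudes(events: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Ground-truth CS and US transient amplitudes for every trial."""
    nc = config.neural
    tau_cs = nc.effective_cs_tau
    cs_amp = np.full(len(events), np.nan)
    us_amp = np.zeros(len(events))
    predicted = np.zeros(len(events))
    for i, row in enumerate(events.itertuples()):
        k = row.trials_since_reversal
        if row.cued:
            cs = int(row.cs_id)
            a_old = nc.cs_amplitude[config.cs_us_map_pre[cs]]
            a_new = nc.cs_amplitude[config.cs_us_map_post[cs]]
            cs_amp[i] = relaxation(a_old, a_new, k, tau_cs)
            v_old = US_VALUE[config.cs_us_map_pre[cs]]
            v_new = US_VALUE[config.cs_us_map_post[cs]]
            predicted[i] = relaxation(v_old, v_new, k, nc.us_surprise_decay)
        else:
            predicted[i] = 0.0  # nothing predicts an uncued outcome
        surprise = US_VALUE[row.us_id] - predicted[i]
        if nc.profile == "serotonin":
            us_amp[i] = nc.us_gain * abs(surprise)
            if row.us_id == "airpuff":
                us_amp[i] += nc.airpuff_us_amplitude
        else:
            us_amp[i] = nc.us_gain * surprise
    return pd.DataFrame(
        {"cs_amplitude": cs_amp, "us_amplitude": us_amp, "predicted_value": predicted}
    )


def generate_fluorescence(
    events: pd.DataFrame,
    lick_times: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple:
    """Two raw fluorescence channels plus ground truth.

    The clean neural dF/F is a sum of event-locked calcium transients; the
    artifact dF/F is a sparse train of fast biexponential dips (log-normal
    amplitudes, a configured fraction locked to lick-bout onsets) shared
    by both channels:

    ``red_raw   = F0_red  * (1 + artifact + noise)``
    ``green_raw = F0_green* (1 + clean + a* . artifact + b* . m(t) + noise)``

    where ``m(t)`` is 1 everywhere except inside each trial's own F0
    window, so that after per-trial baselining the green dF/F equals
    ``clean + a* . red dF/F + b*`` in expectation.
    """
    tm, art, nz = config.timing, config.artifact, config.noise
    fs = tm.sample_rate
    duration = float(events["trial_end"].max()) + 1.0
    n = int(round(duration * fs))

    amps = _per_trial_amplitudes(events, config)
    neural_imp = np.zeros(n)
    for i, row in enumerate(events.itertuples()):
        if row.cued:
            neural_imp[int(round(row.odor_onset * fs))] += amps.at[i, "cs_amplitude"]
        neural_imp[int(round(row.us_onset * fs))] += amps.at[i, "us_amplitude"]
    kernel = _double_exp_kernel(config.neural.kernel_rise, config.neural.kernel_decay, fs)
    clean = signal.fftconvolve(neural_imp, kernel)[:n]

    # artifact transient times: background Poisson + lick-bout-locked
    n_bg = rng.poisson(art.rate * duration)
    times = [rng.uniform(0, duration, n_bg)]
    bouts = segment_lick_bouts(lick_times)
    if len(bouts):
        starts = bouts["start"].to_numpy()
        times.append(starts[rng.random(starts.size) < art.p_lick_locked])
    times = np.sort(np.concatenate(times))
    amp = rng.lognormal(np.log(art.amp_median), art.amp_sigma, times.size)
    flip = rng.random(times.size) >= art.p_majority_sign
    amp *= np.where(flip, -art.sign, art.sign)
    art_imp = np.zeros(n)
    idx = np.clip(np.round(times * fs).astype(int), 0, n - 1)
    np.add.at(art_imp, idx, amp)
    if art.shape == "plateau":
        art_kernel = _plateau_kernel(art.duration, art.edge_sd, fs)
    else:
        art_kernel = _double_exp_kernel(art.kernel_rise, art.kernel_decay, fs)
    artifact = signal.fftconvolve(art_imp, art_kernel)[:n]

    # b* mask: zero inside each trial's own F0 baseline window
    offset_mask = np.ones(n)
    for row in events.itertuples():
        align = row.odor_onset if row.cued else row.us_onset
        i1 = int(round(align * fs))
        i0 = max(i1 - int(round(fs)), 0)
        offset_mask[i0:i1] = 0.0

    green = nz.f0_green * (
        1.0
        + clean
        + art.slope * artifact
        + art.offset * offset_mask
        + rng.normal(0.0, nz.green_sd, n)
    )
    red = nz.f0_red * (1.0 + artifact + rng.normal(0.0, nz.red_sd, n))

    ground_truth = {
        "clean_dff": clean,
        "artifact_dff": artifact,
        "offset_mask": offset_mask,
        "slope": art.slope,
        "offset": art.offset,
        "cs_amplitude": amps["cs_amplitude"].to_numpy(),
        "us_amplitude": amps["us_amplitude"].to_numpy(),
        "predicted_value": amps["predicted_value"].to_numpy(),
        "cs_adaptation_tau": config.neural.effective_cs_tau,
        "lick_adaptation_tau": config.behavior.lick_adaptation_tau,
    }
    return green, red, ground_truth


# ---------------------------------------------------------------------------
# sessions and experiments


def generate_session(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    session_index: int = 0,
    n_trials: Optional[int] = None,
    global_trial_start: int = 0,
    global_reversal_trial: Optional[int] = None,
) -> SessionBundle:
    """One complete synthetic session (schedule, licks, fluorescence)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = generate_trial_schedule(
        config, rng, session_index, n_trials, global_trial_start, global_reversal_trial
    )
    licks = generate_licking(events, config, rng)
    green, red, truth = generate_fluorescence(events, licks, config, rng)
    bundle = SessionBundle(
        green_raw=green,
        red_raw=red,
        lick_times=licks,
        events=events,
        sample_rate=config.timing.sample_rate,
        session_index=session_index,
        ground_truth=truth,
    )
    bundle.validate()
    return bundle


def generate_experiment(config: SimConfig) -> List[SessionBundle]:
    """All sessions of one animal, with session days relative to the
    reversal session and a single global trial axis across sessions."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_sessions + 1)
    count_rng = np.random.default_rng(children[0])
    counts = []
    for _ in range(config.n_sessions):
        if config.trials_per_session is not None:
            counts.append(config.trials_per_session)
        else:
            counts.append(int(np.clip(round(count_rng.normal(223.0, 30.0)), 140, 346)))
    if config.reversal_trial >= counts[config.reversal_session]:
        raise ValueError(
            f"reversal_trial ({config.reversal_trial}) must be smaller than the "
            f"number of trials in the reversal session ({counts[config.reversal_session]})"
        )
    global_reversal = sum(counts[: config.reversal_session]) + config.reversal_trial
    sessions = []
    start = 0
    for s in range(config.n_sessions):
        rng = np.random.default_rng(children[s + 1])
        sessions.append(
            generate_session(config, rng, s, counts[s], start, global_reversal)
        )
        start += counts[s]
    return sessions


# ---------------------------------------------------------------------------
# trial-course simulator (dynamics-level)


def simulate_response_course(
    n_pre: int,
    n_post: int,
    old: float,
    new: float,
    tau: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial metric course around a reversal: constant ``old`` before,
    relaxing to ``new`` with time constant ``tau`` (trials) after, plus
    i.i.d. Gaussian noise.  This is the same relaxation law the session
    generator applies to cue amplitudes and anticipatory lick rates,
    expressed directly on a trial axis."""
    k = np.arange(1, n_post + 1)
    post = relaxation(old, new, k, tau)
    values = np.concatenate([np.full(n_pre, old), post])
    return values + rng.normal(0.0, noise_sd, values.size)
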