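"""Raw two-channel traces to artifact-corrected per-trial dF/F.

The correction follows the dual-fluorophore regression procedure: the
activity-independent (red) channel's per-trial dF/F distribution is fit
with a two-Gaussian mixture, the crossing point of the two weighted
component densities defines a boundary separating quiescent samples from
movement-artifact samples, an ordinary least-squares line of green on
red is fit on the artifact side of that boundary, and the green channel
is corrected per sample as ``green - a*red - b``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ArtifactModel",
    "DffTrial",
    "DffSession",
    "DegenerateMixtureError",
    "CrossingPointError",
    "DegenerateRegressorError",
    "downsample",
    "gaussian_smooth",
    "compute_dff",
    "fit_red_mixture",
    "fit_artifact_regression",
    "correct_green",
    "process_session",
    "clean_reference_session",
]


class DegenerateMixtureError(RuntimeError):
    """The two-Gaussian fit collapsed (no second mode, or a vanishing
    component)."""


class CrossingPointError(RuntimeError):
    """No density crossing exists between the two component means."""


class DegenerateRegressorError(RuntimeError):
    """The selected red dF/F values have (near-)zero variance."""


# ---------------------------------------------------------------------------
# basic signal operations


def downsample(trace: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean decimation by an integer factor.

    A trailing partial block is discarded.  ``factor=1`` is the identity.
    """
    if not float(factor).is_integer() or factor <= 0:
        raise ValueError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    trace = np.asarray(trace, dtype=float)
    if factor == 1:
        return trace.copy()
    n = (trace.size // factor) * factor
    return trace[:n].reshape(-1, factor).mean(axis=1)


def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    # np.pad(mode="reflect") caps the pad width at n-1 per call; iterate for
    # very short inputs so smoothing stays defined down to length 2.
    while pad > 0:
        step = min(pad, x.size - 1)
        if step <= 0:
            raise ValueError("trace too short for the requested smoothing kernel")
        x = np.pad(x, step, mode="reflect")
        pad -= step
    return x


def gaussian_kernel(sd_ms: float, sample_rate: float = 1000.0, truncate: float = 4.0) -> np.ndarray:
    """Unit-sum Gaussian kernel truncated at +/- ``truncate`` SDs."""
    if sd_ms <= 0:
        raise ValueError("kernel SD must be > 0")
    sd = sd_ms / 1000.0 * sample_rate  # samples
    radius = int(math.ceil(truncate * sd))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def gaussian_smooth(
    trace: np.ndarray,
    sd_ms: float,
    sample_rate: float = 1000.0,
    truncate: float = 4.0,
) -> np.ndarray:
    """Convolve with a truncated, renormalized Gaussian (reflected edges).

    Reflection keeps constants exactly constant at the boundaries; output
    length equals input length.
    """
    trace = np.asarray(trace, dtype=float)
    k = gaussian_kernel(sd_ms, sample_rate, truncate)
    radius = (k.size - 1) // 2
    if radius == 0:
        return trace.copy()
    padded = _reflect_pad(trace, radius)
    return signal.fftconvolve(padded, k, mode="valid")


# ---------------------------------------------------------------------------
# per-trial dF/F


@dataclass
class DffTrial:
    """One trial's two-channel dF/F, time-locked to odor onset (or to the
    scheduled cue time on uncued trials)."""

    trial_index: int
    t: np.ndarray                # s, relative to the alignment event
    green: np.ndarray            # dF/F
    red: np.ndarray              # dF/F
    valid_mask: np.ndarray       # False within the trial-edge exclusion zone
    align_time: float            # absolute session time of the alignment event
    us_time_rel: float           # US onset relative to alignment (s)
    cued: bool
    session_day: int
    f0_green: float
    f0_red: float
    corrected: Optional[np.ndarray] = None
    valid: bool = True
    correction_applied: bool = False


@dataclass
class DffSession:
    """All trials of one session plus the fitted artifact model."""

    trials: List[DffTrial]
    sample_rate: float
    events: pd.DataFrame
    model: Optional["ArtifactModel"] = None

    def pooled(self, channel: str, valid_only: bool = True) -> np.ndarray:
        chunks = []
        for tr in self.trials:
            if not tr.valid:
                continue
            x = getattr(tr, channel)
            if x is None:
                continue
            chunks.append(x[tr.valid_mask] if valid_only else x)
        if not chunks:
            return np.empty(0)
        return np.concatenate(chunks)

    def apply_correction(self, model: "ArtifactModel", force: bool = False) -> None:
        """Fill ``corrected`` on every trial; refuses to correct twice
        unless ``force`` is set (the correction is affine, so applying the
        same model twice subtracts the artifact estimate twice)."""
        for tr in self.trials:
            if tr.correction_applied and not force:
                raise RuntimeError("session already corrected; pass force=True to re-correct")
            if tr.valid:
                tr.corrected = correct_green(tr.green, tr.red, model)
            tr.correction_applied = True
        self.model = model


def compute_dff(
    green: np.ndarray,
    red: np.ndarray,
    events: pd.DataFrame,
    sample_rate: float = 1000.0,
    f0_window: float = 1.0,
    edge_exclusion: float = 1.0,
) -> DffSession:
    """Per-trial dF/F for both channels.

    F0 is the mean fluorescence over the ``f0_window`` seconds preceding
    odor onset (the scheduled cue time on uncued trials); the trial span
    runs from the foreperiod start through the end of the ITI.  Samples
    within ``edge_exclusion`` seconds of either trial edge are flagged
    invalid (filtering artifacts); trials whose F0 is non-positive or
    whose F0 window falls outside the recording are flagged invalid
    rather than dropped.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red traces must have equal length")
    n = green.size
    fs = float(sample_rate)
    edge = int(round(edge_exclusion * fs))
    trials: List[DffTrial] = []
    for row in events.itertuples():
        cued = bool(row.cued)
        align = row.odor_onset if cued else row.us_onset
        i0 = int(round(row.trial_start * fs))
        i1 = min(int(round(row.trial_end * fs)), n)
        ia = int(round(align * fs))
        j0 = ia - int(round(f0_window * fs))
        t = (np.arange(i0, i1) - ia) / fs
        valid = True
        if j0 < 0 or ia > n or i0 < 0 or i1 <= i0:
            valid = False
            f0g = f0r = np.nan
            g = r = np.full(i1 - i0 if i1 > i0 else 0, np.nan)
        else:
            f0g = float(green[j0:ia].mean())
            f0r = float(red[j0:ia].mean())
            if f0g <= 0 or f0r <= 0:
                valid = False
                logger.warning("trial %d flagged invalid: non-positive F0", row.trial_index)
                g = np.full(i1 - i0, np.nan)
                r = np.full(i1 - i0, np.nan)
            else:
                g = (green[i0:i1] - f0g) / f0g
                r = (red[i0:i1] - f0r) / f0r
        mask = np.zeros(i1 - i0, dtype=bool)
        if valid and mask.size > 2 * edge:
            mask[edge:-edge] = True
        trials.append(
            DffTrial(
                trial_index=int(row.trial_index),
                t=t,
                green=g,
                red=r,
                valid_mask=mask,
                align_time=float(align),
                us_time_rel=float(row.us_onset - align),
                cued=cued,
                session_day=int(row.session_day),
                f0_green=f0g,
                f0_red=f0r,
                valid=valid,
            )
        )
    return DffSession(trials=trials, sample_rate=fs, events=events)


# ---------------------------------------------------------------------------
# two-Gaussian mixture on the red channel


@dataclass
class ArtifactModel:
    """Two-Gaussian mixture on the red dF/F distribution, the density
    crossing point used as a boundary, and the regression parameters used
    to correct the green channel."""

    weights: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    means: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    sds: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    boundary: float = np.nan
    side: str = "below"           # which side of the boundary is used for regression
    slope: float = np.nan         # a
    offset: float = np.nan        # b, dF/F
    r_squared: float = np.nan
    n_points_used: int = 0
    n_mixture_samples: int = 0
    log_likelihood: float = np.nan
    session_id: Optional[str] = None

    def to_json(self, path) -> None:
        d = {
            "weights": list(map(float, self.weights)),
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "boundary": float(self.boundary),
            "side": self.side,
            "slope": float(self.slope),
            "offset": float(self.offset),
            "r_squared": float(self.r_squared),
            "n_points_used": int(self.n_points_used),
            "n_mixture_samples": int(self.n_mixture_samples),
            "log_likelihood": float(self.log_likelihood),
            "session_id": self.session_id,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ArtifactModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            boundary=d["boundary"],
            side=d["side"],
            slope=d["slope"],
            offset=d["offset"],
            r_squared=d["r_squared"],
            n_points_used=d["n_points_used"],
            n_mixture_samples=d["n_mixture_samples"],
            log_likelihood=d["log_likelihood"],
            session_id=d.get("session_id"),
        )


def _em_once(x, w, mu, var, tol, max_iter, var_floor):
    n = x.size
    prev = -np.inf
    ll = np.nan
    for _ in range(max_iter):
        log_comp = (
            np.log(w)
            - 0.5 * np.log(2 * np.pi * var)
            - 0.5 * (x[:, None] - mu) ** 2 / var
        )
        log_tot = logsumexp(log_comp, axis=1)
        ll = log_tot.mean()
        resp = np.exp(log_comp - log_tot[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = resp.T @ x / nk
        var = np.maximum((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk, var_floor)
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return w, mu, var, ll


def _density_crossings(w, mu, sd) -> np.ndarray:
    """All roots of w1*phi1(x) = w2*phi2(x) (closed-form quadratic on the
    log densities)."""
    (w1, w2), (m1, m2), (s1, s2) = w, mu, sd
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + math.log(w1 * s2 / (w2 * s1))
    )
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            raise CrossingPointError("identical components: no crossing point")
        return np.array([-c / b])
    disc = b * b - 4 * a * c
    if disc < 0:
        raise CrossingPointError("no real density crossing")
    return np.array(
        [(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)]
    )


def _boundary_from_mixture(w, mu, sd, data_skew: float) -> tuple:
    """Boundary and regression side from the fitted two-Gaussian mixture.

    Separated components (means further apart than half the wider SD):
    the boundary is the density crossing lying between the means and the
    artifact component is the one not centered at zero (larger absolute
    mean).  Overlapping components (a narrow quiescent core inside a
    broad artifact-dominated one, the other shape real control-channel
    distributions take): the between-means crossing is meaningless, so
    the boundary is the crossing on the artifact-tail side of the narrow
    component, the side given by the sample skewness.
    """
    roots = _density_crossings(w, mu, sd)
    separated = abs(mu[1] - mu[0]) > 0.5 * max(sd)
    if separated:
        lo, hi = min(mu), max(mu)
        inside = roots[(roots > lo) & (roots < hi)]
        if inside.size == 0:
            # one density dominates the whole between-means interval
            # (heavy broad component); treat as the overlapping geometry
            separated = False
        elif inside.size > 1:
            xs = np.linspace(lo, hi, 1024)[1:-1]
            dens = (
                w[0] * stats.norm.pdf(xs, mu[0], sd[0])
                + w[1] * stats.norm.pdf(xs, mu[1], sd[1])
            )
            inside = inside[[np.argmin(np.abs(inside - xs[np.argmin(dens)]))]]
        if separated:
            boundary = float(inside[0])
            artifact_comp = int(np.argmax(np.abs(mu)))
            side = "below" if mu[artifact_comp] < mu[1 - artifact_comp] else "above"
            return boundary, side
    null_comp = int(np.argmin(sd))
    side = "below" if data_skew < 0 else "above"
    null_mean = mu[null_comp]
    cand = roots[roots < null_mean] if side == "below" else roots[roots > null_mean]
    if cand.size == 0:
        raise CrossingPointError(
            f"no density crossing on the {side} side of the quiescent component"
        )
    # the crossing nearest the quiescent core separates it from the tail
    return float(cand[np.argmin(np.abs(cand - null_mean))]), side


def _is_degenerate(w, mu, sd, min_weight: float) -> bool:
    # "no second mode": a vanishing component, or two same-scale
    # components too close to form a second mode (a two-Gaussian mixture
    # of comparable SDs is bimodal only when the means are more than
    # ~2 SD apart), the shape EM produces on unimodal data.  A narrow
    # quiescent core inside a broad artifact component (large SD ratio)
    # is genuine structure, not degeneracy.
    if w.min() < min_weight:
        return True
    return max(sd) / min(sd) < 3.0 and abs(mu[1] - mu[0]) < 2.0 * math.sqrt(sd[0] * sd[1])


def fit_red_mixture(
    red_samples: np.ndarray,
    max_samples: int = 20_000,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 200,
    min_samples: int = 1000,
    min_weight: float = 0.02,
    subsample_seed: int = 0,
    fallback_quantile: Optional[float] = None,
    session_id: Optional[str] = None,
) -> ArtifactModel:
    """Fit a two-component Gaussian mixture to pooled red dF/F values and
    locate the boundary at the crossing of the weighted densities.

    EM runs on the raw samples (subsampled above ``max_samples`` for
    speed) with a deterministic quantile initialization plus perturbed
    restarts; components are ordered by mean.  Raises
    :class:`DegenerateMixtureError` when the fit has no second mode and
    :class:`CrossingPointError` when no usable density crossing exists -
    unless ``fallback_quantile`` is given, in which case that quantile of
    the samples is used as the boundary (logged).
    """
    x = np.asarray(red_samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_samples:
        raise ValueError(f"need >= {min_samples} valid samples, got {x.size}")
    rng = np.random.default_rng(subsample_seed)
    if x.size > max_samples:
        x = x[rng.choice(x.size, max_samples, replace=False)]
    scale = x.std()
    if scale == 0:
        raise DegenerateMixtureError("red samples are constant")
    var_floor = (1e-4 * scale) ** 2

    q25, q75 = np.quantile(x, [0.25, 0.75])
    base_mu = np.array([q25, q75])
    if base_mu[0] == base_mu[1]:
        base_mu = base_mu + np.array([-0.5, 0.5]) * scale
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            mu0 = base_mu.copy()
        else:
            mu0 = base_mu + rng.normal(0, 0.5 * scale, 2)
        w, mu, var, ll = _em_once(
            x, np.array([0.5, 0.5]), mu0, np.full(2, scale**2), tol, max_iter, var_floor
        )
        if best is None or ll > best[3]:
            best = (w, mu, var, ll)
    w, mu, var, ll = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], np.sqrt(var[order])

    side = "below"
    boundary = np.nan
    failure = None
    if _is_degenerate(w, mu, sd, min_weight):
        failure = DegenerateMixtureError(
            "two-Gaussian fit is degenerate (no second mode or vanishing "
            f"component): weights={w}, means={mu}, sds={sd}"
        )
    else:
        try:
            boundary, side = _boundary_from_mixture(w, mu, sd, float(stats.skew(x)))
        except CrossingPointError as exc:
            failure = exc
    if failure is not None:
        if fallback_quantile is None:
            raise failure
        boundary = float(np.quantile(x, fallback_quantile))
        side = "below" if stats.skew(x) < 0 else "above"
        logger.warning(
            "%s; falling back to the %.0fth percentile boundary",
            failure, 100 * fallback_quantile,
        )

    return ArtifactModel(
        weights=w,
        means=mu,
        sds=sd,
        boundary=float(boundary),
        side=side,
        n_mixture_samples=int(x.size),
        log_likelihood=float(ll),
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# regression and correction


def fit_artifact_regression(
    green_dff: np.ndarray,
    red_dff: np.ndarray,
    boundary: float,
    side: str = "below",
    min_points: int = 100,
    var_tol: float = 1e-12,
) -> tuple:
    """OLS of green on red restricted to the artifact side of the boundary.

    Returns ``(slope, offset, r_squared, n)``.
    """
    g = np.asarray(green_dff, dtype=float)
    r = np.asarray(red_dff, dtype=float)
    if g.shape != r.shape:
        raise ValueError("green and red arrays must have equal shape")
    keep = np.isfinite(g) & np.isfinite(r)
    keep &= (r < boundary) if side == "below" else (r > boundary)
    n = int(keep.sum())
    if n < min_points:
        raise ValueError(f"only {n} sample pairs on the {side} side of the boundary (need >= {min_points})")
    rs, gs = r[keep], g[keep]
    if rs.var() < var_tol:
        raise DegenerateRegressorError("selected red values have near-zero variance")
    res = stats.linregress(rs, gs)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), n


def correct_green(green_dff: np.ndarray, red_dff: np.ndarray, model: ArtifactModel) -> np.ndarray:
    """``corrected = green - a*red - b`` per sample."""
    g = np.asarray(green_dff, dtype=float)
    r = np.asarray(red_dff, dtype=float)
    if g.shape != r.shape:
        raise ValueError("green and red arrays must have equal shape")
    return g - model.slope * r - model.offset


# ---------------------------------------------------------------------------
# session-level convenience


def process_session(
    bundle,
    fluor_smooth_sd_ms: float = 100.0,
    downsample_factor: int = 1,
    f0_window: float = 1.0,
    edge_exclusion: float = 1.0,
    boundary_side: str = "auto",
    smooth: bool = True,
    mixture_max_samples: int = 20_000,
    fallback_quantile: Optional[float] = None,
    session_id: Optional[str] = None,
) -> DffSession:
    """Raw session -> corrected per-trial dF/F.

    downsample -> Gaussian smooth (100 ms SD) -> per-trial dF/F ->
    two-Gaussian boundary on the pooled valid red samples -> OLS of green
    on red on the artifact side -> per-sample correction of every trial.
    """
    fs = bundle.sample_rate / downsample_factor
    green = downsample(bundle.green_raw, downsample_factor)
    red = downsample(bundle.red_raw, downsample_factor)
    if smooth:
        green = gaussian_smooth(green, fluor_smooth_sd_ms, fs)
        red = gaussian_smooth(red, fluor_smooth_sd_ms, fs)
    session = compute_dff(green, red, bundle.events, fs, f0_window, edge_exclusion)
    model = fit_red_mixture(
        session.pooled("red"),
        max_samples=mixture_max_samples,
        fallback_quantile=fallback_quantile,
        session_id=session_id,
    )
    if boundary_side != "auto":
        model.side = boundary_side
    slope, offset, r2, n = fit_artifact_regression(
        session.pooled("green"), session.pooled("red"), model.boundary, model.side
    )
    model.slope, model.offset, model.r_squared, model.n_points_used = slope, offset, r2, n
    session.apply_correction(model)
    return session


def clean_reference_session(
    bundle,
    fluor_smooth_sd_ms: float = 100.0,
    f0_window: float = 1.0,
    edge_exclusion: float = 1.0,
    smooth: bool = True,
) -> DffSession:
    """Ground-truth reference: the artifact- and noise-free neural signal
    pushed through the identical smoothing and per-trial baselining, so
    corrected output can be compared to clean truth like-for-like.

    Requires a synthetic bundle carrying ``ground_truth``.
    """
    if bundle.ground_truth is None:
        raise ValueError("bundle has no ground truth")
    f0 = 1.0
    clean_raw = f0 * (1.0 + bundle.ground_truth["clean_dff"])
    fs = bundle.sample_rate
    if smooth:
        clean_raw = gaussian_smooth(clean_raw, fluor_smooth_sd_ms, fs)
    return compute_dff(clean_raw, clean_raw, bundle.events, fs, f0_window, edge_exclusion)
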