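"""Reversal-learning time courses and their exponential characterization.

Per-trial metric courses (anticipatory lick rate or CS response
amplitude) concatenated across sessions are fit, after the reversal, by
``A + B*exp(-t/tau)`` over a fixed post-reversal window, with the last
50 pre-reversal trials summarized by a constant.  A fit enters group
analyses only when (i) the last 100 pre-reversal trials differ from
post-reversal trials 100-200 (Welch t-test, alpha=0.05), (ii) the change
follows the direction of the reversal, and (iii) tau > 1 trial.  Time
constants are compared between groups (Welch t / one-way ANOVA), within
animals (paired differences against zero) and across readouts (OLS of
neural tau on behavioral tau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "TrialCourse",
    "ExpFit",
    "build_trial_course",
    "moving_average",
    "fit_reversal",
    "inclusion_check",
    "evaluate_course",
    "compare_taus",
    "anova_taus",
    "paired_tau_difference",
    "regress_tau",
    "fitted_amplitude_difference",
]

EXCLUSION_REASONS = (
    "no_pre_post_difference",
    "wrong_trend",
    "tau_not_gt_1",
    "insufficient_trials",
)


@dataclass
class TrialCourse:
    """A per-trial metric for one animal x one CS, concatenated across
    sessions in trial order.  ``reversal_sign`` is +1 when the reversal
    should increase the metric (positive reversal) and -1 when it should
    decrease it."""

    values: np.ndarray           # smoothed course used for fitting
    reversal_index: int          # position of the first post-reversal trial
    reversal_sign: int
    smoothing_n: int = 1
    raw_values: Optional[np.ndarray] = None
    label: str = ""

    @property
    def n_pre(self) -> int:
        return self.reversal_index

    @property
    def n_post(self) -> int:
        return self.values.size - self.reversal_index


@dataclass
class ExpFit:
    """Constant + exponential characterization of one course."""

    A: float = np.nan            # asymptote, metric units
    B: float = np.nan            # initial offset; value at t=0 would be A+B
    tau: float = np.nan          # trials
    pre_level: float = np.nan    # constant fit over the last 50 pre-reversal trials
    sse: float = np.nan
    converged: bool = False
    at_cap: bool = False
    tau_cap: float = np.nan
    n_pre: int = 0
    n_post: int = 0
    included: Optional[bool] = None
    exclusion_reason: Optional[str] = None
    label: str = ""

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.A + self.B * np.exp(-np.asarray(t, float) / self.tau)


def moving_average(values: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average of width ``n`` with edge-truncated windows
    (the window shrinks near the ends, so the output length equals the
    input length).  ``n=1`` is the identity."""
    if n < 1:
        raise ValueError("smoothing width must be >= 1")
    x = np.asarray(values, dtype=float)
    if n == 1 or x.size == 0:
        return x.copy()
    half_lo = (n - 1) // 2
    half_hi = n // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def build_trial_course(
    values: Sequence[float],
    reversal_index: int,
    reversal_sign: int,
    smoothing_n: int = 1,
    label: str = "",
) -> TrialCourse:
    """Assemble and (optionally) smooth a concatenated trial course."""
    raw = np.asarray(values, dtype=float)
    if not (0 <= reversal_index <= raw.size):
        raise ValueError("reversal_index out of bounds")
    if reversal_sign not in (-1, 1):
        raise ValueError("reversal_sign must be -1 or +1")
    return TrialCourse(
        values=moving_average(raw, smoothing_n),
        reversal_index=int(reversal_index),
        reversal_sign=int(reversal_sign),
        smoothing_n=int(smoothing_n),
        raw_values=raw,
        label=label,
    )


# ---------------------------------------------------------------------------
# exponential fitting


def _profiled_sse(theta: float, t: np.ndarray, y: np.ndarray, cap: float):
    """SSE at tau = cap*sigmoid(theta), with A and B profiled out by
    linear least squares."""
    tau = cap * expit(theta)
    X = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef, tau


def fit_reversal(
    course: TrialCourse,
    post_window: int = 200,
    tau_cap: float = 225.0,
    pre_window: int = 50,
    tau_starts: Sequence[float] = (5.0, 20.0, 60.0, 120.0, 200.0),
) -> ExpFit:
    """Fit ``A + B*exp(-t/tau)`` to the first ``post_window`` trials after
    the reversal (t = 1 on the first post-reversal trial), with tau
    constrained to (0, tau_cap] through a sigmoid reparameterization and
    A, B profiled out at each tau; a constant summarizes the last
    ``pre_window`` pre-reversal trials.  Multi-start Nelder-Mead; the
    best SSE wins.  A fit pushed to the cap is returned at tau=tau_cap
    with ``at_cap`` set.
    """
    rev = course.reversal_index
    y = course.values[rev : rev + post_window]
    pre = course.values[max(rev - pre_window, 0) : rev]
    fit = ExpFit(
        tau_cap=float(tau_cap),
        n_pre=course.n_pre,
        n_post=course.n_post,
        label=course.label,
    )
    fit.pre_level = float(pre.mean()) if pre.size else np.nan
    if y.size < 3:
        return fit
    t = np.arange(1.0, y.size + 1.0)
    best = None
    for tau0 in tau_starts:
        tau0 = min(tau0, 0.99 * tau_cap)
        res = optimize.minimize(
            lambda th: _profiled_sse(th[0], t, y, tau_cap)[0],
            x0=[logit(tau0 / tau_cap)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return fit
    sse, coef, tau = _profiled_sse(best.x[0], t, y, tau_cap)
    fit.converged = bool(best.success) or np.isfinite(sse)
    fit.sse = sse
    fit.A, fit.B = float(coef[0]), float(coef[1])
    if tau > 0.99 * tau_cap:
        fit.at_cap = True
        # re-profile A, B exactly at the cap
        _, coef, _ = _profiled_sse(np.inf, t, y, tau_cap)
        tau = tau_cap
        fit.A, fit.B = float(coef[0]), float(coef[1])
    fit.tau = float(tau)
    return fit


def inclusion_check(
    course: TrialCourse,
    fit: Optional[ExpFit],
    alpha: float = 0.05,
    pre_test_window: int = 100,
    post_test_range: tuple = (100, 200),
    min_trials: int = 50,
) -> tuple:
    """Apply the three inclusion criteria in order; always returns a
    verdict ``(included, reason)`` and mirrors it onto ``fit``.

    1. The last ``pre_test_window`` pre-reversal trials must differ from
       post-reversal trials ``post_test_range`` (two-sided Welch t-test).
    2. The change must follow the expected direction of the reversal.
    3. The fitted time constant must exceed 1 trial.
    """
    rev = course.reversal_index

    def verdict(ok: bool, reason: Optional[str]):
        if fit is not None:
            fit.included, fit.exclusion_reason = ok, reason
        return ok, reason

    if course.n_pre < min_trials or course.n_post < min_trials:
        return verdict(False, "insufficient_trials")
    pre = course.values[max(rev - pre_test_window, 0) : rev]
    lo, hi = post_test_range
    if course.n_post >= hi:
        post = course.values[rev + lo : rev + hi]
    else:
        # short course: compare against its second half so the test still
        # probes the settled regime
        post = course.values[rev + course.n_post // 2 :]
    t, p = stats.ttest_ind(pre, post, equal_var=False)
    if not p < alpha:
        return verdict(False, "no_pre_post_difference")
    trend = np.sign(post.mean() - pre.mean())
    if trend != course.reversal_sign:
        return verdict(False, "wrong_trend")
    if fit is None or not fit.converged or not fit.tau > 1.0:
        return verdict(False, "tau_not_gt_1")
    return verdict(True, None)


def evaluate_course(
    course: TrialCourse,
    post_window: int = 200,
    tau_cap: float = 225.0,
    alpha: float = 0.05,
    **check_kwargs,
) -> ExpFit:
    """Fit + inclusion check, skipping the (relatively costly) fit when the
    course already fails the pre/post difference or trend criterion."""
    rev = course.reversal_index
    probe = inclusion_check(course, None, alpha=alpha, **check_kwargs)
    if probe[1] in ("insufficient_trials", "no_pre_post_difference", "wrong_trend"):
        fit = ExpFit(n_pre=course.n_pre, n_post=course.n_post, label=course.label)
        fit.included, fit.exclusion_reason = probe
        pre = course.values[max(rev - 50, 0) : rev]
        fit.pre_level = float(pre.mean()) if pre.size else np.nan
        return fit
    fit = fit_reversal(course, post_window=post_window, tau_cap=tau_cap)
    inclusion_check(course, fit, alpha=alpha, **check_kwargs)
    return fit


# ---------------------------------------------------------------------------
# group statistics


def _group_stats(taus: np.ndarray) -> dict:
    taus = np.asarray(taus, dtype=float)
    return {
        "mean": float(taus.mean()),
        "sem": float(taus.std(ddof=1) / np.sqrt(taus.size)) if taus.size > 1 else np.nan,
        "n": int(taus.size),
    }


def compare_taus(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Unpaired Welch comparison of two groups of time constants."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"group_a": _group_stats(a), "group_b": _group_stats(b),
            "t": float(t), "p": float(p)}


def anova_taus(*groups: Sequence[float]) -> dict:
    """One-way ANOVA across more than two groups of time constants."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    F, p = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return {"groups": [_group_stats(np.asarray(g, float)) for g in groups],
            "F": float(F), "p": float(p)}


def paired_tau_difference(
    tau_treatment: Sequence[float], tau_control: Sequence[float]
) -> dict:
    """Within-animal treatment-minus-control differences and a one-sample
    t-test against zero."""
    a, b = np.asarray(tau_treatment, float), np.asarray(tau_control, float)
    if a.shape != b.shape:
        raise ValueError("treatment and control must be matched pairs")
    diff = a - b
    if diff.size < 2:
        raise ValueError("need at least two pairs")
    if np.allclose(diff, diff[0]) and diff.std(ddof=1) == 0:
        if np.all(diff == 0):
            return {"differences": diff, "mean": 0.0, "t": 0.0, "p": 1.0}
        raise ValueError("degenerate one-sample test: differences have zero variance")
    t, p = stats.ttest_1samp(diff, 0.0)
    return {"differences": diff, "mean": float(diff.mean()), "t": float(t), "p": float(p)}


def regress_tau(
    tau_neural: Sequence[float], tau_behavior: Sequence[float]
) -> dict:
    """OLS of the neural time constant on the behavioral one, with the
    overall-regression F test and the count of pairs above the identity
    line."""
    y, x = np.asarray(tau_neural, float), np.asarray(tau_behavior, float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 matched (neural, behavioral) pairs")
    res = stats.linregress(x, y)
    n = x.size
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        F = np.inf
    else:
        F = r2 / ((1.0 - r2) / (n - 2))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": r2,
        "F": float(F),
        "p": float(res.pvalue),
        "n": int(n),
        "n_above_identity": int(np.sum(y > x)),
    }


def fitted_amplitude_difference(
    fit_fast: ExpFit, fit_slow: ExpFit, trials: int
) -> np.ndarray:
    """Pointwise difference of the two normalized fitted curves over the
    post-reversal trial axis (t = 1..trials).

    Each curve is rescaled to span [0, 1] over the window; a flat curve
    (B = 0) normalizes to zeros, so two flat fits give a constant (zero)
    difference.
    """
    for f in (fit_fast, fit_slow):
        if not f.converged:
            raise ValueError("both fits must have converged")
    t = np.arange(1.0, trials + 1.0)

    def norm(f: ExpFit) -> np.ndarray:
        c = f.curve(t)
        span = c.max() - c.min()
        if span == 0:
            return np.zeros_like(c)
        return (c - c.min()) / span

    return norm(fit_fast) - norm(fit_slow)
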