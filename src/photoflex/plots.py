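"""Fitted-curve overlays for reversal courses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import ExpFit, TrialCourse

__all__ = ["plot_course_fit"]


def plot_course_fit(course: TrialCourse, fit: ExpFit, path) -> Path:
    """Trial course (gray) with the pre-reversal constant and the
    post-reversal exponential fit (black) overlaid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rev = course.reversal_index
    x = np.arange(course.values.size) - rev
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(x, course.values, color="0.6", lw=0.8, label="course")
    if np.isfinite(fit.pre_level):
        ax.plot([x[0], -1], [fit.pre_level] * 2, color="k", lw=2)
    if fit.converged:
        t = np.arange(1.0, course.n_post + 1.0)
        ax.plot(t, fit.curve(t), color="k", lw=2, label=f"tau={fit.tau:.1f}")
    ax.axvline(0, color="r", ls=":", lw=1)
    ax.set_xlabel("trials from reversal")
    ax.set_ylabel(course.label or "metric")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
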