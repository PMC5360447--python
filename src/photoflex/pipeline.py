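"""End-to-end orchestration: simulate -> preprocess -> behavior ->
responses -> dynamics, with a hashed output manifest for reproducibility.

Each stage reads the previous stage's on-disk outputs (or the in-memory
results of the same run), so stages can also be re-run individually from
the CLI.  All randomness derives from the single configured seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as beh
from . import dynamics as dyn
from . import io as pio
from . import preprocess as pp
from . import responses as resp
from .config import RunConfig, US_VALUE
from .synthetic import generate_experiment

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "behavior", "responses", "dynamics")

#: on-disk evidence that a stage has already produced its outputs
_STAGE_MARKERS = {
    "simulate": "sessions",
    "preprocess": "corrected",
    "behavior": "behavior.tsv",
    "responses": "responses.tsv",
    "dynamics": "fits.tsv",
}


class PipelineDependencyError(RuntimeError):
    pass


def _check_dependencies(config: RunConfig) -> None:
    out = Path(config.out_dir)
    enabled = set(config.stages)
    for stage in enabled:
        i = STAGE_ORDER.index(stage)
        for upstream in STAGE_ORDER[:i]:
            if upstream in ("behavior",) and stage in ("responses",):
                continue  # responses depend on preprocess, not on behavior
            if upstream not in enabled and not (out / _STAGE_MARKERS[upstream]).exists():
                raise PipelineDependencyError(
                    f"stage '{stage}' requires outputs of disabled stage '{upstream}'"
                )


def _session_dirs(out: Path) -> list:
    return sorted((out / "sessions").glob("s*"))


def _reversal_sign(cs: int, config: RunConfig) -> int:
    dv = US_VALUE[config.sim.cs_us_map_post[cs]] - US_VALUE[config.sim.cs_us_map_pre[cs]]
    return 1 if dv > 0 else -1


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a manifest of every
    output file with its content hash.  A stage failure aborts with the
    failing stage named; outputs written so far are preserved."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_dependencies(config)
    an = config.analysis
    logger.info("pipeline start: seed=%d stages=%s", config.sim.seed, config.stages)
    config.to_yaml(out / "run_config.yaml")

    report = {"stages_run": [], "outputs": [], "seed": config.sim.seed}
    bundles = None
    dff_sessions: Optional[list] = None

    try:
        if "simulate" in config.stages:
            bundles = generate_experiment(config.sim)
            for b in bundles:
                d = pio.write_session(b, out / "sessions" / f"s{b.session_index:03d}")
                report["outputs"].extend(sorted(str(p) for p in d.iterdir()))
            report["stages_run"].append("simulate")

        def load_bundles():
            nonlocal bundles
            if bundles is None:
                bundles = [pio.read_session(d) for d in _session_dirs(out)]
            return bundles

        if "preprocess" in config.stages:
            dff_sessions = []
            (out / "corrected").mkdir(exist_ok=True)
            for b in load_bundles():
                sid = f"s{b.session_index:03d}"
                sess = pp.process_session(
                    b,
                    fluor_smooth_sd_ms=an.fluor_smooth_sd_ms,
                    downsample_factor=an.downsample_factor,
                    f0_window=an.f0_window,
                    edge_exclusion=an.edge_exclusion,
                    boundary_side=an.boundary_side,
                    smooth=an.smooth_before_regression,
                    session_id=sid,
                )
                dff_sessions.append(sess)
                sess.model.to_json(out / "corrected" / f"{sid}_artifact_model.json")
                pio.write_dff_session(sess, out / "corrected" / f"{sid}_dff.h5")
                report["outputs"].append(str(out / "corrected" / f"{sid}_artifact_model.json"))
                report["outputs"].append(str(out / "corrected" / f"{sid}_dff.h5"))
            report["stages_run"].append("preprocess")

        if "behavior" in config.stages:
            tables = []
            for b in load_bundles():
                duration = b.green_raw.size / b.sample_rate
                trace = beh.lick_rate(
                    b.lick_times, duration, b.sample_rate, an.lick_smooth_sd_ms
                )
                tab = beh.anticipatory_table(
                    b.events, trace, an.anticipatory_window, an.anticipatory_baseline,
                    an.max_ili, b.lick_times,
                )
                tab.insert(0, "session_index", b.session_index)
                tables.append(tab)
            behavior_table = pd.concat(tables, ignore_index=True)
            report["outputs"].append(str(pio.write_table(behavior_table, out / "behavior.tsv")))
            report["stages_run"].append("behavior")

        if "responses" in config.stages:
            if dff_sessions is None:
                dff_sessions = [
                    pio.read_dff_session(
                        out / "corrected" / f"{d.name}_dff.h5",
                        pio.read_session(d).events,
                    )
                    for d in _session_dirs(out)
                ]
            tables = []
            for b, sess in zip(load_bundles(), dff_sessions):
                tab = resp.build_response_table(
                    sess, window=an.response_window, us_baseline=an.us_baseline_window
                )
                tab.insert(0, "session_index", b.session_index)
                tables.append(tab)
            response_table = pd.concat(tables, ignore_index=True)
            response_table = resp.with_zscores(response_table)
            report["outputs"].append(str(pio.write_table(response_table, out / "responses.tsv")))
            if response_table["session_day"].nunique() >= 2:
                summary = resp.day_summary(response_table)
                report["outputs"].append(str(pio.write_table(summary, out / "day_summary.tsv")))
            report["stages_run"].append("responses")

        if "dynamics" in config.stages:
            responses_df = pio.read_table(out / "responses.tsv")
            behavior_df = pio.read_table(out / "behavior.tsv")
            fits, tau_pairs = [], []
            for cs in (1, 2, 3, 4):
                sign = _reversal_sign(cs, config)
                entry = {"cs_id": cs, "reversal_sign": sign}
                taus = {}
                for kind, df, col, n_smooth, window in (
                    ("neural", responses_df[(responses_df["event_class"] == "CS")],
                     "amplitude", an.neural_smoothing_n, an.cs_post_window),
                    ("licking", behavior_df[behavior_df["cued"].astype(bool)],
                     "anticipatory_lick", an.lick_smoothing_n, an.lick_post_window),
                ):
                    sub = df[df["cs_id"] == cs].sort_values("global_trial")
                    sub = sub[np.isfinite(sub[col])]
                    values = sub[col].to_numpy()
                    rev_idx = int((sub["trials_since_reversal"] <= 0).sum())
                    course = dyn.build_trial_course(
                        values, rev_idx, sign, n_smooth, label=f"CS{cs}_{kind}"
                    )
                    fit = dyn.evaluate_course(
                        course, post_window=window, tau_cap=an.tau_cap, alpha=an.alpha,
                        pre_test_window=an.pre_test_window,
                    )
                    fits.append(
                        {
                            "course": f"CS{cs}_{kind}", "cs_id": cs, "kind": kind,
                            "reversal_sign": sign, "A": fit.A, "B": fit.B,
                            "tau": fit.tau, "pre_level": fit.pre_level, "sse": fit.sse,
                            "converged": fit.converged, "at_cap": fit.at_cap,
                            "included": fit.included, "exclusion_reason": fit.exclusion_reason,
                            "n_pre": fit.n_pre, "n_post": fit.n_post,
                        }
                    )
                    taus[kind] = fit
                if (
                    taus["neural"].included
                    and taus["licking"].included
                ):
                    entry.update(
                        tau_neural=taus["neural"].tau, tau_licking=taus["licking"].tau
                    )
                    tau_pairs.append(entry)
            fits_df = pd.DataFrame(fits)
            report["outputs"].append(str(pio.write_table(fits_df, out / "fits.tsv")))
            summary: dict = {"n_tau_pairs": len(tau_pairs), "tau_pairs": tau_pairs}
            if len(tau_pairs) >= 3:
                summary["tau_regression"] = dyn.regress_tau(
                    [p["tau_neural"] for p in tau_pairs],
                    [p["tau_licking"] for p in tau_pairs],
                )
            report["outputs"].append(str(pio.write_json(summary, out / "dynamics_summary.json")))
            report["stages_run"].append("dynamics")
    except Exception as exc:
        stage = report["stages_run"][-1] if report["stages_run"] else "setup"
        raise RuntimeError(
            f"pipeline failed after stage '{stage}': {exc}"
        ) from exc

    manifest = {
        str(Path(p).relative_to(out)): pio.file_digest(p) for p in sorted(set(report["outputs"]))
    }
    pio.write_json({"seed": config.sim.seed, "files": manifest}, out / "manifest.json")
    report["manifest"] = manifest
    logger.info("pipeline done: %d output files", len(manifest))
    return report
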