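"""Synthetic-session generator: schedule structure, lick statistics,
fluorescence construction and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import photoflex as pf
from photoflex import behavior as beh
from photoflex import preprocess as pp
from photoflex.synthetic import (
    generate_licking,
    generate_trial_schedule,
    relaxation,
)


def _schedule(config, seed=0, **kw):
    return generate_trial_schedule(config, np.random.default_rng(seed), **kw)


class TestConfigValidation:
    def test_map_must_be_bijection(self):
        with pytest.raises(ValueError, match="bijection"):
            pf.SimConfig(cs_us_map_pre={1: "large", 2: "large", 3: "neutral", 4: "airpuff"})

    def test_uncued_fraction_range(self):
        with pytest.raises(ValueError, match="uncued_fraction"):
            pf.SimConfig(uncued_fraction=1.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            pf.BehaviorConfig(baseline_rate=-1.0)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="fluorescence"):
            pf.NoiseConfig(f0_green=0.0)

    def test_bad_timing_range(self):
        with pytest.raises(ValueError, match="range"):
            pf.TimingConfig(foreperiod_range=(4.0, 3.0))


class TestTrialSchedule:
    def test_cued_us_onset_is_three_seconds_after_odor(self, small_config):
        ev = _schedule(small_config)
        cued = ev[ev.cued]
        assert np.allclose(cued.us_onset - cued.odor_onset, 3.0)

    def test_row_count_and_cued_uncued_conservation(self):
        cfg = pf.SimConfig(trials_per_session=200, uncued_fraction=0.3,
                           reversal_session=0, n_sessions=1, reversal_trial=100)
        ev = _schedule(cfg)
        assert len(ev) == 200
        assert ev.cued.sum() + (~ev.cued).sum() == 200
        assert ev.loc[~ev.cued, "cs_id"].isna().all()
        assert ev.loc[~ev.cued, "odor_onset"].isna().all()

    def test_same_seed_identical_schedule(self, small_config):
        a, b = _schedule(small_config, seed=3), _schedule(small_config, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_reversal_switches_contingency_map(self):
        cfg = pf.SimConfig(trials_per_session=300, reversal_session=0,
                           n_sessions=1, reversal_trial=150)
        ev = _schedule(cfg)
        pre = ev[(~ev.post_reversal) & ev.cued]
        post = ev[ev.post_reversal & ev.cued]
        for row in pre.itertuples():
            assert row.us_id == cfg.cs_us_map_pre[int(row.cs_id)]
        for row in post.itertuples():
            assert row.us_id == cfg.cs_us_map_post[int(row.cs_id)]
        # trial counter restarts at 1 on the first post-reversal trial
        assert post.trials_since_reversal.iloc[0] == 1

    def test_uncued_proportion_matches_binomial_expectation(self):
        # 10,000 draws at p=0.2: the sample proportion is within +/-2%
        # (5 binomial SDs) of the target
        cfg = pf.SimConfig(trials_per_session=10_000, uncued_fraction=0.2,
                           reversal_session=0, n_sessions=1, reversal_trial=5000)
        ev = _schedule(cfg, seed=1)
        prop = (~ev.cued).mean()
        assert abs(prop - 0.2) < 0.02

    def test_reversal_trial_outside_session_rejected(self):
        cfg = pf.SimConfig(reversal_session=0, n_sessions=1, reversal_trial=50)
        with pytest.raises(ValueError, match="reversal_trial"):
            generate_trial_schedule(cfg, np.random.default_rng(0), n_trials=40)

    def test_default_trial_count_in_observed_range(self):
        cfg = pf.SimConfig(n_sessions=1, reversal_session=0, reversal_trial=20)
        counts = [len(_schedule(cfg, seed=s)) for s in range(10)]
        assert all(140 <= c <= 346 for c in counts)


class TestRelaxation:
    def test_pre_reversal_returns_old_value(self):
        assert relaxation(2.0, 5.0, 0, 10.0) == 2.0

    def test_zero_tau_switches_in_one_trial(self):
        assert relaxation(2.0, 5.0, 1, 0.0) == 5.0

    def test_large_k_approaches_new_value(self):
        assert relaxation(2.0, 5.0, 1000, 10.0) == pytest.approx(5.0, abs=1e-6)


class TestLicking:
    def test_zero_anticipatory_rate_gives_null_metric(self, expert_config):
        b = dataclasses.replace(
            expert_config.behavior,
            anticipatory_rate={k: 0.0 for k in pf.US_IDENTITIES},
            consummatory_rate={k: 0.0 for k in pf.US_IDENTITIES},
        )
        cfg = dataclasses.replace(expert_config, behavior=b)
        ev = _schedule(cfg, seed=2)
        licks = generate_licking(ev, cfg, np.random.default_rng(2))
        trace = beh.lick_rate(licks, float(ev.trial_end.max()))
        tab = beh.anticipatory_table(ev, trace)
        vals = tab.loc[tab.cued, "anticipatory_lick"].dropna()
        assert abs(vals.mean()) < 3 * vals.sem()

    def test_configured_rate_difference_recovered(self):
        # >=200 cued expert trials: the large-vs-neutral anticipatory gap
        # equals the configured rate difference up to sampling error
        cfg = pf.SimConfig(n_sessions=1, trials_per_session=300,
                           reversal_session=0, reversal_trial=299, seed=5)
        ev = _schedule(cfg, seed=5)
        licks = generate_licking(ev, cfg, np.random.default_rng(5))
        trace = beh.lick_rate(licks, float(ev.trial_end.max()))
        tab = beh.anticipatory_table(ev, trace)
        m = tab[tab.cued].groupby("us_id")["anticipatory_lick"].mean()
        expected = (cfg.behavior.anticipatory_rate["large"]
                    - cfg.behavior.anticipatory_rate["neutral"])
        assert m["large"] - m["neutral"] == pytest.approx(expected, abs=0.8)

    def test_negative_anticipatory_rate_rejected(self):
        rates = {"large": -2.0, "small": 3.0, "neutral": 0.3, "airpuff": 0.3}
        with pytest.raises(ValueError, match="rates"):
            pf.BehaviorConfig(anticipatory_rate=rates)

    def test_lick_times_strictly_increasing(self, small_session):
        assert np.all(np.diff(small_session.lick_times) > 0)


class TestFluorescence:
    def test_identity_case_green_equals_clean(self, small_config):
        # a*=0, no artifacts, no noise: the green dF/F is exactly the
        # clean trace's dF/F
        cfg = dataclasses.replace(
            small_config,
            artifact=dataclasses.replace(small_config.artifact, slope=0.0,
                                         rate=0.0, p_lick_locked=0.0),
            noise=dataclasses.replace(small_config.noise, green_sd=0.0, red_sd=0.0),
        )
        bundle = pf.generate_session(cfg)
        got = pp.compute_dff(bundle.green_raw, bundle.red_raw, bundle.events,
                             bundle.sample_rate)
        ref = pp.clean_reference_session(bundle, smooth=False)
        for a, b in zip(got.trials, ref.trials):
            assert np.allclose(a.green, b.green, atol=1e-12)

    def test_ground_truth_reconstructs_green_at_zero_noise(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            noise=dataclasses.replace(small_config.noise, green_sd=0.0, red_sd=0.0),
        )
        bundle = pf.generate_session(cfg)
        gt = bundle.ground_truth
        rebuilt = cfg.noise.f0_green * (
            1.0 + gt["clean_dff"] + gt["slope"] * gt["artifact_dff"]
            + gt["offset"] * gt["offset_mask"]
        )
        assert np.allclose(rebuilt, bundle.green_raw, atol=1e-9)

    def test_experiment_is_bit_deterministic(self):
        cfg = pf.SimConfig(n_sessions=2, trials_per_session=12,
                           reversal_session=1, reversal_trial=6, seed=123)
        e1, e2 = pf.generate_experiment(cfg), pf.generate_experiment(cfg)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.green_raw, b.green_raw)
            assert np.array_equal(a.red_raw, b.red_raw)
            assert np.array_equal(a.lick_times, b.lick_times)
            pd.testing.assert_frame_equal(a.events, b.events)

    def test_session_days_relative_to_reversal(self):
        cfg = pf.SimConfig(n_sessions=3, trials_per_session=12,
                           reversal_session=1, reversal_trial=6, seed=1)
        days = [s.events.session_day.iloc[0] for s in pf.generate_experiment(cfg)]
        assert days == [-1, 0, 1]

    def test_bundle_validates(self, small_session):
        small_session.validate()
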