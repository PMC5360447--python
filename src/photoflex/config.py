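"""Configuration objects for simulation and analysis.

``SimConfig`` holds the full generative parameter set for synthetic
sessions; ``RunConfig`` adds the analysis-stage parameters and output
paths used by the end-to-end pipeline.  Every analysis default is the
value used throughout the package: 50 ms lick smoothing, 100 ms
fluorescence smoothing, a 1 s pre-odor F0 window, 1.5 s response
windows, the 315 ms bout rule, the 500-2800 ms anticipatory window with
a -500..500 ms baseline, 50/100/200-trial fit windows, a 225-trial tau
cap and alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

US_IDENTITIES = ("large", "small", "neutral", "airpuff")

#: Relative reward value of each outcome, used both by the lick generator
#: (anticipatory licking scales with value) and by the neural generator
#: (cue responses and prediction errors scale with value).  The air puff
#: carries zero *reward* value; its aversive salience is modelled as a
#: separate additive response term in :class:`NeuralConfig`.
US_VALUE = {"large": 1.0, "small": 0.5, "neutral": 0.0, "airpuff": 0.0}


def _check_range(name: str, rng: tuple) -> None:
    lo, hi = rng
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or lo > hi:
        raise ValueError(f"{name} must be a finite range with 0 <= low <= high, got {rng}")


def _check_map(name: str, mapping: dict) -> None:
    if set(mapping.keys()) != {1, 2, 3, 4}:
        raise ValueError(f"{name} must map CS ids 1-4, got keys {sorted(mapping)}")
    if sorted(mapping.values()) != sorted(US_IDENTITIES):
        raise ValueError(f"{name} must be a bijection onto {US_IDENTITIES}, got {mapping}")


@dataclass
class TimingConfig:
    """Trial timing (seconds); defaults follow the task structure:
    variable foreperiod, 1 s odor, fixed 2 s trace, variable ITI."""

    foreperiod_range: tuple = (3.0, 4.0)
    odor_duration: float = 1.0
    trace_duration: float = 2.0
    iti_range: tuple = (4.0, 8.0)
    us_window: float = 1.5      # outcome-consumption period before the ITI starts
    sample_rate: float = 1000.0  # Hz, fluorescence and lick resolution

    def __post_init__(self) -> None:
        _check_range("foreperiod_range", self.foreperiod_range)
        _check_range("iti_range", self.iti_range)
        for name in ("odor_duration", "trace_duration", "us_window", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NeuralConfig:
    """Event-locked transient model.

    ``profile`` selects the US response law: ``"serotonin"`` responds to
    the magnitude of the value prediction error plus a persistent air-puff
    term; ``"dopamine"`` responds to the signed prediction error.  CS
    amplitudes scale with the value currently predicted by the cue, which
    relaxes toward the post-reversal value with ``cs_adaptation_tau``
    (trials; slow for the serotonin-like profile, ~4x faster for the
    dopamine-like one).
    """

    profile: str = "serotonin"
    cs_amplitude: dict = field(
        default_factory=lambda: {"large": 0.05, "small": 0.03, "neutral": 0.0, "airpuff": 0.0}
    )
    us_gain: float = 0.06               # dF/F per unit |prediction error|
    airpuff_us_amplitude: float = 0.03  # additive, serotonin profile only
    kernel_rise: float = 0.2            # s, indicator onset time constant
    kernel_decay: float = 1.5           # s, indicator decay time constant
    cs_adaptation_tau: float = 80.0     # trials since reversal (global trial axis)
    us_surprise_decay: float = 40.0     # trials; relaxation of the predicted value
    dopamine_cs_adaptation_tau: float = 20.0

    def __post_init__(self) -> None:
        if self.profile not in ("serotonin", "dopamine"):
            raise ValueError(f"unknown neural profile {self.profile!r}")
        if set(self.cs_amplitude) != set(US_IDENTITIES):
            raise ValueError("cs_amplitude must have one entry per US identity")
        amps = list(self.cs_amplitude.values()) + [self.us_gain, self.airpuff_us_amplitude]
        if not np.all(np.isfinite(amps)):
            raise ValueError("neural amplitudes must be finite")
        for name in ("kernel_rise", "kernel_decay", "cs_adaptation_tau", "us_surprise_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def effective_cs_tau(self) -> float:
        return self.cs_adaptation_tau if self.profile == "serotonin" else self.dopamine_cs_adaptation_tau


@dataclass
class BehaviorConfig:
    """Lick generator: baseline bouts everywhere, value-scaled anticipatory
    licking between odor onset + 0.5 s and outcome delivery, and
    consummatory licking after rewards."""

    baseline_rate: float = 0.5     # Hz, session-wide
    anticipatory_rate: dict = field(
        default_factory=lambda: {"large": 6.0, "small": 3.0, "neutral": 0.3, "airpuff": 0.3}
    )
    lick_adaptation_tau: float = 20.0  # trials since reversal (global trial axis)
    intra_bout_ili: float = 0.14       # s, typical inter-lick interval inside a bout
    bout_size_mean: float = 3.0        # licks per spontaneous bout (geometric)
    refractory: float = 0.07           # s, lick dead time
    consummatory_rate: dict = field(
        default_factory=lambda: {"large": 8.0, "small": 5.0, "neutral": 0.0, "airpuff": 0.0}
    )
    consummatory_duration: float = 1.5  # s after US onset

    def __post_init__(self) -> None:
        rates = [self.baseline_rate, *self.anticipatory_rate.values(), *self.consummatory_rate.values()]
        if any(r < 0 or not np.isfinite(r) for r in rates):
            raise ValueError("lick rates must be finite and >= 0")
        if set(self.anticipatory_rate) != set(US_IDENTITIES) or set(self.consummatory_rate) != set(US_IDENTITIES):
            raise ValueError("per-US rate dicts must have one entry per US identity")
        if self.lick_adaptation_tau < 0:
            raise ValueError("lick_adaptation_tau must be >= 0")
        for name in ("intra_bout_ili", "bout_size_mean", "refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        max_rate = self.baseline_rate + max(
            max(self.anticipatory_rate.values()), max(self.consummatory_rate.values())
        )
        if max_rate * self.refractory >= 0.95:
            raise ValueError("configured lick rate is incompatible with the refractory period")


@dataclass
class ArtifactConfig:
    """Shared movement-artifact model: sparse biexponential transients with
    log-normal amplitudes (negative dips by default, matching the skewed
    control-channel distributions), a fraction locked to lick-bout onsets,
    coupled into the green channel with slope ``slope`` (a*) and dF/F
    offset ``offset`` (b*)."""

    slope: float = 0.8           # a*, unitless coupling into the green channel
    offset: float = 0.0          # b*, dF/F offset of the green-vs-red relation
    rate: float = 0.9            # Hz, background transient rate
    amp_median: float = 0.3      # dF/F, log-normal amplitude median
    amp_sigma: float = 0.4       # log-normal shape
    sign: float = -1.0           # sign of the majority transients
    p_majority_sign: float = 0.7  # fraction of transients carrying `sign`
    #                               (the rest flip: movement can couple
    #                               light in either direction); 1.0 gives
    #                               fully one-sided dips, 0.5 symmetric
    p_lick_locked: float = 0.1   # probability a lick-bout onset spawns a transient
    shape: str = "plateau"       # brief movement epochs give the control
    #                              channel its shifted second mode
    duration: float = 0.05       # s, plateau length
    edge_sd: float = 0.02        # s, plateau edge smoothing
    kernel_rise: float = 0.05    # s, biexponential option
    kernel_decay: float = 0.3    # s

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.slope, self.offset, self.amp_median, self.amp_sigma])):
            raise ValueError("artifact parameters must be finite")
        if self.rate < 0 or not (0 <= self.p_lick_locked <= 1):
            raise ValueError("artifact rate must be >= 0 and p_lick_locked in [0, 1]")
        if self.amp_median <= 0 or self.amp_sigma <= 0:
            raise ValueError("amplitude distribution parameters must be > 0")
        if self.sign not in (-1.0, 1.0):
            raise ValueError("sign must be -1.0 or +1.0")
        if not 0.0 <= self.p_majority_sign <= 1.0:
            raise ValueError("p_majority_sign must lie in [0, 1]")
        if self.shape not in ("plateau", "biexp"):
            raise ValueError("artifact shape must be 'plateau' or 'biexp'")
        for name in ("kernel_rise", "kernel_decay", "duration", "edge_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NoiseConfig:
    green_sd: float = 0.01   # measurement noise, dF/F units at 1 kHz
    red_sd: float = 0.01
    f0_green: float = 100.0  # baseline fluorescence, arbitrary units
    f0_red: float = 50.0

    def __post_init__(self) -> None:
        if self.green_sd < 0 or self.red_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.f0_green <= 0 or self.f0_red <= 0:
            raise ValueError("baseline fluorescence levels must be > 0")


@dataclass
class SimConfig:
    """Full generative parameter set for a synthetic experiment.

    ``trials_per_session=None`` draws each session's trial count from the
    observed distribution (normal with mean 223, SD 30, clipped to the
    140-346 range).  The reversal occurs at trial ``reversal_trial`` of
    session ``reversal_session``; session days are reported relative to
    that session (reversal day = 0).
    """

    n_sessions: int = 5
    trials_per_session: Optional[int] = None
    reversal_session: int = 2
    reversal_trial: int = 73
    cs_us_map_pre: dict = field(
        default_factory=lambda: {1: "large", 2: "small", 3: "neutral", 4: "airpuff"}
    )
    cs_us_map_post: dict = field(
        default_factory=lambda: {1: "airpuff", 2: "neutral", 3: "small", 4: "large"}
    )
    uncued_fraction: float = 0.0
    timing: TimingConfig = field(default_factory=TimingConfig)
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_session is not None and self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if not (0 <= self.reversal_session < self.n_sessions):
            raise ValueError("reversal_session must index an existing session")
        if self.reversal_trial < 0:
            raise ValueError("reversal_trial must be >= 0")
        if (
            self.trials_per_session is not None
            and self.reversal_trial >= self.trials_per_session
        ):
            raise ValueError(
                f"reversal_trial ({self.reversal_trial}) must fall inside the reversal "
                f"session ({self.trials_per_session} trials)"
            )
        if not (0 <= self.uncued_fraction < 1):
            raise ValueError("uncued_fraction must lie in [0, 1)")
        _check_map("cs_us_map_pre", self.cs_us_map_pre)
        _check_map("cs_us_map_post", self.cs_us_map_post)
        # allow dicts from YAML for the nested sections
        for name, cls in (
            ("timing", TimingConfig),
            ("neural", NeuralConfig),
            ("behavior", BehaviorConfig),
            ("artifact", ArtifactConfig),
            ("noise", NoiseConfig),
        ):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, cls(**val))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("timing",):
            for rng_key in ("foreperiod_range", "iti_range"):
                d["timing"][rng_key] = list(d["timing"][rng_key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "timing" in d and isinstance(d["timing"], dict):
            t = dict(d["timing"])
            for rng_key in ("foreperiod_range", "iti_range"):
                if rng_key in t:
                    t[rng_key] = tuple(t[rng_key])
            d["timing"] = t
        for key in ("cs_us_map_pre", "cs_us_map_post"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters shared by the pipeline and the CLI."""

    fluor_smooth_sd_ms: float = 100.0
    lick_smooth_sd_ms: float = 50.0
    downsample_factor: int = 1
    f0_window: float = 1.0
    edge_exclusion: float = 1.0
    boundary_side: str = "auto"      # {auto, below, above}
    smooth_before_regression: bool = True
    response_window: float = 1.5
    us_baseline_window: float = 1.0
    anticipatory_window: tuple = (0.5, 2.8)
    anticipatory_baseline: tuple = (-0.5, 0.5)
    max_ili: float = 0.315
    alpha: float = 0.05
    lick_smoothing_n: int = 3
    neural_smoothing_n: int = 1
    lick_post_window: int = 200
    cs_post_window: int = 225
    tau_cap: float = 225.0
    pre_fit_window: int = 50
    pre_test_window: int = 100

    def __post_init__(self) -> None:
        if self.boundary_side not in ("auto", "below", "above"):
            raise ValueError("boundary_side must be auto, below or above")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulation parameters, analysis
    parameters, stage toggles and the output directory."""

    out_dir: str = "photoflex_run"
    stages: tuple = ("simulate", "preprocess", "behavior", "responses", "dynamics")
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: Optional[int] = None  # overrides sim.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisConfig(**self.analysis)
        self.stages = tuple(self.stages)
        known = {"simulate", "preprocess", "behavior", "responses", "dynamics"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        d["analysis"]["anticipatory_window"] = list(self.analysis.anticipatory_window)
        d["analysis"]["anticipatory_baseline"] = list(self.analysis.anticipatory_baseline)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "analysis" in d and isinstance(d["analysis"], dict):
            for key in ("anticipatory_window", "anticipatory_baseline"):
                if key in d["analysis"]:
                    d["analysis"][key] = tuple(d["analysis"][key])
        return cls(**d)
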