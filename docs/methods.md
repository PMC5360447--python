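# Methods

This note documents the models, defaults and numerical choices behind
`photoflex`, and what the synthetic-data studies do and do not establish
about real recordings.

## Analysis pipeline

### Per-trial ΔF/F₀ and smoothing

Raw traces are (optionally) block-mean decimated to 1 kHz, then smoothed
by convolution with a Gaussian kernel of 100 ms SD (50 ms for the lick
indicator). Kernels are truncated at ±4 SD and renormalized to unit sum;
edges are handled by reflection, so constants are preserved exactly.
ΔF/F₀ is computed per trial with F₀ the mean fluorescence over the 1 s
before odor onset (before the scheduled cue time on uncued trials); the
trial span runs from foreperiod start to the end of the ITI. The first
and last 1000 ms of each trial are excluded from artifact-model fitting
(filtering artifacts) but retained for response extraction. Trials with a
non-positive F₀ are flagged invalid, never silently dropped.

### Two-Gaussian boundary

A two-component Gaussian mixture is fit to the pooled valid red ΔF/F₀
samples of a session by EM on the raw samples (quantile-based
deterministic initialization plus nine perturbed restarts, relative
log-likelihood tolerance 1e-8, at most 200 iterations, variance floor at
(1e-4 × sample SD)²; above 20,000 samples a fixed-seed subsample is used,
which bounds the EM cost without materially affecting the boundary).
Two geometries arise:

* **Separated components** (mean gap > 0.5 × wider SD): the boundary is
  the density crossing point between the means, found in closed form from
  the quadratic log-density equality; the artifact component is the one
  not centered at zero, and its side of the boundary is used for the
  regression.
* **Overlapping components** (a narrow quiescent core inside a broad
  artifact-dominated component — the shape per-trial baselining produces
  whenever artifacts contaminate F₀ windows): the between-means crossing
  is meaningless, so the boundary is the crossing on the artifact-tail
  side of the narrow component, with the side chosen by the sample
  skewness.

A fit is *degenerate* ("no second mode") when a component's weight falls
below 2% or when the two components have comparable SDs (ratio < 3) and
means closer than 2·√(σ₁σ₂) — the classic condition under which a
two-Gaussian mixture cannot be bimodal, and the shape EM produces on
unimodal data. Degenerate fits raise; callers may opt into a quantile
fallback boundary, which is logged.

### Regression and correction

Ordinary least squares of green on red ΔF/F₀, restricted to valid samples
on the artifact side of the boundary (at least 100 pairs; regressor
variance above 1e-12), gives slope *a* and offset *b*; every sample of
every trial is then corrected as green − a·red − b. The correction is
affine; re-correcting an already-corrected session is refused unless
forced.

Two properties of this procedure are worth knowing when interpreting
corrected traces:

* The intercept *b* absorbs the mean neural signal at artifact-selected
  samples, so corrected traces carry a constant offset of roughly minus
  the session-mean signal level (~0.005 ΔF/F under the generator's
  defaults). Response measures that subtract a baseline (US responses,
  anticipatory licking) and all z-scored quantities are immune; raw CS
  amplitudes are shifted uniformly.
* Because green and red ΔF/F₀ are normalized by different baselines,
  trials whose F₀ window contains an artifact acquire a small corrected
  bias of −a(1−a)·E[s²], where s is the artifact's F₀-window shift. The
  effect is quadratic in per-event artifact area and negligible for brief
  artifacts, but grows for sustained movement epochs — a genuine
  limitation of ratiometric per-trial baselining, not of this
  implementation.

### Responses and licking

CS amplitude: mean corrected ΔF/F₀ over [onset, onset + 1.5 s), half-open
in samples, no further baseline (the per-trial F₀ already references the
pre-odor second). US amplitude: mean over [US, US + 1.5 s) minus mean over
[US − 1 s, US). A slow cue transient still decaying through the pre-US
baseline makes a response-free US window slightly negative — expected, and
reproduced by the generator. z-scoring uses the n−1 SD throughout; the
"expert" convention estimates mean/SD from all pre-reversal CS and US
responses per animal, the "across-days" convention normalizes per animal
and event identity over all days.

Anticipatory licking: mean smoothed lick rate over 0.5-2.8 s after odor
onset minus the mean over −0.5-0.5 s. Bouts chain licks separated by at
most 315 ms (a gap of exactly 315 ms joins); single licks are kept and
flagged. The blink metric is the first difference of the per-frame mean
eye-region intensity; event detection from it is a thresholding utility
whose threshold must be calibrated per recording — no default is imposed.

### Reversal dynamics

Courses are built per animal × CS by concatenating trials across sessions
(centered moving average, edge-truncated; width 3 for licking, 1 for
neural courses — smoothing is part of the licking analysis convention and
is not applied to neural courses by default). The exponential
A + B·exp(−t/τ) is fit to post-reversal trials (t = 1 on the first
post-reversal trial) by profiled least squares: at any τ the optimal A, B
are a linear solve, so the search is one-dimensional in τ, parameterized
as τ = cap·sigmoid(θ) to enforce (0, cap]. Nelder-Mead runs from five
starts (τ₀ ∈ {5, 20, 60, 120, 200}); the best SSE wins. This profiled
search reaches the same objective as a three-parameter simplex but
converges deterministically and was verified against an exhaustive τ grid.
Fits pushed within 1% of the cap are returned at the cap and flagged.
Licking fits use a 200-trial post window; CS fits use the full course with
the 225-trial cap. Both limits are configuration keys.

Inclusion requires, in order: (1) the last 100 pre-reversal trials differ
from post-reversal trials 100-200 (two-sided Welch t-test at α = 0.05;
courses shorter than 200 post trials compare against their second half);
(2) the change matches the reversal direction; (3) τ > 1. Courses with
fewer than 50 pre- or post-reversal trials are excluded as insufficient.
The first failed criterion is reported as the exclusion reason. Group
comparisons use Welch t-tests (the unequal-variance form is the safe
default where the test is otherwise unspecified), one-way ANOVA for more
than two groups, one-sample t-tests on paired within-animal differences,
and OLS with the overall-regression F test for the neural-vs-behavioral τ
relationship.

## Synthetic-data generator

The generator exists so that every stage has ground truth; its defaults
are the study conditions for the validation suite.

**Task structure.** Four odors map to large reward (value 1), small
reward (0.5), neutral (0) and air puff (0); the reversal swaps
large↔air puff and small↔neutral. Foreperiod U(3,4) s, 1 s odor, 2 s
trace, 1.5 s outcome window, ITI U(4,8) s, 1 kHz sampling. Session length
defaults to a draw from N(223, 30²) clipped to 140-346 trials; the
reversal occurs at trial 73 of the middle session. Uncued outcomes
(US at the scheduled cue time, uniformly drawn) occur with a configurable
probability (default 0).

**Learning law.** Any learned quantity relaxes after the reversal as
old + (new − old)(1 − e^(−k/τ)), with k the number of trials since
reversal counted on the *global* trial axis; a per-odor course therefore
relaxes about four times faster on its own trial axis. Cue-response
amplitudes relax with τ = 80 trials for the serotonin-like profile and 20
for the dopamine-like one; anticipatory lick rates with τ = 20; the
predicted outcome value (which sets surprise) with τ = 40.

**Neural signal.** Event-locked impulses convolved with a peak-normalized
double-exponential kernel (0.2 s rise, 1.5 s decay — slow-indicator
dynamics; configurable). Cue amplitudes scale with the currently
predicted value (defaults 0.05/0.03/0/0 ΔF/F by outcome). Outcome
amplitudes follow a configurable surprise law: the serotonin-like profile
responds to |delivered − predicted| value with a persistent additive
air-puff term (0.03), the dopamine-like profile to the signed difference.
These laws are qualitative stand-ins encoding the target phenomenology —
no quantitative outcome-response law is claimed.

**Licking.** Spontaneous bouts (geometric size, mean 3; ~140 ms
intra-bout intervals) at an overall baseline of 0.5 Hz; anticipatory
licking between odor + 0.5 s and outcome at the value-scaled rate
(6/3/0.3/0.3 Hz by outcome), consummatory licking after rewards. Rates
are realized by a dead-time (70 ms) Poisson process whose intensity is
compensated as λ = r/(1 − r·τ_dead) so realized rates equal configured
rates in expectation.

**Artifacts.** Sparse movement epochs shared by both channels: 50 ms
plateaus with 20 ms Gaussian edges, log-normal amplitudes (median 0.3
ΔF/F, σ = 0.4), 70% dips / 30% brightenings, at 0.9 Hz background plus
10% of lick-bout onsets. The green channel couples with slope a* (default
0.8). Brief epochs keep per-trial baselining in its valid regime (see the
quadratic-bias note above) while the total artifact power still dominates
the uncorrected error — the regime in which the correction is the
operative step. A biexponential transient shape is available as an
option. The offset b* (default 0) is injected at the ΔF/F level outside
each trial's own F₀ window, because a constant raw-fluorescence offset
cancels exactly under per-trial baselining; as a consequence the fitted
offset recovers b* attenuated by the fraction of artifact samples inside
F₀ windows (~17% under defaults).

**Noise and determinism.** Per-sample Gaussian measurement noise
(SD 0.01 ΔF/F at 1 kHz) in both channels; baseline fluorescence 100
(green) and 50 (red) arbitrary units. All randomness flows through
explicitly threaded generators seeded from a single root; an identical
configuration reproduces bit-identical sessions.

## Validation studies and problem sizes

The batch studies (`photoflex.validation`, run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use single
sessions of 140 trials — the low end of the observed per-session range —
so a hundred-session study completes in minutes: artifact recovery over
10 seeded sessions (a* = 0.8, b* = 0.02); the zero-neural null check over
100 sessions; τ recovery from courses of 100 + 400 trials at
τ ∈ {10, 50, 150} with noise SD 0.3·|B| (fits use the full post course
with the 225 cap; at τ = 10 only ~10 trials carry information about B, so
B's median error sits at the estimator's information limit of ~14% and
the A/B recovery is summarized by the pooled median across τ settings);
learning-rate ordering over 100 cohorts of 8 slow (τ = 80) vs 3 fast
(τ = 20) simulated animals; inclusion calibration on 1000 null courses
(evaluated unsmoothed — a 3-trial moving average induces serial
correlation that inflates the t statistic, which is a property of the
test, not of the implementation); and the anticipatory-licking value
ordering over 100 expert-stage sessions.

**What passing does and does not show.** The generator emulates trial
structure, value-scaled responses, adaptive relaxation, lick-locked and
background artifacts, and measurement noise. It does not emulate
photobleaching or slow drift (the per-trial F₀ convention is the defense
in real data), hemodynamic or pH confounds, indicator nonlinearity or
saturation, inter-animal variability in kinetics, or artifact waveforms
beyond brief epochs. Passing the suite shows the pipeline is correct and
well-calibrated under the stated generative assumptions; it does not by
itself validate those assumptions against any particular recording
system.

## Known limitations

* The mixture boundary assumes the control channel separates into a
  quiescent core plus an artifact component; recordings whose artifact
  distribution is heavy but unimodal-concentric are handled by the
  skew-side crossing, but pathological cases fall back (explicitly,
  logged) to a quantile boundary or raise.
* The regression intercept is only identifiable up to the mean signal
  level at artifact times; all downstream measures that matter are
  baseline-subtracted or z-scored.
* Sustained (multi-second) movement epochs violate the per-trial
  baselining assumptions quadratically in epoch area; such data need
  either longer F₀ windows or artifact-epoch exclusion before this
  pipeline.
* The exponential model assumes a single relaxation process; courses with
  distinct fast and slow phases will be summarized by an intermediate τ.
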