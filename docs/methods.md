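# Methods

This note documents the models implemented in `olfrl`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Task model and sequence generation

A session is a sequence of trials, each presenting one of three odor cues
with fixed reward probabilities (CS100 → 1.0, CS50 → 0.5, CS0 → 0.0).
Timing per trial: odor 0–1 s, wait 1–2.7 s, outcome at 2.7 s; onsets are
spaced by a uniform 10–12 s jitter.  Sequences are pseudo-random under
three constraints: equal cue counts (so `n_trials` must divide by 3; 150
for training-style sessions, 120 with 40 trials per cue for scanner-style
sessions), no cue more than 3 times in a row, and no more than 3
consecutive rewarded trials.

Cues are drawn sequentially, weighted by each cue's remaining count, with
cues that would violate a constraint excluded from the draw; a dead end
restarts the whole session and a configuration that keeps dead-ending
raises an error rather than truncating.  Rewards default to
`reward_balance="exact"`: each cue's rewards come from a finite pool of
`round(p · n_cue)` rewarded assignments sampled without replacement, so the
realized session-level reward frequency equals the programmed probability
even though the run constraint occasionally forces an unrewarded placement.
This matters downstream: the TD value of CS50 converges to the *realized*
reward frequency, and only the balanced scheme makes it converge to 0.5.
The alternative `reward_balance="bernoulli"` draws every reward
independently and re-draws a draw that would extend a rewarded run past 3
(which for p < 1 deterministically yields an unrewarded trial); this biases
the CS50 frequency to roughly 0.45 because CS50 is over-represented in the
positions following three rewards (CS100 cannot appear there).  The small
residual effect of the balanced scheme is a slight shift of rewarded CS50
trials toward the session end (forced unrewarded placements consume the
pool early), visible as a percent-scale upward bias of late-session
V(CS50).

## Trial-based TD(0)

Each trial has three timepoints: baseline (state `s0`), cue (one state per
odor), outcome (state `s2`, value pinned at 0 because the trial ends
there).  Rewards are binary and occur only at the outcome.  The prediction
error is `δ_t = r_t + V(s_t) − V(s_{t−1})` and updates the previous state's
value, `V(s_{t−1}) += α δ_t`; no eligibility traces, no discounting.  At
the outcome this gives `δ2 = r − V(CS)`, asserted as an identity in the
tests.  Both within-trial deltas are computed from the values as they stood
at trial start and then applied together; because `δ1` never updates the
cue state, the alternative sequential convention is numerically identical
here, but it is kept behind an explicit flag (`pre_update_deltas`).

Initial values: zeros for learning simulations; 0 / 0.5 / 1 for CS0 / CS50
/ CS100 when modeling sessions of already-trained animals (used for the
fMRI-style regressors).  With either initialization and α ∈ (0, 1], all
values stay in [0, 1] (property-tested).  The default learning rate is
α = 0.28, the value obtained from the pupil fit below.

## Pupil observation model

Per trial, pupil dilation is summarized by three window averages of the
percent change from baseline: d(0) over −2..0 s, d(1) over 0..2.7 s, d(2)
over 2.7..5.4 s relative to odor onset.  The observation model is

    d(t) = Σ_{τ=0..t} a_τ V(s_{t−τ}) + Σ_{τ=0..t−1} b_τ |δ(t−τ)|,

a ragged sum implemented literally at each t (so d(0) = a₀V(s0), and
V(s2) = 0 contributes nothing at t = 2).  The "distance" minimized is the
sum of squared differences between modeled and observed window means over
trials — least squares, chosen because for fixed α the model is linear in
(a, b) and the inner problem solves in closed form.  The fit therefore
scans α on a 0.02 grid over (0, 1), solves (a, b) exactly at each point,
and refines the best α with a bounded scalar minimization (tolerance 1e-6);
multi-start is unnecessary given the grid.  Per-trial window means are the
default fit granularity (per-cue-type averages behind a flag) because the
per-trial values retain the outcome-history signal that identifies α.
Per-session fits are averaged into the study-level α; a joint fit over
sessions is available behind `joint=True`.  Excluded trials are simply
omitted from the loss.  A flat loss profile in α (pure noise input) is
flagged as non-identifiable rather than reported as an estimate.

Preprocessing: per trial, the mean diameter over −2..0 s is the baseline
for the percent change; any trial whose percent-change series jumps more
than 5 percentage points between consecutive frames (blinks, detection
failures) is excluded entirely, as is a trial whose window is not covered
by the trace.

## Behavior

A go-response is ≥3 licks within the anticipatory window (1.5–2.8 s) or
within the reward window (2.8–4.1 s), evaluated per window (the "or" is
read disjunctively; 2+2 licks across windows is not a go).  Hits and
correct rejections define performance, and sessions above 80% meet the
inclusion criterion.

The outcome-history regression models anticipatory lick counts of CS50
trials as Poisson with log link; column n of the design codes the outcome
of the n-th previous CS50 trial (+1 rewarded / −1 unrewarded), n = 1..6.
The satiety variant codes the n-th previous CS100/CS0 trial (+1/−1)
instead.  Trials without a full 6-back history are dropped.  An intercept
is included (counts have a nonzero baseline; removable by flag), and the
exposure offset is omitted because the window length is constant.
Standardization uses the standard deviation of the observed counts for
σ(μ_t) — fitted means give near-identical scaling.  Sessions with zero
count variance or a constant regressor column are flagged and skipped.
Group inference is a one-sample t test per lag across sessions.

## Spike detection and unit QC

Channels of a recording site are referenced by subtracting the per-sample
channel median (removes common-mode movement artifacts exactly), band-pass
filtered 300–5000 Hz with a 4th-order Butterworth applied forward-backward
(zero phase, so spike timestamps are not shifted), and thresholded at 7.5×
the per-channel median absolute deviation — the raw MAD, not the
1.4826-scaled σ estimate.  Local maxima of the absolute signal (a
negative-only mode is available) closer than 1 ms are merged, and events
detected on several channels of a tetrode within that distance collapse to
the channel with the largest peak.  Waveforms are the −10..+21 samples
around the peak.  QC: units with ≥2% inter-spike intervals below 2 ms are
rejected; Tu units need baseline rates below 5 Hz (putative striatal
projection neurons) and aPC units below 10 Hz (putative principal cells).

One calibration subtlety: median subtraction of channel-*independent*
noise inflates single-channel extremes relative to the MAD scale (about
one false event per second on a 4-channel site at the 7.5× threshold in
pure Gaussian noise).  The detector-accuracy property (recall and
precision ≥ 0.95 for spikes whose band-passed amplitude is 10× MAD) is
therefore tested on the filtered trace directly, while median subtraction
is tested by its exact identity: detection after median subtraction is
bit-identical with and without a common-mode artifact.

## Population vectors

Session populations are concatenated into a pseudo-population by matching
trials on (cue, presentation order, CS50 outcome); each CS50 outcome group
keeps the minimum trial count over sessions, dropping the last trials of
richer sessions.  Rates are counts divided by bin width (Hz).  Deviation
from baseline is the Euclidean distance between the population vector and
the per-unit baseline vector B (window −2..−1.25 s, averaged across all
raw trials — B is not pair-averaged), computed on pair-averaged vectors
(consecutive trial pairs averaged; an odd trailing trial is dropped).  Two
binning modes: 500 ms bins stepped by 125 ms for display, non-overlapping
250 ms bins for statistics.  Cross-type correlation averages the Pearson r
between every pair of (pair-averaged) trial vectors from two cue types at
each bin; zero-variance vectors skip the pair.  Trajectories embed the
trial-averaged population matrix with m = 4 delayed coordinates (delay one
bin) and project to 3 PCA components; the PCA is fitted jointly across
trial types so trajectories share axes.

## Unit classification and coding tests

Responsiveness compares each task window (CS 0–1 s, wait 1–2.5 s, US
2.7–3.7 s) to baseline (−1.5..−0.5 s) per unit and cue, with
Benjamini–Hochberg correction across all (unit × cue × window) tests and
direction from the median difference.  With only two paired conditions the
Friedman statistic degenerates to a sign test, which is the default
method; an exact Wilcoxon signed-rank is available as `method="wilcoxon"`.
Note the wait window is 1.5× the width of the baseline window, so the
paired null is not exchangeable for rank tests on rates; calibration
checks use the equal-width CS window.

auROC profiles compare the across-trial rate distribution in a 500 ms
window (stepped 125 ms) against the pooled −1.8..−1.4 s baseline
distribution, per condition (CS0, unrewarded CS50, rewarded CS50, CS100),
with midrank tie handling; profiles are concatenated across conditions,
reduced to 5 principal components (fewer if rank-deficient, logged), and
clustered agglomeratively with average linkage on Euclidean distance —
the linkage method is not dictated by the source analyses; average linkage
is a neutral default.  The tree is cut at a fraction of the maximum
linkage height (0.45 / 0.5 for the two regions in the original analyses;
an absolute-distance mode is provided since the original scale is not
recoverable).  Flat clusters are mapped to archetypes by threshold rules
on the cluster-mean profile: below 0.45 mean auROC in the task windows →
inhibited; late-wait mean above 0.55 and rising by ≥0.05 over early wait →
ramping; CS-window mean above 0.55 without the ramp → transient; elevated
otherwise → sustained; flat profiles → untuned (a class the synthetic null
archetype produces).

Coding tests on per-trial rates grouped by cue: monotonic RP requires both
adjacent two-tailed rank-sum comparisons significant (p < 0.05) in the
value order ({R0} < {R50} < {R100}; reversed for inhibited clusters); if
it fails, cue dominance requires the strongest response to beat the
second-strongest.  The distributed-coding test removes individually
monotonic units and runs a one-way ANOVA with Tukey HSD on the remainder's
per-trial summed rates.  Reward surprise requires a positive mean rate
jump (rate in a post-outcome window minus the 2.2–2.7 s pre-outcome rate)
on rewarded CS50 trials and a significantly larger jump than CS100,
tested in both post-outcome windows (2.7–3.2 s and 3.2–4.5 s); outcome
discrimination compares the post-outcome rate between rewarded and
unrewarded CS50 trials, one-directional by design; both invert for
inhibited units.  The chance level for a specific strict cue ordering
among units that discriminate all three cue pairs is n_discriminative / 3!
= n/6.  History/satiety effects run a one-way ANOVA with Tukey HSD over
the four CS50 subgroups (previous CS50 rewarded / unrewarded; preceding
trial CS100 / CS0) on rates or population distances.

## Event-related BOLD GLM

The HRF is a gamma kernel with time-to-peak 1.0 s (shape 4), normalized to
unit peak — rodent hemodynamics peak far earlier than the human canonical
response; the exact empirical kernel used in the source analyses is not
published in a reusable form, so generator and fitter share this
parametric kernel and all tests are self-consistent in it.  Events are
zero-duration sticks convolved on a TR/16 oversampled grid and sampled at
volume onsets (TR = 1.3 s), so events need not align with acquisitions.
Design variants: GLM 1 (one CS regressor + V(CS) parametric modulator,
four US-type regressors: reward after CS100, reward after CS50, no reward
after CS50, no reward after CS0); GLM 2 (per-cue CS regressors, CS50
modulated by the previous CS50 outcome ±1 — the first CS50 trial carries
no history and contributes zero); GLM 3 (per-cue CS regressors, one US
regressor with −V(CS) and binary r modulators, deliberately not
orthogonalized so shared variance is discarded and entry order is
irrelevant); and a beta-series design with one regressor per event per
trial.  All variants append an HRF-convolved lick regressor, an optional
CSF nuisance series, and a constant.  Modulators are mean-centered over
their events (the convention of standard SPM-style modulation; the source
is silent), which makes the modulator beta invariant to constant shifts
(property-tested).

Estimation is voxel-wise OLS without prewhitening; rank deficiency raises
an error naming the collinear columns.  Group statistics replace the
repeated-measures sandwich estimator of the original pipeline with
ordinary one-sample t tests across sessions — a documented simplification
that ignores within-animal covariance — with Benjamini–Hochberg control
per tail at q = 0.025 (two-sided).  Percent signal change scales an event
beta by the *region-mean* constant-term beta (not a whole-brain scaler),
preserving ventral regions recorded with lower coil sensitivity.
Frame-wise displacement is the sum of absolute first differences of the
six realignment parameters (first frame 0); an event is low-motion when
the frame at and after it has FD ≤ 0.05 mm.  Beta-series connectivity
correlates region-averaged per-trial betas per event type, Fisher
z-transforms per session, tests the z's against zero across sessions with
Bonferroni correction over region pairs (FDR per tail in voxel mode), and
reports the group correlation as tanh of the mean z.

## Synthetic-data generators

The generators produce data with the statistical structure the analyses
assume — nothing more.  Defaults are chosen to mimic the study conditions:

- **Licking agent**: tonic rate 0.4 Hz; anticipatory rate
  `6 Hz × V(CS)` during the delay, shifted ±0.8 Hz by the previous CS50
  outcome on CS50 trials and −0.5 Hz after any rewarded trial (satiety);
  8 Hz consumption bursts on rewarded trials.  These rates put session
  performance at 85–97% (minimum over 20 sessions ≈ 85–91%), safely above
  the 80% criterion, with the cue ordering CS100 > CS50 > CS0 in
  anticipatory licking.
- **Pupil**: window means follow the observation model with α = 0.28,
  a = (0, 6, 2), b = (10, 3) (percent-scale coefficients; a₀ = 0 because
  baseline-referenced data have d(0) ≈ 0 by construction) plus i.i.d.
  Gaussian noise (default SD 0.5%); the 20 Hz trace renders the window
  means piecewise-constant so re-windowing recovers them exactly.
- **Units**: archetype mixture (transient 0.35, ramping 0.30, inhibited
  0.20, sustained 0.10, unmodulated 0.05), baseline rates 1.5–4.5 Hz
  (below the Tu QC cutoff), inhomogeneous Poisson spikes.  Transient units
  are either value-monotonic or single-cue responders whose cue preference
  probabilities (0.1 / 0.35 / 0.55) scale responder counts with value, so
  the summed population response stays value-ordered.  Ramping amplitudes
  scale with V(CS) and carry a ±2 Hz previous-CS50-outcome shift — the
  only history effect in the population, so transient clusters serve as
  negative controls.  US responses of excited archetypes scale with
  surprise (≈1.05 − reward probability), making CS50→R jumps exceed CS100
  jumps.
- **Voltage**: Gaussian noise with biphasic templates whose band-passed
  peak is calibrated to the stated MAD multiple; optional common-mode
  artifact shared by all channels.
- **BOLD**: a 24×24×4 labeled grid of abstract region slabs (no
  anatomy), voxel series = design × region betas + AR(1) noise
  (coefficient 0.3, mild fMRI-like autocorrelation), baseline 100 so
  percent signal change is well-defined; ground-truth betas are returned.

What passing tests on these data do *not* show: robustness to real pupil
segmentation artifacts beyond the 5% rule, spike-sorting errors (the
generator plants ground-truth units), hemodynamic model mismatch (the
generator uses the fitter's kernel), realistic fMRI noise structure
(motion, physiology, spatial correlation), or anatomical effects.  All
generators are bit-exact reproducible from a seed.

## Problem sizes and numerical conventions

The test suite and the acceptance script use desk-scale problem sizes
chosen to keep the full run in tens of seconds while leaving the
statistical checks well-powered: 100 sessions × 150 trials for TD
convergence; 10,000 sessions for the sequence-constraint sweep; 20
replicates per generative α ∈ {0.1, 0.3, 0.5} for pupil recovery; 100
sessions for the lick-history recovery; 120 units for the end-to-end
clustering and population patterns.  Random draws all flow from
`numpy.random.Generator` seeds; window membership uses half-open
`[start, end)` intervals; rank-based tests use midranks throughout, with
exact small-sample behavior delegated to SciPy.  Statistical acceptance
bands in the tests are 3-standard-error bands where sampling error
dominates and small absolute floors (~0.01) where deterministic
convergence bias dominates.

## Known limitations

- The group-level BOLD inference ignores repeated-measures covariance
  (one-sample t in place of a sandwich estimator).
- OLS without prewhitening under AR(1) noise gives slightly optimistic
  single-session standard errors; group inference, which the pipeline
  relies on, is unaffected under the null (calibration-tested).
- The balanced reward pools make rewards exchangeable but not independent
  within a session; analyses treating CS50 outcomes as i.i.d. coin flips
  would see a tiny negative serial dependence.
- The clustering cutoffs are expressed as fractions of the maximum linkage
  height; absolute cutoffs from other pipelines do not transfer.
- `simulate_population` generates single sessions; cross-session
  pseudo-populations are built by calling it repeatedly with different
  seeds, which makes units across sessions statistically independent —
  real simultaneously recorded populations share latent variability.
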