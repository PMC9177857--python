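# olfrl

Analysis toolkit for odor-guided reinforcement learning in head-fixed mice.
In the underlying task, three odor cues predict a water reward with
probability 1.0, 0.5 and 0 (CS100, CS50, CS0); each trial is 1 s of odor, a
1.7 s wait, and the outcome 2.7 s after odor onset, with onsets jittered
between 10 and 12 s.  The package reimplements, as a tested library, the
full computational chain used to study how reward prediction (RP) and its
trial-by-trial updating are represented in behavior, pupil, single units and
BOLD:

- **`olfrl.task` / `olfrl.synth`** — synthetic-data generators: constrained
  pseudo-random trial sequences (equal cue counts, no cue more than 3 times
  in a row, no more than 3 consecutive rewarded trials), value-scaled
  anticipatory licking with outcome-history and satiety effects, pupil
  traces from the observation model, unit populations built from functional
  archetypes, 30 kHz voltage with inserted spikes, and event-related BOLD
  phantoms with AR(1) noise.
- **`olfrl.td`** — trial-based TD(0) with three timepoints per trial
  (baseline, odor, outcome).  The prediction error compares successive
  value predictions, `delta_t = r_t + V(s_t) − V(s_{t−1})`, and updates the
  previous state's value by `alpha * delta`; at outcome this reduces to
  `delta = r − V(CS)`.
- **`olfrl.pupil`** — preprocessing (percent change from the −2..0 s
  baseline; trials with >5% frame-to-frame jumps excluded) and the
  observation model `d(t) = Σ a_τ V(s_{t−τ}) + Σ b_τ |δ(t−τ)|` over the
  three trial windows, whose fit yields the learning rate α (grid search
  over α with an exact inner least-squares solve).
- **`olfrl.behavior`** — go/no-go classification (≥3 licks in the
  anticipatory 1.5–2.8 s or reward 2.8–4.1 s window), session performance
  `(Hits + Correct rejections) / total`, and the Poisson outcome-history
  regression `log μ_t = β·X` with ±1 outcome coding over 6 trials back,
  coefficients standardized as `exp(β_n σ(x_n)/σ(y)) − 1`.
- **`olfrl.ephys`** — spike detection (channel-median subtraction,
  300–5000 Hz 4th-order Butterworth, 7.5×MAD threshold, 1 ms minimum peak
  distance, per-tetrode deduplication) and unit QC (<2% refractory
  violations; <5 Hz baseline in Tu, <10 Hz in aPC).
- **`olfrl.population`** — cross-session population vectors with matched
  trials, Euclidean deviation from the baseline vector, cross-trial-type
  Pearson correlation, and time-embedded (m = 4 delays) PCA trajectories.
- **`olfrl.units`** — responsiveness vs baseline with Benjamini–Hochberg
  correction, sliding-window auROC response profiles, PCA + hierarchical
  clustering into transient / ramping / inhibited / sustained groups, and
  the coding tests: monotonic RP, single-cue dominance, distributed
  population coding, reward surprise (CS50→R jump > CS100 jump), outcome
  discrimination, the n!/6 chance level for strict cue orderings, and
  history/satiety ANOVAs.
- **`olfrl.fmri`** — miniature event-related GLM engine: fast-peaking gamma
  HRF, stick-function designs in three variants (value-modulated CS;
  per-cue CS with a CS50 outcome-history modulator; single US with −V(CS)
  and r modulators, not orthogonalized), voxel-wise OLS, one-sample group
  t maps with per-tail FDR, contrast intersections, region-scaled percent
  signal change, frame-wise displacement, and beta-series functional
  connectivity (per-trial betas, Fisher z, Bonferroni-corrected group
  tests).

## Worked example

```python
import numpy as np
from olfrl.task import TaskConfig, generate_trial_sequence
from olfrl import td, synth, pupil, behavior

cfg = TaskConfig(seed=0)                      # 150 trials, cues rewarded at 1.0/0.5/0.0
seq = generate_trial_sequence(cfg)

# TD(0) learning from naive initial values
trace = td.run_td_session(seq, alpha=0.28, init="zeros")
late = trace[trace["trial_index"] > 100]
for cs in ("CS100", "CS50", "CS0"):
    print(f"V({cs}) late-session mean: {late.loc[late.cs == cs, 'V_cs'].mean():.3f}")

# recover the learning rate from a synthetic pupil session
_, windows = synth.simulate_pupil(seq, noise_sd=0.5, rng=1)
fit = pupil.fit_session(seq, windows)
print(f"fitted learning rate alpha = {fit.alpha:.3f}")

# behavioral performance of the synthetic agent
licks = synth.simulate_agent_behavior(seq, td=td.run_td_session(seq, init="trained"), rng=2)
classified = behavior.classify_session(seq, licks)
print(f"session performance = {behavior.session_performance(classified['outcome_class']):.1f}%")
```

prints

```
V(CS100) late-session mean: 1.000
V(CS50) late-session mean: 0.439
V(CS0) late-session mean: 0.000
fitted learning rate alpha = 0.276
session performance = 90.7%
```

The deterministic cues converge to their reward probabilities; the CS50
value fluctuates around 0.5 within a single session (0.439 here) because
TD keeps chasing the recent outcome history — averaged over 100 sessions it
sits at 0.5.  The pupil fit recovers the generative learning rate 0.28 to
within the noise, and the agent comfortably exceeds the 80% inclusion
criterion.

A thin CLI wraps the batch tasks:

```sh
olfrl simulate --preset training --seed 1 --out session01
olfrl td session01/trials.tsv
olfrl behavior --trials session01/trials.tsv --licks session01/licks.tsv
olfrl pupil-fit --sessions .
```

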