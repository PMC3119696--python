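# transgroup

Stimulus synthesis and behavioral/eye-movement analysis toolbox for
transsaccadic perceptual-grouping experiments.

When people scan a scene, each object about to be fixated has already been
glimpsed peripherally.  A classic way to ask whether the *perceptual
organization* extracted from that glimpse survives the saccade is a
two-contour grouping display: a field of local elements latently contains
two closed contours; before the saccade one subset of Gaussian blobs is
brightened (grouping by luminance similarity), and after the saccade the
elements become Gabor patches whose orientations trace one contour
(grouping by collinearity), with a small target square to be judged as
inside or outside the contour.  Whether the previewed contour matches the
test contour is the manipulation; manual reaction time is the measure.
This package implements the whole machinery of such a study so the design
is reproducible and testable end to end:

* **Stimuli** — random radial-frequency-pattern contours
  r(θ) = r₀ + Σᵢ Aᵢ sin(fᵢθ + φᵢ), compatibility-based selection of a
  second latent contour, jittered equidistant element placement,
  proximity-cue-free background fill (rank-sum p > 0.3), stratified
  25/25/50 inside/outside target allocation, and Gaussian/Gabor display
  rendering to grayscale PNG (`contours`, `layout`, `stimset`, `render`).
* **Simulator** — trial tables with the assumed statistical structure:
  shifted-lognormal saccadic latencies (median 213 ms), condition-
  dependent 2D landing distributions, lognormal manual RTs with additive
  condition effects and a linear landing-error dependence, additional-
  saccade counts and near-ceiling accuracy (`simulate`).
* **Pipeline** — eye-movement trial censoring (landing > 1.5°, saccade
  duration > 85 ms, > 2 additional saccades, slow-second-fixation rule
  with a derivable 240 ms cutoff) and pilot stimulus-set screening
  (`trials`).
* **Statistics** — discrete-time survival/hazard tables (5 and 15 ms
  bins, five-bin smoothed hazard), per-subject median normalization,
  landing-adjusted log-RT repeated-measures contrasts (error term =
  subject×condition interaction), analysis of variance of variance for
  landing spread, within-subject logistic accuracy models, 90%
  iso-frequency landing regions, and minimum-bounding-rectangle coarse
  shape analysis (`stats`).

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Simulate an experiment (7 subjects × 500 trials), censor it, and run the
reaction-time analysis:

```python
from transgroup import (SimulationConfig, simulate_experiment, censor_trials,
                        adjust_rt_for_landing, condition_contrasts,
                        derive_fixation_cutoff)

trials = simulate_experiment(SimulationConfig(), seed=7)
print(f"median saccadic latency: {trials.saccade_latency_ms.median():.0f} ms")
retained, report = censor_trials(trials)
print(f"retained after censoring: {100 * report.retained_fraction:.2f}%")
print(f"derived fixation cutoff: {derive_fixation_cutoff(trials):.0f} ms")
correct = retained[retained.correct & (retained.rt_ms <= 1500)]
adjusted, slope = adjust_rt_for_landing(correct)
effects = condition_contrasts(adjusted, covariate_slope=slope)
print(f"omnibus condition effect: F{effects.omnibus_df} = {effects.omnibus_F:.2f}")
for c in effects.contrasts:
    print(f"  {c.name:24s} {c.diff_ms:+6.1f} ms   F(1,{c.df[1]}) = {c.F:5.2f}  p = {c.p:.4f}")
```

Output:

```
median saccadic latency: 213 ms
retained after censoring: 84.00%
derived fixation cutoff: 240 ms
omnibus condition effect: F(4, 24) = 7.90
  neutral_vs_object         +11.4 ms   F(1,24) =  4.44  p = 0.0458
  uniform_vs_random          +1.8 ms   F(1,24) =  0.04  p = 0.8376
  same_vs_different         -43.3 ms   F(1,24) = 27.08  p = 0.0000
  same_vs_localized         -20.1 ms   F(1,24) =  6.09  p = 0.0211
  different_vs_localized    +23.2 ms   F(1,24) =  7.48  p = 0.0115
```

The simulator was configured with a 35 ms Same−Different effect, a −10 ms
Localized advantage, ~15% censorable trials, and a slow-trial penalty
switching on at a 240 ms final fixation; the pipeline recovers each of
these from the raw trial table (the printed contrasts carry sampling
noise at this experiment size).

A command-line interface wraps the same functionality:

```bash
transgroup generate --n-sets 80 --seed 1 --out stimuli/     # PNG + JSON stimulus sets
transgroup simulate --seed 1 --out trials.csv
transgroup analyze censor --in trials.csv --out retained.csv --report report.json
transgroup analyze all --in retained.csv --out results/     # tables + figures
```

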