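# cuecode

Single-unit spike-train analysis for a rodent cue-discrimination task, with
a synthetic-session simulator so every stage can be exercised and calibrated
without any recorded data.

## The problem

In tasks where distinct cues (a light or a sound, presented on one of four
track arms) predict whether reward will be available at a receptacle, the
question is which *features* of a cue — its sensory identity, its physical
location, its predicted outcome — are encoded by nucleus-accumbens units,
whether those codes live in separate, independent, or joint populations of
units, and whether they persist from cue onset through the nosepoke hold
until the outcome is revealed.  `cuecode` implements the complete analysis
chain for such sessions:

1. **Screening** — keep units with ≥ 200 spikes; exclude units whose
   post-cue firing drifts within a block (Mann–Whitney U on first vs second
   half of trials); call survivors *cue-modulated* when 1 s pre- vs
   post-cue rates differ (Wilcoxon signed-rank, p < .01); classify FSI vs
   MSN by the absence of interspike intervals > 2 s.
2. **Sliding-window stepwise Poisson GLM** — for each unit and each 500 ms
   window (100 ms steps, 11 windows spanning −0.25 s … +0.75 s around cue
   onset, nosepoke, or outcome), regress the spike count *y_t* on cue
   identity, location, outcome, approach behaviour, trial length, trial
   number, and trial history by forward selection: a candidate block enters
   when its deviance drop passes a χ² test at p < .01.  Variance
   attribution uses the deviance pseudo-R²,
   R² = 1 − D(model)/D(intercept), with the partial R² of a predictor the
   drop in R² when it is removed from the final model.  Population
   proportions of selected units are z-scored against a shuffle null that
   permutes each unit's per-trial counts and reruns the whole sweep.
3. **Pseudoensemble LDA decoding** — trial × unit rate matrices aligned by
   condition labels, 10-fold cross-validated linear discriminant analysis
   (Ledoit–Wolf shrinkage), against a per-unit column-shuffle null.
4. **Coding overlap** — selections recoded to binary unit vectors, compared
   across features/events by the phi coefficient over the 6 × 6 grid of
   post-event windows; the mean of the 36 correlations is z-scored against
   a unit-permutation null, labelling population pairs *separate*
   (z < −1.96), *independent*, or *joint* (z > 1.96).
5. **Population structure** — Gaussian-smoothed (σ = 100 ms) PETHs,
   z-scored peak-sorted heatmaps, and split-half within- vs across-block
   PETH correlations summarized by a linear mixed model with a per-unit
   random intercept.
6. **Behaviour** — per-block 2 × 2 chi-square discrimination, the
   3-consecutive-day learning criterion, and a mixed model of approach
   proportions with cue outcome/identity fixed effects and a per-rat
   random intercept.

The simulator generates sessions with the task's exact structure — two
100-trial blocks (light, sound), a deterministic clockwise arm cycle,
pseudorandom outcomes with run length ≤ 2 and per-arm balance,
outcome-dependent approach probabilities, and inhomogeneous-Poisson spike
trains with planted epoch/feature tuning, optional drift, and MSN/FSI
interspike-interval structure — so every downstream statistic can be tested
for calibration and parameter recovery against known ground truth.

## Worked example

```python
import numpy as np
import cuecode as cc

rng = np.random.default_rng(42)
config = cc.SessionConfig(rng_seed=42)
tuning = cc.make_tuning_population(24, rng, identity_fraction=0.4)
trials, spikes = cc.simulate_session(config, tuning, rng)

screen = cc.screen_units(spikes, trials)
kept = screen[screen["cue_modulated"]]
print(f"{len(trials)} trials, {len(screen)} units, "
      f"{screen['excluded_for_drift'].sum()} drift-excluded, "
      f"{len(kept)} cue-modulated "
      f"({(kept['direction'] == 'decrease').sum()} decreasing)")

units = {u: spikes[u] for u in kept["unit_id"]}
null = cc.shuffle_proportion_test(units, trials, n_shuffle=20, rng=rng)
post = null[(null.predictor == "identity") & (null.window_center >= 0.25)]
print(post[["window_center", "observed", "shuffle_mean", "z"]]
      .round(3).to_string(index=False))
```

prints

```
200 trials, 24 units, 3 drift-excluded, 17 cue-modulated (10 decreasing)
 window_center  observed  shuffle_mean     z
          0.25     0.059         0.006 2.924
          0.35     0.118         0.003 8.721
          0.45     0.118         0.009 5.050
          0.55     0.118         0.009 5.050
          0.65     0.059         0.006 2.924
          0.75     0.059         0.006 2.924
```

The 24 simulated units yield 17 cue-modulated survivors of the screening
funnel (most with decreased post-cue firing, matching the planted mix).  In
every window fully after cue onset, the observed proportion of units whose
final model includes cue identity sits far above the shuffle null
(z > 1.96): the planted identity code is recovered at the population level.

A command-line interface mirrors the library:

```sh
cuecode all --out results/run1 --seed 7        # full pipeline + manifest
cuecode simulate --out results/sim --seed 3    # session bundle only
cuecode validate results/sim/session           # invariant check
```

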