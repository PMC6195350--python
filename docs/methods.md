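# Methods

This note documents the models, numerical choices, and known limits of the
`cuecode` pipeline, in the order the method runs.

## Synthetic sessions

**Task structure.** A session is two blocks (light, sound) of
`n_trials_per_block` trials (default 100).  Locations cycle
deterministically 1→2→3→4→1 over the whole session.  Outcome labels are
drawn by sequential constrained sampling: per arm, an available-quota of
⌊n_arm/2⌋ (+1 with probability ½ when n_arm is odd) enforces per-arm
near-balance, and a candidate outcome is rejected when it would create a
run of three equal outcomes.  Dead ends are rare and handled by restarting
the block (bounded retries).  This matches the task's constraints exactly
for every seed, which the property tests verify.

**Behaviour and event times.** Approach is Bernoulli per trial with
cue-type probabilities; the defaults are the approach percentages observed
in well-trained animals on this task (light 0.97/0.34, sound 0.91/0.35
for available/unavailable).  Nosepoke latency and inter-trial intervals
are shifted lognormals (latency: median 1.8 s + 0.5 s floor; ITI: median
3 s + 1.5 s floor).  These distributions are conventions, not claims about
the animals — the task literature does not specify them — and both are
configurable `DistributionSpec`s.  On approach trials the outcome is
revealed `reward_delay` = 1 s after the nosepoke and the next trial starts
after a 1 s post-outcome dwell plus an ITI; on skip trials the animal
proceeds directly to the next trial.

**Spike trains.** Inhomogeneous Poisson with piecewise-constant rate.
Epochs: pre-cue [t_cue−1, t_cue), post-cue [t_cue, t_cue+1), nosepoke hold
[t_np, t_out), post-outcome [t_out, t_out+1); these are exactly the windows
the analyses use.  Within an epoch the rate is
`baseline × drift(trial) × ∏ active effect factors`; between epochs only
`baseline × drift` applies.  An effect factor (epoch, feature) is active
when the trial matches the unit's preferred level of that feature
(`cue_any` is always active).  Drift is multiplicative and linear in the
within-block trial index (`1 + slope·i`), the simplest alternative the
Mann–Whitney exclusion should catch.  When the nosepoke falls within 1 s of
the cue, the post-cue epoch is truncated at the nosepoke so the rate
function stays single-valued.

**FSI/MSN structure.** FSI-like units run on `max(rate, floor)` with an
8 Hz floor.  At that floor a > 2 s interspike interval has probability
e⁻¹⁶ per interval; any residual long gap is closed by inserting a
uniformly-placed spike, so the ISI-based class definition holds by
construction rather than with high probability.  MSN-like units use low
baselines (default 3 Hz) and naturally produce ISIs > 2 s over a session.

**What the simulator does not emulate:** spike-sorting noise, refractory
periods, bursting, rate covariation across units (beyond shared trial
labels), behaviourally-locked kinematics, and position/LFP signals.
Passing tests therefore certify the *statistics* — calibration and
recovery under Poisson firing with planted effects — not robustness to
every property of real recordings.

## Screening

Rates are counts in half-open windows `[event+lo, event+hi)` divided by
width.  The drift test compares post-cue (1 s) rates for the first vs
second half of each block's trials with a two-sided Mann–Whitney U at
α = 0.05 per block (the analysis tradition states only "a significant
change"; the α and the choice of the post-cue second are our documented
decisions, both configurable).  Expected null exclusion over two blocks is
1 − (1 − α)² ≈ 9.75%, which the acceptance tests verify by simulation.
Cue modulation is a Wilcoxon signed-rank on paired 1 s pre/post rates
pooled over all trials (p < .01), with direction from the sign of the mean
difference; all-zero differences are reported as p = 1, not modulated.
The funnel is monotone: spike floor → drift exclusion → modulation test.

## Stepwise Poisson GLM

The response is the integer spike count per window (a valid Poisson
likelihood; windows have constant width so counts and rates are
proportional).  Predictor blocks, in the fixed tie-break order: identity
(1 column), location (3 indicators, arm 1 reference), outcome, approach,
trial length (standardized), trial number (standardized), history (outcome
at t−1 and t−2 plus one missing indicator covering each block's first two
trials — kept as an indicator rather than dropping trials so every trial is
fitted).  Categorical predictors enter as whole blocks; the deviance-drop
χ² test uses df = number of columns added.  Predictors constant over the
included trials (e.g. approach in nosepoke-aligned fits, which use approach
trials only) are dropped with a warning.

Fitting uses a batched IRLS Newton solver written for this pipeline: all
unit × window responses that share a candidate design are fitted in one
vectorized call, which is what makes the shuffle null (a full sweep per
shuffle) affordable.  Numerical guards: the linear predictor is capped at
±30 (this bounds coefficients under perfect separation and flags the fit),
a 1e-9 ridge stabilizes near-singular normal equations, and per-response
convergence is declared at a 1e-9 relative deviance change.  The solver is
cross-checked against statsmodels GLM in the test suite, and the full
forward path is checked against exhaustive subset enumeration (statsmodels
fits) on small orthogonal designs.

Partial R² is deviance-based: R² = 1 − D(model)/D(intercept-only), and the
partial for a selected predictor is R²(final) − R²(final − predictor),
floored at 0; a zero null deviance yields a missing value.  The shuffle
null permutes each unit's per-trial counts independently within each
window (the design stays fixed), reruns the entire stepwise sweep, and
z-scores the observed selection proportion per predictor × window against
the shuffle mean and sample SD; zero-SD cells carry a signed-infinity
sentinel and a flag.  Significance is |z| > 1.96 throughout.

## Decoding

Pseudoensembles subsample every unit's trials, per class, down to the
minimum per-class count across units (without replacement) and align the
i-th sampled trial within a class across units.  The min-count rule is our
documented choice; the source analyses do not state how trials were
aligned across sessions.  The classifier is LDA with the least-squares
solver and Ledoit–Wolf shrinkage — with ~100 pseudotrials and a hundred or
more units the pooled covariance is near-singular and plain LDA is not
estimable.  Folds are stratified; the ensemble is rebuilt (re-subsampled)
on every iteration, otherwise the iterations would be redundant.  The
shuffle null permutes each column of the pseudoensemble matrix
independently, destroying each unit's label alignment while preserving its
rate distribution; z uses the shuffle sample SD.  Chance levels (1/2 for
identity and outcome, 1/4 for location) are verified by null simulation.

## Overlap

Selections are binarized per unit; two binary vectors are compared by
Pearson correlation, which equals the phi coefficient from the 2 × 2
table.  Constant vectors carry no overlap information and yield a missing
entry, excluded from the mean rather than imputed as zero.  The matrix
covers the 6 windows fully after the event (centers +0.25 … +0.75 s) —
6 × 6 = 36 correlations, matching the analysis's bookkeeping; which six
windows the original figures used is ambiguous, and this reading is our
documented choice.  The permutation null shuffles one feature's unit
ordering, with the same permutation applied to all six of that feature's
windows within one shuffle, so only the across-feature pairing is nulled
while the feature's temporal structure is preserved.  Labels: separate
(z < −1.96), joint (z > 1.96), independent otherwise; all entries missing
→ "not assessable".

## Population structure

Smoothing evaluates the Gaussian kernel (σ = 100 ms default) directly at
each grid point, normalized so the rate integrates to the spike count;
conservation is exact to 1e-6 for spikes ≥ 5σ from the grid edges.  PETHs
average smoothed single-trial traces on a −1 … +2 s span around cue onset
(the span is a configurable display choice).  For heatmaps, z-scoring per
unit uses the mean/SD over the pooled time bins of the conditions being
compared so that both conditions share one scale; flat rows (SD 0) are
flagged and sorted last.  Sorting is by time of the row maximum (or
minimum, for inhibited-unit displays), and one condition's order can be
applied to another.

Split-half analysis: per condition, trials are shuffled (controlling for
time-in-session) and split into halves, the extra trial joining the first
half; the 6 pairwise correlations among the four half-PETHs give 6 rows
per unit (2 within-condition, 4 across).  The mixed model `r ~ comparison
type + (1 | unit)` is fitted by ML and compared to the intercept-only null
by a likelihood-ratio χ² (df = 5).  Singular random-effect fits (including
zero-variance boundary fits, detectable as non-finite profiled
likelihoods) fall back to OLS with a warning.

## Behaviour

The 2 × 2 discrimination test is Pearson's chi-square without continuity
correction (none is mentioned in the analysis tradition; a flag enables
it), validated against the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) to
1e-10.  The learning criterion is the earliest day starting three
consecutive days significant in *both* blocks, with the per-block reading
of the daily test.  The approach model uses session-level proportions as
the response (a trial-level logistic variant would be a natural extension
but the proportion model matches the analysis being reproduced), cue
outcome and identity as fixed effects, rat as a random intercept, and LRTs
against the model with the term removed; an optional block-half term
probes within-session learning.

## Pipeline and determinism

One root seed feeds named `SeedSequence` child streams, one per stage, so
stage toggles do not shift other stages' randomness and reruns are
bit-identical (the manifest records SHA-256 hashes and the test suite
asserts equality).  The bundle validator re-checks every trial-table and
spike-train invariant with row references; bundle CSVs carry 1 µs time
resolution, and re-reading collapses rounding ties.

## Problem sizes

The test suite and the acceptance script run deliberately scaled problem
sizes — e.g. 20 null sessions × 40 units at 20 shuffles for GLM
calibration (with a single 100-shuffle run as a smoke test), 40 decoder
null runs at 20 iterations/20 shuffles, 200 constructed populations per
overlap scenario, 1000 units for screening calibration, and one 443-unit
session for the split-half bookkeeping — chosen so each statistical band
(binomial or Monte-Carlo) is tight enough to be meaningful at desk scale.
The 20-shuffle z is noticeably lumpier than the 100-shuffle version
(its null exceedance band is wider than the nominal 5%), which the
calibration tests account for explicitly.

## Known limitations

- The Poisson solver flags but does not refit separated candidates; capped
  coefficients near ±30/SD of a column indicate separation.
- The overlap statistic treats missing (constant-vector) cells as absent;
  with very sparse selections entire comparisons can become "not
  assessable" rather than degrading gracefully.
- Mixed models use a random intercept only; random slopes are out of
  scope.
- The simulator's epoch-constant rates make planted effects exactly
  recoverable by window-aligned analyses; temporally smeared real effects
  will show lower recovery than the acceptance numbers suggest.
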