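# Methods

`reachkin` analyses 2D center-out reaching movements of the kind recorded
with a planar robotic manipulandum: a participant holds a handle (with a
biological hand or an artificial arm), sees a cursor via a mirror setup,
and makes fast reaches from a home position at the origin to visual
targets in the forward half-plane. Positions are in cm (+y away from the
body), sampled nominally at 200 Hz. The package covers the full chain
from raw trajectories to group inference, plus a generative simulator
that makes every stage testable without access to recorded data.

## Trajectory segmentation

Tangential speed is the magnitude of the central-difference derivative of
position, smoothed with a zero-phase (forward-backward) Butterworth
low-pass filter at 8 Hz. The filter order is 2 per pass (effective 4th
order), the standard choice in movement science; both the order and the
cutoff are config knobs, and the filter can alternatively be applied to
positions before differentiation (`filter_target="position"`). Edges use
reflective padding, so a constant series passes through unchanged and no
temporal lag is introduced. Filtering can produce microscopic negative
speed excursions near zero; these are clipped at 0.

Landmarks:

* **Onset** — the first sample with speed strictly above 3.5 cm/s. The
  search is anchored at the first sample where speed rises above 10% of
  its eventual peak; this operationalises "the participant's first
  movement" and skips low-amplitude sensor jitter before the reach.
* **Peak** — the speed maximum between onset and the end of the trial
  window.
* **Termination, visually guided ("main") task** — the first local speed
  minimum after the peak whose speed is below 50% of peak speed, i.e. the
  end of the first reach before any secondary correction. A local
  minimum is `s[i] < s[i-1] and s[i] <= s[i+1]` (ties broken toward the
  earlier index). When no qualifying minimum exists the last sample of
  the trial window is used; for bell-shaped single reaches the two rules
  coincide. The trial window ends at the sample nearest 1 s after onset
  (the task's imposed maximum movement time).
* **Termination, no-vision ("loc2d") task** — the start of the first
  quiescent run: speed below 3.5 cm/s for longer than 1 s.

Exclusion rules flag rather than drop trials: endpoints closer than 2 cm
to home or with depth below 1 cm (accidental initiation); speed above
10 cm/s at the last sample of the main-task window (reach unfinished);
loc2d movement times above 10 s or target misses above 20 cm. Detection
failures (speed never above threshold, quiescence never reached) become
excluded reaches with their own reasons (`no_movement`, `unterminated`) —
two states the canonical exclusion taxonomy does not name but a robust
pipeline needs; when an accidental-initiation rule also fires, that more
specific reason wins.

## Endpoint error measures

Per trial: absolute error = Euclidean endpoint-to-target distance; the
error vector = endpoint − target; the initial directional error = the
unsigned angle between home→(position at peak speed) and home→target, a
proxy for the feedforward plan before sensory feedback acts; and the
corrective angle = the unsigned angle between the direction vector at
peak speed and the direction vector at movement end. Both vectors in the
corrective angle are anchored at home by default, consistent with the
direction-vector definition used for the initial error; an alternative
peak-anchored reading (position-at-peak → endpoint) is exposed via
`corrective_anchor="peak"` since the anchoring is genuinely ambiguous in
the protocol this follows. All angles lie in [0, 180]°. A reach whose
position at peak speed coincides with home has no defined direction and
raises a dedicated error.

Per participant and arm, error vectors from all targets are overlaid as
if made to a single target and decomposed:

* **bias** = the centroid of the overlaid error vectors (reported as a
  vector, its magnitude, and its angle from `atan2`);
* **noise** = `sqrt(sum |e_i − mean|² / (n − 1))`, the spatial SD of
  endpoints about their own centroid, pooled over both coordinates. The
  sample (n−1) divisor is chosen because the quantity is called a
  standard deviation; note the pooling convention means isotropic
  per-axis scatter σ yields noise = σ·√2.

The decomposition identity `mean |e|² = |bias|² + Var_pop` (population
divisors) is asserted to 1e-9 inside `decompose` on every call, so any
numerical inconsistency fails loudly rather than silently.

Absolute errors are log-transformed (natural log) before averaging to
correct the right skew of error distributions; the base only rescales
and cancels in any downstream F or t statistic. A zero error under the
log is replaced by machine epsilon with a warning. Outliers among
per-participant transformed errors use Tukey fences (1.5 × IQR beyond
the quartiles, linear-interpolation quartiles), applied per arm with
groups pooled. The Fitts'-law check regresses movement time on the index
of difficulty log2(2D/W) by ordinary least squares. 1D localization
ability is the mean absolute difference between estimated and true
positions along the tube axis.

## Statistics

The central design is an ANCOVA: the artificial-arm (or nondominant-arm)
measure is the dependent variable, the same participant's intact-arm
measure the covariate, and group (control / acquired / congenital) the
between-subject factor. The model uses Type III sums of squares with
sum-to-zero group coding (matching mainstream ANOVA software), fitted
through statsmodels OLS. Reported per effect: F, (df_effect, df_error),
p, and partial eta² = SS_effect / (SS_effect + SS_error). Group means
are adjusted to the grand covariate mean. Post hoc pairwise contrasts on
the adjusted means use the model's coefficient covariance for the
standard error, with Tukey HSD p-values from the studentized-range
distribution (q = |t|·√2). Cohen's d for a contrast is defined as the
adjusted-mean difference over √MSE — a choice that had to be made
explicitly, since "d" is underdetermined in covariate-adjusted designs.
Passing `covariate=None` reduces the machinery exactly to a one-way
ANOVA (used e.g. for device-type comparisons).

Bias angles are circular, so group equality of mean directions uses the
Watson-Williams k-sample test: F = K·(N−k)(ΣRᵢ − R) / ((k−1)(N − ΣRᵢ)),
with Rᵢ the within-group resultant lengths, R the pooled resultant, and
K = 1 + 3/(8κ̂) the concentration correction, κ̂ estimated from the mean
resultant length by the standard piecewise approximation. The test
assumes concentrated samples; a warning fires when the weighted mean
resultant length drops below 0.45.

Bayes factors:

* **t designs** — the default JZS Bayes factor: the alternative places a
  Cauchy(0, scale) prior on the standardized effect size, and BF10 is
  the ratio of the Cauchy-mixed noncentral-t marginal likelihood to the
  central-t null likelihood, computed by adaptive quadrature. Two-sample
  designs use effective N = n1·n2/(n1+n2). The package default scale is
  0.707; analyses that follow the published protocol pass scale 1.39
  (the observed main-task effect size, so the null is "no effect as
  large as the main effect").
* **correlations** — a Jeffreys-style BF with a stretched beta prior on
  ρ (width κ, κ=1 uniform), integrating the exact sampling density of
  Pearson r (Gaussian-hypergeometric form) over the prior.
* **inclusion BFs** — approximated as exp((BIC_without − BIC_with)/2)
  for a nested model pair. This is explicitly an approximation to the
  model-averaged inclusion BF of Bayesian-ANOVA software, not a
  replication of it; published inclusion BFs are therefore not treated
  as checkable targets.

Dependent correlations sharing a variable are compared with Steiger's Z:
the difference of Fisher z transforms scaled by the pooled-r covariance
term, two-sided p from the standard normal. Two-sample location uses the
pooled-variance t or the Mann-Whitney test; the Mann-Whitney statistic W
follows the common statistical-suite convention (rank sum of the first
sample minus its minimum, i.e. U of sample 1) with a tie-corrected
normal approximation — the convention matters because published W values
are convention-dependent.

## Cohort table and usage scoring

The packaged participant table transcribes a published cohort of 20
acquired (ALD), 21 congenital (CLD) and 20 control (CO) rows; asterisked
ids mark participants with valid intact-arm data only, who are excluded
from artificial-arm analyses (leaving 14 acquired, 18 congenital, 19
controls). A transcription guard (the PAL column sums to 17.46) is
tested.

The PAL score is the sum of 27 item ratings (0/1/2) over the maximum 54.
The combined usage score z-transforms weekly wear time and PAL against a
reference population (sample SD) and sums them. The reference defaults
to all prosthesis users present in the table, both groups pooled and
intact-only rows included — the choice that best matches the printed
score column (recomputed scores correlate > 0.9999 with it); because the
original normalization population is not recoverable exactly (41 listed
vs 44 recruited users), exact equality is not claimed and the check is
correlation-based.

History derivations: acquired — age at amputation = age − years since
amputation, experience = years since amputation − limbless years;
congenital — experience = age − age at first artificial arm use.
Negative derived values are rejected as data errors. On the packaged
table these derivations give the headline gap of ~29.25 years more
artificial-arm experience in the congenital group, t(30) = −7.86, and a
near-zero usage-score difference, t(30) = −0.25.

## The synthetic reach generator

Each simulated trial is two minimum-jerk submovements with a quiescent
lead-in (0.15 s) and tail. Phase 1 (feedforward) pushes toward a drawn
endpoint `target + bias + N(0, σ_exec² I)` with the normalized
minimum-jerk profile `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` (peak speed 15D/8T);
the initial direction is rotated by a planning angle θ ~ N(0, σ_plan²)
that decays with the travelled fraction (angle θ·(1−s)), so the early
path carries the planning error while the phase-1 endpoint equals the
drawn feedforward endpoint exactly — this keeps the endpoint marginal
analytic (mean = bias, isotropic SD σ_exec) independent of σ_plan.
Phase 2 (feedback) starts at the inter-submovement velocity valley and
removes a `feedback_gain` fraction of the remaining target error, adding
N(0, σ_fb² I). Ground truth recorded per trial: the planning angle, both
endpoints, the movement-start / onset-threshold-crossing / valley /
settle times.

Defaults are chosen to emulate a 1-s fast-reach protocol: movement
duration 0.8 s split 60/40 between phases, 200 Hz sampling, 60 targets
in a 3-radii (8/12/16 cm) × 20-direction fan over 120° centered
straight-ahead. The true target coordinates of the protocol this
emulates are not published numerically, so the layout is configurable
and never claimed to match; all layouts must keep targets ≥ 4 cm from
home so accidental-initiation rules cannot fire on valid reaches.

Group presets place participant-level parameters on lognormal
hyper-distributions (spread 0.25) around: control = acquired (σ_plan 3°,
σ_exec 1.0 cm, σ_fb 0.4 cm, bias 0.5 cm) and congenital with planning
and execution noise inflated 1.7× — the inflation sits on σ_plan and
σ_exec because those drive the measured initial directional error and
first-reach endpoint noise, reproducing the qualitative group ordering
(congenital noise > acquired ≈ control) at roughly the reported effect
sizes. Intact-arm parameters are shared across groups. Seeding fans a
master seed out through `numpy.random.SeedSequence.spawn`, so
per-participant streams are independent and every run is bit-reproducible.

What the generator does **not** emulate: sensor noise and dropout,
biomechanical arm dynamics, continuous feedback control (LQG-style),
target-location-dependent error anisotropy, within-session learning or
fatigue. Passing tests therefore demonstrate that the analysis chain
recovers the statistical structure it assumes — separable planning
noise, endpoint bias, execution scatter, feedback correction — not that
real reaching data satisfy those assumptions.

## Numerical and design choices

* Zero-phase filtering with `padtype="even"`; filter idempotence holds
  away from the padded edges for band-limited signals.
* Quartiles by linear interpolation; local-minimum ties break earlier.
* The JZS integral splits at zero to keep adaptive quadrature stable;
  an estimated relative error above 1e-4 raises rather than returning a
  doubtful value.
* Trajectory CSVs and stage TSVs are written with shortest-round-trip
  float text and read back with exact (round-trip) parsing, so the
  pipeline is re-entrant from any intermediate file at the bit level and
  a fixed config + seed reproduces byte-identical outputs.
* Validation sizes used by the test-suite experiments: 1,000 random
  speed profiles for the termination oracle, 50 random datasets for the
  ANCOVA oracle, 5,000 replicates for the Watson-Williams and Steiger
  null calibrations, 2,000 for ANCOVA power, and a 3×3 bias/scatter grid
  with 500 replicates of 60 trials for parameter recovery (run at the
  endpoint-marginal level, with a trajectory-level pass on top).

## Known limitations

* The Watson-Williams concentration correction is a small-sample
  approximation; heavily dispersed samples (warned at r̄ < 0.45) can
  distort its size.
* The BIC inclusion BF can diverge from model-averaged inclusion BFs
  when many models are in play.
* `noise_sd` is a square root of an unbiased variance estimate and so
  carries the usual ~1/(4·df) downward Jensen bias (≈0.2% at 60 trials,
  both coordinates pooled); the bias-magnitude estimator is upward
  biased near zero true bias, which is why parameter recovery checks the
  bias *vector*.
* Group usage presets are qualitative stand-ins bracketing published
  summary ranges, not fits to any raw dataset.
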