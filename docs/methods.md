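# Methods

## The observer model

Upright perception in the dark is modeled as Bayesian inference on head
orientation.  The observer senses its head-in-space angle H_S through a
noisy, in principle unbiased channel (otoliths + neck proprioception) and
combines it with a Gaussian prior over head positions peaked near upright
(mean H_Sp, SD σ_HSp).  The systematic error of the subjective visual
vertical (SVV) is the gap between the true configuration and the
posterior estimate, plus an uncompensated ocular-torsion term:

    μ_SVV = w · (H_S − H_Sp)  −  (1 − w) · b  −  ΔE_H · sin(H_S)

    w = σ̂² / (σ_HSp² + σ̂²),       σ̂ = α₀ + α₁ · |H_S|

* `w·H_S` is the **A-effect** term: the prior drags the head estimate
  toward upright, so the SVV errs toward the tilt; it grows with tilt
  because the sensory noise σ̂ grows (slope α₁ per degree of tilt).
* `−ΔE_H·sin(H_S)` is the **E-effect** term: the brain under-registers the
  ocular counterroll, pushing the SVV away from the tilt at small angles.
* `b` is an additive bias on the *sensed* head signal (the sensed value is
  H_S + b).  It enters with weight −(1−w) because it propagates through
  the posterior mean: when the sensed tilt *decays* (b opposing the tilt),
  the head estimate shrinks and the SVV error grows **toward** the tilt.
  A printed variant of this equation swaps the prior/sensory weights
  (putting σ_HSp² on H_S); that form is inconsistent with the w·H_S
  reduction at H_Sp = 0 and with the sign of the adaptation scenario, so
  the self-consistent posterior-mean form above is used throughout.

The noise law uses the *true* head angle (the law is written in |H_S|),
not the sensed one.  ΔE_H is a fixed amplitude in degrees; it is never
allowed to drift (small torsion changes cannot produce large SVV changes
through this term, and measured torsion drifts are small).

Defaults (`ObserverParams`) are representative published fit values for a
healthy adult: σ_HSp = 6.5°, H_Sp = 0°, α₀ = 2.2°, α₁ = 0.07/°,
ΔE_H = 14°.  At a 20° tilt these give μ_SVV ≈ −0.1°, i.e. the mild
E-effect typical of small tilts; individual planted biases are layered on
top by the cohort generator (below).

### Decision rule

The model above yields only the mean SVV error, so binary 2AFC choices
need a response model.  A line at deviation d from the gravitational
meridian is judged "tilted right" with probability

    P(right) = λ/2 + (1 − λ) · F((d − μ_SVV) / s),

F the standard logistic CDF, s the decision scale (deg), λ a lapse rate in
[0, 0.1].  A logistic (not probit) is used deliberately: the analysis
fits a logistic GLM, so the generating model is correctly specified and
the psychometric *precision* — the 75 %−50 % distance — equals exactly
s·ln 3.  Default scales are therefore 0.7/ln 3 ≈ 0.637° upright and
2.0/ln 3 ≈ 1.820° tilted, reproducing precisions of 0.7° and 2.0°.

Reaction times are log-normal (shape 0.15 in log units) with
condition-specific means (640 ms upright, 686 ms tilted, 661 ms
post-tilt), censored to the task's 300–1500 ms response window.

### Time-varying scenarios

`ScenarioSchedule` makes one model quantity drift while the head is
tilted; the three named mechanisms differ in their fingerprints:

| kind           | during tilt                  | after return to upright     |
|----------------|------------------------------|-----------------------------|
| `sensory_drift`| sensed tilt decays (b ramps) | residual after-response, same-signed aftereffect |
| `prior_drift`  | H_Sp moves toward the tilt   | drift was *away* from tilt  |
| `noise_growth` | α₁ grows, w rises            | no aftereffect: σ̂ = α₀ at H_S = 0 |

Both linear and exponential (time constant `time_constant`) ramps are
available; linear is the default because the analysis summarizes drift as
a linear slope and the data do not constrain the functional form.  The
post-tilt residual is `aftereffect_gain` times the change accumulated by
tilt end (frozen from the realized state, so capped trajectories are
handled correctly), decaying with time constant `aftereffect_decay`
(infinite — persistent — by default, since the study reports a single
aftereffect value, not a washout curve).  The `bias_*` anchor fields let
a generator pin the bias channel exactly at segment starts.

## The adaptive task

A session is 100 upright + 500 tilted + 150 post-tilt trials (750 total),
with a 30-s pause whenever the head moves (avoiding semicircular-canal
transients; the model is purely static).  Trials run in blocks of ten:
five deviations drawn i.i.d. uniformly from the current probing range,
folded modulo 180° into (−90°, 90°] (a line is the same stimulus rotated
by 180°), each presented once radiating into the upper and once into the
lower hemifield, in a seeded shuffled order.  Per trial: 1 s fixation,
line onset (the scenario state is advanced to this instant), response
after the reaction time, then a 0.2-s inter-trial interval.  The 0.2 s is
a deliberate calibration: with the tilted-condition reaction times it
puts the 500-trial tilt segment at ≈ 15–16 min, the duration regime the
paradigm is meant to occupy.  Missed trials (probability 0.5 % by
default) are re-queued at the end of the block's remaining order, so
every planned (deviation, hemifield) pair is answered exactly once.

After each block the range re-centers on the SVV estimated from the last
30 answered trials of the segment and its amplitude halves:
360, 180, 90, 45, 22.5, 11.25, then the 10° floor (±5° around the
center).  Strict halving from 360° reaches the floor at the 7th block;
descriptions putting the floor at a 9th block are treated as descriptive
rather than schedule-defining.  Every head-position change resets the
range to 360°, and the 30-trial estimation window never crosses a
segment boundary.

The running 30-trial estimate uses a logistic GLM when the responses
overlap; with the steep slopes and wide ranges of early blocks the
responses are usually perfectly separable, in which case the estimate is
the midpoint between the largest deviation answered "left" and the
smallest answered "right" (unanimous responses return the presented-range
edge nearest the implied PSE).  The original task software's internal
estimator is not documented; these fallback rules are this package's own.

## The torsion generator

Emulates the output of a video-oculography torsion tracker: 100-Hz
binocular samples with white measurement noise (SD 0.08°, below the
system's stated 0.1° noise level).  Per eye:

    torsion(t) = −gain · H_S(t) + drift·ramp(t) + aftereffect + ε(t)

with an instantaneous counterroll (gain ≈ 0.20; any dynamic transient is
hidden inside the 30-s pauses), a linear drift ramp across the tilt
segment scaled to the segment's trial count (signed toward the tilt), a
constant post-tilt offset, and a static interocular offset (0.3°, left
eye positive) so the binocular-averaging contract is exercised.  The
pre-tilt upright recording defines the reference baseline; per-trial
torsion is the mean binocular value between line onset and response
(which window the original analysis used is not documented; this is the
adopted contract).  Not modeled: iris-pattern image processing, blinks,
saccadic torsion transients, dynamic counterroll.

## The analysis pipeline

* **Psychometric fit**: binomial-logit GLM of response-is-right on
  deviation; PSE = −intercept/slope, precision = ln 3/slope (analytic;
  identical to locating the 50 % and 75 % points of a logistic).  On
  perfect separation or non-convergence the window is re-fit with a
  ridge-penalized logistic (inverse penalty C = 10) so every window
  reports a value; the `converged` flag stays False for auditing.
  Unanimous windows fall back to the range-edge rule and carry no slope.
* **Windows**: within each head-position segment, the first 50 answered
  trials are discarded (the range is still too wide to estimate reliably)
  and 100-trial windows advance in steps of 50; a window is emitted only
  if it fits entirely inside the segment.  The 500-trial tilt segment
  yields 8 windows, the 150-trial post-tilt segment 1, the 100-trial
  baseline segment none — its single baseline estimate is instead the
  100-trial fit over the whole segment (the converged later trials
  dominate).  Windows never cross segment boundaries.
* **Drift**: OLS of the windowed series on window-center trial index,
  scaled to deg/500 trials (primary axis), plus a second regression on
  window-center time giving deg/min.
* **Aftereffect**: mean post-tilt windowed value minus the pre-tilt
  baseline, same contract for SVV and torsion.
* **Group statistics**: condition means ± SEM (SD/√n); paired t-tests for
  left/right symmetry after sign reversal and for difference from zero;
  Spearman correlations (drift vs aftereffect; SVV vs torsion) computed
  once per subject after averaging the left value with the sign-reversed
  right value.  Significance is labeled at a flat p < 0.01; raw p-values
  are always reported and no multiplicity correction is applied.
  Group drift is reported both as the mean of per-subject slopes (primary
  here, since it matches the per-subject recovery audit) and is available
  per-subject for pooled-fit variants.

## The cohort generator

Twelve virtual subjects, each with a left- and a right-tilt session in
randomized order.  Per-condition behaviour is drawn from Gaussians whose
means are the target group values and whose between-subject SDs are the
group SEMs × √12 (n = 12):

| quantity                  | left tilt        | right tilt      |
|---------------------------|------------------|-----------------|
| baseline SVV (deg)        | −0.2 (SD 2.08), shared across conditions |
| initial tilt SVV (deg)    | +0.2 (SD 5.20)   | −2.6 (SD 4.50)  |
| SVV drift (deg/500 tr)    | −5.4 (SD 4.85)   | +2.2 (SD 7.27)  |
| SVV aftereffect (deg)     | −3.9 (SD 2.08)   | +2.55 (SD 3.46) |
| counterroll gain          | 0.20 (SD 0.069), truncated to [0.02, 0.5] |
| torsion drift (deg/500 tr)| −0.8 (SD 1.04)   | +0.6 (SD 0.69)  |
| torsion aftereffect (deg) | −0.2 (SD 1.04)   | +0.2 (SD 1.04)  |
| precision base/tilt/post  | 0.7 (0.346) / 2.0 (1.04) / 1.3 (0.346) |
| RT base/tilt/post (ms)    | 640 (97) / 686 (87) / 661 (104) |

Drift and aftereffect are drawn independently, as are the SVV and torsion
quantities (observed correlations are null); `couple_*` knobs introduce
correlations for power experiments.  Draws that must be positive are
redrawn inside physiological bounds (redraws logged).  The default lapse
rate is 0: the analysis GLM carries no lapse term, and a single lapse at
an extreme angle inside a 100-trial window has enormous leverage on the
slope; lapses remain available in the response model for robustness
studies.  Post-tilt decision noise uses the printed post-tilt precision
(1.3°), completing the three-segment noise profile.

Given the draws, the generator *solves* the sensory-bias schedule that
realizes them through the observer model: the planted SVV path during
tilt is linear in answered-trial index, anchored so the first analysis
window (trials 51–150, center 100.5) recovers the planted initial bias;
the per-500-trials slope is converted to deg/min via the subject's
expected trial duration (fixation + mean RT + inter-trial interval); the
post-tilt bias is a persistent residual giving exactly baseline +
aftereffect.  Inverting `μ = μ_static − (1−w)·b` per segment makes the
planted values exact model properties, so pipeline error — not generator
error — is what recovery tests measure.

### What the generator does and does not emulate

It reproduces the *statistical* structure of the study: trial counts and
schedule, adaptive-range dynamics, drift/aftereffect magnitudes and
between-subject spread, counterroll gains, torsion noise, reaction-time
profiles, session durations.  It does not model the physiology producing
those numbers (real sensory adaptation dynamics, canal transients,
fatigue, or the minority of subjects whose drift opposes the tilt as a
distinct subpopulation — they arise here only as Gaussian tail draws).
Passing recovery tests therefore certifies the pipeline and paradigm
implementation, and the attainability of the planted effect sizes — not
any claim about human subjects.

## Numerical choices and degenerate inputs

* Reproducibility: every stochastic step draws from a generator spawned
  via `SeedSequence([master, subject, condition])`; identical seeds give
  bit-identical trial logs, traces and CSVs.
* Angle folding maps raw draws to (−90°, 90°] with the −90° tie sent to
  +90°; ray angles live in (−180°, 180°] with 0 = up.
* Between-subject sampling is i.i.d. Gaussian; a 12-subject group mean
  therefore carries the planted SEM as its sampling SD, and recovery
  checks use a 2-planted-SEM band (≈ 95 % of replications per quantity).
* Separation handling, the unanimity edge rule, and the midpoint
  tie-break are described above; fits whose slope is non-positive after
  the ridge fallback report the separating midpoint and no precision.
* Degenerate group inputs (zero between-subject variance) make t-tests
  undefined; they are flagged `degenerate` rather than erroring.
* Problem sizes: the full study is 12 subjects × 2 sessions × 750 trials
  plus 100-Hz traces; simulation and analysis of the whole study take a
  few seconds on one CPU, and the complete test suite runs in well under
  a minute.

## Known limitations

* The posterior-mean bias weighting −(1−w) is a modeling commitment; an
  alternative reading that biases the comparison signal instead would
  flip the drift/aftereffect signs and is rejected on that evidence.
* Per-subject calibration beyond group mean/SEM is impossible — no
  individual-level source values exist — so subject files are exchangeable
  draws, not reconstructions of particular participants.
* The linear-in-trial-index planted path is converted to continuous time
  through the *expected* trial duration; realized durations differ by
  reaction-time noise and missed-trial overhead (≈ 1 %), a bias far below
  the recovery tolerances.
* The pooled-fit variant of group drift (one regression through all
  subjects' points) is not the primary estimate; per-subject slopes
  averaged across the cohort are.
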