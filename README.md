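# svvdrift

Virtual-observer simulation and analysis of **subjective visual vertical
(SVV) drift during sustained head tilt**, with simultaneous ocular
counterroll.

When the head is held tilted for many minutes, the perceived direction of
gravity is not stable: SVV reports drift toward the tilt, and after the
head returns upright a same-signed aftereffect remains.  Whether these
perceptual changes track torsional eye position is a central question in
vestibular psychophysics.  This package provides the complete
computational apparatus for studying that question in silico — for
psychophysicists designing adaptive SVV experiments, and for
methodologists who want to verify that a sliding-window psychometric
pipeline actually recovers the drift and aftereffect parameters planted
in a synthetic cohort.

It contains, as importable library code under `src/svvdrift/`:

* **observer** — a Bayesian spatial-perception model of verticality.  The
  SVV error at head tilt H_S is

      μ_SVV = w·(H_S − H_Sp) − (1 − w)·b − ΔE_H·sin(H_S),
      w = σ̂²/(σ_HSp² + σ̂²),  σ̂ = α₀ + α₁·|H_S|

  (prior peak H_Sp and SD σ_HSp; sensory noise α₀ + α₁|H_S|; sensed-head
  bias b; uncompensated torsion amplitude ΔE_H), plus a lapse-contaminated
  logistic 2AFC decision rule and three time-varying drift scenarios
  (sensory adaptation, prior drift, noise growth) with distinct
  drift/aftereffect fingerprints.
* **task** — the adaptive 2AFC paradigm: 750 trials (100 upright, 500
  tilted 20°, 150 post-tilt), blocks of 10 line orientations (5 angles ×
  2 hemifields), a probing range that re-centers on the last 30 responses
  and halves from 360° to a 10° floor, missed-trial re-queueing, and a
  full reset at every head-position change.
* **torsion** — synthetic 100-Hz binocular torsion traces: counterroll
  (gain ≈ 20 %) opposite the tilt, slow drift toward it, post-tilt
  offset, < 0.1° measurement noise.
* **analysis** — the pipeline: logistic psychometric fits (PSE +
  precision = ln 3/slope), 100-trial windows stepping 50 with the
  discard-first-50 rule, linear drift regressions per trial index and per
  minute, aftereffects vs the pre-tilt baseline, and group statistics
  (means ± SEM, paired t-tests at p < 0.01, Spearman correlations after
  sign-flip averaging of the two tilt directions).
* **cohort** — a calibrated synthetic study: 12 subjects × 2 sessions
  drawn from Gaussian group distributions (SD = SEM·√12), with observer
  schedules solved so each session realizes its planted drift and
  aftereffect exactly.

See `docs/methods.md` for the model, calibration and design decisions.

## Worked example

The numbered scripts under `analysis/` replay the whole study:

```
$ python analysis/01_simulate_study.py --seed 1
simulated 24 sessions (seed 1)
answered trials per session: [750]

$ python analysis/03_group_stats.py --seed 1
group statistics over 12 subjects (seed 1)
   left drift_svv          estimate -3.41 +- 1.05 SEM | planted draws -3.54
   left aftereffect_svv    estimate -4.10 +- 0.66 SEM | planted draws -3.98
   left drift_torsion      estimate -1.13 +- 0.21 SEM | planted draws -1.17
  right drift_svv          estimate +3.87 +- 2.56 SEM | planted draws +4.28
  right aftereffect_svv    estimate +0.92 +- 0.73 SEM | planted draws +0.84
  right drift_torsion      estimate +0.11 +- 0.12 SEM | planted draws +0.11
  svv_drift_vs_aftereffect: rho +0.17, p 0.60

$ python analysis/04_scenarios.py
sensory_drift : drift +0.230 deg/min (toward tilt), aftereffect +3.226 deg
prior_drift   : drift -0.117 deg/min (away from tilt), aftereffect -0.616 deg
noise_growth  : drift +0.366 deg/min (toward tilt), aftereffect +0.000 deg
```

Reading the output: each session's SVV drift is the slope of the windowed
psychometric series over the 500 tilted trials, in degrees per 500
trials; negative means leftward.  For this seed the left-tilt cohort
drifts −3.41°/500 trials against planted subject draws averaging −3.54 —
the pipeline estimate tracks the planted truth to about a tenth of a
degree, with the spread between seeds dominated by which 12 subjects were
drawn, not by pipeline error.  The aftereffect rows compare post-tilt SVV
with the pre-tilt baseline; the drift–aftereffect correlation is null
here because the generator draws the two independently.  The scenario
lines show the three mechanistic fingerprints: only sensory-signal
adaptation yields drift toward the tilt *and* a same-signed aftereffect;
a prior drifting toward the tilt moves the SVV the other way; growing
sensory noise drifts the SVV but leaves no aftereffect.

The same machinery is scriptable from a shell:

```
svvdrift simulate --seed 1 --out bundle/ --subjects 2
svvdrift analyze --log bundle/S01_left_trials.csv \
                 --torsion bundle/S01_left_torsion.csv --out out/
svvdrift scenario --kind sensory_drift --out scenario.csv
svvdrift reproduce --seed 1 --out study/
```

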