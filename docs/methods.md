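# Methods

This note documents the models behind `hiecod`: what the pipeline computes,
what the synthetic-data generator emulates, the numerical choices that are
not forced by the protocol description, and what the test suite does and
does not demonstrate about real recordings.

## Protocol model

The session is 2 sets of 10 runs of 4 s departing every 16 s, with 2 min
20 s between sets and 16-s active recoveries at 6 km/h.  Time zero is the
onset of the first run of set 1 and every window is half-open `[start, end)`
in seconds, so the 1000-Hz EMG, 10-Hz NIRS and breath streams index
identically.  Set 2 therefore starts at 10 × 16 + 140 = 300 s, and a "set
window" spans from the first run onset to the end of the last recovery
(160 s), which is also the averaging window for set-level V̇O₂ and Hbdiff
(the protocol text does not fix this window; a continuous window matches the
way set-level traces are usually reported).

The COD distance adjustment `t_SL × 22 / t_COD` is scale-invariant in the
time unit and reduces to `ratio × 22 m`.  Maximal sprint speed is 10 m over
the fastest 10-m split across both recorded 40-m sprints.  Relative
intensities are plain distance/duration speeds expressed against MSS and
vV̇O₂max.  Note that an average-speed COD intensity computed this way is
necessarily ≈ ratio × the straight-line %MSS (≈ 64 %MSS for a 0.75 ratio);
an intensity near 51 %MSS cannot be obtained from distance/duration alone,
so the pipeline reports the distance/duration value and leaves any such
discrepancy visible rather than reproducing it.

## EMG chain

Band-pass: 4th-order Butterworth 20–450 Hz applied forward-backward
(zero phase, doubled effective order).  Envelope: centered 50-ms moving RMS
with shrinking windows at the edges.

Burst detection is a double-threshold segmentation.  The inactivity
reference is taken from the 3-s "ready" period before each run: the
band-passed signal is rectified, cut into non-overlapping 50-ms windows, and
the three lowest-amplitude windows provide the pooled mean + 2 SD threshold.
The statistics are deliberately computed on the *rectified samples*, not on
the smoothed envelope: the envelope of Gaussian noise of SD σ concentrates
tightly around ≈ σ, so a "mean + 2 SD of the three lowest envelope windows"
threshold would fall *below* the typical noise envelope and chatter
constantly, whereas the rectified-sample statistics put it near 2σ.

Numerical choices, each visible as a module constant:

* **Threshold floor** — 0.1 % of the analysis-window envelope peak.  On
  noise-free signals the inactivity statistics give a threshold of exactly
  zero while zero-phase IIR filtering leaves ~1e-4 relative ringing between
  contractions; the floor sits an order of magnitude above the ringing,
  three below any contraction, and is inert once real noise is present.
* **Smear correction** — the centered 50-ms RMS window extends a burst's
  envelope support by half a window on each side, so detected region edges
  are pulled inward by 25 ms (`smear_s`, settable to 0 for envelopes that
  were not smoothed).
* **Minimum burst duration 50 ms; minimum inter-burst gap 20 ms.**  With
  200-ms contractions every 280 ms, RMS smoothing leaves only ≈ 30 ms of
  sub-threshold envelope between strides; a merge rule at a full window
  (50 ms) would fuse consecutive strides, while 20 ms still absorbs
  threshold chatter.

Run summaries use five consecutive mid-run strides chosen to minimize the
coefficient of variation of peak RMS (ties resolved toward the window
centred on the run middle, then the earlier window) — an explicit
operationalization of "similar peak amplitudes".  The normalization
reference is, per muscle, the mean amplitude of the five largest-peak
contractions of the fastest 22-m sprint; run amplitudes are percentages of
it.  A run with fewer than five detected strides is excluded and logged;
set values are means over the remaining runs.

Onset accuracy is threshold-limited: a raised-cosine contraction reaches a
2-SD threshold only ~30 ms into its rise, so sub-10-ms onset agreement with
ground truth is achievable when the effective threshold is far below the
contraction amplitude (the noise-free check in the acceptance suite) but
not at a 10:1 amplitude-to-noise ratio, where only the detection *count* is
scored.

## NIRS

Hbdiff = (HbO₂ − HHb)/2 in μM, reported as change from the mean of the 30 s
immediately preceding the first run.  The differential pathlength factor
(3.83) travels as metadata; concentrations are accepted as emitted by the
instrument, so no Beer–Lambert reconstruction is performed.  Set summaries
are the window mean and the mean of the second half of the window
("plateau"), which for a mono-exponential with τ = 10 s over a 160-s set
differs from the asymptote by < 0.1 %.  No motion-artifact rejection is
applied.

## Cardiorespiratory and performance outcomes

Breaths are block-averaged over consecutive 5-s bins.  V̇O₂max is the
highest sliding 30-s mean of the incremental test (stages of 60 s, +0.5 km/h
from 8 km/h); vV̇O₂max is the lowest stage speed held ≥ 60 s whose own best
30-s mean reaches V̇O₂max within 2 %.  When breath noise places the single
best 30-s window inside the partial final stage so that no completed stage
reaches it within tolerance, the estimator falls back to the last completed
stage at or below the speed where the maximum occurred — the standard
"last completed stage" convention.

Jump fatigue is `mean height / pre-test height × 100 − 100` with the mean of
the two trials at each timepoint; lactate accumulation is the post-set minus
post-warm-up concentration; the condition-level lactate value is the mean of
the two per-set accumulations.

## Magnitude-based inference

All strictly positive outcomes are compared on the natural-log scale and
back-transformed to percent for reporting; signed outcomes that can be
non-positive (Hbdiff changes, jump percent decrements) are analysed on the
raw scale, since a blanket log-transform is undefined for them.  SWC = 0.2 ×
the between-subject SD of the straight-line reference values (earliest
timepoint), on the analysis scale.  Chance triples use the t distribution
with n − 1 degrees of freedom and SE = SD/√n — the standard
formulation of the spreadsheet-based MBI computation; with n = 11 the
difference from a normal formulation is well inside the Monte-Carlo
tolerance the tests enforce (±0.5 percentage points against a 200,000-draw
oracle).  A degenerate SE of 0 yields indicator probabilities.  The
probability scale is implemented with left-open/right-closed bins so the
printed boundaries partition [0, 1] exactly; "unclear" takes precedence when
both directions exceed 5 %.

The pipeline emits two comparison families per outcome: set 2 vs set 1
within each condition, and COD vs SL on each subject's mean across sets.

## Synthetic-data generator

The generator defines the study conditions and always emits ground truth
(stride onsets/offsets and amplitudes, plateau values, per-subject effect
draws, per-set V̇O₂ targets) sufficient to score every downstream stage.

**Cohort** (n = 11): MSS 6.4 ± 0.25 m/s, vV̇O₂max 15.1 ± 1.0 km/h snapped to
the 0.5-km/h stage grid, V̇O₂max 55 ± 5 mL/min/kg, CMJ 37.3 ± 4.5 cm,
DJ 23.7 ± 6.2 cm, straight/COD sprint-time ratio 0.75 ± 0.02 truncated to
(0, 1).  All randomness flows from one root seed through substreams keyed by
(subject, purpose, condition), so any subset regenerates independently.
Streams that represent subject traits — carrier phases (electrode/muscle
geometry), breath timestamps, relative aerobic engagement, resting lactate —
are keyed without the condition, which makes the zero-effect, zero-noise
configuration produce *identical* data in both conditions (every
between-condition difference is then exactly 0, a pipeline-level test).

**EMG**: each stride is a 200-ms raised-cosine RMS envelope repeating every
280 ms (14 strides per 4-s run) riding on a deterministic unit-RMS carrier
(four tones at 60/110/170/260 Hz with per-channel random phases), plus
additive white noise (default SD 15 μV).  An amplitude-modulated in-band
carrier — rather than emitting the rectified envelope itself — is what makes
the generated signal survive the 20–450 Hz analysis band-pass; the
modulation envelope is the ground truth.  Run amplitudes are 85 % of the
per-muscle sprint amplitude (250–350 μV), with per-set, per-condition mean
decrements (e.g. semitendinosus −15 %/−19 % with COD vs −5 %/−8 % in
straight line) plus a 6-percentage-point between-subject SD.  The reference
sprint uses the same stride shape and interval, which makes the programmed
normalized amplitude an exact target for the chain.  Active recoveries
contain low-amplitude (40 μV) jog strides that stop 3.4 s before each
departure, leaving the ready period quiet.  At the default noise level the
recovered normalized amplitudes carry a small (≈ +2–3 %) systematic
inflation — noise power adds to burst RMS relatively more than to the
higher-amplitude sprint reference — which is why exact recovery is asserted
on noise-free signals only.

**NIRS**: Hbdiff drops mono-exponentially (τ = 10 s) to a per-subject
plateau (−8 μM vastus lateralis, −6 μM biceps femoris, 15 % between-subject
SD) within each set and recovers toward baseline with the same τ between
sets (recovery kinetics are not otherwise constrained); HbO₂ and HHb move
symmetrically about resting values of 60/40 μM with 0.3 μM white noise.

**V̇O₂**: breath-by-breath values (mean interval 2.5 s) follow first-order
kinetics (τ_on 25 s, τ_off 40 s) whose set plateaus are solved analytically
so that the *mean over the set window* equals the per-subject target — the
quantity the analysis recovers.  Targets: set 1 at 81.3 (SL) / 79.9 (COD)
%V̇O₂max with 8 % between-subject SD; set 2 = set 1 × (1 + 5.4 % SL /
8.1 % COD).  Breath noise is 4 %.

**Scalar outcomes**: effects are multiplicative on the natural-log scale —
`log y = log(baseline) + subject + condition·[COD] + timepoint + noise` — so
the inference engine's log-transform assumption holds exactly.  Lactate
accumulation: baseline 8 mmol/L over a 2-mmol/L post-warm-up value,
condition effect +9.7 % (SD 10.4 %), set-2 effect +10 %, between-subject SD
45 %.  The between-subject value is deliberately large: with a mean paired
difference near +10 % and an SD of differences near 10 %, only a smallest
worthwhile change of roughly 9 % (0.2 × ≈ 45 %) reproduces the reported
"possibly higher" classification texture; tighter spreads would push every
cohort to "very likely/almost certainly higher".  RPE baseline 6 (set-2
+25 %), jump timepoint decrements of −3.6/−3.3 % (CMJ) and −6.7/−6.8 % (DJ)
with no condition effect, two trials per timepoint.

What the generator does **not** emulate: within-run amplitude variability
and stride-interval jitter, electromyographic crosstalk and motion
artifacts, NIRS adipose-tissue heterogeneity and probe-pressure drift,
breath-by-breath V̇O₂ kinetics coupling to stride, and any
condition-by-timepoint interaction beyond the multiplicative effects above.
Passing tests therefore demonstrate correctness of the computational chain
under controlled statistical structure, not robustness to every artifact of
field recordings.

## Problem sizes and runtime

The default study (11 subjects × 2 conditions of 8-channel 1000-Hz EMG over
~500 s, plus NIRS, breath and incremental-test traces) generates, processes
and infers in roughly 15 s on one CPU, holding one trial in memory at a
time.  Parameter-recovery checks average 200 resampled 11-subject cohorts
(scalar outcomes and breath traces only), and the inference engine is
verified against a 200,000-draw Monte-Carlo oracle on a 75-point grid.

## Known limitations

* Detected burst onsets are threshold-crossing times; at realistic
  noise-to-amplitude ratios they lag the true envelope support start by the
  rise time to threshold (tens of ms for slow-rising contractions).  No
  shape-specific extrapolation is attempted.
* Normalized EMG amplitudes inherit a small positive bias at finite noise
  (see above).
* The MBI implementation intentionally reproduces the spreadsheet-style
  computation, including its limitations; it provides no null-hypothesis
  p-values, interval estimates, or Bayesian reformulation.
* `process` regenerates signals from the seed rather than re-reading the
  signal TSVs; the TSV round-trip (4-decimal μV/μM precision) is exercised
  by the I/O layer and validator instead.
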