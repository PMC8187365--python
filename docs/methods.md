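# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, what the synthetic data does and does not emulate, and where
the open design decisions were resolved.

## Trace model and file format

All recordings are uniformly sampled, unit-annotated 1-D signals (`Trace`)
with a pacing schedule (`StimulusTrain`) and assay metadata
(`RecordingMeta`). On disk a recording is a two-column CSV
(`time_s,value`) plus a flat JSON sidecar; floats are serialized with their
shortest round-trip representation, so write → read → write is
byte-identical, and the time column is checked against the sampling grid to
within 0.25 sample periods. Times on disk are always seconds; milliseconds
appear only in reported biomarkers. Micrometres are stored as ASCII `um`
(`µm` accepted on read). Capacitance is mandatory for clamp recordings
because densities are reported in pA/pF. Validation returns *findings*
(code, message, index) rather than exceptions, so a QC step can list every
problem at once; `read_trace` refuses files whose findings include
non-finite samples.

## Synthetic recordings

The generators are phenomenological, not biophysical; their purpose is to
produce traces whose ground truth is exactly known so that every analysis
stage can be closed-loop tested.

**Action potentials.** Each beat is a linear upstroke (1 ms) from the
resting potential (−80 mV default) to the peak (+40 mV default), followed
by a logistic repolarization whose time constant is `apd90/12`. The
logistic midpoint is placed analytically so that the 90% repolarization
crossing lands exactly at that beat's target APD90, which makes
APD20/50/90 of a noiseless beat computable in closed form. Per-beat APD90
follows a stationary AR(1) process with user-set mean, marginal SD and
lag-1 coefficient. EADs are injected at a uniformly random phase within
the 40–90% repolarization window as a raised-cosine depolarizing hump
during which repolarization pauses; the net rise therefore equals the
requested amplitude exactly, and the beat's effective APD90 (recorded in
the ground truth) is extended by the hump width (40 ms default). Resting
and peak potentials are conventional textbook values, not claims about any
dataset. The ground-truth APD arithmetic assumes the hump does not
re-cross the tracked repolarization thresholds, which holds for hump
amplitudes below ~20% of the AP amplitude.

**Ca²⁺ / sarcomere / force transients.** The cycle shape is
`(1 − e^(−t/τ_rise))·e^(−t/τ_decay)`, rescaled to unit peak and multiplied
by the requested amplitude, then linearly detrended within each pacing
cycle so the signal returns exactly to baseline at the next stimulus (the
residual it removes is ≤ ~4% of peak at the default time constants).
Assay defaults emulate the study conditions: Ca²⁺ at 20 Hz imaging, 10 s
of 1 Hz pacing, baseline 100 AU and ΔF/F₀ = 0.5 (τ 100/200 ms); sarcomere
length at 240 Hz video, resting length 1.80 µm, 5% shortening
(τ 50/120 ms); trabecula force at 10 kHz, ~1 g resting tension, 0.8 g
cycles (τ 60/150 ms). Secondary events (EAD-like Ca²⁺ events,
aftercontractions) are smaller copies of the cycle shape injected after
~90% relaxation of the primary — later than the 70% the detector requires,
so the measured event amplitude is not eroded by the still-decaying
primary — and always end before the next stimulus. Failures replace a
cycle with flat baseline. Premature force cycles couple 300–450 ms before
their stimulus and replace the stimulus-evoked cycle (refractoriness);
automatic cycles arrive as a Poisson process placed 300–450 ms after a
stimulus (mid-diastole). Rates that cannot fit a cycle between beats are
refused.

**Ramp current.** `I(V) = ḡ·s·a(V−Δ)·i(V−Δ)·(V−E_rev)` with Boltzmann
activation (V½ −2.5 mV, slope 6 mV) and inactivation (V½ 0 mV, slope
12 mV) gates, ḡ = 70 nS, E_rev = +40 mV, plus white noise. These defaults
put the inward peak of the binned I–V at 0 mV and its density at
~8.4 pA/pF for a 100 pF cell, inside the 6.5–9.3 pA/pF range the analysis
is calibrated against. The enhancer scale multiplies the conductance; the
shift moves both gates along the voltage axis (a −15 mV gate shift moves
the measured I–V peak by about −13 to −15 mV, the difference coming from
the voltage-dependent driving force).

What the generators do **not** emulate: stimulus artifacts, upstroke
velocity and its pharmacology, motion artifacts in imaging, photobleaching
and dye-loading gradients, Ca²⁺ alternans and waves, mechanical latency
between stimulus and contraction onset, run-down, and any biophysical
channel gating. Tests passing on synthetic data therefore validate the
*analysis arithmetic and detector logic*, not robustness to every
real-world artifact.

## Biomarker conventions

Repolarization fractions are referenced to (peak − pre-stimulus baseline),
the conventional APD definition. Threshold crossings are linearly
interpolated; the first crossing after the peak wins. A level never
reached before the next stimulus yields an *absent* APD; absent beats are
excluded from STV (the formula needs finite values) and counted separately
as incomplete-repolarization beats. STV uses the most recent
`window_s·pacing_hz` beats (20 at 1 Hz) and divides by the number of beats
used, exactly as the formula is printed.

The EAD detector smooths with a 5 ms moving average (so white noise cannot
fake a 5 mV net rise), then reports each local minimum between the 20% and
90% crossings that is followed by a rise ≥ 5 mV lasting ≥ 10 ms before the
voltage falls back below the minimum. The 5 mV / 10 ms defaults are
exposed; they correspond to 5× a 1 mV noise floor, and at 2× threshold
amplitude the detector's measured sensitivity is 100% with zero false
positives on seeded noisy sets.

Secondary-event detection for transients operationalizes "a change in
slope before the next stimulus" as an amplitude criterion: after recovery
passes 70% of the primary excursion, any new excursion in the primary
direction ≥ 10% of the primary amplitude counts. This is noise-robust
where a raw derivative-sign rule is not; both thresholds are exposed.
Contraction failure is an excursion below 10% of the reference (vehicle
median) amplitude, measured on a 15 ms-smoothed trace so a single extreme
noise sample cannot promote a flat segment above threshold. Failures are
excluded from amplitude averaging but kept in incidence denominators.
Incidence is reported both per transient (events in the last 100) and per
cell (cells with ≥ 1 event over total cells), since both conventions are
in use.

The five-phase transient fit places boundaries at the 10% excursion
departure, the 90% rising crossing, the 90% falling crossing and the 10%
recovery crossing; default polynomial degrees are (1, 3, 4, 3, 3)
(baseline, contraction, peak region, relaxation, return-to-baseline).
Each phase is fitted only to samples strictly inside its boundaries, so
the flat-baseline fit is not polluted by the first rising sample. The
quartic peak region and cubic tail keep per-phase RMSE below 0.5% of the
amplitude on noiseless transients; a non-monotone landmark sequence (e.g.
a failure) returns an explicit "unfittable" marker.

Sarcomere length is the reciprocal of the dominant spatial frequency in a
1.2–2.4 µm band of the Hann-windowed, 8×-zero-padded magnitude spectrum,
with quadratic interpolation around the peak bin; if no in-band peak of
the unpadded spectrum exceeds 3× the spectral median the function returns
a "no striation" finding instead of a number. Accuracy on 256-pixel
profiles at 0.1 µm/pixel is ≤ 0.005% noiseless and ≤ 0.2% at 20% noise.

## Force-cycle analysis

Cycles are prominence-detected peaks on a 5 ms-smoothed trace; each
cycle's baseline is the minimum between the previous cycle's peak and its
own (never reaching back past the previous peak), which makes amplitudes
immune to slow resting-tension drift (tested at 0.1 g/min) and correct for
cycles riding on an incompletely relaxed predecessor. Onset is where the
smoothed trace last sat within 5% of the cycle amplitude above baseline.
Classification: stimulus-locked within ±50 ms of a stimulus; otherwise
premature if the onset falls within 500 ms before the next stimulus;
otherwise spontaneous. The premature window is a configuration choice —
extrasystoles in the synthetic data couple 300–450 ms before their
stimulus, so any window ≥ 450 ms classifies them correctly; no claim is
made about measured coupling intervals in real tissue. Sub-threshold
candidate peaks (< 50% of the running median amplitude) that follow ≥ 70%
relaxation of a stimulus-locked cycle are folded into that cycle as
aftercontractions rather than counted as cycles, so every independent
cycle carries exactly one of the three labels. Spontaneous-cycle rate is
reported in cycles/min; no pathological cutoff is imposed.

Analysis windows follow the study design: `pre_first_event` takes the 30
cycles immediately preceding the first aftercontraction-bearing cycle
(refused, with the available count, if fewer precede it; falls back to
`end_of_record` with an explicit finding when no event exists);
`end_of_record` takes the final 30.

## Concentration–effect fitting

The Hill model is fitted in log₁₀-concentration space. The deterministic
multi-start grid (20 EC50 starts across the data's log range × Hill
coefficients {0.5, 1, 2, 4}) is screened by profiled linear least squares
— floor and ceiling are linear given the occupancy — and the three best
starts are refined by bounded nonlinear least squares. This is exactly as
reproducible as refining every start and ~100× faster; noiseless
self-consistency is ~10⁻¹⁶ relative, and fitting in log-concentration
makes EC50 scale exactly with a rescaling of the concentration axis.

Two readings of "EC50" are supported: the half-maximal-effect
concentration (the fit's `ec50_um`, the standard Hill midpoint) and the
concentration at which the fitted curve reaches a stated response level
(`concentration_at_response`), covering the "concentration inducing a
50-point increase" reading. Both are emitted by the CE analysis script.

`fit_hill` optionally fixes the Hill coefficient and/or the floor. When
responses are percent changes relative to each cell's own vehicle
baseline, the response at zero concentration is 0 *by construction*, so
anchoring `floor = 0` is the statistically honest model rather than a
convenience. The noisy-recovery simulation reflects the assay design:
each concentration's datapoint is the mean over 6 cells with per-cell
noise of 5% of the ceiling; with the anchored fixed-slope fit the median
relative EC50 error over 200 replicates is ~7%. A free-floor or
free-slope fit on single-replicate 4-point data is near the information
limit and cannot do better than ~16–30% — a property of the design, not
of the optimizer.

## Statistics and reporting

Two conditions: Student's t-test (paired or unpaired); three or more:
one-way ANOVA plus pairwise t contrasts with Bonferroni adjustment
(`p_adj = min(1, m·p)`), significance at α = 0.05. The post-hoc is
implemented and labeled as Bonferroni-adjusted pairwise comparisons.
Identical paired vectors are reported as t = 0, p = 1 (zero-variance
differences mean no effect by definition). The pipeline driver derives
per-cell seeds deterministically from the base seed, so a rerun of the
same configuration is byte-identical; reports are a single sorted-key JSON
plus per-assay CSVs, and no figures are produced by the core.

## Problem sizes

The validation suite uses 100 × 20-beat AP trains for the closed loop,
500-transient sets for detector operating characteristics, 200 replicates
for the noisy EC50 study, and 6 cells × 3 conditions for the demo
pipeline; the full test suite runs in under a minute and the acceptance
script in a few seconds.

## Known limitations

* Detector thresholds were chosen against the synthetic noise models;
  real recordings with drifting baselines or artifacts will need the
  exposed thresholds revisited.
* The ramp I–V assumes traces are already series-resistance compensated
  and makes no leak subtraction; whether reported densities in comparable
  experiments are leak-subtracted is generally unstated, and the module
  documents that it assumes not.
* Ca²⁺ baselines come from only the 2 pre-stimulus frames available at
  20 Hz, so residual decay from the previous transient biases ΔF/F₀
  slightly low (≈ −0.01 at default kinetics).
* Whether an EAD that triggers a full re-excitation should count as an
  EAD or a separate beat is ambiguous; the detector counts net
  depolarizations within one stimulus window, and abortive re-excitations
  large enough to cross the stimulus boundary would be segmented as beats.
* `apply_drug_effect` scales one named parameter and the event
  probabilities; combination pharmacology beyond that (e.g. kinetics
  changes) must be expressed directly in generator parameters.
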