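# cardiomarker

Quantitative analysis stack for in-vitro cardiac safety-pharmacology
recordings from adult human cardiomyocytes and trabeculae: stimulus-locked
biomarker extraction (APD20/50/90, STV(APD90), ΔF/F₀, sarcomere shortening,
force amplitude), arrhythmia-event detection and incidence (early
afterdepolarizations, EAD-like Ca²⁺ events, aftercontractions, contraction
failures, premature contractions, enhanced automaticity), late-INa
voltage-ramp I–V analysis, and Hill EC50 concentration–effect fitting.
It is aimed at electrophysiology / contractility labs that pace cells at
1 Hz and need reproducible, scriptable versions of the analyses usually
done in vendor software — plus a synthetic-trace generator with auditable
ground truth, so every detector and estimator can be validated end to end
without any experimental download.

## The quantities it computes

* **APD_p** — time from the upstroke crossing of `V_peak − p·(V_peak −
  V_baseline)` to the first downward crossing after the peak, linearly
  interpolated (p = 0.2, 0.5, 0.9 by default).
* **STV(APD90)** — short-term variability from Poincaré plots over 20 s of
  beats: `STV = Σ|APDₙ₊₁ − APDₙ| / (n_beats·√2)`.
* **EAD** — a net depolarization ≥ 5 mV sustained ≥ 10 ms between the 20%
  and 90% repolarization crossings (phase 2/3).
* **Ramp I–V** — for the CiPA-style command waveform (−80 mV hold →
  −95 mV/200 ms → −20 mV/50 ms → +40 mV/200 ms → 100 ms ramp from +40 to
  −95 mV), ramp-segment current mapped to voltage by the affine ramp law,
  averaged in 1 mV bins and normalized to cell capacitance (pA/pF); the
  inward peak is the signed minimum.
* **ΔF/F₀** and **% sarcomere shortening** — transient amplitudes relative
  to the pre-stimulus baseline; sarcomere length itself estimated from the
  striation intensity profile by FFT with quadratic peak interpolation.
* **Aftercontraction / EAD-like Ca²⁺ event** — a secondary excursion
  ≥ 10% of the primary amplitude after ≥ 70% relaxation, before the next
  stimulus. **Contraction failure** — excursion below 10% of the reference
  amplitude. Incidences are events per 100 transients/cycles, or cells
  with events per total cells.
* **Hill fit** — `r(c) = floor + (ceiling − floor)·cʰ/(cʰ + EC50ʰ)`,
  nonlinear least squares in log₁₀-concentration from a deterministic
  multi-start grid; EC50 is the half-maximal-effect concentration, and the
  fitted curve can be inverted for any response level.

## Worked example

The numbered scripts under `analysis/` run a three-arm demo study
(vehicle → late-INa-enhancer-like challenge → challenge + inhibitor) on
synthetic recordings and write tables under `results/`:

```bash
python analysis/01_simulate_recordings.py   # archive traces (scratch/)
python analysis/02_ap_biomarkers.py         # APD / STV / EAD table
python analysis/03_late_ina_iv.py           # ramp I-V per condition
python analysis/04_contractility_ce.py      # 4-point C-E curve + EC50
python analysis/05_force_trabecula.py       # trabecula windows + incidence
python analysis/06_full_report.py           # end-to-end pipeline report
```

`06_full_report.py` prints, among others:

```
[ap] metric = apd90_ms
  vehicle: 298 +/- 0.24, +0.0% vs vehicle
  challenge: 421 +/- 2.4, +41.2% vs vehicle
  challenge_plus_inhibitor: 309 +/- 0.37, +3.4% vs vehicle
```

i.e. the challenge prolongs mean APD90 by ~41% and the inhibitor restores
it to within ~3% of vehicle; the same report contains the raised
STV(APD90), per-cell EAD incidence, the ~3× increase in peak late-INa
density with its leftward I–V shift, and the contractility changes.
`04_contractility_ce.py` recovers the generator's EC50:

```
EC50 (half-maximal, h=1, floor=0): 0.0120 uM (generator: 0.012 uM)
```

The same functionality is exposed as a CLI (`cardiomarker synth|validate|
analyze-ap|analyze-iv|analyze-ca|analyze-contraction|analyze-force|
fit-ce|run`) for use on recordings stored in the package's CSV + JSON
sidecar trace format (see `cardiomarker.trace_io`).

## Layout

```
src/cardiomarker/    library: trace_io, synthetic, late_ina, ap_biomarkers,
                     transient_biomarkers, force_biomarkers, pharmacology,
                     reporting, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py
docs/methods.md      models, assumptions, parameter choices, limitations
```
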