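# Methods

## Problem and model

Real-time tumor-tracking radiotherapy of lung lesions steers the beam with a
correlation model that maps external LED surrogate motion to the internal
tumor position, refreshed by sparse stereo X-ray imaging, and a prediction
model that forecasts the position ~115 ms ahead to compensate robot latency.
Setup error is largely removed by image guidance; what remains for the
CTV-to-PTV margin is a chain of five intrafraction error sources, treated as
independent and summarized per patient *j* and axis *i* (S-I, L-R, A-P):

1. **Segmentation** — registration of the tracked centroid between
   reference projections and live X-ray images. Not observable in treatment
   logs; assigned from phantom measurements as 0.38 ± 0.54 mm on every axis,
   so Σ_S = 0.54 mm and U_S = 0.38 + 2·0.54 = 1.46 mm.
2. **Deformation** — motion of arbitrary CTV points relative to the tracked
   centroid. Assigned by rule: (Σ_D, U_D) = (0.75, 1.5) mm when the centroid
   motion range is ≤ 2 cm or the centroid stays inside the CTV, else
   (1.25, 2.5) mm.
3. **Correlation** — at each imaging time T_i, the error is the imaged
   position minus the correlation-model position, e_i = X_i − x(T_i), with
   x(·) linearly interpolated from the 26 Hz trace.
4. **Prediction** — for each predictor sample at time t, the error is the
   correlation-model position at t + 115 ms minus the predictor output.
5. **Targeting** — machine delivery accuracy from end-to-end phantom tests,
   summarized per axis by its mean and SD.

Each measured source is summarized two ways:

* **Expanded uncertainty** U = |μ| + 2σ, where μ is the signed mean and σ
  the sample SD (n − 1) of the error distribution pooled over all of the
  patient's fractions. μ is the absolute value of the signed mean, not the
  mean of absolute errors (a `mean_abs` flag provides the alternative
  reading); the pooled near-zero prediction means make this the consistent
  convention.
* **Systematic/random split** over fractions f = 1…N_f:
  σ_f is the within-fraction sample SD, σ = √(Σ_f σ_f² / N_f) (RMS, N_f
  divisor), and Σ = √(Σ_f ⟨e⟩_f² / (N_f − 1)) — the RMS of the per-fraction
  mean shifts about zero with an N_f − 1 divisor, implemented literally
  (a grand-mean-centred variant is available behind `center_grand_mean`).

Two margin recipes combine the budget per axis:

* **van Herk**: M = 2.5·√(Σ_S² + Σ_D² + Σ_C² + Σ_P² + Σ_T²)
  + β·(√(σ_C² + σ_P² + σ_p²) − σ_p), with penumbra width σ_p = 6.4 mm and
  β = 0.84 (80% prescription isodose in lung). M = 0 when every component
  is 0 because the penumbra term cancels.
* **Expanded-uncertainty budget (k = 2)**: each step's U is halved to a
  standard uncertainty, combined in quadrature and re-expanded, which
  reduces to U_combined = √(U_S² + U_D² + U_C² + U_P² + U_T²).

**Coverage** of a global margin is the percentage of patients whose
individual van Herk M fits inside it (M ≤ threshold). Coverage is evaluated
on M only — not on U or max(M, U) — because that convention reproduces all
of the reference cohort's population statements simultaneously.

## Numerical and design choices

* **Interpolation** of the 26 Hz trace is linear in time for both the
  imaging-time and horizon-shifted lookups; at < 40 ms gaps higher-order
  schemes are immaterial.
* **Gating**: all statistics use only samples coincident with beam-on
  intervals. Gating is idempotent; a fraction left with < 2 imaging samples
  is excluded with a warning.
* **Horizon pairing across gaps**: after gating, the modeler trace has no
  samples inside beam-off blocks. A predictor sample whose t + 115 ms lookup
  would interpolate across a gap wider than 3× the median sampling step is
  dropped rather than bridged — interpolating across a gap would fabricate
  the reference position. Boundary samples at the stream end are likewise
  dropped, never extrapolated.
* **Sign conventions**: correlation error is imaging minus modeler;
  prediction error is horizon-shifted modeler minus predictor. All margin
  inputs are SDs or absolute means, so signs only affect plots.
* **Percentiles**: the 1–99% motion range uses linear interpolation between
  order statistics (numpy default).
* **Rounding**: margins are reported at 0.1 mm. Comparisons against the
  bundled reference tables use ±0.1 mm tolerance because the reference
  inputs are themselves rounded to 0.1 mm; one reference patient's S-I
  margin recomputes to 4.5 mm vs the tabulated 4.6 mm, consistent with
  input rounding.
* **Degenerate σ_P**: prediction errors are orders of magnitude below
  correlation errors; values pass through as computed, with no flooring.
* **Frames and dialects**: vendor log formats are proprietary, so the
  package defines open CSV dialects (`time_s,si_mm,lr_mm,ap_mm`; beam file
  `start_s,end_s`). A robot→patient rotation matrix is accepted as config
  (validated orthonormal to 1e-9) and defaults to identity, since synthetic
  logs are written directly in the patient frame.
* **t-test**: subgroup comparisons default to the pooled-variance Student
  form; Welch is a flag. No multiple-testing correction is applied.
* **Patient-level motion range** for the uncertainty correlations is the
  mean of the patient's per-fraction ranges (max or pooled would also be
  defensible; the choice is configurable by building the table directly).

## Synthetic-data generator

The generator emulates the study conditions of a ~22-patient, 3–5
fractions/patient lung-tracking cohort; its defaults are fixed, not tuning
knobs:

* breathing period 4 s with 5% cycle-to-cycle period jitter (quasi-periodic
  breathing); per axis, position(t) = drift·t + A·(cos^{2p}(πφ(t)) − ½) with
  p = 1 by default. The waveform is scaled so its peak-to-peak excursion
  equals the configured amplitude A; p > 1 sharpens the inhale peak.
* per-axis peak-to-peak amplitudes (9.0, 8.5, 4.8) mm S-I/L-R/A-P, drawn
  per patient with between-patient SDs (7.3, 5.6, 3.5) mm truncated at
  0.5 mm; baseline drift (0.3, 0.1, 0.1) mm/min.
* correlation model = truth + per-fraction systematic offset + N(0, σ)
  noise, σ = (1.1, 0.8, 1.0) mm; the offset is redrawn each fraction from
  N(0, (0.3, 0.2, 0.2) mm) so the systematic component Σ_C is a recoverable
  quantity. Predictor = correlation model at t + 115 ms + N(0,
  (0.12, 0.12, 0.08) mm).
* imaging every 40 s (exactly on the 26 Hz grid, so injected residuals are
  recoverable sample-for-sample); fraction length 1720 s (~29 min, 43
  image pairs, within the typical 30–50); beam-on in 60 s on / 10 s off
  blocks (≥ 50% duty).
* by default the per-patient residual SDs scale with relative amplitude
  (`noise_amplitude_coupling = 0.5`), emulating the observed association
  between motion range and tracking-error dispersion; set 0 to decouple.
* all randomness flows from one seed through spawned per-patient and
  per-fraction substreams, so identical configurations re-serialize
  byte-identically.

What the generator does **not** emulate: non-Gaussian and heteroscedastic
residuals, correlation-model refresh transients after each imaging update,
baseline shifts at imaging updates, cardiac motion, hysteresis between
inhale and exhale paths, and imaging segmentation failures. Tests passing
on synthetic cohorts therefore validate the *estimators* (error series,
decomposition, margin algebra, coverage, associations) under a known truth;
they do not certify clinical error magnitudes, which enter only through the
bundled reference tables.

## Problem sizes used in tests and the acceptance script

Reference-cohort computations use the full bundled 22-patient tables.
Simulation checks use deliberately compact cohorts — e.g. 6 patients ×
3–5 fractions × 900 s for noise recovery (≈ 500 imaging residuals,
≈ 4.7·10⁵ prediction residuals), 22 patients × 600 s for the
fraction-level association check, and 200 replicate patients for the
systematic-recovery Monte Carlo — sizes at which the 3-standard-error
recovery criteria are already sharp.

## Known limitations

* Segmentation and deformation budgets are assigned constants/rules, not
  measured from logs; the package cannot detect their misestimation.
* Eq-level ambiguity in whether the pooled-sample SD or the RMS-of-fraction
  SDs feeds the margin's random term is resolved in favour of the
  fraction-wise RMS; both are exposed.
* The open CSV dialects are not parsers for vendor binary/text logs;
  clinical use requires an export step.
* Coverage treats each patient's margin as exact; no uncertainty on M
  itself is propagated.
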