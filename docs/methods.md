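# Methods

## Signal model

A screw–bone system excited by a laser pulse is modeled as a superposition of
damped harmonic modes. After a trigger at `t_k`, mode *i* contributes

    v_i(t) = A_i · exp(−ζ_i ω_i (t − t_k)) · sin(ω_{d,i} (t − t_k)),

with natural angular frequency `ω_i = 2π f_i`, damping ratio `0 < ζ_i < 1`,
damped frequency `f_{d,i} = f_i √(1 − ζ_i²)`, and amplitude `A_i ≥ 0` in
velocity units. Every pulse re-excites all modes; earlier pulses keep ringing
down (at the default ζ = 0.01 a mode decays by e⁻⁶⁰ within one 100 ms pulse
period, so pulse-to-pulse carry-over is negligible but is simulated anyway —
the noiseless signal stays exactly linear in the amplitudes).

Acquisition defaults follow the measurement protocol: a 10 Hz pulse train,
16 pulses, 1.6 s record. The sampling rate is a free choice of this package
(no instrument value is available): **50 kHz**, ten times the top of the
1000–5000 Hz search band, so the band sits far from Nyquist and each 2500 Hz
cycle has 20 samples. Rates at or below twice the highest mode frequency are
rejected.

Noise has two parts:

* stationary white Gaussian noise, `broadband_sd` (velocity units, default 0
  for the bare simulator; 0.02 in the end-to-end run configuration, which
  gives ≥ 10 dB post-average SNR for unit-amplitude modes anywhere in the
  band);
* an **ablation transient**: white noise confined to
  `[t_k, t_k + ablation_transient_duration]` after each pulse (default 4.5 ms
  or less, i.e. inside the purge window) with standard deviation
  `ablation_transient_gain × ΣA_i` (dimensionless gain scaled to the signal;
  if all amplitudes are zero the gain is used as an absolute SD). This is a
  stand-in for the plume/plasma disturbance, not a physical plasma model.

## Fixation-force law and cohorts

The simulator links resonance frequency to fixation force through

    RF(F) = c0 + c1·ln F,   clamped to rf_clamp,

defaults `c0 = 4000 Hz`, `c1 = 400 Hz per ln(Nm)`, clamp 1000–5000 Hz. The
logarithmic form encodes the two-regime behavior of screw fixation (fast RF
rise where friction dominates at low force, slow rise where axial force
dominates) with a single smooth curve; a linear relation can be emulated by
fitting over a narrow force range, and the validation module always fits both
forms rather than assuming either.

Cohorts default to **30 specimens in six groups of five**, mimicking a
polyurethane-foam test-block series (five solid densities 0.08–0.48 g/cm³
plus one cellular foam). Group torque means scale with density
(`6 Nm·cm³/g × density`, cellular foam derated ×0.6, SD 10% of the mean) —
chosen once as realistic pedicle-screw insertion torques (≈0.3–3 Nm).
Derived measures per specimen:

* RF: `RF(torque) + N(0, rf_noise_sd)`, default SD 80 Hz;
* ISQ: inverse affine map of the noisy RF plus `N(0, isq_noise_sd)`,
  default SD 1.5 ISQ units, clipped to [0, 100];
* POF: `600 N/Nm × torque + N(0, 30 N)`. The proportional law (zero
  intercept) keeps ln POF an affine function of ln torque, so a noiseless
  cohort is *exactly* log-linear in every force pair — the property the
  statistical-recovery tests rely on.

Randomness: one root seed; specimen *i* consumes substream
`SeedSequence(seed, spawn_key=(i,))`, so enlarging a cohort never changes the
draws of earlier specimens.

What the generator does **not** emulate: multimodal spectra of real
screw–bone constructs, frequency-dependent vibrometer sensitivity, speckle
dropouts, mains hum, non-Gaussian plasma noise, inhomogeneous or anisotropic
bone, and any coupling between insertion torque and damping. Passing tests
demonstrate that the chain recovers what this model produces, not that the
model matches any particular instrument.

## Measurement chain

Stage order is **segment → average → purge → FFT → detect**. For
trigger-aligned segments purging and averaging are both linear, time-indexed
operations and commute exactly (tested), so the order is not a degree of
freedom that affects results.

* **Segmentation**: a trigger maps to the nearest sample at or after its
  time; segments are half-open `[trigger, trigger + segment_length)` in
  samples (default 100 ms = one pulse period). Triggers without a full
  window are dropped with a warning; zero usable triggers is an error.
* **Averaging**: pointwise mean. Segments are stacked so the reduction runs
  along the fast memory axis, where numpy applies pairwise summation — the
  mean of 2^k identical segments is then bit-exact.
* **Purge**: the first 4.5 ms after the trigger are discarded and
  [4.5 ms, 100 ms] analyzed — the reading under which the purge removes the
  ablation transient. At 50 kHz this keeps 4775 of 5000 samples.
* **Spectrum**: magnitude FFT under a rectangular window, no zero-padding by
  default (an option pads to a power of two and updates the resolution
  metadata). The segment mean is subtracted first (configurable) so DC
  leakage cannot creep toward the 1000 Hz band edge; an argmax is invariant
  to any monotone transform of magnitudes, so reporting amplitude rather
  than power changes nothing downstream.
* **Detection**: argmax of magnitude on the closed band [1000, 5000] Hz;
  ties break to the lowest frequency (the ascending-grid argmax, hence
  deterministic). Out-of-band maxima are ignored. The frequency resolution
  is `sampling_rate / transform_length` ≈ 10.47 Hz at the defaults.

An all-zero (or constant) averaged record is rejected with a "no signal"
diagnostic rather than returning the band edge.

## ISQ map and strength classes

The ISQ↔RF map is affine through the anchors 3000 Hz ↔ ISQ 0 and 8000 Hz ↔
ISQ 100 (both configurable; the published anchors are approximate and the
true proprietary map need not be affine, but two anchors support nothing
richer). RF → ISQ clamps out-of-range inputs to 0 or 100 with a warning
instead of failing: poorly fixed screws genuinely resonate below the ISQ-0
anchor. Correlation strength: |R| < 0.3 weak, 0.3–0.7 moderate (boundaries
inclusive, following the interval notation), > 0.7 strong.

## Validation statistics

Both approximations are ordinary least squares; the logarithmic fit is the
linear fit on `(ln x, y)`, so its R is the Pearson correlation of the
transformed predictor (identical to √R² of the fitted curve for a simple
regression). Natural log is used — the base affects only the slope. The
p-value is the standard two-sided t-test on `t = R√((n−2)/(1−R²))` with
n − 2 df (verified against quadrature of the t density in the tests).
Conventions:

* model preference = larger |R|; exact ties go to linear (parsimony);
* in a measure pair the predictor is the later measure in the canonical
  order (RF, ISQ, torque, POF), so the log transform lands on the mechanical
  force, and the log model is silently skipped for a pair whose predictor
  has non-positive values (e.g. a clamped ISQ of 0);
* missing data: pairwise complete cases per cell; a cell with < 3 pairs or a
  constant measure is reported unavailable, never fabricated;
* significance tiers .05/.01/.001, `n.s.` above .05; no multiple-testing
  correction (six cells, descriptive use);
* complete pairs are sorted lexicographically before fitting, making every
  fit — and therefore the correlation table — bit-identical under specimen
  permutations.

No confidence intervals for R and no regression diagnostics beyond the fits
are produced, and there is no per-group modeling.

## End-to-end runs

`run_end_to_end` draws a ground-truth cohort, simulates one vibrometer record
per specimen with a single mode at that specimen's RF, runs the measurement
chain, and derives ISQ from the **detected** RF through the inverse map — so
with all noise off the RF–ISQ correlation is exactly 1 even though detected
RFs are quantized to the frequency grid. Per-specimen analysis failures are
logged and skipped; a run fails only if every specimen does. All artifacts
(config copy, cohort CSV, matrix CSV/JSON, pair plots, report JSON) are
regenerable bit-identically from the config and seed on one platform.

## Problem sizes and I/O precision

The test suite uses 30-specimen cohorts, 1.6 s × 50 kHz records, 50 seeded
recovery simulations across 1500–4500 Hz, 100-replicate Monte-Carlo checks of
the σ²/N averaging law and model preference, and 200+ replicates for the
noise-degrades-correlation trend — sizes at which every statistical check is
stable under the fixed seeds. WAV records are stored as float32 (the only
loss in that round trip); CSV records and cohort tables are written with
17 significant digits and parsed with pandas' round-trip float precision, so
they round-trip float64 exactly.

## Known limitations

* Single-mode records in the end-to-end run: real constructs show several
  modes, and mode-tracking across specimens is out of scope.
* The detected RF is grid-quantized; sub-bin interpolation is deliberately
  not applied because the downstream index uses the peak bin directly.
* The ISQ map is a two-point affine stand-in for a proprietary device scale.
* The fixation law's coefficients are package defaults, not calibrated
  against any physical dataset; only the *structure* (log in force, affine
  in ISQ) carries over to interpretation of real measurements.
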