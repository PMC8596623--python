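# laser-rfa

Resonance frequency analysis (RFA) of pedicle-screw fixation from laser
Doppler vibrometry, as a tested, reusable Python pipeline.

## The problem

Pedicle-screw loosening is a major failure mode of spinal instrumentation,
and there is no established intraoperative way to quantify how firmly a screw
is fixed. One non-contact approach excites the screw with a pulsed laser
(ablation recoil acts as a massless hammer tap) and records the induced
vibration with a laser Doppler vibrometer. The screw–bone system rings at a
resonance frequency (RF) that rises with fixation force, so the RF can serve
as a stability index — analogous to the dental implant stability quotient
(ISQ), whose magnetic-RFA scale is anchored at roughly 3000 Hz (ISQ 0) and
8000 Hz (ISQ 100).

This package implements the complete measurement and validation chain:

1. **Signal simulation** (`signal_model`) — impulse-excited, exponentially
   damped multimode screw vibration under a 10 Hz pulse train (16 pulses,
   1.6 s record), with an early broadband ablation transient and additive
   noise; plus cohorts of synthetic specimens whose RF follows a logarithmic
   law in fixation force.
2. **RF extraction** (`pipeline`) — trigger-synchronized segmentation,
   time-synchronous averaging, purge of the first 4.5 ms after each pulse,
   rectangular-window FFT, and peak detection restricted to 1000–5000 Hz:

   `RF = argmax_{f in [1000, 5000] Hz} |X(f)|` of the averaged, purged record.
3. **Stability index** (`stability`) — the affine ISQ↔RF map
   `RF(ISQ) = 3000 + 50·ISQ` Hz and the weak/moderate/strong correlation
   classes at |R| = 0.3 and 0.7.
4. **Validation statistics** (`validation`) — paired best-fit approximations
   `y = a + b·x` (linear) and `y = a + b·ln x` (logarithmic) for every pair
   of the four fixation measures (RF, ISQ, peak insertion torque, pull-out
   force), with Pearson R, the two-sided t-test
   `t = R·sqrt((n−2)/(1−R²))`, and a model comparison preferring the larger
   |R|.

## Worked example

```python
import numpy as np
from laser_rfa import (ModalMode, NoiseModel, simulate_record, analyze_record,
                       rf_to_isq, CohortSpec, generate_cohort, CorrelationStudy)

# a single 2500 Hz mode, 16 pulses at 10 Hz, mild noise
record = simulate_record([ModalMode(2500.0, damping_ratio=0.02)],
                         noise=NoiseModel(broadband_sd=0.02), seed=1)
result = analyze_record(record)
print(result.rf, result.resolution)        # 2502.6178010471203 10.471204188481675
```

The detected RF (2502.6 Hz) sits within one frequency-resolution bin
(10.47 Hz = 1 / 95.5 ms of analyzed signal) of the mode's damped frequency
2499.5 Hz.

```python
cohort = generate_cohort(CohortSpec(seed=1))   # 30 specimens, 6 density groups
print(CorrelationStudy(cohort).fit().summary())
```

```
Fixation-measure correlation study
specimens: 30
------------------------------------------------------------------------------
pair                    model                R           p    n  strength
------------------------------------------------------------------------------
rf ~ isq                linear           0.962    2.82e-17   30  strong (p < .001)
rf ~ peak_torque        logarithmic      0.967    3.38e-18   30  strong (p < .001)
rf ~ pullout            logarithmic      0.958     1.1e-16   30  strong (p < .001)
isq ~ peak_torque       logarithmic      0.931    8.67e-14   30  strong (p < .001)
isq ~ pullout           logarithmic      0.930    1.01e-13   30  strong (p < .001)
peak_torque ~ pullout   linear           0.998    5.11e-36   30  strong (p < .001)
------------------------------------------------------------------------------
```

Because the generator's RF law is logarithmic in torque, the logarithmic
approximation wins the RF-vs-force comparisons while RF vs ISQ (an affine
relation) stays linear — the qualitative pattern RFA validation studies look
for. Each R is classified against the 0.3/0.7 breakpoints and marked at the
.05/.01/.001 significance tiers.

The same chain is available from the shell:

```bash
laser-rfa simulate --n 30 --seed 1 --out cohort.csv
laser-rfa validate --cohort cohort.csv --out report/
laser-rfa analyze --input record.wav --purge-ms 4.5 --segment-ms 100 \
                  --band 1000:5000 --out result.json
laser-rfa isq --rf 5500          # -> 50
laser-rfa run --out run/         # end-to-end: simulate records -> RFs -> table
```

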