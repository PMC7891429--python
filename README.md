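# myoperf

Pixelwise myocardial blood flow (MBF) quantification from dynamic
contrast-enhanced (DCE) cardiac MRI, with native-T1-based signal
nonlinearity correction and Fermi-constrained deconvolution — plus the
machinery to study how the *choice* of native T1 values (population vs.
subject-specific, systolic vs. diastolic, global vs. regional) propagates
into the MBF estimates.

Intended for researchers in quantitative cardiac perfusion MRI who want a
tested, scriptable reference implementation of the SR-FLASH signal-model
conversion chain and of the T1-choice experiments, validated end-to-end on
a synthetic phantom with known ground truth.

## Method

A saturation-recovery FLASH series is converted pixel by pixel from signal
intensity to gadolinium concentration through the signal equation

    SI(T1) = c·[(1 − e^(−TD/T1))·a^(n−1) + (1 − e^(−TR/T1))·(1 − a^(n−1))/(1 − a)],
    a = cos α · e^(−TR/T1)

(TR = 2.2 ms, TD = 21.2 ms, α = 12°, n = 31 by default). The scale `c` is
calibrated per pixel from the pre-contrast baseline and the pixel's native
T1; the equation is inverted for T1 at every timepoint (it is strictly
monotone, so a bracketed root search suffices) and T1 maps to concentration
via `1/T1 = 1/T1₀ + r1·[CA]` with r1 = 5.0 L·mmol⁻¹·s⁻¹.

Each myocardial concentration curve, truncated to the first pass (valley
after the arterial-input peak), is then deconvolved against the
blood-pool arterial input function under a Fermi impulse-response model
`h(t) = A(1+e^(−τ/k))/(1+e^((t−τ)/k))`; the fitted `h(0) = A` gives
`MBF = 60·A/1.05` in mL/(min·g). The AIF-to-tissue delay is fitted on a
frame-resolution shift grid. Regional values are pixel means over AHA
sectors (6/12/18/24, nested). See `docs/methods.md` for the full model
description, parameter defaults, and design rationale.

Because no imaging data ships with the method, the package includes a
first-class synthetic phantom (`myoperf.synthetic`): annular myocardium
with regional native-T1 heterogeneity including an elevated-T1 perfusion-
deficit sector, a gamma-variate first-pass input with recirculation, tissue
curves generated at known MBF, and signal formation through the forward
model at a configurable SNR.

## Worked example

```python
import numpy as np
from myoperf import default_cohort_config, generate_phantom, run_variant
from myoperf.regions import build_t1_assignment
from myoperf.experiments import measure_subject_t1

cfg = default_cohort_config()                 # cohort-mean T1/MBF values
ph = generate_phantom(cfg, "diastole")        # noisy phantom, SNR 20

t1 = measure_subject_t1(ph)                   # blood ROI + 25% mid-wall band
print(f"blood T1 = {t1['blood']*1000:.0f} ms, myo T1 = {t1['myocardium']*1000:.0f} ms")

assignment = build_t1_assignment(
    "global_scalar", shape=ph.series.shape, geometry=ph.geometry,
    blood_t1=t1["blood"], myo_t1=t1["myocardium"], phase="diastole")
res = run_variant(ph, assignment)
print(f"global MBF = {res.global_mbf:.3f} mL/(min.g)")
for name, m in zip(("anterior", "anteroseptal", "inferoseptal",
                    "inferior", "inferolateral", "anterolateral"),
                   res.sector_means):
    print(f"  {name:14s} {m:.3f}")
```

prints

```
blood T1 = 1891 ms, myo T1 = 1293 ms
global MBF = 0.529 mL/(min.g)
  anterior       0.569
  anteroseptal   0.553
  inferoseptal   0.569
  inferior       0.361
  inferolateral  0.560
  anterolateral  0.562
```

The measured global myocardial T1 (1293 ms) sits above the 1259 ms
background because the inferior sector carries the elevated-T1 deficit
(sector mean 1425 ms). The inferior sector's reduced flow (truth
0.35 mL/(min·g), background 0.61) is clearly resolved in the sector means;
at baseline SNR 20 the estimates scatter a few percent below the noiseless
values.

A thin CLI wraps the same calls: `myoperf phantom`, `myoperf mbf`,
`myoperf experiment 1..5` (see `--help`).

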