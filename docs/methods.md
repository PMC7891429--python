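# Methods

## Problem

Dynamic contrast-enhanced (DCE) cardiac MRI records the first pass of a
gadolinium bolus through the left ventricle (LV) and the myocardium of a
short-axis slice. Myocardial blood flow (MBF, mL·min⁻¹·g⁻¹) can be
quantified from these series by deconvolving each pixel's contrast-agent
concentration curve against the arterial input function (AIF) measured in
the LV blood pool. The obstacle is that the measured signal intensity (SI)
is a *nonlinear* function of concentration; converting SI to concentration
requires a signal model and the native (pre-contrast) T1 of the tissue the
signal comes from. This package implements that conversion, the
deconvolution, and a set of experiments that quantify how the *choice* of
native T1 values (population-averaged vs. subject-specific, systolic vs.
diastolic, global vs. regional) propagates into pixelwise MBF.

## Signal model

The DCE readout is a saturation-recovery FLASH (SR FLASH) sequence. With
repetition time `TR`, saturation-to-readout delay `TD`, flip angle `α`, and
`n` phase-encoding steps to the k-space center, the signal of a pixel with
relaxation time `T1` is

    SI(T1) = c · [ (1 − e^(−TD/T1)) · a^(n−1)
                  + (1 − e^(−TR/T1)) · (1 − a^(n−1)) / (1 − a) ],
    a      = cos α · e^(−TR/T1)

with `c` a scanner-arbitrary scale proportional to equilibrium
magnetization, assumed constant over the series. Defaults follow the
reference protocol: TR = 2.2 ms, TD = 21.2 ms, α = 12°, n = 31. `TD` is the
delay to the *start* of the FLASH readout; the protocol's TI = 90 ms (delay
to the k-space center) never enters the model, which consumes TD and n.
Contrast concentration follows the fast-exchange relaxivity relation
`1/T1 = 1/T1₀ + r1·[CA]` with r1 = 5.0 L·mmol⁻¹·s⁻¹.

Per pixel the pipeline: (1) estimates the baseline SI as the temporal
median before contrast arrival; (2) calibrates `c` in closed form from the
baseline and the assigned native T1; (3) inverts SI(T1) for T1 at every
timepoint; (4) converts T1 to concentration. The model is strictly
decreasing in T1, so the inversion is a bracketed Brent root search on
(0.005, 5.0) s with absolute tolerance 1e-6 s. Signals outside the
attainable range (noise excursions above the short-T1 asymptote) are
clamped to the bracket edge and flagged rather than aborting the pipeline.
Negative recovered concentrations from baseline noise are retained by
default — clipping would bias the deconvolution residual — with an optional
clip flag. All internal times are seconds; configs accept protocol-sheet
units (ms, degrees) at the boundary. `a` is evaluated literally as
`cos α · e^(−TR/T1)`; slice-profile effects on the effective flip angle are
not modeled, and the saturation pulse is assumed ideal (no B1 or
saturation-efficiency correction).

## Curve processing

The AIF is the spatial mean SI over a blood-pool ROI (an input; no
automatic segmentation). Contrast arrival is the first frame exceeding
`median + 5·SD` of all earlier frames for two consecutive frames — the rule
itself is not prescribed by the source protocol, so the threshold factor is
configurable; a tiny relative floor keeps it meaningful on noiseless data.
The first pass ends at the valley after the AIF maximum; to keep noise
minima from truncating the first pass early, the upturn is searched on a
3-frame moving-median smoothed curve and the returned index is the raw
curve's argmin between peak and upturn. When no recirculation upturn exists
the series end is used, with a warning.

## Fermi-constrained deconvolution

Tracer kinetics give `C_tissue = C_aif * h` (causal convolution). The
impulse response is modeled by a Fermi function

    h(t) = A · (1 + b) / (1 + b·e^(t/k)),   b = e^(−τ/k)

normalized so `h(0) = A` exactly; `A` estimates flow by the central-volume
argument, `MBF = 60·A/ρ` with tissue density ρ = 1.05 g/mL (configurable;
the source reports mL/(min·g) without stating a density, and 1.05 is the
accepted myocardial value). The discrete convolution uses a left-rectangle
rule scaled by the frame interval after linear resampling to a uniform grid
at the median RR interval (ECG-gated frames are near-uniform at rest).

Fitting is bounded least squares over (A, τ, k) with A ∈ [0, 10] s⁻¹,
τ ∈ [0, 30] s, k ∈ [0.1, 60] s, start values A = peak(tissue)/peak-integral
of the AIF, τ = 2 s, k = 5 s. The AIF-to-tissue transit delay is searched
on a grid of {−2 … +3} frames (physiologic delays at rest span a few
frames; a continuous-shift search is not attempted), keeping the shift with
the minimal residual norm. The per-pixel map solver batches all myocardial
pixels through a vectorized projected Levenberg–Marquardt iteration with an
analytic Jacobian — the same objective, bounds and shift grid as the scalar
reference fitter, which the tests cross-check it against. Because the
objective is mildly non-convex, each shift is started both from the
previous shift's solution and from the heuristic start, and non-converged
pixels get three seeded, jittered restarts before being flagged and left
missing (NaN) in the map. Regional MBF is the arithmetic mean over
converged pixels of a region.

## Geometry and T1 assignment

Contours are closed polygons in pixel coordinates (pixel centers at integer
coordinates, 0-based); the myocardial mask is pixels inside the epicardial
and outside the endocardial contour. Regional T1 *measurement* uses a
mid-wall band obtained by offsetting 25% of the local wall thickness from
both contours along centroid rays — robust against partial-volume pixels at
the blood and epicardial interfaces. The offset applies to T1 measurement
only; perfusion uses the full annulus. Sectors are equal angular bins about
the centroid, counterclockwise from a reference angle representing the
anterior RV insertion (default 90°, image "up", since a phantom has no
anatomical landmark); 6 sectors are the mid-ventricular AHA segments and
12/18/24 sectors are constructed hierarchically inside them, so nesting is
exact by construction (including angular ties, which go to the lower
sector). Finer sectors split segments by *angle*; a transmural split is an
alternative reading of "halves/thirds/quarters" but the angular one matches
the sectional T1-value usage.

A `T1Assignment` fixes the conversion variant: `none` (baseline subtraction
only, no nonlinearity correction), `global_scalar`, `sectoral` (6–24 sector
means broadcast to the annulus), `population_average` (cohort-mean
constants), or `pixel_map` (per-pixel native map — the "true" assignment on
phantoms). The AIF is always converted with the blood T1 of its own cardiac
phase.

## Synthetic phantom

No imaging data accompanies the method, so validation runs on a generated
mid-ventricular slice with known truth: a circular blood pool carrying a
gamma-variate first-pass concentration curve `A(t−t₀)^α e^(−(t−t₀)/β)`
(α = 3, β = 2 s, onset 8 s) with a delayed (13 s), scaled (0.18)
recirculation copy, peak-calibrated to 3.72 mmol/L — the measured diastolic
AIF maximum of the reference cohort; an annular myocardium whose sector
tissue curves are the AIF convolved with a Fermi response at known MBF
(background 0.61 mL/(min·g), the cohort's resting global mean; one deficit
sector at 0.35 with τ = 2.5 s, k = 4 s); and native T1 maps per cardiac
phase (diastolic blood 1891 ms, myocardium 1259 ms; systolic 1897/1249 ms).

The deficit's T1 elevation is a smooth raised-cosine angular bump scaled so
the deficit-sector *mean* equals the cohort's 1425 ms, plus a small angular
ripple (15 ms, period π). Smoothness is deliberate: with piecewise-constant
sector T1, sector refinements beyond the truth's granularity would change
nothing and the sectoring experiment would degenerate; a smooth profile
keeps every refinement resolving real structure, as inter-segment
continuity does in vivo. The generator enforces the observed deficit
phenotype (elevated T1 together with reduced flow).

Signals are formed through the forward model only (the pipeline's inversion
is never called by the generator, so round trips are genuine checks), with
per-tissue proton-density-like scales (equal for blood and myocardium by
default) and Gaussian noise on SI at a configured baseline SNR (default 20;
magnitude SNR is high enough that Rician ≈ Gaussian, and a Rician option
exists). One frame per cardiac interval per phase is generated (70 frames,
RR = 1 s); the acquisition's 4–6 frames per interval are not reproduced
since the analysis uses one frame per phase anyway. Systole is emulated by
a thicker wall (smaller endocardial radius) and phase-specific T1 values.
Proton-density calibration frames, motion, coil-sensitivity effects, Gibbs
dark-rim artifacts and T1-mapping (MOLLI) bias are not simulated — scanner-
side corrections and T1-map reconstruction are upstream of this pipeline.
Passing phantom tests therefore demonstrates correctness of the numerical
chain under the stated signal model, not robustness to those acquisition
artifacts.

Default problem sizes — a 64×64 grid (~460 myocardial pixels), 70 frames,
5-point T1 grids, 50 noisy replicates in the recovery check — were chosen
as the smallest sizes at which sector statistics are stable.

## Experiments and statistics

`run_variant` executes the full pipeline under one T1 assignment;
`t1_sweep` maps global MBF over blood/myocardial T1 grids;
`phase_cross_experiment` crosses systolic/diastolic series with matched and
mismatched phase T1 (plus the systolic-AIF-on-diastolic-series swap);
`sectoring_experiment` runs global/6/12/18/24-sector T1 variants and
compares consecutive refinements pixelwise. Paired comparisons are
summarized by Bland–Altman bias, SD of differences, 95% limits of agreement
(bias ± 1.96·SD), Pearson r, and a paired test — a t-test by default with a
Wilcoxon switch that is *never* selected automatically (silent
normality-gated test switching harms reproducibility). Percent differences
are relative to the pair mean (Bland–Altman convention). No
multiple-testing correction is applied. Whether an MBF surface depends
"predominantly" on the blood-minus-myocardium T1 difference is quantified
by projecting the surface onto a cubic polynomial in that difference: the
projection variance is the across-difference part, the residual the
along-iso-difference part.

## Known limitations

- The Fermi amplitude estimates flow only while the bolus stays
  intravascular-dominant; no extraction-fraction or two-compartment
  modeling, no model-independent (SVD/Tikhonov) deconvolution, no stress or
  flow-reserve analysis.
- Pixel-level statistics pool dependent pixels; p-values from pixelwise
  paired tests do not model that dependence and are reported descriptively.
- Radial offset banding assumes star-shaped contours about the centroid
  (true for all practical short-axis segmentations).
- The phantom's noise model is spatially white; structured physiological
  noise (motion residue, breathing drift) is absent.
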