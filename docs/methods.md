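# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `dtiphysio`, and what the synthetic scenario battery does
and does not establish about real data.

## Signal model and ADC inversion

The DW signal along direction `g_i` at weighting `b_i` is
`S_i = S0 exp(-b_i g_i^T D g_i)` with a multiplicative, time-dependent
physiological perturbation `S_i -> S_i (1 + f(t_i, g_i))`.  Taking
logarithms and linearizing `ln(1 + f) ~ f` moves the perturbation into the
ADC domain as an additive term with a 1/b scale, which is why every noise
regressor column is divided by the effective b of its volume.

ADCs are inverted against the arithmetic mean of the low-DW volumes:
`adc_i = ln(S_ref / S_i) / (b_i - b_low)`.  For the default two-shell
scheme (b = 700 / b = 100 s/mm²) this inversion is **exact only when the
reference shell is b = 0** or acquired along the same direction as the DW
volume.  With a b = 100 reference acquired along its own directions the
estimator picks up a direction-dependent bias of order
`(b_low / b_eff)(ADC_i - c)` where `c` is the log-mean reference
attenuation.  Two facts make this acceptable:

* the bias is itself a quadratic form in `g_i`, i.e. it lies in the span of
  the tensor design `X`, so **residuals — and every residual-based model
  comparison — are unaffected**; only the absolute tensor values (MD, and
  FA by a few percent) shift, identically for all six models;
* scenarios whose purpose is to verify the forward-inverse identity or
  exact parameter recovery use a b = 0 reference (`make_scheme(b_low=0)`),
  where the inversion is exact to machine precision.

Voxels with non-positive signal are flagged invalid and excluded from fits
rather than aborting the run.

## Physiological phases and regressors

Cardiac peaks are detected on a 0.5–3 Hz band-passed pulse trace (3rd-order
Butterworth, zero-phase), as local maxima separated by at least 0.33 s with
prominence at least 0.3× the MAD-based robust amplitude, then refined to
the raw-trace maximum within ±0.15 s.  Inter-beat intervals outside
[0.33, 2.0] s are flagged.  The cardiac phase advances linearly from 0 to
2π between consecutive peaks.  The respiratory phase is the
histogram-equalized detrended belt amplitude (100 equal-width bins on |a|),
signed by the 1-s-smoothed amplitude derivative and mapped to [0, 2π):
inhalation occupies [0, π], exhalation (π, 2π).  Phases are **never
extrapolated** outside the recording/beat span — that is a hard error,
because silently extrapolated regressors corrupt the design.

Regressors are sine/cosine Fourier terms of each phase up to the second
harmonic, evaluated at the true acquisition time of every (volume, slice)
pair; the design matrix is therefore assembled and solved per slice.

## The apodization weight

Pulsation-locked dropout is modeled through
`A(g_z) = Θ(|g_z| - q0) exp(-((|g_z| - q0)/σ_A)²)` with `Θ(0) = 1`,
`q0 = 0.5` and `σ_A = 0.5` by default.  The gate-plus-Gaussian form
captures the reconstruction's apodization response to the k-space shift
induced by through-plane tissue motion, which grows with the z-gradient
amplitude; `q0` depends on reconstruction details and is exposed as a
parameter.  The exact functional form and width are design choices of this
package (the structure — a Gaussian times a Heaviside gate acting on
|g_z| — is fixed; the width is configurable).  No cross-terms between
regressors are formed: they would inflate the condition number of the
extended design and destabilize the fit.  The design assembly reports the
condition number and warns (never aborts) above 1e6, naming the most
collinear column pair.

## Robust fitting

Model (vi) is IRLS with a Geman–McClure-type kernel:
`w_i = 1 / (1 + (ε_i / C)²)²` with the non-outlier spread
`C = 3 × 1.4826 × median(|ε|)`, at most 20 iterations, stopping when no
weight moves by more than 1e-4.  The spread is proportional to the median
absolute residual; the proportionality constant places the outlier cut at
three MAD-estimated standard deviations.  The factor 3 matters: the
effective number of directions is the count of residuals inside C, and
only those inlier residuals enter the adjusted error.  A cut at one SD
would keep only ~68% of clean Gaussian residuals and truncate the tail,
biasing the robust model's adjusted rms ~45% low on outlier-free data — a
spurious "noise reduction" that would mask the real behavior of the
model family.  At three SD the clean-data truncation bias is ~1%, while
genuine outliers (50% dropout is ~9 noise SD at SNR 20) still receive
weights below 0.1.  Residuals at machine precision (noiseless, consistent
data) are treated as "no outliers" (all weights 1) via a relative floor on
C.  No slice-wise signal-loss handling is attempted (whole-slice motion
artifacts are out of scope).

## Assessment statistics

* adjusted rms error: `sqrt(Σ ε² / (N − p))` per voxel, with the model's
  nominal total regressor count p; for the robust fit N is the per-voxel
  effective direction count and only inlier residuals enter the sum.
  The dof adjustment makes correction sometimes *increase* the adjusted
  error — that is intended and preserved.
* δrms: ROI mean of the per-voxel adjusted rms, then the relative
  difference to the standard model, as a percentage (negated when
  presented as a "reduction").  Averaging before the ratio is one of two
  defensible readings; the per-voxel-ratio alternative is a one-line
  change in `metrics.delta_rms_percent`.
* δFA: ROI mean of |ΔFA| divided by ROI mean standard-model FA, percent.
* ncFA: zero-lag normalized cross-correlation (no mean removal) of ΔFA
  maps against the robust-fitting reference; `metrics.pearson_fa` exposes
  the mean-centered variant for sensitivity analysis.
* Rician summary: maximum-likelihood (ν, σ) on the raw adjusted-rms
  samples (bin-free; the log-likelihood uses the exponentially scaled
  Bessel `i0e` for stability), mode by bounded 1-D maximization of the
  fitted density.  FA of negative-eigenvalue tensors is computed without
  clipping to preserve difference-map comparability.

## Simulator and scenario battery

The default phantom is a 32×32×12 grid: an anisotropic rod
(diag(1.7, 0.2, 0.2)×10⁻³ mm²/s, FA ≈ 0.870) in an isotropic background
(0.7×10⁻³ mm²/s, FA = 0), S0 = 1000, with the four lowest slices forming
the "basal" slab where dropout acts.  Heart rate is 1 Hz with 0.07 s
interval SD (clipped to [0.7, 1.5] s), breathing ~0.3 Hz with slow
frequency drift, both sampled at 100 Hz starting 10 s before the scan.
Beat times are quantized to the sampling grid so the systolic waveform
peak of every beat falls exactly on a sample — this makes the
detection-phase-regression loop exactly closable and lets tests verify
peak recovery to one sample.  Default perturbation: 5% first-harmonic
cardiac modulation, 2% respiratory modulation, 50% maximal dropout shaped
by A(g_z) inside a systolic phase window [0, π/2), SNR defined as
S0 / (per-channel Gaussian SD) before magnitude formation.  Dropout is
restricted to the strong diffusion gradients (the weak low-DW gradients
are exempt), and a `dropout_apod_width` override provides a
model-misspecification stress variant.

Scenario choices that deserve justification:

* **Recovery scenario (log domain).**  A physical `(1 + f)` modulation is
  not exactly within the linearized model span after the log transform
  (third-order leakage lands on the unrepresented third harmonic), and
  modulation of the low-DW reference shifts the ADC origin in a way no
  noise regressor can absorb.  The exact-recovery scenario therefore
  applies the perturbation as `exp(f)` to the DW volumes only — a
  perturbation exactly within the model span — while all comparison
  scenarios keep the physical signal-domain default.  The residual
  few-percent bias under the physical form at 5% modulation is a genuine
  property of the linearization, shared with any implementation.
* **Gated scenario (cardiac-only, noise-free).**  Gating clusters the
  cardiac phase of each slice across volumes, so the variance available to
  cardiac regressors comes only from heart-rate variability.  Free-running
  respiratory modulation would be captured equally by models (iii) and
  (v), and thermal noise at realistic SNR would swamp the small
  HRV-transmitted cardiac variance (the dof penalty then exceeds the
  explained variance for every extended model).  The gated scenario
  therefore isolates the residual cardiac-locked modulation mechanism:
  cardiac-only 5% modulation, no measurement noise, and a 0.5 s diastolic
  trigger delay that keeps every slice outside the systolic dropout
  window.  It demonstrates the mechanism ordering — linear models ≫
  apodized models ≫ robust — not absolute noise levels.
* **Outlier scenario.**  Full default perturbation at SNR 20 with
  nongated timing; evaluated in the basal ROI over three seeds.

What passing the battery shows: the estimators implement their models
exactly (identity and recovery scenarios), and the qualitative performance
orderings — robust fitting wins when outliers dominate, linear regressors
win when only small modulation remains — emerge from the intended
mechanisms.  What it does not show: absolute reduction percentages on real
brains (real anatomy, motion, eddy currents, steady-state effects and
coil-dependent noise are not simulated), nor performance under
reconstruction pipelines whose apodization differs from the modeled form.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on the assembled design; rank checked by
  SVD at relative tolerance 1e-10 (identically-zero regressor columns —
  e.g. a fully gated-out apodized block — are excluded from the solve and
  their weights reported as 0, so the model degrades gracefully).
* The standard fit is literally the extended fit with an empty Q; the
  reduction property is structural, not numerical.
* Robust IRLS solves batched weighted normal equations per voxel
  (6×6, via einsum); weights are scale-equivariant by construction.
* FA is computed from an eigen-decomposition of the symmetric tensor
  (`numpy.linalg.eigh`), eigenvalues sorted descending; FA of the zero
  tensor is defined as 0.
* All simulation randomness flows through `numpy.random.default_rng`
  seeded from a single integer; datasets are bit-reproducible.

## Known limitations

* No motion/eddy-current correction (assumed done upstream); gradient
  directions are interpreted in the image frame without reorientation.
* The two-shell ADC reference bias discussed above affects absolute MD/FA
  at the few-percent level with a b = 100 reference.
* Peak-detection thresholds are fixed, testable defaults, not a validated
  clinical beat detector; severely arrhythmic traces will need curation.
* Aliasing of cardiac harmonics beyond evaluation at true slice times is
  not modeled; heart-rate-variability and respiration-volume regressors
  from the fMRI literature are out of scope.
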