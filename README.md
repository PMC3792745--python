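# dtiphysio

Retrospective physiological-noise correction for diffusion tensor imaging
(DTI) using peripheral measurements, via an **extended tensor model**.

DTI estimates a per-voxel diffusion tensor **D** from diffusion-weighted
(DW) signals `S_i = S0 exp(-b_i g_i^T D g_i)`.  Cardiac pulsation and
respiration perturb those signals — from small quasi-periodic modulations
up to outright signal loss when brain-tissue motion during the diffusion
gradients shifts the k-space centre — which inflates the tensor-fit error
and biases fractional anisotropy (FA), most severely in the brainstem and
cerebellum.  This package is for diffusion-MRI methodologists who record
pulse-oximeter and breathing-belt traces during the scan and want to
regress that physiology out of the tensor fit instead of discarding or
gating data.

## The model

The standard linear tensor fit solves `adc = X d + ε`, where `adc_i` is the
per-direction apparent diffusion coefficient, `X` the N×6 design built from
the gradient directions, and `d` the six unique tensor elements.  The
extended tensor model augments the design with m physiological noise
regressors `Q` derived from the cardiac phase φ_c (linear between detected
heartbeats) and the respiratory phase φ_r (histogram-equalized belt
amplitude, RETROICOR-style):

    adc = [X | Q] (d, p) + ε_cor

Because the regressors are evaluated at the true acquisition time of each
slice, `Q` (and hence the design) changes slice to slice.  Two regressor
families are provided, mirroring the model family (i)–(vi):

| model | noise regressors                                   | total p |
|-------|-----------------------------------------------------|---------|
| (i)   standard          | —                                 | 6       |
| (ii)  lin_cardiac       | sin/cos φ_c to 2nd harmonic       | 10      |
| (iii) lin_cardiac_resp  | cardiac + respiratory Fourier     | 14      |
| (iv)  nonlin_cardiac    | A(g_z)·(sin φ_c, cos φ_c)         | 8       |
| (v)   nonlin_cardiac_lin_resp | respiratory Fourier + A(g_z)·cardiac | 12 |
| (vi)  robust            | — (outlier down-weighting)        | 6       |

The apodization weight `A(g_z) = Θ(|g_z| − q0) · exp(−((|g_z| − q0)/σ_A)²)`
(default q0 = 0.5) targets the pulsation-locked dropout that affects
high-|g_z| diffusion directions.  The robust comparator (vi) is an IRLS fit
that down-weights directions whose residuals exceed a spread proportional
to the median tensor-fit error.

Models are compared by the degrees-of-freedom-adjusted rms tensor-fit error
`sqrt(Σε² / (N − p))`, its ROI-level percent change δrms, the relative FA
change δFA, the normalized cross-correlation ncFA of FA-difference maps
against the robust reference, and the mode of a Rician fit to the
whole-brain error histogram.

A fully specified simulator generates 66-volume two-shell acquisitions
(60 directions at b = 700 s/mm², 6 low-DW volumes at b = 100 s/mm²) with
nongated (TR 8.5 s) or cardiac-gated (blocks of three slices per cardiac
cycle) slice timing, synthetic pulse/breathing traces, multiplicative
physiological modulation, cardiac-locked basal dropout and Rician noise —
with full ground truth for every component.

## Worked example

```sh
dtiphysio run-all --out demo --seed 1 --snr 30
```

simulates a nongated dataset (5% cardiac + 2% respiratory modulation, 50%
cardiac-locked basal dropout, SNR 30), fits all six models and evaluates
them against the basal ROI, printing:

```
                         label  p_total  rician_mode  delta_rms_brain_pct  delta_rms_roi_pct  delta_fa_pct  ncfa_vs_ref
model
standard                   (i)        6     0.000149                  NaN                NaN           NaN          NaN
lin_cardiac               (ii)       10     0.000112           -10.893441          -6.440671      9.607409     0.391639
lin_cardiac_resp         (iii)       14     0.000107           -12.388366          -6.845235      9.776991     0.058904
nonlin_cardiac            (iv)        8     0.000137           -10.205217         -14.302379      7.178285     0.236768
nonlin_cardiac_lin_resp    (v)       12     0.000135           -11.371327         -14.388273      6.673652     0.025754
robust                    (vi)        6     0.000111           -28.235160         -50.941828     37.428178          NaN
```

Reading the table: `delta_rms_roi_pct` is the change of the adjusted rms
tensor-fit error in the basal ROI relative to the standard model — negative
means noise explained, so robust fitting (vi) removes the most error
(~51%) in this outlier-rich nongated regime, the apodized nonlinear models
(iv)/(v) capture part of the dropout (~14%), and the linear models (ii)/
(iii) only the small modulation (~6%).  `rician_mode` is the mode (in ADC
units, mm²/s) of the Rician fit to the whole-brain error histogram, and
`ncfa_vs_ref` compares each model's FA-difference map with the robust
reference.  On a gated dataset (`--mode gated`) the ordering flips: the
linear models explain the most residual noise.

The library surface mirrors scikit-learn — `TensorLLS` and
`RobustTensorLLS` are estimators with `fit(X, y)` and fitted attributes
(`tensor_`, `noise_weights_`, `residual_`, `weights_`, `n_effective_`) —
so they compose with sklearn tooling; `fit_standard` / `fit_extended` /
`fit_robust` are functional wrappers.

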