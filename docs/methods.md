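# Methods

This note records the models, defaults and numerical choices behind
`fuslink`, and what the synthetic-data tests do and do not demonstrate
about real acquisitions.

## Signal model for simulated ultrafast stacks

The generator adopts the three-subspace decomposition that motivates SVD
clutter filtering of ultrafast Doppler data:

```
frames = tissue + blood + noise
```

- **Tissue** is a sum of `tissue_rank` rank-1 components: a spatially
  smooth complex map (Gaussian-filtered white noise, smoothing scale
  ~1/12 of the field of view) times a slow temporal trace
  `(1 + 0.3 sin(2π f t + φ))·e^{iθ}` with `f` drawn from the 0.02–0.3 Hz
  physiological-drift band. The sum is energy-scaled so that tissue
  carries `tissue_to_blood_energy_ratio` (default 100) times the expected
  blood energy. Tissue is therefore exactly low-rank, spatiotemporally
  coherent and high-energy — the regime in which truncating the leading
  singular components of the Casorati matrix removes it.
- **Blood** is a zero-mean circular complex Gaussian whose instantaneous
  power is `baseline · (1 + Δ(t)/100)`. Doppler frequency content is not
  modelled: power Doppler only uses `|s|²`, so only the second moment
  matters. Every pixel of the default field is perfused (`vessel_mask`
  all true) — at the fUS voxel scale all brain tissue carries capillary
  blood — and only `active_mask` responds to stimulation. A sparse vessel
  mask is still accepted for experiments, but note that pixels with
  near-zero baseline power develop a relatively large stimulus-locked
  power residue through the clutter filter (subspace leakage), which is a
  filtering artifact of a non-physical configuration, not of the GLM.
- **Noise** is i.i.d. circular complex Gaussian with per-sample standard
  deviation `noise_sigma` (default 0.1, i.e. 1 % of blood baseline
  power). Blood and noise, being independent circular Gaussians, are
  drawn as a single sample with summed variances; this is statistically
  identical to separate draws and halves generation cost.

The CBV response Δ(t) rises exponentially to the plateau
`response_amplitude_pct` during stimulation (time constant `rise_tau_s`)
and decays exponentially after offset (`decay_tau_s`), restarting at each
epoch. The closed form gives the ground-truth 10–90 % rise time
`rise_tau_s · ln 9`. Defaults — 15 % plateau, 2 s rise constant, 3 s decay
— are realistic evoked-response values for sensory-stimulation fUS in
anesthetised mice; the plateau amplitude is a free parameter of the
simulation, not a value calibrated against any particular experiment.

## Stimulation protocol

`make_stimulus_protocol(20, 20, 20, 10)` is the canonical block design: a
20 s baseline followed by ten cycles of 20 s whisker stimulation and 20 s
rest, 420 s in total. The boxcar regressor samples the stimulation
indicator at power-Doppler frame start times (`on ≤ t < off`).

## Clutter filtering

The stack is reshaped to the Casorati matrix C (space × time) and the
projection onto the subspace of the `n_remove` largest singular values is
subtracted. The default cutoff is 60, the fixed value used for the
in-vivo acquisitions this pipeline targets; for synthetic stacks any
`n_remove ≥ tissue_rank` annihilates the tissue component.

Two exact solvers are provided. `"lapack"` computes the full SVD of C;
`"gram"` obtains the same leading subspace from the eigendecomposition of
the Gram matrix on the smaller Casorati dimension (spatial covariance for
long acquisitions), which is how production ultrafast-Doppler pipelines
handle matrices with 10⁵ time samples. `"auto"` (default) switches to the
Gram route when the aspect ratio exceeds 8. No truncated or randomised
decomposition is used.

A note on repeated filtering: removing the `n` leading components is not
idempotent on full-rank data — a second application removes the *next*
`n` components, so `filter_n ∘ filter_n = filter_2n` (tested). The
operation is a fixed point exactly when the input rank does not exceed
`n_remove` (e.g. after a rank-deficient clutter component has been
annihilated), which is the projector property the tests assert.

## Power Doppler and detrending

Power-Doppler frames are means of `|s|²` over non-overlapping blocks
(default 200 ultrafast frames; 500 Hz → 2.5 Hz, one frame per 400 ms). A
trailing partial block is discarded and logged. Overlapping blocks are
not supported. Detrending fits a per-pixel polynomial (default degree 1)
over the whole time course and subtracts it, adding back the temporal
mean so that baseline levels survive for percent-change computations;
degree 0 is the identity.

## Activation mapping

Each masked pixel's time course is regressed on the design (stimulus
boxcar + intercept) by ordinary least squares. The stimulus coefficient's
t statistic (df = frames − rank) is converted one-sided (activation =
CBV increase; a two-sided flag exists) to a p-value and then to a z score
by upper-tail quantile matching. A pixel is active when
`p < alpha_family / n_tests` with `n_tests` the brain-mask pixel count —
the Bonferroni threshold is always derived, never hardcoded. Zero-variance
pixels (detected by temporal variance at float precision) are reported
with z = 0, p = 1 rather than raising. Drift is handled by the explicit
detrend stage rather than drift columns; on designs where the drift is
orthogonal to the boxcar the stimulus estimate is unchanged (tested). An
optional normalised exponential kernel can smooth the boxcar; the default
is the raw boxcar since fUS responses are fast relative to 20 s blocks.
No residual-autocorrelation correction is applied, so nominal p-values
assume exchangeable residuals — adequate for the simulated noise, a known
simplification for real colored noise.

## Descriptors

The movie is averaged over the roi-restricted active pixels; one epoch per
stimulation is cut from `baseline_window_s` (default 10 s) before onset to
the end of rest; per-epoch ΔCBV% is computed against the pre-onset
baseline mean and epochs are averaged point-wise (trial-averaged trace,
matching the one-mean-time-course-per-animal convention; per-trial
descriptor averaging is deliberately not offered).

- **Steady-state ΔCBV** is the trace mean over 7–20 s post-onset.
- **Rise time** is the interval between the first crossings of 10 % and
  90 % of the steady-state reference after onset, linearly interpolated
  between frames; ties exactly at a threshold resolve to the earliest
  frame. The reference defaults to the 7–20 s window mean for consistency
  with the ΔCBV descriptor; an explicit `steady_ref` (e.g. the asymptotic
  plateau of a fitted step response) can be passed instead. For an
  exponential rise with τ = 2 s the window-mean reference biases the
  estimate by about −2 % (the window mean sits slightly below the
  asymptote); with the asymptotic reference the estimate equals τ·ln 9
  to interpolation accuracy.
- Undefined metrics (no active pixels, non-positive plateau, never-crossed
  threshold) propagate as NaN with a reason code in `DescriptorSet.flags`,
  never as zeros, so cohort statistics can treat them as missing.

## Histology quantification

Sections are 8-bit grayscale throughout (colour input is converted by
standard luminance weighting, but the generator emits grayscale
directly). Mean gray intensity is `mean(region) − mean(background)`; the
background zone is an explicit mask outside the tissue. Negative
background-subtracted means are retained, not clipped — clipping would
bias group means — and flagged below −5 gray levels. Area fraction counts
pixels `≥ threshold` (inclusive comparison, default 64 on the 0–255
scale; at threshold 0 the fraction is 100 %). Animal aggregation averages
left/right sides within a section, then sections; a missing side
contributes the available side with a warning.

## Cohort generation and linking statistics

`CohortSpec` defines, per region, the linear link
`myelin = intercept + β_pixels·n_active + β_dcbv·ΔCBV + β_rise·rise + ε`,
`ε ~ N(0, residual_sd)`. The first region listed is the *anchor*: each
animal's anchor myelin level is drawn from its group distribution and the
link is inverted for the descriptor with the largest |β| (the others come
from cohort-level descriptor distributions); remaining regions are
generated forward from the shared descriptors. This construction makes
full-model OLS unbiased for every region's coefficients while letting
group means control the anchor myelin distribution. Default rise-time
coefficients are negative — −1.57 (anchor/S1BF), −1.38 (thalamus), −2.26
(internal capsule) — encoding that demyelination delays the response.
Pixel counts are rounded to integers after inversion and the linked mean
recomputed, so the link stays exact.

Spearman correlations use midranks; p-values come from the t
approximation for n ≥ 8 and the exact permutation distribution below
(cohorts of 8 sit at the boundary). Benjamini–Hochberg adjustment (via
statsmodels) covers only the unique off-diagonal pairs. Stepwise
regression is bidirectional from the constant model with entry/removal
thresholds 0.05/0.10 (the conventional defaults of the classic routine;
a backward-only flag exists since the direction convention is not
universal); predictors are unstandardised so estimates are on the raw
descriptor scales; collinear candidates are dropped with a warning, and
missing descriptor values are excluded listwise with counts reported.
Note that with three null candidates the constant model is returned with
probability (1 − p_enter)³ ≈ 0.857, not higher — a property of any
stepwise procedure at these thresholds.

## Problem sizes used in tests

Test and acceptance acquisitions use a 16 × 16 plane at 250 Hz with
100-frame blocks (the same 2.5 Hz power-Doppler rate as the full-scale
acquisition), a ~100-pixel responding patch, and the full 420 s protocol.
These sizes were chosen because descriptor signal-to-noise is governed by
the per-trace-point sample count (block × active pixels × trials): the
reduced geometry keeps that product close to the full-scale acquisition,
so recovery tolerances transfer. What the synthetic tests do **not**
exercise: real speckle statistics and Doppler spectra, motion (none is
corrected, by design), spatially correlated physiological noise, vascular
anatomy, and staining artifacts in histology — passing tests demonstrate
the correctness of the computations, not robustness to those real-data
effects.

## Known limitations

- No prewhitening or cluster-level inference in the GLM.
- No parametric hemodynamic-response fitting; descriptors are
  model-free summaries of the trial-averaged trace.
- The clutter-filter cutoff is a plain integer per run; no adaptive
  rank selection.
- Histology assumes uniform acquisition settings across sections; no
  stain normalisation.
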