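# Methods

This note documents the models, numerical choices, and limitations behind
`dynapet`. It is the package's own account of its science; every number
quoted here is recomputed by the test suite or `scripts/acceptance.py`.

## Scope and design

`dynapet` is a desk-scale laboratory for studying how count statistics
propagate through dynamic-PET quantification. It couples

1. a multi-organ ellipsoid phantom driven by compartment-model kinetics,
2. an image-space count model with Poisson noise, binomial dose thinning,
   and Poisson bootstrap replicates,
3. a bank of small residual attention U-Nets trained per count level on a
   static late-uptake frame (frame-by-frame denoising routed by count
   matching), and
4. the quantification stack: TAC extraction, 1-TCM / irreversible 2-TCM
   fitting with blood volume and delay, Patlak and Logan graphical
   analysis at ROI and voxel level, and bias / RMSE / SSIM /
   significance-testing evaluation.

Everything runs on one CPU in minutes; nothing requires a GPU or
projection-space reconstruction.

## Kinetic models

Tissue curves follow the standard serial-compartment formulation. For the
one-tissue model, `CT = K1 exp(-k2 t) (*) Cp(t - delay)`; the macro
parameter is the total volume of distribution `VT = K1/k2` (ml·cm⁻³).
For the irreversible two-tissue model (`k4 = 0`),

    CT = Ki * ∫0^t Cp + K1 k2/(k2+k3) * exp(-(k2+k3) t) (*) Cp,
    Ki = K1 k3 / (k2 + k3)   (ml·min⁻¹·cm⁻³),

the sum of trapped and free compartments. The measured curve is
`(1-vB)·CT + vB·Cb` with whole blood identified with plasma (`Cb = Cp`);
no metabolite or plasma-fraction correction is modelled.

Convolutions with exponential kernels are evaluated *exactly for a
piecewise-linear input* on a uniform 1-s grid via a first-order recursive
filter (`scipy.signal.lfilter`), with series fallbacks for small `k·dt`.
This avoids quadrature drift across 5-s early frames; the forward models
agree with independent stiff-ODE integration to better than 0.1 %
relative error (tested on random parameter draws).

Frame values are trapezoid averages of the continuous curve over each
half-open frame interval `[start, end)`, which is exact for
piecewise-linear curves because all protocol frame boundaries fall on
whole seconds.

### Fitting

`fit_compartment` performs bounded weighted least squares
(`scipy.optimize.least_squares`, TRF) over the micro-parameters with the
blood delay resolved by an outer grid search (default −30…+30 s, 1 s
step, warm-started along the grid) followed by parabolic refinement and
a seeded 5-start multistart at the chosen delay. Default bounds:
K1, k2, k3 ∈ [0, 5], vB ∈ [0, 0.5]. Weights are uniform by default with
an optional frame-duration scheme; the choice is configurable because
published practice varies. On noiseless synthetic TACs the fitted Ki and
VT land within 1 % of truth and injected delays are recovered within one
grid step.

### Dual blood supply

The liver receives arterial and portal-venous blood. `dual_input`
implements a simplified flow-weighted surrogate: the portal component is
the arterial curve dispersed through a unit-mass kernel
`ka·exp(-ka t)` and the mixed input is `fa·Ca + (1-fa)·Cpv`
(defaults fa = 0.25, ka = 1 min⁻¹, both fittable). This captures the
delayed, dispersed portal contribution without attempting to reproduce
any particular optimization-derived estimation scheme.

## Graphical analysis

Patlak: OLS of `CT/Cp` on `∫Cp/Cp` over frames with mid-time ≥ t\*
(default t\* = 25 min for the FDG-like protocol); the slope is reported
as Ki. Logan: OLS of `∫CT/CT` on `∫Cp/CT` (default t\* = 2 min); the
slope is VT. Plasma integrals use trapezoid on the fine input grid;
tissue integrals use trapezoid over frame mid-times with a zero anchor
at t = 0. Frame inclusion is by mid-time; regression is unweighted.

One consequence worth stating explicitly: the measured curve contains
the fractional blood volume, so graphical slopes on noiseless data
estimate `(1-vB)·Ki` (Patlak) and `(1-vB)·VT + vB` (Logan), not the pure
tissue macro-parameters. The pure-consistency checks in the tests
therefore use vB = 0 curves, while phantom-map checks compare against
the perfusion-scaled values. In the low-dose experiments all biases are
relative to a full-dose reference, which cancels this term.

Voxelwise maps vectorize the same OLS. Voxels violating preconditions
(non-positive CT for Logan) are excluded from the output mask rather
than clamped, and negative slopes are retained so noise-induced bias
remains measurable.

## Phantom and count model

The default phantom is a 32³ grid of 4 mm voxels (128 mm field): a
low-uptake soft-tissue **body** ellipsoid enclosing liver, lung, psoas
muscle, thalamus (irreversible 2-TCM with literature-plausible FDG
parameters), two blood pools (descending aorta, right ventricle), and a
reversible-tracer lesion (VT = 2.0) with a necrotic low-VT core.
Regions are layered last-writer-wins, so the core overwrites the lesion
interior. The body background matters: real images have soft tissue
everywhere, and without it per-slice mean normalization (below) produces
pathological dynamic ranges on near-empty slices.

The arterial input is an analytic linear-rise/tri-exponential curve
(amplitudes A1–A3, rates l1 > l2 > l3, appearance delay t0) with a peak
near 100 kBq/ml at ~30 s — a realistic bolus shape whose parameters are
stored with the phantom so IDIF extraction can be validated against the
analytic curve.

Counts are modelled in image space:

    counts[v, f] = conc[v, f] · voxel-volume(ml) · duration(s)
                   · sensitivity · dose_fraction.

The default sensitivity (60 counts per kBq/ml·ml·s) puts ~10⁴ counts
into an ml-scale blood ROI in an early 5-s frame at full dose —
LAFOV-like statistics. Poisson noise is applied per voxel-frame; dose
reduction is binomial thinning of the *acquired* counts (matching the
practice of sub-sampling an acquired scan, and conserving events exactly
against the complement stream); bootstrap replicates are per-voxel
Poisson resamples of the observed counts (the large-count limit of
multinomial list-mode bootstrapping), 10 replicates by default.

What this deliberately omits: reconstruction noise correlations,
scatter/randoms, attenuation, TOF, partial-volume blurring, and motion.
Consequently noise between voxels is independent — real parametric-map
noise is spatially correlated — and passing tests here demonstrate
correctness of the quantification machinery under the stated count
model, not performance on scanner data.

Every stochastic operation takes an explicit seed; a master seed fans
out through `numpy.random.SeedSequence.spawn` (documented in
`spawn_seeds`), making full experiments bit-reproducible.

## Denoiser

The denoising framework trains one network per count-reduction factor
on a *single static late-uptake frame* (the 10-min window at 50–60 min
of the phantom scan): the full-count frame is the target, its binomially
thinned version the input. The canonical factor ladder is
1/2 … 1/300 (seven levels). At inference each dynamic frame is routed to
the network whose training-condition total counts are nearest in log
space (ties to the lower-count level, clamping at the ladder ends), so
short early frames use aggressively-trained networks and long late
frames gentle ones.

Architecture: a 2D U-Net over three consecutive slices (predicting the
middle one), with max pooling, bilinear ×2 upsampling, batch
normalization, PReLU activations, additive attention gates on the skip
connections (single 1×1 projections), and a residual connection from
the input middle slice to the output. The repository default is depth 3
with 16 base channels and one conv per stage — ~0.25 M parameters,
trainable on one CPU in about a minute per level. Larger configurations
(e.g. two convs per stage, wider channels, ~11 M parameters) are
expressible through `NetConfig` but are not the test default.

Each input slice is normalized by its own mean; the target is normalized
by the input middle-slice mean (so the residual path sees consistent
scales), and predictions are un-normalized by that same mean. Zero-mean
slices bypass the network entirely. Edge slices replicate the boundary
slice to fill the 3-slice window. Final predictions average the three
per-view volumes (transverse, coronal, sagittal).

The network stack is implemented on a compact numpy reverse-mode
autodiff engine written for this package (`denoiser/autograd.py`):
im2col+BLAS convolutions, pooling/upsampling, batch-norm built from
differentiable primitives, and Adam. Gradients are validated against
central differences in the test suite; float32 is the compute dtype,
with float64 available for the gradient checks.

Training minimizes MSE with Adam. The `TrainConfig` default learning
rate is 1e-5 — appropriate for a clinical-scale network on full
volumes — while the desk-scale preset (`demo_train_config`) uses 2e-3
with batch 16 and ~30 epochs, which the ~0.25 M-parameter network needs
to converge on mean-normalized 32×32 slices within its epoch budget. Training pairs can draw several independent thinning
realizations per factor (`n_realizations`, demo uses 3) to enlarge the
~90-slice dataset. A 90/10 train/validation split with early stopping
(patience 10) guards against overfitting; the best-validation weights
are restored. The final 1×1 convolution is zero-initialized so the
residual network starts exactly at the identity — training can only
improve on the noisy input, never start worse.

Because the clean phantom is piecewise constant with high-contrast
edges, isotropic Gaussian smoothing *increases* RMSE against truth at
these count levels (edge bias dwarfs the noise), which is why the
classical comparator loses and the learned, edge-preserving denoiser
wins; this mirrors the real motivation for learned denoising over
linear filters.

## Evaluation

AUC is trapezoid over frame mid-times with a zero anchor at t = 0
(units × min). Percent bias is `100·(x-ref)/ref` with the full-dose
non-denoised run of the same replicate as reference; ground-truth-
referenced biases are additionally recorded under `*_vs_truth` metrics
(an extension possible only because the phantom truth is known). RMSE
is the root mean squared difference over an optional mask. SSIM uses a
Gaussian window (σ = 1.5, truncated at 3.5σ), K1 = 0.01, K2 = 0.03,
data range = max of the reference volume, Gaussian-weighted population
moments, and edge-cropped averaging; it is implemented in-package and
cross-checked against scikit-image in the tests. Paired two-tailed
t-tests gate significance at α/n_comparisons (Bonferroni), α = 0.01;
zero-variance differences return p = 1 by convention with a warning.

The experiment runner (`run_low_dose_experiment`) simulates a full-dose
acquisition once per replicate, thins it down the dose ladder, applies
each method (none / network bank / Gaussian), extracts blood and tissue
TACs (the lesion via a 60 %-of-max isocontour inside a parent VOI on the
duration-weighted post-10-min mean image), fits compartment models
(DA input for liver/muscle/thalamus/lesion, RV input for lung), builds
Patlak maps over the body, and emits one tidy record per
region × dose × method × metric × replicate plus a manifest with every
seed and a config hash. Problem sizes in the shipped configurations
(32³ phantom, 3 replicates for end-to-end comparisons, 50 replicates for
moment and recovery checks) were chosen as the smallest that leave the
Monte-Carlo properties clearly resolved.

## Known limitations

- Image-space count proxy: no reconstruction correlations or
  non-negativity bias, so absolute bias magnitudes are smaller than in
  scanner data; directional/monotone properties are the meaningful ones.
- The 60 %-of-max lesion threshold is applied to a configurable static
  summary (duration-weighted mean after 10 min) because isocontour
  practice varies; the choice is recorded in the experiment manifest.
- The dual-input liver model is a fixed-parameter surrogate, not an
  optimization-derived estimate.
- Graphical slopes inherit the (1-vB) perfusion scaling discussed above.
- The denoiser bank is trained on one phantom's static frame; nothing
  here demonstrates transfer to other anatomies or real scanners.
- Frame denoising helps exactly where noise dominates. On parametric
  maps (voxel level) the denoised arm has lower RMSE and higher SSIM
  against the full-dose reference at every reduced dose. On ROI-mean
  compartmental fits, however, the non-denoised arm is already nearly
  unbiased under this count model — ROI averaging over homogeneous
  regions is itself an optimal unbiased noise reducer, and the
  image-space proxy has no reconstruction-induced degradation — while
  static-trained networks necessarily distort early blood-phase frames
  whose content resembles no training slice. The end-to-end experiment
  therefore shows a denoising benefit for parametric imaging but not
  for ROI-level macro-parameters at desk scale; with reconstructed
  clinical data, where the non-denoised arm degrades sharply at low
  counts, the balance is reported to differ.
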