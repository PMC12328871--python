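# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic data do and do not emulate, and the numerical
conventions a maintainer needs.

## Acquisition model and phantom

The phantom is a 2-D single-slice object on a `grid × grid` raster
(default 64) with an elliptical "brain" mask occupying ~34% of the
field of view. Each metabolite has a non-negative amplitude map: a
smooth Gaussian-filtered random field giving ±20% regional variation,
rescaled so the mask-mean equals its target exactly. Ratio targets are
specified as pairs (e.g. `Lac/Pyr: 0.256`) and propagated to absolute
means with pyruvate anchored at 1; metabolites not constrained by a
target default to small values (alanine 0.06, pyruvate hydrate 0.08 in
pyruvate units), consistent with the minor peaks of the in-vivo
spectrum.

Voxel FIDs are sums of decaying complex exponentials
`A e^{iφ} e^{(2πi f₀ − π·FWHM) t}` — Lorentzian lines after Fourier
transform. Chemical shifts use standard hyperpolarised-¹³C assignments
(pyruvate 171.0, hydrate 179.5, alanine 176.5, lactate 183.2,
bicarbonate 161.0 ppm) with the carrier on pyruvate; the printed
2 kHz = 122.4 ppm window fixes the Hz-per-ppm conversion (≈16.34 Hz/ppm)
rather than a hard-coded field strength. Default linewidth is 8 Hz
FWHM for every peak; since all lines share one shape, window-capture
fractions cancel in ratios.

Acquisition box-averages the cube to the 16×16 matrix and applies an
orthonormal 2-D DFT (k-space origin at `floor(N/2)`, array index
`(row, col) = (y, x)`). Phase encodes are visited centre-out, ties
broken counter-clockwise from +kx. Optional polarisation consumption
scales shot n by `sin(FA)·cos(FA)^{n−1}·e^{−n·TR/T₁}` per metabolite
(T₁ defaults: 30 s pyruvate/lactate, 20 s bicarbonate); it is off by
default because the analysis uses AUC ratios, not rate fits. Noise is
circular complex Gaussian in k-space; `sd` is the total complex std
(component variance `sd²/2`). "SNR" means (max magnitude of the
noiseless reconstructed spatial spectrum) / sd — since every transform
is orthonormal, the same sd applies in all domains.

The T₂w guide is rendered at 128×128 from the same analytic ellipse
(bright parenchyma, darker interior structure, mild texture, 1 px
blur), then 2×2 block-averaged to 64×64, so guide edges co-localise
with the mask boundary by construction.

Not emulated: B₀/B₁ inhomogeneity, chemical-exchange dynamics during
the scan, coil sensitivity, motion, multi-slice/3-D, and spatially
varying phase. Passing tests therefore demonstrate correctness of the
reconstruction chain under ideal-instrument assumptions, not robustness
to those confounds.

## Tensor denoising

Truncated HOSVD with core ranks (8, 8, 12), applied to the
spatial-domain `(x, y, frequency)` tensor (the k-space alternative is a
config switch). Complex SVDs are used directly, never stacked
real/imaginary. The projector is idempotent, reduces to the identity at
full ranks, and obeys the quasi-optimality bound
`‖T − T̂‖² ≤ Σₖ Σ_{i>rₖ} σ²_{k,i}`. A HOOI refinement (alternating
subspace updates) exists behind `hosvd_truncate(..., hooi_iters=n)` but
is off by default: the single-pass HOSVD is deterministic and
oracle-checkable against dense per-mode SVDs. No automatic rank
selection is provided.

## Guided super-resolution

Each spectral bin solves
`min_x ‖Dx − y‖² + λ Σₑ wₑ (xᵢ − xⱼ)²` with `D` the block-mean
operator (verified adjoint) and 4-neighbour edge weights
`wₑ = exp(−(|∇g|/(k·s))²)`, `s = 1.4826·median(|∇g|)` over all guide
edges, `k` = `edge_scale` (default 2). The robust normalisation makes
weights invariant to affine intensity transforms of the guide; a
constant guide yields uniform weights, i.e. plain Tikhonov-graph
interpolation. Weights are clamped at 1e−6 so underflow cannot
disconnect regions. Defaults: λ = 0.05, target grid 64.

The normal equations are SPD; the default solver is a cached sparse LU
factorisation, reused across all 128 bins (and across noise seeds with
the same guide). Jacobi-preconditioned CG is available
(`solver="cg"`), with non-convergence flagged on the result together
with the data-consistency residual `‖Dx̂ − y‖/‖y‖`; on anatomy-shaped
inputs at the default λ the residual is ~1e−3, comfortably inside the
0.01 contract. Because the objective is quadratic, the solution
operator is linear, which the tests exploit. Real and imaginary parts
share the same real operator. Two modes exist: `per_bin` (default, the
CSI data are super-resolved before quantification) and
`per_metabolite_map` (quantify first, super-resolve AUC maps); on
noiseless phantoms the whole-mask ratios of the two agree within 2%,
bounding the impact of this unrecorded choice.

## Spectral quantification

Spectral processing before integration: exponential apodisation of
4 Hz, first-point halving (trapezoid-rule weighting of a causal FID,
which removes the flat DFT pedestal that otherwise biases every window
integral), zero-filling ×8 (sinc interpolation onto a 0.1-ppm grid so
off-bin peak positions do not change capture fractions).

Integration is complex-mode by default: for each peak window
(±1.5 ppm), a complex polynomial baseline (order 1) is least-squares
fitted on flanking baseline points — outside every window, ≥1.6 ppm
from every peak centre, within 2.8 ppm of the window centre — and the
AUC is `|∫(S − baseline) df|` over the window. The peak's own area is
then independent of its phase, while the dispersion-mode tails of
neighbouring peaks are mostly removed by the local fit and their
residual lies in quadrature, entering only at second order. A
magnitude-spectrum mode (real baseline via `baseline_correct`, then
trapezoidal `integrate_peak`) is provided and tested, but with this
crowded peak layout (hydrate only 3.7 ppm from lactate) its broad
`1/Δf` tails bias ratios by tens of percent, so it is not the default.
The local window/flank defaults were fixed against the noiseless
analytic phantom (errors ≤0.6% for all three ratios in both study
conditions) before any noisy evaluation.

Whole-ROI ratios are ratios of ROI-summed AUCs, where the ROI sum in
complex mode is taken over the complex window integrals *before* the
magnitude: signal phases are coherent across voxels, noise is not, so
this suppresses the Rician bias that per-voxel magnitudes acquire on
weak peaks (≈+5% on bicarbonate at SNR 20 otherwise). Per-voxel maps
remain magnitudes for display; the mean of voxel ratios is reported
alongside the ratio of sums in every CSV. Ratio maps mask voxels whose
denominator AUC is below 5% of its ROI maximum. The brain ROI is the
Otsu threshold of the T₂w guide, largest connected component, closed
with a radius-2 disc and hole-filled; the phantom's exact mask is
available as `source="phantom_truth"` for calibration tests.

## Group statistics

Pooled-variance two-sided Student's t-test (`df = n₁ + n₂ − 2`), with
Welch behind a flag; sample SDs use n−1. Zero pooled variance yields
t = 0/p = 1 for equal means and a flagged infinite t otherwise. Percent
change is `100·(m_t − m_pre)/m_pre`. No multiple-testing correction is
applied (recorded in the output); the null calibration test checks the
empirical type-I error at α = 0.05 over 10,000 simulated n=5 pairs.

## Locomotor tracking

Sessions emulate an 11-h dark-phase recording (19:00–06:00) in a
30×19 cm cage at 5 fps, ~3 px/cm. The simulator produces bursty
movement: straight bouts at 8 cm/s toward uniform random waypoints,
each followed by a pause sized so every bout+pause cycle has exactly
the commanded mean speed — the realised hourly distance is therefore an
unbiased, duration-independent estimate of the command. Rendering
paints an anti-aliased bright disc on a dark background with static
bright discs in opposite corners (water bottle, feeder) and optional
Gaussian pixel noise, quantised to uint8. Tracking subtracts the
temporal-median background (computed from ≤101 sampled frames; static
distractors cancel), thresholds at 40% of the median per-frame peak,
takes the intensity-weighted centroid of the largest connected
component, interpolates and flags empty frames, and marks the output
low-confidence above 10% gaps. Distance per wall-clock hour drops steps
below 0.2 cm (tracking jitter at rest would otherwise accumulate into
fake distance — bout steps at 5 fps are ~1.6 cm); the trailing partial
hour is excluded. Long sessions are rendered and tracked in 30-min
chunks to keep memory flat; the chunking is exact apart from gap
interpolation at chunk borders.

## Problem sizes and reproducibility

Default experiment sizes: 64-grid phantom, 16×16×128 acquisition,
10 seeds per CSI condition; locomotion validation uses 20 seeded
sessions of 2 h (the pacing argument above makes the hourly expectation
independent of session length, and the full 11-h chain is a pure
scale-up). Every stochastic step takes an explicit integer seed and is
bit-reproducible; pipeline runs emit a manifest (config hash, stage
parameters, output digests) from which a run can be replayed exactly.

## Known limitations

- The guide must be co-registered; no registration is performed.
- Quantification assumes the peak table matches the acquisition
  (windows are fixed in ppm, not fitted); overlapping peaks closer than
  ~3 linewidths bias each other's AUC at the few-percent level.
- The whole-ROI coherent complex sum assumes a spatially uniform
  zero-order phase per metabolite, which holds for this simulator but
  only approximately in vivo.
- Single-slice 2-D only; slice thickness is carried as metadata.
- The tracker is single-animal and assumes the animal is the only
  moving bright object.
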