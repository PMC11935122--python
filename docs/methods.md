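# Methods

## Scope and model of the data

`stedqc` analyses 2D STED frames of the endoplasmic reticulum: nonnegative
photon-count images with a known physical pixel size (20 nm by default)
and, for movies, a frame interval (4.6 s by default). Three kinds of frame
flow through the pipeline: high-dose "ground truth" acquisitions, ~70×
lower-dose gentle acquisitions, and denoised predictions of the latter on
a normalized [0, 1] scale. The package does not train or run a denoising
network; it simulates, rescales, quality-controls and quantifies around
one.

## Synthetic phantoms and the acquisition model

The phantom generator draws `n_seed_nodes` points uniformly at random,
connects them by Delaunay triangulation, and prunes edges of over-degree
nodes (preserving connectivity) until degrees approach
`junction_target_order` (default 3, matching the 3-way dominance of
healthy ER networks). Edges are rendered as constant-width anti-aliased
strokes (`tube_width_nm`, default 100 nm — a typical apparent ER tubule
width at STED resolution); sheets are filled soft-edged ellipses
(`sheet_area_px_range`, default 200–1200 px ≈ 0.08–0.48 µm² at 20 nm
pixels) anchored on network nodes. Ground truth is exact: every pixel with
nonzero rendered density carries a class label, and the generating graph
(node coordinates and degrees) is stored alongside.

The acquisition model is deliberately minimal: the density map is
convolved with an isotropic Gaussian PSF (`psf_fwhm_nm`, default 90 nm —
an effective post-depletion STED resolution), scaled by the per-pixel
photon budget `dose_per_unit_density × line_accumulations`, and Poisson
sampled; independent Poisson dark counts (`dark_count_rate`, default 0.01
per pixel) are added. The two stock regimes encode the high/low dose
pairing: 56.3 × 6 versus 4.8 × 1 dose units, a 70.375-fold per-pixel
budget ratio. No depletion-beam physics, photobleaching or fluorophore
photophysics is modelled — only the effective resolution and photon
statistics matter downstream.

Movies perturb the phantom between frames: a fraction
`rearrangement_rate` of edges has its endpoints jittered (σ = 2 px) and
sheets drift with the same rate scaling. The rate is a phenomenological
knob — adjacent-frame structural overlap decreases monotonically with it —
not a model of ER remodelling kinetics. "Denoised predictions" are
emulated as the blurred noiseless rendering plus low-variance Gaussian
read noise, min-max normalized to [0, 1]: this reproduces the one property
that matters for the pipeline, a normalized output needing rescaling.

All randomness flows from one integer seed per operation through
`numpy.random.SeedSequence`, so every output is bit-reproducible.

### What the simulator does not emulate

Real STED data has structured background (out-of-focus haze, uneven
illumination), registration error between the dose pair, detector
afterpulsing, and genuinely network-generated predictions whose failure
modes (over-smoothing, structured hallucination) are richer than blurred
renderings. Passing tests on phantoms therefore demonstrate correctness of
the *computations* — metric formulas, topology extraction, bookkeeping —
not performance claims about any particular denoiser on microscope data.

## Rescaling

`fit_rescale` pools all pixels of all training prediction/ground-truth
pairs and solves ordinary least squares for a single global
(scale, offset); `apply_rescale` applies the affine map and then clips to
the 1st/99th percentile band of the pooled ground-truth pixels (linear
interpolation between order statistics). Clipping after (not before) the
affine map is the convention here and is recorded in the serialized
parameter file. The fit requires ≥ 1000 pixels and non-constant
predictions; train/test separation is structural (the fit only ever sees
the training lists) and asserted in the pipeline runner.

## QC metrics and resolution

MAE, SSIM and PSNR use their standard definitions (SSIM: Gaussian-weighted
11×11 window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, population covariances;
scikit-image backend). PSNR of identical images reports an infinite
sentinel rather than raising, so batch reports never abort. Pearson
correlation is computed on flattened pixel vectors and refuses
zero-variance input.

FRC: both images are Hann-apodized, Fourier transformed, and correlated
per integer-radius frequency ring (real part of the ring-summed
cross-spectrum over the geometric mean of ring-summed powers). The
resolution is 1/f\* at the first crossing below the 1/7 threshold, after a
3-ring moving average (raw FRC curves are noisy and the crossing is
otherwise unstable), with linear interpolation between rings. A curve that
never crosses reports the Nyquist bound 2 × pixel size with a flag — with
20 nm pixels nothing finer than 40 nm is ever reported.

The rolling FRC map evaluates this on `block_size_px` blocks (default 64)
along a `stride_px` grid (default 16); blocks whose mean intensity is at
or below `background_intensity` (default 20 counts) in *both* images carry
no structure to correlate and are masked out of the mean/min summaries.
Block mean (rather than max or quantile) is the validity statistic; it is
exposed as a parameter. When judging a prediction, its ground-truth
counterpart is the natural second input; for ground-truth resolution, two
independent acquisitions of the same field are paired.

The total score ranks model runs within a cohort: SSIM mapped linearly so
the cohort max → 1, MAE and resolution (lower better) so the cohort
min → 1, averaged over the three. A metric constant across the cohort
contributes 0.5 to every run. The score is invariant to affine
re-expression of any metric and is only defined for cohorts of ≥ 2.

## Hallucination checks

Temporal: the adjacent-frame SSIM trace of the prediction movie is
compared with the trace of a detector dark-noise movie. Each trace is
scored against its own movie's dynamic range; judging sparse dark counts
on a bright movie's range would make near-empty frames look almost
identical and invert the contrast. A transition is flagged as a possible
hallucination when its SSIM does not exceed the dark band's
mean + 2 sd — i.e. the frames cohere no better than pure noise. The
2-sd rule is the simplest defensible cut and is configurable (`n_sd`).

Spatial: for every pixel of the *low-dose input*, intensities are summed
over a 10×10 window centred on it (even windows put the extra row/column
toward larger indices; borders are mirror-padded without repeating the
edge pixel) using an integral image, so integer sums are exact. Sums ≤ 5
are background, (5, 25] uncertain, > 25 signal — for integer counts
exactly the grouping "≤ 5 / 6–25 / > 25". Window size and thresholds are
parameters and should be adapted to the dose regime. The classification
never reads the prediction.

## ER structure

Frames are background-subtracted with a rolling ball (radius 15 px) so
haze is not misread as sheets. Segmentation is width-based: Otsu
foreground on the lightly smoothed frame (σ = 1 px), then a morphological
opening with a disk of radius `tube_max_width_nm / 2` (default 100 nm =
5 px) — regions surviving the opening are wider than any tubule and are
labelled sheet, the remaining foreground is tube. Sheet fragments smaller
than `min_sheet_area_px` (default 150 px ≈ 0.06 µm², below the footprint
of any plausible sheet) are junction-overlap artifacts of the width
criterion and are relabelled tube. Externally produced label maps with the
same class codes (0 background / 1 tube / 2 sheet / 3 SBT) are accepted in
place of the built-in segmenter, and SBT pixels are always merged into
sheets before fractions are computed. Class fractions default to the
ER-pixel denominator (tube + sheet = 1), with a flag for whole-frame
denominators.

Skeleton analysis thins the tube mask to single-pixel width
(8-connectivity), clusters adjacent branch pixels (≥ 3 skeleton
neighbours) into junction nodes, and counts the distinct branches leaving
each cluster as its order; pixels with one neighbour are endpoints. Since
every non-node skeleton pixel has exactly two neighbours, each branch
segment contributes exactly two node incidences (walked explicitly from
its end pixels), so the handshake identity — degrees summing to twice the
edge incidences — holds exactly; isolated closed loops carry no node and
are skipped. Instances: tubes and sheets are 8-connected components of
their masks; gaps are 4-connected background components not touching the
image border (the standard foreground-8/background-4 duality avoids
paradoxical topology). Foreground fraction binarizes with Otsu by default
(a fixed threshold is available) and counts the fraction of
above-threshold pixels.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 128–256 px phantoms,
movies of 4–20 frames, 5–20 seeds per property, rFRC at 64-px blocks with
16–32 px strides. These sizes keep every property measurable (e.g. a
100 nm PSF recovered within [80, 130] nm by the rFRC mean) while each
suite completes in seconds. Quantile definition is linear interpolation
between order statistics; FRC ring frequencies are k/(N·pixel size) for
rings fully inside the square spectrum; stacks are ordered (t, y, x) with
singleton axes dropped on write; CSV outputs use '.' decimals and one
header row; label TIFFs are uint8 with the documented code table.

## Known limitations

- The width-based segmenter, applied to PSF-blurred frames, merges tubes
  that run closer than the PSF width into sheet-width regions: on 90 nm
  blurred renderings of dense networks the tube-fraction error is ~0.25,
  versus ≤ 0.15 (typically ~0.05) on sharp renderings. Segmentation of
  real data should run on the denoised (deconvolved-quality) predictions,
  and learned segmenters can be substituted via external label maps.
- FRC assumes the two inputs share structure with independent noise;
  feeding it correlated noise (e.g. the same frame twice) reports the
  Nyquist bound, not a physical resolution.
- The hallucination flag is a statistical screen, not a correction; it
  cannot see hallucinations that happen to cohere across frames.
- Z-stacks are treated as independent planes; no 3D PSF or 3D
  skeletonization.
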