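# Methods

## Model

Two 3D U-Net generators, one per imaging domain, each with one input
channel and four output channels: a translated image plus the three BCD
instance representations. The trunks are encoder–decoders with LeakyReLU
(slope 0.2) activations and instance normalisation; downsampling is a
stride-2 convolution, upsampling nearest-neighbour ×2 followed by a 3×3×3
convolution and skip concatenation (nearest+conv has a trivial adjoint and
avoids the checkerboard artefacts of learned upsampling; trilinear blending
adds nothing at these widths). Both output heads are 1×1×1 convolutions
reading the same final decoder feature map, so translation and segmentation
share every weight except the heads, and removing the translation head
cannot change the segmentation output.

Discriminators follow the PatchGAN pattern: strided 4×4×4 convolutions
(strides 2,2,2,1,… then a final stride-1 single-channel layer), batch
normalisation except on the first layer, LeakyReLU 0.2, and an unbounded
patch score map for the least-squares GAN objective. The segmentation
discriminator is identical but takes the 3-channel BCD stack (2 channels in
the BC ablation).

## Objectives

The total is the **unweighted sum** of eight generator-side terms: two image
LSGAN terms, L1 cycle consistency in both domains, two supervised
segmentation terms (BCE on B and C, MSE on D), structural consistency
(L1 between `G(y)[S]` and `F(G(y)[I])[S]`), and two segmentation-adversarial
LSGAN terms. All means are per-voxel / per-patch-element, which keeps the
terms on comparable scales under uniform weighting. Synthesized images are
detached before any segmentation loss uses them, so segmentation objectives
never backpropagate into a translation head (covered by an explicit
gradient-isolation test). Each iteration updates the three discriminators
first (real vs. detached fakes, the two fake streams of the segmentation
discriminator pooled by element count), then both generators jointly against
the refreshed discriminators. The LSGAN fake label defaults to 0, matching
the reference CycleGAN implementation; a `-1` convention is available via
`lsgan_fake_label` and both identities are asserted in tests.

## BCD representation

* `B` — binary foreground.
* `C` — voxels within `contour_radius` (Chebyshev, default 1) of an
  inter-instance or instance–background interface, computed by 6-neighbour
  label disagreement on both sides of the interface.
* `D` — inside an instance, Euclidean distance to the instance's own
  boundary-voxel set (boundary voxels themselves are 0), clipped at
  `d_clip_in = 8` voxels and normalised; on background, minus the distance
  to the nearest foreground voxel, clipped at `d_clip_out = 16`. Distances
  are in voxel units by default (a `sampling` argument switches to physical
  units). Because inside distances are per instance, touching instances
  both fall to `D = 0` at their shared interface, which is the cue that
  lets the watershed split them.

Decoding: seeds are 6-connected components of
`{B > 0.9, C < 0.8, D > 0}` with ≥ 8 voxels; marker-controlled watershed
floods `−D` restricted to `{B > 0.6}`; instances under 27 voxels are
dropped and IDs renumbered in deterministic seed-raster order. The clips
bound the regression target (stable MSE), and conservative seed thresholds
keep markers inside high-confidence interiors. The flooding itself is
scikit-image's watershed, which is deterministic for fixed inputs.

## Synthetic benchmark

The generator emulates the study setting: two modalities of densely packed
nuclei whose geometry statistics match while appearance differs. Defaults
per 64³ volume: 35 randomly rotated ellipsoids, per-axis radii uniform in
4.5–7 voxels (≈ 4 µm nuclei at the working resolution the benchmark
emulates), centre spacing ≥ 12 voxels (dart throwing with rejection;
overlaps resolved to the nearest centre, so closely touching instances
occur, ~10% foreground). Nucleus size matters beyond realism: with much
smaller instances the one-voxel contour band covers most of each nucleus,
the interior class nearly vanishes, and watershed seeding becomes fragile
under domain shift. Appearance presets: source (EM-like) foreground
mean +0.50 on background −0.50, noise σ 0.10, correlated texture amplitude
0.08, axial blur σ 0.5; target (ExM-like) **inverted contrast** — foreground
−0.40 on background +0.45 — noisier (σ 0.12) and more axially blurred
(σ 1.0). The inter-domain foreground-mean gap (0.9) exceeds the 0.4 the
benchmark contract requires, and the contrast sign flip makes the
source-only baseline fail decisively, which is exactly the regime the
method targets. Target-domain ground truth is written to disk for
evaluation but quarantined: the training loader raises on any attempt to
read target labels.

What the phantoms do **not** model: realistic microscope PSFs and noise
physics, intensity inhomogeneity across a volume, non-ellipsoidal nucleus
shapes, and anisotropic voxel grids (supported but not default). Passing
tests therefore demonstrate the machinery and the adaptation effect under a
controlled intensity/contrast gap, not performance on real EM/ExM data.

## Problem sizes

The tested desk-scale preset is: crop 16³, generator depth 2 / width 8,
3-layer discriminators (3³ patch score map on a 16³ crop) with base width
32, batch 1, AdamW (lr 2·10⁻³ cosine-annealed to 0, weight decay 10⁻⁴),
600 iterations. A full-scale preset (depth 4 / width 32, 5-layer
discriminators, crop 64³, batch 8, 10⁶ iterations) ships in
`trainer.PRESETS` but is not exercised by the tests. Patch-map granularity
matters at small crops: a discriminator that emits a single global score
per 16³ crop fails to penalise wrongly rendered nuclei (a few percent of
voxels), whereas the 3³ map gives local gradients and reliable contrast
inversion.

Whole volumes are segmented by tiled inference (default 16³ tiles,
4-voxel overlap) with cosine-ramp blending of the per-channel predictions
before a single global decode.

## Numerical choices and degenerate inputs

* Intensities are min–max normalised to [−1, 1] per volume at read time;
  constant volumes map to −1 (deterministic).
* BCE probabilities are clipped to [1e−7, 1 − 1e−7]; the clip zeroes the
  gradient where active.
* `smooth_upsampled_masks` resolves voxels claimed by several smoothed
  instances by the larger blurred value, ties to the smaller ID.
* AP-50 uses strict IoU > 0.5 (guaranteeing one-to-one matching),
  confidence = mean predicted B per instance (1.0 when decoding encoded
  ground truth), ties broken by larger instance then lower ID, and
  all-point interpolation of the precision–recall curve. Empty ground truth
  scores 1.0 against empty predictions, 0.0 otherwise.
* Axes are (z, y, x) everywhere; published (x, y, z) voxel sizes are
  reversed at the metadata boundary.

## Known limitations

Pure-NumPy training is single-device and orders of magnitude slower than a
GPU framework, so the shipped configurations are deliberately small; GAN
training at this scale is noisy, and the acceptance-level training checks
are framed as majority-over-seeds comparisons rather than absolute scores.
The augmentation-aware cycle property and the adaptation gain are stochastic
properties of an adversarial optimisation; individual seeds can fail even
though the effect is robust in the majority sense.
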