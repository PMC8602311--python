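# Methods

`rcmstain` reimplements a deep-learning virtual-histology pipeline for
reflectance confocal microscopy (RCM) of skin: registration of time-lapse
acetic-acid staining experiments, an adversarially trained 7-slice-to-1-slice
virtual staining network, analytic and learned pseudo-H&E colorization, and
a nuclear-morphometry evaluation suite.  Everything is testable end to end
on synthetic phantoms with exact ground truth.

## Data model

An `ImageStack` is a Z x H x W grayscale volume normalized to [0, 1]
(per-stack min–max with 0.1/99.9 percentile clipping, recorded in
metadata), with the axial step between optical sections (default 1.52 µm)
and the lateral pixel pitch (default 0.5 µm/px) attached.  A
`DisplacementField` stores per-pixel (dy, dx) in pixels with **pull
semantics**: the value at output pixel (y, x) names the source location
(y + dy, x + dx) in the moving image.  The convention matters because a
recovered field is the *inverse* of an applied one; tests compose the two
and require the composition to vanish.

## Phantoms

The phantom generator emulates the contrast relations of acetic-acid
staining experiments, not the optics:

- background: low-pass-filtered Gaussian noise ("speckle"), level
  0.32 ± 0.06, grain 1 px by default — coherent speckle lives at the
  resolution limit, which is about one pixel at 0.5 µm/px;
- nuclei: non-overlapping random ellipses (eccentricity ≤ 0.9, radii
  5–12 px so the evaluator's 10–25 px diameter window applies), dark in
  the unstained channel (x0.15) and bright after "staining" (+0.6,
  approaching the acetowhitening regime); lateral geometry is shared
  across slices with a smooth per-slice intensity modulation (axial
  correlation);
- melanin-rich cells: a configurable fraction of cells rendered bright
  (≥ 0.85) in *both* channels, mirroring melanin's strong endogenous
  reflectance;
- sensor noise: i.i.d. Gaussian (σ = 0.02 by default), independent
  between the two channels except in the time-lapse simulator, where one
  realization is shared across frames so that frames differ only where
  the stain signal grows.

Enforced invariants: stained ≥ unstained at nucleus pixels; mean staining
contrast over nuclei > 5 σ; melanin mask ⊆ cell support; bit-exact
reproducibility per seed.  The phantoms have no PSF, no depth-dependent
SNR falloff and no coherent speckle statistics; a test passing on them
shows the pipeline's mechanics and learnability, not clinical performance.

## Pyramid elastic registration

`estimate_dvf` builds a factor-2 image pyramid (4 levels by default,
stopping early when a level would fall below the correlation window),
initializes with a global phase-correlation translation at the coarsest
level, and then per level: warps the moving image by the current field,
scores every integer offset within a ±4 px search window by normalized
cross-correlation over a 16 px box, refines the best offset with a 1-D
parabola fit per axis (clamped to ±0.5 px), zeroes updates where local
texture or correlation is too weak, clips components to the search radius
(multi-scale correlation can produce abnormal field values), smooths the
increment with a Gaussian of σ = block/2, and accumulates.  Stack
registration applies this slice-wise; time-lapse registration chains
consecutive-frame fields by composition.  On phantoms this corrects a
40 px (20 µm) planted shift to ≈ 0.04 px median residual and 10 px smooth
elastic warps to < 0.1 px RMS.

The exact pyramid constants are this package's choices (4 levels, 16 px
windows, ±4 px search, 2 sweeps per level); the construction follows the
standard multi-scale block-matching lineage.

## Learned fine registration

Soft training means a fixed small budget (default 2000 iterations, far
fewer in tests) with no early stopping: the bridge network only has to
*resemble* the stained domain well enough to make registration of target
against bridge-output well-conditioned.  The fine rounds then use a
restricted pyramid (2 levels, ±2 px, no global stage): after coarse
registration the residuals are small, and a global phase-correlation
between a blurry network rendering and a sharp target can hallucinate
large shifts.

The DVF network predicts a dense 2-channel field from a (moving, fixed)
pair; its head is zero-initialized so the initial prediction is the
identity warp.  Its loss is

    w1 · MSE(I_r, I_r,gt) + w2 · MSE(φ, φ_gt) + w3 · TV(φ)/N_px

with default weights (1, 0.02, 0.01) — the weighting is this package's
choice, exposed in the API.  Gradients flow through a differentiable
bilinear warp into the field only.  Supervision comes from carefully run
pyramid registrations of a seeded ~10% subset of pairs.

## Networks and losses

All networks run on a small in-package reverse-mode autodiff engine over
numpy (float64), with conv2d/conv3d as explicit kernel-offset sums,
batch normalization, bilinear up/downsampling with exact transpose
gradients, spectral normalization by per-forward power iteration (the
scale treated as constant in the backward pass), and Adam.  A
finite-difference check through the full U-Net holds to ~1e-9 relative
error.

The stainer is an attention U-Net: the first encoder block applies three
3x3x3 convolutions, depth-valid and laterally "same"-padded, collapsing a
7-slice input 7 → 5 → 3 → 1; four further 2D blocks (three 3x3 convs with
batch norm and leaky ReLU 0.2, residual add from block input, 2x2 average
pooling) descend to /32.  The decoder mirrors with bilinear 2x upsampling
and additive attention gates (1x1 projections, ReLU, 1x1, sigmoid) that
weight each skip pixel-wise; decoder blocks carry no residual.  Where the
block input and output widths differ the residual passes a 1x1
projection, and the entry block's residual takes the central input slice
— the per-block residual add needs *some* map between mismatched
shapes, and these are the minimal ones.  Channel widths (base 48 doubling
to a 768 cap at full scale; much smaller in tests) are configurable.

The discriminator stacks five conv blocks (3x3 stride 1, then 2x2 stride
2, leaky ReLU, spectral norm), global-average-pools to the channel
vector, and ends in a 1024-wide two-layer fully connected head with a
sigmoid, so scores live in (0, 1).  It scores images unconditionally —
the loss definitions apply D to the generated or real image alone, not to
an (input, output) pair — a deliberate departure from canonical
conditional-GAN practice, kept because the least-squares objectives are
defined on the image alone.

Losses: the generator minimizes BerHu(target, output) with
δ = 0.2 · std(target) per image, plus α·TV(output) (anisotropic TV — the |∇y|+|∇x| sum,
declared here because TV comes in several variants)
plus λ·(1 − D(output))², with (α, λ) = (0.02, 15).  The discriminator
minimizes D(fake)² + (1 − D(real))².  BerHu is continuous at δ (both
branches equal δ).

## Training schedule

Adam with 1e-4 (generator) and 1e-5 (discriminator); batches of 12
patches of 256x256x7 at full scale.  Generator iterations per
discriminator iteration follow

    t_GperD = max(3, floor(12 − 0.25 · floor(t_D / 1000)))

so the ratio is 12 through the first 1000 discriminator iterations
(12 000 generator steps), 11 from t_D = 1000 (floor of 11.75), and
reaches the floor of 3 by t_D = 36 000.  Fresh batches are drawn for every step.  Augmentation uses
90°-multiple rotations and axis flips by default — arbitrary-angle
rotation would interpolate all seven slices — plus optional mild elastic
deformations applied identically to every slice and the target.
Divergence is monitored with an EMA (half-life 50 steps); non-finite
losses abort with a diagnostic.

Desk scale: tests train at 64x64 with base widths 6–16 and ≤ 10
discriminator iterations (≈ 120 generator steps), which already halves
the structural loss and produces nucleus-bright outputs on phantoms; the
supervised pseudo-H&E renderer uses a 1e-3 step size (plain regression)
and reaches < 0.05 MAE against its analytic targets in ≈ 200 iterations.
Full-scale budgets (~40 000 discriminator iterations) are configuration-
supported but not exercised.

## Pseudo-H&E rendering

The analytic renderer extracts the nuclear foreground
max(1.2·I_stained − 0.8·I_unstained, 0) and colorizes by Beer–Lambert
absorption, per RGB channel c:

    I[c] = exp(−β_hematoxylin[c]·I_fg) · exp(−β_eosin[c]·I_input)
           [· exp(−β_brown[c]·I_melanin,labeled)]

with β_hematoxylin = [0.84, 1.2, 0.36], β_eosin = [0.2, 2, 0.8],
β_brown = [0.12, 0.24, 0.28] (empirical, overridable).  Melanin is first
estimated as I_input wherever I_target·I_input strictly exceeds 0.2 —
ties fall to the background, reading the strict inequality as printed —
and then curated; on phantoms the curation step is replaced by the exact
melanin mask.  The foreground can exceed 1 (up to 1.2); it is not clipped
before rendering, since the exponential tolerates it.  Channels are
strictly positive and ≤ 1; zero melanin reduces the extended form to the
base form bit-for-bit.  8-bit export rounds half-to-even after scaling by
255.

The learned renderer (two input channels: stained image — virtual or
actual — and unstained input; three output channels) is trained to
reproduce these analytic targets and serves both inference paths.

## Nuclear morphometry

Segmentation: Gaussian smoothing with σ = smoothing_scale/2.35 (the
scale is read as a FWHM, CellProfiler's convention, default 6), an adaptive
minimum-cross-entropy (Li) threshold computed on ~50 px tiles — tiles
split evenly so no sliver tiles appear at borders, tile thresholds
clamped to [0.7, 1.5]x the global Li threshold, bilinear interpolation
between tiles — times a correction factor 1.05; distance-transform
watershed declumping (peaks at least diameter_min/2 apart); objects
outside 10–25 px equivalent diameter or touching the border discarded.

Matching: predicted objects are expanded by 4 px (~2 µm) by
nearest-label assignment (no merging) to absorb residual registration
error, then matched to ground truth by any-overlap: one shared pixel
suffices, a prediction overlapping two ground-truth objects counts one TP
and marks both matched.  Sensitivity = TP/(TP+FN), precision =
TP/(TP+FP); no TN is defined.  Zero denominators raise rather than
return a value.

Morphology per object: area (pixel count), compactness (mean squared
distance of the object's pixels from its centroid, divided by the area),
eccentricity (from the second-moment effective ellipse), integrated
intensity (sum over the object).  Per image: Pearson correlation
(undefined and signaled for constant images), SSIM (Gaussian window
σ = 1.5, K1 = 0.01, K2 = 0.03, data range 1.0), and gray-level
co-occurrence contrast (8 levels, 1 px horizontal offset).  The
evaluation report carries per-image metrics, per-object tables for both
arms, total counts, and 25/50/75 quartiles ready for violin plots.

## Inference

Sliding-window staining emits N−6 slices for an N-slice stack (window k
covers slices k..k+6 and is reported at the central depth); stacks
shallower than seven slices are rejected rather than padded, since
padding would fabricate tissue.  Stacks should be registered first —
slice misalignment degrades the 3D context the network depends on — and
`stain_stack` warns (or auto-registers) otherwise.  Mosaics larger than
one tile are stained tile-wise with overlapping tiles and cosine-ramp
blending; a mosaic no larger than one tile reduces exactly to whole-image
inference.  Exact interior agreement between tiled and whole-image
inference holds beyond the receptive field of the tile border, which for
the full 5-level network exceeds any desk-scale tile; the property is
therefore verified on a 2-level configuration (measured receptive radius
36 px), while seam smoothness of the blended full network is checked
directly.

## Numerical and design notes

- Registration identity: registering an image to itself yields fields
  < 0.25 px; low-texture and weak-correlation pixels receive no update.
- Sub-pixel parabola fits fall back to the integer optimum when the
  curvature vanishes or the optimum sits on the search boundary.
- BerHu with a flat target would have δ = 0; δ is floored at 1e-12 so a
  perfect flat match still scores exactly zero.
- The time-lapse stain ramp is a smoothstep (monotone by construction);
  per-frame drift is constant-velocity with the cumulative field
  recorded per frame.
- Checkpoints are numpy `.npz` state dictionaries (`vsaa.npz`,
  `vshe.npz`, `bridge_A.npz`, `bridge_Aprime.npz`, `dvfnet_B.npz`);
  training curves are plain CSV.
- The full training workflow persists per-stage artifacts and can resume
  from stage checkpoints; with identical seeds the downstream stages
  reproduce exactly.

## Known limitations

- The numpy networks are CPU-bound; everything is exercised at reduced
  resolution, width and budget.  The architecture and losses are
  full-fidelity, the training scale is not.
- Phantom realism is limited to the stated contrast relations; no claim
  transfers to clinical RCM data.
- Registration and staining are slice-wise 2D; volumetric (3D) fields
  are out of scope.
- The "concentration" metric sometimes reported alongside these
  morphology panels has no standard definition; integrated intensity ("nuclear
  reflectance") is computed instead and labeled as such.
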