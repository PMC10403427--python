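# Methods

## Problem setting

Serial-section electron microscopy (ssEM) cuts a tissue block into 30–50 nm
sections that are imaged individually. Sectioning destroys axial continuity
and adds nonlinear in-plane deformation, so the sections must be registered
before biological structures (neurites, mitochondria) can be reconstructed
in 3-D. Registration faces two antagonistic failure modes:

* **Overregistration** — a pairwise registrator driven by pixel similarity
  will happily erase the *genuine* morphological change between adjacent
  sections, flattening every tilted neurite into a pipe perpendicular to
  the section plane.
* **Cumulative error** — registering each section to its already-warped
  predecessor accumulates whatever directional residual each pairwise step
  leaves behind, bending or breaking neurites over long spans.

`emflowreg` implements a registration framework that addresses both: dense
optical-flow pairwise registration whose data term is measured in a
*feature* (descriptor) space rather than pixel space; a rigid anchoring of
the first and last sections; a **structural regression** step that
estimates the total accumulated error and removes a weighted fraction of it
from every interior section; and a split strategy that extends the
procedure to long series.

## Pipeline

Given sections s_1 … s_n (n ≥ 3):

1. **Endpoint anchoring.** s_1 is the undeformed reference. s_n is placed
   by a rigid transform (rotation + translation) estimated from SIFT
   keypoint matches filtered with RANSAC, or supplied externally (by the
   long-series benchmark chain). Neither endpoint is ever deformed.
2. **Sequential registration.** For i = 2 … n−1 the flow
   F_{i→i−1} = E(s_i, ws_{i−1}) is estimated between the raw section and
   the previously *warped* section, and ws_i = φ_F(s_i) is produced by
   backward warping. All flows are backward (target→source) displacement
   maps in pixels, sampled bilinearly for intensities and nearest-neighbor
   for labels.
3. **Structural regression.** Over a short span a neurite is approximately
   a cylinder, so the per-step registration residuals Δe_i share a
   direction and their sum e_i = Σ_{j≤i} Δe_j grows monotonically. The
   total accumulated error is therefore visible as the misalignment between
   ws_{n−1} (deformably registered, carrying the full error) and ws_n (the
   rigid anchor): the flow between those two sections approximates e_{n−1}.
   Each interior section is compensated by warping it with that error flow
   scaled by a per-section weight

       w_i = (Σ_{j≤i} d_j) / (Σ_{j≤n} d_j),   d_1 := 0,

   where d_i = ‖feat(ws_i) − feat(ws_{i−1})‖₂ is the descriptor distance
   between consecutive *warped* sections. Weights are nondecreasing and end
   at w_n = 1; when all distances vanish they fall back to the linear ramp
   (i−1)/(n−1). Endpoints receive no compensation: the full weight lands on
   section n−1, pulling it onto the anchor frame. The sign convention —
   error flow estimated with moving = ws_{n−1}, reference = ws_n and
   applied with positive weight — is fixed by requiring that compensation
   restore known tilted axes on drift phantoms, and is asserted by tests.
4. **Long series.** Structural regression relies on the cylinder
   approximation, which fails over long spans. A long stack is split into
   `n_segments` near-equal short series that share single boundary sections
   ("benchmarks"): with shared boundaries the segments occupy
   n_total + n_segments − 1 slots, the base length is slots / n_segments,
   and earlier segments take one extra slot each until the remainder is
   spent. The benchmarks form a coarse series of their own and are rigidly
   chained (pairwise SIFT+RANSAC, composed into the first benchmark's
   frame); each short series is then registered and compensated
   independently with its endpoints pinned by the chain, and the results
   are restacked (each shared benchmark emitted once, at its exact rigid
   placement). `n_segments` is a user choice: more segments when error
   accumulates quickly, fewer when it does not.

## Descriptors

The per-pixel descriptor standing behind the photometric loss and the
weights is a fixed multi-scale bank: Gaussian-smoothed intensity and both
first derivatives at σ = 1, 2, 4 px (nine channels), each channel
standardized to zero mean and unit variance per image. Standardization
makes the features exactly invariant to global affine intensity changes
(a·img + b, a > 0) and insensitive to contrast drift between sections; the
derivative channels emphasize *where* structure sits over *how* it looks,
which is the property the framework needs from a descriptor. The extractor
is deterministic and training-free, so every downstream formula is exactly
testable; a learned per-pixel descriptor model can be substituted through
the same interface (`CallableExtractor`).

## Pairwise flow estimators

Two backends implement one interface.

**Classical (default).** A coarse-to-fine pyramid (up to five octaves, 2×
per octave, coarsest side ≥ 16 px) with iterative multi-channel
Lucas–Kanade refinement computed on the descriptor maps of both images.
Numerical safeguards, each adopted after observing a concrete failure mode
on synthetic data: per-iteration updates are clipped to 1 px and Gaussian
smoothed (undamped iteration can diverge); out-of-bounds warp samples are
masked out of the windowed normal equations (edge-fill bands otherwise drag
the solution on large displacements); the per-level loop early-stops when
the mean update drops below 0.01 px and keeps the lowest-residual iterate;
and the coarsest level is seeded with a global translation from phase
correlation, which extends the capture range to the 15–30 px shared drifts
the long-series chain must survive.

**Learned ("pwc-lite" style).** A coarse-to-fine cost-volume matcher: the
frozen descriptor pyramid provides per-level unit-normalized features; at
each octave a local correlation volume (search radius 4 px) is decoded into
a flow increment by a temperature-controlled soft-argmax and Gaussian
smoothing, and flows are upsampled ×2 between octaves. The trainable
parameters are three per level (log-temperature, gain, log-smoothing-σ) —
a deliberately small vector, so the model trains by plain stochastic
gradient descent with simultaneous-perturbation (SPSA) gradient estimates
of the unsupervised loss, two function evaluations per step, without an
autodiff dependency. The coarsest level keeps at least 4× the search radius
per side; cost volumes on smaller levels sample mostly padding and are
counterproductive. Inference is deterministic for fixed parameters; inputs
whose sides are not multiples of 2^(levels−1) are reflect-padded and
cropped back.

**Losses.** Training minimizes L = L_ph + λ_s·L_smooth + λ_a·L_aug:

* L_ph — squared L2 distance between the descriptors of the reference and
  the descriptors of the *warped moving image* (features of the warp, never
  a warp of the features), normalized by pixel·channel count so λ values
  are resolution-independent.
* L_smooth — mean Charbonnier penalty (ρ(x) = √(x²+ε²) − ε, ε = 10⁻³) of
  the finite differences of both flow components.
* L_aug — augmentation consistency: the prediction on the original pair,
  held fixed as a pseudo-label and transported through a sampled spatial
  transform (small rotation + shift, with gain/bias appearance jitter),
  must match the prediction on the augmented pair over the validly
  transported region (Charbonnier distance, masked mean).

Defaults λ_s = 5.0 and λ_a = 0.25 were calibrated once so that on typical
synthetic pairs the smoothness term is about half and the augmentation term
about a fifth of the photometric term; both are exposed in configuration.
Training hyperparameters (batch 4, learning rate 0.05 with 1/(1+0.01·t)
decay, perturbation 0.05, step clip 0.2) are package configuration, not
derived quantities.

## Synthetic data

The generator provides every ground truth the tests need.

* **TPS deformation.** Thin-plate-spline fields (r²·log r kernel plus
  affine part, via `scipy.interpolate.RBFInterpolator`) interpolate
  displacement vectors drawn i.i.d. from N(0, σ²) at control points placed
  uniformly inside a margin. Eight zero-displacement anchors at the frame
  corners and edge midpoints pin the section frame: without them the
  spline's affine part extrapolates without bound outside the control hull
  (fields an order of magnitude larger than the control vectors), which is
  neither a realistic sectioning deformation nor recoverable. Every random
  control vector is still exactly interpolated. Defaults: 10 controls,
  σ = 4 px, margin 16 px. Fields are returned in the backward convention;
  registration pairs also carry the fixed-point-inverted field, i.e. the
  ground truth for the moving→reference direction.
* **Cylinder phantoms.** Each neurite is a disk whose center moves linearly
  with section index (a tilted cylinder, the geometry the cumulative-error
  model assumes), with a membrane ring and interior texture that travels
  sub-pixel-accurately with the disk, over a static textured background
  with per-section sensor noise. Tilts are drawn uniformly within a bound
  and centered to zero mean; `margin_px` reserves border room so injected
  drifts keep every tube in frame. Ground-truth per-section centroids are
  returned.
* **Drift injection.** Translating section i by the prefix sum Σ_{j≤i} δ_j
  constructs a stack whose interiors carry exactly the cumulative error
  e_i = Σ Δe_j of the error model; this is the input for the compensation
  experiments (a stack standing in for a sequential-registration result
  with known accumulated error, its last section at the rigid anchor
  placement). Re-registering a pre-drifted stack instead would let the
  pairwise estimator absorb the drift and collapse the tilts, confounding
  the quantity under test.
* All randomness flows from a single seed through named substreams
  (controls, vectors, geometry, texture, noise), so components are
  independently reproducible and bit-identical across processes.

## Evaluation

* **NCC** — zero-normalized cross-correlation in [−1, 1], computed over an
  optional mask (by default the warp-validity intersection should be used
  so border fill does not depress scores); undefined inputs (zero
  variance, < 2 pixels) raise rather than return a silent value.
* **Dice / top-k Dice** — per-label Dice 2|A∩B|/(|A|+|B|); the headline
  score selects the k = 50 largest-area nonzero labels on the *first*
  ground-truth section (ties broken by ascending id) and averages their
  whole-volume Dice, so axial breaks depress the score even when single
  sections overlap well. Fewer than k labels: all are used and the count is
  reported.
* **Endpoint error** — mean Euclidean distance between estimated and
  ground-truth displacement vectors, in pixels.

## Problem sizes and reference results

The reference experiments (module `emflowreg.experiments`, re-run from
scratch by `scripts/acceptance.py`) use: 128×128 textured pairs for flow
recovery (10 seeds); 16-section 160×160 phantoms with 8 neurites for the
drift and serial studies (drift δ = (1, 0) px/section for the former, per-
section TPS σ = 3 px for the latter); 27-section stacks split 3 ways for
long-series checks; and 50 64×64 TPS pairs, 100 SGD iterations, 20 held-out
pairs for the training study. With the default classical estimator these
sizes give (seed 0): shift EPE ≈ 0.04 px, TPS EPE ≈ 6–9 % of the mean true
displacement, ≈ 80 % median reduction of centroid RMS by structural
regression, top-k Dice 0.77 → 0.94 and NCC-to-ground-truth 0.71 → 0.88
for the end-to-end phantom study, and a decreasing training loss with the
trained model beating the identity NCC baseline on 20/20 held-out pairs.

## What the synthetic studies do and do not show

The phantoms reproduce the *geometry* of the problem (tilted tubes, shared
drift, local nonlinear deformation) but not the appearance statistics of
real EM: no section folds, cracks, dust, staining or charge artifacts, no
genuine inter-section morphological change beyond the linear tilt, and far
less texture than tissue. Passing these studies demonstrates that the
mechanics — warping conventions, error estimation, weighting, stacking —
are correct and that the estimators recover the deformations the generator
produces; it does not certify accuracy on real ssEM volumes, which depends
on descriptor quality and on artifacts this package explicitly does not
model (folds and cracks are out of scope).

## Degenerate inputs and tie-breaks

Stacks need n ≥ 3 and sections ≥ 8 px per side; intensities are normalized
to [0, 1] at load time by the storage dtype's full range. Center crops put
odd remainders' extra pixel on the leading (top/left) side. Image-sequence
ordering is lexicographic and requires zero-padded numeric names; mixed
widths are rejected rather than guessed. Collinear TPS control draws are
resampled from the next substream. Rigid registration raises a typed error
on keypoint-poor or pure-noise inputs instead of returning a silent
identity. Flow storage order is (dy, dx), dy first.
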