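# Methods

`nigraseg` implements a fully automated pipeline for segmenting the
substantia nigra (SN) from neuromelanin-sensitive MRI (NM-MRI) volumes and
for turning the segmentation into a Parkinson's-disease (PD) screening
statistic. This note describes the models and procedures, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical conventions the implementation commits to.

## Pipeline

Input is an NM-MRI volume with a paired T1-weighted volume; output is a
binary SN mask, a voxelwise uncertainty map, the SN hyperintense region and
a PD/HC call. Stages:

1. **Prior construction (training time).** From a training subset (default
   20 subjects), every candidate volume is affinely registered to every
   other; the candidate whose propagated SN label attains the highest mean
   Dice against the others' annotations becomes the *template*. All other
   subjects are then registered to the template and their binary SN labels
   accumulated; the *SN-prior probability map* (SPPM) is the voxelwise
   label frequency normalized by the number of contributing subjects
   (template's own label included), so every voxel holds a multiple of
   `1/n`.
2. **ROI localization (inference).** The template is registered to the
   input scan, carrying the SPPM with it; a cubic ROI (64 voxels full
   scale, 32 at desk scale) is centred on the registered prior's argmax
   voxel (lexicographically smallest index on ties) and shifted — never
   shrunk — to fit the grid.
3. **Segmentation.** A priority-gated attention 3D U-Net maps the
   normalized ROI plus the SPPM crop to voxelwise SN probabilities;
   test-time dropout (TTD) aggregates N stochastic passes into a mean
   probability map and a population-standard-deviation uncertainty map;
   the mean is binarized at 0.5 (strict) and stitched back into the full
   grid.
4. **Hyperintensity.** A 2D U-Net with TTD segments the midbrain from
   axial T1 slices. The hyperintensity cut-off is `t = mu + alpha * sigma`
   (`alpha = 1.5`) with `mu`, `sigma` the mean and population standard
   deviation over midbrain-minus-SN voxels; the hyperintense region is the
   set of segmented-SN voxels strictly brighter than `t`.
5. **Identification.** A case is called PD when its hyperintense size is
   strictly below a criterion: either the area in the axial slice with the
   largest SN cross-section (default 61.2 mm²) or the total voxel count
   (default 400 voxels). Sweeping the criterion yields the ROC; the AUC is
   computed tie-aware as the probability that a random PD case scores
   below a random HC case.

## Registration

The paper-level contract is "affine registration"; the algorithm is this
package's choice: SimpleITK multi-resolution optimization of normalized
correlation, run in two stages — a similarity transform (rotation,
isotropic scale, translation) from a moments initialization, then a full
affine polish. The metric is restricted to a dilated bright-foreground mask
of the fixed image: on head-sized fields of view the uniform background
otherwise flattens the rotation basin so severely that optimizers stall
several degrees from the optimum. Full metric sampling and fixed iteration
budgets make results deterministic. On phantoms with known poses (±10°
rotation, ±5% scale, ±5 mm translation) the recovered transform is
typically within 0.1 mm / 1° of truth; failures fall back to the identity
transform flagged `success=False`.

## Networks

Both networks are encoder–decoders with two 3×3(×3) convolutions +
instance normalization + ReLU per level, strided-convolution downsampling,
nearest-upsampling + convolution decoding, and a 1×1 sigmoid head. Channel
widths double per level from a base of 16 (desk scale: 8). Instance
normalization is used because mini-batches of two make batch statistics
unreliable. Attention gates follow the additive formulation; the priority
variant derives its gating signal from the SPPM crop through one learned
strided convolution per level (stride 2^level), so the prior steers
attention at every scale. Spatial dropout (rate 0.2) after every
convolution block except the first encoder level doubles as Monte-Carlo
dropout for TTD. The output convolution's bias is initialized to −2 so the
untrained network predicts background; with a foreground occupying well
under 1% of the ROI this removes the large false-positive term from the
initial loss and roughly halves the epochs needed to converge.

The networks are built on an in-repo reverse-mode autodiff engine over
numpy (im2col convolutions forward, transposed-convolution matmuls
backward), dimension-agnostic between the 2D and 3D models. Every
primitive's gradient is pinned against finite differences in the test
suite.

## Training

Asymmetric similarity loss (soft F-beta, beta = 1.5, so false negatives
weigh more than false positives — appropriate for a tiny target), Adam,
mini-batch 2, random 3D rotation augmentation (±10° per axis), model
selection by best validation Dice at threshold 0.5 with dropout off.
Defaults follow the full-scale recipe (learning rate 0.001, up to 1000
epochs); the desk-scale configurations used by the tests and the
acceptance script train a depth-3, base-8 network on 32³ ROIs for a few
dozen epochs at learning rate 0.01 — the higher rate compensates for the
~100× shorter schedule and is validated by the convergence tests. Desk
training additionally adds fresh Gaussian noise (SD 0.03 on the
normalized crop) to each training image per step, exposing the network to
new noise realizations every epoch; under the phantom noise model this
measurably improves boundary robustness on held-out subjects. The
loss uses soft counts with epsilon 1e−6; at beta = 1 it reduces exactly to
the soft-Dice loss (tested in closed form).

## Test-time dropout

`s = mean`, `u = population std` over N dropout-on passes (N = 30 default;
desk runs use 6–10). The population (1/N) convention is deliberate and
consistent between the uncertainty map and the hyperintensity sigma. With
dropout rate 0 or N = 1 the uncertainty is exactly zero and the mean equals
the single deterministic pass. Passes are batched through the network in
chunks of 8 for throughput; the stream of dropout masks is seeded, so
results are reproducible.

## Synthetic phantoms

No public NM-MRI dataset with SN annotations exists, so the package ships
a phantom generator that every stage is tested against. A phantom is a
96×96×64, 1 mm isotropic volume containing a bright midbrain ellipsoid
(semi-axes 16/13/11 mm), two mirrored crescent-shaped SN regions built as
the difference of offset ellipsoids (concave, partial-volume-blurred
boundary), and one small hyperintense spherical core per crescent standing
in for nigrosome-1. The NM channel stacks four tissue intensities
(background 90, midbrain 140, SN 152, core 185–200); the T1 channel has
midbrain contrast only. Gaussian smoothing (0.7 mm) then Gaussian noise
(SD 5) emulate the partial-volume "vague boundary" regime: SN-vs-midbrain
contrast is about 2.4 noise SDs. Each subject receives a random
similarity pose (rotation ±10° per axis, isotropic scale ±5%, translation
±5 mm); masks are evaluated analytically under the pose, so ground truth
is exact and the generating affine doubles as the registration oracle.

Cohort structure mirrors the clinical picture: PD phantoms draw SN
crescents scaled by 0.89 ± 0.04 versus 1.0 ± 0.04 for HC (SN volumes of
roughly 210 vs 290 mm³, near reported annotated volumes), and hyperintense
cores of radius 1.1 ± 0.1 mm versus 1.5 ± 0.1 mm with lower core contrast
(185 vs 200). Both effects shrink the PD hyperintense signal, which is
what the identification statistic detects.

What the phantoms do **not** emulate: Rician noise statistics (Gaussian is
the default; Rician is out of scope), intensity inhomogeneity/bias fields,
anisotropic clinical voxels (0.43×0.43×3 mm), anatomy beyond the
midbrain/SN, inter-subject shape variability beyond affine pose and
isotropic scale, and annotation noise. Passing tests therefore demonstrate
that the machinery is correct and that the pipeline discriminates cohorts
whose effect sizes are built in — not that clinical accuracy figures
transfer.

## Numerical conventions and edge cases

- Voxel coordinates are 0-based; boxes are half-open `[lo, lo+edge)`;
  physical volume = voxel count × voxel volume from the NIfTI affine.
- `dice(empty, empty) = 1`; precision/sensitivity 0/0 is 1 only when both
  masks are empty, else 0.
- Inter-rater reliability `r = |A1 ⊙ A2| / |A1|` uses voxel counting, so it
  is the fraction of the reference annotation confirmed by the second
  rater; it is deliberately asymmetric.
- Bhattacharyya distance: 64 equal-width bins over the union range;
  zero-product bins contribute nothing; disjoint supports are capped at
  `ln(1e6)` with a warning.
- Intensity normalization: percentile-clipped (0.5/99.5) min–max to [0, 1],
  applied to the ROI crop (not the full volume) so the background does not
  compress the midbrain/SN contrast; constant inputs map to 0.5 with a
  warning.
- Hyperintensity and identification comparisons are strict (`>` for
  brighter-than-t, `<` for smaller-than-criterion), so scores exactly at a
  boundary are negative.
- Registration ties in template selection resolve to the lowest subject
  index; SPPM argmax ties resolve lexicographically.

## Design choices that were genuinely open

- **Template's own label in the SPPM count:** included, with the subset
  size as denominator — this keeps the prior's support covering the
  template's own SN and keeps values exact multiples of `1/n`.
- **Attention resampling direction:** the classic gate reduces the skip
  feature to the gating grid (kernel-2 stride-2 projection) and upsamples
  the coefficient map linearly back; the priority gate operates at the
  skip's own scale because the SPPM branch already produces
  matched-resolution features.
- **Hyperintense domain:** restricted to the segmented SN (configurable to
  the whole midbrain), since the statistic is defined as the hyperintense
  region *of the SN*.
- **Sigma conventions:** population (1/N) everywhere (TTD uncertainty and
  hyperintensity background), keeping the two equations consistent.
- **Binarization threshold 0.5, strict:** no threshold is prescribed for
  the probability maps; 0.5 with a strict inequality is the neutral choice
  and the tie rule is pinned by tests.

## Problem sizes

Desk-scale defaults keep every workflow single-CPU friendly: phantom grids
96×96×64; prior bundles built from 5 subjects; 3D training on ~12 ROI
crops of 32³ for ≤60 epochs (minutes, not hours); TTD with 6–10 passes in
cohort evaluations; evaluation cohorts of 30 HC + 30 PD. Full-scale
settings (64³ ROI, base 16 channels, depth 4, N = 30, 1000 epochs) are
reachable through the same configuration objects.

## Known limitations

- The registration defaults are tuned for head-sized single-modality
  volumes with a bright central structure; cross-modality use requires
  switching the metric to mutual information (`metric="mattes"`).
- numpy-based training is practical at desk scale only; full-scale
  training (64³, depth 4, 1000 epochs) is supported by the code but slow
  without a GPU framework.
- The identification criteria (61.2 mm², 400 voxels) are clinical values
  carried over as defaults; on phantoms they are arbitrary units, and
  cohort discrimination is therefore reported as AUC rather than at a
  fixed criterion.
- `evaluate_cohort` treats per-case failures as skips with a logged id;
  systematic registration failure (e.g., non-brain inputs) is not
  distinguished from sporadic failure.
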