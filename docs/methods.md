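# Methods

`aneucad` implements a two-step computer-assisted detection (CAD) system
for cerebral aneurysms in time-of-flight MR angiography (TOF-MRA):
fully automatic artery segmentation first, then per-voxel aneurysm
detection with a 3D fully convolutional network, followed by
sphere-marker post-processing and a lesion-level evaluation protocol.
This note records the model, its assumptions, the tunable parameters,
the synthetic data used to validate it, and the design decisions taken
where the procedure was genuinely open.

## Step one: automatic artery segmentation

The segmentation stage assumes the TOF-MRA intensity regime: flowing
blood and the skull/scalp rim are the bright structures, the brain
parenchyma and air are dark, and vessel voxel intensity is approximately
Gaussian, `N(mu, sigma)`.

1. **Bias-field correction.** A smooth multiplicative shading field is
   estimated with the N4 algorithm (the modern successor of N3; 3
   fitting levels, 50 iterations per level, estimated on a 2x-shrunk
   copy) and divided out; the output is rescaled to preserve the global
   mean.  A near-constant image (foreground coefficient of variation
   below 1e-3) is returned unchanged: the histogram-sharpening step of
   the estimator is degenerate there and there is no bias to remove.
2. **Histogram normalization** (optional, off by default for
   single-case runs): a monotone piecewise-linear map aligning the
   volume's foreground deciles to a reference scan.  It matters only
   when a trained model is applied across scanners; with no reference
   there is nothing to align to.
3. **Sigmoid vessel enhancement.**  Voxelwise
   `f(x) = (Max - Min) / (1 + exp(-(x - beta)/alpha)) + Min` with
   `alpha = 400`, `beta = 600`.  `Max`/`Min` default to the input's own
   extrema, so the transform is a contrast remap inside the native
   dynamic range; this keeps the later *relative* thresholds (30 % of
   the maximum) meaningful, which a fixed rescale to [0, 1] would not.
4. **Skull stripping.**  A bounding cube is shrunk onto the head: from
   the centre of each of the six volume faces a ray marches inward and
   the first voxel at or above the contact threshold (default: the same
   30 %-of-maximum used for growing) seeds an auto-threshold region
   growing with band `[0.30 * max, max]`.  The grown mask is smoothed by
   binary morphological closing (ball radius 2 — fills contact gaps
   without growing thin structures) and the shell is cut to the
   background value (the volume minimum).  Face-centre rays (rather than
   all face contact points) are used; one seed per face suffices because
   the shell is connected within the growing band.
5. **Vessel segmentation.**  The stripped volume is binarized strictly
   above the background level (Otsu threshold by default — the
   background level is otherwise undefined), 26-connected components are
   ranked by voxel count, and the top five are taken as seed regions —
   in practice the main arterial branches.  The Gaussian vessel model is
   fitted over the union of those components (sample mean, n-1 standard
   deviation), and region growing with band `[mu - sigma, mu + sigma]`
   from one seed per component yields the vessel mask.
6. **Mesh and VOI.**  The vessel surface is extracted by marching cubes
   (iso-value 0.5 on the 1-voxel zero-padded mask, so border-touching
   masks still close), with vertices in world millimetres.  The vessel
   mask dilated by a Euclidean sphere of radius 10 voxels is the volume
   of interest (VOI) passed to the detector; the dilation is computed
   via the exact Euclidean distance transform, which is equivalent to
   binary dilation with the lattice ball and much faster at radius 10.

**Seed placement inside a component.**  The nominal seed is the
component's maximum-intensity voxel (deterministic, favours the vessel
core; ties broken by lexicographic index).  Under the Gaussian intensity
model, however, the maximum of a few thousand draws lies far above
`mu + sigma`, i.e. *outside* the automatic growing band, for essentially
every real or simulated vessel.  The composite segmentation therefore
relocates any out-of-band seed to its component's in-band voxel with
intensity closest to `mu` (deterministic tie-break).  Growing still
starts inside the main branches and the output intensities all lie in
`[mu - sigma, mu + sigma]`.

Connectivity is 26-neighbourhood throughout (standard for bright tubular
structures); region growing is implemented as connected-component
labelling of the threshold band, which is exactly equivalent to
flood fill and is verified against a brute-force BFS oracle in the
tests.

## Step two: detection network

The detector is an encoder–decoder fully convolutional network of the
improved 3D-UNet family: residual *context blocks* (two 3x3x3
convolutions with instance normalization and leaky ReLU around an
identity shortcut) at each of `depth` resolution levels, 2x max-pool
downsampling with a channel-doubling convolution, nearest-neighbour
upsampling with a channel-halving convolution, skip concatenation
(the context aggregation pathway) and a two-convolution localization
block per decoder level.  Segmentation heads (1x1x1 convolutions to two
classes) sit on the final decoder level and on the
`deep_supervision_levels` levels below it; the auxiliary heads are
upsampled and summed into the output, so their gradients are injected
deep into the decoder (deep supervision).  Weights are Glorot-uniform
initialized from a stated seed; all computation is float32 numpy with a
purpose-built reverse-mode autodiff tape (the gradient of every op is
verified against directional finite differences in the tests).

Two topologies are exercised:

| scale      | block    | depth | base filters | aux heads |
|------------|----------|-------|--------------|-----------|
| full       | 128^3    | 4     | 16           | 2         |
| test (CPU) | 32^3     | 3     | 4            | 1         |

The full-scale topology reproduces the study protocol; the test scale
runs the identical code on one CPU in minutes and is what the test
suite and the synthetic study use.

**Training.**  Loss is the equally weighted sum of voxelwise softmax
cross-entropy and soft Dice on the summed output (the standard
companion of this architecture family; no loss is part of the stated
protocol).  Optimization is Adam at batch size 1.  The full-scale
learning rate is 5e-4; at test scale one block is one gradient step per
epoch, so the scaled-down study uses 1e-3 to reach convergence within
the ~200-epoch early-stopping budget.  Early stopping monitors a
held-out validation split (10 % of blocks) when one is used; the
scaled-down study instead monitors training loss (a 2-block validation
split is statistically meaningless), with patience 15.  The
best-monitored-loss weights are restored.

**Inference.**  The preprocessed, skull-stripped volume is masked by
the VOI, cropped to content, resampled to the network block and
z-scored using the statistics of the VOI voxels — the region the model
actually reads — so vessel contrast is on a comparable scale however
much of the block the VOI occupies.  The block is passed through the
network; the softmax aneurysm probability is
zeroed outside the VOI.  Probabilities are binarized strictly above
0.5; each 26-connected component of at least `min_component_size`
voxels (default 5 — suppresses single-voxel noise; the protocol states
no floor) becomes one detection: a sphere at the component centroid
with the same radius used to dilate the training annotations, scored by
the component's maximum likelihood, and mapped back to
original-resolution world coordinates through the block grid's spacing.

## Training-set preparation

Each (image, label) pair is expanded 8-fold: the full factorial of
transverse flip, discrete Gaussian smoothing (variance 4.0 voxel^2,
kernel width capped at 32 taps), and histogram equalization, applied in
that order and including the identity.  The factorial structure is what
the stated counts pin down (76 -> 608, 20 -> 160, 96 -> 768 are all
x8).  The "discrete Gaussian noise filter" is implemented as discrete
Gaussian *smoothing* — the parameter names (variance, max kernel width)
belong to that filter family, not to additive-noise injection.  Labels
are categorical and undergo only the flip.  Volumes are cropped to
content and resampled to the block size (linear for images, nearest for
labels — no new label values).  Aneurysm annotations are replaced by
filled spheres of shared radius `max(4, ceil(0.03 * axis))` at the
component centroid, drawn in block space (the radius rule reconciles
"above 3 voxels" with "above 3 % of the axis" at a 128 axis).

## Evaluation protocol

A detection sphere is a true positive iff strictly more than 30 % of
some annotated aneurysm's voxels lie inside it (overlap is always
measured on the aneurysm's side); an aneurysm is detected if at least
one detection captures it; one sphere capturing two aneurysms is a
single TP that marks both detected.  Sensitivity is
`100 * detected / total` (one decimal); the false-positive rate is
`FP detections / cases` (two decimals).  Subgroup sensitivities are
reported for sex, age band (< 60 / >= 60 years), hypertension, size bin
(< 3.0, 3.0-4.9, 5.0-9.9, >= 10.0 mm) and arterial location; an empty
stratum is *undefined*, never 0.  k-fold splitting is seeded and
deterministic.

## Synthetic phantoms

The phantom generator emulates the intensity statistics the pipeline
assumes, not anatomy:

- dark noisy background (`N(50, 10)`, clipped at 0);
- a bright spherical shell (intensity ~1200) hugging the volume
  periphery — the brightest structure, so the bounding-box rays and the
  30 %-of-max band find and remove it.  Anatomically the bright rim in
  TOF is scalp fat rather than bone; the phantom is faithful to the
  algorithm's assumption, not to anatomy;
- an arterial tree of smoothed 3D random-walk centerlines (default 3
  branches, tube radius 2-3 voxels) with i.i.d. `N(300, 20)` voxel
  intensities;
- aneurysms as spheres displaced from a random centerline point by
  `r_vessel + r_aneurysm - 1`, i.e. overlapping the vessel wall,
  sharing the vessel intensity law (radius 3-6 voxels by default);
- an optional smooth multiplicative bias field (cubic-interpolated 4^3
  Gaussian grid), off by default;
- a guaranteed dark moat (4 voxels) between shell and tree, so skull
  stripping provably cannot remove vessels, and an attachment rule that
  keeps every aneurysm within 10 voxels of vessel, so 100 % VOI
  coverage is achievable.

Default phantom size is 64^3 at 1 mm; cohort generation jitters the
per-case mm spacing so physical aneurysm diameters span the requested
size bins while voxel radii stay in range, and draws patient metadata
(sex ~63 % female, age ~N(57, 14), hypertension ~50 %, location
weighted toward the internal carotid artery) so the subgroup code paths
are exercised.  Everything is deterministic given the seed.

**What the phantoms do not model:** partial-volume effects, flow
artefacts and in-plane saturation, vessel caliber tapering, true
aneurysm morphology (lobulated, fusiform), skull-base signal, and
inter-scanner intensity variation.  Passing the synthetic study shows
the pipeline's machinery is correct and self-consistent at desk scale;
it does not certify clinical performance.

## Scaled-down study conditions

The synthetic end-to-end study trains on 20 phantoms and tests on 8
held-out phantoms at the test-scale topology, without the 8-fold
augmentation (at one CPU it multiplies training time roughly eightfold;
measured on this study it also reduced held-out sensitivity, so the
desk-scale protocol trains unaugmented); training runs at most 200
epochs with patience 15 on training loss and in practice stops near
epoch 90.  Detection quality is summarized over two replicate studies
(two cohort seeds) rather than a single 8-case test set, since one
miss in so small a sample moves the rate by 12-17 points.  The
VOI-coverage check uses 10 phantoms at the default 64^3 spec.  These
sizes are the package's desk-scale protocol; the full-scale settings
remain the defaults of `PipelineConfig`.

## Numerical choices and degenerate inputs

- Region growing drops out-of-band seeds with a warning and errors only
  when none remain; the composite vessel segmentation relocates such
  seeds as described above.
- A constant seed-component sample floors `sigma` at a machine-epsilon
  scale with a warning rather than failing.
- Component ranking ties break toward the smaller lexicographic
  centroid; in-component seed ties toward the smaller lexicographic
  index — all orderings are deterministic.
- Strict inequalities throughout: foreground is `> background`,
  aneurysm is `likelihood > 0.5`, a true positive needs overlap
  `> 0.30`.
- Volumes must be finite; spacing positive; label volumes carry a
  legend and reject unknown labels.
- The detection-count-vs-threshold relationship is monotone for
  blob-shaped likelihood fields (the detector's actual output regime)
  and is tested there; it is not a theorem for arbitrary fields, where
  raising the threshold can split components.

## Known limitations

- The numpy network trains at one gradient step per block (batch 1); at
  full 128^3 scale a training run is CPU-days, so full-scale results
  are not part of the test suite — the topology is, and the identical
  code runs at both scales.
- DICOM support covers single-series scalar axial stacks; multi-frame
  and oblique acquisitions are reoriented or rejected on read.
- The bias-field stage assumes non-negative intensities.
- Histogram normalization needs an explicit reference volume; the
  pipeline skips it otherwise.
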