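# Methods

## Problem and model

The package segments femur (class 1) and other bone (class 2, pelvis /
acetabulum) in 3D CT of the hip, slice by slice. The difficulty concentrates
at the femoral-head/acetabulum interface, where the joint space can be
narrowed or destroyed in diseased hips. The system divides the task in two:
separating bone from soft tissue (easy, intensity-driven) and separating
femur from acetabulum (hard, shape-driven), with a third module suppressing
false positives on slices that contain no femur at all.

**Bone/soft-tissue separator.** A modified 2D U-Net with exactly two 2×2
max-pooling stages and two stride-2 transposed convolutions. Each of the five
resolution blocks (two encoder, bottleneck, two decoder) holds three 3×3
convolutions; a final 1×1 convolution projects to a sigmoid bone probability.
That makes 15 convolutions + 2 deconvolutions + 1 projection = 18
parameterized layers. Pooling layers carry no trainable weights, take no part
in backpropagation, and are excluded from the count. The 3-convs-per-block
decomposition is this package's reading of the 18-layer total; the count and
the pooling-exclusion rule are verified by `count_parameterized_layers` and
are invariant to channel width.

**Main femur segmenter.** `stack_count` (default 2) encoder–decoder
hourglasses in sequence, each again with two pooling and two deconvolution
stages and two 3×3 convolutions per block. Dense connections span the whole
stack: a block at a given resolution receives the channel-concatenation of
every earlier same-resolution block output (the fused input seeds the
full-resolution registry). Each hourglass ends in its own 1×1 sigmoid head;
all heads are trained (intermediate supervision), the last is the
prediction. Ablating the dense connections (`dense_connections=False`)
changes the parameter count by an amount computable in advance from the
layer tables in `plan_main_hourglass`.

**Fusion.** The separator's output is fused into the main net by channel
concatenation at the input resolution. The fusion tensor is the *bone
probability map* (one channel): during training the ground-truth bone mask
plays this role, at test time the separator's prediction does. Using the
probability map rather than a wider feature tensor is what makes the
train-time contract (ground-truth masks as fusion input) and the test-time
contract (predicted features as fusion input) type-compatible; the separator
still exposes its full-resolution feature tensor for experimentation.

**Slice classifier.** Twelve 3×3 convolutions in four blocks with 2×2
pooling after each, global average pooling, then two fully connected layers
(14 parameterized layers total) ending in a sigmoid femur-presence
confidence. It consumes the bone-windowed input — the same one the separator
sees — because femur presence is a bone-shape question; the choice of window
here was open and this is the package's decision. At inference each
half-slice is gated by its own confidence (elementwise product with the
femur probability map, before the fixed 0.5 threshold); the reported
per-slice confidence is the maximum of the two halves.

## Preprocessing

Hounsfield windowing maps `[level − width/2, level + width/2]` linearly to
[0, 1] with clamping — the symmetric level/width convention. Two windows are
used: 40/200 HU (bone highlight; saturates at −60 and +140 HU) and 500/1000
HU (femur input; suppresses soft tissue). The 200 HU bone threshold utility
uses an inclusive comparison (HU ≥ 200); strictness was unspecified and does
not matter for realistic noise.

Slices are resized to the network input size — bilinear for images, nearest
neighbour for labels (preserving the label value set). Resizing, not
cropping, was the open choice here. The mid-split/mirror augmentation cuts
each slice at the middle column and flips the right half left-right, so one
H×W slice yields two H×(W/2) samples that both look like left hips; it is
applied at train and test time, and the inverse (un-flip, concatenate) is
exact. Recombination of the two half-predictions was unspecified;
concatenation of the un-mirrored halves is the chosen inverse.

## Losses and training regime

The segmentation loss is `L = a·diceLoss + b·crossEntropy` with ε = 1e−6 in
the soft-Dice ratio and probability clamping at 1e−6 in the cross-entropy;
`a = b = 1` by default (the weights are declared hyper-parameters without
stated values). Intermediate supervision sums `head_weights[i] ·
L(head_i)`, default `(0.5, 1.0)`. The cross-entropy supports a
positive-class weight for imbalance; default 1.

The three stages train independently with Adam (lr 1e−3, desk-scale choice)
on the mirrored half-slice dataset: the separator on all slices against the
bone mask; the main net only on femur-positive halves, with the ground-truth
bone mask as fusion input; the classifier on all halves against the per-half
femur flag. `assemble` wires the trained handles into the test-time
pipeline. Joint fine-tuning after assembly is not implemented: the training
regime is the independent-then-assemble reading, which the modular design
favours. Seeded, single-threaded runs reproduce loss trajectories exactly.

## Networks on CPU

The models run on a compact reverse-mode autodiff engine written on numpy
(`hipseg.engine`): im2col convolutions, stride-2 transposed convolutions,
2×2 max pooling, channel concatenation, dense layers, sigmoid/ReLU, soft
Dice and binary cross-entropy, and Adam. Analytic gradients of every
primitive are tested against central finite differences in float64.
Activations are float32; interior gradient buffers are freed as
backpropagation proceeds and column matrices are recomputed in the backward
pass, keeping peak memory around 2 GB at the default problem sizes.

## The phantom generator

`hipseg.phantom` emulates the data regime the system expects: 3D volumes
with 12-bit stored intensities (air at stored 0 = −1024 HU), per-axis mm
spacing, soft-tissue body on air background, bone rendered as a bright
cortical shell (default 1200 HU) over trabecular interior (300 HU), and
additive Gaussian noise (default σ = 30 HU). Geometry is
parametric-primitive — femoral head sphere, oblique neck, vertical shaft,
hemispherical acetabular cup shell, iliac slab — not atlas-based; this is
sufficient to exercise windowing, the networks and the metrics without any
clinical-data dependency. The superior slices contain pelvis but no femur,
guaranteeing genuine negatives for the classifier. All geometry scales with
the physical extent, so the same spec works at the 64×64×60 / 3 mm default
and at 512×512 clinical resolution.

Disease-like variants deform the labels before rendering, locating the head
as the femur's largest inscribed sphere (Euclidean distance transform) so
the operations work on any labelling with a femur: OA adds osteophyte-like
rim protrusions to head and cup; ONFH subtracts a crater from the superior
head; FNF clears a two-slice gap through the neck (splitting the femur into
head and shaft components); DDH removes the lateral cup and displaces the
head superolaterally (≈0.7 r lateral, 0.2 r superior, with seeded jitter).
Severities are free parameters chosen for visual plausibility; no published
geometric description of the clinical cases exists, so they are *not*
calibrated to Crowe/ARCO/Garden stages. The phantoms share none of the
texture, anatomy variability, partial-volume or artefact structure of real
CT: passing the end-to-end tests demonstrates that the pipeline's mechanics
(windows, fusion, supervision, gating, re-stacking, metrics) work as
specified, not that clinical-grade accuracy transfers.

## Evaluation metrics

DOC is computed on full voxel sets. Hausdorff and mean surface distance are
computed on surface voxels (class voxels with a 6-connected neighbour
outside the class), with Euclidean distances scaled by the per-axis spacing;
this follows standard surface-distance practice, and HD on surfaces is *not*
guaranteed to equal HD on full sets, which is documented rather than hidden.
MSD is the symmetric average nearest-surface distance,
`(Σ_{x∈A} d(x,B) + Σ_{y∈B} d(y,A)) / (|A|+|B|)` — the formula was
unspecified and this symmetric form is the package's definition. Nearest
neighbours come from a k-d tree and are tested for exact agreement with
O(N²) brute force. Degenerate cases: DOC of two empty sets is an error; an
empty prediction against a nonempty truth scores DOC 0 with HD/MSD reported
as undefined (`None`), never infinite. A pixel-unit reading is available by
passing unit spacing.

## Desk-scale study conditions

The end-to-end experiment in `tests/test_acceptance.py` fixes: 25 phantoms
(64×64×60 at 3 mm; five per condition, seeds derived from a fixed base),
train on 20, hold out one case per condition; network input 64×64 (halves
64×32), base_channels 8, stack_count 2; batch 16, Adam lr 1e−3; 6 epochs for
the separator, 8 for the main net, 10 for the classifier. The segmentation
nets train on every third slice with the subsampling phase staggered across
cases (so all slice positions, including the femur boundary, appear in the
dataset); the classifier — far cheaper per sample — trains on every slice,
since slice localisation is precisely its task. These problem sizes are the
package's CPU-scale defaults; the full-resolution clinical regime (256×256
halves, tens of thousands of iterations) is supported by the same code
paths but is not exercised by the tests.

## Known limitations

* Phantom realism, as above; no muscle/tendon structures, no metal implants.
* No DICOM ingestion, orientation/affine handling, or anisotropic reslicing
  (NIfTI with diagonal affine only).
* No joint fine-tuning of the assembled pipeline; no hyper-parameter search.
* No 95th-percentile Hausdorff or volumetric-similarity metrics.
* The engine is single-process numpy: adequate for desk-scale slices,
  orders of magnitude slower than a GPU framework at clinical resolution.
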