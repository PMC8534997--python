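# Methods

This note documents the models and procedures implemented in `gaitkit`,
the choices made where the underlying methods are under-specified, and
what the synthetic experiments do and do not demonstrate.

## Synthetic walker

The generator emulates a studio capture protocol: a subject walks in
sagittal view across a uniformly lit chroma-green background, twice in
each direction, for each gait condition; a session records 9 conditions
(normal, plus 4 pathological types × 2 severities) × 4 sequences = 36
sequences, and 23 sessions over a 21-subject pool give 828 sequences.
Sessions beyond the subject pool reuse subjects, emulating capture on two
days.

The walker is a 2D stick figure: 13 articulated joints (head, neck,
mid-hip, and shoulder/elbow/wrist, hip/knee/ankle per side) mapped onto
the BODY_25 keypoint indices; facial and foot indices are emitted with
confidence 0. Joint angles follow a sinusoidal base gait — thigh swing
±0.5 rad about the vertical, swing-phase knee flexion up to 0.7 rad, arm
swing in counter-phase with the same-side leg — and the figure advances
one step length per half cycle. Limbs are rendered as thick segments
(half-width ≈ 3% of figure height) plus head and torso ellipses, so
silhouettes are single connected blobs; the ground-truth mask is exactly
the rendered support, and the RGB frame composites the sprite over the
noisy green background (per-pixel uniform noise, ±8 of 255 per channel).

Gait types perturb the base gait qualitatively the way the pathologies
present in the sagittal plane:

| type       | deviation (severity 1)                                         |
|------------|----------------------------------------------------------------|
| scissor    | torso pitched 0.30 rad forward, steps shortened 40%, both ankles swept in a circular drag (5 px) |
| spastic    | one (right) leg swept circularly (6 px); right arm static at the waist, against the chest at severity 2 |
| steppage   | knee-flexion amplitude ×1.8 (exaggerated knee lift)            |
| propulsive | torso pitched 0.45 rad, steps halved at doubled cadence, both arms to the chest, 1.5 px joint jitter |

Severity 2 multiplies each type's deviation parameters by **1.6**. The
underlying protocol describes severity only as an overall exaggeration of
the type's symptoms; a single documented constant keeps the two levels
separable yet overlapping. The propulsive cadence doubling is kept fixed
(not scaled by 1.6) so the gait period remains commensurate with
`frames_per_cycle`; severity instead scales its stoop, step shortening
and jitter.

What the generator does **not** model: 3D kinematics, perspective,
clothing and appearance variation, self-occlusion, motion blur, real
pathological biomechanics (ground-reaction timing, asymmetric cadence),
or pose-estimation failure modes. Passing tests on this data show the
pipeline's machinery is correct and that the five synthetic classes are
separable from their energy images; they say nothing quantitative about
accuracy on real patients.

## Segmentation

The background model is learned from one background-only frame in HSV.
Each channel's valid interval is the [0.5th, 99.5th] percentile of its
histogram; hue is circular, so the hue distribution is rotated to centre
its circular mean at 0.5 before taking percentiles. This range rule makes
the model accept ≥ 99% of noisy background pixels while staying tight —
the published procedure specifies histograms but no range rule, so the
percentile choice is this package's own. A pixel is foreground when its
hue leaves the hue interval, **or** both its saturation and value leave
theirs (hue is the discriminative channel over chroma green; the S∧V
clause guards against desaturated clothing with accidentally matching
hue). A bimodal background yields one interval spanning both modes — a
documented degradation, not an error.

Cleanup is morphological opening then closing with a 5×5 elliptical
footprint (the published pipeline states only that morphological filtering
is applied), followed by selection of the largest connected component.
Opening-then-closing is idempotent on the fixtures used in the tests, the
output has at most one component, and widening all background intervals
can only shrink the foreground.

## Representations

All sequences are resampled to 10 fps by index subsampling
(`round-half-up(k · src/target)`) and mirrored so they face left-to-right
(mask flip; pose x-reflection with left/right index swap). Silhouettes
are cropped to their bounding box, scaled so the box height is 224 with
aspect preserved, binarized at 0.5 after bilinear resize, and placed with
the whole-silhouette centroid at column 112 (clipping overflow). The
centroid anchor was chosen over a top-half-centroid for simplicity; the
published pipeline says only "horizontally aligned".

Gait cycles are delimited from the silhouette bounding-box width: the
width reaches a local minimum at each mid-stance (twice per cycle), so
after a 3-frame moving average, minima are found (prominence 5% of the
signal range) and **alternate** minima bound full cycles. A constant
signal or fewer than three minima yields "no cycle found" (an empty
list). On synthetic walkers the detected lengths match the configured
period within ±1 frame.

Energy images are the exact pixel-wise mean of the normalized binary
frames; whole-sequence and per-cycle scopes share the code path, and SEI
is the identical averaging applied to skeletons rasterized from BODY_25
poses (3 px segments, drawn when both endpoint confidences exceed 0.1).
Values are 8-bit quantized (`round(255·v)`) on disk.

## Classifier

Input 224×224×3 (the grayscale energy image replicated to three
channels), five 3×3 stride-2 'same' convolutions with widths
(32, 32, 32, 64, 64), each followed by batch normalization and ReLU;
flatten (7·7·64 = 3136) → dense 512 → ReLU → dropout 0.5 → dense 5 →
softmax. Counting batch-norm moving statistics as parameters (4 per
channel), the total is exactly **1,684,421** (conv 74,816 + norm 896 +
dense 1,608,709). The three-channel input and 'same' padding are jointly
forced by this total: with one input channel the conv term loses 576
parameters and no other consistent reading reproduces the printed count;
the channel-width pattern (32, 32, 32, 64, 64) is likewise the unique
assignment under "32 in the first layer, doubled for the last two" that
matches it. ReLU placement after normalization follows the VGG-style
lineage the architecture descends from.

Training: categorical cross entropy, Nadam (Adam with Nesterov momentum,
β₁ = 0.9, β₂ = 0.999) at learning rate 0.001, batch 32, shuffled each
epoch from the model seed, early stopping on validation loss
(patience 10, best weights restored). Epochs and batch size are not
pinned by the architecture and default to 50/32. The entire network —
forward, backward, optimizer — is NumPy; training is bit-reproducible for
a fixed seed and data order. Batch-norm moving statistics use momentum
0.9 rather than the common 0.99: with the tens of update steps a small
training set provides, a 0.99 average never converges and inference-mode
predictions diverge wildly from training-mode behaviour; 0.9 converges
within ~60 steps and is otherwise immaterial. Dropout is inverted
(identity at inference). Checkpoints are HDF5 (config as YAML attribute,
one group per layer).

## Evaluation

Cross-validation is subject-wise with the overlapping-window rule
V_k = {S_{2k−1}, S_{2k}, S_{2k+1}}; with 21 subjects and 10 folds every
subject is tested at least once and odd-indexed interior subjects twice.
Fold accuracies are averaged unweighted, matching the protocol as stated.
Scoring is at sequence level (argmax of the whole-sequence
representation); per-cycle voting is available but not the default, as
the scoring unit is not specified by the protocol. Confusion matrices are
row percentages in the fixed order (scissor, spastic, steppage, normal,
propulsive); zero-support rows are undefined (NaN), not zero. Cross-dataset
evaluation trains once on one domain and tests on another through a 1-to-1
label mapping (scissor↔diplegic, spastic↔hemiplegic, steppage↔neuropathic,
normal↔healthy, propulsive↔Parkinsonian), reporting in the test domain's
vocabulary.

## Explanations

Both attribution methods differentiate the *pre-softmax* class score
(standard practice; invariant to constant score shifts). Saliency is the
input gradient's per-pixel magnitude, max-reduced over the three
replicated channels and rescaled to max 1 (an identically zero gradient
stays all-zero). Grad-CAM weights a conv layer's post-ReLU activations by
their spatially averaged gradients, clips negatives, upsamples bilinearly
to 224×224 and rescales; the default layer is the last (fifth) conv
layer, the coarsest and most class-specific. Overlays use a perceptually
uniform colormap at 50% alpha.

## Run sizes

The test suite and acceptance script use scaled-down but structurally
faithful experiments, chosen as the package's own desk-scale defaults:
walkers of 16–20-frame cycles × 2–3 cycles; the class-recovery task
trains on 40 sequences/class over 10 synthetic subjects with a
2-subject held-out split, 8 epochs in batches of 16, three seeds, plus
one label-permutation null; the end-to-end pipeline smoke run uses 5
sessions (180 sequences) with 2 training epochs and a single
subject-disjoint fold. Headline accuracies of the real studio datasets
are not reproduced here — they require the original recordings; the
synthetic class-recovery task verifies the pipeline end to end instead.

## Known limitations

- The NumPy network is CPU-bound; it is sized for desk-scale experiments,
  not for training on real video corpora.
- The cycle detector assumes sagittal walking with visible leg scissoring;
  it reports "no cycle" on degenerate inputs rather than guessing.
- Chroma-key segmentation presumes a uniform background; there is no
  shadow model and no multi-person handling (pose files with several
  people take the highest-confidence person).
- Severity grading, subject morphology and the 1.6 severity factor are
  synthetic conventions, not clinical calibrations.
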