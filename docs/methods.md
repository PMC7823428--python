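# Methods

## Learning protocol

All four strategies share one two-phase protocol. In the source phase an
embedder `f(·, θ)` is trained from scratch on the source label space; in
the adaptation phase `θ` is frozen and a lightweight classifier is built
from the C×K support images of an episode. Episodic scoring draws K
support and Q query images per class without replacement (disjoint by
construction), adapts, and scores the adapted classifier on the C×Q
queries; the grid reports mean error and its standard error over repeated
episodes. C is always the full novel label space of the target dataset,
not a sampled subset.

Source training uses Adam with learning rate 1e-4 — 30 epochs for the two
classifier methods, 15 for the two metric methods — with the best epoch
kept by a stratified 10% held-out slice of the source training data
(classification accuracy for the classifier methods, triplet loss for the
metric methods; the protocol names no criterion, so this is the package's
choice). Training draws are augmented (horizontal/vertical flips at p=0.5,
rotation uniform in 0–30° counter-clockwise with bilinear interpolation
and reflect padding, hue/saturation/brightness/contrast jitter with factor
0.1, center crop of 0.875 of the side resized back to the input
resolution). Adaptation of the classifier heads uses SGD (lr 0.01,
momentum 0.9, weight decay 1e-3, 100 epochs) on fixed support features;
metric methods instead fit a one-vs-all linear SVM with soft margin C=1
(scikit-learn LinearSVC, primal solve for determinism, no feature
normalization — exposed as a flag).

### Classifier heads

The linear head is an affine map followed by softmax. The cosine head
holds one prototype per class and scores by cosine similarity; similarity
is fed to the softmax unscaled (an optional temperature exists but is off
by default). During adaptation the prototypes are *imprinted* —
initialized at the normalized mean of each class's support embeddings —
and then refined by the gradient protocol above. Imprinting matters: with
random initialization the 100-epoch refinement demonstrably stops short of
the class-mean solution (a nearest-cosine-centroid oracle on identical
episodes scores about ten points higher), which both depresses accuracy
and erases the expected improvement with K. Imprinted heads track the
oracle and recover the monotone error-vs-K behavior.

### Metric objectives

The triplet hinge uses squared Euclidean distances throughout (no square
roots, hence no numerical epsilons) with margin m=1. Triplets are mined
uniformly at random among valid (anchor, positive, negative) index
combinations; the adversarial variant is the package's hard-negative
mechanism, so the plain triplet network does no hard mining. The
hard-negative generator is a three-layer fully connected net (hidden
widths 2d and d, ReLU, linear output) consuming the concatenated triplet.
Updates alternate within each batch: a generator step on its own objective
(J_hard + λ1·J_reg + λ2·J_adv, all weights default 1, adversarial margin
α=1), then an embedder step on the triplet hinge with the regenerated
synthetic negative treated as constant — whether generator gradients
should flow into the embedder is unspecified in the protocol, and
alternating updates are the package's resolution, recorded in the config.

## Backbones

Standard residual topologies: basic blocks for depths 18/34 (512-d
features), bottlenecks for depth 50 (2048-d), 7×7 stride-2 stem with
max-pooling, global average pooling at the top, He fan-out initialization,
batch normalization with running statistics for evaluation. The `tiny`
backbone (3×3 stem, four basic blocks, 64-d features) exists for CPU-scale
experiments. The metric head is a single fully connected layer + ReLU to
128 dimensions regardless of backbone. Parameter counts are reported by
`Embedder.n_parameters()` (about 11.2M / 21.3M / 23.8M for depths
18/34/50 without their source classifier) but not asserted, since
published "about N million" figures depend on which heads are counted.
All tensors are float32; evaluation-mode embedding is a pure function of
the weights, which is what makes the bitwise-frozen-embedder contract
testable.

## Class catalogs

The packaged tables carry the published per-class train/test counts of the
38-class crop-disease corpus (54,305 images), its 21-class rearrangement
by common disease name, and the six-class coffee-leaf corpus (1,747
images). The remapping derives the disease-name catalog from the
crop-disease rows: non-healthy diseases merge with summed counts; healthy
rows pool and are subsampled to a configurable target (default 5,000,
split proportionally between train and test) — the published table's
healthy row (4,909/1,200) cannot be reproduced exactly from the printed
information, so counts are config-driven. Class ids are assigned
alphabetically by disease name (case-insensitive), healthy last, which
reproduces the published ordering. Two printed rows (Cercospora 440,
Northern Leaf Blight 817) disagree with the sums of their source rows
(410, 788); the derivation trusts the source rows, and the shipped copy of
the printed table keeps the printed values.

Domain splits: in the crop-disease formulation classes C1–C6 are the novel
target domain and C7–C38 the source; in the disease-name formulation the
three smallest diseases (CD1, CD4, CD19 — 1,278 images together) are the
target and the remaining 18 classes the source. An external catalog can be
declared all-target (the coffee corpus is never trained on).

## The leaf simulator

Images are generated, not photographed: a randomized convex-ish leaf
silhouette (radially perturbed ellipse with low-order harmonics) on a
plain or cluttered background, with class-conditional lesions drawn inside
the silhouette — disjoint disks (spots; placement guarantees the
connected-component count equals the drawn lesion count), dense small dots
(pustules), large irregular patches (blotch), thresholded smooth noise
(mosaic), and a marginal band (scorch). A domain preset then applies
illumination gain, hue shift, blur and the background type; the "field"
preset (cluttered background, gain 0.55–0.90, blur σ=1, hue shift 0.08)
shifts per-channel means by ~0.4 relative to a "lab" rendering of the
same classes, versus ~0.01 between two lab draws — a measurable stand-in
for the lab-to-field acquisition gap. Everything is deterministic given
the argument tuple and one integer seed; per-image seeds are derived
through `numpy` seed sequences.

What the simulator does *not* emulate: photographic texture, lesion
morphology beyond coarse shape/color statistics, occlusion, scale
variation, background-leaf confusion, or label noise. Passing tests
therefore demonstrate that the learners recover *class-conditional color
and shape structure under a controlled appearance shift* — not
field-grade performance on real photographs.

## The synthetic benchmark

The desk-scale study configuration trains every strategy on five
well-separated synthetic disease classes (40 images each, 80% train, lab
domain, 32×32 pixels, tiny backbone) and adapts to three novel classes
(80 images each) with K ∈ {5, 25}, Q = 50 queries per class, 30 episodes
per cell. These sizes are the package's choice of a configuration a
single CPU core trains in minutes; image size 32 is the smallest the
generator supports, and the full-scale protocol values (K up to 50, 100
repeats, 224-px inputs, deep backbones) remain available through the
config. A frozen-random-embedder control (same architecture, untrained,
same adaptation) anchors the comparison: trained baselines roughly halve
its error at every K.

## Numerical choices and degenerate inputs

* Squared distances in all metric losses; no epsilon terms.
* Cosine similarity rejects zero-norm vectors rather than patching them.
* SVM ties resolve to the lowest class index (argmax semantics).
* Batch-norm batches of size 1 are skipped during training.
* Softmax is computed with max subtraction; cross-entropy in float64.
* Episode seeds derive from `base_seed + repeat` mixed with K; training,
  generation and augmentation all stream from explicit generators, so any
  stage reruns bit-identically on one machine.
* Augmentation crops may fall below the 32-px generation minimum; they are
  transient training inputs, not dataset members.

## Known limitations

* The numpy networks are CPU-bound: the deep backbones (18/34/50) are
  practical for contract checks and inference on small batches, not for
  full-scale training runs.
* Fine-tuning at the protocol learning rate (Adam 1e-4) needs tens of
  epochs to converge on desk-scale data; very short schedules underfit.
* Mean error under heavy episode overlap (Q=50 from pools of 80) makes
  repeats correlated; standard errors are reported but understate
  pool-level variance.
* The simulator's class difficulty is calibrated for separability, so
  absolute error values are not comparable to published results on real
  corpora; qualitative orderings (error falls with K; trained embedders
  beat random ones; the linear baseline transfers best) are the meaningful
  outputs.
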