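# Methods

`coverseg` implements a two-part recipe for label-efficient 3D neuron
segmentation in volume electron microscopy (EM): a *data-level* component
that decides **where** a fixed annotation budget should be spent
(coverage-based greedy selection of sub-volumes in a learned patch-embedding
space), and a *model-level* component that decides **how** to learn from the
few labeled sub-volumes together with the large unlabeled remainder
(mixed-view consistency regularization with axial-through spatial mixing).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not establish.

## Coordinate and label conventions

Volumes are stored `(z, y, x)` with z the section axis, the anisotropic
direction of serial-section EM. Indices are 0-based; crop windows are
half-open, so adjacent crops tile exactly. Instance id 0 is the background /
ignore label everywhere (cortical EM ground truth commonly leaves myelin
unannotated); evaluation drops gt-0 voxels by default and affinity edges
touching id 0 are 0.

## Patch representation (siamese stop-gradient learning)

The unlabeled volume is partitioned into patches by a sliding window
(default stride 8×40×40 voxels); each patch is mapped by an encoder `f` to
an L-dimensional embedding (L = 80 by default). `f` is trained with the
stop-gradient siamese objective: two augmented views of one patch pass
through weight-sharing encoder + projector `g`; a predictor `h` on each
branch matches the *detached* projection of the other branch under the
symmetrized negative cosine similarity

    L = ½ N(h(g(f(v₁))), sg[g(f(v₂))]) + ½ N(h(g(f(v₂))), sg[g(f(v₁))]).

Detaching one branch per term is the collapse-prevention mechanism; the
gradient contract is tested by finite differences against a loss in which
the target branch is frozen.

Augmentations must preserve patch semantics in anisotropic data:
reflections; in-plane rotations restricted to multiples of 90° (so the z
axis is never mixed into xy); Gaussian blur applied in-plane; additive
Gaussian noise; per-section integer in-plane shifts with reflect padding
("simulated misalignment", the standard ssEM misregistration model);
photometric scale/shift; and random voxel masking with an exact
⌊fraction·n⌋ count. Magnitudes (blur σ ∈ [0, 1], noise sd 0.05, shift ≤ 2
voxels, masking 10%) are package defaults chosen to be mild relative to the
[0, 1] intensity range; none of the downstream algorithms depend on them.

The encoder architecture is a pluggable contract. The built-in desk-scale
stand-in is a small strided 3D conv stack with global average pooling and a
linear head; training uses Adam (lr 1e-3 for this small stack). A 200-step
run on synthetic patches drives the symmetrized loss from ≈ −0.74 toward
−1, which only shows the optimization is wired correctly — it says nothing
about representation quality on real EM.

## Coverage-based selection (CCR and CGS)

Let U be the set of N patch embeddings. Each vector covers its K nearest
neighbors in U (Euclidean by default, K = 30); the constrained coverage
rate of a selected set S is

    CCR(S, U) = |∪_{v∈S} V(v, U)| / |U|.

Selection is greedy over an annotation budget of sub-volume sizes: every
candidate window (sliding at a configurable scan stride) contributes the
embeddings of the patches fully contained in it; the window with the
largest incremental covered count is committed. Coverage is monotone
submodular, so greedy is within (1 − 1/e) of the exhaustive optimum under a
cardinality budget; the suite verifies this bound — and exact agreement of
the first greedy step with a brute-force singleton argmax — on instances
small enough to enumerate.

Numerical choices, all made for determinism where the procedure itself is
silent:

* KNN ties break to the smaller index; greedy ties break to the
  lexicographically smaller (z, y, x) origin. KNN is exact (chunked brute
  force) — approximate indexes do not honor the tie rule.
* Self-inclusion: `v ∈ V(v, U)` always (distance 0 is minimal).
* Selected sub-volumes may not spatially overlap; candidates overlapping a
  prior choice are excluded. Overlapping picks would double-annotate
  voxels.
* The candidate scan stride defaults to the patch stride. When the budget
  is tight relative to the volume, aligning the scan stride's z component
  with the sub-volume depth (as the demo pipeline does) guarantees the
  non-overlap constraint can always be satisfied; an unaligned greedy run
  can fragment the z-axis and exhaust the candidate space.
* CCR keeps all of U in the denominator, including patches already inside
  selected sub-volumes.

Variants: a fixed-radius coverage function (coverage sets of variable
cardinality; ignores embedding density) and negative-cosine distance.
Baselines: seeded uniform non-overlapping random selection and a maximally
even equispaced lattice.

## Affinity graphs and post-processing

Ground truth for the segmentation network is a 3-channel affinity graph:
channel c at voxel p is 1 iff p and its −1 neighbor along axis c (channel
order z, x, y) carry the same nonzero instance id. The first plane along
each axis has no predecessor and gets 0. The included post-processor
(threshold edges, connected components, components renumbered by
first-voxel raster order) is plumbing for end-to-end demos — real pipelines
use watershed plus graph agglomeration, which is out of scope. For dense
label volumes with connected instances the round trip labels → affinity →
components is exact up to relabeling, and raising the threshold can only
refine, never merge.

## Axial-through spatial mixing

CutMix-style mixing with a binary mask Π that is constant along z: the zero
region is either a random axis-aligned D×⌊βH⌋×⌊βW⌋ block (β sampled
uniformly from [0.25, 0.5] per batch by default; any β ∈ (0, 1) is valid)
or one random in-plane quadrant ("quarter", interpreted as exactly one of
the four H/2×W/2 quadrants). Because the mask is axial-through, the mixed
volume has no section-to-section seam, so z-affinities remain well defined
— the motivation for the design in anisotropic data. Mixing is a pure
voxelwise copy; the affinity mask is the same in-plane mask broadcast over
channels, and seam affinities straddling the rectangle boundary are
deliberately not recomputed.

## Mixed-view consistency objective

With two labeled pairs, two unlabeled volumes, and masks Π₁–Π₃:

* `intra_l` — cross-entropy (per-channel Bernoulli, predictions clipped to
  [1e−7, 1−1e−7]) of S on the Π₁-mix of the augmented labeled views against
  the Π₁-mix of their affinity graphs;
* `intra_u` — squared error of S on the Π₂-mix of the augmented unlabeled
  views against the Π₂-mix of stop-gradient pseudo labels S(u₁), S(u₂)
  computed on the un-augmented inputs (same network, no EMA teacher);
* `inter_l` / `inter_u` — one forward pass on the Π₃-mix of a labeled and
  an unlabeled view, scored by masked-mean cross-entropy against y₁ on the
  Π₃=1 region and masked-mean squared error against S(u₁) on the Π₃=0
  region; an empty region contributes 0 with a warning.

Total: `intra_l + inter_l + λ(intra_u + inter_u)`, λ = 0.2. All reductions
are means over the relevant channel-voxel set (masked means for the inter
terms), keeping components comparable across mask sizes. Training warms up
on `intra_l` alone (pseudo labels from a random network are noise) before
switching to the full objective; the warm-up length is a config parameter.
Augmentations used during this training are photometric-only, because the
affinity targets are fixed to the un-augmented geometry.

Training runs on a lightweight reverse-mode autodiff core written for this
package (numpy arrays, scipy convolutions, Adam with the standard moment
estimates). The default backbone is a two-layer residual 3D conv net with
sigmoid outputs — a stand-in for the usual residual symmetric U-Net slot,
which is pluggable via the `SegmentationModel` contract. The reference
learning rate for full-scale training is 1e-4; the desk-scale smoke runs
use 5e-3, appropriate for a backbone with ~300 parameters, and 16×32×32
crops. The packaged smoke run (200 steps, 8 synthetic 24×64×64 volumes,
warm-up 50) reduces the 20-step mean supervised loss to ≈ 30–36% of its
initial value across seeds.

## Evaluation metrics

From the sparse contingency table of proposal A vs ground truth T:
`VI = H(A|T) + H(T|A)` (split and merge conditional entropies; natural log
by default with a base-2 option, since published VI numbers do not always
state a base) and the adapted Rand error
`1 − 2Σp_ij²/(Σa_i² + Σb_j²)` — one minus the F-score of same-segment
ordered voxel pairs *including* self-pairs, which is what the squared-
probability formula implies. Note scikit-image's `adapted_rand_error`
counts distinct pairs only (n(n−1) convention) and so differs at small n;
the suite therefore cross-checks ARAND against a brute-force pair-counting
oracle and VI against scikit-image in bits.

## Synthetic test bed — what it shows and what it does not

* `synth_instances`: anisotropic nearest-seed tessellation (seed distances
  stretched 5× along z), every voxel labeled 1..n, each instance one
  6-connected component (a repair pass reassigns rare digitization
  fragments), intensity 0.9 in interiors, darkened by 0.6 on
  inter-instance faces, Gaussian noise sd 0.05, clipped to [0, 1]. This
  reproduces the properties downstream code relies on — dense labels,
  boundary contrast, z-anisotropy — not EM texture, membranes, or
  organelles.
* `synth_embeddings`: n isotropic Gaussian clusters (unit within-cluster
  sd) whose centers are `cluster_separation` apart (default 20, i.e.
  unambiguous cluster structure in 80 dimensions), each cluster occupying
  one contiguous block of the patch grid. The demo scenario — 6 clusters ×
  128 patches in 6 z-slabs, budget 6, K = 30 — is the recovery setting
  selection is designed for: greedy coverage reaches ≈ 99% CCR versus
  ≈ 87–95% for seeded random selection.

Passing these tests shows the algorithms are implemented correctly and
behave as designed under their own assumptions. It does not show that the
selected sub-volumes improve segmentation of real EM volumes, that the tiny
backbone approaches U-Net accuracy, or that the encoder's embeddings are
biologically meaningful — those claims require full-scale training on real
data, outside this package's scope.

## Problem sizes

Test and demo sizes are chosen for single-CPU runs: embeddings N ≤ ~10³,
volumes ≤ 24×64×64, training ≤ 200 steps on 16×32×32 crops. All generators
and training loops are deterministic given a single seed (sub-seeds are
spawned per stage and recorded in the pipeline report).
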