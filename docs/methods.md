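# Methods

`tomopick` localizes copies of arbitrary macromolecules in cryo-electron
tomograms by deep metric learning: a 3D convolutional network maps every
subvolume of a tomogram onto a unit hypersphere, where cosine similarity
reflects macromolecular identity. A single picked example (reference
workflow) or the mean of a selected embedding cluster (clustering workflow)
defines a target vector; similarity maps against that target are reduced to
particle coordinates by region-growing maximum detection, non-maxima
suppression, and confidence/size thresholding. No retraining is needed per
target species.

## The embedding network

The trunk is `n_blocks` convolutional blocks. Each block applies two 3x3x3
convolutions (unit zero-padding): the first doubles the channel count, the
second preserves it; every convolution is followed by group normalization
and a leaky rectifier (slope 0.1). A 2x2x2 max pool follows the first block
and an adaptive max pool to 2x2x2 follows the last, so the trunk output is
2x2x2 spatially for any admissible input edge. The head flattens the
feature tensor, applies dropout, then fully connected layers down to
`out_dim`, and finally L2-normalizes. With the default configuration
(5 blocks, 64 base channels, input 37^3) the trunk emits 2x2x2x1024
features and the head a unit 32-vector.

Unstated details we had to fix: the head uses two hidden layers (2048, 512
for the full profile); group-norm uses 64 groups clamped to the channel
count; the leaky slope is 0.1. These are declared defaults in
`NetworkConfig`, not values inferred from elsewhere.

The network is implemented as a compact NumPy layer stack
(`tomopick.nn`): im2col + GEMM 3D convolution, manual backpropagation, and
an Adam optimizer. Analytic gradients of every layer are verified against
central finite differences in the test suite.

### Desk profile

Training the full architecture is a GPU-scale undertaking. The shipped desk
profile (`desk_config`: 3 blocks, base 8, input 17^3, head 128-64-32)
preserves the architecture family — same block structure, pooling scheme,
normalization, and unit-sphere head — at a size where training and
tomogram-scale inference complete in minutes on one CPU core. All
end-to-end tests and the worked example use this profile; the full profile
is exercised for its shape contract.

## Training

Triplet loss on cosine *distance* d = 1 − cos:
`L(a,p,n) = max(d(a,p) − d(a,n) + α, 0)`, α = 0.2 by default. Negatives are
mined online per batch under the semihard rule
`d(a,p) < d(a,n) < d(a,p) + α_miner` (α_miner = 0.2), keeping for each
(anchor, positive) pair only the hardest qualifying negative. Batches are
class-balanced (5 classes x 5 instances by default). Adam (lr 1e-3) runs
for a fixed number of epochs; after each epoch the model is scored by
nearest-class-medoid retrieval on the validation split (macro-F1; medoids
on the hypersphere from up to 32 training embeddings per class), and the
best-scoring epoch's checkpoint is returned (ties go to the earlier epoch).

Note on the distance convention: the published form of this loss family is
sometimes written with cosine *similarity* in the distance role, which read
literally would reward dissimilar positives; implementing D as
1 − cos makes the semihard inequality and the loss meaningful, and
similarity is used only for maps and retrieval.

Two training details matter at desk scale:

- **Centered initialization.** Freshly initialized networks emit embeddings
  clustered in a tight cap of the hypersphere (a large shared mean feature
  component dominates), starving the triplet loss of signal. Before epoch 1
  the final pre-normalization layer's bias is shifted by the negative mean
  of its output over a probe batch of training data, spreading the initial
  embeddings over the sphere. This is a data-dependent initialization, not
  an architectural change.
- **A background class.** Training pools include a particle-free
  (noise-only) class alongside the particle classes, mirroring the practice
  of including noise/background among the data classes. Without it the
  embedding of empty-ice windows is unconstrained and similarity maps lose
  contrast over the background, which is most of any tomogram.

Four augmentations are implemented (in-plane rotation only — preserving the
missing-wedge orientation; dropout of 5–20% of voxels to the subvolume
mean; 1–2 voxel shifts; Gaussian noise with sigma drawn from U(0, 0.3)).
Rotation augmentation is essential: single-reference picking requires the
embedding to be invariant to the particle's unknown in-plane orientation,
and without it same-class embeddings at different rotations drift apart
even when nearest-medoid retrieval still looks healthy. The desk-scale
fixtures therefore train with rotation augmentation enabled and the other
three disabled: dropout/shift/noise exist to prevent overfitting over very
long training runs, and at tens of epochs on small pools their added
corruption measurably delays convergence instead. Translation robustness —
needed because the sliding-window lattice lands up to stride/2 voxels off
every particle center — comes from jittering the training-pool extraction
windows (below), which supplies in-distribution offsets. Each augmentation
is unit-tested in isolation.

## Sliding-window embedding

Windows of edge `box_len` slide with a stride (2 in the full-scale recipe;
the desk fixtures use 3, recorded in the grid metadata).
Origins run `0, s, 2s, …` per axis; trailing voxels that cannot host a full
window are never embedded, so the outer shell of the tomogram is
unpickable. Each window is z-score normalized (per-subvolume mean 0, SD 1),
making picking invariant to linear intensity rescaling between tomograms; a
constant window (empty ice) is flagged degenerate and embedded as zeros
input. Window centers are `origin + box_len // 2`.

## Localization

- **Map** — cosine similarity of each target against every window vector,
  arranged on the stride lattice.
- **Locate** — 26-connected local maxima at or above `floor` (default 0.5)
  are visited in descending peak order; each grows a connected region of
  lattice points with value ≥ max(peak − `tolerance`, floor)
  (tolerance default 0.2). Weaker maxima inside an already-grown region are
  absorbed (fusion keeps the higher peak). The candidate center is the
  similarity-weighted centroid of the region mapped back to voxels;
  region size is the lattice point count (multiply by stride^3 for voxels).
- **NMS** — greedy by descending similarity (ties broken by (z, y, x)
  order); a candidate is accepted only if its `box_len` cube has IoU < 0.6
  with every accepted cube. The threshold deliberately matches the
  evaluation IoU so suppression and scoring are mutually consistent.
- **Pick** — similarity ≥ `min_similarity` and region size within
  [size_min, size_max], sorted by similarity. With `auto_size_band=(lo,
  hi)` the band is derived per target as [lo*S, hi*S] where S is the best
  candidate's region size — the headless analogue of tuning the size
  threshold per species from an example particle.

Multiple targets are picked independently; a location may appear under
several labels. The `exclusive` option assigns contested locations to the
higher-similarity label; its overlap criterion (IoU ≥ 0.15 by default) is
deliberately looser than same-label NMS because different targets localize
the same particle with centroids a few voxels apart.

## Clustering workflow

Up to 400,000 embeddings (clamped to the grid size) are subsampled
uniformly and projected to 2D with UMAP (seeded; the pinned random state
also forces UMAP's reproducible single-threaded path). Clusters are
selected by a closed polygon under the even-odd ray-crossing rule (boundary
points count as inside; self-intersecting polygons are accepted under the
same rule). The selected rows' high-dimensional embeddings are averaged and
re-normalized — re-normalization restores the unit-norm invariant and
changes no cosine ranking — and the result is used exactly like a reference
target. The lasso of an interactive tool is replaced by polygon vertices
supplied via file/CLI, with an optional scatter-plot export for authoring
vertices; this keeps the toolkit headless and testable.

## Evaluation

A pick is a true positive when the IoU of its cube with a ground-truth cube
is strictly greater than 0.6 (both cubes of the evaluation `box_len`).
Matching is greedy one-to-one in descending pick similarity, each pick
claiming the unmatched truth of maximal IoU; greedy equals optimal
assignment whenever particles are separated by more than a box diagonal,
which the simulator's `min_separation` guarantees in our scenes. Precision,
recall, and F1 (harmonic mean) are reported per class plus macro (mean of
per-class scores) and pooled (scores of summed counts) rows, since either
averaging convention may be wanted.

## Synthetic scenes

The simulator replaces a physical-optics pipeline with the minimum
structure the method depends on:

1. **Shape library** — procedural particle species (ellipsoids, rods,
   xy-plane rings, three-arm crosses, symmetric blob clusters) in a cubic
   box, peak-normalized, with the size scale interpolated across the
   library (real training panels span a wide molecular-weight range, and
   size diversity is what keeps same-family species distinguishable after
   wedge corruption). Each density carries a faint additive center bump
   (5% amplitude) so the recorded center is a strict local maximum of the
   clean volume without acting as a shared bright beacon across classes.
   A deterministic redraw loop guarantees all pairwise normalized
   cross-correlations < 0.95; the repertoire saturates near 12 classes
   (earlier for small boxes), reported as an error. Optional fiducial
   (dense bead) and vesicle (shell) classes are off by default.
2. **Placement** — rejection sampling of centers with a minimum
   center-to-center separation (a conservative sphere proxy for overlap)
   and boxes fully inside the volume; a bounded attempt budget reports how
   many particles were placed on failure.
3. **Rendering** — densities pasted at their centers with a random
   rotation about z per particle (full SO(3) behind a flag), plus an
   occupancy map labeling each voxel with its particle's class.
4. **Forward model** — a Fourier-space missing-wedge mask for single-axis
   tilt about y (coefficients whose (k_z, k_x) direction lies within
   90° − `wedge_half_angle` of the k_z axis are zeroed; default half-angle
   60° mirrors a ±60° tilt range), then additive Gaussian noise
   (`noise_sigma`, relative to unit particle contrast), then a global sign
   flip so protein is dark (the common reconstruction convention; recorded
   in metadata and applied consistently to scenes and training pools).

What this emulates: missing-wedge anisotropy (z-elongation), controllable
SNR, crowding, rotation diversity, ground truth. What it does not:
CTF/defocus, detector MTF, dose fractionation, reconstruction artifacts
beyond the wedge, membrane-bound geometry. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under wedge + noise
corruption, not performance on experimental tomograms.

Training pools are extracted from fully simulated scenes
(`make_scene_pools`): windows are cut at ground-truth centers (jittered by
up to 2 voxels per axis) and at particle-free positions (the background
class), then z-scored. Cutting from whole scenes matters: the
missing-wedge mask acts on the entire volume, so real windows carry
long-range z-streaks from neighboring particles that per-box rendering
cannot produce, and a model trained on isolated boxes misreads scene
windows. The window jitter matters equally: the sliding-window lattice
never lands exactly on a particle center, and without jittered training
examples the embedding degrades sharply at sub-stride offsets. A simpler
per-box generator (`make_subvolume_pools`) is kept for lightweight tests.

## Fixture conditions and problem sizes

The end-to-end fixture trains the desk profile on 5 particle classes plus
the background class — 150 scene-extracted subvolumes per class (120
train / 30 val), box 17, rotation-only augmentation, margins
α = α_miner = 0.8, 35 epochs — then picks on a held-out 96^3 tomogram
containing 8 particles of each trained species (`min_separation` 16, wedge
60°, noise sigma 0.2 — a moderate value within the U(0, 0.3) range the
augmentation recipe treats as realistic). A 6th species, never trained on,
is used for the generalization (separability) check. Wide margins matter
at this scale: semihard mining stops pushing a negative once its distance
exceeds d(a,p) + α_miner, so the margin sets the cross-class separation
the training equilibrium can reach, and picking thresholds need that
separation. Picking uses stride 3, floor 0.5, tolerance 0.2, NMS IoU 0.6,
similarity floor 0.75, a per-target size band (0.3–3x the best candidate's
region size), and exclusive contested-location assignment; evaluation is
IoU > 0.6 at box 17. The stride matters: the evaluation criterion
(IoU > 0.6 between 17-cubes) tolerates only ~1.7 voxels of center error,
and a stride-4 lattice leaves up to 2 voxels of quantization before
centroid interpolation — stride 3 brings the residual localization error
comfortably inside the criterion. Particles are placed at least 4 voxels
inside the window lattice's reach (`edge_margin`), since the outer shell
of any tomogram is unpickable by construction. Determinism checks run
reduced copies of the same pipeline twice and compare bytes.

## Numerical choices and degenerate inputs

- float32 throughout the network; similarity math in float64 where cheap.
- Constant subvolumes: flagged degenerate, embedded as zeros input rather
  than erroring mid-tomogram.
- A zero vector reaching L2 normalization raises (degenerate embedding).
- Cluster selections whose mean embedding nearly cancels (norm < 1e-6)
  raise with advice to tighten the selection.
- Max-pool gradients split ties equally; group-norm epsilon 1e-5.
- Locate tie-breaks: maxima ordered by (−value, z, y, x); NMS by
  (−similarity, z, y, x). Both make runs bit-reproducible.
- One master seed fans out (via `SeedSequence.spawn`) to weight
  initialization, shuffling, augmentation, placement, rotation, and noise
  streams; all are recorded in run manifests.

## Known limitations

- The desk profile's absolute accuracy is not comparable to a full-scale
  GPU-trained model; it exists to exercise every pipeline stage honestly.
- The forward model omits CTF and detector effects; transfer to
  experimental data is untested here.
- Greedy pick/truth matching can differ from optimal assignment in heavily
  overlapping scenes (not produced by the simulator's separation
  constraint).
- UMAP is reproducible per seed but not across library versions.
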