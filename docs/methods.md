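# Methods

This package implements a three-stage pipeline for estimating spot-level
gene expression on whole-slide images (WSIs) from bulk RNA-seq, after
learning on spatial-transcriptomics (ST) data:

1. **Spot Embedding Generator (SEG)** — maps spot images plus the sample's
   spatial graph to per-spot expression; trained on ST samples where
   per-spot truth exists.
2. **Gene Expression Predictor (GEP)** — reuses the trained, head-less SEG
   on WSI tiles and fuses the tile embeddings with an encoding of the
   sample's bulk profile; trained so the spot-average of its output
   reconstructs the true bulk profile.
3. **Spot Label Predictor (SLP)** — a CNN classifier of tumor vs non-tumor
   spots, used to gate a tumor-only average expression profile for
   downstream analyses.

## Patch extraction

ST samples carry pixel coordinates per spot; a half-open window
`[x-112, x+112) x [y-112, y+112)` is cropped around each spot center,
giving exactly 224 x 224 patches.  Windows that leave the image raise an
error naming the spot — silent clamping would mis-center the patch.

WSIs lack coordinates and are tiled on a non-overlapping grid (default
512 x 512, scanned row-major).  A pixel is foreground when the arithmetic
mean of its three channel values is below 220; a tile survives when at
least half of its pixels are foreground (a tie at exactly half survives).
Trailing partial tiles are discarded to preserve the fixed-size contract.
Surviving tiles are resized to 224 x 224 (bilinear, half-pixel center
alignment) and their integer (row, column) indices become the (x, y)
coordinates used for the spatial graph, so adjacent tiles sit at distance 1.

## Spatial graph

For each spot, Euclidean distances to all other spots are divided by that
row's maximum; an edge `i -> j` exists when the normalized distance is
strictly below a threshold (default 0.1, logged).  Because normalization is
per row the graph may be asymmetric; the attention layer consumes row-wise
neighbor sets, so no symmetrization is applied (an OR-symmetrization switch
exists but is off).  Isolated spots are legal — the self coefficient
handles them (below).

## SEG architecture

Six CNN blocks (convolution 3x3 stride 1 'same', ReLU; 2x2 max pooling
from the second block on), a flatten + linear projection to the CNN
embedding length `e_c`, and an intermediate FC layer `ReLU(W E + B)`.
A single graph-attention layer with `h` heads follows.  Per head, the raw
score of neighbor k for spot j is

    score(j,k) = ReLU(a_s . (W_s E_j) + a_n . (W_n E_k)),

normalized by a softmax restricted to j's neighbor set.  Non-neighbors are
excluded from the softmax support (masked with -inf rather than scored at
zero, which would let them contribute exp(0) = 1).  The self coefficient is

    alpha_s(j) = 1 / (1 + sum_k alpha_n(j,k)),

which evaluates to exactly 1/2 whenever j has neighbors and exactly 1 for
isolated spots; the layer deliberately de-emphasizes a spot's own features
relative to its spatial context.  An alternative mode computing alpha_s
from the pre-softmax scores exists behind a flag, off by default.  Each
head emits `f(alpha_s W's E_j + sum_k alpha_n(j,k) W'n E_k)` with f = ReLU
by default (configurable to ELU); value matrices W' are separate parameters
from the score matrices W unless `tie_value_weights` is set.  Head outputs
are concatenated (e = h * e_a) and two FC layers project to the p genes.
The two head layers are detached when the encoder is transferred.

Implementation notes: the score matrix over all (j, k) pairs is formed as a
broadcast outer sum of per-spot self and neighbor parts, so the layer is a
handful of matrix products; `alpha_s` is computed as `1/(1 + S/S')` where
S' equals S for rows with neighbors, making the 1/2 exact in floating
point.  Pixels are scaled to [0, 1] before the CNN.

## GEP architecture

The bulk profile passes through two FC layers (ReLU after the first) to an
embedding `Z1` of length e.  Alignment matrices give `E4 = W_spots E3^T`
and `Z2 = W_bulk Z1`, and both are z-score normalized before fusion.  The
axis matters, and the stated operation fixes it only for `Z2` (a vector has
only its feature axis).  We normalize each spot column of `E4` across its e
features — the same axis as `Z2`, so the two summands are normalized
identically and are commensurate for any number of spots.  The alternative
(`spot_norm_axis='spots'`: each feature across the sample's spots) is
available but not the default, for a substantive reason: it forces every
embedding feature, informative or not, to unit variance across spots,
whitening away the encoder's signal-to-noise structure; in the bundled
synthetic studies this injects enough spot-level noise into the decoded
expression to cancel the resolution the frozen encoder provides (and it
degenerates for single-spot samples, which are rejected under that axis).
The normalized bulk vector is broadcast-added to every spot column and
three FC layers (ReLU, ReLU, linear) decode per-spot expression.  The
linear output is intentional: expression targets are unbounded above.

Training minimizes the MSE between the column-mean of the decoded
expression and the true bulk vector.  The encoder is frozen; since it
receives no gradient, its embeddings are precomputed once per sample before
the epoch loop (bit-identical, much faster), and the encoder parameter hash
is asserted unchanged afterwards.

## SLP and threshold selection

Five CNN blocks (each with pooling), a global max pool, two FC layers and a
two-class softmax.  The stated objective for this stage — maximizing F1 —
is not differentiable, so optimization uses cross-entropy with the stated
procedure realized as model selection: per epoch, the decision threshold is
chosen on a stratified 20% validation split by maximizing Youden's
J = sensitivity + specificity - 1 (candidates are the observed
probabilities; ties take the smallest threshold), and the epoch with the
best validation F1 at its threshold supplies the final parameters.  The
threshold is persisted in the checkpoint and reused as-is on new slides
rather than re-fit per test image.

## Tensor engine

No deep-learning framework is used; the models run on a compact in-repo
reverse-mode autodiff engine over numpy arrays (`stgat.autograd`), with
convolution via im2col, max pooling with argmax routing, and Adam.  All
primitive gradients are validated against central finite differences in the
test suite, and the attention layer against a triple-loop oracle.  Model
parameters default to float32; float64 is available per config (the oracle
tests use it).  Checkpoints serialize the parameter dict deterministically,
so identical seeds reproduce identical bytes.

## Synthetic tissue generator

The generator plants exactly the structure the models assume:

- spots on a regular grid (default 12 x 12) with a contiguous tumor region
  (disk in grid coordinates; half-plane available); cohort generation
  varies disk center and radius per sample so tumor fractions span a range,
  as in real cohorts;
- images: each spot owns a square cell of tissue; tumor cells are darker by
  `intensity_contrast` (default 40 gray levels on a tissue gray of 200,
  background 245, per-pixel Gaussian noise sd 8);
- expression: log-normal base with per-gene baselines (log-sd 1, shared
  across a cohort), a log-scale shift of `marker_effect` (default 2) on
  `n_marker_genes` (default 5 of 50) in tumor spots, log-scale noise
  (sd 0.3), then one pass of neighbor mixing (weight 0.3) over the same
  adjacency the models consume;
- bulk = spot-average expression + Gaussian noise (sd 0.01).

Spot spacing defaults to 224 px with a 136 px margin, so a 224 x 224 crop
covers essentially one spot's tissue cell — matching the geometry of the
assay the pipeline targets, where crop size and inter-spot distance are of
the same order.  (An earlier 56 px spacing made every crop span a 4 x 4
cell neighborhood, blurring the per-spot image signal the encoder is meant
to learn.)

What the generator does *not* emulate: H&E stain color and texture, cell
morphology, segmentation artifacts, batch effects between cohorts, and
count noise models (expression is log-normal, not negative binomial).
Passing tests therefore demonstrate that the pipeline recovers planted
image-expression structure end to end, not that it meets any particular
accuracy on real tissue.

## Desk-scale study conditions

The bundled studies (`stgat.experiments`, also run by
`scripts/acceptance.py`) use cohorts of 8 samples (6 train / 2 held out) on
12 x 12 grids with 50 genes.  The reduced model configs average-pool the
224 x 224 patches by 7x before the first block (a config knob; the patch
contract is unchanged), use conv channels (8, 8, 16, 16, 32, 32),
e_c = 32, e_a = 16, h = 2 for the encoder and (8, 8, 16, 16, 32) for the
classifier.  Training lengths: encoder 200 epochs, predictor 1000 epochs
(its per-epoch cost is tiny once embeddings are precomputed), classifier 30
epochs, Adam at 1e-3.  Full-scale defaults (channel widths 32-256,
e_c = 512, e_a = 256) are configurable; the hidden widths of the original
full-scale setting are not fixed by the sources this package follows, so
they are exposed as configuration rather than constants.

## Numerical choices and edge cases

- Masked softmax rows with no neighbors produce an all-zero coefficient row
  (and alpha_s = 1) rather than NaN; the guarded denominator keeps row sums
  exactly 1 for neighbor rows.
- Z-scores guard a zero variance with a 1e-12 additive term inside the
  square root; constant slices normalize to zero.
- The expression loss is a mean over entries (not a sum), so its scale is
  invariant to spot count and gene count; this differs from a summed
  squared norm only by a constant factor per sample.
- Mini-batching applies to the CNN and FC stages; the attention step always
  runs on the full per-sample graph, since each row's softmax needs every
  neighbor.
- Duplicate spot coordinates are allowed (distance zero, logged);
  zero-variance genes inside the variance selection get p = 1 (logged).
- Evaluation correlation is one Pearson r per sample over flattened
  spot x gene entries; a per-spot option exists.  The t-test is Welch,
  two-sided; raw p-values order the report and a Benjamini-Hochberg column
  is provided for convenience.

## Known limitations

- The bulk-reconstruction objective constrains only the spot-average, so
  spot-level resolution in the predictor emerges indirectly, through the
  frozen encoder's embeddings and the nonlinearity of the decoder; nothing
  in the loss pins its sign or scale.  At desk scale the
  flattened-correlation margin over a spot-constant bulk baseline is small
  (order 0.01, averaged over 10 held-out slides in the bundled study), it
  depends on the feature-axis normalization above, and whether a given
  training run couples to the informative direction at all is itself
  seed-dependent — some training seeds yield a margin indistinguishable
  from zero.  The within-gene alignment of predictions with planted truth
  is the clearer signal of resolution.
- The per-row normalized graph is directed by construction; algorithms
  expecting symmetric adjacency should use the symmetrize switch.
- Training is single-threaded CPU numpy; full-scale configs (224 px inputs,
  256-wide channels) are supported but slow, and GPU execution is out of
  scope.
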