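# Methods

This note records the models, algorithms, numerical choices, and known
limitations behind `retwave`.  It is written for a reader who wants to know
exactly what is computed and why, in the package's own terms.

## Wave simulator

The simulator is a three-state excitable-medium cellular automaton on an
H×W grid, rendered as a calcium-imaging-like movie.  Per frame:

* every **quiescent** cell with k active 4-neighbours becomes active with
  probability 1 − (1 − `recruit_prob`)^k (recruitment),
* every remaining quiescent cell self-initiates with probability
  `strength_alpha` × 1e-4 (spontaneous wave initiation; the 1e-4 scale makes
  α = 0.5 yield roughly one initiation per 20 frames on a 32×32 grid),
* **active** cells stay active `active_duration_frames` frames, then enter
  a **refractory** period of `refractory_mean_frames` ±
  `refractory_jitter_frames` frames during which they cannot be recruited.

Rendering is a leaky calcium trace: intensity decays by
`calcium_decay_per_frame` (default 0.85) each frame and is reset to 1 while
a cell is active, plus Gaussian pixel noise (σ = 0.02) clipped to [0, 1].
The refractory period sets the quiet gaps between waves; with the defaults
a 3000-frame, 32×32 movie contains ≈ 25–30 wave events of ≈ 50–90 frames.

This automaton reproduces the *statistical* structure downstream stages
depend on — spatially contiguous propagating events separated by
inactivity, event frequency controlled by α, calcium-style decay, a matched
frame rate (11.7 Hz default) — and nothing else.  It is not a biophysical
model: there is no cholinergic/ionotropic distinction, no retina-shaped
mask, no velocity or domain-size calibration to recordings.

**Event segmentation** is threshold + run-length: a frame is active iff any
pixel exceeds `activity_threshold` (0.5), and maximal runs of ≥
`min_event_frames` (2) active frames become half-open events [start, end).
This is deliberately simpler than watershed segmentation of real calcium
movies; for clean simulated movies the two coincide at event granularity,
which is all the pipeline consumes.

**Shuffle controls.**  Spatial shuffling draws an *independent* pixel
permutation per frame, so only the per-frame intensity histogram over time
survives.  Temporal shuffling applies one global permutation of frame order
and keeps the original event index-ranges, so batch assembly still samples
"events" whose content is temporally scrambled (a per-event permutation
would be a milder control; the global variant is the one implemented).
Spatiotemporal composes temporal-then-spatial with sub-seeds spawned from
the one shuffle seed, so it equals the composition of the two singles.

## Contrastive objective

Embeddings are L2-normalized projector outputs; similarities are cosines at
temperature τ (default 0.5, the standard SimCLR operating point — the
temperature is not otherwise constrained by the problem).  For anchor i
with positive p(i) (the frame `pair_gap` later in the same event; default
gap 1 = "consecutive"), the per-anchor loss is

    −log [ exp(s_ip/τ) / (exp(s_ip/τ) + Σ_{j outside i's event} exp(s_ij/τ)) ]

averaged over anchors that have a positive.  Same-event frames other than
the positive appear in neither numerator nor denominator: they are neither
attracted nor repelled.  No image augmentations are applied — the positive
pairs are temporal, which is the point of the objective.

Batches are whole events, permuted per epoch and accumulated until the
frame count first *exceeds* `batch_frame_threshold` (3000 at full scale);
the remainder forms a final smaller batch, so each epoch covers every event
exactly once.  Optimization is Adam (lr 1e-4 at full scale) for 100 epochs
at full scale.

The neural-network layer is a compact NumPy engine (`_nn.py`): im2col
convolutions, ReLU, 2×2 average pooling, residual blocks, He fan-in
initialization, reverse-mode gradients checked against finite differences
in the test suite, and Adam.  Two backbones are provided: `tiny-conv`
(4 conv blocks, channel widths c·{1,2,4,8}, global average pooling, linear
embedding) for desk-scale work, and `resnet18-like` (3×3 stem + 8 residual
blocks, widths 64–512, no batch normalization) mirroring the full-scale
architecture.  The 3-stage MLP projector defaults to 8192³ and is removed
for readout evaluation.  Grayscale frames are min-max normalized per movie,
bilinearly resized to the encoder input, and replicated to 3 channels so
the same backbone accepts RGB task images.

## Tasks and readout

Base images are either drawn from a local CIFAR archive (one random image
from each of 10 random classes) or rendered synthetically (smooth random
texture + 1–3 random colored shapes), so the package runs with no external
data.  The translation task applies integer shifts drawn uniformly from
[−16, 16]² with zero fill ("affine up to 16 px" is implemented as pure
translation, which is the parameterization actually given).  The color task
applies, in fixed order, brightness, contrast, saturation (multiplicative
factors 1 ± u) and a hue rotation (±u half-turns), u ~ U[0.5, 1.0] with
random sign; values are clipped to [0, 1] after each stage.  Full scale is
5000 train / 1000 test images per base (50,000/10,000 total).

The readout is one linear layer on frozen backbone features, trained with
Adam and cross-entropy (full scale: lr 1e-4, 100 epochs, batch 100; the
optimizer family is a package choice — only lr/epochs/batch are pinned by
the protocol).  Encoder immutability is asserted by hashing the weights
before and after.

## Manifold geometry

All analyses receive a P×M×N manifold tensor (defaults P=50, M=20 at full
scale); activations wider than `max_N` = 2000 are first reduced by a seeded
Gaussian random projection, which preserves general position (feature
subsampling would not).

**Simulation capacity.**  For a candidate dimension N, features are
Gaussian-projected to N and each of `n_dichotomies` (50) random balanced
±1 labelings of the P manifolds is tested for *exact* linear separability
of all P·M points.  The separability decision uses convex duality: the
labeled points are separable with bias iff the origin lies outside the
convex hull of the label-signed augmented points y_i(x_i, 1); the
minimum-norm point of that hull is found by non-negative least squares
(an exact active-set method), and a positive residual (> 1e-7) certifies
separability.  This decision was validated against an LP feasibility oracle
(HiGHS) on dichotomies straddling the transition (40/40 agreement) and is
roughly an order of magnitude faster.  N_c brackets the 0.5 crossing of the
separable fraction by integer bisection (with an early stop once a majority
of dichotomies settles the side) and is refined by linear interpolation
between the bracketing dimensions; α_sim = P/N_c.  The bisection stops when
the bracket is within 2% of N, which bounds the interpolation error well
below the Monte-Carlo noise of 50 dichotomies.

**Mean-field capacity, dimension, radius.**  Following the point-cloud
replica analysis, each manifold (after subtracting the global mean of all
P·M points) is represented in its own subspace: axis coordinates s_j of the
centered points divided by the center norm, augmented to s̃_j = (s_j, 1).
For each Gaussian direction T in this (D+1)-space, the convex program

    v(T) = argmin ‖v − T‖²  s.t.  s̃_jᵀ v ≤ 0 for all j

is solved through its dual (again NNLS: T − v = S̃ μ, μ ≥ 0).  The
inverse capacity is the average squared margin cost E‖T − v‖², so
α_c = 1/E‖T − v‖²; manifold estimates are combined as the inverse of the
mean inverse capacity.  When the constraint is active, T − v is a conic
combination of hull points; rescaling it to unit center coordinate yields
the **anchor point** a(T).  R_M is the root-mean-square anchor norm (in
units of the center norm) and D_M the mean squared alignment
(T·â)² of the Gaussian direction with the unit anchor.  Degenerate cases
fall out correctly: a zero-extent manifold has only the center constraint,
giving E[max(g,0)²] = 1/2 and hence α_c = 2, R_M = D_M = 0; rank-deficient
clouds use the reduced SVD basis.  With 200 Gaussian samples the
Monte-Carlo standard error on α_c is a few percent; the test suite checks
α_c against α_sim within 15% on random ensembles, and both routes are
invariant under rotation and global scaling by construction (checked).

**Participation ratio** is (Σλ)²/Σλ² over covariance eigenvalues, computed
from singular values of the centered activation matrix.  **Center
correlation** is the mean absolute Pearson correlation over all P(P−1)/2
pairs of manifold centers after subtracting the global mean (absolute
rather than signed, so opposite-direction clustering also counts).
**Explained-variance dimension** is the smallest k whose top-k eigenvalues
reach the target fraction (0.9).

## Experiment profiles and problem sizes

`ExperimentConfig` bundles three profiles:

* **full** — full-scale hyperparameters (ResNet backbone, 8192³ projector,
  100 epochs, batch threshold 3000, 5000/1000 images per base, P=50, M=20).
  Exposed for completeness/cluster use; not exercised by the test suite.
* **desk** — 32×32 movies of 3000 frames, tiny-conv (16 base channels,
  128-dim embedding, 64³ projector), 20 epochs, 500/100 images per base,
  P=20, M=10.
* **tiny** — the test-suite profile: 24×24 movies of 900 frames, 8 base
  channels, 64-dim embedding, 6 epochs, 120/40 images per base, P=10, M=8.

The directional-replication tests use the tiny profile with 30 pre-training
epochs at lr 3e-4 and a lr 1e-3 / 100-epoch readout: small enough for a CPU
test run, large enough that contrastive pre-training moves the loss
substantially (≈ 5.1 → 3.5).  Epoch count matters more than movie size
here: the benefit of wave pre-training over random initialization has a
transient — partially trained encoders (≈ 20 epochs at this scale)
*underperform* He initialization on the translation readout, and the
advantage appears only once the loss has descended well past its plateau.
At reduced scale the readout also needs a larger learning rate (1e-3) than
the full-scale protocol (1e-4) simply because it takes ~40× fewer gradient
steps; the full-scale values remain the defaults of the `full` profile.

**What the scaled-down replication does and does not reproduce.**  Across
seeds, unshuffled-wave pre-training beats random initialization on
translation-task accuracy, and it lowers pairwise center correlations —
the global separability mechanism.  Two full-scale geometry effects do
*not* emerge at this scale, and the corresponding directional tests fail
honestly rather than being loosened: (i) final-layer translation-manifold
capacity of pre-trained networks sits slightly below random initialization
(confirmed with both the mean-field α_c and the independent α_sim route,
which agree, so it is not an estimator artifact); (ii) temporally shuffled
pre-training does not inflate the participation ratio above the unshuffled
condition, because at this scale the temporal-shuffle objective is
unlearnable for the small encoder (its loss stays flat or rises) and the
condition remains near random initialization, while unshuffled training
raises PR from ≈ 1.5 to ≈ 2.2.  Both effects plausibly require the
full-scale regime (deep residual backbone, ~2×10⁵ frames, 100 epochs).

## What the synthetic data does and does not show

The synthetic movies reproduce contiguous propagation, α-controlled event
frequency, calcium decay, and inter-event silence, but not the noise
structure, vignetting, non-stationarity, or spatial correlations of real
macroscope recordings; the synthetic base images are far simpler than
natural images (large single shapes, smooth textures).  Passing the
directional tests therefore shows that the *mechanism* — temporal
contrastive learning on spatiotemporally structured activity improving
linear separability of translated objects — operates as described at small
scale on data with the stated statistics.  It does not certify effect sizes
on natural images or real retinal recordings, and the small-scale readout
accuracies are far below full-scale ones.

## Known limitations

* No batch normalization in either backbone; at full depth (`resnet18-like`)
  contrastive training without normalization layers may need smaller
  learning rates than the defaults.
* The temporal-shuffle condition at small scale barely reduces the
  contrastive loss (its positives are random frame pairs, and the small
  encoder lacks the capacity to memorize them), so effects that depend on
  that condition *actively learning* extraneous features are attenuated
  relative to full scale.
* `simulation_capacity` assumes points in general position after Gaussian
  projection; exactly duplicated manifolds across the P set would make
  balanced dichotomies non-generic.
* The mean-field procedure treats manifolds independently (no
  correlated-center corrections); with strongly correlated centers α_c can
  deviate from α_sim by more than the quoted 15%.
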