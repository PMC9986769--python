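# Methods

## Problem

Craniomaxillofacial (CMF) surgical planning needs accurate 3D anatomical
landmarks on the mandible, maxilla and nasal bones. Segmentation-based
landmarking fails exactly where it matters most — severely deformed or
post-surgical bone — so this package treats landmarking as *imputation on the
landmark manifold*: given the pixel-space positions of a few landmarks
(`L_input`, size n), predict the positions of the remaining landmarks
(size m), using only geometric relations between points, never images.

The vocabulary is fixed at 14 landmarks: nine mandibular (Me, Gn, Pg, B, Id,
CorL, CorR, CdL, CdR), four maxillary (ANS, A, Pr, PNS) and nasion (Na).
Five input/target partitions are built in (`three-regular`, `three-cross`,
`five`, `six`, `nine`); all satisfy n + m = 14 and keep the menton (Me) in
the input set, since it serves as the geometric reference origin.

## Model

The relational reasoning network (RRN) is a two-stage composition of small
trainable *relational units* (RUs):

    G_i  = (1/(n-1)) Σ_{j≠i} g_θij( features(o_i, o_j) )      pairwise stage
    RRN  = (1/n) Σ_i f_φi( G_i )                              global stage

There are n(n−1) pairwise units g (one **unshared** parameter block per
ordered pair) and n global units f — n² RUs in total (25 / 9 / 36 / 81 for
the five / three / six / nine configurations). Mean aggregation in both
stages makes the prediction invariant to the order in which input landmarks
are listed; the package additionally canonicalizes the input-set order to the
vocabulary order so predictions are bit-for-bit reproducible.

Each ordered pair is described by a 19-component geometric feature vector:
the pixel-space positions of both landmarks and of Me, spherical coordinates
(r, θ, φ — physics convention, θ polar from +z, φ = atan2(y, x), zero vector
mapping to zeros) of the three difference vectors o_A−Me, o_B−Me, o_B−o_A,
and the mandible extent d1 (diagonal of the bounding box of the input-set
mandibular landmarks). Features are pure pixel-space quantities; voxel
spacing enters only at evaluation. No feature standardization is applied
before the first RU layer — the RU's leading batch normalization is the
normalizer.

Two RU architectures are provided:

- **MLP RU** — three fully connected layers with two batch normalizations
  and two ReLUs; hidden widths default (256, 256), output `relation_dim`
  (default 256).
- **Dense-block RU** — linear projection of the input to a
  `relation_dim`-length sequence, one dense block of 4 kernel-3
  1-D convolutions with growth rate 4 (channel concatenation after each
  layer), then a linear projection to the output width. The 1-D convolution
  is implemented channels-last as three tap GEMMs with output-shifting,
  which keeps the whole unit inside batched matrix products.

Each global unit emits 3m values. Internally the head is parametrized as
offsets from Me, affinely normalized by the training-set offset mean and
standard deviation (set at the start of `train()`), so optimization starts
at the mean shape and learns residuals; predictions are always absolute
pixel coordinates and the loss below is unchanged by this reparametrization.

**Loss.** Mean squared error over the *per-input* predictions:
`(1/(n·m)) Σ_i Σ_k ‖f_φi(G_i)_k − o_k‖²` in pixel space. The consensus
(averaged) prediction is what is evaluated and reported.

**Dropout variants.** `regular` masks hidden activations (rate 0.5);
`variational` multiplies hidden activations by learnable-variance Gaussian
noise (1 + √α·ε) with an approximate KL penalty 0.5·Σ log(1 + 1/α) pulling
toward the N(0, I) prior (weight 1e-4; inference uses the noise mean, so it
is deterministic); `targeted` builds, per weight matrix per RU, the target
set of the γ-fraction smallest-magnitude weights (ties by index) and drops
each independently with probability α per optimization step (defaults
γ = α = 0.5).

## Training

Adam (lr 1e-3, default moments) on mini-batches of 64 cases, cosine-decayed
to a 0.1 lr floor over the epoch budget; budgets follow the convergence
behaviour of the two architectures: 100 epochs for the regular-dropout MLP,
20 for everything else. All randomness (initialization, batching, noise)
derives from one master seed split into named substreams, so runs are
exactly reproducible. Parameters are float32 by default (`RUSpec.dtype`);
gradient correctness of the underlying tape is verified against numerical
differentiation in float64.

After the optimization loop the batch-norm inference statistics are
re-estimated exactly: one pass over the training set under the final weights
(noise layers disabled) replaces the exponential moving average, which
otherwise lags the moving weights and mis-calibrates evaluation mode. The
variance accumulators run in float64 because the E[x²]−m² form cancels
catastrophically in single precision on pixel-scale activations. Batch-norm
ε is 1e-3: large enough that float32 rounding on ~10²-scale features cannot
dominate a degenerate zero-variance feature.

## Synthetic cohort

The CBCT cohort this method was designed for is not public, so the package
generates a stand-in with the same study conditions:

- **Template**: 14 landmarks placed anatomically on a nominal 256×256×512
  grid (midsagittal plane x = 128, z superior), mirror-symmetric
  coronoid/condylar pairs, the anterior chain Me–Gn–Pg–B–Id closely spaced
  (≤ 15 px between neighbours) and the five sparse mandibular landmarks
  pairwise ≥ 40 px apart.
- **Shape model**: 6 fixed population modes — smooth low-frequency
  displacement fields evaluated at the template landmarks, normalized to
  unit RMS — drawn once per template seed. Per-case shape is a random linear
  combination of these modes, so deviations at different landmarks are
  coherent the way real anatomical variation is (the premise that makes both
  landmark imputation and shape-interpolation augmentation meaningful).
  Every case draws healthy variation at 4 px RMS per landmark (~2.5 mm);
  deformity severity adds 0 / 6 / 15 px RMS for normal / deformed / severe,
  mixed at 70% / 27% / 3%.
- **Pose**: random similarity transform per case — rotation ≤ 10°, scale
  0.9–1.1, translation ≤ 20 px.
- **Annotation noise**: Gaussian jitter, σ = 1 px per axis (single-observer
  repeatability; inter-observer spread is reported around 3 px and would be
  the right scale for multi-annotator simulations).
- **Spacing**: 0.754 × 0.754 × 0.377 mm, one of the two resolutions the
  cohort was scanned at, so millimetre errors are on the clinical scale.
- **Augmentation**: convex interpolation of 2 or 3 randomly chosen base
  cases (k uniform on {2, 3}, Dirichlet(1) weights) plus uniform
  per-component noise bounded by ±5 px — rigid transforms generate no new
  relations, so shape-space interpolation is used instead. Augmented cases
  record their parent case ids.

What the generator does **not** emulate: imaging artifacts (metal, braces),
observer-specific bias, left/right asymmetry of deformities beyond what the
random modes produce, and anatomy outside the 14-landmark set. Passing tests
on this cohort therefore demonstrate that the architecture recovers
low-dimensional, coherent shape variation under the published noise and
augmentation conditions — not performance on real CBCT annotations.

## Evaluation

Cross-validation is fourfold over *base* cases; augmented cases join the
training side only, assigned to their primary (largest-weight) parent's
fold, and any augmented case with a parent in the current test fold is
excluded from that fold's training set, so no information about a held-out
subject leaks into training. Errors are Euclidean distances in anatomical
space: per-axis pixel residuals scaled by the case's voxel spacing. Reports
give per-landmark mean ± standard deviation across cases (with RMSE as an
extra column — the mean±std presentation and the RMSE name are reconciled by
reporting both), outliers (default threshold mean + 3σ per landmark), and a
Table-style row with "—" for input landmarks. Method comparisons use a
paired two-sided t-test at the 0.05 level; identical sequences are reported
as not-different with p = 1.

The mean-position baseline (predicting each target landmark at its
training-set mean position) is the floor any relational model must beat; on
the default synthetic cohort it sits at ~13 mm against ~3.5 mm for the
trained network.

### Noise floor of the synthetic protocol

The headline error on this synthetic cohort is bounded below by the noise
conditions, not by the network. An oracle linear estimator trained under the
identical conditions (noisy augmented training folds, clean held-out base
cases) reaches ~2.8 mm; decomposing it, the pose-and-mode geometry alone is
essentially exactly invertible (~0.24 mm), the 1 px annotation jitter alone
raises the floor to ~2.0 mm (about 13 degrees of freedom are fitted from 15
noisy input coordinates, so test-input jitter propagates with leverage
above one, on top of the ~0.95 mm irreducible target jitter), and the ±5 px
augmentation noise adds errors-in-variables attenuation to ~2.8 mm. The
trained RRN sits at this floor (~3.5 mm with the full severity mix), and
beats the mean-position baseline on every landmark by roughly 4×. Reported
sub-millimetre localization errors for chain landmarks in the clinical
literature are only attainable when evaluation targets carry no independent
annotation noise; with any realistic noise model the per-landmark floor is
the annotation noise itself.

## Scaled-down problem sizes

The bundled experiments run the full cohort of the study conditions
(250 base + 5,000 augmented cases) but reduce the relational-unit width
(`relation_dim` 32 instead of 256) so a fourfold cross-validated training of
the 25-RU dense network completes in minutes on one CPU core; width probes
at 64 showed no accuracy change at this problem size, so the reduction does
not alter the conclusions. The noise-free recovery experiment uses 100 base
+ 800 augmented cases for the same reason.

## Known limitations

- The printed trainable-parameter counts of the original architectures are
  not reproducible from the published description (hidden widths and
  relation dimensionality are unstated) and are deliberately not targeted.
- The dense-block RU follows the textual description (one dense block);
  a figure in the source material shows two blocks — the text is followed.
- The variational dropout scheme is an approximate multiplicative-noise
  formulation with a simple KL surrogate, not the exact Bayesian posterior.
- Whether the published loss also penalized the consensus prediction is
  unstated; this implementation penalizes per-input predictions only,
  matching the formula.
- φ (azimuth) wraps at ±π; cases whose pair directions straddle the wrap
  present a discontinuous feature to the network. Any consistent convention
  shares this property.
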