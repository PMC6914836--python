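# Methods

## Decoding model

The decoder treats a whole-brain volume as a *sequence* of axial slices and
reads it the way a recurrent network reads a sentence. The convolutional
feature extractor (conv3-16, conv3-16, conv3-16, conv3-16, conv3-32,
conv3-32, conv3-32, conv3-32; all kernels 3×3, ReLU) downsamples each slice
with stride 2 on the odd-numbered layers and stride 1 on the even-numbered
ones. Zero-padding is SAME with ceil-division under stride: layer output
size is `ceil(n / stride)`, which is the only padding convention under which
a 74 × 92 slice flattens to 5 × 6 × 32 = 960 features after the four
stride-2 layers. The bi-directional LSTM runs two independent units over
the slice sequence, one inferior→superior and one superior→inferior; their
final-step outputs (40 each by default) are **concatenated** — the merge
rule is a design choice here, concatenation being the standard
bi-directional contract — and a fully-connected softmax layer yields one
probability per state. Argmax ties break to the lowest class index.

Convolution is implemented as cross-correlation (no kernel flip), the
prevailing deep-learning convention. The whole model, its backward pass and
the LRP engine are plain numpy over an explicit per-layer forward cache.
This is a deliberate design: relevance propagation needs every intermediate
activation and per-layer control of the backward rules, and at the package's
problem sizes (slices up to ~100², sequences of ~10–80 slices) vectorized
numpy is fast enough for CPU training in minutes. Correctness of the
backward pass is pinned by a central-difference gradient check at 1e-4
relative tolerance.

## Training

ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on categorical cross-entropy;
defaults: learning rate 1e-4, batch 32, up to 60 epochs, global
gradient-norm clipping at threshold 5, Glorot-normal weight initialization
(variance 2/(fan_in + fan_out)) with zero biases. Dropout is inverted
dropout on layer outputs: drop 30% on conv layers 1–2, 40% on layers 3–4,
50% on the remaining conv layers and on the concatenated LSTM output that
feeds the softmax layer; placement on outputs (post-ReLU) is a design
choice. Early stopping monitors validation cross-entropy with patience 5 and
restores the best weights; when no validation set is supplied a stratified
20% split is carved from the training data. All randomness (split,
shuffling, dropout) derives from the config seed, and since the numerics
are plain numpy the training loop is strictly deterministic: two runs with
the same seed are bit-identical.

For the desk-scale end-to-end protocol (below) the package uses learning
rate 1e-3 with ≤30 epochs: the 1e-4 default is calibrated for tens of
thousands of samples over 60 epochs, and at ~1.3k samples a proportionally
larger step reaches the same optimum in the shorter budget.

## Relevance propagation

Relevance is seeded at the **pre-softmax logit** of the target state (the
softmax is monotone per logit, so attributing the logit attributes the
decision; decomposing the probability instead would only rescale maps).
Three backward rules cover the network:

* **ε-rule** for every weighted connection (output layer, the LSTM gate and
  candidate projections, the convolution layers):
  `R_{i←j} = z_ij / (z_j + ε·sign(z_j)) · R_j` with `z_ij = a_i w_ij`,
  `z_j = Σ_i z_ij`, `sign(0) := +1`, ε = 0.001 by default. Biases absorb no
  relevance, so conservation is exact only for bias-free layers (the
  package's initializer sets biases to zero; trained models deviate by the
  bias share, which is the documented approximation).
* **Gate/source rule** for multiplicative connections: in
  `h_s = o_s ⊙ tanh(C_s)` and in each product of the cell update, the
  sigmoid gate receives zero relevance and the gated signal all of it. The
  additive cell update `C_s = f⊙C_{s-1} + i⊙C'` is split between its two
  terms by the ε-rule with `z₁ = f⊙C_{s-1}`, `z₂ = i⊙C'` (the additive
  split is not dictated by the gate rule and is recorded as a design
  choice).
* **Transparent nonlinearities**: ReLU and tanh pass relevance unchanged.

Relevance landing on zero-padding is discarded (it is provably zero, since
padded activations are zero). The relevance reaching the two LSTM
directions flows through the ε-rule over the concatenated final-h weights —
no ad-hoc 50/50 split. Propagation is linear in the seed, so scaling the
seed scales every voxel relevance; this and layer-wise conservation are
asserted in the tests, with conservation measured as
`|out − in| ≤ tol · Σ|in|` because the signed layer sums of a batch can
nearly cancel and make a naive relative error ill-conditioned.

## Brain maps

Only correctly decoded TRs acquired 5–15 s (inclusive) after their block's
onset are decomposed — the window where the hemodynamic response is
strongest. Each map is smoothed (3 mm FWHM Gaussian), averaged within state
per subject, then across subjects for the group map. Maps are restricted to
positive relevance (evidence *for* the state) before thresholding at the
90th percentile of the positive in-mask support; the percentile is computed
with linear interpolation over in-mask voxels only (including out-of-brain
zeros would distort the threshold). Whether positive-restriction precedes
the percentile is exposed as a flag (`positive_only`), defaulting to the
restricted order.

## Preprocessing

Fixed order: 3 mm FWHM Gaussian smoothing of each frame → per-voxel linear
detrend + standardization (zero mean, unit variance; zero-variance voxels
map to zero, never NaN) → zero-phase Butterworth highpass with 128 s cutoff
→ box mask. The filter is order 5 applied forward–backward (the order and
phase behavior are design choices; only the family and cutoff are fixed by
the protocol), so the realized amplitude gain is |H(f)|². The brain mask
marks voxels above 5% of each volume's maximum and takes the filled
per-axis bounding box over the dataset — a box, not a contour. Coordinates
are 0-based voxel indices; the NIfTI affine is carried unmodified. Events
use half-open intervals `[onset, onset + duration)` and TR timestamps are
`index × TR` with no slice-timing offset.

## Baselines

* **GLM**: voxelwise OLS of `Y = Xβ + ε` with one HRF-convolved boxcar per
  state plus intercept; per-predictor t-tests with dof `T − P`, two-sided p,
  Benjamini–Hochberg FDR thresholding (q = 0.1 by default). The per-state
  contrast is the state's own coefficient against baseline.
* **Searchlight**: for every in-mask voxel, the sphere of radius 5.6 mm
  (brute-force integer-offset enumeration, Euclidean in millimetres) is
  classified with a linear SVM under stratified 5-fold cross-validation;
  the method's overall accuracy is the maximum over locations and its
  predictions come from the best-location sphere (ties to the lowest linear
  voxel index). Spheres with fewer than two in-mask voxels are missing.
* **Whole-brain lasso**: one-vs-rest L1-penalized logistic regression over
  all voxels, minimized by proximal gradient (ISTA) with backtracking line
  search — chosen over accelerated variants because it guarantees the
  penalized objective is monotone non-increasing per iteration, which the
  package asserts. The intercept is unpenalized; convergence at 1e-8
  relative objective change; λ is selected on validation accuracy over a
  grid. A multinomial-softmax variant is a possible extension; one-vs-rest
  is the implemented reading of the binary formulation.

## Synthetic data

The generator emulates a four-state visual block paradigm: per run,
`blocks_per_state` blocks of each state (20 s default) separated by 10 s
rest, in a shuffled per-sweep order. Voxel signal is baseline (100) +
linear drift (0.01/volume) + a slow sine (120 s period, amplitude 1) +
i.i.d. Gaussian noise (σ = 1), and voxels of state k's ROI additionally
carry `effect_amplitude ×` (state-k boxcar ⊛ double-gamma HRF). The HRF
peaks at ~6 s with a ~16 s undershoot; the convolution kernel is scaled to
unit sum so a sustained block plateaus exactly at the effect amplitude —
with the default amplitude 5 and noise 1 the plateau SNR is literally 5.
Default ROIs are four disjoint radius-3 spheres in the x–y quadrants of the
16 × 16 × 12 grid (~123 voxels, ~4% of the grid each). The drift has both a
linear and a sinusoidal part so detrending and highpass filtering are
independently testable; the 120 s sine deliberately sits near the 128 s
cutoff, where it is only partially attenuated, as slow physiological drift
would be.

What the generator does *not* model: head motion, spatially correlated
noise, physiological confounds, between-run session effects, anatomical
variability between subjects (all subjects share the ROI layout; only noise
and block order differ). Passing recovery tests therefore demonstrates the
correctness of the pipeline's machinery and its behavior under the stated
noise model — not performance on real fMRI, where registration error and
structured noise dominate.

## End-to-end recovery protocol

The heavy acceptance check generates 11 subjects at the study conditions
(8 train / 3 held out), preprocesses with the full chain, trains a 40-unit
model (≤30 epochs, lr 1e-3, the dropout schedule above, seed fixed), and
requires (a) held-out decoding accuracy ≥ 0.90 over hemodynamically valid
TRs and (b) per-state group relevance maps whose top decile overlaps the
planted ROI at F1 ≥ 0.5 (chance ≈ 0.04). Accuracy is evaluated over the
5–15 s post-onset window because the paradigm itself bounds the
all-TR accuracy: the BOLD response is near zero for the first ~5 s of each
20 s block, so those TRs are undecodable in principle (the measured decoding
time course is at chance at offsets 0–4 s and at 1.0 from ~6 s on, giving an
all-TR ceiling near 0.81). Both accuracies are reported by the package. The
problem sizes (16 × 16 × 12 grid, ~1.3k training samples, 250-volume runs)
are chosen so the whole protocol runs in a few minutes on one CPU core.

## Numerical notes and limitations

* ε stabilization makes the LRP backward total deviate from the seed by
  O(ε/|z_j|) per layer; conservation tests use ε = 1e-9 and the default
  0.001 is a compromise between conservation and numerical stability on
  near-zero pre-activations.
* A negative target logit yields a negative seed; the evidence-for reading
  of relevance assumes a positive prediction score, so such samples are
  flagged by `RelevanceMap.logit` and the map-aggregation stage only
  consumes correctly decoded samples (whose target logit is almost always
  the largest and positive in practice).
* `lasso_fit` is first-order; at λ = 0 on well-conditioned problems it
  matches an independent second-order solver to ~1e-3, but tight tolerances
  need many iterations — it is a reference implementation, not a speed
  champion.
* Searchlight accuracy ties are common on strong-signal synthetic data;
  the lowest-index tie-break means the reported best location can be any
  sphere that sees informative voxels, not necessarily the ROI center.
* The percentile threshold uses linear interpolation, so an infinitesimal
  quantile sits marginally above the minimum and can exclude exactly the
  minimum voxel.
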