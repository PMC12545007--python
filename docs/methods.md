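# Methods

This note documents the models implemented in `eegflow`, the choices made
where the design was genuinely open, and what the synthetic benchmark does and
does not establish.

## The invertible generative classifier (EEG-InvNet)

The core model is a normalizing flow over 2-s, 21-electrode EEG windows
(`21 x 128` samples at 64 Hz by default).  The network stacks `n_stages`
stages; each stage begins with a Haar squeeze that halves the temporal
resolution and doubles the channel count (means in the first half of the
output channels, differences `a - b` in the second), followed by
`blocks_per_stage` blocks of

1. **activation normalization** — learned per-channel affine transform,
   initialized on the first training batch so post-layer activations have
   zero mean and unit variance per channel;
2. **invertible linear** — a learned square channel-mixing matrix, initialized
   random-orthogonal, `log|det|` computed directly by `slogdet` (channel
   counts stay at or below 168, so LU-based parameterizations are
   unnecessary); non-singularity is asserted after every optimizer step;
3. **additive coupling** — one half of the channels is shifted by a small
   convolutional network (two same-padded convolutions, kernel 3, hidden
   width twice the input channels, ELU in between) of the other half.  The
   transformed half alternates between blocks so all channels are updated.
   The final convolution is zero-initialized, so every coupling starts as the
   identity, which stabilizes early training.  The Jacobian is unit-triangular:
   `log|det| = 0`.

Because every layer is bijective and dimension-preserving, the model assigns
exact densities by the change of variables
`log p(x|c) = log N(z; mu_c, diag(sigma_c^2)) + log|det df/dx|` with one
learnable diagonal-Gaussian latent prior per class (means initialized at 0,
standard deviations at 1).  With a 128-sample window the internal feature
maps are `42x64`, `84x32`, `168x16`; a 64-sample window halves each stage's
temporal size.  (The dimension-preserving rule `C x T -> 2C x T/2` is forced
by invertibility; any printed stage-size table that does not preserve
`C·T` cannot be realized by a bijection.)

**Classification and loss.**  Posteriors use Bayes' rule with uniform class
priors.  Training minimizes

    L(x, c) = -log softmax(log p(x|c') / t)[c]  -  alpha * log p(x|c),

where `t = exp(log_t)` is a learned temperature (initialized to the input
dimensionality so initial class logits are O(1)) and `alpha` is fixed to the
inverse of the input dimensionality (1/2688 for `21 x 128`), recomputed from
the configuration.  The generative term uses the true class only.

**Input scaling and noise.**  Raw windows are divided per channel by the
training-set median absolute deviation; the constant `log|det|` of this
scaling is folded into reported densities so they refer to input units.
Gaussian noise of std 1e-3 (scaled units) is added during likelihood training
to avoid degenerate densities on quantized signals.

**Optimization.**  AdamW (lr 1e-3, weight decay 1e-5, batch 64) under cosine
annealing with warm restarts every 25 epochs.  These defaults are exposed in
the training API and were not tuned for maximum accuracy.  All training is
deterministic given the seed.

Gradients come from a compact reverse-mode automatic differentiation engine
on numpy arrays (`eegflow.autodiff`), written for exactly the operations
these models need; every primitive's gradient is verified against central
finite differences in the test suite.  The moving-cosine and convolution
kernels use batched FFT correlations for speed on one CPU.

## Prototype visualizations

**Class prototypes** invert each class's latent mean: `x_c = f^{-1}(mu_c)`,
mapped back to input units by undoing the channel scaling.

**Per-electrode prototypes** optimize a single-electrode signal `x*` to make
the classifier favor a target class while marginalizing over the other
electrodes.  The marginal likelihood is approximated by Monte Carlo: training
windows are drawn (pooled across both classes) and electrode `e_k` is
replaced by `x*`; the average density is computed with a logsumexp.  For the
classification term only, per-sample log densities are divided by the
classifier's learned temperature before pooling, preventing a few background
samples from dominating; the generative term stays unscaled.  The total
objective mirrors the training loss: classification score plus `alpha` times
the marginal log-likelihood, with the same `alpha`.

Optimization uses Adam (lr 0.01) from a zero signal for 500 steps with fresh
64-sample background mini-batches by default; these sizes converge on the
synthetic task in a few CPU-minutes per electrode, and a `fixed_background`
switch exists for strict monotonicity checks.  The reported `mean_posterior`
is the average softmax probability of the target class over a fixed held-out
background set of 10,240 samples.

## EEG-CosNet and pattern transforms

The compact network is three steps: spatial filtering `h1 = Ws^T x`, absolute
moving cosine similarity of each spatially filtered channel with its own
temporal filter (stride 1, valid positions only; a 128-sample window with
64-tap filters gives 65 offsets), temporal averaging, and a sigmoid over a
linear readout.  Zero-norm segments define similarity 0 (no class evidence)
and propagate zero gradient.  Every feature lies in [0, 1], and predictions
are invariant to jointly flipping the sign of a spatial+temporal filter pair.

Training is by distillation: binary cross-entropy against the pathological-
class probabilities predicted by a trained EEG-InvNet (soft targets, no
temperature sharpening), same optimizer family and restart schedule.

For interpretation, discriminative weights are transformed into generative
patterns: each spatial filter is multiplied by the empirical electrode
covariance (estimated over all time points of all training windows, no
shrinkage by default; a shrinkage flag exists).  No whitening across filters
is applied, because each spatial filter pairs with its own temporal filter.
Classifier weights are multiplied elementwise by the mean absolute-cosine
feature over the training set — the mean-feature reading of the transform;
the covariance-of-features alternative can be computed from the exported
features if wanted.  Filters are ranked by this transformed classifier
weight (stable sort, ties by filter index).

## The sub-delta Fourier mixture

For 2-s windows the DFT bin 1 sits at 0.5 Hz.  Three features per electrode
are kept — Re(bin 0), Re(bin 1), Im(bin 1); 63 features for 21 electrodes —
using the unnormalized forward DFT so features are bit-for-bit reproducible.
The classifier is one shared 8-component diagonal Gaussian mixture in which
every component carries a learnable per-class weight (softmax over classes);
the class-conditional density reweights components by these class weights.
Training is by gradient descent on the same combined classification +
generative loss (alpha = 1/63, learned temperature) rather than EM, which
makes the "learnable class weight" formulation direct and shares the
optimizer infrastructure.  Means are seeded k-means++-style (random
initialization frequently leaves planted clusters uncovered, which gradient
descent cannot repair across well-separated modes); features are standardized
internally during fitting and the parameters de-standardized afterwards.
Variances carry a 1e-6 floor; a component whose raw variance collapses below
1e-8 is re-initialized with a warning.

## Preprocessing

Clinical-corpus reduction: drop the first 60 s, keep the next 120 s,
polyphase anti-aliased resampling to 64 Hz (exactly 7,680 samples), reorder
to the canonical 21-electrode 10-20 montage (FP1 ... O2; clinical labels like
`EEG FP1-REF` and modern names T7/T8/P7/P8 are alias-resolved), and cut
non-overlapping 2-s windows (overlap is configurable).  Recordings shorter
than 3 minutes are skipped with a logged reason; missing electrodes raise an
error naming them.  The recorded reference is kept; no re-referencing is
applied.  The sub-delta lowpass zeroes every DFT bin strictly above the
cutoff on the full signal, so it is idempotent and exactly preserves DC and
retained components.

## Spectral validation

Bandpower maps use 10-s windows with 5-s hop, a Hamming taper, squared
magnitude of the one-sided DFT without density normalization (ratios cancel
the normalization), the median across all windows of a class pooled over
recordings, band averages over delta (0-4), theta (4-8), alpha (8-14), low
beta (14-20), high beta (20-30), and low gamma (30-50, truncated at the
32-Hz Nyquist of 64-Hz data), and report `log(median pathological power) -
log(median healthy power)` per electrode — written as a difference of logs so
swapping the classes negates every value exactly.  Sub-delta amplitude maps
are class-wise means of |DFT| at bins 0 and 0.5 Hz of the 2-s windows.

## Synthetic data: what it emulates and what it does not

Each recording is 1/f-shaped Gaussian background noise (beta = 1, RMS 10 uV)
plus localized sources whose amplitude depends on the class: 10-Hz activity
at O1/O2 (healthy 12 uV, pathological 4 uV), 2-Hz activity at T3/T4 (4 vs
12 uV), and a 0.3-Hz frontal drift at FP1/FP2 (12 vs 4 uV).  Oscillatory
sources are amplitude-modulated with a random phase per recording so no
phase locking is learnable.  Defaults: 200 recordings per class, 60 s at
64 Hz, 75% train split — sized so the full study (generation, flow training,
prototypes, distillation, mixture fit) runs in minutes on one CPU.

The generator produces stationary Gaussian-plus-oscillation signals with
fixed topographies.  It does not model artifacts (eye blinks, muscle),
nonstationarity, inter-subject variability, volume-conduction realism, or
label noise.  Passing the recovery suite therefore shows that the
implementations are correct and that planted effects of realistic size are
found where they were planted — not that clinical-level accuracies transfer
to real corpora.

## Benchmark problem sizes

The end-to-end study run by the tests and by `scripts/acceptance.py` uses the
generator defaults (200 recordings per class, 12,000 windows, 75% train) and a
reduced 2-stage x 2-block flow trained for 12 epochs, which separates the
planted classes essentially perfectly.  Distillation uses 6,000 training
windows for 10 epochs (lr 1e-2, batch 256); self-distillation from a known
random CosNet teacher uses 4,000 windows; the pattern-recovery task uses
1,500 single-source windows; the mixture recovery task uses 10,000 windows
(8,000 train / 2,000 test).  Per-electrode prototypes in the benchmark run
200 optimization steps.  These sizes are the package's defaults for a
desk-scale study; all of them are arguments, not constants.

## Numerical notes and limitations

* All computation is float64; flow round-trips are exact to ~1e-11 and the
  acceptance bound of 1e-4 refers to the single-precision contract.
* `log|det J|` of every layer is analytic; tests compare against brute-force
  finite-difference Jacobians on small instances (tolerance 1e-3, limited by
  the finite-difference step).
* Cosine similarities are clipped to [-1, 1] against floating-point drift;
  zero-norm segments contribute 0 with zero gradient.
* Binary classification only; the latent priors, the mixture class weights,
  and the CosNet sigmoid all assume two classes.
* Affine couplings are not provided; the additive form keeps `log|det| = 0`
  and is the variant the visualization methods are designed around.
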