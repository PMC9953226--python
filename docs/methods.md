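# Methods

## The structure–potency fingerprint

An SPFP is the concatenation `[structure | potency]` of two binary
modules. The structure module is a folded extended-connectivity
fingerprint (Morgan algorithm, radius 2 — bond diameter 4 — binary,
no feature invariants) of fixed length 2048, computed with RDKit. The
potency module cumulatively encodes pIC50 over [5, 11]: with L bits
the per-bit resolution is r = 6/L (0.06 log units at the default
L = 100), and a value p sets bits 0..k with k = ⌊(p − 5)/r + ε⌋
clamped to [0, L−1]. Bit 0 is the lowest-potency interval.

Conventions worth stating explicitly:

* **Interval rule.** Intervals are half-open, [5 + k·r, 5 + (k+1)·r);
  a value exactly on an interior boundary belongs to the higher
  interval (8.0 → 51 set bits at default resolution). A small guard
  ε = 1e−9 is added before flooring so decimal resolutions such as
  0.06, which are not exactly representable in binary, cannot push a
  boundary value into the lower interval; the same clamp maps
  p = 11.0 into the last interval.
* **Validity.** A bit pattern is a valid potency module iff it is a
  non-empty contiguous prefix of ones. The all-zero pattern is
  invalid: every in-range potency sets at least one bit, so an empty
  module encodes no interval and cannot be decoded.
* **Decoding.** A valid module with k+1 set bits decodes to
  5 + k·r + r/2, the center of its interval, so every decoded value
  carries a constant half-width of r/2 (±0.03 at default L).

## The conditional VAE

Per activity class, an encoder q(z|X, c) maps the concatenation of
potency module X and condition c (the structure module) through tanh
hidden layers of sizes (512, 256, 128) to the mean and log-variance of
a diagonal Gaussian over the d-dimensional latent z; the decoder
p(X|z, c) maps [z | c] through the mirrored stack (128, 256, 512) to
per-bit Bernoulli logits. Training minimizes the batch mean of

    BCE(X, X̂) + β · KL( q(z|X,c) ‖ N(0, I) ),

with the cross-entropy summed over the L module bits and the KL in
closed form. We read the objective as BCE + β·KL (not a ½–½ average of
the two terms): a tunable β is only meaningful as a multiplier on the
KL, as in a β-VAE. σ from the hyperparameter grid is applied as the
standard deviation of prior sampling at prediction time,
z ~ N(0, σ²I); training always uses the N(0, I) prior in the KL. These
are the most standard readings of the two generation-relevant knobs;
alternatives (σ inside the training prior, a literal two-term average)
were considered and rejected as inconsistent with the grids.

Training details: Adam, Glorot-uniform initialization, inverted
dropout on hidden activations, maximum 150 epochs. A 10% split of the
training set is held out internally; the learning rate is halved
whenever that validation loss fails to improve for 10 consecutive
epochs ("steadily reduced" made concrete), and training stops early
after 20 stalled epochs with the best weights restored. A non-finite
loss raises a training-diverged error naming the epoch. All
randomness — initialization, shuffling, reparameterization noise,
prediction sampling — flows from the config seed, so fits are
bit-reproducible.

Prediction draws z from the σ-scaled prior, decodes under the query's
structure module, binarizes at 0.5 (threshold exposed in the config),
and applies the validity criterion; invalid samples are redrawn up to
`max_sampling_attempts` (default 100; no canonical value exists). On
exhaustion a deterministic repair is applied — the longest prefix of
positions with probability ≥ 0.5, forced to length ≥ 1 — and the
result is flagged `valid=False` so the benchmark never drops cells.
In practice the fallback decodes almost identically to a valid sample,
because the decoder's probability profile is monotonically decreasing
along the module for a trained model.

Hyperparameters are tuned by grid search with internal 5-fold
cross-validation on decoded-prediction MAE; the full grid is latent
dimension {16, 32, 64}, learning rate {0.1, 0.01, 0.001}, dropout
{0, 0.5}, batch size {16, 32, 64}, β {1, 2}, σ {0.01, 0.1, 1}.
Diverging grid points score infinity and are never selected while a
finite-scoring point exists.

The network is implemented directly in NumPy with hand-written
backpropagation (verified against numerical differentiation in
development); no GPU path is provided or needed at these model sizes.

## Baselines

* **SVR** with a precomputed Tanimoto kernel, T(a,b) = |a∧b|/|a∨b|;
  C tuned over {0.001 … 10000} by 5-fold CV on MAE; ε stays at the
  library default (only C is tuned). T of two all-zero vectors is
  defined as 1.0 so K(x,x) = 1 holds universally and the Gram matrix
  stays well-formed.
* **RFR** with grids: trees {50, 100, 200}, min-split {2, 3, 5, 10},
  min-leaf {1, 2, 5, 10}; 5-fold CV on MAE.
* **DNN**: feed-forward tanh regressor (scikit-learn MLPRegressor),
  Adam, squared-error loss (the standard choice for regression), up to
  200 epochs with early stopping; depth {2, 3}, width {100, 300, 500}
  (a discretization of the 100–500 range), batch {16, 64}, learning
  rate {0.1, 0.01, 0.001}, tuned on an internal 90:10 split. The
  MLPRegressor has no dropout, so that axis is fixed at 0 and
  regularization is carried by early stopping.
* **kNN** by Tanimoto similarity, k ∈ {1, 3, 5}, prediction = mean
  neighbor potency; similarity ties broken by ascending training
  index for determinism.
* **MR**, the mean regressor, predicts the training mean everywhere.
* **y-randomization** shuffles potencies across a class (structures
  untouched, potency multiset conserved) to give a chance-level
  control.

## Evaluation protocol

Classes are split 90:10 into train and test uniformly at random
(80:20 available as a control), over 10 independent trials; within a
trial every method is fit on identical training data and scored on
identical test data (asserted in tests). Metrics are MAE and RMSE of
predicted vs. experimental pIC50, overall and on the ⌈10%⌉ most potent
test compounds (ceiling count; cutoff ties resolved by stable order).
Method pairs are compared with the two-sided paired Wilcoxon
signed-rank test on per-trial metric values, α = 0.05, zero
differences dropped, exact null for ≤ 25 non-zero pairs and the normal
approximation above; per-compound pairing is available through the
same function by passing per-compound errors. The implementation is
cross-checked in the tests against brute-force sign-permutation
enumeration.

## Synthetic activity classes

The generator emulates the gross statistics of curated
target-based activity classes: compounds fall into a small number of
analog-series-like clusters, fingerprints are sparse (per-cluster
background bit probabilities from Beta(0.2, 2)), and potency is a
noisy linear function of 40 "signal" bits whose per-cluster
probabilities are set to 0.1 or 0.8 — the across-cluster contrast that
makes potency learnable from structure. Potencies are
center + 0.3·(signal count − class mean) + N(0, 0.4²), clipped to
[5, 11], with the default center pIC50 7 placing the median in the
high-nanomolar range and the overall spread near one log unit — which
puts the mean-regressor MAE near 0.8, where benchmark controls on real
classes typically sit. A single seed feeds three child RNG streams
(profiles, compounds, noise), so each stage is independently
reproducible, and the exact generative map is returned alongside the
class for recovery tests.

What the generator does **not** emulate: real substructure-potency
causality (bits are abstract, not chemistry), activity cliffs,
inter-class potency-distribution differences, assay noise structure,
or any particular target. Passing benchmarks on these classes
demonstrates that the pipeline learns a structure-encoded signal and
that its controls behave correctly — not that any method attains a
particular accuracy on real activity classes, whose published medians
(MAE ≈ 0.4–0.5 for learning methods, ≈ 0.8–0.9 for MR) this package
treats as qualitative orderings only.

## Problem sizes and defaults in tests

The benchmark-scale tests and acceptance checks run on synthetic
classes of 1000 compounds (learning sanity, single split) and 600
compounds (10-trial controls), with the CVAE at a reduced desk-scale
configuration (hidden sizes 128–64–32, latent 16, ≤ 40 epochs) that
reaches the same qualitative behavior as the full architecture on
these class sizes; the (512, 256, 128)/150-epoch configuration remains
the package default for real use. Baseline grids collapse to single
sensible points in those sweeps (`desk_scale=True` in
`spfp.methods.default_factories`); full grids are used when tuning is
itself under test.

## Known limitations

* Decoded predictions are quantized to interval centers, bounding
  accuracy below r/2 even for a perfect model.
* The CVAE's sampling validity rate depends on σ and training quality;
  the fallback keeps predictions total but marks them invalid rather
  than resampling indefinitely.
* Curation's medicinal-chemistry liability rules and aggregation
  advisor are exposed only as a caller-supplied predicate hook; the
  PAINS screen uses RDKit's standard catalog. Anti-target omission is
  a caller-supplied exclusion list.
* Duplicate-measurement merging defaults to the arithmetic mean of
  pIC50 values per compound-target pair (median and max available);
  no minimum class size is enforced by default.
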