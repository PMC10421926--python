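# Methods

`synthehr` generates synthetic electronic-health-record (EHR) cohorts with a
two-stage model — a masked sequential autoencoder over heterogeneous records
and a Wasserstein GAN with gradient penalty (WGAN-GP) trained in the
autoencoder's latent space — and evaluates the result with statistical
similarity, downstream-utility and privacy-attack metrics.  This note
describes the model, the numerical choices, what the bundled simulator does
and does not emulate, and the known limitations at the problem sizes the
package targets.

## Data model

A cohort couples a value container and a mask container.  Each patient
record holds static numeric features s^n, static categorical features s^c,
a variable-length sequence of measurement times u_τ, temporal numerics
t^n_τ and temporal categoricals t^c_τ, τ = 1..T(i), with 1 ≤ T(i) ≤ T_max.
Every entry carries a binary mask m (1 = observed).  Missingness is data,
not an error state: masks are modeled and generated jointly with values.
Two representation choices are ours:

- **step_present channel.**  Sequence length is exposed to the networks as
  one extra binary per-step channel that is 1 for the first T(i) steps and
  0 on padding.  It is trained and generated like any other mask; at
  synthesis the generated length T̂ is the leading run of ones after
  thresholding at 0.5, floored at 1.  This makes length generation
  learnable instead of requiring a separate length model.
- **Explicit missing slot.**  Each categorical feature's one-hot block has
  one slot per category plus a final "missing" slot, so unobserved entries
  have a well-defined encoding.  The mask channel remains authoritative:
  at synthesis, a mask of 1 with a codec vote for "missing" falls back to
  the most probable real category.

On disk a cohort is two delimited tables (static: one row per patient;
temporal: long format `patient_id, step, time, feature, value`).  Missing
entries are simply absent; each step writes one row under the time field so
steps with no observed features, and tied timestamps, survive a round trip.
Timestamps may tie (simultaneous measurements); they must be non-decreasing
within a record.

Preparation follows common practice for these cohorts: per-feature outlier
filtering at the 0.1/99.9 percentiles (computed on observed values only),
truncation of long sequences to their **last** T_max steps, padding to
T_max, and a per-patient 80/20 train/test split.  Outlier filtering
defaults to masking the offending value rather than dropping the patient —
dropping is available as `mode="drop_patient"` — because masking preserves
cohort size and the realism of the missingness pattern.

## Stochastic (frequency-proportional) normalization

Skewed marginals and discrete-jump CDFs (lab values recorded as multiples
of 5, alarm thresholds from a small set) are the classic trigger for GAN
mode collapse.  The normalizer assigns each unique observed value of a
feature a sub-interval of [0,1] whose width is the value's empirical
frequency, in ascending value order; the forward map replaces a value by a
uniform draw from its interval, and the inverse maps any point of [0,1] to
the value owning the containing interval.  The forward marginal is
approximately Uniform(0,1) — easy for the GAN — and the inverse is exact
on observed values for every seed.

Numerical conventions: intervals are half-open [lower, upper) with the
final interval closed at 1.0, so the inverse is total and unambiguous; an
interior boundary point belongs to the interval on its right; inputs
outside [0,1] are clipped first; uniform draws that round up to the open
endpoint are nudged down one ulp so the round trip is exact bit-for-bit.
Ascending-value iteration makes the map rank-preserving, so normalization
is monotone in distribution.  Fully continuous features degenerate to an
empirical-CDF rank transform with 1/n jitter buckets, which is supported
natively.  Measurement times are normalized with the same algorithm, as
one pooled feature.  Each feature draws from a named substream of the
master seed (CRC32 of the feature name), so per-feature results do not
depend on processing order.  Normalizers are fitted on the training split
only.  Serialization stores float hex strings for bit-exact round trips.

The ablation alternative (`stochastic_norm=False`) is plain min-max
scaling; its inverse is linear, so synthetic values are not restricted to
the observed support — grid-valued features come back off-grid, which is
precisely the failure mode the stochastic normalizer removes.

## Categorical codec

One codec per scope (static, temporal).  A single-hidden-layer MLP encoder
(hidden width 2·d_c, tanh-bounded output) maps the concatenated one-hot
blocks to a d_c-dimensional embedding; one linear-softmax head per feature
maps back to a probability vector over its V_k + 1 slots.  Training
minimizes the sum over heads of the softmax cross entropy.  d_c defaults
to min(16, ceil(ΣV_k / 2)).  The temporal codec is applied per step with
shared weights — the only shape-stable choice under varying step counts.
Ties in the decoding argmax break to the lower vocabulary index.  The
tanh bound keeps embeddings on the same scale as the normalized numerics,
which keeps the autoencoder's MSE terms commensurable.

## Masked sequential autoencoder

The encoder consumes, per step, the concatenation [t^n, t^ce, u, temporal
masks, step_present] through a GRU; the final recurrent state is joined
with (a) a feed-forward static branch over [s^n, s^ce, static masks] and
(b) a mean-pooled summary of the per-step inputs (a skip connection past
the recurrence, which measurably improves value reconstruction), then
projected linearly to the latent e ∈ R^{d_e}.  The decoder mirrors this:
static heads from an MLP on e, and a GRU fed e at every step whose head
also sees a normalized step-position channel.  Value heads are linear;
mask heads are sigmoid logits.

The reconstruction loss is binary cross entropy on every mask channel plus
λ times the mean squared error on values — and every squared-error term is
gated so that entries whose mask is 0, and padded steps, contribute
exactly zero (bit-identically zero, not approximately).  λ defaults to 1.
Categorical embeddings are reconstructed as embeddings (MSE) and decoded
through the frozen codec, rather than end-to-end through the softmax
heads.  Training uses Adam (lr 1e-3 default), minibatches over patients,
and a fixed seed; a NaN loss aborts with the history retained.  Defaults:
d_e = 64, hidden = 128.

## Latent WGAN-GP

The generator (MLP, depth 3, width 256; input z ~ N(0, I), d_z = d_e by
default) maps noise to latents.  Training happens in standardized latent
space — each latent coordinate centered and scaled by the training
latents' mean and SD — because the gradient penalty's unit-norm target is
only meaningful at an isotropic scale; the returned generator folds the
destandardization back in as a fixed affine output map.  The critic (same
shape) is trained 5 steps per generator step with the gradient penalty
η·(‖∇D(ẽ)‖−1)² on per-sample interpolates ẽ = εe + (1−ε)ê, one scalar
ε ~ U[0,1] per sample, η = 10.  Adam with β = (0.5, 0.9).  The penalty
requires differentiating through the critic's input gradient; the
package's autodiff engine (below) builds backward passes out of
differentiable primitives, so second-order gradients are exact.

Checkpoint selection defaults to the sliced-Wasserstein rule: every 25
generator steps, the mean 1-D Wasserstein distance over 64 random
projections between a real latent slice and a generated sample is
recorded, and the best iterate is returned.  Finite WGAN training orbits
the target distribution rather than converging to it — the final iterate
is an essentially random point on that orbit — so distance-based selection
buys a large fidelity improvement for negligible cost.  ``checkpoint="final"``
restores the last iterate.

## Synthesis

Sampling M records: draw ê = G(z), decode with the trained decoder, derive
T̂ from step_present (threshold 0.5, leading run, floor 1), realize masks,
decode categoricals, renormalize numerics and times, emit mask-0 entries
as missing, and sort each record's times non-decreasing (generation does
not guarantee order).  Every synthetic numeric therefore lies on the
observed training support.

**Masks and categoricals are sampled, not thresholded.**  The mask heads
are trained with BCE and the categorical heads with softmax cross
entropy — exactly the negative log-likelihoods of Bernoulli and
categorical conditionals — so drawing m̂ ~ Bernoulli(p̂) and categories
from the head distribution is sampling from the fitted model.  The
alternative (threshold at 0.5 / argmax; available as
`mask_mode="threshold"`, `categorical_mode="argmax"`) collapses whenever
the latent does not resolve individual entries: under
missing-completely-at-random patterns the per-entry mask is independent
of everything else, the BCE-optimal prediction is the marginal rate, and
thresholding then declares a feature always-observed or never-observed.
Sampling reproduces the marginal missingness by construction and degrades
gracefully toward thresholding as reconstruction sharpens.  Sequence
lengths keep the deterministic threshold rule because the step-present
probabilities do vary sharply across the cut point and reconstruct well.

**Bucket-matching post-processor** (off by default): per numeric feature,
buckets are real-sample quantile intervals; synthetic values are re-ranked
and per-bucket occupancies allocated by largest remainder to match the
real proportions exactly, with within-bucket values drawn from the real
empirical distribution there.  The map is rank-preserving, idempotent for
a fixed seed, and has no trainable parameters; with 200 buckets on 10^4
samples it drives the two-sample KS statistic below 0.01 regardless of how
mismatched the input was (the deviation inside any bucket is bounded by
the bucket mass ≈ 0.005 plus rounding).  It is applied per feature
independently, on observed entries only, and left off by default because
marginal matching can slightly erode joint-structure utility.

## Evaluation

*Statistical similarity*: per numeric feature — mean, SD, missing rate
(mask-0 slots over slots within the true T(i); padding is not a
missingness event), and the two-sample KS statistic on observed values;
per categorical feature — per-category ratios among observed entries.

*Utility (TSTR)*: train a classifier on real vs. on synthetic data, score
both on the real held-out test set (AUC and average precision).  RF and
logistic regression consume a flattened table — static features plus, per
temporal feature, last observed value, mean of observed and observation
count, with missing summaries imputed by training means; the GRU variant
consumes the sequences directly.  The random-subset test repeats TSTR on
random feature subsets and applies a one-sided one-sample t-test of
H₀: mean |performance difference| ≥ X (default X = 0.04); small p rejects
H₀, i.e. supports fidelity within X.

*Privacy*: (1) membership inference — distance from each query record to
its nearest synthetic record; the adversary applies the
accuracy-maximizing threshold on the pooled balanced queries (an upper
bound on attack power); ideal balanced accuracy 0.5.  (2) re-identification
— the adversary knows a random half of a training record's flattened
features, matches on them against the synthetic set, and succeeds if all
unknown numerics agree within 0.05 (min-max normalized) and unknown
categoricals exactly; the reference is the same procedure against held-out
real records, with the same per-record known-feature draws so that
replacing the synthetic set by the holdout reproduces the baseline
exactly.  known_fraction = 1 is degenerate (vacuous success) and flagged.
(3) attribute inference — kNN (k = 5) classifiers trained on synthetic
vs. real data predict a sensitive attribute on real evaluation records;
binary attributes report AUC, multi-class ones the mean of all pairwise
one-vs-one AUCs.  All attacks share one distance: Euclidean on min-max
scaled numerics plus Hamming on categoricals, combined additively.  These
are declared defaults, not claimed reproductions of any particular
published configuration.

## Toy cohort simulator

The simulator provides ground-truth-known cohorts shaped like inpatient
EHR data: skewed continuous laws (gamma, lognormal), grid-valued laws
(multiples of 5), bimodal mixtures, nonuniform categoricals, exponential
inter-measurement gaps (cumulative, hence non-decreasing times), sequence
lengths 1 + Poisson clipped to [1, T_max], per-feature MCAR missingness
with optional severity-dependent (MAR) tilt, and a binary outcome from a
logistic model on a latent severity plus a standardized covariate, with
the intercept calibrated by root finding to a target prevalence (default
0.10).  The `mimic-like` preset uses 3 static numerics, 3 static
categoricals, 10 temporal numerics (missingness 0.30–0.80), 2 temporal
categoricals, lengths 1–30.

What it does not emulate: real measurement-time clustering (ward
routines), cross-feature physiological constraints, informative dropout,
code vocabularies of realistic size, or longitudinal non-stationarity.
Passing tests on the simulator therefore demonstrate that the machinery is
correct and calibrated on data with the declared difficulty axes — not
that clinical-grade fidelity would be reached on a credentialed cohort.

## Problem sizes and known limitations

The test and acceptance runs use n = 2000 patients, T_max = 30, d_e = 64,
hidden width 128, 32 autoencoder epochs and 1500 GAN iterations — sizes
chosen so a full simulate–train–synthesize–evaluate cycle completes in a
few minutes on one CPU.  At these sizes:

- Numeric value heads are MSE point estimates, so decoded normalized
  values concentrate around conditional means; renormalized marginals
  compress toward the median and per-feature KS statistics for temporal
  numerics sit in the 0.2–0.45 range (static features are better).  The
  end-to-end fidelity bounds in the acceptance tests were calibrated at
  these levels and frozen.  The bucket-matching post-processor is the
  provided remedy when marginal fidelity matters more than joint-structure
  utility.
- Temporal categorical ratios lean toward majority categories, because
  embedding reconstruction is also mean-seeking and the softmax at a mean
  embedding is not the marginal.
- TSTR transfer for low-prevalence outcomes is weak (the synthetic-trained
  model loses most of the real-trained AUC); recovering it requires
  substantially more capacity and training than these budgets allow.

None of these are bugs in the procedure; they are the fidelity/compute
trade-off at desk scale, and all reported bounds were measured, not
assumed.

## Autodiff engine

No deep-learning framework is assumed: the networks run on a small
reverse-mode automatic-differentiation engine over numpy float64 arrays
(`synthehr.nn`).  Every backward rule is itself written in the engine's
differentiable primitives, so gradients of gradients — needed for the
WGAN-GP penalty — are exact; correctness is verified against finite
differences, including the double-backprop path.  Training is
single-threaded and bit-reproducible for a fixed seed.
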