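# Methods

## Integration network

The encoder maps M aligned omics blocks to a d_k-dimensional Gaussian
latent code per sample:

1. one affine sub-network per block, D_m → d (default d = 25; each
   sub-network is a single affine layer);
2. column-wise concatenation to d_k = M·d (100 for four blocks);
3. batch normalization, GELU (exact x·Φ(x), not the tanh approximation);
4. sample-wise scaled dot-product self-attention with learned projections
   W^Q, W^K, W^V (d_k × d_k, no bias) — queries, keys and values are all
   projections of the same N × d_k activation, so attention mixes
   information across *samples*, not features;
5. batch normalization, one fully-connected d_k → d_k layer, and two
   affine heads producing μ and log σ².

The variance head predicts log σ² rather than σ² so sampling
z = μ + exp(log σ²/2) ⊙ ε (reparameterization) stays numerically stable.
The decoder is a shared trunk (affine d_k → d_k, batch norm, GELU) with
one linear output head per block; the discriminator is a single affine
map d_k → 1 with a sigmoid, its output clamped to [1e-7, 1 − 1e-7]
before logarithms.

Counted as the architecture table prints them (inputs, concatenation,
normalizations, activations, attention, the two latent heads, outputs),
the default model has 19 layers: 10 encoder, 5 decoder, 4 discriminator.
Dropping attention removes exactly one encoder layer.

## Training

Losses:

* reconstruction — mean over blocks of the squared Frobenius distance
  between input and reconstruction, averaged over the samples in the
  batch (the per-sample average makes the loss comparable across batch
  sizes, including the kept final partial batch);
* discriminator — binary cross-entropy, prior draws labeled 1 and
  encoder outputs (detached) labeled 0;
* generator-adversarial — the non-saturating form −E log D(z). The
  printed adversarial objective mixes all three cross-entropy terms in
  one expression; minimizing that sum jointly is degenerate, so the
  standard adversarial-autoencoder split is used.

Each minibatch takes two steps. First a *generator* step updates encoder
and decoder on λ₁·L_rec + λ₂·L_adv with the discriminator frozen; the two
gradients are summed **before** the Adam update. (An earlier design used
separate Adam optimizers for the reconstruction and regularization
phases; because Adam normalizes gradient scale, that makes λ₂ inert —
any λ₂ > 0 produces identical updates. The summed-gradient form restores
the intended trade-off and matches the single total-loss objective.)
Second, a *discriminator* step updates D on a fresh N(0, I) prior sample
of batch size versus the detached latent batch.

Defaults: d = 25, 600 epochs (the synthetic benchmark uses 200 — see
below), batch size 64, Adam at 1e-4 (a grid of ten rates is exposed as
`LEARNING_RATE_GRID`), seed 2, λ₁ = 1, λ₂ = 1e-4, Glorot-uniform
initialization from the run seed, batches reshuffled per epoch, final
incomplete minibatch kept. Training is bit-reproducible given the seed
on a fixed platform. The prior is the standard normal on d_k dimensions.

At inference Z = μ, batch norms use running statistics (momentum 0.9),
and attention runs over the full sample set in one pass, so Z is
deterministic and independent of batching. During training attention
operates within each minibatch.

On prior matching: with the default λ₂ = 1e-4 the reconstruction term
dominates and the latent scale is set by the data, not the prior (latent
standard deviations of 5–15 are typical on the benchmark). When the
adversarial term is dominant (λ₁ = 0, λ₂ = 1) the latent means fall
within ±0.5 and the per-dimension standard deviations within (0.3, 1.7)
of the prior's — but only in the statistics a *linear* discriminator can
see; a single affine discriminator cannot constrain higher moments. The
test suite asserts the property in that adversarially-dominated
configuration.

## Gaussian mixture clustering

Subtypes are maximum-posterior components of a K-component
full-covariance mixture fitted to Z by EM (ties broken toward the lower
component index; labels are 1-based). K is supplied per dataset; BIC is
available as a report, not a selector. Numerical choices: ridge 1e-6 on
covariance diagonals, Cholesky-based density evaluation, log-sum-exp
responsibilities, tol 1e-4 on the per-sample mean log-likelihood gain,
max 500 iterations, 10 restarts. Each restart seeds means by k-means++,
hard-assigns samples to the nearest seed and takes one M-step before
iterating; initializing instead from the pooled covariance makes the
responsibilities nearly uniform in high dimensions and collapses all
components onto the global mean. The per-iteration log-likelihood trace
is exposed and must be non-decreasing (tolerance 1e-8).

## Evaluation

*Survival.* The K-group log-rank statistic accumulates observed-minus-
expected event counts over distinct event times with the hypergeometric
variance; χ² = uᵀV⁻¹u on K−1 groups (pseudo-inverse for degenerate V).
The permutation calibration permutes cluster labels: an initial batch of
min(max(10/p_asym, 1e4), 1e6) permutations, then batches of 1e5 until
both ends of the 95% CI lie within 10% of the estimate and the interval
excludes 0.05, capped at 1e6. The empirical p is (1 + b)/(1 + n), so it
is floored at 1/(n + 1) and never zero. The CI is Wald on the binomial
proportion, switching to Wilson when the tail count is below 5. The
permutation tail is right-sided (χ²-type statistics are one-sided by
construction). A vectorized batch path evaluates thousands of permuted
statistics at once; it is tested to agree with the readable
per-event-time implementation to 1e-8 and with `lifelines` to 1e-9.

*Clinical enrichment.* Numeric labels: tie-corrected Kruskal–Wallis
(asymptotic p). Categorical labels: Pearson chi-square without
continuity correction, permutation-calibrated in batches of 1e3 up to
1e5 until the CI clears 0.05. Missing entries are dropped per label;
single-level labels are skipped with a warning. The enrichment count is
the number of labels with p < 0.05.

*Cross-method comparison.* Friedman rank test with average-tie ranks and
tie correction (implemented directly; scipy's version refuses fewer than
three methods), cross-checked against scipy where applicable.

*Curves.* Kaplan–Meier per subtype via lifelines.

## Synthetic data generator

Emulates exactly the structure the pipeline assumes: K clusters with iid
categorical labels (uniform proportions by default), M blocks in which a
fraction (default 0.2) of features carries cluster-specific mean shifts
of magnitude `cluster_separation` (default 3) with random signs over
N(0, noise_sd²) noise (default sd 1), and per-cluster exponential
survival with uniform censoring (each sample censored with probability
`censor_rate` = 0.2 at a uniform fraction of its true time). Default
per-cluster mean survivals are geomspace(20, 80, K) arbitrary time
units — a spread chosen once to give the K-group log-rank test clear
power at N = 400 while keeping within-cluster overlap realistic. The
benchmark configuration is N = 400, blocks of 200/200/50/200 features,
K = 4, trained 200 epochs (descent has plateaued there at this sample
size; the full 600-epoch default is tuned to cohort-scale inputs).

What the generator does **not** emulate: feature–feature correlation
within blocks, non-Gaussian marginals (counts, β-values), batch effects,
missing data, or survival that violates proportional hazards. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the assumed generative model, not performance on
real tumors.

## Known limitations

* The whole network is dense numpy on one CPU; cohort sizes in the
  thousands train in minutes, but GPU-scale data is out of scope.
* Single-head attention only; no transformer stacks.
* No automatic choice of K, no consensus clustering, no multivariate
  Cox adjustment; per-dataset p-values are reported raw, without
  multiple-testing correction across datasets.
* Missing omics values are rejected at load rather than imputed.
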