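# sadln

Integrative cancer-subtype discovery from multi-omics data with a
self-attention adversarial autoencoder.

## The problem

Tumors of one cancer type split into molecular subtypes with different
survival and treatment response. No single data layer tells the whole
story: copy number, mRNA expression, miRNA expression and DNA methylation
each carry part of the signal, measured on the same patients. `sadln`
integrates M such feature blocks into one low-dimensional representation
per sample, clusters that representation into subtypes, and scores the
subtypes the way the subtyping literature does — by differential survival
and clinical-covariate enrichment, both calibrated by permutation.

## The model

Each omics block x^m (N samples × D_m features) passes through its own
affine sub-network y^m = W_m x^m + b_m mapping to d = 25 dimensions. The
concatenated representation Y = [y^1 … y^M] (d_k = M·d = 100 for four
blocks) is batch-normalized, passed through a GELU, and mixed **across
samples** by scaled dot-product self-attention: with Q = Y′W^Q, K = Y′W^K,
V = Y′W^V,

    ω_ij = softmax_j( q_i · k_j / √d_k ),   z_i = Σ_j ω_ij v_j,

so each sample's embedding borrows strength from similar co-batched
samples. Two fully-connected heads produce the Gaussian latent parameters
μ and log σ²; training samples z = μ + σ ⊙ ε (reparameterization), while
inference uses Z = μ. A decoder reconstructs every block from Z, and a
discriminator D trained to tell prior draws z′ ~ N(0, I) from encoder
outputs regularizes the latent distribution adversarially. The generator
objective is

    L = λ₁ ‖X − X̂‖²/M + λ₂ · (−E log D(z)),    λ₁ = 1, λ₂ = 1e-4.

Subtypes are the maximum-posterior components of a full-covariance
Gaussian mixture p(z) = Σ_k π_k N(z | μ_k, Σ_k) fitted to Z by EM.

Evaluation uses the K-group log-rank test with an adaptive permutation
schedule (initial batch min(max(10/p, 1e4), 1e6), then batches of 1e5
until the 95% CI of the empirical p is within 10% of the estimate and
clear of 0.05), Kruskal–Wallis / chi-square clinical enrichment with
1e3-permutation batches, Friedman rank comparison across datasets, and
Kaplan–Meier curves.

## Worked example

```python
import numpy as np
from sadln import SADLN, SimulationConfig, simulate_multiomics, zscore_blocks
from sadln.gmm import ari, gmm_assign, gmm_fit
from sadln.evaluate import permutation_pvalue_logrank

cfg = SimulationConfig(seed=2)   # N=400, blocks 200/200/50/200, K=4
dataset, truth, clinical = simulate_multiomics(cfg)
dataset = zscore_blocks(dataset)

res = SADLN(dataset, epochs=200, seed=2).fit()
latent = res.transform()
fit = gmm_fit(latent.Z, K=4, seed=2)
labels = gmm_assign(fit, dataset.sample_ids).labels

print(res.summary().splitlines()[-1])
print(f"latent shape: {latent.Z.shape}")
print(f"ARI vs simulated truth: {ari(labels, truth):.2f}")
perm = permutation_pvalue_logrank(clinical.survival_time, clinical.event, labels, seed=2)
print(f"permutation log-rank p = {perm.p_hat:.2e} ({perm.n_perm:,} permutations)")
print(f"-log10 p = {-np.log10(perm.p_hat):.1f}")
```

prints

```
Final losses (epoch 200): decoder 137.8804, discriminator 1.8988, generator 0.5688, total 137.8805
latent shape: (400, 100)
ARI vs simulated truth: 1.00
permutation log-rank p = 1.00e-06 (1,000,000 permutations)
-log10 p = 6.0
```

The adjusted Rand index of 1.00 says the pipeline recovered the four
planted clusters exactly; the permutation log-rank p sits at its floor
1/(n_perm + 1), i.e. no permuted labeling out of a million separated
survival as well as the called subtypes, giving −log10 p = 6.0.

The same pipeline runs from the shell:

```bash
sadln simulate --n-samples 400 --seed 2 --out sim/
sadln subtype sim/cnv.tsv sim/mrna.tsv sim/mirna.tsv sim/meth.tsv \
      --k 4 --epochs 200 --seed 2 --out run/
sadln evaluate --assignments run/assignments.tsv --clinical sim/clinical.tsv --out eval/
```

Ablation flags `--no-attention`, `--lambda1`, `--lambda2` switch off the
attention layer, the reconstruction loss, or the adversarial regularizer.

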