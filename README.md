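# scDMAC

Deep clustering for single-cell RNA-seq count matrices, combining three
stages that each target a specific pathology of scRNA-seq data:

1. **ZINB denoising autoencoder** — models each count X_ij with a
   zero-inflated negative binomial, ZINB(x | π, μ, θ) = π·δ(x) +
   (1−π)·NB(x | μ, θ), fitted by negative log-likelihood on raw counts with
   per-cell size factors scaling the mean head. The fitted conditional mean
   replaces the noisy, dropout-riddled counts.
2. **Masked autoencoder** — corrupts the denoised matrix by replacing a
   Bernoulli(p_j)-masked subset of entries with values shuffled within each
   gene, then trains an encoder/decoder to (a) predict which entries were
   replaced (cross-entropy L_m) and (b) reconstruct the clean matrix with a
   mask-weighted MSE (W_ij = λM_ij + (1−λ)(1−M_ij)). The combined loss is
   γ_m·L_m + (1−γ_m)·L_rec. This forces the embedding to encode gene–gene
   dependencies rather than individual values.
3. **Weighted soft clustering** — soft K-means in embedding space
   (Gaussian-kernel weights with an optional inflation exponent, centers as
   weighted means) plus Student-t soft assignments q and a sharpened target
   p (p_ik ∝ q_ik²/Σ_i q_ik); minimizing KL(p‖q) self-trains the encoder
   toward confident, well-separated clusters. The total objective is
   α·L_zinb + β·L_mask + φ·L_kmeans + θ·L_cluster.

The package is aimed at practitioners who want a fully seeded, CPU-only,
inspectable implementation: every stage is a plain NumPy feed-forward
network trained on a small built-in reverse-mode autodiff tape, and a
simulator of clustered ZINB counts (cluster-specific means, gene-wise
dispersion, mean-dependent dropout, library-size variation) provides ground
truth for every claim the test suite makes.

## Worked example

```python
import scdmac as sd

# simulate 600 cells x 200 genes, 3 clusters, ~45% zeros
X, labels, true_means, true_dropout = sd.simulate(sd.SimulationConfig(seed=0))

res = sd.fit(X, n_clusters=3, config=sd.ScDMACConfig().derive(0))
print("ARI:", round(sd.adjusted_rand_index(labels, res.labels), 4))
print("NMI:", round(sd.normalized_mutual_information(labels, res.labels), 4))
print("silhouette:", round(sd.silhouette(res.embedding, res.labels), 4))
```

Output:

```
ARI: 0.9902
NMI: 0.9809
silhouette: 0.8329
```

ARI/NMI compare the recovered partition against the simulation's ground
truth (1.0 = perfect agreement, ~0 = chance); the silhouette score measures
how compact and separated the clusters are in the learned embedding.

The same pipeline is available from the shell:

```bash
scdmac simulate --seed 0 --out sim/
scdmac fit sim/matrix.mtx --n-clusters 3 --seed 0 --out fit/
scdmac evaluate fit/labels.tsv sim/labels.tsv --embedding fit/embedding.tsv
```

`scdmac ablate` runs the three ablated variants (no denoiser / unweighted
reconstruction / no mask predictor) against the full model on shared
simulations; `scdmac sweep` scans the masking ratio, λ, or γ_m.

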