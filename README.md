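# mdsmc — molecular subclassification of MDS and secondary AML

`mdsmc` clusters patients with myelodysplastic syndromes (MDS) and
secondary acute myeloid leukemia (sAML) into molecular clusters (MCs)
from genomic data alone — gene-level somatic mutation calls on a
targeted myeloid panel, functional pathway flags, and a mutually
exclusive karyotype category — deliberately excluding morphology and
bone-marrow blast counts, which track disease stage rather than
molecular pathogenesis. It is written for biostatisticians and
computational hematologists who want a tested, reproducible
reimplementation of autoencoder + consensus-clustering subclassification
that runs end-to-end on synthetic cohorts with known ground truth.

## Method

Given the binary profile $x_i \in \{0,1\}^p$ of patient $i$:

1. **Linear autoencoder.** An encoder $z_i = W_e^\top x_i + b_e$ maps
   profiles to a $d{=}16$-dimensional latent space; a linear decoder
   through a sigmoid reconstructs the bits. Training minimizes mean
   Bernoulli cross-entropy by full-batch gradient descent, so the
   embedding is deterministic given the seed.
2. **Subsample consensus.** For each candidate cluster count $K$,
   repeatedly draw 80% of patients without replacement, fit a
   $K$-component Gaussian mixture (spherical covariances with a
   variance floor; best of 5 restarts) on their latent coordinates, and
   accumulate for every co-sampled pair whether the two patients landed
   in the same component. The consensus matrix
   $C_{ij} = \#\text{co-clustered}/\#\text{co-sampled}$ estimates the
   probability that $i$ and $j$ belong together; the final partition is
   average-linkage agglomeration on $1 - C$ cut at $K$.
3. **Model order.** $K$ is chosen to maximize the mean silhouette of
   the consensus partition, measured on the Hamming distance between
   the binary profiles (the latent-space and consensus-distance
   silhouette traces are also reported).
4. **Validation.** Five disjoint 20% test folds; the whole pipeline is
   refit on each 80% training complement. Fold agreement is the
   adjusted Rand index (ARI), both symmetric (shared training patients,
   each model's own labels) and directional (one fold's model assigns
   another fold's patients via the stored mixture).
5. **Characterization.** Per-cluster feature frequencies, permutation
   feature importance (mean decrease in out-of-bag accuracy of a
   bagged-tree classifier, flagged at $\ge 0.01$), and within-cluster
   pairwise co-occurrence fractions.
6. **Survival.** Kaplan–Meier per MC, pairwise log-rank tests, Cox
   proportional hazards with clinical covariates (Efron ties), Harrell's
   C with paired bootstrap comparison, logistic regression of treatment
   response on cluster membership, and aggregation of MCs into risk
   groups by clustering their survival curves over the landmark window
   where every curve stays above $S(t) > 0.25$.

A `synthetic_cohort` generator draws cohorts from a latent-class model
(cluster-specific Bernoulli gene bits, karyotype categories, Weibull
survival, censoring, treatment/response labels) so every stage is
testable against planted ground truth; `preset_mds_like()` is a
six-cluster preset imitating published signatures (an NK+SF3B1+TET2
cluster, a del5q cluster, a complex-karyotype+TP53 short-survival
cluster, ...).

## Worked example

```python
from mdsmc import (preset_mds_like, simulate, encode_features,
                   fit_autoencoder, select_k, adjusted_rand_index)
from mdsmc.embedding import EmbeddingConfig
from mdsmc.consensus import ConsensusConfig

cohort = simulate(preset_mds_like(n_patients=2000, seed=1))
X = encode_features(cohort.records)
emb = fit_autoencoder(X, EmbeddingConfig(seed=1))
model = select_k(
    emb,
    ConsensusConfig(n_iterations=50, K_grid=tuple(range(2, 11)), seed=1),
    X,
)
print("selected K:", model.K_selected)
print("ARI vs planted labels:",
      round(adjusted_rand_index(model.labels, cohort.true_labels), 3))
```

prints

```
selected K: 6
ARI vs planted labels: 0.975
```

i.e. the silhouette scan recovers the six planted clusters and the
consensus partition agrees with the planted labels at ARI 0.975 —
individual patients are almost always co-assigned with their true
molecular group. The same pipeline is available from the shell:

```sh
mdsmc simulate --n 2000 --seed 1 --out cohort.tsv
mdsmc report --cohort cohort.tsv --seed 1 --iterations 50 --k-max 10 --out run/
```

which writes cluster labels, silhouette traces, signature tables,
the five-fold stability report and the survival risk grouping under
`run/`, together with a manifest (config hash + seed) that makes the
run bit-for-bit reproducible.

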