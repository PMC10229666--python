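# Methods

## Model and assumptions

The package treats a patient's genomic state as a binary vector: one
indicator per panel gene (all variants in a gene are OR-ed; no variant
allele fractions), one indicator per functional pathway group (1 iff
any member gene is mutated; the RAS pathway
{NRAS, KRAS, PTPN11, CBL, NF1, RIT1} is the shipped default), and a
block of eight mutually exclusive karyotype one-hots
(NK, del5q, del7q, del20q, trisomy8, delY, complex, other_abnormal).
Karyotype is modeled as a single categorical because published cluster
tables show each abnormal-karyotype cluster carrying exactly one
category in 100% of members. When a raw karyotype string matches
several categories, a fixed precedence applies
(complex > del7q > del5q > del20q > trisomy8 > delY > other); three or
more recognized abnormalities are coded complex. This precedence is a
package decision — how multi-abnormality patients were categorized in
the source cohorts is not documented — and is recorded in run metadata.

Clustering assumes patients are exchangeable draws from a finite set of
molecular classes whose gene probabilities are class-conditionally
independent (the latent-class assumption). The pipeline does not model
clonal hierarchy, VAF, or longitudinal change.

## Embedding

The encoder and decoder are both single linear maps (the decoder
through a sigmoid); depth is deliberately not configurable. Training is
full-batch gradient descent on mean Bernoulli cross-entropy.
Defaults: latent dimension 16, 2000 epochs, learning rate 2.0,
Glorot-style uniform initialization from the seeded stream. The large
step size is correct for this loss: the mean-BCE gradient is scaled by
1/(n·p), so per-parameter updates are tiny; at learning rate 0.01 the
model stays essentially at initialization, while at 2.0 the loss falls
from ~0.70 to ~0.03 and the trace is stable across seeds. A non-finite
loss aborts with the learning rate and epoch in the message.

## Consensus clustering

Each of `n_iterations` (default 100) iterations draws
⌈0.8·n⌉ patients without replacement, fits a Gaussian mixture on their
latent coordinates and increments pair counts (co-sampled;
co-clustered). Substreams are keyed by (K, iteration), so results do
not depend on the order in which the K grid is scanned. Pairs never
co-sampled (vanishingly rare at the defaults for n ≥ 100) get consensus
0 with a logged warning.

Numerical choices that matter:

- **Covariance structure.** The mixture uses spherical covariances
  with a variance floor (`gmm_reg_covar`, default 1.0) expressed as a
  fraction of the mean per-dimension latent variance. Diagonal
  mixtures with a small floor systematically spend components on the
  diffuse "halo" of patients carrying sporadic background mutations
  and on within-cluster anisotropy from secondary lesions, cutting
  planted-structure recovery to ARI 0.5–0.8; the spherical + floor
  configuration recovers ARI ≥ 0.96 across seeds on the preset.
  Diagonal and full covariances remain available in the config.
- **Empty components.** At K above the effective structure a converged
  fit legitimately leaves components empty under hard assignment. The
  fit is retried on fresh substreams up to 3 times and the last fit is
  then used with a logged warning; only non-finite fits are fatal.
  During the K scan, a K at which the consensus matrix collapses to
  fewer distinct rows than K is scored out (silhouette −1) rather than
  aborting the scan.
- **Final partition.** Average-linkage agglomeration on 1 − consensus
  (complete linkage available), cut at K. Deterministic.
- **Model-order selection.** Three mean-silhouette traces are computed
  for every candidate K's consensus partition: on the Hamming distance
  between binary profiles, on latent Euclidean distance, and on the
  consensus dissimilarity. The profile silhouette drives the argmax
  (ties toward smaller K). The other two are reported but are poor
  selectors, for reasons the test data make vivid: the
  consensus-distance silhouette saturates near 1 for any coarse but
  stable merge (a stable 2-way split scores ~1 by construction, so the
  argmax degenerates to tiny K), while the latent silhouette keeps
  rewarding splits of genuine within-cluster substructure — composite
  pathway bits and secondary lesions form real sub-blobs — and
  over-resolves.
- **Cluster naming.** Labels are relabeled so MC1 is the largest
  cluster; the ordering is a presentation convention recorded in the
  outputs.

New patients are assigned by the posterior of a diagonal Gaussian
mixture parameterized by the per-cluster latent means and variances of
the final partition with empirical weights; posteriors sum to 1 within
1e-9.

## Stability validation

Five disjoint 20% test folds (a seeded balanced assignment); the whole
pipeline — autoencoder, consensus scan, silhouette selection — is refit
independently on each 80% training complement. Symmetric ARI compares
two folds' own labels on the intersection of their training sets;
"asymmetric" ARI is defined as model-transfer agreement: fold f's
encoder + mixture assigns fold g's training patients and the result is
compared with fold g's native labels. (The directional variant is not
uniquely defined in the literature; model transfer is the natural
choice because it exercises only machinery the pipeline already has.)
The latent-class baseline is a Bernoulli-mixture fit by EM
(best-of-restarts, parameters clamped to [1e-4, 1−1e-4], monotone
log-likelihood) with BIC model-order selection — maximum likelihood
rather than full Bayesian posterior sampling, which suffices for the
comparison the baseline exists for (it cannot resolve clusters that
share a genomic profile).

## Characterization

"Mean decrease in accuracy" is realized as out-of-bag permutation
importance of a bagged-tree classifier (500 trees, every feature
eligible at each split) trained to predict cluster labels: per tree,
OOB accuracy minus accuracy after permuting one column within the OOB
set, averaged over 10 permutations and all trees; features at
importance ≥ 0.01 are flagged. Globally constant columns contribute
exactly 0. Co-occurrence tables are plain within-cluster AND-fractions
in tidy long format.

## Survival layer

Kaplan–Meier estimation, log-rank tests, Cox regression and the
concordance index are delegated to lifelines (Greenwood variance,
log-log intervals, Efron tie handling); this package adds the
risk-group aggregation and the paired bootstrap of C-index differences.
Risk aggregation: the landmark t\* is the largest time at which every
cluster's survival stays above the floor (default 0.25; if a curve
starts below it the shortest observed horizon is used with a warning);
curves are embedded as S(t) on a 100-point grid over [0, t\*], and
average-linkage clustering on L2 curve distance is cut either at a
requested group count or at the count maximizing the silhouette of the
curve clustering. A merge-height "knee" cut was tried and rejected: it
merges planted hazard tiers whenever tier spacings are unequal. Groups
are numbered by decreasing pooled median survival.

## Synthetic cohorts

`SimulationSpec` draws cluster labels from the mixing weights, gene
bits from cluster-specific Bernoulli probabilities, one karyotype
category per patient from cluster-specific simplex rows, event times
from cluster-specific Weibulls, and censoring as the minimum of an
exponential draw and an administrative horizon; treatment flags and
HMA-response labels follow cluster-specific probabilities/log-odds.
One master seed expands into fixed per-stage substreams, so adding a
stage never perturbs earlier draws.

`preset_mds_like()` plants six clusters over the 40-gene default panel:
NK-sparse; NK+SF3B1+TET2; del5q (+DNMT3A/TP53); NK+TET2+ASXL1
(+SRSF2/RUNX1); del7q (+RAS genes); complex+TP53. Defining lesions are
carried by 100% of members — echoing the purity of published cluster
signatures — so every cluster pair differs in at least two
deterministic bits, while secondary lesions stay at ≤ 0.25 and
background mutation noise at 0.02 per gene. That is the "strong
separation" regime: between-cluster separation dominates within-cluster
substructure, which is what makes the planted partition the one a
clustering method should find. Weibull scales
(60, 90, 55, 33, 20, 9 months; shape 1.2) order the clusters into
survival tiers; censoring combines an exponential rate of 1/80 per
month with a 120-month administrative horizon.

What the generator does **not** emulate — and hence what passing tests
do not establish about real cohorts: mutation co-occurrence and
mutual-exclusivity correlations within a cluster (bits are
class-conditionally independent), VAF and clonal architecture, panel
heterogeneity across centers, non-proportional hazards beyond what
Weibull scale differences induce, and informative censoring. Results on
real registry data additionally depend on panel composition and
karyotype coding choices.

## Problem sizes and evaluation configuration

The shipped evaluation (tests and `scripts/acceptance.py`) runs the
preset at n = 2000 patients with 50 consensus iterations over
K ∈ {2,…,10} and five-fold refitting — sizes chosen so the full
recovery-plus-stability evaluation completes in minutes on a single
CPU while keeping every stage's statistical behavior visible. Unit
tests use smaller planted fixtures (n ≈ 100–300) and hand-computable
tables.

## Known limitations

- Model-order selection inherits silhouette's biases; on data whose
  substructure is as strong as its cluster structure no silhouette
  variant identifies a unique "true" K (and the package will report
  the finer/coarser scale the profile silhouette prefers).
- The consensus matrix is O(n²) memory; cohorts beyond a few tens of
  thousands of patients need a sparser accumulation strategy.
- The latent-class baseline is a point estimate; posterior uncertainty
  over the baseline partition is out of scope.
- Risk-group aggregation on external cohorts is sensitive to the
  landmark window when some cluster's survival drops below the floor
  early.
- Running the pipeline on the original restricted-access patient-level
  data (dbGaP phs001898.v1.p1) is an external check: published figures
  for that cohort — 14 clusters, a largest NK-only cluster holding
  ~26% of cases and a smallest with ~2%, five aggregated risk groups —
  are what such a run is expected to reproduce, but no such data ships
  with, or is fetched by, this package.
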