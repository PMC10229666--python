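"""Subsample consensus clustering with Gaussian-mixture components.

The core procedure: repeatedly draw a subsample of patients, fit a
K-component Gaussian mixture on their latent coordinates, and record
for every co-sampled pair whether the two patients landed in the same
component.  The ratio of co-clustering to co-sampling counts is the
consensus matrix; the final partition is average-linkage agglomeration
on ``1 - consensus``; the number of clusters is the value of K whose
partition maximizes the mean silhouette (by default measured on the
Hamming distance between the binary profiles themselves).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from mdsmc.embedding import LatentEmbedding

logger = logging.getLogger(__name__)

_GMM_RETRIES = 3


@dataclass(frozen=True)
class ConsensusConfig:
    """Knobs of the consensus procedure.

    ``gmm_reg_covar`` floors the component variances at this fraction
    of the mean per-dimension latent variance — without it the mixture
    spends components on the diffuse halo of patients carrying sporadic
    background mutations instead of on the cluster cores.
    ``selection_space`` picks the silhouette used for model-order
    selection: "profile" (default; Hamming distance between the binary
    profiles), "latent" (Euclidean in the embedding) or "consensus"
    (1 - consensus dissimilarity).  All traces are always recorded.
    The profile silhouette is the default because the latent one keeps
    rewarding splits of real within-cluster sub-structure (composite
    pathway bits), while the consensus one saturates near 1 for any
    coarse but stable merge.
    """

    n_iterations: int = 100
    subsample_fraction: float = 0.8
    K_grid: tuple[int, ...] = tuple(range(2, 21))
    gmm_covariance: str = "spherical"
    gmm_restarts: int = 5
    gmm_reg_covar: float = 1.0
    final_linkage: str = "average"
    selection_space: str = "profile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if any(k < 2 for k in self.K_grid):
            raise ValueError("K_grid values must be >= 2")
        if self.gmm_covariance not in ("spherical", "diagonal", "full"):
            raise ValueError("gmm_covariance must be spherical/diagonal/full")
        if self.final_linkage not in ("average", "complete"):
            raise ValueError("final_linkage must be 'average' or 'complete'")
        if self.gmm_restarts < 1:
            raise ValueError("gmm_restarts must be >= 1")
        if self.gmm_reg_covar < 0:
            raise ValueError("gmm_reg_covar must be >= 0")
        if self.selection_space not in ("profile", "latent", "consensus"):
            raise ValueError("selection_space must be profile/latent/consensus")


@dataclass
class ConsensusMatrix:
    patient_ids: list[str]
    co_cluster_counts: np.ndarray  # (n, n) int
    co_sample_counts: np.ndarray   # (n, n) int

    def __post_init__(self) -> None:
        self.co_cluster_counts = np.asarray(self.co_cluster_counts)
        self.co_sample_counts = np.asarray(self.co_sample_counts)
        n = len(self.patient_ids)
        if self.co_cluster_counts.shape != (n, n) or self.co_sample_counts.shape != (n, n):
            raise ValueError("count matrices must be n x n")

    @property
    def consensus(self) -> np.ndarray:
        """Co-clustering frequency; pairs never co-sampled are 0 (logged)."""
        never = self.co_sample_counts == 0
        off_diag_never = never & ~np.eye(len(self.patient_ids), dtype=bool)
        if off_diag_never.any():
            logger.warning(
                "%d patient pairs were never co-sampled; their consensus is 0",
                int(off_diag_never.sum()) // 2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(never, 0.0, self.co_cluster_counts / np.maximum(self.co_sample_counts, 1))
        np.fill_diagonal(C, 1.0)
        return C

    def validate(self) -> None:
        C = self.consensus
        if not np.allclose(C, C.T):
            raise AssertionError("consensus matrix not symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise AssertionError("consensus diagonal not 1")
        if C.min() < 0 or C.max() > 1:
            raise AssertionError("consensus entries outside [0,1]")
        if (self.co_cluster_counts > self.co_sample_counts).any():
            raise AssertionError("co_cluster exceeds co_sample")


@dataclass
class ClusterModel:
    """Final partition plus the machinery to assign new patients.

    ``cluster_names`` maps label k -> "MC{k+1}"; labels are relabeled so
    MC1 is the largest cluster (size-descending order, a presentation
    convention recorded here rather than anything identifiable from the
    data itself).
    """

    K_selected: int
    labels: np.ndarray
    silhouette_by_K: dict[int, float]
    latent_silhouette_by_K: dict[int, float]
    profile_silhouette_by_K: dict[int, float]
    consensus_ref: ConsensusMatrix
    latent_centroids: np.ndarray    # (K, d)
    latent_variances: np.ndarray    # (K, d) diagonal covariances
    cluster_weights: np.ndarray     # (K,) empirical
    patient_ids: list[str] = field(default_factory=list)

    @property
    def cluster_names(self) -> list[str]:
        return [f"MC{k + 1}" for k in range(self.K_selected)]

    def validate(self) -> None:
        present = np.unique(self.labels)
        if len(present) != self.K_selected or present.min() < 0:
            raise AssertionError("labels do not cover exactly K_selected clusters")
        for v in self.silhouette_by_K.values():
            if not (-1.0 <= v <= 1.0):
                raise AssertionError("silhouette outside [-1,1]")

    def save(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "K_selected": int(self.K_selected),
            "labels": self.labels.tolist(),
            "patient_ids": self.patient_ids,
            "silhouette_by_K": {str(k): v for k, v in self.silhouette_by_K.items()},
            "latent_silhouette_by_K": {
                str(k): v for k, v in self.latent_silhouette_by_K.items()
            },
            "profile_silhouette_by_K": {
                str(k): v for k, v in self.profile_silhouette_by_K.items()
            },
            "latent_centroids": self.latent_centroids.tolist(),
            "latent_variances": self.latent_variances.tolist(),
            "cluster_weights": self.cluster_weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        p = json.loads(Path(path).read_text())
        n = len(p["labels"])
        empty = ConsensusMatrix(
            p["patient_ids"] or [str(i) for i in range(n)],
            np.zeros((n, n), dtype=int),
            np.zeros((n, n), dtype=int),
        )
        return cls(
            K_selected=p["K_selected"],
            labels=np.array(p["labels"], dtype=int),
            silhouette_by_K={int(k): v for k, v in p["silhouette_by_K"].items()},
            latent_silhouette_by_K={
                int(k): v for k, v in p["latent_silhouette_by_K"].items()
            },
            profile_silhouette_by_K={
                int(k): v for k, v in p.get("profile_silhouette_by_K", {}).items()
            },
            consensus_ref=empty,
            latent_centroids=np.array(p["latent_centroids"]),
            latent_variances=np.array(p["latent_variances"]),
            cluster_weights=np.array(p["cluster_weights"]),
            patient_ids=p["patient_ids"],
        )


def _fit_gmm(
    Z: np.ndarray, K: int, cfg: ConsensusConfig, seed_key: tuple[int, ...],
    reg_covar: float,
) -> GaussianMixture:
    """Best-of-restarts GMM; refits on a new substream if the hard
    assignment leaves a component empty, then proceeds with a warning."""
    cov = {"spherical": "spherical", "diagonal": "diag", "full": "full"}[cfg.gmm_covariance]
    last = None
    for attempt in range(_GMM_RETRIES):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=seed_key + (attempt,))
        )
        gm = GaussianMixture(
            n_components=K,
            covariance_type=cov,
            n_init=cfg.gmm_restarts,
            reg_covar=reg_covar,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(Z)
        last = gm
        if len(np.unique(gm.predict(Z))) == K:
            return gm
        logger.debug("empty GMM component at K=%d (attempt %d); refitting", K, attempt)
    logger.warning(
        "GMM left an empty component at K=%d after %d substream refits; "
        "using the last fit", K, _GMM_RETRIES,
    )
    return last


def run_consensus(Z: LatentEmbedding | np.ndarray, K: int, cfg: ConsensusConfig,
                  patient_ids: list[str] | None = None) -> ConsensusMatrix:
    """Accumulate co-clustering frequencies over subsampled GMM fits.

    Each iteration draws ``ceil(subsample_fraction * n)`` patients
    without replacement, fits a K-component mixture on their latent
    coordinates (best of ``gmm_restarts`` by log-likelihood) and
    increments the co-sample count for every co-sampled pair and the
    co-cluster count for pairs assigned to the same component.
    Substreams are keyed by (K, iteration), so results are independent
    of the order in which K values are visited.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if isinstance(Z, LatentEmbedding):
        coords, ids = Z.coordinates, list(Z.patient_ids)
    else:
        coords = np.asarray(Z)
        ids = patient_ids or [str(i) for i in range(len(coords))]
    n = len(coords)
    m = int(np.ceil(cfg.subsample_fraction * n))
    # variance floor relative to the data scale, invariant to embedding norm
    reg_covar = max(cfg.gmm_reg_covar * float(coords.var(axis=0).mean()), 1e-8)

    co_cluster = np.zeros((n, n), dtype=np.int32)
    co_sample = np.zeros((n, n), dtype=np.int32)
    for it in range(cfg.n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(K, it))
        )
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        gm = _fit_gmm(coords[idx], K, cfg, seed_key=(K, it, 1), reg_covar=reg_covar)
        lab = gm.predict(coords[idx])
        same = (lab[:, None] == lab[None, :]).astype(np.int32)
        co_sample[np.ix_(idx, idx)] += 1
        co_cluster[np.ix_(idx, idx)] += same
    return ConsensusMatrix(ids, co_cluster, co_sample)


def final_partition(C: ConsensusMatrix | np.ndarray, K: int,
                    linkage_method: str = "average") -> np.ndarray:
    """Cut an agglomerative tree on 1 - consensus at K groups."""
    M = C.consensus if isinstance(C, ConsensusMatrix) else np.asarray(C, dtype=float)
    n = len(M)
    if K > len(np.unique(M.round(12), axis=0)):
        raise ValueError(f"K={K} exceeds the number of distinct consensus rows")
    if K == 1:
        return np.zeros(n, dtype=int)
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    tree = linkage(squareform(D, checks=False), method=linkage_method)
    return fcluster(tree, t=K, criterion="maxclust") - 1


def _consensus_silhouette(C: np.ndarray, labels: np.ndarray) -> float:
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    if len(np.unique(labels)) < 2:
        return -1.0
    return float(silhouette_score(D, labels, metric="precomputed"))


def _size_ordered_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster 0 (MC1) is the largest; ties by first occurrence."""
    uniq, counts = np.unique(labels, return_counts=True)
    first_seen = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first_seen[u]))
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def _moment_params(
    coords: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    K = labels.max() + 1
    d = coords.shape[1]
    mu = np.zeros((K, d))
    var = np.zeros((K, d))
    w = np.zeros(K)
    for k in range(K):
        members = coords[labels == k]
        mu[k] = members.mean(axis=0)
        var[k] = members.var(axis=0) + 1e-4
        w[k] = len(members) / len(coords)
    return mu, var, w


def select_k(
    Z: LatentEmbedding, cfg: ConsensusConfig, X: "object | None" = None
) -> ClusterModel:
    """Run consensus at every K in the grid and keep the silhouette winner.

    Three mean-silhouette traces are computed for every candidate K's
    consensus partition: on the binary profiles (Hamming distance), on
    the latent embedding (Euclidean) and on the consensus dissimilarity
    1 - consensus.  The trace named by ``cfg.selection_space`` drives
    the argmax (profile by default; requires ``X``, the binary feature
    matrix the embedding was trained on).  Ties break toward smaller K.
    """
    if not cfg.K_grid:
        raise ValueError("K_grid must be non-empty")
    coords = Z.coordinates
    space = cfg.selection_space
    D_profile = None
    if X is not None:
        V = X.values if hasattr(X, "values") else np.asarray(X)
        D_profile = squareform(pdist(V, metric="hamming"))
    elif space == "profile":
        logger.warning(
            "selection_space='profile' but no feature matrix given; "
            "falling back to the latent silhouette"
        )
        space = "latent"
    sil_by_K: dict[int, float] = {}
    latent_sil_by_K: dict[int, float] = {}
    profile_sil_by_K: dict[int, float] = {}
    best: tuple[float, int] | None = None
    best_artifacts: tuple[ConsensusMatrix, np.ndarray] | None = None
    for K in sorted(cfg.K_grid):
        C = run_consensus(Z, K, cfg)
        try:
            labels = final_partition(C, K, linkage_method=cfg.final_linkage)
        except ValueError:
            # consensus collapsed to fewer distinct rows than K: this
            # model order is unachievable on the data; score it out
            sil_by_K[K] = latent_sil_by_K[K] = -1.0
            if D_profile is not None:
                profile_sil_by_K[K] = -1.0
            continue
        multi = len(np.unique(labels)) > 1
        sil_by_K[K] = _consensus_silhouette(C.consensus, labels)
        latent_sil_by_K[K] = (
            float(silhouette_score(coords, labels)) if multi else -1.0
        )
        if D_profile is not None:
            profile_sil_by_K[K] = (
                float(silhouette_score(D_profile, labels, metric="precomputed"))
                if multi
                else -1.0
            )
        sil = {
            "latent": latent_sil_by_K[K],
            "consensus": sil_by_K[K],
            "profile": profile_sil_by_K.get(K, latent_sil_by_K[K]),
        }[space]
        if best is None or sil > best[0]:  # strict > : ties keep smaller K
            best = (sil, K)
            best_artifacts = (C, labels)
    assert best is not None and best_artifacts is not None
    _, K_sel = best
    C, labels = best_artifacts
    labels = _size_ordered_relabel(labels)
    mu, var, w = _moment_params(coords, labels)
    model = ClusterModel(
        K_selected=int(len(np.unique(labels))),
        labels=labels,
        silhouette_by_K=sil_by_K,
        latent_silhouette_by_K=latent_sil_by_K,
        profile_silhouette_by_K=profile_sil_by_K,
        consensus_ref=C,
        latent_centroids=mu,
        latent_variances=var,
        cluster_weights=w,
        patient_ids=list(Z.patient_ids),
    )
    model.validate()
    return model


def fit_cluster_model(Z: LatentEmbedding, K: int, cfg: ConsensusConfig) -> ClusterModel:
    """Consensus model at a fixed K (no model-order search)."""
    C = run_consensus(Z, K, cfg)
    labels = _size_ordered_relabel(final_partition(C, K, linkage_method=cfg.final_linkage))
    mu, var, w = _moment_params(Z.coordinates, labels)
    sil = _consensus_silhouette(C.consensus, labels)
    model = ClusterModel(
        K_selected=int(len(np.unique(labels))),
        labels=labels,
        silhouette_by_K={K: sil},
        profile_silhouette_by_K={},
        latent_silhouette_by_K={
            K: float(silhouette_score(Z.coordinates, labels))
            if len(np.unique(labels)) > 1
            else -1.0
        },
        consensus_ref=C,
        latent_centroids=mu,
        latent_variances=var,
        cluster_weights=w,
        patient_ids=list(Z.patient_ids),
    )
    model.validate()
    return model


def assign_new(model: ClusterModel, Z_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior cluster assignment of new latent coordinates.

    Uses a diagonal-covariance Gaussian mixture parameterized by the
    stored per-cluster centroids/variances and empirical weights.
    Returns ``(labels, posterior)`` with posterior rows summing to 1.
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    d = model.latent_centroids.shape[1]
    if Z_new.shape[1] != d:
        raise ValueError(f"coordinates have dim {Z_new.shape[1]}, model expects {d}")
    mu, var, w = model.latent_centroids, model.latent_variances, model.cluster_weights
    # log N(z; mu_k, diag var_k) + log w_k, normalized with logsumexp
    log_det = np.log(var).sum(axis=1)
    diff = Z_new[:, None, :] - mu[None, :, :]
    maha = (diff**2 / var[None, :, :]).sum(axis=2)
    log_like = -0.5 * (maha + log_det[None, :] + d * np.log(2 * np.pi))
    log_post = log_like + np.log(np.maximum(w, 1e-300))[None, :]
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return post.argmax(axis=1), post
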