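"""Stability validation: cross-validation folds, ARI, latent-class baseline.

The clustering is validated the way the original analysis was: split
the cohort into five disjoint 20% test folds, refit the whole pipeline
(autoencoder + consensus + silhouette model-order selection)
independently on each fold's 80% training complement, and compare the
five partitions.  Symmetric agreement is the adjusted Rand index on
patients shared by two training sets; the directional ("asymmetric")
variant assigns one fold's patients with another fold's model and
compares to their native labels.  A Bernoulli-mixture (latent class)
EM fit serves as the coarser baseline model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import adjusted_rand_score

from mdsmc.cohort import BinaryFeatureMatrix
from mdsmc.consensus import ClusterModel, ConsensusConfig, assign_new, select_k
from mdsmc.embedding import EmbeddingConfig, LatentEmbedding, encode, fit_autoencoder


@dataclass
class FoldPlan:
    """Five disjoint test folds of 20%; training sets are complements."""

    n_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    fold_assignments: np.ndarray | None = None  # test-fold id per patient

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0,1)")
        if abs(self.train_fraction - (1 - 1 / self.n_folds)) > 1e-9:
            raise ValueError(
                "train_fraction inconsistent with n_folds when training sets "
                "are fold complements"
            )

    def materialize(self, n: int) -> "FoldPlan":
        if self.fold_assignments is not None:
            return self
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(0,)))
        assignment = np.arange(n) % self.n_folds
        rng.shuffle(assignment)
        return replace(self, fold_assignments=assignment)


@dataclass
class StabilityReport:
    fold_K_selected: list[int]
    symmetric_ari: np.ndarray      # (F, F), unit diagonal, NaN where no overlap
    asymmetric_ari: np.ndarray     # (F, F), directional: model f on fold g
    min_ari: float
    modal_K: int

    def validate(self) -> None:
        F = len(self.fold_K_selected)
        if self.symmetric_ari.shape != (F, F) or self.asymmetric_ari.shape != (F, F):
            raise AssertionError("ARI matrices must be F x F")
        if np.nanmax(self.symmetric_ari) > 1 + 1e-12:
            raise AssertionError("ARI exceeds 1")
        if not np.allclose(np.diag(self.symmetric_ari), 1.0):
            raise AssertionError("symmetric ARI diagonal must be 1")


def adjusted_rand_index(a, b) -> float:
    """Pair-counting adjusted Rand index between two partitions.

    1 for identical partitions up to relabeling; 0 expected under
    independent random partitions of the same sizes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(a, b))


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """Training/test sizes for a fractional split: floor(f*n), remainder."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0,1)")
    n_train = int(np.floor(train_fraction * n))
    return n_train, n - n_train


def cross_fold_stability(
    X: BinaryFeatureMatrix,
    cfg: ConsensusConfig,
    plan: FoldPlan,
    embed_cfg: EmbeddingConfig | None = None,
) -> StabilityReport:
    """Refit the full pipeline per fold and cross-compare the partitions.

    For folds f, g: symmetric ARI compares each model's own labels on
    the intersection of their training sets; asymmetric ARI encodes
    fold g's training patients with fold f's autoencoder, assigns them
    with fold f's mixture (``assign_new``) and compares against fold
    g's native labels.  Entries with empty overlap are NaN and excluded
    from ``min_ari``.
    """
    embed_cfg = embed_cfg or EmbeddingConfig()
    plan = plan.materialize(X.n_patients)
    F = plan.n_folds
    fold_models: list[tuple[np.ndarray, LatentEmbedding, ClusterModel]] = []
    for f in range(F):
        train_idx = np.flatnonzero(plan.fold_assignments != f)
        Xf = BinaryFeatureMatrix(
            [X.patient_ids[i] for i in train_idx],
            list(X.feature_names),
            X.values[train_idx],
        )
        emb = fit_autoencoder(Xf, replace(embed_cfg, seed=embed_cfg.seed + f))
        model = select_k(emb, replace(cfg, seed=cfg.seed + 1000 * (f + 1)), Xf)
        fold_models.append((train_idx, emb, model))

    sym = np.full((F, F), np.nan)
    asym = np.full((F, F), np.nan)
    for f in range(F):
        idx_f, emb_f, model_f = fold_models[f]
        sym[f, f] = 1.0
        lab_f = dict(zip(idx_f, model_f.labels))
        for g in range(F):
            if g == f:
                asym[f, g] = 1.0
                continue
            idx_g, _, model_g = fold_models[g]
            lab_g = dict(zip(idx_g, model_g.labels))
            shared = np.intersect1d(idx_f, idx_g)
            if len(shared) >= 2:
                sym[f, g] = adjusted_rand_index(
                    [lab_f[i] for i in shared], [lab_g[i] for i in shared]
                )
            # transfer: model f labels fold g's training patients
            Xg = BinaryFeatureMatrix(
                [X.patient_ids[i] for i in idx_g],
                list(X.feature_names),
                X.values[idx_g],
            )
            transferred, _ = assign_new(model_f, encode(emb_f, Xg))
            asym[f, g] = adjusted_rand_index(transferred, model_g.labels)

    both = np.concatenate([sym[~np.isnan(sym)], asym[~np.isnan(asym)]])
    Ks = [m.K_selected for _, _, m in fold_models]
    vals, counts = np.unique(Ks, return_counts=True)
    report = StabilityReport(
        fold_K_selected=Ks,
        symmetric_ari=sym,
        asymmetric_ari=asym,
        min_ari=float(both.min()),
        modal_K=int(vals[np.argmax(counts)]),
    )
    report.validate()
    return report


def latent_class_baseline(
    X: BinaryFeatureMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite Bernoulli-mixture (latent class) fit by EM.

    Returns ``(labels, theta, loglik_trace)`` where ``theta`` is the
    (K, p) matrix of per-class Bernoulli parameters (clamped to
    [eps, 1-eps]) and the trace is from the best restart; the
    log-likelihood is non-decreasing over EM iterations.
    """
    V = X.values if isinstance(X, BinaryFeatureMatrix) else np.asarray(X, dtype=float)
    n, p = V.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    eps = 1e-4
    if K == 1:
        theta = np.clip(V.mean(axis=0, keepdims=True), eps, 1 - eps)
        ll = float(
            (V * np.log(theta) + (1 - V) * np.log(1 - theta)).sum()
        )
        return np.zeros(n, dtype=int), theta, np.array([ll])

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        theta = np.clip(
            V[rng.choice(n, size=K, replace=False)] * 0.8 + 0.1, eps, 1 - eps
        )
        pi = np.full(K, 1.0 / K)
        trace: list[float] = []
        for _ in range(max_iter):
            log_comp = V @ np.log(theta).T + (1 - V) @ np.log(1 - theta).T
            log_joint = log_comp + np.log(pi)[None, :]
            mx = log_joint.max(axis=1, keepdims=True)
            ll = float((mx.squeeze(1) + np.log(np.exp(log_joint - mx).sum(axis=1))).sum())
            trace.append(ll)
            resp = np.exp(log_joint - mx)
            resp /= resp.sum(axis=1, keepdims=True)
            Nk = resp.sum(axis=0) + 1e-12
            pi = Nk / n
            theta = np.clip((resp.T @ V) / Nk[:, None], eps, 1 - eps)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol * abs(trace[-2]):
                break
        if best is None or trace[-1] > best[0]:
            log_comp = V @ np.log(theta).T + (1 - V) @ np.log(1 - theta).T
            labels = (log_comp + np.log(pi)[None, :]).argmax(axis=1)
            best = (trace[-1], labels, theta, np.array(trace))
    assert best is not None
    return best[1], best[2], best[3]


def latent_class_select_k(
    X: BinaryFeatureMatrix | np.ndarray,
    K_grid: tuple[int, ...] = tuple(range(1, 11)),
    seed: int = 0,
) -> int:
    """Model-order selection for the latent-class baseline by BIC."""
    V = X.values if isinstance(X, BinaryFeatureMatrix) else np.asarray(X, dtype=float)
    n, p = V.shape
    best_K, best_bic = None, np.inf
    for K in sorted(K_grid):
        _, _, trace = latent_class_baseline(V, K, seed=seed)
        n_params = K * p + (K - 1)
        bic = -2 * trace[-1] + n_params * np.log(n)
        if bic < best_bic:
            best_K, best_bic = K, bic
    assert best_K is not None
    return best_K
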