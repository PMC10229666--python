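"""Consensus clustering: matrix invariants, partition recovery, assignment."""

import numpy as np
import pytest

from mdsmc.cohort import BinaryFeatureMatrix
from mdsmc.consensus import (
    ConsensusConfig,
    ConsensusMatrix,
    assign_new,
    final_partition,
    fit_cluster_model,
    run_consensus,
    select_k,
)
from mdsmc.embedding import EmbeddingConfig, LatentEmbedding, fit_autoencoder
from mdsmc.validation import adjusted_rand_index
from sklearn.mixture import GaussianMixture

FAST = ConsensusConfig(n_iterations=30, gmm_restarts=2, seed=0)


def _embedding(Z):
    n, d = Z.shape
    return LatentEmbedding(
        patient_ids=[f"P{i}" for i in range(n)],
        coordinates=np.asarray(Z, dtype=float),
        training_loss_trace=np.zeros(1),
        feature_names=[f"F{j}" for j in range(5)],
        W_enc=np.zeros((5, d)),
        b_enc=np.zeros(d),
        W_dec=np.zeros((d, 5)),
        b_dec=np.zeros(5),
    )


def test_consensus_matrix_invariants(two_blob_embedding):
    Z, _ = two_blob_embedding
    C = run_consensus(_embedding(Z), 2, FAST)
    C.validate()
    M = C.consensus
    assert np.allclose(np.diag(M), 1.0)
    assert np.allclose(M, M.T)
    assert (M >= 0).all() and (M <= 1).all()
    assert (C.co_cluster_counts <= C.co_sample_counts).all()


def test_two_blobs_consensus_separates(two_blob_embedding):
    Z, truth = two_blob_embedding
    M = run_consensus(_embedding(Z), 2, FAST).consensus
    within = M[:100, :100][np.triu_indices(100, 1)]
    cross = M[:100, 100:]
    assert within.mean() >= 0.95
    assert cross.mean() <= 0.05


def test_full_sample_deterministic_gmm_gives_binary_consensus(two_blob_embedding):
    """With no subsampling and a stable mixture every iteration repeats the
    same partition, so consensus entries are exactly 0 or 1."""
    Z, _ = two_blob_embedding
    cfg = ConsensusConfig(
        n_iterations=10, subsample_fraction=1.0, gmm_restarts=4, seed=1
    )
    M = run_consensus(_embedding(Z), 2, cfg).consensus
    assert set(np.unique(M)) <= {0.0, 1.0}


def test_equivalence_with_direct_gmm_on_separable_blobs(two_blob_embedding):
    """Degenerate single-iteration full-sample consensus equals the direct
    GMM partition."""
    Z, _ = two_blob_embedding
    cfg = ConsensusConfig(
        n_iterations=1, subsample_fraction=1.0, gmm_restarts=4, seed=2
    )
    labels = final_partition(run_consensus(_embedding(Z), 2, cfg), 2)
    direct = GaussianMixture(
        2, covariance_type="spherical", n_init=4,
        reg_covar=float(Z.var(axis=0).mean()), random_state=0,
    ).fit(Z).predict(Z)
    assert adjusted_rand_index(labels, direct) == 1.0


class TestFinalPartition:
    def test_perfect_blocks_recovered(self):
        M = np.kron(np.eye(2), np.ones((5, 5)))
        labels = final_partition(M, 2)
        assert adjusted_rand_index(labels, np.repeat([0, 1], 5)) == 1.0

    def test_all_ones_single_cluster(self):
        labels = final_partition(np.ones((6, 6)), 1)
        assert set(labels) == {0}

    def test_noisy_three_blocks_recovered(self):
        truth = np.repeat([0, 1, 2], 8)
        M = np.where(truth[:, None] == truth[None, :], 0.9, 0.1)
        np.fill_diagonal(M, 1.0)
        assert adjusted_rand_index(final_partition(M, 3), truth) == 1.0

    def test_k_exceeding_distinct_rows_rejected(self):
        with pytest.raises(ValueError):
            final_partition(np.ones((4, 4)), 3)


def test_pair_never_cosampled_has_zero_consensus():
    counts = np.array([[2, 0], [0, 2]])
    M = ConsensusMatrix(["a", "b"], counts, counts.copy()).consensus
    assert M[0, 1] == 0.0 and np.allclose(np.diag(M), 1.0)


@pytest.fixture(scope="module")
def planted_four():
    """Four well-separated binary clusters, encoded and embedded."""
    rng = np.random.default_rng(13)
    n_per, p = 60, 24
    rows, truth = [], []
    for k in range(4):
        probs = np.full(p, 0.03)
        probs[6 * k : 6 * k + 6] = 0.95
        rows.append((rng.random((n_per, p)) < probs).astype(int))
        truth += [k] * n_per
    X = BinaryFeatureMatrix(
        [f"P{i}" for i in range(4 * n_per)],
        [f"G{j}" for j in range(p)],
        np.vstack(rows),
    )
    emb = fit_autoencoder(X, EmbeddingConfig(latent_dim=8, epochs=800, seed=3))
    return X, emb, np.array(truth)


def test_select_k_recovers_planted_four(planted_four):
    X, emb, truth = planted_four
    cfg = ConsensusConfig(
        n_iterations=30, K_grid=tuple(range(2, 8)), gmm_restarts=3, seed=4
    )
    model = select_k(emb, cfg, X)
    assert model.K_selected == 4
    assert adjusted_rand_index(model.labels, truth) >= 0.9
    assert all(-1 <= v <= 1 for v in model.silhouette_by_K.values())
    assert all(-1 <= v <= 1 for v in model.profile_silhouette_by_K.values())


def test_cluster_names_ordered_by_size(planted_four):
    X, emb, _ = planted_four
    model = fit_cluster_model(emb, 4, FAST)
    sizes = np.bincount(model.labels)
    assert (np.diff(sizes) <= 0).all()
    assert model.cluster_names[0] == "MC1"


def test_row_permutation_permutes_labels(planted_four):
    """On separable data the recovered partition is invariant to patient
    order (compared as partitions, label ids aside)."""
    X, emb, truth = planted_four
    perm = np.random.default_rng(5).permutation(X.n_patients)
    emb_p = _embedding(emb.coordinates[perm])
    cfg = ConsensusConfig(n_iterations=20, subsample_fraction=1.0,
                          gmm_restarts=3, seed=6)
    lab = final_partition(run_consensus(emb, 4, cfg), 4)
    lab_p = final_partition(run_consensus(emb_p, 4, cfg), 4)
    assert adjusted_rand_index(lab[perm], lab_p) == 1.0


def test_monotone_separation_property():
    """Widening the planted probability gap never hurts median recovery."""
    rng = np.random.default_rng(10)
    scores = []
    for gap in (0.3, 0.6, 0.9):
        aris = []
        for rep in range(3):
            p_hi, p_lo = 0.5 + gap / 2, 0.5 - gap / 2
            a = (rng.random((50, 12)) < np.r_[np.full(6, p_hi), np.full(6, p_lo)]).astype(int)
            b = (rng.random((50, 12)) < np.r_[np.full(6, p_lo), np.full(6, p_hi)]).astype(int)
            X = BinaryFeatureMatrix(
                [f"P{i}" for i in range(100)],
                [f"G{j}" for j in range(12)],
                np.vstack([a, b]),
            )
            emb = fit_autoencoder(X, EmbeddingConfig(latent_dim=4, epochs=400, seed=rep))
            lab = final_partition(
                run_consensus(emb, 2, ConsensusConfig(n_iterations=20, gmm_restarts=2, seed=rep)), 2
            )
            aris.append(adjusted_rand_index(lab, np.repeat([0, 1], 50)))
        scores.append(np.median(aris))
    assert scores[0] <= scores[1] + 1e-9 and scores[1] <= scores[2] + 1e-9


class TestAssignNew:
    def test_posteriors_normalized_and_consistent(self, planted_four):
        X, emb, truth = planted_four
        model = fit_cluster_model(emb, 4, FAST)
        labels, post = assign_new(model, emb.coordinates)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert adjusted_rand_index(labels, model.labels) >= 0.99

    def test_held_out_accuracy(self, planted_four):
        X, emb, truth = planted_four
        half = X.n_patients // 2
        idx = np.arange(X.n_patients)
        train, test = idx[::2], idx[1::2]
        emb_train = _embedding(emb.coordinates[train])
        model = fit_cluster_model(emb_train, 4, FAST)
        labels, _ = assign_new(model, emb.coordinates[test])
        assert adjusted_rand_index(labels, truth[test]) >= 0.9

    def test_dimension_mismatch_rejected(self, planted_four):
        X, emb, _ = planted_four
        model = fit_cluster_model(emb, 4, FAST)
        with pytest.raises(ValueError, match="dim"):
            assign_new(model, np.zeros((3, 2)))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ConsensusConfig(subsample_fraction=0.0)
    with pytest.raises(ValueError):
        ConsensusConfig(K_grid=(1, 2))
    with pytest.raises(ValueError):
        ConsensusConfig(gmm_covariance="banded")
    with pytest.raises(ValueError):
        ConsensusConfig(selection_space="umap")
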