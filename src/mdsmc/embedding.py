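"""Linear autoencoder embedding of binary genomic profiles.

The encoder is a single linear map ``Z = X W_e + b_e`` to a
``latent_dim``-dimensional space (16 by default); the decoder maps back
through a sigmoid and the model is trained on mean Bernoulli
cross-entropy by full-batch gradient descent.  Keeping both maps linear
and the optimizer full-batch makes the embedding deterministic given
the seed and cheap to audit; the clustering layer operates on ``Z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mdsmc.cohort import BinaryFeatureMatrix


@dataclass(frozen=True)
class EmbeddingConfig:
    latent_dim: int = 16
    epochs: int = 2000
    learning_rate: float = 2.0
    batch_size: int | None = None  # None = full batch (default, deterministic)
    loss: str = "bernoulli_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("bernoulli_cross_entropy", "squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class LatentEmbedding:
    """Fitted encoder with the training cohort's latent coordinates."""

    patient_ids: list[str]
    coordinates: np.ndarray          # (n, latent_dim)
    training_loss_trace: np.ndarray  # per-epoch mean loss
    feature_names: list[str]
    W_enc: np.ndarray                # (p, d)
    b_enc: np.ndarray                # (d,)
    W_dec: np.ndarray                # (d, p)
    b_dec: np.ndarray                # (p,)
    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    @property
    def latent_dim(self) -> int:
        return self.W_enc.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "patient_ids": self.patient_ids,
            "feature_names": self.feature_names,
            "config": self.config.__dict__,
            "W_enc": self.W_enc.tolist(),
            "b_enc": self.b_enc.tolist(),
            "W_dec": self.W_dec.tolist(),
            "b_dec": self.b_dec.tolist(),
            "coordinates": self.coordinates.tolist(),
            "training_loss_trace": self.training_loss_trace.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "LatentEmbedding":
        p = json.loads(Path(path).read_text())
        return cls(
            patient_ids=p["patient_ids"],
            coordinates=np.array(p["coordinates"]),
            training_loss_trace=np.array(p["training_loss_trace"]),
            feature_names=p["feature_names"],
            W_enc=np.array(p["W_enc"]),
            b_enc=np.array(p["b_enc"]),
            W_dec=np.array(p["W_dec"]),
            b_dec=np.array(p["b_dec"]),
            config=EmbeddingConfig(**p["config"]),
        )


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _loss_value(X: np.ndarray, Xhat: np.ndarray, loss: str) -> float:
    if loss == "bernoulli_cross_entropy":
        eps = 1e-12
        return float(
            -np.mean(X * np.log(Xhat + eps) + (1 - X) * np.log(1 - Xhat + eps))
        )
    return float(np.mean((X - Xhat) ** 2))


def reconstruction_loss(model: LatentEmbedding, X: BinaryFeatureMatrix) -> float:
    """Mean reconstruction loss of a (possibly untrained) model on X."""
    Z = X.values @ model.W_enc + model.b_enc
    A = Z @ model.W_dec + model.b_dec
    Xhat = _sigmoid(A) if model.config.loss == "bernoulli_cross_entropy" else A
    return _loss_value(X.values, Xhat, model.config.loss)


def _init_params(
    p: int, d: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # scaled uniform init from the seeded stream
    s_enc = np.sqrt(6.0 / (p + d))
    s_dec = np.sqrt(6.0 / (d + p))
    W_enc = rng.uniform(-s_enc, s_enc, size=(p, d))
    W_dec = rng.uniform(-s_dec, s_dec, size=(d, p))
    return W_enc, np.zeros(d), W_dec, np.zeros(p)


def initial_model(X: BinaryFeatureMatrix, cfg: EmbeddingConfig | None = None) -> LatentEmbedding:
    """Seed-initialized, untrained model (baseline for loss comparisons)."""
    cfg = cfg or EmbeddingConfig()
    p = X.n_features
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    W_enc, b_enc, W_dec, b_dec = _init_params(p, cfg.latent_dim, rng)
    return LatentEmbedding(
        patient_ids=list(X.patient_ids),
        coordinates=X.values @ W_enc + b_enc,
        training_loss_trace=np.empty(0),
        feature_names=list(X.feature_names),
        W_enc=W_enc,
        b_enc=b_enc,
        W_dec=W_dec,
        b_dec=b_dec,
        config=cfg,
    )


def fit_autoencoder(X: BinaryFeatureMatrix, cfg: EmbeddingConfig | None = None) -> LatentEmbedding:
    """Train the linear autoencoder and return the fitted embedding.

    Training is full-batch gradient descent unless ``cfg.batch_size`` is
    set; the loss trace has one entry per epoch (evaluated after the
    update) and a non-finite loss aborts with diagnostics.
    """
    cfg = cfg or EmbeddingConfig()
    V = X.values
    n, p = V.shape
    if cfg.latent_dim >= p:
        raise ValueError(f"latent_dim {cfg.latent_dim} must be < n_features {p}")
    if np.unique(V, axis=0).shape[0] < 2:
        raise ValueError("X is degenerate: fewer than 2 distinct rows")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    batch_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    W_enc, b_enc, W_dec, b_dec = _init_params(p, cfg.latent_dim, rng)
    bce = cfg.loss == "bernoulli_cross_entropy"

    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        if cfg.batch_size is None:
            batches = [np.arange(n)]
        else:
            order = batch_rng.permutation(n)
            batches = [
                order[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)
            ]
        for idx in batches:
            Xb = V[idx]
            m = len(idx)
            Z = Xb @ W_enc + b_enc
            A = Z @ W_dec + b_dec
            Xhat = _sigmoid(A) if bce else A
            # dL/dA: identical form for BCE+sigmoid and 0.5-scaled SE
            dA = (Xhat - Xb) / (m * p) * (1.0 if bce else 2.0)
            dW_dec = Z.T @ dA
            db_dec = dA.sum(axis=0)
            dZ = dA @ W_dec.T
            dW_enc = Xb.T @ dZ
            db_enc = dZ.sum(axis=0)
            W_enc -= cfg.learning_rate * dW_enc
            b_enc -= cfg.learning_rate * db_enc
            W_dec -= cfg.learning_rate * dW_dec
            b_dec -= cfg.learning_rate * db_dec

        A = (V @ W_enc + b_enc) @ W_dec + b_dec
        Xhat = _sigmoid(A) if bce else A
        trace[epoch] = _loss_value(V, Xhat, cfg.loss)
        if not np.isfinite(trace[epoch]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(learning_rate={cfg.learning_rate}); reduce the step size"
            )

    return LatentEmbedding(
        patient_ids=list(X.patient_ids),
        coordinates=V @ W_enc + b_enc,
        training_loss_trace=trace,
        feature_names=list(X.feature_names),
        W_enc=W_enc,
        b_enc=b_enc,
        W_dec=W_dec,
        b_dec=b_dec,
        config=cfg,
    )


def encode(model: LatentEmbedding, X_new: BinaryFeatureMatrix) -> np.ndarray:
    """Apply the stored linear encoder to new profiles (no refitting)."""
    if list(X_new.feature_names) != list(model.feature_names):
        raise ValueError(
            "feature columns of X_new do not match the training feature_names"
        )
    return X_new.values @ model.W_enc + model.b_enc
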