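"""Molecular signatures of clusters.

Three views of what defines each molecular cluster (MC): per-cluster
feature frequencies (the bar-plot data), permutation feature importance
as mean decrease in out-of-bag accuracy of a bagged-tree classifier
trained to predict cluster labels from the binary features, and
within-cluster pairwise co-occurrence fractions (the circos data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from mdsmc.cohort import BinaryFeatureMatrix


@dataclass(frozen=True)
class ImportanceConfig:
    n_trees: int = 500
    n_permutations: int = 10
    importance_cutoff: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.importance_cutoff < 0:
            raise ValueError("importance_cutoff must be >= 0")
        if self.n_trees < 1 or self.n_permutations < 1:
            raise ValueError("n_trees and n_permutations must be >= 1")


@dataclass
class ClusterSignature:
    cluster: int
    frequencies: dict[str, float]
    important_features: list[str]          # ordered by global importance, desc
    co_occurrence: dict[tuple[str, str], float]

    def validate(self) -> None:
        for f, v in self.frequencies.items():
            if not (0.0 <= v <= 1.0):
                raise AssertionError(f"frequency of {f} outside [0,1]")
        for (i, j), v in self.co_occurrence.items():
            cap = min(self.frequencies[i], self.frequencies[j])
            if v > cap + 1e-12:
                raise AssertionError(f"co-occurrence({i},{j}) exceeds min frequency")


def feature_frequencies(X: BinaryFeatureMatrix, labels) -> pd.DataFrame:
    """Per-cluster column means: fraction of members carrying each feature."""
    labels = np.asarray(labels)
    if len(labels) != X.n_patients:
        raise ValueError("labels do not align with X rows")
    rows = {}
    for k in np.unique(labels):
        members = X.values[labels == k]
        if len(members) == 0:
            raise ValueError(f"cluster {k} is empty")
        rows[int(k)] = members.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=X.feature_names)


def mean_decrease_accuracy(
    X: BinaryFeatureMatrix, labels, cfg: ImportanceConfig | None = None
) -> pd.Series:
    """Permutation importance: mean decrease in out-of-bag accuracy.

    A bagged-tree (random forest with all features eligible per split)
    classifier is trained to predict cluster labels; per tree, accuracy
    on its out-of-bag samples is compared against accuracy after
    permuting one column within the OOB set, and the drop is averaged
    over trees and permutations.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ImportanceConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("importance requires >= 2 clusters")
    V = X.values
    n, p = V.shape
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=None,   # plain bagging: every feature eligible
        bootstrap=True,
        random_state=int(np.random.default_rng(cfg.seed).integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(V, labels)
    perm_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))

    drops = np.zeros(p)
    n_used = 0
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sample_idx)
        if len(oob) == 0:
            continue
        n_used += 1
        X_oob, y_oob = V[oob], labels[oob]
        base_acc = (tree.predict(X_oob) == y_oob).mean()
        for j in range(p):
            col = X_oob[:, j]
            if (col == col[0]).all():
                continue  # constant within OOB: permutation changes nothing
            acc_sum = 0.0
            X_perm = X_oob.copy()
            for _ in range(cfg.n_permutations):
                X_perm[:, j] = perm_rng.permutation(col)
                acc_sum += (tree.predict(X_perm) == y_oob).mean()
            drops[j] += base_acc - acc_sum / cfg.n_permutations
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return pd.Series(drops / n_used, index=X.feature_names).sort_values(ascending=False)


def important_features(
    importance: pd.Series, cutoff: float = 0.01
) -> list[str]:
    """Features whose mean decrease in accuracy meets the cutoff."""
    return list(importance[importance >= cutoff].index)


def pairwise_cooccurrence(X: BinaryFeatureMatrix, labels) -> pd.DataFrame:
    """Within-cluster fraction of members carrying both features of a pair.

    Tidy long format (cluster, feature_i, feature_j, co_occurrence) over
    unordered pairs including the diagonal (where it equals the feature
    frequency) — the substrate for circos-style rendering.
    """
    labels = np.asarray(labels)
    if len(labels) != X.n_patients:
        raise ValueError("labels do not align with X rows")
    out = []
    feats = X.feature_names
    for k in np.unique(labels):
        members = X.values[labels == k]
        both = members.T @ members / len(members)
        for i in range(len(feats)):
            for j in range(i, len(feats)):
                out.append(
                    {
                        "cluster": int(k),
                        "feature_i": feats[i],
                        "feature_j": feats[j],
                        "co_occurrence": float(both[i, j]),
                    }
                )
    return pd.DataFrame(out)


def cluster_signatures(
    X: BinaryFeatureMatrix, labels, cfg: ImportanceConfig | None = None
) -> list[ClusterSignature]:
    """Full signature per cluster: frequencies, flagged features, co-occurrence."""
    cfg = cfg or ImportanceConfig()
    freq = feature_frequencies(X, labels)
    imp = mean_decrease_accuracy(X, labels, cfg)
    flagged = important_features(imp, cfg.importance_cutoff)
    cooc = pairwise_cooccurrence(X, labels)
    sigs = []
    for k in freq.index:
        sub = cooc[cooc["cluster"] == k]
        sigs.append(
            ClusterSignature(
                cluster=int(k),
                frequencies=freq.loc[k].to_dict(),
                important_features=flagged,
                co_occurrence={
                    (r.feature_i, r.feature_j): r.co_occurrence
                    for r in sub.itertuples()
                },
            )
        )
        sigs[-1].validate()
    return sigs
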