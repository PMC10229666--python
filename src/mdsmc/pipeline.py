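"""End-to-end orchestration: encode -> embed -> cluster -> characterize -> survive.

``run_pipeline`` executes every stage in order against one cohort
table, writes all artifacts (labels, signatures, stability report,
survival report) plus a reproducibility manifest, and can resume a
partially completed run by skipping stages whose artifacts exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

import mdsmc
from mdsmc import survival as surv
from mdsmc.characterize import (
    ImportanceConfig,
    feature_frequencies,
    mean_decrease_accuracy,
    pairwise_cooccurrence,
)
from mdsmc.cohort import (
    FeatureSchema,
    encode_features,
    read_cohort,
    write_cohort,
    write_feature_matrix,
)
from mdsmc.consensus import ConsensusConfig, select_k
from mdsmc.embedding import EmbeddingConfig, fit_autoencoder
from mdsmc.simulate import preset_mds_like, simulate
from mdsmc.validation import FoldPlan, cross_fold_stability


@dataclass
class RunConfig:
    cohort_path: str
    out_dir: str
    schema: FeatureSchema = field(default_factory=FeatureSchema)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    folds: FoldPlan = field(default_factory=FoldPlan)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    risk: surv.RiskGroupingConfig = field(default_factory=surv.RiskGroupingConfig)
    seed: int = 0
    run_validation: bool = True

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one master seed into every stage's substream."""
        return replace(
            self,
            seed=seed,
            embedding=replace(self.embedding, seed=seed + 1),
            consensus=replace(self.consensus, seed=seed + 2),
            folds=replace(self.folds, seed=seed + 3),
            importance=replace(self.importance, seed=seed + 4),
        )

    def manifest(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (dict,)):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple, set, frozenset)):
                return sorted(map(enc, o)) if isinstance(o, (set, frozenset)) else [enc(v) for v in o]
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o

        cfg = enc(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config": cfg, "config_hash": digest, "version": mdsmc.__version__}


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Run every stage; returns a dict of artifact paths and key results.

    With ``resume=True``, stages whose artifact files already exist in
    ``out_dir`` are skipped and downstream stages are recomputed from
    the persisted artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "feature_matrix.tsv",
        "labels": out / "cluster_labels.tsv",
        "silhouette": out / "silhouette_by_K.tsv",
        "frequencies": out / "cluster_feature_frequencies.tsv",
        "importance": out / "feature_importance.tsv",
        "cooccurrence": out / "cooccurrence.tsv",
        "stability": out / "stability_report.json",
        "risk_groups": out / "risk_groups.json",
        "survival_medians": out / "cluster_survival.tsv",
        "manifest": out / "manifest.json",
    }

    records = read_cohort(cfg.cohort_path, cfg.schema)
    X = encode_features(records, cfg.schema)
    if not (resume and paths["matrix"].exists()):
        write_feature_matrix(X, paths["matrix"])
    (out / "schema.yaml").write_text(cfg.schema.to_yaml())

    if resume and paths["labels"].exists():
        lab_df = pd.read_csv(paths["labels"], sep="\t")
        labels = lab_df["cluster"].to_numpy()
        emb = fit_autoencoder(X, cfg.embedding)
        model = None
    else:
        emb = fit_autoencoder(X, cfg.embedding)
        model = select_k(emb, cfg.consensus, X)
        labels = model.labels
        pd.DataFrame(
            {"patient_id": X.patient_ids, "cluster": labels,
             "MC": [f"MC{l + 1}" for l in labels]}
        ).to_csv(paths["labels"], sep="\t", index=False)
        pd.DataFrame(
            {
                "K": sorted(model.silhouette_by_K),
                "consensus_silhouette": [
                    model.silhouette_by_K[k] for k in sorted(model.silhouette_by_K)
                ],
                "latent_silhouette": [
                    model.latent_silhouette_by_K[k]
                    for k in sorted(model.latent_silhouette_by_K)
                ],
                "profile_silhouette": [
                    model.profile_silhouette_by_K.get(k, float("nan"))
                    for k in sorted(model.silhouette_by_K)
                ],
            }
        ).to_csv(paths["silhouette"], sep="\t", index=False)

    if not (resume and paths["frequencies"].exists()):
        feature_frequencies(X, labels).to_csv(paths["frequencies"], sep="\t")
        imp = mean_decrease_accuracy(X, labels, cfg.importance)
        imp.rename("mean_decrease_accuracy").to_frame().assign(
            important=lambda d: d["mean_decrease_accuracy"]
            >= cfg.importance.importance_cutoff
        ).to_csv(paths["importance"], sep="\t")
        pairwise_cooccurrence(X, labels).to_csv(paths["cooccurrence"], sep="\t", index=False)

    if cfg.run_validation and not (resume and paths["stability"].exists()):
        report = cross_fold_stability(X, cfg.consensus, cfg.folds, cfg.embedding)
        paths["stability"].write_text(
            json.dumps(
                {
                    "fold_K_selected": report.fold_K_selected,
                    "modal_K": report.modal_K,
                    "min_ari": report.min_ari,
                    "symmetric_ari": report.symmetric_ari.tolist(),
                    "asymmetric_ari": report.asymmetric_ari.tolist(),
                },
                indent=2,
            )
        )

    if not (resume and paths["risk_groups"].exists()):
        times = np.array([r.survival_time for r in records])
        events = np.array([r.event for r in records])
        curves, data = {}, {}
        rows = []
        for k in np.unique(labels):
            mask = labels == k
            name = f"MC{k + 1}"
            curves[name] = surv.kaplan_meier(times[mask], events[mask])
            data[name] = (times[mask], events[mask])
            rows.append({"MC": name, "n": int(mask.sum()),
                         "median_os_months": curves[name].median})
        pd.DataFrame(rows).to_csv(paths["survival_medians"], sep="\t", index=False)
        grouping = surv.aggregate_risk_groups(curves, cfg.risk, survival_data=data)
        paths["risk_groups"].write_text(
            json.dumps(
                {
                    "assignment": grouping.assignment,
                    "n_groups": grouping.n_groups,
                    "landmark_time": grouping.landmark_time,
                    "group_medians": {str(k): v for k, v in grouping.group_medians.items()},
                    "group_median_ci": {
                        str(k): list(v) for k, v in grouping.group_median_ci.items()
                    },
                },
                indent=2,
            )
        )

    manifest = cfg.manifest()
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "labels": labels,
        "model": model,
        "manifest": manifest,
    }


def make_fixture(seed: int = 0, n: int = 200, path: str | Path | None = None):
    """Small packaged cohort (n ~ 200) for tests and examples.

    Generated programmatically from the six-cluster preset; returns the
    cohort and writes the TSV when ``path`` is given.
    """
    spec = preset_mds_like(n_patients=n, seed=seed)
    cohort = simulate(spec)
    if path is not None:
        write_cohort(cohort.records, path)
    return cohort
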