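"""Synthetic MDS/sAML-like cohorts with planted latent-class structure.

The generator draws each patient from one of ``K_true`` latent classes:
independent Bernoulli gene bits within class, a mutually exclusive
karyotype category per class, Weibull survival with class-specific
scale, independent exponential (or administrative) censoring, and
class-dependent treatment / response labels.  It exists so every
downstream stage — embedding, consensus clustering, validation,
characterization, survival — is testable without any restricted-access
download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from mdsmc.cohort import (
    DEFAULT_GENE_PANEL,
    KARYOTYPE_LEVELS,
    PatientRecord,
)

_WEIGHT_TOL = 1e-12


@dataclass
class SimulationSpec:
    """Full parameterization of a synthetic cohort.

    Survival is Weibull(shape, scale) in months per cluster
    (shape = 1 recovers the exponential); observed time is the minimum
    of the event time, an exponential censoring draw with rate
    ``censoring_rate`` and the administrative horizon ``admin_censor_time``.
    """

    n_patients: int
    gene_names: tuple[str, ...]
    mixing_weights: np.ndarray                 # (K,)
    gene_probs: np.ndarray                     # (K, n_genes) in [0,1]
    karyotype_probs: np.ndarray                # (K, 8) rows on the simplex
    weibull_shape: np.ndarray                  # (K,) > 0
    weibull_scale: np.ndarray                  # (K,) months > 0
    censoring_rate: float = 0.0                # per month; 0 = no random censoring
    admin_censor_time: float = np.inf          # months
    hma_prob: np.ndarray | None = None         # (K,) treatment assignment prob
    hsct_prob: np.ndarray | None = None        # (K,)
    response_log_odds: np.ndarray | None = None  # (K,) log-odds of HMA response
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.gene_probs = np.asarray(self.gene_probs, dtype=float)
        self.karyotype_probs = np.asarray(self.karyotype_probs, dtype=float)
        self.weibull_shape = np.asarray(self.weibull_shape, dtype=float)
        self.weibull_scale = np.asarray(self.weibull_scale, dtype=float)
        K = self.K_true
        if self.hma_prob is None:
            self.hma_prob = np.full(K, 0.3)
        if self.hsct_prob is None:
            self.hsct_prob = np.full(K, 0.1)
        if self.response_log_odds is None:
            self.response_log_odds = np.full(K, -1.0)
        self.hma_prob = np.asarray(self.hma_prob, dtype=float)
        self.hsct_prob = np.asarray(self.hsct_prob, dtype=float)
        self.response_log_odds = np.asarray(self.response_log_odds, dtype=float)
        self.validate()

    @property
    def K_true(self) -> int:
        return len(self.mixing_weights)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def validate(self) -> None:
        K, G = self.K_true, self.n_genes
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(self.mixing_weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("mixing_weights must sum to 1")
        if (self.mixing_weights < 0).any():
            raise ValueError("mixing_weights must be non-negative")
        if self.gene_probs.shape != (K, G):
            raise ValueError(f"gene_probs shape {self.gene_probs.shape} != ({K},{G})")
        if ((self.gene_probs < 0) | (self.gene_probs > 1)).any():
            raise ValueError("gene_probs must be in [0,1]")
        if self.karyotype_probs.shape != (K, len(KARYOTYPE_LEVELS)):
            raise ValueError(
                f"karyotype_probs shape {self.karyotype_probs.shape} != ({K},8)"
            )
        row_sums = self.karyotype_probs.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > _WEIGHT_TOL:
            raise ValueError("karyotype_probs rows must sum to 1")
        if (self.weibull_shape <= 0).any() or (self.weibull_scale <= 0).any():
            raise ValueError("weibull shape and scale must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        for name in ("hma_prob", "hsct_prob"):
            v = getattr(self, name)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} must be in [0,1]")

    def to_yaml(self) -> str:
        payload = {
            "n_patients": int(self.n_patients),
            "gene_names": list(self.gene_names),
            "mixing_weights": self.mixing_weights.tolist(),
            "gene_probs": self.gene_probs.tolist(),
            "karyotype_probs": self.karyotype_probs.tolist(),
            "weibull_shape": self.weibull_shape.tolist(),
            "weibull_scale": self.weibull_scale.tolist(),
            "censoring_rate": float(self.censoring_rate),
            "admin_censor_time": (
                None if np.isinf(self.admin_censor_time) else float(self.admin_censor_time)
            ),
            "hma_prob": self.hma_prob.tolist(),
            "hsct_prob": self.hsct_prob.tolist(),
            "response_log_odds": self.response_log_odds.tolist(),
            "seed": int(self.seed),
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationSpec":
        p = yaml.safe_load(text)
        admin = p.get("admin_censor_time")
        return cls(
            n_patients=p["n_patients"],
            gene_names=tuple(p["gene_names"]),
            mixing_weights=np.array(p["mixing_weights"]),
            gene_probs=np.array(p["gene_probs"]),
            karyotype_probs=np.array(p["karyotype_probs"]),
            weibull_shape=np.array(p["weibull_shape"]),
            weibull_scale=np.array(p["weibull_scale"]),
            censoring_rate=p.get("censoring_rate", 0.0),
            admin_censor_time=np.inf if admin is None else float(admin),
            hma_prob=np.array(p["hma_prob"]) if "hma_prob" in p else None,
            hsct_prob=np.array(p["hsct_prob"]) if "hsct_prob" in p else None,
            response_log_odds=(
                np.array(p["response_log_odds"]) if "response_log_odds" in p else None
            ),
            seed=p.get("seed", 0),
        )


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    true_labels: np.ndarray

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if len(self.records) != len(self.true_labels):
            raise ValueError("records and true_labels length mismatch")


# per-stage substreams keyed by position: adding a stage at the end never
# perturbs earlier draws
_STAGES = ("labels", "genes", "karyotype", "survival", "censor", "clinical", "treatment")


def simulate(spec: SimulationSpec, n_patients: int | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw a cohort from the latent-class generative model.

    Fully reproducible from ``spec.seed``; ``n_patients`` / ``seed``
    override the spec values without mutating the spec.
    """
    spec.validate()
    n = int(n_patients if n_patients is not None else spec.n_patients)
    master = int(seed if seed is not None else spec.seed)
    streams = {
        stage: np.random.default_rng(np.random.SeedSequence(master, spawn_key=(idx,)))
        for idx, stage in enumerate(_STAGES)
    }

    K = spec.K_true
    z = streams["labels"].choice(K, size=n, p=spec.mixing_weights)
    bits = streams["genes"].random((n, spec.n_genes)) < spec.gene_probs[z]
    kt_draws = streams["karyotype"].random(n)
    kt_cum = np.cumsum(spec.karyotype_probs, axis=1)
    kt_index = (kt_draws[:, None] > kt_cum[z]).sum(axis=1)

    # numpy's weibull(a) draws scale-1 Weibull with shape a; rescale per cluster
    event_time = spec.weibull_scale[z] * streams["survival"].weibull(
        spec.weibull_shape[z], size=n
    )

    censor_time = np.full(n, spec.admin_censor_time)
    if spec.censoring_rate > 0:
        censor_time = np.minimum(
            censor_time, streams["censor"].exponential(1.0 / spec.censoring_rate, size=n)
        )
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clin = streams["clinical"]
    age = np.clip(clin.normal(72, 9, size=n), 20, 95)
    sex = np.where(clin.random(n) < 0.6, "M", "F")
    blast = np.clip(clin.gamma(1.5, 6.0, size=n), 0, 100)
    hb = np.clip(clin.normal(10, 1.5, size=n), 4, 18)
    plt = np.clip(clin.lognormal(np.log(110), 0.7, size=n), 5, 1500)
    wbc = np.clip(clin.lognormal(np.log(5), 0.6, size=n), 0.3, 200)

    treat = streams["treatment"]
    hma = treat.random(n) < spec.hma_prob[z]
    hsct = treat.random(n) < spec.hsct_prob[z]
    resp_p = 1.0 / (1.0 + np.exp(-spec.response_log_odds[z]))
    responded = (treat.random(n) < resp_p) & hma
    resp_kind = treat.choice(["CR", "mCR", "HI"], size=n, p=[0.3, 0.2, 0.5])

    records: list[PatientRecord] = []
    for i in range(n):
        flags = set()
        if hma[i]:
            flags.add("HMA")
        if hsct[i]:
            flags.add("HSCT")
        genes = frozenset(
            g for g, bit in zip(spec.gene_names, bits[i]) if bit
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                mutated_genes=genes,
                karyotype_category=KARYOTYPE_LEVELS[kt_index[i]],
                age=round(float(age[i]), 1),
                sex=str(sex[i]),
                blast_pct=round(float(blast[i]), 1),
                hemoglobin=round(float(hb[i]), 1),
                platelets=round(float(plt[i]), 1),
                wbc=round(float(wbc[i]), 1),
                diagnosis_label="MDS",
                treatment_flags=frozenset(flags),
                response_label=(str(resp_kind[i]) if responded[i] else ("none" if hma[i] else None)),
                survival_time=round(float(observed[i]), 3),
                event=int(event[i]),
            )
        )
    return SyntheticCohort(records=records, true_labels=z)


def preset_mds_like(n_patients: int = 2000, seed: int = 0) -> SimulationSpec:
    """Six-cluster preset loosely imitating published molecular signatures.

    Clusters (defining lesions carried by every member, echoing the
    100% cluster-purity signatures of real molecular clusters):

    0. NK, mostly unmutated with occasional DNMT3A/JAK2/RAS hits
    1. NK + SF3B1 + TET2 (longest survival tier)
    2. del5q with DNMT3A/TP53 hits
    3. NK + TET2 + ASXL1 with SRSF2/RUNX1
    4. del7q + RAS-pathway hits
    5. complex karyotype + TP53 (shortest survival tier)

    Every cluster pair differs in at least two deterministic defining
    bits (karyotype one-hots or 100%-penetrant lesions), while secondary
    lesion probabilities stay <= 0.25 — so planted between-cluster
    separation dominates within-cluster heterogeneity (the "strong
    separation" regime).  Weibull scales are ordered so planted risk
    tiers exist; HMA use and response log-odds vary by cluster so the
    treatment-response layer is exercised.
    """
    genes = DEFAULT_GENE_PANEL
    gidx = {g: j for j, g in enumerate(genes)}
    K = 6
    P = np.full((K, len(genes)), 0.02)

    def set_probs(k: int, **probs: float) -> None:
        for g, p in probs.items():
            P[k, gidx[g]] = p

    set_probs(0, DNMT3A=0.11, JAK2=0.11, NRAS=0.05, KRAS=0.05)
    set_probs(1, SF3B1=1.0, TET2=1.0, DNMT3A=0.24)
    set_probs(2, DNMT3A=0.17, TP53=0.17)
    set_probs(3, TET2=1.0, ASXL1=1.0, SRSF2=0.25, RUNX1=0.20)
    set_probs(4, NRAS=0.15, CBL=0.15, PTPN11=0.10)
    set_probs(5, TP53=0.44)

    KT = np.zeros((K, len(KARYOTYPE_LEVELS)))
    kt = {name: j for j, name in enumerate(KARYOTYPE_LEVELS)}
    KT[0, kt["NK"]] = 1.0
    KT[1, kt["NK"]] = 1.0
    KT[2, kt["del5q"]] = 1.0
    KT[3, kt["NK"]] = 1.0
    KT[4, kt["del7q"]] = 1.0
    KT[5, kt["complex"]] = 1.0

    return SimulationSpec(
        n_patients=n_patients,
        gene_names=genes,
        mixing_weights=np.array([0.25, 0.20, 0.15, 0.15, 0.12, 0.13]),
        gene_probs=P,
        karyotype_probs=KT,
        weibull_shape=np.full(K, 1.2),
        weibull_scale=np.array([60.0, 90.0, 55.0, 33.0, 20.0, 9.0]),
        censoring_rate=1.0 / 80.0,
        admin_censor_time=120.0,
        hma_prob=np.array([0.20, 0.10, 0.20, 0.35, 0.40, 0.50]),
        hsct_prob=np.array([0.10, 0.05, 0.08, 0.12, 0.15, 0.20]),
        response_log_odds=np.array([-1.5, -1.2, -1.0, -0.2, -1.0, -1.8]),
        seed=seed,
    )
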