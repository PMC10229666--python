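"""Cohort tables and their deterministic binary feature encoding.

A cohort is a per-patient TSV/CSV with gene-level mutation calls, a
karyotype category, clinical covariates, treatment / response labels and
right-censored survival.  ``encode_features`` turns parsed records into
the patients x features 0/1 matrix that the clustering consumes:
one indicator per panel gene, one per functional pathway group (1 iff
any member gene is mutated), and a block of mutually exclusive
karyotype one-hots.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

KARYOTYPE_LEVELS: tuple[str, ...] = (
    "NK",
    "del5q",
    "del7q",
    "del20q",
    "trisomy8",
    "delY",
    "complex",
    "other_abnormal",
)

# Precedence used when a raw karyotype string matches several mutually
# exclusive categories (complex always wins; NK never co-occurs).
KARYOTYPE_PRECEDENCE: tuple[str, ...] = (
    "complex",
    "del7q",
    "del5q",
    "del20q",
    "trisomy8",
    "delY",
    "other_abnormal",
)

SEX_LEVELS = ("M", "F")
TREATMENT_LEVELS = ("HMA", "HSCT", "venetoclax", "other")
RESPONSE_LEVELS = ("CR", "mCR", "HI", "none")

#: ~40-gene targeted myeloid panel used as the default gene list.  Any
#: gene list can be supplied through :class:`FeatureSchema`.
DEFAULT_GENE_PANEL: tuple[str, ...] = (
    "TET2", "SF3B1", "ASXL1", "DNMT3A", "SRSF2", "TP53", "RUNX1", "U2AF1",
    "ZRSR2", "JAK2", "NRAS", "KRAS", "CBL", "PTPN11", "NF1", "RIT1",
    "EZH2", "STAG2", "BCOR", "BCORL1", "IDH1", "IDH2", "NPM1", "FLT3",
    "CEBPA", "GATA2", "ETV6", "PHF6", "WT1", "KIT", "MPL", "CALR",
    "CSF3R", "SETBP1", "GNAS", "GNB1", "PPM1D", "DDX41", "RAD21", "SMC3",
)

#: Default RAS-pathway membership; editable through the schema.
DEFAULT_PATHWAY_GROUPS: dict[str, frozenset[str]] = {
    "RAS_pathway": frozenset({"NRAS", "KRAS", "PTPN11", "CBL", "NF1", "RIT1"}),
}

MANDATORY_COLUMNS = (
    "patient_id",
    "mutations",
    "karyotype",
    "survival_months",
    "event",
)

NUMERIC_COLUMNS = ("age", "blast_pct", "hemoglobin", "platelets", "wbc")


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the declared schema."""


class CohortRowError(ValueError):
    """Raised when individual rows cannot be parsed; carries row details."""

    def __init__(self, message: str, rows: Sequence[tuple[int, str]]):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: genomic profile, clinical covariates and outcome."""

    patient_id: str
    mutated_genes: frozenset[str]
    karyotype_category: str
    age: float | None = None
    sex: str | None = None
    blast_pct: float | None = None
    hemoglobin: float | None = None
    platelets: float | None = None
    wbc: float | None = None
    diagnosis_label: str = ""
    treatment_flags: frozenset[str] = frozenset()
    response_label: str | None = None
    survival_time: float = 0.0
    event: int = 0

    def __post_init__(self) -> None:
        if self.karyotype_category not in KARYOTYPE_LEVELS:
            raise ValueError(
                f"karyotype_category {self.karyotype_category!r} not one of {KARYOTYPE_LEVELS}"
            )
        if self.blast_pct is not None and not (0.0 <= self.blast_pct <= 100.0):
            raise ValueError(f"blast_pct {self.blast_pct} outside [0, 100]")
        if self.survival_time < 0:
            raise ValueError(f"survival_time {self.survival_time} < 0")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


@dataclass(frozen=True)
class FeatureSchema:
    """Declares the feature space: gene panel, pathway groups, karyotype levels.

    ``min_feature_frequency`` drops columns rarer than the given fraction
    of patients at encoding time (default 0: keep the whole panel — rare
    lesions are mitigated by pathway grouping, not by filtering).
    """

    gene_list: tuple[str, ...] = DEFAULT_GENE_PANEL
    pathway_groups: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_GROUPS)
    )
    karyotype_levels: tuple[str, ...] = KARYOTYPE_LEVELS
    min_feature_frequency: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.gene_list)) != len(self.gene_list):
            raise ValueError("gene_list contains duplicate symbols")
        if tuple(self.karyotype_levels) != KARYOTYPE_LEVELS:
            raise ValueError(f"karyotype_levels must be {KARYOTYPE_LEVELS} in order")
        if not (0.0 <= self.min_feature_frequency < 1.0):
            raise ValueError("min_feature_frequency must be in [0, 1)")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return (
            tuple(self.gene_list)
            + tuple(sorted(self.pathway_groups))
            + tuple(f"KT_{k}" for k in self.karyotype_levels)
        )

    def to_yaml(self) -> str:
        payload = {
            "gene_list": list(self.gene_list),
            "pathway_groups": {k: sorted(v) for k, v in self.pathway_groups.items()},
            "karyotype_levels": list(self.karyotype_levels),
            "min_feature_frequency": float(self.min_feature_frequency),
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureSchema":
        payload = yaml.safe_load(text)
        return cls(
            gene_list=tuple(payload["gene_list"]),
            pathway_groups={
                k: frozenset(v) for k, v in payload.get("pathway_groups", {}).items()
            },
            karyotype_levels=tuple(payload.get("karyotype_levels", KARYOTYPE_LEVELS)),
            min_feature_frequency=float(payload.get("min_feature_frequency", 0.0)),
        )


@dataclass
class BinaryFeatureMatrix:
    """Patients x features 0/1 matrix with ordered ids and feature names."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.patient_ids)}, {len(self.feature_names)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        self.values = self.values.astype(np.float64)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def karyotype_block(self) -> np.ndarray:
        cols = [i for i, f in enumerate(self.feature_names) if f.startswith("KT_")]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.astype(int), columns=self.feature_names, copy=True
        )
        df.insert(0, "patient_id", self.patient_ids)
        return df


# --- karyotype string normalization -------------------------------------

_KARYOTYPE_ALIASES: dict[str, str] = {
    "nk": "NK", "normal": "NK", "46,xx": "NK", "46,xy": "NK",
    "del5q": "del5q", "del(5q)": "del5q", "-5": "del5q", "5q-": "del5q",
    "del7q": "del7q", "del(7q)": "del7q", "-7": "del7q", "7q-": "del7q",
    "del20q": "del20q", "del(20q)": "del20q", "-20": "del20q", "20q-": "del20q",
    "trisomy8": "trisomy8", "+8": "trisomy8", "tri8": "trisomy8",
    "dely": "delY", "-y": "delY",
    "complex": "complex",
    "other": "other_abnormal", "other_abnormal": "other_abnormal",
    "abnormal": "other_abnormal",
}

_KARYOTYPE_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"del\(5", "del5q"), (r"del\(7", "del7q"), (r"del\(20", "del20q"),
    (r"\+8", "trisomy8"), (r"-y", "delY"), (r"complex", "complex"),
)


def normalize_karyotype(raw: str) -> str:
    """Map a raw karyotype string to one of the eight categories.

    Exact aliases are tried first; otherwise cytogenetic sub-patterns are
    scanned and, if several categories match, the fixed precedence
    complex > del7q > del5q > del20q > trisomy8 > delY resolves the tie.
    Raises :class:`ValueError` for strings with no mapping.
    """
    s = str(raw).strip()
    if s in KARYOTYPE_LEVELS:
        return s
    key = s.lower().replace(" ", "")
    if key in _KARYOTYPE_ALIASES:
        return _KARYOTYPE_ALIASES[key]
    hits = {cat for pat, cat in _KARYOTYPE_PATTERNS if re.search(pat, key)}
    if len(hits) >= 3:
        return "complex"
    for cat in KARYOTYPE_PRECEDENCE:
        if cat in hits:
            return cat
    raise ValueError(f"unknown karyotype string {raw!r}")


def _parse_set(cell: object, sep: str = ";") -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text or text.lower() in ("nan", "none", "na"):
        return frozenset()
    parts = re.split(r"[;,]", text)
    return frozenset(p.strip() for p in parts if p.strip())


def _parse_float(cell: object) -> float | None:
    if cell is None:
        return None
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def read_cohort(
    path: str | Path | io.TextIOBase, schema: FeatureSchema | None = None
) -> list[PatientRecord]:
    """Read a cohort TSV/CSV into :class:`PatientRecord` objects.

    Unparseable numeric fields become missing (``None``), never zero.
    Missing mandatory columns raise :class:`CohortSchemaError` naming
    them; rows whose karyotype string has no mapping are collected into
    a single :class:`CohortRowError`.
    """
    del schema  # feature space plays no role in parsing; kept for symmetry
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing mandatory columns: {missing}")

    records: list[PatientRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            karyotype = normalize_karyotype(row["karyotype"])
        except ValueError as exc:
            bad_rows.append((int(i), str(exc)))
            continue
        sex = str(row.get("sex", "")).strip() or None
        if sex is not None and sex not in SEX_LEVELS:
            sex = None
        response = str(row.get("response", "")).strip() or None
        if response is not None and response not in RESPONSE_LEVELS:
            response = None
        numeric = {c: _parse_float(row.get(c)) for c in NUMERIC_COLUMNS}
        diagnosis = row.get("diagnosis", "")
        if diagnosis is None or (isinstance(diagnosis, float) and math.isnan(diagnosis)):
            diagnosis = ""
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                mutated_genes=_parse_set(row["mutations"]),
                karyotype_category=karyotype,
                sex=sex,
                diagnosis_label=str(diagnosis),
                treatment_flags=_parse_set(row.get("treatments")),
                response_label=response,
                survival_time=_parse_float(row["survival_months"]) or 0.0,
                event=int(float(row["event"])),
                **numeric,
            )
        )
    if bad_rows:
        raise CohortRowError(
            f"{len(bad_rows)} rows with unmappable karyotype strings", bad_rows
        )
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records in the TSV dialect :func:`read_cohort` accepts."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "mutations": ";".join(sorted(r.mutated_genes)),
                "karyotype": r.karyotype_category,
                "age": r.age,
                "sex": r.sex,
                "blast_pct": r.blast_pct,
                "hemoglobin": r.hemoglobin,
                "platelets": r.platelets,
                "wbc": r.wbc,
                "diagnosis": r.diagnosis_label,
                "treatments": ";".join(sorted(r.treatment_flags)),
                "response": r.response_label,
                "survival_months": r.survival_time,
                "event": r.event,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def encode_features(
    records: Sequence[PatientRecord], schema: FeatureSchema | None = None
) -> BinaryFeatureMatrix:
    """Encode records into the binary clustering substrate.

    Columns, in deterministic schema order: one indicator per panel gene
    (1 iff the gene is mutated — all variants per gene are OR-ed, no
    VAF), one indicator per pathway group (1 iff any member mutated),
    then the eight mutually exclusive karyotype one-hots.  Columns with
    frequency below ``schema.min_feature_frequency`` are dropped and
    reported in ``dropped_features``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    schema = schema or FeatureSchema()
    if not schema.gene_list:
        raise ValueError("schema gene_list must be non-empty")

    names = list(schema.feature_names)
    n, p = len(records), len(names)
    values = np.zeros((n, p), dtype=np.float64)
    gene_idx = {g: j for j, g in enumerate(schema.gene_list)}
    pathway_names = sorted(schema.pathway_groups)
    kt_offset = len(schema.gene_list) + len(pathway_names)
    kt_idx = {k: kt_offset + j for j, k in enumerate(schema.karyotype_levels)}

    for i, rec in enumerate(records):
        for g in rec.mutated_genes:
            j = gene_idx.get(g)
            if j is not None:
                values[i, j] = 1.0
        for j, pw in enumerate(pathway_names):
            if rec.mutated_genes & schema.pathway_groups[pw]:
                values[i, len(schema.gene_list) + j] = 1.0
        values[i, kt_idx[rec.karyotype_category]] = 1.0

    dropped: list[str] = []
    if schema.min_feature_frequency > 0:
        freqs = values.mean(axis=0)
        keep = freqs >= schema.min_feature_frequency
        # never drop karyotype one-hots: they encode a categorical
        keep[kt_offset:] = True
        dropped = [names[j] for j in range(p) if not keep[j]]
        values = values[:, keep]
        names = [names[j] for j in range(p) if keep[j]]

    return BinaryFeatureMatrix(
        patient_ids=[r.patient_id for r in records],
        feature_names=names,
        values=values,
        dropped_features=dropped,
    )


def write_feature_matrix(X: BinaryFeatureMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> BinaryFeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    ids = df["patient_id"].tolist()
    feats = [c for c in df.columns if c != "patient_id"]
    return BinaryFeatureMatrix(ids, feats, df[feats].to_numpy())
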