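"""Readers and writers for every artifact the pipeline touches.

All tabular formats are plain text: genotypes as CSV or a PLINK ``.raw``-style
dialect, phenotypes as CSV, association maps and similarity networks as
TAB-separated matrices with row and column headers, cluster assignments as
JSON, and the SNP-to-gene annotation as a two-column TSV.  Subject alignment
between genotype and phenotype tables is always by identifier, never by row
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeTable",
    "CohortSpec",
    "read_genotypes",
    "read_phenotypes",
    "read_matrix",
    "write_matrix",
    "read_snp_gene_map",
    "read_assignment",
    "write_assignment",
]

#: PLINK .raw meta columns that may precede the per-SNP dosage columns.
_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")

#: Covariates required by the association regressions.
COVARIATE_COLUMNS = ("age", "sex", "education")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive-coded dosage matrix.

    ``dosages`` holds minor-allele counts in {0, 1, 2}; missing genotypes are
    ``NaN``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FormatError("duplicate subject ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError("duplicate SNP ids in genotype matrix")
        if self.dosages.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise FormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        bad = ~np.isin(finite, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.where(
                np.isfinite(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
            )
            r, c = rows[0], cols[0]
            raise FormatError(
                f"genotype value {self.dosages[r, c]!r} at subject "
                f"{self.subject_ids[r]!r}, SNP {self.snp_ids[c]!r} is not in {{0,1,2}}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.subject_ids, columns=self.snp_ids)


@dataclass
class PhenotypeTable:
    """Subject-level quantitative traits with diagnosis and covariates.

    ``qt_values`` is subjects x ROIs; covariates are age (years), sex
    (binary), education (years).
    """

    subject_ids: list[str]
    diagnosis: pd.Series  # indexed by subject id
    covariates: pd.DataFrame  # columns age/sex/education, indexed by subject id
    roi_ids: list[str]
    qt_values: np.ndarray  # subjects x ROIs
    modality: str = ""

    def __post_init__(self) -> None:
        self.qt_values = np.asarray(self.qt_values, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FormatError("duplicate subject ids in phenotype table")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise FormatError("duplicate ROI ids in phenotype table")
        if self.qt_values.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise FormatError("QT matrix shape does not match subject/ROI ids")
        missing_cov = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing_cov:
            raise FormatError(f"phenotype table lacks covariate columns: {missing_cov}")
        incomplete = self.covariates[list(COVARIATE_COLUMNS)].isna().any(axis=1)
        if incomplete.any():
            subjects = list(self.covariates.index[incomplete])
            raise FormatError(f"missing covariates for subjects: {subjects}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def qt_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.qt_values, index=self.subject_ids, columns=self.roi_ids)


@dataclass(frozen=True)
class CohortSpec:
    """A case-control comparison group, e.g. AD vs. HC."""

    name: str
    case_labels: frozenset = field(default_factory=frozenset)
    control_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_labels", frozenset(self.case_labels))
        object.__setattr__(self, "control_labels", frozenset(self.control_labels))
        if not self.case_labels or not self.control_labels:
            raise ValueError(f"cohort {self.name!r}: case and control labels must be nonempty")
        if self.case_labels & self.control_labels:
            raise ValueError(f"cohort {self.name!r}: case/control labels overlap")

    @property
    def labels(self) -> frozenset:
        return self.case_labels | self.control_labels


def read_genotypes(path: str | Path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv`` or ``plink_raw`` dialect.

    CSV: first column is the subject id, remaining columns are SNPs.
    PLINK raw: whitespace-separated with FID/IID (and optionally
    PAT/MAT/SEX/PHENOTYPE) meta columns; the subject id is the IID.
    Missing genotypes are "NA".
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        subject_ids = [str(s) for s in df.index]
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        if "IID" not in df.columns:
            raise FormatError(f"{path}: PLINK .raw file lacks an IID column")
        subject_ids = [str(s) for s in df["IID"]]
        df = df.drop(columns=[c for c in _PLINK_META if c in df.columns])
        df.index = subject_ids
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    snp_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric genotype entry ({exc})") from exc
    return GenotypeMatrix(subject_ids, snp_ids, values)


def write_genotypes(geno: GenotypeMatrix, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    df = geno.to_frame()
    if dialect == "csv":
        df.index.name = "subject_id"
        df.to_csv(path, na_rep="NA")
    elif dialect == "plink_raw":
        out = df.copy()
        out.insert(0, "IID", geno.subject_ids)
        out.insert(0, "FID", geno.subject_ids)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_phenotypes(path: str | Path, modality: str = "") -> PhenotypeTable:
    """Read a phenotype CSV: subject_id, diagnosis, age, sex, education, ROI_*."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["subject_id", "diagnosis", *COVARIATE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    subject_ids = [str(s) for s in df["subject_id"]]
    if len(set(subject_ids)) != len(subject_ids):
        dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate subject ids {dupes}")
    roi_cols = [c for c in df.columns if c not in required]
    df.index = subject_ids
    return PhenotypeTable(
        subject_ids=subject_ids,
        diagnosis=df["diagnosis"].astype(str),
        covariates=df[list(COVARIATE_COLUMNS)].astype(float),
        roi_ids=roi_cols,
        qt_values=df[roi_cols].to_numpy(dtype=float),
        modality=modality,
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"subject_id": pheno.subject_ids})
    df["diagnosis"] = pheno.diagnosis.loc[pheno.subject_ids].to_numpy()
    for c in COVARIATE_COLUMNS:
        df[c] = pheno.covariates.loc[pheno.subject_ids, c].to_numpy()
    qt = pheno.qt_frame()
    for c in pheno.roi_ids:
        df[c] = qt[c].to_numpy()
    df.to_csv(path, index=False)


def write_matrix(frame: pd.DataFrame, path: str | Path, kind: str = "association_map") -> None:
    """Write a labelled matrix as TSV; networks must be square/symmetric in [0,1]."""
    if kind == "network":
        _validate_network_frame(frame, str(path))
    elif kind != "association_map":
        raise ValueError(f"unknown matrix kind {kind!r}")
    frame.to_csv(path, sep="\t", float_format="%.17g")  # lossless round trip


def read_matrix(path: str | Path, kind: str = "association_map") -> pd.DataFrame:
    """Read a labelled TSV matrix; validates symmetry and range for networks."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.columns = [str(c) for c in frame.columns]
    frame.index = [str(i) for i in frame.index]
    if kind == "network":
        _validate_network_frame(frame, str(path))
    elif kind != "association_map":
        raise ValueError(f"unknown matrix kind {kind!r}")
    return frame


def _validate_network_frame(frame: pd.DataFrame, where: str) -> None:
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or list(frame.index) != list(frame.columns):
        raise FormatError(f"{where}: network matrix must be square with matching labels")
    if not np.allclose(values, values.T, atol=1e-12):
        raise FormatError(f"{where}: network matrix is not symmetric")
    if values.min() < 0 or values.max() > 1:
        raise FormatError(f"{where}: network entries must lie in [0, 1]")


def read_snp_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of SNP id -> closest gene symbol."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            snp, gene = parts[0].strip(), parts[1].strip()
            if snp in mapping and mapping[snp] != gene:
                raise FormatError(
                    f"{path}:{lineno}: SNP {snp!r} mapped to both "
                    f"{mapping[snp]!r} and {gene!r}"
                )
            mapping[snp] = gene
    return mapping


def write_assignment(assignment: dict[str, int], path: str | Path) -> None:
    """Write a cluster assignment as JSON {snp_id: cluster_index} (0-based)."""
    with open(path, "w") as fh:
        json.dump({str(k): int(v) for k, v in assignment.items()}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_assignment(path: str | Path) -> dict[str, int]:
    with open(path) as fh:
        raw = json.load(fh)
    return {str(k): int(v) for k, v in raw.items()}
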