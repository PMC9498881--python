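"""Synthetic genotype/phenotype cohorts with planted SNP-cluster structure.

The generator emulates the shape of an imaging-genetics study: additive
Binomial(2, MAF) genotypes for a panel of candidate SNPs, per-subject
covariates (age, sex, education), diagnosis groups supporting case-control
cohort splits, and region-of-interest (ROI) quantitative traits in which
disjoint ROI blocks carry the additive signal of planted SNP clusters.

Every ROI ``r`` inside cluster ``c``'s signature receives the contribution
``effect_size * sum_{j in c} g_ij`` plus covariate effects plus Gaussian
noise; ROIs outside all signatures are covariates plus noise only.  Diagnosis
labels are assigned independently of genotype, because cohort splitting, not
disease genetics, is what downstream stages exercise.  A single integer seed
drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PhenotypeTable

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort", "generate_association_map"]

#: Diagnosis group proportions mirroring a 202 AD / 218 LMCI / 296 EMCI /
#: 255 HC cohort (N = 971).
DEFAULT_GROUPS = {
    "AD": 202 / 971,
    "LMCI": 218 / 971,
    "EMCI": 296 / 971,
    "HC": 255 / 971,
}

#: Fixed covariate sampling distributions: age ~ N(75, 6), sex ~ Bernoulli(0.5),
#: education ~ N(16, 2).
COVARIATE_DISTRIBUTIONS = {
    "age": ("normal", 75.0, 6.0),
    "sex": ("bernoulli", 0.5),
    "education": ("normal", 16.0, 2.0),
}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


def _even_partition(n_items: int, n_parts: int) -> list[list[int]]:
    """Split 0..n_items-1 into n_parts contiguous near-equal blocks."""
    bounds = np.linspace(0, n_items, n_parts + 1).round().astype(int)
    return [list(range(bounds[i], bounds[i + 1])) for i in range(n_parts)]


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults match the study shape this package targets: 54 candidate SNPs,
    116 atlas ROIs, two planted SNP clusters whose ROI signatures are
    disjoint blocks, and diagnosis groups in the proportions of a
    971-subject AD cohort.
    """

    n_subjects: int = 500
    n_snps: int = 54
    n_rois: int = 116
    n_planted_clusters: int = 2
    cluster_memberships: list[list[int]] | None = None
    roi_signatures: list[list[int]] | None = None
    effect_size: float = 1.0  # QT units per minor allele
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise_sd: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.03, "sex": 0.25, "education": -0.05}
    )
    group_proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_memberships is None:
            self.cluster_memberships = _even_partition(self.n_snps, self.n_planted_clusters)
        else:
            self.n_planted_clusters = len(self.cluster_memberships)
        if self.roi_signatures is None:
            # Equal disjoint blocks, leaving a trailing run of null ROIs.
            size = self.n_rois // (self.n_planted_clusters + 1)
            self.roi_signatures = [
                list(range(c * size, (c + 1) * size)) for c in range(self.n_planted_clusters)
            ]
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1 or self.n_rois < 1:
            raise ConfigurationError("n_subjects, n_snps and n_rois must be positive")
        flat = [i for block in self.cluster_memberships for i in block]
        if sorted(flat) != list(range(self.n_snps)):
            raise ConfigurationError(
                "cluster_memberships must partition SNP indices 0..n_snps-1"
            )
        if any(len(block) == 0 for block in self.cluster_memberships):
            raise ConfigurationError("every planted cluster must be nonempty")
        seen: set[int] = set()
        for sig in self.roi_signatures:
            block = set(sig)
            if block & seen:
                raise ConfigurationError("roi_signatures must be pairwise disjoint")
            if not block <= set(range(self.n_rois)):
                raise ConfigurationError("roi_signatures indices out of range")
            seen |= block
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high < 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"group_proportions must sum to 1 (got {total})")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted SNP cluster labels."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_labels: dict[str, int]  # snp_id -> planted cluster index
    config: SimulationConfig


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s, r = config.n_subjects, config.n_snps, config.n_rois

    subject_ids = [f"subj{i:04d}" for i in range(n)]
    snp_ids = [f"rs{i + 1:06d}" for i in range(s)]
    roi_ids = [f"ROI_{j + 1}" for j in range(r)]

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    dosages = rng.binomial(2, mafs[np.newaxis, :], size=(n, s)).astype(float)

    age = rng.normal(*COVARIATE_DISTRIBUTIONS["age"][1:], size=n)
    sex = rng.binomial(1, COVARIATE_DISTRIBUTIONS["sex"][1], size=n).astype(float)
    education = rng.normal(*COVARIATE_DISTRIBUTIONS["education"][1:], size=n)

    groups = list(config.group_proportions)
    diagnosis = rng.choice(groups, size=n, p=[config.group_proportions[g] for g in groups])

    eff = config.covariate_effects
    covariate_part = (
        eff.get("age", 0.0) * age + eff.get("sex", 0.0) * sex + eff.get("education", 0.0) * education
    )

    qt = np.tile(covariate_part[:, np.newaxis], (1, r))
    for c, (members, signature) in enumerate(zip(config.cluster_memberships, config.roi_signatures)):
        allele_sum = dosages[:, members].sum(axis=1)
        for roi in signature:
            qt[:, roi] += config.effect_size * allele_sum
    qt += rng.normal(0.0, config.noise_sd, size=(n, r))

    genotypes = GenotypeMatrix(subject_ids, snp_ids, dosages)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "education": education}, index=subject_ids
    )
    phenotypes = PhenotypeTable(
        subject_ids=subject_ids,
        diagnosis=pd.Series(diagnosis, index=subject_ids, dtype=str),
        covariates=covariates,
        roi_ids=roi_ids,
        qt_values=qt,
        modality="synthetic",
    )
    true_labels = {
        snp_ids[i]: c
        for c, members in enumerate(config.cluster_memberships)
        for i in members
    }
    return SyntheticCohort(genotypes, phenotypes, true_labels, config)


def generate_association_map(
    n_snps: int,
    n_rois: int,
    cluster_memberships: list[list[int]],
    signal: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Directly fabricate a nonnegative SNP x ROI association map.

    Rows belonging to the same planted cluster share an elevated-mean column
    block; used as a fast fixture for the network and clustering stages,
    bypassing the regressions.  With ``signal=0`` rows are i.i.d. noise;
    with ``noise_sd=0`` rows within a cluster are identical.
    """
    if signal < 0:
        raise ValueError("signal must be nonnegative")
    flat = [i for block in cluster_memberships for i in block]
    if sorted(flat) != list(range(n_snps)):
        raise ValueError("cluster_memberships must partition SNP indices")
    rng = np.random.default_rng(seed)
    k = len(cluster_memberships)
    templates = np.zeros((k, n_rois))
    blocks = _even_partition(n_rois, k)
    for c, cols in enumerate(blocks):
        templates[c, cols] = 1.0
    values = np.empty((n_snps, n_rois))
    for c, members in enumerate(cluster_memberships):
        values[members, :] = signal * templates[c]
    values = np.abs(values + rng.normal(0.0, noise_sd, size=(n_snps, n_rois)))
    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    roi_ids = [f"ROI_{j + 1}" for j in range(n_rois)]
    return pd.DataFrame(values, index=snp_ids, columns=roi_ids)
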