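"""SNP-QT association mapping via covariate-adjusted linear regression.

For every (SNP, ROI) pair within a case-control cohort, the ROI quantitative
trait is regressed on [intercept, dosage, age, sex, education] by ordinary
least squares::

    y = alpha * g + Gamma * Z + eps

and the two-sided t-test p-value on the additive SNP effect ``alpha`` is
recorded as ``-log10(p)``.  The resulting SNP x ROI significance map is then
row-normalized to unit Euclidean norm so that each SNP is represented as a
directional unit vector over the brain.

``fit_snp_qt`` fits a single pair through statsmodels OLS; the map-wide
``build_association_map`` solves the normal equations once per SNP for all
ROI responses simultaneously, which is algebraically identical and orders of
magnitude faster for dense SNP x ROI grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import COVARIATE_COLUMNS, CohortSpec, GenotypeMatrix, PhenotypeTable

__all__ = [
    "RegressionResult",
    "AssociationMap",
    "fit_snp_qt",
    "build_association_map",
    "normalize_rows",
]

logger = logging.getLogger(__name__)

#: -log10(p) is capped here to guard against floating-point underflow of
#: extreme p-values.
LOG10P_CAP = 300.0


class DegenerateFitError(ValueError):
    """Raised when too few usable subjects remain to fit the regression."""


@dataclass(frozen=True)
class RegressionResult:
    """One SNP-QT ordinary-least-squares fit."""

    alpha: float
    alpha_se: float
    p_value: float
    n_used: int
    degenerate: bool = False  # zero-variance dosage within the cohort


@dataclass
class AssociationMap:
    """SNP x ROI matrix of -log10(p) association strengths.

    ``normalized`` marks whether rows have been scaled to unit L2 norm;
    ``zero_rows`` lists SNPs whose row was all zero and therefore could not
    be normalized.
    """

    snp_ids: list[str]
    roi_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    zero_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.snp_ids), len(self.roi_ids)):
            raise ValueError("association map shape does not match id lists")
        if (self.values < 0).any():
            raise ValueError("association map entries must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.snp_ids, columns=self.roi_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = False) -> "AssociationMap":
        return cls(
            snp_ids=[str(i) for i in frame.index],
            roi_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            normalized=normalized,
        )


def _cohort_subjects(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeTable, cohort: CohortSpec
) -> list[str]:
    """Subjects present in both tables whose diagnosis is in the cohort."""
    geno_ids = set(genotypes.subject_ids)
    labels = cohort.labels
    return [
        s
        for s in phenotypes.subject_ids
        if s in geno_ids and phenotypes.diagnosis.loc[s] in labels
    ]


def _design(covariates: pd.DataFrame, dosage: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(dosage)), dosage, covariates.to_numpy(dtype=float)]
    )


def fit_snp_qt(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    snp_id: str,
    roi_id: str,
    cohort: CohortSpec,
) -> RegressionResult:
    """OLS of one ROI trait on one SNP dosage plus covariates within a cohort.

    Subjects with a missing dosage for this SNP are dropped pairwise.  A
    zero-variance dosage yields a flagged result with ``p_value = 1``.
    """
    subjects = _cohort_subjects(genotypes, phenotypes, cohort)
    geno = genotypes.to_frame()
    dosage = geno.loc[subjects, snp_id].to_numpy(dtype=float)
    keep = np.isfinite(dosage)
    used = [s for s, k in zip(subjects, keep) if k]
    dosage = dosage[keep]

    n_params = 2 + len(COVARIATE_COLUMNS)  # intercept + dosage + covariates
    if len(used) < n_params + 1:
        raise DegenerateFitError(
            f"SNP {snp_id!r} x ROI {roi_id!r} in cohort {cohort.name!r}: "
            f"{len(used)} usable subjects < {n_params + 1} required"
        )
    if np.ptp(dosage) == 0:
        return RegressionResult(0.0, np.nan, 1.0, len(used), degenerate=True)

    y = phenotypes.qt_frame().loc[used, roi_id].to_numpy(dtype=float)
    X = _design(phenotypes.covariates.loc[used], dosage)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        alpha=float(fit.params[1]),
        alpha_se=float(fit.bse[1]),
        p_value=float(np.clip(fit.pvalues[1], np.nextafter(0, 1), 1.0)),
        n_used=len(used),
    )


def build_association_map(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    cohort: CohortSpec,
    snp_set: list[str] | None = None,
    roi_set: list[str] | None = None,
) -> AssociationMap:
    """Build the unnormalized -log10(p) map over every (SNP, ROI) pair.

    Per SNP, one least-squares solve covers all ROI responses at once (the
    design matrix is shared).  Degenerate pairs are recorded as p = 1 with a
    warning, never a crash.
    """
    snp_set = list(snp_set) if snp_set is not None else list(genotypes.snp_ids)
    roi_set = list(roi_set) if roi_set is not None else list(phenotypes.roi_ids)
    subjects = _cohort_subjects(genotypes, phenotypes, cohort)

    geno = genotypes.to_frame().loc[subjects, snp_set]
    qt = phenotypes.qt_frame().loc[subjects, roi_set].to_numpy(dtype=float)
    cov = phenotypes.covariates.loc[subjects, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)

    n_params = 2 + cov.shape[1]
    values = np.zeros((len(snp_set), len(roi_set)))
    n_degenerate = 0
    for i, snp in enumerate(snp_set):
        dosage = geno[snp].to_numpy(dtype=float)
        keep = np.isfinite(dosage)
        n = int(keep.sum())
        if n < n_params + 1 or np.ptp(dosage[keep]) == 0:
            n_degenerate += len(roi_set)
            continue  # row stays 0 == -log10(1)
        X = np.column_stack([np.ones(n), dosage[keep], cov[keep]])
        Y = qt[keep]
        # pinv keeps rank-deficient designs (e.g. a constant covariate within
        # a cohort) consistent with the statsmodels path in fit_snp_qt
        XtX_pinv = np.linalg.pinv(X.T @ X)
        beta = XtX_pinv @ (X.T @ Y)
        resid = Y - X @ beta
        dof = n - np.linalg.matrix_rank(X)
        sigma2 = (resid**2).sum(axis=0) / dof
        var_alpha = XtX_pinv[1, 1] * sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[1] / np.sqrt(var_alpha)
        pvals = 2 * stats.t.sf(np.abs(tstat), dof)
        pvals = np.clip(pvals, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            row = -np.log10(pvals)
        values[i] = np.minimum(np.nan_to_num(row, nan=0.0, posinf=LOG10P_CAP), LOG10P_CAP)
    if n_degenerate:
        logger.warning(
            "cohort %s: %d SNP-ROI pairs degenerate (recorded as p=1)",
            cohort.name,
            n_degenerate,
        )
    return AssociationMap(snp_set, roi_set, values, normalized=False)


def normalize_rows(assoc: AssociationMap) -> AssociationMap:
    """Scale each SNP row to unit Euclidean norm; all-zero rows are flagged."""
    norms = np.linalg.norm(assoc.values, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    values = assoc.values / safe[:, np.newaxis]
    zero_rows = tuple(s for s, z in zip(assoc.snp_ids, zero) if z)
    if zero_rows:
        logger.warning("all-zero association rows left unnormalized: %s", zero_rows)
    return replace(assoc, values=values, normalized=True, zero_rows=zero_rows)
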