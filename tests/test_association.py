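import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpnets import (
    AssociationMap,
    CohortSpec,
    GenotypeMatrix,
    PhenotypeTable,
    build_association_map,
    fit_snp_qt,
    normalize_rows,
)
from snpnets.association import DegenerateFitError

COHORT = CohortSpec("all", {"AD"}, {"HC"})


def make_tables(dosages, qt, age=None, sex=None, edu=None, diagnosis=None):
    n = dosages.shape[0]
    subject_ids = [f"s{i}" for i in range(n)]
    geno = GenotypeMatrix(subject_ids, [f"rs{j}" for j in range(dosages.shape[1])], dosages)
    cov = pd.DataFrame(
        {
            "age": age if age is not None else np.full(n, 70.0),
            "sex": sex if sex is not None else np.zeros(n),
            "education": edu if edu is not None else np.full(n, 14.0),
        },
        index=subject_ids,
    )
    qt = np.asarray(qt, dtype=float)
    if qt.ndim == 1:
        qt = qt[:, np.newaxis]
    pheno = PhenotypeTable(
        subject_ids=subject_ids,
        diagnosis=pd.Series(
            diagnosis if diagnosis is not None else ["AD"] * (n // 2) + ["HC"] * (n - n // 2),
            index=subject_ids,
        ),
        covariates=cov,
        roi_ids=[f"ROI_{k}" for k in range(qt.shape[1])],
        qt_values=qt,
    )
    return geno, pheno


def ols_oracle(y, X):
    """Closed-form OLS on the dosage coefficient: normal equations + t CDF."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return beta[1], se, p


class TestFitSnpQt:
    def test_noiseless_fixture_recovers_effect_exactly(self, rng):
        g = rng.integers(0, 3, size=40).astype(float)
        geno, pheno = make_tables(g[:, None], 2.0 * g + 5.0)
        res = fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)
        assert res.alpha == pytest.approx(2.0, abs=1e-8)
        assert res.p_value < 1e-12

    def test_subject_order_irrelevant(self, rng):
        g = rng.integers(0, 3, size=30).astype(float)
        y = 0.5 * g + rng.normal(size=30)
        geno, pheno = make_tables(g[:, None], y)
        res1 = fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)
        # permute phenotype rows; alignment must be by id, not order
        perm = rng.permutation(30)
        pheno2 = PhenotypeTable(
            subject_ids=[pheno.subject_ids[i] for i in perm],
            diagnosis=pheno.diagnosis.iloc[perm],
            covariates=pheno.covariates.iloc[perm],
            roi_ids=pheno.roi_ids,
            qt_values=pheno.qt_values[perm],
        )
        res2 = fit_snp_qt(geno, pheno2, "rs0", "ROI_0", COHORT)
        assert res1.alpha == pytest.approx(res2.alpha, abs=1e-12)
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_matches_closed_form_oracle_on_random_fixtures(self):
        """alpha and p agree with the normal-equations + t-CDF oracle to 1e-8."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = 200
            g = rng.integers(0, 3, size=n).astype(float)
            age = rng.normal(75, 6, n)
            sex = rng.integers(0, 2, n).astype(float)
            edu = rng.normal(16, 2, n)
            y = rng.normal(0, 1, n) + 0.3 * g + 0.05 * age - 0.1 * sex
            geno, pheno = make_tables(g[:, None], y, age, sex, edu)
            res = fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)
            X = np.column_stack([np.ones(n), g, age, sex, edu])
            alpha, se, p = ols_oracle(y, X)
            assert res.alpha == pytest.approx(alpha, abs=1e-8)
            assert res.alpha_se == pytest.approx(se, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_zero_variance_dosage_flagged(self):
        geno, pheno = make_tables(np.ones((20, 1)), np.arange(20.0))
        res = fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)
        assert res.degenerate and res.p_value == 1.0

    def test_too_few_subjects_raises(self):
        geno, pheno = make_tables(np.array([[0.0], [1.0], [2.0]]), np.arange(3.0))
        with pytest.raises(DegenerateFitError):
            fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)

    def test_missing_dosage_dropped_pairwise(self, rng):
        g = rng.integers(0, 3, size=30).astype(float)
        y = g + rng.normal(size=30)
        g_missing = g.copy()
        g_missing[:5] = np.nan
        geno, pheno = make_tables(g_missing[:, None], y)
        res = fit_snp_qt(geno, pheno, "rs0", "ROI_0", COHORT)
        assert res.n_used == 25
        # equals a fit on the complete subset
        geno2, pheno2 = make_tables(g[5:, None], y[5:])
        res2 = fit_snp_qt(geno2, pheno2, "rs0", "ROI_0", COHORT)
        assert res.alpha == pytest.approx(res2.alpha, abs=1e-10)


class TestBuildAssociationMap:
    def test_map_entries_match_single_pair_fits(self, rng):
        n = 60
        dosages = rng.integers(0, 3, size=(n, 2)).astype(float)
        qt = rng.normal(size=(n, 3)) + dosages[:, [0]] * 0.5
        geno, pheno = make_tables(dosages, qt)
        assoc = build_association_map(geno, pheno, COHORT)
        assert assoc.values.shape == (2, 3)
        assert (assoc.values >= 0).all()
        for i, snp in enumerate(geno.snp_ids):
            for j, roi in enumerate(pheno.roi_ids):
                res = fit_snp_qt(geno, pheno, snp, roi, COHORT)
                assert assoc.values[i, j] == pytest.approx(-np.log10(res.p_value), abs=1e-8)

    def test_null_pvalues_uniform(self):
        """With QT independent of SNP, p-values are Uniform(0,1) (KS, alpha=0.01)."""
        rng = np.random.default_rng(77)
        n = 400
        dosages = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        qt = rng.normal(size=(n, 300))
        geno, pheno = make_tables(dosages, qt)
        assoc = build_association_map(geno, pheno, COHORT)
        pvals = 10.0 ** (-assoc.values[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_snp_row_is_zero(self):
        dosages = np.column_stack([np.ones(20), np.arange(20) % 3]).astype(float)
        geno, pheno = make_tables(dosages, np.arange(20.0))
        assoc = build_association_map(geno, pheno, COHORT)
        np.testing.assert_array_equal(assoc.values[0], 0.0)  # -log10(1) = 0


class TestNormalizeRows:
    def test_three_four_five_triangle(self):
        assoc = AssociationMap(["a"], ["r1", "r2"], np.array([[3.0, 4.0]]))
        norm = normalize_rows(assoc)
        np.testing.assert_allclose(norm.values, [[0.6, 0.8]])
        assert norm.normalized

    def test_zero_row_unchanged_and_flagged(self):
        assoc = AssociationMap(["a", "b"], ["r1", "r2"], np.array([[0.0, 0.0], [1.0, 1.0]]))
        norm = normalize_rows(assoc)
        np.testing.assert_array_equal(norm.values[0], [0.0, 0.0])
        assert norm.zero_rows == ("a",)

    def test_rows_have_unit_norm(self, rng):
        values = np.abs(rng.normal(size=(10, 7)))
        assoc = AssociationMap([f"s{i}" for i in range(10)], [f"r{j}" for j in range(7)], values)
        norm = normalize_rows(assoc)
        np.testing.assert_allclose(np.linalg.norm(norm.values, axis=1), 1.0, atol=1e-12)
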