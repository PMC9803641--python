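"""Contrast regressions, paired tests, biomarker screens, demographics."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from conftest import toy_matrix, toy_samples
from scipy import stats

from dcmmet.association import (
    biomarker_correlation,
    classify_tier,
    cohort_summary,
    fisher_exact_rxc,
    fit_contrast,
    paired_change,
)
from dcmmet.multiplicity import from_meff
from dcmmet.types import DCM_BY_DIET_CONTRAST, DIET_CONTRAST, DISEASE_CONTRAST

BANDS = from_meff(511, alpha=0.05)


class TestFitContrast:
    def test_covariate_free_toy_closed_form(self):
        # groups (0,0,1,1), y (0,1,1,2): beta 1, se 1/sqrt(2), t sqrt(2) on 2 df
        m = toy_matrix([[0.0], [1.0], [1.0], [2.0]])
        s = toy_samples(4, disease=["control", "control", "DCM", "DCM"])
        out = fit_contrast(m, s, DISEASE_CONTRAST, covariates=())
        assert out.beta[0] == pytest.approx(1.0)
        assert out.se[0] == pytest.approx(0.70710678, abs=1e-6)
        assert out.p[0] == pytest.approx(0.29289322, abs=1e-6)
        assert out.direction[0] == 1

    def test_identical_groups_give_null_result(self):
        m = toy_matrix([[1.0], [2.0], [1.0], [2.0]])
        s = toy_samples(4, disease=["DCM", "DCM", "control", "control"])
        out = fit_contrast(m, s, DISEASE_CONTRAST, covariates=())
        assert out.beta[0] == pytest.approx(0.0)
        assert out.p[0] == pytest.approx(1.0)

    def test_zero_variance_metabolite_flagged(self):
        m = toy_matrix([[3.0], [3.0], [3.0], [3.0]])
        s = toy_samples(4, disease=["DCM", "DCM", "control", "control"])
        out = fit_contrast(m, s, DISEASE_CONTRAST, covariates=())
        assert out.p[0] == 1.0
        assert out.note[0] == "zero-variance"

    def test_small_group_rejected(self):
        m = toy_matrix(np.random.default_rng(0).standard_normal((4, 2)))
        s = toy_samples(4, disease=["DCM", "control", "control", "control"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_contrast(m, s, DISEASE_CONTRAST, covariates=())

    def test_agrees_with_statsmodels(self, small_log):
        import statsmodels.api as sm

        samples, mlog, _ = small_log
        out = fit_contrast(mlog, samples, DISEASE_CONTRAST, covariates=("age", "sex"))
        sub = samples.set_index("sample_id")
        X = pd.DataFrame(
            {
                "const": 1.0,
                "group": (sub.disease == "DCM").astype(float),
                "age": sub.age,
                "sex": (sub.sex == "female").astype(float),
            }
        )
        for met in mlog.metabolites[:5]:
            fit = sm.OLS(mlog.values.loc[sub.index, met], X).fit()
            row = out.set_index("metabolite_id").loc[met]
            assert row.beta == pytest.approx(fit.params["group"], abs=1e-10)
            assert row.se == pytest.approx(fit.bse["group"], abs=1e-10)
            assert row.p == pytest.approx(fit.pvalues["group"], abs=1e-10)

    def test_agrees_with_normal_equations_oracle(self):
        """Brute-force (X'X)^-1 X'y per metabolite on random small designs."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            n, m = 20, 7
            y = rng.standard_normal((n, m))
            disease = np.array(["DCM"] * 10 + ["control"] * 10)
            s = toy_samples(n, disease=list(disease))
            s["age"] = rng.uniform(1, 13, n)
            mat = toy_matrix(y)
            out = fit_contrast(mat, s, DISEASE_CONTRAST, covariates=("age", "sex"))
            X = np.column_stack(
                [
                    np.ones(n),
                    (disease == "DCM").astype(float),
                    s.age.to_numpy(),
                    (s.sex == "female").to_numpy(dtype=float),
                ]
            )
            for j in range(m):
                beta_hat = np.linalg.solve(X.T @ X, X.T @ y[:, j])
                resid = y[:, j] - X @ beta_hat
                s2 = resid @ resid / (n - X.shape[1])
                se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
                assert abs(out.beta[j] - beta_hat[1]) < 1e-10
                assert abs(out.se[j] - se) < 1e-10

    def test_part2_sign_convention(self, small_log):
        """In the within-DCM contrast a negative beta means higher in DCM-NT."""
        samples, mlog, _ = small_log
        out = fit_contrast(mlog, samples, DCM_BY_DIET_CONTRAST, covariates=())
        sub = samples[(samples.disease == "DCM")].set_index("sample_id")
        met = mlog.metabolites[0]
        nt_mean = mlog.values.loc[sub.index[sub.diet == "NT"], met].mean()
        t_mean = mlog.values.loc[sub.index[sub.diet == "T"], met].mean()
        beta = out.set_index("metabolite_id").beta[met]
        assert np.sign(beta) == np.sign(t_mean - nt_mean)


class TestClassifyTier:
    @pytest.mark.parametrize(
        "p,expect", [(1.08e-10, "fdr"), (0.003, "nominal"), (0.5, "ns"), (9.784735812133073e-05, "nominal")]
    )
    def test_band_assignment(self, p, expect):
        assert classify_tier(p, BANDS) == expect


class TestPairedChange:
    def make_pair(self, diffs):
        n = len(diffs)
        base = toy_matrix(np.zeros((n, 1)), samples=[f"dog{i:03d}" for i in range(n)])
        fu = toy_matrix(np.asarray(diffs, dtype=float)[:, None], samples=[f"dog{i:03d}_m9" for i in range(n)])
        pairs = {f"dog{i:03d}": f"dog{i:03d}_m9" for i in range(n)}
        return base, fu, pairs

    def test_zero_mean_differences(self):
        base, fu, pairs = self.make_pair([1, -1, 0, 2, -2, 0])
        out = paired_change(base, fu, pairs)
        assert out.t[0] == pytest.approx(0.0)
        assert out.p[0] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        base, fu, pairs = self.make_pair([1, 2, 3, 4])
        out = paired_change(base, fu, pairs)
        assert out.t[0] == pytest.approx(3.872983, abs=1e-5)
        assert out.df[0] == 3
        assert out.p[0] == pytest.approx(0.030466, abs=1e-5)
        # scipy cross-check
        sp = stats.ttest_1samp([1, 2, 3, 4], 0.0)
        assert out.p[0] == pytest.approx(sp.pvalue, abs=1e-12)

    def test_constant_nonzero_differences_degenerate(self):
        base, fu, pairs = self.make_pair([2, 2, 2, 2])
        out = paired_change(base, fu, pairs)
        assert np.isnan(out.p[0])
        assert "degenerate" in out.note[0]

    def test_fewer_than_three_pairs_rejected(self):
        base, fu, pairs = self.make_pair([1, 2])
        with pytest.raises(ValueError, match="3"):
            paired_change(base, fu, pairs)


class TestBiomarkerCorrelation:
    def test_perfect_and_inverse_correlation(self):
        y = np.linspace(0.5, 2.0, 10)
        m = toy_matrix(np.column_stack([y, -y]))
        s = toy_samples(10, ctni=y)
        out = biomarker_correlation(m, s)
        assert out.r[0] == pytest.approx(1.0)
        assert out.r[1] == pytest.approx(-1.0)
        assert out.p[0] < 1e-20

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30) + 1.5
        m = toy_matrix(X)
        s = toy_samples(30, ctni=y)
        out = biomarker_correlation(m, s)
        for j in range(4):
            r, p = stats.pearsonr(X[:, j], y)
            assert out.r[j] == pytest.approx(r, abs=1e-12)
            assert out.p[j] == pytest.approx(p, abs=1e-12)

    def test_t_transform_consistency(self):
        # r = 0.71 at n = 75 corresponds to t ~ 8.6 on 73 df and a p on
        # the order of 1e-12 (a printed r rounded to 2 decimals only pins
        # the p down to about an order of magnitude)
        r, n = 0.71, 75
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert t == pytest.approx(8.614, abs=2e-3)
        assert 1e-13 < p < 1e-11

    def test_constant_biomarker_rejected(self):
        m = toy_matrix(np.random.default_rng(1).standard_normal((5, 2)))
        s = toy_samples(5, ctni=np.ones(5))
        with pytest.raises(ValueError, match="constant"):
            biomarker_correlation(m, s)


class TestFisherExact:
    def test_two_by_two_enumeration(self):
        assert fisher_exact_rxc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = fisher_exact_rxc(table)
            theirs = stats.fisher_exact(table)[1]
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_matches_r_on_2x4_table(self):
        table = [[5, 1, 3, 7], [2, 6, 4, 1]]
        ours = fisher_exact_rxc(table)
        script = (
            "cat(fisher.test(matrix(c(5,2,1,6,3,4,7,1), nrow=2))$p.value)"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        assert ours == pytest.approx(float(res.stdout.strip()), abs=1e-8)


class TestCohortSummary:
    def test_kruskal_wallis_reference_values(self):
        h, p = stats.kruskal([1, 2], [3, 4])
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(0.1213, abs=1e-4)

    def test_summary_table_structure(self, small_cohort):
        samples, _, _ = small_cohort
        out = cohort_summary(samples)
        assert set(out.variable) == {"age", "body_weight", "ctni", "sex"}
        assert ((out.p >= 0) & (out.p <= 1)).all()
        assert (out.loc[out.variable == "sex", "test"] == "fisher-exact").all()

    def test_single_level_variable_omitted(self):
        s = toy_samples(12)
        s["sex"] = "male"
        with pytest.warns(UserWarning, match="single level"):
            out = cohort_summary(s)
        assert "sex" not in set(out.variable)

    def test_identical_groups_h_zero(self):
        h, p = stats.kruskal([1.0, 2.0], [1.0, 2.0])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
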