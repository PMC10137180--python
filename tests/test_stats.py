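import numpy as np
import pandas as pd
import pytest

from neurograph import (
    behavior_correlation,
    chi_square_2x2,
    correlation_p_from_r,
    demographics_report,
    normality_check,
    significant_nodes,
    t_from_summary,
    two_sample_t,
)
from neurograph.atlas import CohortTable, SubjectRecord, synthetic_atlas
from neurograph.stats import DegenerateDataError, GroupDiffTable


class TestTTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_summary_matches_raw(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(15), rng.standard_normal(9) - 0.3
        t_raw, p_raw = two_sample_t(x, y)
        t_sum, p_sum = t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_summary_equal_means_zero_t(self):
        t, _ = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert t == 0.0

    def test_larger_n_increases_t(self):
        t1, _ = t_from_summary(1.0, 1.0, 10, 0.5, 1.0, 10)
        t2, _ = t_from_summary(1.0, 1.0, 20, 0.5, 1.0, 20)
        assert abs(t2) > abs(t1)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestChiSquare:
    def test_proportional_table_zero(self):
        chi2, p = chi_square_2x2(2, 4, 1, 2)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_transpose_invariance(self):
        a = chi_square_2x2(8, 15, 4, 14)[0]
        b = chi_square_2x2(8, 4, 15, 14)[0]
        assert a == pytest.approx(b)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2(0, 0, 4, 14)


class TestNormalityCheck:
    def test_normal_data_mostly_passes(self):
        hits = sum(
            normality_check(np.random.default_rng(s).standard_normal(50))
            for s in range(100)
        )
        assert hits >= 90

    def test_exponential_data_mostly_fails(self):
        hits = sum(
            not normality_check(np.random.default_rng(s).exponential(1.0, 50))
            for s in range(100)
        )
        assert hits >= 90

    def test_constant_vector_is_false(self):
        assert normality_check(np.full(20, 3.0)) is False

    def test_tiny_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            normality_check([1.0, 2.0])


class TestCorrelationInference:
    def test_p_matches_permutation_test(self):
        rng = np.random.default_rng(5)
        n, B = 30, 10_000
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_exact = correlation_p_from_r(r_obs, n)
        perm_r = np.empty(B)
        for b in range(B):
            perm_r[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.abs(perm_r) >= abs(r_obs)).mean()
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / B) + 1e-3
        assert abs(p_perm - p_exact) < mc_err


def _cohort_with_scores(n_per_group=10, seed=0, upsit=None):
    rng = np.random.default_rng(seed)
    records = []
    for g, n in (("AD", n_per_group), ("NC", n_per_group)):
        for i in range(n):
            idx = len(records)
            scores = {"UPSIT": float(upsit[idx]) if upsit is not None else float(
                rng.uniform(5, 35))}
            records.append(
                SubjectRecord(f"{g}{i}", g, 65 + rng.standard_normal() * 5,
                              "M" if rng.random() < 0.5 else "F",
                              float(rng.uniform(8, 16)), scores)
            )
    return CohortTable(records)


class TestBehaviorCorrelation:
    def test_perfect_correlation(self):
        atlas = synthetic_atlas(4)
        n = 20
        rng = np.random.default_rng(7)
        vals = rng.uniform(10, 30, n)
        cohort = _cohort_with_scores(10, seed=7, upsit=vals)
        auc = {"clustering": np.column_stack([vals] * 4) * 0.01}
        rows = pd.DataFrame([{"metric": "clustering", "region": "SYN01.L"}])
        out = behavior_correlation(auc, cohort, atlas, "UPSIT", rows).frame
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "n_used"] == n

    def test_missing_scores_excluded_pairwise(self):
        atlas = synthetic_atlas(4)
        cohort = _cohort_with_scores(10, seed=8)
        del cohort.records[0].scores["UPSIT"]
        del cohort.records[5].scores["UPSIT"]
        rng = np.random.default_rng(8)
        auc = {"degree": rng.uniform(0, 5, (20, 4))}
        rows = pd.DataFrame([{"metric": "degree", "region": "SYN02.R"}])
        out = behavior_correlation(auc, cohort, atlas, "UPSIT", rows).frame
        assert out.loc[0, "n_used"] == 18


class TestSignificantNodes:
    def _table(self, pvals):
        frame = pd.DataFrame(
            {
                "metric": "degree",
                "region": [f"r{i}" for i in range(len(pvals))],
                "mean_AD": 1.0,
                "mean_NC": 0.0,
                "t": 1.0,
                "p": pvals,
                "direction": "AD>NC",
                "significant": [p < 0.05 for p in pvals],
            }
        )
        return GroupDiffTable(frame)

    def test_all_null_empty(self):
        assert significant_nodes(self._table([0.5] * 6)).empty

    def test_alpha_one_returns_all(self):
        assert len(significant_nodes(self._table([0.5, 0.9, 0.2]), alpha=1.0)) == 3

    def test_bh_never_superset_of_uncorrected(self):
        rng = np.random.default_rng(9)
        pvals = rng.uniform(0, 0.2, 20).tolist()
        tab = self._table(pvals)
        plain = set(significant_nodes(tab, 0.05)["region"])
        bh = set(significant_nodes(tab, 0.05, fdr=True)["region"])
        assert bh <= plain


class TestDemographics:
    def test_report_contains_expected_tests(self):
        cohort = _cohort_with_scores(12, seed=10)
        rep = demographics_report(cohort).frame
        assert set(rep["variable"]) >= {"age", "education", "sex (M/F)", "UPSIT"}
        assert (rep.loc[rep["variable"] == "sex (M/F)", "test"] == "chi2").all()
        assert (rep.loc[rep["variable"] == "age", "test"] == "t").all()
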