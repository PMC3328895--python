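import numpy as np
import pytest
from scipy import stats as spstats

from tearfilm.stats import (
    compare_classifiers,
    lilliefors_test,
    one_way_anova,
    tukey_hsd,
)
from tearfilm.tables import load_fixture_table


def lilliefors_oracle(x):
    """Direct sorted-loop sup distance against the fitted normal CDF."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    mu, sd = x.mean(), x.std(ddof=1)
    d = 0.0
    for i, v in enumerate(x):
        F = spstats.norm.cdf((v - mu) / sd)
        d = max(d, abs(F - (i + 1) / n), abs(F - i / n))
    return d


class TestLilliefors:
    def test_statistic_matches_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = lilliefors_test(x, n_mc=100, seed=0)
        assert res.statistic == pytest.approx(lilliefors_oracle(x), abs=1e-12)

    def test_statistic_matches_oracle_random(self, rng):
        x = rng.normal(size=25)
        res = lilliefors_test(x, n_mc=100, seed=0)
        assert res.statistic == pytest.approx(lilliefors_oracle(x), abs=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            lilliefors_test(rng.standard_normal(30), alpha=0.05, n_mc=10_000, seed=0).reject
            for _ in range(1000)
        )
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_strongly_non_normal_rejected(self, rng):
        x = rng.exponential(size=200) ** 2
        assert lilliefors_test(x, n_mc=2000, seed=0).reject

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            lilliefors_test([2.0, 2.0, 2.0, 2.0])

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            lilliefors_test([1.0, 2.0, 3.0])


class TestAnova:
    def test_reference_grayscale_cooccurrence_block(self):
        table = load_fixture_table("cooccurrence", "grayscale")
        res = one_way_anova(list(table.rows().values()))
        assert res.F == pytest.approx(18.29, rel=0.005)
        assert res.ss_between == pytest.approx(1165.72, rel=0.005)
        assert (res.df_between, res.df_within) == (4, 30)
        assert res.p_value < 0.05

    def test_identical_means_zero_between(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        assert res.ss_between == pytest.approx(0.0, abs=1e-12)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_ss_total_matches_brute_force(self, rng):
        groups = [rng.normal(loc=i, size=7) for i in range(4)]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        brute = ((allv - allv.mean()) ** 2).sum()
        assert res.ss_total == pytest.approx(brute, abs=1e-9)
        assert res.df_total == allv.size - 1

    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc=i * 0.5, size=9) for i in range(5)]
        res = one_way_anova(groups)
        F, p = spstats.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_shift_invariance(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        a = one_way_anova(groups)
        b = one_way_anova([g + 17.3 for g in groups])
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_scale_invariance_of_F(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        a = one_way_anova(groups)
        b = one_way_anova([g * 4.2 for g in groups])
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_two_groups_F_equals_t_squared(self, rng):
        g1 = rng.normal(size=10)
        g2 = rng.normal(loc=0.8, size=10)
        res = one_way_anova([g1, g2])
        t, _ = spstats.ttest_ind(g1, g2)
        assert res.F == pytest.approx(t ** 2, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="zero within"):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])


class TestTukey:
    def test_reference_cooccurrence_grayscale_verdict(self):
        table = load_fixture_table("cooccurrence", "grayscale")
        rows = table.rows()
        res = tukey_hsd(list(rows.values()), labels=list(rows))
        svm = res.labels.index("SVM")
        for j, lbl in enumerate(res.labels):
            if lbl != "SVM":
                assert res.significant[svm, j]
        assert res.best_set == ("SVM",)

    def test_matches_scipy_significance(self, rng):
        groups = [rng.normal(loc=i * 0.8, size=8) for i in range(4)]
        res = tukey_hsd(groups)
        sp = spstats.tukey_hsd(*groups)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert res.significant[i, j] == (sp.pvalue[i, j] < 0.05)

    def test_identical_groups_not_significant(self):
        res = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert not res.significant.any()

    def test_extreme_separation_significant(self, rng):
        g1 = rng.normal(0.0, 0.1, size=5)
        g2 = rng.normal(100.0, 0.1, size=5)
        res = tukey_hsd([g1, g2])
        assert res.significant[0, 1] and res.significant[1, 0]

    def test_never_significant_with_self(self, rng):
        res = tukey_hsd([rng.normal(size=5) for _ in range(3)])
        assert not np.diag(res.significant).any()
        np.testing.assert_array_equal(res.significant, res.significant.T)


class TestCompareClassifiers:
    def test_markov_lab_with_pinned_exclusion(self):
        table = load_fixture_table("markov", "lab")
        rep = compare_classifiers(table.rows(), excluded=["NB"])
        assert rep.anova.df_between == 3
        assert rep.anova.df_within == 36
        assert rep.anova.F == pytest.approx(47.11, rel=0.005)
        assert rep.best_set == ("SVM",)

    def test_butterworth_lab_accepts_null(self):
        table = load_fixture_table("butterworth", "lab")
        rep = compare_classifiers(table.rows(), excluded=[])
        assert rep.anova.p_value > 0.05
        assert not rep.anova_rejects
        assert rep.tukey is None
        assert rep.best_set == ()

    def test_identical_rows_no_tukey(self):
        rows = {f"c{i}": np.array([50.0, 60.0, 70.0, 55.0, 65.0]) for i in range(5)}
        rep = compare_classifiers(rows, excluded=[])
        assert rep.anova.F == pytest.approx(0.0, abs=1e-12)
        assert rep.tukey is None

    def test_automatic_exclusion_of_non_normal_row(self, rng):
        rows = {f"c{i}": rng.normal(50.0, 5.0, size=50) for i in range(3)}
        rows["weird"] = np.concatenate([rng.normal(10, 0.01, 25), rng.normal(90, 0.01, 25)])
        rep = compare_classifiers(rows, seed=3)
        assert "weird" in rep.excluded

    def test_too_few_rows_after_exclusion(self, rng):
        rows = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_classifiers(rows, excluded=["a"])

    def test_unknown_exclusion_rejected(self, rng):
        rows = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        with pytest.raises(ValueError, match="unknown"):
            compare_classifiers(rows, excluded=["zzz"])
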