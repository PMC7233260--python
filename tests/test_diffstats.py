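"""ANOVA, t-test, and Tukey HSD behavior, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from diurnalqpcr import SimulationDesign, generate_dataset, quantile_normalize
from diurnalqpcr.data_io import SampleAnnotation
from diurnalqpcr.diffstats import (
    DEGENERATE,
    NOT_TESTABLE,
    OK,
    PAIRS,
    _anova_f,
    _pooled_t,
    one_way_anova_time,
    pairwise_t_tests,
    tukey_hsd,
    two_factor_anova,
)
from diurnalqpcr.normalization import NormalizedMatrix


def _make_norm(values, anns):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(genes, [a.sample_id for a in anns], values)


def _anns(spec):
    """spec: iterable of (region, zt, count)."""
    anns, i = [], 0
    for region, zt, n in spec:
        for _ in range(n):
            i += 1
            anns.append(SampleAnnotation(f"s{i}", f"a{i}", region, zt))
    return anns


BALANCED_2x3 = _anns(
    [(r, z, 2) for r in ("DVC", "CeA") for z in ("ZT3", "ZT5", "ZT9")]
)


class TestTwoFactorAnova:
    def test_constructed_effects_highly_significant(self):
        """Region adds +1, time adds (0, 0, +1); tiny residual noise."""
        base = []
        for a in BALANCED_2x3:
            y = 10.0 + (1.0 if a.region == "DVC" else 0.0) + (1.0 if a.zt == "ZT9" else 0.0)
            base.append(y)
        rng = np.random.default_rng(0)
        y = np.array(base) + rng.normal(0, 1e-4, len(base))
        res = two_factor_anova(_make_norm(y, BALANCED_2x3), BALANCED_2x3)[0]
        assert res.status == OK
        assert res.p_region < 1e-6 and res.p_time < 1e-6

    def test_all_equal_is_not_testable(self):
        res = two_factor_anova(_make_norm(np.full(12, 5.0), BALANCED_2x3), BALANCED_2x3)[0]
        assert res.status == NOT_TESTABLE

    def test_matches_statsmodels_type2(self, rng):
        """Cross-check F and p against statsmodels anova_lm (Type II SS)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        anns = _anns(
            [("DVC", "ZT3", 3), ("DVC", "ZT5", 6), ("DVC", "ZT9", 5),
             ("CeA", "ZT3", 4), ("CeA", "ZT5", 5), ("CeA", "ZT9", 6)]
        )
        y = rng.normal(20, 1, len(anns))
        res = two_factor_anova(_make_norm(y, anns), anns)[0]
        df = pd.DataFrame(
            {"y": y, "region": [a.region for a in anns], "zt": [a.zt for a in anns]}
        )
        table = sm.stats.anova_lm(smf.ols("y ~ C(region) + C(zt)", df).fit(), typ=2)
        assert res.f_region == pytest.approx(table.loc["C(region)", "F"], rel=1e-8)
        assert res.p_region == pytest.approx(table.loc["C(region)", "PR(>F)"], rel=1e-8)
        assert res.f_time == pytest.approx(table.loc["C(zt)", "F"], rel=1e-8)
        assert res.p_time == pytest.approx(table.loc["C(zt)", "PR(>F)"], rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        """Pure-noise response rejects at ~5% for the time effect."""
        rng = np.random.default_rng(42)
        anns = _anns(
            [("DVC", "ZT3", 7), ("DVC", "ZT5", 18), ("DVC", "ZT9", 15),
             ("CeA", "ZT3", 7), ("CeA", "ZT5", 18), ("CeA", "ZT9", 15)]
        )
        n_genes = 1000
        values = rng.normal(0, 1, size=(n_genes, len(anns)))
        results = two_factor_anova(_make_norm(values, anns), anns)
        rate = np.mean([r.p_time <= 0.05 for r in results])
        assert 0.03 <= rate <= 0.07


DVC_GROUPS = _anns([("DVC", "ZT3", 3), ("DVC", "ZT5", 3), ("DVC", "ZT9", 3)])


class TestOneWayAnova:
    def test_identical_group_means_gives_f_zero(self):
        y = [1, 2, 1.5, 1, 2, 1.5, 1, 2, 1.5]
        out = one_way_anova_time(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        assert out.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_within_variance_unequal_means_degenerate(self):
        y = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        out = one_way_anova_time(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        assert out.iloc[0]["status"] == DEGENERATE
        assert out.iloc[0]["p"] == 0.0

    def test_all_equal_not_testable(self):
        out = one_way_anova_time(_make_norm(np.full(9, 3.0), DVC_GROUPS), DVC_GROUPS, "DVC")
        assert out.iloc[0]["status"] == NOT_TESTABLE

    def test_matches_scipy_f_oneway(self, rng):
        y = rng.normal(0, 1, 9)
        out = one_way_anova_time(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        ref = sps.f_oneway(y[:3], y[3:6], y[6:])
        assert out.iloc[0]["F"] == pytest.approx(ref.statistic, rel=1e-10)
        assert out.iloc[0]["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_equals_t_squared(self, rng):
        """With two groups the one-way F is the square of the pooled t."""
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 10))
            b = rng.normal(0.5, 1, rng.integers(2, 10))
            f, p_f, _, _, status = _anova_f([a, b])
            t, p_t, _ = _pooled_t(a, b)
            assert status == OK
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p_f == pytest.approx(p_t, rel=1e-10)


class TestPairwiseT:
    def test_identical_groups(self):
        t, p, status = _pooled_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == 1.0 and status == OK

    def test_zero_pooled_variance_distinct_means(self):
        t, p, status = _pooled_t(np.array([0.0, 0, 0]), np.array([1.0, 1, 1]))
        assert p == 0.0 and status == DEGENERATE

    def test_too_small_group_not_testable(self):
        _, p, status = _pooled_t(np.array([1.0]), np.array([1.0, 2]))
        assert status == NOT_TESTABLE and np.isnan(p)

    def test_matches_closed_form_oracle(self, rng):
        """p equals the explicit pooled-t CDF formula to 1e-10."""
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 5)
        _, p, _ = _pooled_t(a, b)
        sp2 = (4 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 8
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 8)
        assert p == pytest.approx(p_oracle, abs=1e-10)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_to_gene_constant(self, rng):
        y = rng.normal(0, 1, 9)
        a = pairwise_t_tests(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        b = pairwise_t_tests(_make_norm(y + 7.3, DVC_GROUPS), DVC_GROUPS, "DVC")
        for pa, pb in zip(PAIRS, PAIRS):
            col = f"p_{pa[0]}_{pa[1]}"
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col], abs=1e-10)


class TestTukey:
    def test_identical_groups_all_p_one(self):
        y = [1.0, 2, 3, 1, 2, 3, 1, 2, 3]
        out = tukey_hsd(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        for a, b in PAIRS:
            assert out.iloc[0][f"p_{a}_{b}"] == pytest.approx(1.0)

    def test_matches_scipy_tukey_hsd(self, rng):
        """Unbalanced groups: agree with scipy's Tukey-Kramer implementation."""
        anns = _anns([("DVC", "ZT3", 4), ("DVC", "ZT5", 7), ("DVC", "ZT9", 5)])
        y = rng.normal(0, 1, len(anns))
        out = tukey_hsd(_make_norm(y, anns), anns, "DVC")
        g = {"ZT3": y[:4], "ZT5": y[4:11], "ZT9": y[11:]}
        ref = sps.tukey_hsd(g["ZT3"], g["ZT5"], g["ZT9"])
        idx = {"ZT3": 0, "ZT5": 1, "ZT9": 2}
        for a, b in PAIRS:
            assert out.iloc[0][f"p_{a}_{b}"] == pytest.approx(
                ref.pvalue[idx[a], idx[b]], abs=1e-8
            )

    def test_monotone_in_mean_difference(self):
        """Larger |mean difference| gives smaller adjusted p, MSE held fixed."""
        spread = np.array([-1.0, 0.0, 1.0])  # identical within-group spread
        p_prev = 1.1
        for shift in (0.0, 0.5, 1.0, 2.0):
            y = np.concatenate([spread, spread, spread + shift])
            out = tukey_hsd(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
            p = out.iloc[0]["p_ZT5_ZT9"]
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_studentized_range_oracle(self):
        """Adjusted p equals the studentized-range tail at q = |diff| / se."""
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 9)
        out = tukey_hsd(_make_norm(y, DVC_GROUPS), DVC_GROUPS, "DVC")
        groups = [y[:3], y[3:6], y[6:]]
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / 6
        q = abs(groups[0].mean() - groups[1].mean()) / np.sqrt(mse / 2 * (1 / 3 + 1 / 3))
        p_oracle = sps.studentized_range.sf(q, 3, 6)
        assert out.iloc[0]["p_ZT3_ZT5"] == pytest.approx(p_oracle, abs=1e-6)


@pytest.fixture(scope="module")
def null_tables():
    rng = np.random.default_rng(77)
    anns = _anns([("DVC", "ZT3", 7), ("DVC", "ZT5", 18), ("DVC", "ZT9", 15)])
    values = rng.normal(0, 1, size=(1000, len(anns)))
    norm = _make_norm(values, anns)
    return (
        one_way_anova_time(norm, anns, "DVC"),
        pairwise_t_tests(norm, anns, "DVC"),
    )


class TestNullCalibration:
    """Empirical type-I error at alpha = 0.05 under the study's group sizes."""

    def test_oneway_rejection_rate(self, null_tables):
        oneway, _ = null_tables
        rate = (oneway["p"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    @pytest.mark.parametrize("pair", PAIRS)
    def test_ttest_rejection_rate(self, null_tables, pair):
        _, ttests = null_tables
        rate = (ttests[f"p_{pair[0]}_{pair[1]}"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07
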