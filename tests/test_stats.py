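"""Population summaries, Welch contrasts, Bonferroni, correlations,
clonal-variation trend and the repeated-measures approximation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from serialpulse.errors import ValidationError
from serialpulse.stats import (
    ancestor_vs_evolved,
    bonferroni,
    fit_repeated_model,
    summarize_populations,
    trait_correlation,
    variation_trend,
    welch_from_summary,
)


def traits_frame(groups):
    """groups: list of (meta dict, trait values) -> traits table."""
    rows = []
    for meta, values in groups:
        for v in values:
            rows.append(dict(meta, max_growth_rate=v))
    return pd.DataFrame(rows)


def pop_meta(week, rep, **kw):
    base = dict(species="N_capsulatum", pulse="large", diversity="mono",
                week=week, replicate=rep)
    base.update(kw)
    return base


class TestSummarize:
    def test_textbook_mean_and_sd(self):
        table = traits_frame([(pop_meta(1, 1), [1.0, 2.0, 3.0])])
        out = summarize_populations(table, traits=["max_growth_rate"])
        assert out.loc[0, "mean_max_growth_rate"] == pytest.approx(2.0)
        assert out.loc[0, "sd_max_growth_rate"] == pytest.approx(1.0)
        assert out.loc[0, "n_clones"] == 3

    def test_identical_clones_zero_sd(self):
        table = traits_frame([(pop_meta(1, 1), [0.4] * 5)])
        out = summarize_populations(table, traits=["max_growth_rate"])
        assert out.loc[0, "sd_max_growth_rate"] == pytest.approx(0.0)

    def test_order_invariance(self):
        a = traits_frame([(pop_meta(1, 1), [3.0, 1.0, 2.0])])
        b = traits_frame([(pop_meta(1, 1), [1.0, 2.0, 3.0])])
        pd.testing.assert_frame_equal(
            summarize_populations(a, traits=["max_growth_rate"]),
            summarize_populations(b, traits=["max_growth_rate"]),
        )

    def test_singleton_group_sd_is_nan(self):
        table = traits_frame([(pop_meta(1, 1), [0.4])])
        out = summarize_populations(table, traits=["max_growth_rate"])
        assert np.isnan(out.loc[0, "sd_max_growth_rate"])


class TestAncestorVsEvolved:
    def test_equal_groups_t_zero_p_one(self):
        res = ancestor_vs_evolved([1.0, 2.0, 3.0], evolved_values=[1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_swapping_groups_flips_sign_keeps_p(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0, 6.0]
        a = ancestor_vs_evolved(x, evolved_values=y)
        b = ancestor_vs_evolved(y, evolved_values=x)
        assert a.t == pytest.approx(-b.t, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_two_sample_matches_textbook_welch(self):
        # frozen from an independent Welch computation on {1,2,3,4} vs
        # {2,3,4,5,6}: t = -1.5666989, df = 6.9807692, p = 0.1612859
        res = ancestor_vs_evolved([1.0, 2.0, 3.0, 4.0],
                                  evolved_values=[2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-1.5666989036012806, abs=1e-10)
        assert res.df == pytest.approx(6.980769230769231, abs=1e-10)
        assert res.p == pytest.approx(0.16128585628930425, abs=1e-10)

    @given(
        x=st.lists(st.floats(-5, 5), min_size=3, max_size=12),
        y=st.lists(st.floats(-5, 5), min_size=3, max_size=12),
    )
    def test_two_sample_mode_agrees_with_scipy_welch(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            return
        res = ancestor_vs_evolved(x, evolved_values=y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-10)

    def test_summary_mode_satterthwaite_df(self):
        anc = np.array([0.40, 0.42, 0.44, 0.41, 0.43, 0.39, 0.45, 0.40, 0.42, 0.44])
        res = ancestor_vs_evolved(
            anc, evolved_mean=0.35, evolved_se=0.012, evolved_n_effective=12
        )
        se_a2 = anc.var(ddof=1) / anc.size
        pooled = se_a2 + 0.012**2
        df_ref = pooled**2 / (se_a2**2 / 9 + 0.012**4 / 11)
        assert res.df == pytest.approx(df_ref, rel=1e-12)
        assert res.t == pytest.approx((anc.mean() - 0.35) / np.sqrt(pooled), rel=1e-12)

    def test_zero_variance_conventions(self):
        same = ancestor_vs_evolved([1.0, 1.0, 1.0], evolved_values=[1.0, 1.0])
        assert np.isnan(same.t) and "degenerate" in same.note
        diff = ancestor_vs_evolved([1.0, 1.0, 1.0], evolved_values=[2.0, 2.0])
        assert np.isinf(diff.t) and diff.p == 0.0 and diff.significant

    def test_pooled_variance_mode_matches_student(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0, 6.0]
        res = ancestor_vs_evolved(x, evolved_values=y, pooled_variance=True)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == len(x) + len(y) - 2


class TestBonferroni:
    def test_four_test_family_printed_values(self):
        res = bonferroni(0.05, 4)
        assert res.alpha_adjusted == pytest.approx(0.0125)
        assert 100 * res.fwe_uncorrected == pytest.approx(18.55, abs=0.005)
        assert 100 * res.fwe_corrected == pytest.approx(4.91, abs=0.005)

    def test_single_test_identity(self):
        res = bonferroni(0.05, 1)
        assert res.alpha_adjusted == pytest.approx(0.05, rel=1e-12)
        assert res.fwe_uncorrected == pytest.approx(0.05, rel=1e-12)
        assert res.fwe_corrected == pytest.approx(0.05, rel=1e-12)

    def test_ten_test_family_matches_monte_carlo(self, rng):
        res = bonferroni(0.05, 10)
        p = rng.uniform(size=(200_000, 10))
        mc = (p < 0.05).any(axis=1).mean()
        assert res.fwe_uncorrected == pytest.approx(mc, abs=0.005)
        assert res.fwe_uncorrected == pytest.approx(0.401, abs=0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bonferroni(0.0, 4)
        with pytest.raises(ValidationError):
            bonferroni(0.05, 0)


class TestTraitCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = trait_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_matches_covariance_definition(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        res = trait_correlation(x, y)
        ref = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert res.r == pytest.approx(ref, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = trait_correlation(x, y)
        b = trait_correlation(3.0 * x - 1.0, 0.5 * y + 7.0)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_null_correlation_small(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(size=10_000)
            y = rng.normal(size=10_000)
            if abs(trait_correlation(x, y).r) < 0.05:
                hits += 1
        assert hits >= 99

    def test_zero_variance_flagged(self):
        res = trait_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined


def make_summaries(sd_by_week, n_pops=6):
    rows = []
    for week, sds in sd_by_week.items():
        for i, sd in enumerate(sds):
            rows.append(
                {"species": "N_capsulatum", "pulse": "large", "diversity": "mono",
                 "week": week, "replicate": i, "n_clones": 10,
                 "mean_max_growth_rate": 0.1, "sd_max_growth_rate": sd}
            )
    return pd.DataFrame(rows)


class TestVariationTrend:
    def test_identical_sds_give_t_zero(self):
        summaries = make_summaries({1: [0.03, 0.03, 0.03], 13: [0.03, 0.03, 0.03]})
        trend = variation_trend(summaries, "max_growth_rate")
        assert np.isnan(trend.comparison.t) or trend.comparison.t == pytest.approx(0.0)
        assert trend.mean_sd_early == trend.mean_sd_late

    def test_detects_doubled_sd(self):
        summaries = make_summaries(
            {1: [0.030, 0.033, 0.029, 0.035], 13: [0.061, 0.070, 0.058, 0.066]}
        )
        trend = variation_trend(summaries, "max_growth_rate")
        assert trend.comparison.p < 0.05
        assert trend.mean_sd_late > trend.mean_sd_early

    def test_missing_trait_column_errors_with_name(self):
        summaries = make_summaries({1: [0.03] * 3, 13: [0.03] * 3})
        with pytest.raises(ValidationError, match="yield_od"):
            variation_trend(summaries, "yield_od")

    def test_missing_week_errors(self):
        summaries = make_summaries({1: [0.03] * 3})
        with pytest.raises(ValidationError, match="13"):
            variation_trend(summaries, "max_growth_rate")


def synth_summaries(rng, diversity_shift=0.0):
    rows = []
    for pulse in ("large", "small"):
        for diversity in ("mono", "co"):
            for rep in (1, 2, 3):
                subject_effect = rng.normal(scale=0.5)
                for week in (1, 13):
                    resp = rng.normal() + subject_effect
                    if diversity == "co":
                        resp += diversity_shift
                    rows.append(
                        {"species": "N_capsulatum", "pulse": pulse,
                         "diversity": diversity, "week": week, "replicate": rep,
                         "n_clones": 10, "mean_max_growth_rate": resp}
                    )
    return pd.DataFrame(rows)


class TestRepeatedModel:
    def test_null_pvalues_roughly_uniform(self):
        # diversity-effect p-values under pure noise should be uniform
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(120):
            rep = fit_repeated_model(synth_summaries(rng), "max_growth_rate")
            row = rep.table[rep.table.term.str.contains("diversity")].iloc[0]
            pvals.append(row["p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_diversity_effect_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        n = 40
        for _ in range(n):
            rep = fit_repeated_model(
                synth_summaries(rng, diversity_shift=2.5), "max_growth_rate",
                formula="response ~ C(week) + C(pulse) + C(diversity)",
            )
            row = rep.table[rep.table.term.str.contains("diversity")].iloc[0]
            hits += row["p"] < 0.05
        assert hits / n >= 0.8

    def test_incomplete_microcosm_dropped_and_reported(self):
        rng = np.random.default_rng(9)
        data = synth_summaries(rng)
        data = data.drop(data[(data.replicate == 3) & (data.week == 13)
                              & (data.pulse == "large") & (data.diversity == "mono")].index)
        rep = fit_repeated_model(data, "max_growth_rate")
        assert rep.dropped_microcosms == ["N_capsulatum/large/mono/3"]
        assert rep.n_obs == len(data) - 1
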