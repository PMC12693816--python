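"""Allele-group association tests: t, ANOVA+LSD, effect size, screen rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triadscreen.snp_assoc import (
    effect_percent,
    oneway_anova_lsd,
    results_frame,
    snp_screen,
    two_group_t,
)
from triadscreen.synthetic_data import CohortConfig, generate_cohort


class TestTwoGroupT:
    def test_identical_groups_give_zero_t_unit_p(self):
        t, df, p = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_pooled_example(self):
        # means 2 vs 5, pooled sd 1: t = -3/sqrt(2/3) = -3.674, df 4
        t, df, p = two_group_t([1, 2, 3], [4, 5, 6], variant="pooled")
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_swapping_groups_flips_sign_only(self):
        t1, _, p1 = two_group_t([1, 2, 3], [4, 5, 6])
        t2, _, p2 = two_group_t([4, 5, 6], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_df_below_pooled_for_unequal_variances(self):
        a = [1.0, 1.1, 0.9, 1.0, 1.05]
        b = [0.0, 4.0, 8.0, -3.0, 11.0]
        _, df_w, _ = two_group_t(a, b, variant="welch")
        _, df_p, _ = two_group_t(a, b, variant="pooled")
        assert df_w < df_p

    def test_degenerate_equal_constant_groups(self):
        t, _, p = two_group_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_t([1.0], [2.0, 3.0])


class TestAnovaLsd:
    def test_identical_groups_give_zero_f(self):
        f, df1, df2, p, lsd = oneway_anova_lsd([[1, 2], [1, 2], [1, 2]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_f_equals_t_squared_on_two_groups(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, _, p_t = two_group_t(a, b)
        f, _, _, p_f, _ = oneway_anova_lsd([a, b])
        assert f == pytest.approx(t ** 2)
        assert p_f == pytest.approx(p_t)

    def test_lsd_flags_only_pairs_involving_outlier_group(self):
        f, df1, df2, p, lsd = oneway_anova_lsd([[1, 2], [1, 2], [5, 6]])
        flagged = {(i, j) for i, j, pij in lsd if pij <= 0.05}
        assert flagged == {(0, 2), (1, 2)}

    def test_anova_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=7), rng.normal(1, 1, 8), rng.normal(size=6)]
        f, _, _, p, _ = oneway_anova_lsd(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestEffectPercent:
    @pytest.mark.parametrize("hi,lo,expected", [(2.0, 1.0, 100.0), (1.3, 1.0, 30.0), (5.0, 5.0, 0.0)])
    def test_direct_arithmetic(self, hi, lo, expected):
        assert effect_percent(hi, lo) == pytest.approx(expected)

    def test_undefined_for_nonpositive_lower_mean(self):
        with pytest.raises(ValueError):
            effect_percent(1.0, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(0.01, 50.0))
    def test_scale_invariance(self, hi, lo, c):
        assert effect_percent(c * hi, c * lo) == pytest.approx(effect_percent(hi, lo), rel=1e-9)


class TestSnpScreen:
    def test_planted_snp_recovered_on_target_trait(self, cohort):
        expr, traits, geno, truth = cohort
        results, qualifying = snp_screen(geno, traits)
        causal = [r for r in results if r.snp_id == truth.causal_snp_ids[0]
                  and r.trait == "Rb1"]
        assert causal and causal[0].passes and causal[0].in_orf
        assert truth.regulator_ids[0] in qualifying
        # planted allele effect is reported near its 30% design value
        assert causal[0].effect_percent == pytest.approx(30.0, abs=15.0)

    def test_qualifying_requires_orf_by_default(self, cohort):
        expr, traits, geno, truth = cohort
        _, with_orf = snp_screen(geno, traits)
        _, without = snp_screen(geno, traits, require_orf=False)
        assert with_orf <= without

    def test_null_pvalues_approximately_uniform(self):
        # Kolmogorov-Smirnov sanity check on the no-signal generator
        cfg = CohortConfig(rho_target=0.0, snp_effect_pct=0.0, n_snps=150, seed=21)
        _, traits, geno, _ = generate_cohort(cfg)
        results, _ = snp_screen(geno, traits.iloc[:, :1])
        ps = np.array([r.p for r in results])
        assert len(ps) > 100
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_results_frame_is_tidy(self, cohort):
        _, traits, geno, _ = cohort
        results, _ = snp_screen(geno, traits.iloc[:, :2])
        df = results_frame(results)
        assert set(df.columns) >= {"snp_id", "transcript", "trait", "p", "passes"}
        assert len(df) == len(results)
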