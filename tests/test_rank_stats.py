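"""Spearman machinery: hand-checked values, enumeration oracle, screen rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triadscreen.rank_stats import (
    correlation_screen,
    spearman_p,
    spearman_rho,
    spearman_test,
)
from triadscreen.synthetic_data import engineered_screen_fixture


def brute_force_exact_p(x, y):
    """Independent oracle: enumerate every ordering of y, Pearson on ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.array(perm))[0, 1]
        total += 1
        hits += abs(r) >= abs(obs) - 1e-12
    return hits / total


class TestSpearmanRho:
    def test_monotone_relationship_gives_one(self):
        x = np.array([1.0, 2.5, 4.0, 9.0, 20.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_hand_formula_value(self):
        # d = (0, -1, 1, 0), sum d^2 = 2: rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pairwise_na_removal(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])

    def test_zero_rank_variance_flagged_nan(self):
        assert math.isnan(spearman_rho([5, 5, 5, 5], [1, 2, 3, 4]))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=12, unique=True),
           st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_monotone_transform(self, xs, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(xs))
        x = np.array(xs, dtype=float)
        assert spearman_rho(np.exp(x / 1e3), y) == pytest.approx(spearman_rho(x, y))


class TestSpearmanP:
    def test_zero_rho_exact_p_is_one(self):
        # |rho_perm| >= 0 for every permutation
        assert spearman_p(0.0, 5, method="exact") == pytest.approx(1.0)

    def test_t_approx_matches_reported_sig_level(self):
        # rho=0.543 at n=14: t = 2.240 on 12 df, two-tailed p = 4.49e-2
        p = spearman_p(0.543, 14, method="t_approx")
        assert p == pytest.approx(4.49e-2, rel=5e-3)

    def test_exact_matches_brute_force_enumeration_n5(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            rho, p, n = spearman_test(x, y, method="exact")
            assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_exact_handles_ties_in_rank_pattern(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0])
        rho, p, n = spearman_test(x, y, method="exact")
        assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_perfect_rho_under_t_falls_back_to_exact_limit(self):
        assert spearman_p(1.0, 6, method="t_approx") == pytest.approx(2 / 720)

    def test_auto_switches_method_at_n8(self):
        assert spearman_p(0.5, 8, method="auto") == spearman_p(0.5, 8, method="exact")
        assert spearman_p(0.5, 9, method="auto") == spearman_p(0.5, 9, method="t_approx")


class TestCorrelationScreen:
    def test_candidate_rule_any_trait_and_tier_from_best_p(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(20)]
        strong = np.arange(20.0)
        expr = pd.DataFrame(
            {s: [strong[i], rng.normal()] for i, s in enumerate(samples)},
            index=["hit", "noise"],
        )
        traits = pd.DataFrame(
            {"A": strong + rng.normal(0, 0.1, 20), "B": rng.normal(size=20)},
            index=samples,
        )
        res = correlation_screen(expr, traits)
        assert "hit" in res.candidates
        assert res.transcript_tiers["hit"] == "highly_significant"
        assert res.summary["total"] == res.summary["strict"] + res.summary["lenient_only"]

    def test_trait_table_sample_order_is_irrelevant(self):
        expr, traits = engineered_screen_fixture(n_strict=2, n_lenient=2, n_null=2)
        shuffled = traits.sample(frac=1.0, random_state=1)
        a = correlation_screen(expr, traits)
        b = correlation_screen(expr, shuffled)
        assert a.summary == b.summary

    def test_no_shared_samples_raises(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        traits = pd.DataFrame({"T": [1.0, 2.0, 3.0]}, index=["x", "y", "z"])
        with pytest.raises(ValueError):
            correlation_screen(expr, traits)

    def test_screen_invariant_to_monotone_expression_transform(self):
        expr, traits = engineered_screen_fixture(n_strict=3, n_lenient=3, n_null=4)
        a = correlation_screen(expr, traits)
        b = correlation_screen(np.log2(expr + 1.0), traits)
        assert a.candidates == b.candidates
        assert a.transcript_tiers == b.transcript_tiers
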