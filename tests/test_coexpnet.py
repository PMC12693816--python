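"""Co-expression networks and the random-gene-set compactness null."""

import numpy as np
import pandas as pd
import pytest

from triadscreen.coexpnet import (
    build_network,
    candidates_linked_to_pathway,
    compactness_test,
    permutation_null,
)
from triadscreen.rank_stats import spearman_test
from triadscreen.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def noise_pool():
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(size=(60, 42)),
        index=[f"G{i:02d}" for i in range(60)],
        columns=[f"S{i:02d}" for i in range(42)],
    )


class TestBuildNetwork:
    def test_three_perfectly_correlated_genes_form_triangle(self):
        base = np.arange(10.0)
        expr = pd.DataFrame(
            [base, 2 * base + 1, base ** 2], index=["a", "b", "c"]
        )
        net = build_network(expr, ["a", "b", "c"], p_threshold=1e-3)
        assert net.n_edges == 3
        assert net.n_nodes == 3
        assert net.edge_density == pytest.approx(1.0)

    def test_threshold_monotonicity_edges_nest(self, noise_pool):
        genes = list(noise_pool.index[:25])
        loose = build_network(noise_pool, genes, 1e-1)
        tight = build_network(noise_pool, genes, 1e-2)
        loose_edges = {frozenset(e[:2]) for e in loose.edges()}
        tight_edges = {frozenset(e[:2]) for e in tight.edges()}
        assert tight_edges <= loose_edges

    def test_agrees_with_pairwise_bruteforce_oracle(self, noise_pool):
        genes = list(noise_pool.index[:15])
        thr = 0.05
        net = build_network(noise_pool, genes, thr)
        got = {frozenset(e[:2]) for e in net.edges()}
        expected = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                rho, p, _ = spearman_test(noise_pool.loc[a], noise_pool.loc[b],
                                          method="t_approx")
                if p <= thr:
                    expected.add(frozenset((a, b)))
        assert got == expected

    def test_isolated_nodes_excluded_from_count(self, noise_pool):
        genes = list(noise_pool.index[:10])
        net = build_network(noise_pool, genes, 1e-6)
        assert net.n_edges == 0
        assert net.n_nodes == 0
        incl = build_network(noise_pool, genes, 1e-6, include_isolated=True)
        assert incl.n_nodes == 10

    def test_empty_gene_set_rejected(self, noise_pool):
        with pytest.raises(ValueError):
            build_network(noise_pool, [], 0.05)

    def test_candidates_linked_to_pathway_roles(self, cohort, default_config):
        expr, _, _, truth = cohort
        cfg = default_config
        reg = truth.regulator_ids[0]
        genes = [reg] + cfg.family_ids[60:70] + list(cfg.pathway_ids)
        roles = {g: "candidate" for g in [reg] + cfg.family_ids[60:70]}
        roles.update({g: "pathway" for g in cfg.pathway_ids})
        net = build_network(expr, genes, 1e-3, roles=roles)
        assert reg in candidates_linked_to_pathway(net)


class TestPermutationNull:
    def test_replicate_count_and_seed_reproducibility(self, noise_pool):
        a = permutation_null(noise_pool, n_genes=20, n_reps=20, p_threshold=1e-3, seed=7)
        b = permutation_null(noise_pool, n_genes=20, n_reps=20, p_threshold=1e-3, seed=7)
        assert len(a.records) == 20
        assert a.records == b.records
        c = permutation_null(noise_pool, n_genes=20, n_reps=20, p_threshold=1e-3, seed=8)
        assert a.records != c.records

    def test_pool_too_small_rejected(self, noise_pool):
        with pytest.raises(ValueError):
            permutation_null(noise_pool, n_genes=100, n_reps=5, p_threshold=0.05, seed=0)

    def test_noise_pool_edge_counts_match_binomial_expectation(self, noise_pool):
        # 20 genes -> 190 pairs at threshold 0.05: mean edges ~ 9.5
        null = permutation_null(noise_pool, n_genes=20, n_reps=60, p_threshold=0.05, seed=1)
        mean_edges = null.edge_counts.mean()
        assert 4.0 < mean_edges < 16.0

    def test_empirical_p_floor_when_observed_beats_all(self, noise_pool, cohort, default_config):
        expr, _, _, _ = cohort
        cfg = default_config
        genes = list(cfg.pathway_ids)  # tightly mutually correlated
        obs = build_network(expr, genes, 1e-3)
        null = permutation_null(noise_pool, n_genes=16, n_reps=20, p_threshold=1e-3, seed=3)
        res = compactness_test(obs, null)
        assert res.empirical_p_edges == pytest.approx(1 / 21)
        assert res.z_edges > 3


def test_signal_cohort_network_is_compact_vs_random_draws(default_config, cohort):
    expr, _, _, truth = cohort
    cfg = default_config
    genes = [truth.regulator_ids[0]] + list(cfg.pathway_ids)
    roles = {genes[0]: "candidate", **{g: "pathway" for g in cfg.pathway_ids}}
    obs = build_network(expr, genes, 1e-3, roles=roles)
    background = expr.loc[cfg.background_ids]
    null = permutation_null(background, n_genes=38, n_reps=20, p_threshold=1e-3, seed=2)
    res = compactness_test(obs, null)
    assert res.empirical_p_edges <= 0.05
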