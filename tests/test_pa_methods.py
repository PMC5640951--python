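import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from oracles import es_running_sum, hypergeom_upper_tail
from pathbench.genesets import GeneSet, GeneSetCollection
from pathbench.pa_methods import (
    MethodConfig,
    afc_score,
    compute_gene_stats,
    gsa_maxmean,
    gsea_enrichment_score,
    method_config,
    ora_pvalues,
    permutation_pvalues,
    rank_pathways,
    rank_top_k,
)


class TestGeneStats:
    def test_fold_change_is_mean_difference(self):
        D = make_dataset([[2, 2, 1, 1]], n_treatment=2)
        stats = compute_gene_stats(D)
        assert stats.fold_change[0] == pytest.approx(1.0)

    def test_identical_cohorts_give_null_statistics(self):
        D = make_dataset([[3, 4, 3, 4]], n_treatment=2)
        stats = compute_gene_stats(D)
        assert stats.t[0] == 0.0
        assert stats.p[0] == 1.0
        assert stats.fold_change[0] == 0.0

    def test_pooled_t_matches_hand_computation(self):
        # {3,5} vs {1,1}: means 4 and 1, pooled variance 1, se 1 => t = 3,
        # two-sided p with df=2 is 2 * (1 - (0.5 + 0.5*3/sqrt(11))) = 0.09547
        D = make_dataset([[3, 5, 1, 1]], n_treatment=2)
        stats = compute_gene_stats(D)
        assert stats.t[0] == pytest.approx(3.0)
        assert stats.p[0] == pytest.approx(2 * (0.5 - 0.5 * 3 / math.sqrt(11)),
                                           abs=1e-10)

    def test_zero_variance_convention(self):
        D = make_dataset([[2, 2, 1, 1], [1, 1, 1, 1]], n_treatment=2)
        stats = compute_gene_stats(D)
        assert stats.t[0] == np.inf and stats.p[0] == 0.0
        assert stats.t[1] == 0.0 and stats.p[1] == 1.0

    def test_label_swap_negates_statistics(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 9))
        D = make_dataset(values, n_treatment=4)
        swapped = make_dataset(
            np.hstack([values[:, 4:], values[:, :4]]), n_treatment=5
        )
        a, b = compute_gene_stats(D), compute_gene_stats(swapped)
        np.testing.assert_allclose(a.t, -b.t, rtol=1e-10)
        np.testing.assert_allclose(a.fold_change, -b.fold_change, rtol=1e-10)


class TestPathwayScores:
    def test_afc_is_mean_of_member_fold_changes(self):
        D = make_dataset([[2, 2, 1, 1], [0.5, 0.5, 1, 1]], n_treatment=2)
        stats = compute_gene_stats(D)
        assert afc_score(stats, ["g1", "g2"]) == pytest.approx(0.25)

    def test_afc_matches_bruteforce_mean(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(20, 8))
        D = make_dataset(values, n_treatment=4)
        stats = compute_gene_stats(D)
        genes = [f"g{i + 1}" for i in range(20)]
        expected = sum(
            values[i, :4].mean() - values[i, 4:].mean() for i in range(20)
        ) / 20
        assert afc_score(stats, genes) == pytest.approx(expected)

    def test_maxmean_direct_arithmetic(self):
        # member t-statistics {2, -1, -3}: s+ = 2/3, s- = 4/3 => score -4/3
        stats = _stats_with_t([2.0, -1.0, -3.0])
        assert gsa_maxmean(stats, ["g1", "g2", "g3"]) == pytest.approx(-4 / 3)

    def test_maxmean_all_positive_is_plain_mean(self):
        z = [0.5, 1.5, 2.5]
        stats = _stats_with_t(z)
        assert gsa_maxmean(stats, ["g1", "g2", "g3"]) == pytest.approx(np.mean(z))

    def test_maxmean_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=50)
        stats = _stats_with_t(z)
        s_pos = np.mean([max(v, 0) for v in z])
        s_neg = np.mean([max(-v, 0) for v in z])
        expected = s_pos if s_pos > s_neg else -s_neg
        genes = [f"g{i + 1}" for i in range(50)]
        assert gsa_maxmean(stats, genes) == pytest.approx(expected)


def _stats_with_t(t_values):
    from pathbench.pa_methods import GeneStats

    t = np.asarray(t_values, dtype=float)
    return GeneStats(
        gene_ids=tuple(f"g{i + 1}" for i in range(t.size)),
        t=t,
        p=np.full(t.size, 0.5),
        fold_change=t.copy(),
    )


class TestGseaEnrichmentScore:
    def test_all_hits_on_top_is_one(self):
        genes = ["a", "b", "c", "d"]
        es = gsea_enrichment_score(genes, [4, 3, 2, 1], {"a", "b"}, p=0)
        assert es == pytest.approx(1.0)

    def test_all_hits_at_bottom_is_minus_one(self):
        genes = ["a", "b", "c", "d"]
        es = gsea_enrichment_score(genes, [4, 3, 2, 1], {"c", "d"}, p=0)
        assert es == pytest.approx(-1.0)

    def test_weighted_matches_running_sum_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(10)]
        weights = rng.normal(size=10)
        members = {"g1", "g4", "g7"}
        expected, _ = es_running_sum(genes, weights, members, p=1.0)
        assert gsea_enrichment_score(genes, weights, members, p=1.0) == (
            pytest.approx(expected)
        )

    @pytest.mark.parametrize("n_genes", [4, 6, 8])
    @pytest.mark.parametrize("set_size", [1, 2, 3])
    def test_unweighted_equals_classical_ks_for_all_placements(
        self, n_genes, set_size
    ):
        genes = [f"g{i}" for i in range(n_genes)]
        weights = list(range(n_genes, 0, -1))
        for combo in itertools.combinations(genes, set_size):
            expected, _ = es_running_sum(genes, weights, set(combo), p=0)
            got = gsea_enrichment_score(genes, weights, set(combo), p=0)
            assert got == pytest.approx(expected), combo

    def test_set_covering_all_genes_rejected(self):
        with pytest.raises(ValueError, match="every measured gene"):
            gsea_enrichment_score(["a", "b"], [1, 2], {"a", "b"}, p=1)


def _constant_dataset(n_genes, n_per_cohort, up_genes):
    """Zero-variance rows: up_genes get +1 in treatment, others identical."""
    values = np.ones((n_genes, 2 * n_per_cohort))
    for i in up_genes:
        values[i, :n_per_cohort] += 1.0
    return make_dataset(values, n_treatment=n_per_cohort)


class TestOra:
    def test_upper_tail_matches_exhaustive_hypergeometric(self):
        # universe 100, 10 up-DE genes, pathway of 10 holding 5 of them
        D = _constant_dataset(100, 3, up_genes=list(range(5)) + list(range(50, 55)))
        coll = GeneSetCollection(
            sets=(
                GeneSet("PW", "", frozenset(f"g{i + 1}" for i in range(10))),
                GeneSet("REST", "", frozenset(f"g{i + 1}" for i in range(10, 100))),
            )
        )
        table = ora_pvalues(D, coll, method_config("ora"))
        expected = hypergeom_upper_tail(5, 100, 10, 10)
        got = table.set_index("pathway_id").at["PW", "p_up"]
        assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("universe,n_de,set_size,overlap", [
        (20, 5, 6, 2), (30, 10, 8, 5), (25, 4, 10, 0), (12, 6, 4, 4),
    ])
    def test_tail_enumeration_small_universes(
        self, universe, n_de, set_size, overlap
    ):
        from scipy.stats import hypergeom

        expected = hypergeom_upper_tail(overlap, universe, set_size, n_de)
        got = hypergeom.sf(overlap - 1, universe, set_size, n_de)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_pathway_without_de_genes_has_p_one(self):
        D = _constant_dataset(30, 3, up_genes=range(5))
        coll = GeneSetCollection(
            sets=(
                GeneSet("HOT", "", frozenset(f"g{i + 1}" for i in range(5))),
                GeneSet("COLD", "", frozenset(f"g{i + 1}" for i in range(20, 30))),
            )
        )
        table = ora_pvalues(D, coll, method_config("ora")).set_index("pathway_id")
        assert table.at["COLD", "p_up"] == pytest.approx(1.0)
        assert table.at["COLD", "p_down"] == pytest.approx(1.0)

    def test_all_genes_de_up_forces_p_one_everywhere(self):
        D = _constant_dataset(30, 3, up_genes=range(30))
        coll = GeneSetCollection(
            sets=(
                GeneSet("A", "", frozenset(f"g{i + 1}" for i in range(10))),
                GeneSet("B", "", frozenset(f"g{i + 1}" for i in range(10, 30))),
            )
        )
        table = ora_pvalues(D, coll, method_config("ora"))
        np.testing.assert_allclose(table["p_up"], 1.0)


class TestPermutationPvalues:
    @pytest.fixture
    def small(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 6))
        values[:10, :3] += 2.0  # strong up signal for the first set
        D = make_dataset(values, n_treatment=3)
        coll = GeneSetCollection(
            sets=tuple(
                GeneSet(f"P{s}", "", frozenset(f"g{10 * s + j + 1}" for j in range(10)))
                for s in range(4)
            )
        )
        return D, coll

    def test_three_vs_three_enumerates_ten_assignments(self, small):
        D, coll = small
        cfg = method_config("afcs", n_permutations=1000, seed=0)
        table = permutation_pvalues(D, coll, "afc", cfg)
        # exact p-values on a grid of tenths, never zero
        assert ((table["p_up"] * 10).round() == table["p_up"] * 10).all()
        assert (table["p_up"] >= 0.1 - 1e-12).all()
        assert (table["p_down"] >= 0.1 - 1e-12).all()

    def test_enumerated_pvalue_matches_direct_count(self, small):
        """Exact 3v3 p equals an independently coded count over the ten
        distinct label assignments (anchored on the first treatment sample)."""
        D, coll = small
        cfg = method_config("afcs", n_permutations=1000, seed=0)
        table = permutation_pvalues(D, coll, "afc", cfg).set_index("pathway_id")
        genes = sorted(coll["P0"].genes, key=lambda g: int(g[1:]))
        rows = {g: i for i, g in enumerate(D.gene_ids)}
        idx = [rows[g] for g in genes]
        scores = []
        for combo in itertools.combinations(range(6), 3):
            if 0 not in combo:
                continue
            treat = list(combo)
            ctrl = [j for j in range(6) if j not in combo]
            fc = D.values[idx][:, treat].mean(axis=1) - (
                D.values[idx][:, ctrl].mean(axis=1)
            )
            scores.append(fc.mean())
        observed = scores[0]  # identity assignment is (0, 1, 2)
        expected_p = sum(s >= observed for s in scores) / 10
        assert table.at["P0", "p_up"] == pytest.approx(expected_p)

    def test_addone_estimator_floor(self, small):
        """A score above every sampled null lands exactly at 1/(B+1)."""
        D, coll = small
        cfg = method_config("afc", n_permutations=99, seed=1)
        table = permutation_pvalues(D, coll, "afc", cfg).set_index("pathway_id")
        assert table.at["P0", "p_up"] == pytest.approx(1 / 100)

    @pytest.mark.parametrize("name,scorer", [
        ("afc", "afc"), ("afcs", "afc"), ("gsea", "gsea"),
        ("gseas", "gsea"), ("gsa", "gsa"),
    ])
    def test_pvalues_in_unit_interval(self, small, name, scorer):
        D, coll = small
        cfg = method_config(name, n_permutations=50, seed=2)
        table = permutation_pvalues(D, coll, scorer, cfg)
        assert (table["p_up"] > 0).all() and (table["p_up"] <= 1).all()
        assert (table["p_down"] > 0).all() and (table["p_down"] <= 1).all()

    def test_deterministic_under_seed(self, small):
        D, coll = small
        cfg = method_config("gsea", n_permutations=50, seed=9)
        a = permutation_pvalues(D, coll, "gsea", cfg)
        b = permutation_pvalues(D, coll, "gsea", cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_label_swap_exchanges_ranked_lists(self, small):
        D, coll = small
        swapped = make_dataset(
            np.hstack([D.values[:, 3:], D.values[:, :3]]), n_treatment=3
        )
        cfg = method_config("afc", n_permutations=200, seed=4)
        r1 = rank_pathways(D, coll, cfg, 2)
        r2 = rank_pathways(swapped, coll, cfg, 2)
        assert r1.up == r2.down
        assert r1.down == r2.up


class TestRankTopK:
    def _table(self, p_up, scores, p_down=None):
        n = len(p_up)
        return pd.DataFrame(
            {
                "pathway_id": [f"P{i}" for i in range(n)],
                "size": [10] * n,
                "score": scores,
                "p_up": p_up,
                "p_down": p_down if p_down is not None else [1.0] * n,
            }
        )

    def test_sorts_by_ascending_p(self):
        table = self._table([0.01, 0.5, 0.02], [1.0, 1.0, 1.0])
        ranking = rank_top_k(table, 2, signed=True)
        assert ranking.up == ("P0", "P2")

    def test_ties_broken_by_descending_abs_score(self):
        table = self._table([0.1, 0.1, 0.1], [1.0, 3.0, 2.0])
        ranking = rank_top_k(table, 3, signed=True)
        assert ranking.up == ("P1", "P2", "P0")

    def test_full_ties_fall_back_to_lexicographic_id(self):
        table = self._table([0.1] * 3, [2.0] * 3)
        ranking = rank_top_k(table, 3, signed=True)
        assert ranking.up == ("P0", "P1", "P2")

    def test_sign_eligibility(self):
        table = self._table([0.01, 0.02, 0.03], [1.0, -1.0, 1.0],
                            p_down=[0.5, 0.01, 0.5])
        ranking = rank_top_k(table, 3, signed=True)
        assert "P1" not in ranking.up
        assert ranking.down == ("P1",)

    def test_k_larger_than_table_returns_all(self, caplog):
        table = self._table([0.1, 0.2], [1.0, 2.0])
        with caplog.at_level("WARNING"):
            ranking = rank_top_k(table, 10, signed=True)
        assert len(ranking.up) == 2
        assert "exceeds" in caplog.text

    def test_unsigned_method_can_appear_in_both_lists(self):
        table = self._table([0.01], [0.0], p_down=[0.01])
        ranking = rank_top_k(table, 1, signed=False)
        assert ranking.up == ("P0",) and ranking.down == ("P0",)


class TestMethodConfig:
    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            MethodConfig(method="ora", permutation_mode="gene_label")
        with pytest.raises(ValueError):
            MethodConfig(method="gsa", permutation_mode="sample_label")

    def test_variant_factory(self):
        assert method_config("gseas").permutation_mode == "sample_label"
        assert method_config("afc").permutation_mode == "gene_label"
        assert method_config("gsa").permutation_mode == "restandardization"
        with pytest.raises(ValueError, match="unknown"):
            method_config("nope")
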