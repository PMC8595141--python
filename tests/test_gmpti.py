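"""Enrichment scores, the Total Correlation Score and its permutation null."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmpnet.expression import RankedList
from gmpnet.gmpti import (
    GeneModulePair,
    ModuleOverlapError,
    bh_adjust,
    enrichment_score,
    extract_gmp,
    permutation_p,
    rank_targets,
    read_paired_gmt,
    total_correlation_score,
    write_paired_gmt,
)
from helpers import bh_by_hand, es_brute_force


class TestEnrichmentScore:
    def test_top_module_classic_ks_is_one(self, ten_gene_list):
        assert enrichment_score(ten_gene_list, ten_gene_list.genes[:3], 0.0) == 1.0

    def test_bottom_module_classic_ks_is_minus_one(self, ten_gene_list):
        assert enrichment_score(ten_gene_list, ten_gene_list.genes[-3:], 0.0) == -1.0

    def test_bounded_by_one(self, random_ranked_list):
        rng = np.random.default_rng(3)
        ranked = random_ranked_list(100, 3)
        for _ in range(50):
            module = set(rng.choice(ranked.genes, size=rng.integers(1, 30), replace=False))
            assert abs(enrichment_score(ranked, module, 1.0)) <= 1.0 + 1e-12

    def test_no_overlap_errors(self, ten_gene_list):
        with pytest.raises(ModuleOverlapError):
            enrichment_score(ten_gene_list, {"absent1", "absent2"})

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0])
    def test_equals_brute_force_walk_exhaustively(self, weight_exp, random_ranked_list):
        """All modules of size <= 3 over an 8-gene list match a full running-sum walk."""
        ranked = random_ranked_list(8, 42)
        for size in (1, 2, 3):
            for module in combinations(ranked.genes, size):
                fast = enrichment_score(ranked, set(module), weight_exp)
                slow = es_brute_force(ranked, set(module), weight_exp)
                assert fast == pytest.approx(slow, abs=1e-12)

    def test_zero_scores_fall_back_to_equal_weights(self):
        ranked = RankedList(genes=("a", "b", "c", "d"), scores=(0.0, 0.0, 0.0, 0.0))
        assert enrichment_score(ranked, {"a"}, 1.0) == 1.0


class TestTotalCorrelationScore:
    def test_perfectly_separated_modules_reach_two(self, ten_gene_list):
        gmp = GeneModulePair(
            "t", frozenset(ten_gene_list.genes[:3]), frozenset(ten_gene_list.genes[-3:])
        )
        assert total_correlation_score(ten_gene_list, gmp, 0.0).tcs == 2.0

    def test_swap_negates(self, ten_gene_list):
        gmp = GeneModulePair(
            "t", frozenset(ten_gene_list.genes[:3]), frozenset(ten_gene_list.genes[-3:])
        )
        swapped = GeneModulePair("t", gmp.down_genes, gmp.up_genes)
        assert total_correlation_score(ten_gene_list, swapped, 0.0).tcs == pytest.approx(
            -total_correlation_score(ten_gene_list, gmp, 0.0).tcs
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry_and_bounds_random(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.standard_normal(60))[::-1]
        ranked = RankedList(
            genes=tuple(f"g{i:03d}" for i in range(60)),
            scores=tuple(float(s) for s in scores),
        )
        idx = rng.choice(60, size=12, replace=False)
        gmp = GeneModulePair(
            "t",
            frozenset(ranked.genes[i] for i in idx[:6]),
            frozenset(ranked.genes[i] for i in idx[6:]),
        )
        res = total_correlation_score(ranked, gmp)
        swapped = GeneModulePair("t", gmp.down_genes, gmp.up_genes)
        assert -2.0 <= res.tcs <= 2.0
        assert res.tcs == res.es_up - res.es_down
        assert total_correlation_score(ranked, swapped).tcs == pytest.approx(-res.tcs)

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModulePair("t", frozenset({"a", "b"}), frozenset({"b", "c"}))


class TestPermutationP:
    def test_planted_perfect_gmp_gets_p_zero(self, random_ranked_list):
        ranked = random_ranked_list(500, 1)
        gmp = GeneModulePair(
            "t", frozenset(ranked.genes[:10]), frozenset(ranked.genes[-10:])
        )
        p, null = permutation_p(ranked, gmp, n_perm=1000, seed=7, weight_exp=0.0)
        assert p == 0.0
        assert max(abs(x) for x in null.null_scores) < 2.0

    def test_p_equals_recount_of_stored_null(self, random_ranked_list):
        ranked = random_ranked_list(20, 5)
        rng = np.random.default_rng(5)
        idx = rng.choice(20, 8, replace=False)
        gmp = GeneModulePair(
            "t",
            frozenset(ranked.genes[i] for i in idx[:4]),
            frozenset(ranked.genes[i] for i in idx[4:]),
        )
        obs = total_correlation_score(ranked, gmp).tcs
        p, null = permutation_p(ranked, gmp, n_perm=20, seed=3)
        recount = sum(1 for x in null.null_scores if abs(x) >= abs(obs)) / 20
        assert p == recount

    def test_p_on_lattice(self, random_ranked_list):
        ranked = random_ranked_list(50, 6)
        gmp = GeneModulePair(
            "t", frozenset(ranked.genes[5:10]), frozenset(ranked.genes[20:25])
        )
        for n_perm in (7, 20):
            p, _ = permutation_p(ranked, gmp, n_perm=n_perm, seed=2)
            assert round(p * n_perm) == pytest.approx(p * n_perm)

    def test_module_sizes_exceeding_list_error(self, ten_gene_list):
        gmp = GeneModulePair(
            "t",
            frozenset(f"x{i}" for i in range(6)),
            frozenset(f"y{i}" for i in range(6)),
        )
        with pytest.raises(ValueError, match="exceed"):
            permutation_p(ten_gene_list, gmp, n_perm=5, seed=0)

    def test_seed_reproducibility(self, random_ranked_list):
        ranked = random_ranked_list(100, 8)
        gmp = GeneModulePair(
            "t", frozenset(ranked.genes[:5]), frozenset(ranked.genes[50:55])
        )
        r1 = permutation_p(ranked, gmp, n_perm=50, seed=9)
        r2 = permutation_p(ranked, gmp, n_perm=50, seed=9)
        assert r1 == r2


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_hand_implementation(self):
        rng = np.random.default_rng(12)
        p = [float(x) for x in rng.uniform(size=40)]
        assert bh_adjust(p) == pytest.approx(bh_by_hand(p))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRankTargets:
    def _catalog(self, ranked, n_random, seed, k=5, planted=True):
        rng = np.random.default_rng(seed)
        catalog = []
        if planted:
            catalog.append(
                GeneModulePair(
                    "PLANTED",
                    frozenset(ranked.genes[:k]),
                    frozenset(ranked.genes[-k:]),
                )
            )
        for i in range(n_random):
            idx = rng.choice(len(ranked), size=2 * k, replace=False)
            catalog.append(
                GeneModulePair(
                    f"R{i:03d}",
                    frozenset(ranked.genes[j] for j in idx[:k]),
                    frozenset(ranked.genes[j] for j in idx[k:]),
                )
            )
        return catalog

    def test_planted_target_ranks_first(self, random_ranked_list):
        ranked = random_ranked_list(300, 21)
        catalog = self._catalog(ranked, 49, 21)
        results, skipped = rank_targets(ranked, catalog, n_perm=20, seed=21)
        assert skipped == []
        assert results[0].target_id == "PLANTED"

    def test_empty_catalog(self, ten_gene_list):
        assert rank_targets(ten_gene_list, [], n_perm=5, seed=0) == ([], [])

    def test_deterministic_and_order_independent(self, random_ranked_list):
        ranked = random_ranked_list(100, 2)
        catalog = self._catalog(ranked, 10, 2)
        r1, _ = rank_targets(ranked, catalog, n_perm=20, seed=4)
        r2, _ = rank_targets(ranked, list(reversed(catalog)), n_perm=20, seed=4)
        assert r1 == r2

    def test_non_overlapping_target_skipped(self, ten_gene_list):
        good = GeneModulePair(
            "G", frozenset(ten_gene_list.genes[:2]), frozenset(ten_gene_list.genes[-2:])
        )
        bad = GeneModulePair("B", frozenset({"x1"}), frozenset({"x2"}))
        results, skipped = rank_targets(ten_gene_list, [good, bad], n_perm=5, seed=0)
        assert [r.target_id for r in results] == ["G"]
        assert skipped[0][0] == "B"


class TestExtractGMP:
    def test_top_bottom_selection(self, ten_gene_list):
        gmp = extract_gmp(ten_gene_list, "t", 2)
        assert gmp.up_genes == frozenset(ten_gene_list.genes[:2])
        assert gmp.down_genes == frozenset(ten_gene_list.genes[-2:])
        assert not gmp.up_genes & gmp.down_genes

    def test_k_zero_errors(self, ten_gene_list):
        with pytest.raises(ValueError):
            extract_gmp(ten_gene_list, "t", 0)

    def test_modules_too_large_error(self, ten_gene_list):
        with pytest.raises(ValueError, match="exceeds"):
            extract_gmp(ten_gene_list, "t", 6)


class TestPairedGMT:
    def test_roundtrip(self, tmp_path):
        catalog = [
            GeneModulePair("T1", frozenset({"A", "B"}), frozenset({"C"})),
            GeneModulePair("T2", frozenset({"D"}), frozenset({"E", "F"})),
        ]
        p = tmp_path / "catalog.gmt"
        write_paired_gmt(catalog, p)
        assert read_paired_gmt(p) == catalog

    def test_mismatched_pairing_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("T1_up\tT1\tA\nT2_down\tT2\tB\n")
        with pytest.raises(ValueError, match="mismatched"):
            read_paired_gmt(p)

    def test_odd_line_count_errors(self, tmp_path):
        p = tmp_path / "odd.gmt"
        p.write_text("T1_up\tT1\tA\n")
        with pytest.raises(ValueError, match="odd"):
            read_paired_gmt(p)
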