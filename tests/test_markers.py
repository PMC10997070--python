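import math

import numpy as np
import pytest

import dendropy

from plastmark.markers import (
    CombinationResult,
    ScreenConfig,
    clustering_info_similarity,
    enumerate_combinations,
    ranking_table,
    robinson_foulds,
    screen_combinations,
)
from plastmark.models import SubstitutionModel
from plastmark.simulate import simulate_region_alignment, simulate_tree
from plastmark.trees import Node, PhyloTree

from _oracles import cis_bruteforce, random_binary_tree


class TestEnumeration:
    def test_ten_candidates_give_1023_subsets(self):
        subsets = enumerate_combinations([f"r{i}" for i in range(10)])
        assert len(subsets) == 1023

    def test_single_candidate(self):
        assert enumerate_combinations(["x"]) == [("x",)]

    def test_three_candidates_give_seven_ordered_subsets(self):
        subsets = enumerate_combinations(["b", "a", "c"])
        assert subsets == [
            ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
            ("a", "b", "c"),
        ]

    def test_refuses_combinatorial_explosion(self):
        with pytest.raises(ValueError, match="pre-filter"):
            enumerate_combinations([f"r{i}" for i in range(21)])


class TestRobinsonFoulds:
    def test_identical_trees_have_zero_distance(self):
        rng = np.random.default_rng(0)
        tree = random_binary_tree([f"t{i}" for i in range(8)], rng)
        raw, norm = robinson_foulds(tree, tree.copy())
        assert (raw, norm) == (0, 0.0)

    def test_conflicting_quartets_are_maximally_distant(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = PhyloTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        raw, norm = robinson_foulds(t1, t2)
        assert raw == 2
        assert norm == 1.0

    def test_binary_versus_star_counts_all_internal_edges(self):
        n = 7
        rng = np.random.default_rng(1)
        binary = random_binary_tree([f"t{i}" for i in range(n)], rng)
        star = PhyloTree(
            Node(None, 0.0, [Node(f"t{i}", 1.0) for i in range(n)])
        )
        raw, _ = robinson_foulds(binary, star)
        assert raw == n - 3

    def test_leaf_set_mismatch_is_reported(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = PhyloTree.from_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(ValueError, match="[de]"):
            robinson_foulds(t1, t2)

    def test_matches_dendropy_on_random_pairs(self):
        # independent cross-check against an external implementation
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = [f"t{i}" for i in range(7)]
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            raw, _ = robinson_foulds(t1, t2)
            taxa = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.to_newick(), schema="newick", taxon_namespace=taxa
            )
            d2 = dendropy.Tree.get(
                data=t2.to_newick(), schema="newick", taxon_namespace=taxa
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(
                d1, d2
            )
            assert raw == expected

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            trees = [random_binary_tree(labels, rng) for _ in range(3)]
            d01 = robinson_foulds(trees[0], trees[1])[1]
            d12 = robinson_foulds(trees[1], trees[2])[1]
            d02 = robinson_foulds(trees[0], trees[2])[1]
            assert d01 >= 0
            assert d01 == robinson_foulds(trees[1], trees[0])[1]
            assert d02 <= d01 + d12 + 1e-12


class TestClusteringInformation:
    def test_identical_binary_trees_score_one(self):
        rng = np.random.default_rng(4)
        for n in (4, 6, 10, 20):
            tree = random_binary_tree([f"t{i}" for i in range(n)], rng)
            assert clustering_info_similarity(tree, tree.copy()) == pytest.approx(
                1.0
            )

    def test_star_tree_scores_zero_against_anything(self):
        rng = np.random.default_rng(5)
        binary = random_binary_tree([f"t{i}" for i in range(6)], rng)
        star = PhyloTree(
            Node(None, 0.0, [Node(f"t{i}", 1.0) for i in range(6)])
        )
        assert clustering_info_similarity(binary, star) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_matching_oracle_on_six_leaves(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        assert clustering_info_similarity(t1, t2) == pytest.approx(
            cis_bruteforce(t1, t2)
        )

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(10):
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            assert clustering_info_similarity(t1, t2) == pytest.approx(
                clustering_info_similarity(t2, t1)
            )


class TestScreen:
    def _dataset(self, seed=0, n_taxa=10):
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        tree = simulate_tree(n_taxa, seed=seed)
        tree = tree.scale(0.1 / tree.mean_pairwise_distance())
        rng = np.random.default_rng(seed + 40)
        alignments = {}
        for i, mult in enumerate([5.0, 5.0, 5.0, 0.5, 0.5, 0.5, 0.5, 0.5]):
            name = f"m{i}"
            alignments[name] = simulate_region_alignment(
                tree, 600, mult, model, rng=rng, region_name=name
            )
        return tree, alignments

    def test_full_subset_against_its_own_tree_ranks_first(self):
        from plastmark.phylo import (
            fast_jc_distance_matrix,
            neighbor_joining,
            pairwise_differences,
        )
        import pandas as pd
        from plastmark.records import concatenate_alignments

        tree, alignments = self._dataset()
        taxa = sorted(tree.tip_names())
        concat, _ = concatenate_alignments(
            [alignments[k].reorder(taxa) for k in sorted(alignments)]
        )
        diffs, shared = pairwise_differences(concat)
        reference = neighbor_joining(
            pd.DataFrame(
                fast_jc_distance_matrix(diffs, shared),
                index=taxa,
                columns=taxa,
            )
        )
        results = screen_combinations(
            alignments, sorted(alignments), reference, ScreenConfig()
        )
        full = next(r for r in results if len(r.subset) == len(alignments))
        assert full.score_cis == pytest.approx(1.0)
        assert full.score_rf_normalized == pytest.approx(1.0)
        assert results[0].score_cis == pytest.approx(1.0)

    def test_high_signal_regions_dominate_the_top_rank(self):
        from plastmark.simulate import (
            assemble_synthetic_plastomes,
            marker_screen_config,
        )

        hits = 0
        for seed in range(3):
            ds = assemble_synthetic_plastomes(marker_screen_config(seed=seed))
            alignments = {
                k: v
                for k, v in ds.region_alignments.items()
                if k.startswith("m")
            }
            results = screen_combinations(
                alignments,
                sorted(alignments),
                ds.truth.true_tree,
                ScreenConfig(),
            )
            planted = {"m01", "m02", "m03"}
            hits += int(len(planted & set(results[0].subset)) >= 2)
        assert hits >= 2

    def test_ranking_is_deterministic(self):
        tree, alignments = self._dataset(seed=1)
        r1 = screen_combinations(alignments, sorted(alignments), tree)
        r2 = screen_combinations(alignments, sorted(alignments), tree)
        t1 = ranking_table(r1)
        t2 = ranking_table(r2)
        assert t1.equals(t2)

    def test_missing_taxon_drops_region_with_warning(self, caplog):
        tree, alignments = self._dataset(seed=2)
        crippled = alignments["m7"]
        alignments["m7"] = type(crippled)(
            "m7", "gene", crippled.taxa[:-1], crippled.matrix[:-1]
        )
        with caplog.at_level("WARNING"):
            results = screen_combinations(
                alignments, sorted(alignments), tree
            )
        assert "m7" in caplog.text
        assert all("m7" not in r.subset for r in results)
        with pytest.raises(ValueError):
            screen_combinations(
                alignments, sorted(alignments), tree, ScreenConfig(strict=True)
            )

    def test_adding_signal_regions_never_hurts_on_clean_data(self):
        # monotone-signal sanity: supersets of the best subset never
        # rank in a strictly worse score class than the best subset
        tree, alignments = self._dataset(seed=3)
        results = screen_combinations(
            alignments, sorted(alignments), tree, ScreenConfig(metric="cis")
        )
        by_subset = {r.subset: r for r in results}
        best = results[0]
        planted = ("m0", "m1", "m2")
        base = by_subset[planted].score_cis
        for extra in ("m3", "m4", "m5"):
            superset = tuple(sorted(planted + (extra,)))
            assert by_subset[superset].score_cis >= base - 0.15


class TestTanglegramExport:
    def test_writes_two_newicks_and_leaf_map(self, tmp_path):
        from plastmark.markers import export_tanglegram

        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(6)]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        export_tanglegram(t1, t2, tmp_path / "tg")
        assert (tmp_path / "tg" / "reference.nwk").exists()
        assert (tmp_path / "tg" / "subset.nwk").exists()
        import pandas as pd

        leaf_map = pd.read_csv(tmp_path / "tg" / "leaf_map.tsv", sep="\t")
        assert list(leaf_map["leaf_left"]) == sorted(labels)
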