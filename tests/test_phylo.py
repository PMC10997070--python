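import math

import numpy as np
import pandas as pd
import pytest

from plastmark.models import SubstitutionModel, discrete_gamma_rates
from plastmark.phylo import (
    MLSearchConfig,
    SaturatedDistanceError,
    TreeLikelihood,
    bootstrap_support,
    log_likelihood,
    make_ultrametric,
    ml_distance,
    neighbor_joining,
    optimize_ml_tree,
    select_model_aic,
)
from plastmark.records import RegionAlignment
from plastmark.simulate import simulate_region_alignment, simulate_tree
from plastmark.trees import PhyloTree

from _oracles import exhaustive_log_likelihood, random_binary_tree


def tree_distance_frame(tree):
    dists = tree.pairwise_tip_distances()
    labels = sorted(tree.tip_names())
    mat = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = dists[(min(a, b), max(a, b))]
    return pd.DataFrame(mat, index=labels, columns=labels)


class TestMLDistance:
    def test_identical_rows_have_zero_distance(self):
        assert ml_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_jc_closed_form_at_p_ten_percent(self):
        a = "A" * 100
        b = "A" * 90 + "G" * 10
        # -(3/4) ln(1 - 4*0.1/3) = 0.107326 to 6 significant figures
        assert ml_distance(a, b, "JC") == pytest.approx(0.107326, abs=1e-6)

    def test_saturated_pair_raises_unless_capped(self):
        a = "A" * 100
        b = "C" * 75 + "A" * 25
        with pytest.raises(SaturatedDistanceError):
            ml_distance(a, b, "JC")
        assert ml_distance(a, b, "JC", cap_saturated=True) > 1.0

    def test_k2p_equals_jc_without_transition_bias(self):
        # equal transition/transversion composition
        a = "A" * 120
        b = "G" * 4 + "C" * 4 + "T" * 4 + "A" * 108
        jc = ml_distance(a, b, "JC")
        k2p = ml_distance(a, b, "K2P")
        assert k2p == pytest.approx(jc, rel=0.02)

    def test_gtr_numeric_distance_close_to_jc_under_jc_model(self):
        model = SubstitutionModel.jc(alpha=None, ncat=1).with_params(kind="GTR")
        a = "ACGT" * 50
        b = "ACGA" * 50
        jc = ml_distance(a, b, "JC")
        numeric = ml_distance(a, b, model)
        assert numeric == pytest.approx(jc, abs=1e-4)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_on_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        tree = random_binary_tree(labels, rng)
        nj = neighbor_joining(tree_distance_frame(tree))
        assert nj.splits() == tree.splits()
        got = nj.pairwise_tip_distances()
        want = tree.pairwise_tip_distances()
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-9)

    def test_three_taxa_three_point_formulas(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        tree = neighbor_joining(d)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_ultrametric_matrix_recovers_the_generating_topology(self):
        tree = simulate_tree(6, seed=9)
        nj = neighbor_joining(tree_distance_frame(tree))
        assert nj.splits() == tree.splits()

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)


class TestLikelihood:
    def test_two_sequence_single_site_closed_form(self):
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        tree = PhyloTree.from_newick("(x:0.07,y:0.13);")
        aln = RegionAlignment.from_sequences("r", "gene", [("x", "A"), ("y", "A")])
        expect = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * 0.2 / 3)))
        assert log_likelihood(tree, aln, model) == pytest.approx(expect)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(11)
        tree = random_binary_tree([f"t{i}" for i in range(6)], rng, scale=0.3)
        model = SubstitutionModel.gtr(
            [0.3, 0.2, 0.3, 0.2], [1, 2, 1, 1, 2, 1], alpha=0.7, ncat=4
        )
        aln = simulate_region_alignment(tree, 200, 1.0, model, seed=12)
        base = log_likelihood(tree, aln, model)
        for split in list(tree.splits()):
            rerooted = tree.reroot_at_split(split)
            assert log_likelihood(rerooted, aln, model) == pytest.approx(base)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_state_sum_on_five_taxa(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree([f"t{i}" for i in range(5)], rng, scale=0.5)
        model = SubstitutionModel.gtr(
            [0.28, 0.22, 0.26, 0.24],
            rng.uniform(0.5, 3.0, size=6),
            alpha=0.9,
            ncat=2,
        )
        aln = simulate_region_alignment(tree, 40, 1.0, model, seed=seed + 50)
        # punch in some missing data
        aln.matrix[0, 5] = "-"
        aln.matrix[2, 10] = "N"
        assert log_likelihood(tree, aln, model) == pytest.approx(
            exhaustive_log_likelihood(tree, aln, model)
        )

    def test_mismatched_taxon_sets_rejected(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = RegionAlignment.from_sequences(
            "r", "gene", [(t, "ACGT") for t in "abce"]
        )
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(tree, aln, SubstitutionModel.jc())


class TestMLSearch:
    def test_recovers_topology_on_clean_simulation(self):
        model = SubstitutionModel.hky([0.3, 0.2, 0.2, 0.3], kappa=2.0,
                                      alpha=None, ncat=1)
        recovered = 0
        for seed in (0, 1):
            tree = simulate_tree(6, seed=seed).scale(0.08)
            aln = simulate_region_alignment(tree, 2000, 1.0, model,
                                            seed=seed + 30)
            result = optimize_ml_tree(aln)
            if result.tree.splits() == tree.splits():
                recovered += 1
            else:
                # the search must at least beat the true topology's fit
                truth_lnl = TreeLikelihood(
                    tree.copy(), aln, result.model
                ).optimize_branch_lengths(max_passes=3)
                assert result.lnl >= truth_lnl - 1e-6
            assert all(
                b >= a - 1e-6
                for a, b in zip(result.lnl_history, result.lnl_history[1:])
            )
        assert recovered >= 1

    def test_identical_rows_collapse_to_frequency_likelihood(self):
        row = "ACGT" * 25
        aln = RegionAlignment.from_sequences(
            "r", "gene", [(f"t{i}", row) for i in range(4)]
        )
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        result = optimize_ml_tree(aln, MLSearchConfig(fit_model=False),
                                  model=model)
        assert result.lnl == pytest.approx(100 * math.log(0.25), abs=1e-3)

    def test_same_seed_same_result(self):
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        tree = simulate_tree(5, seed=3).scale(0.1)
        aln = simulate_region_alignment(tree, 500, 1.0, model, seed=4)
        r1 = optimize_ml_tree(aln, MLSearchConfig(seed=7), model=model)
        r2 = optimize_ml_tree(aln, MLSearchConfig(seed=7), model=model)
        assert r1.tree.to_newick() == r2.tree.to_newick()
        assert r1.lnl == r2.lnl


class TestBootstrap:
    def _alignment(self, scale=0.3, length=1000, seed=5):
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        tree = simulate_tree(6, seed=seed).scale(scale)
        aln = simulate_region_alignment(tree, length, 1.0, model,
                                        seed=seed + 10)
        return tree, aln

    def test_single_replicate_gives_zero_or_hundred(self):
        tree, aln = self._alignment()
        best = optimize_ml_tree(aln, MLSearchConfig(fast_mode=True)).tree
        supported = bootstrap_support(
            aln, best, MLSearchConfig(n_bootstrap=1, seed=1)
        )
        values = {
            n.support
            for n in supported.postorder()
            if n.support is not None
        }
        assert values <= {0.0, 100.0}

    def test_strong_signal_gives_high_support(self):
        tree, aln = self._alignment()
        supported = bootstrap_support(
            aln, tree, MLSearchConfig(n_bootstrap=100, seed=2)
        )
        true_splits = tree.splits()
        below = supported.below_sets()
        for node in supported.postorder():
            if node.support is not None:
                assert node.support >= 95.0

    def test_seeded_supports_are_reproducible(self):
        tree, aln = self._alignment()
        s1 = bootstrap_support(aln, tree, MLSearchConfig(n_bootstrap=20, seed=3))
        s2 = bootstrap_support(aln, tree, MLSearchConfig(n_bootstrap=20, seed=3))
        assert s1.to_newick(include_support=True) == s2.to_newick(
            include_support=True
        )

    def test_zero_replicates_leave_supports_absent(self):
        tree, aln = self._alignment()
        out = bootstrap_support(aln, tree, MLSearchConfig(n_bootstrap=0))
        assert all(n.support is None for n in out.postorder())


class TestModelSelection:
    def test_aic_table_is_internally_consistent_and_jc_competitive(self):
        model = SubstitutionModel.jc(alpha=None, ncat=1)
        tree = simulate_tree(5, seed=6).scale(0.1)
        aln = simulate_region_alignment(tree, 1500, 1.0, model, seed=7)
        best, table = select_model_aic(aln, tree)
        # AIC = 2k - 2 lnL row by row
        for _, row in table.iterrows():
            assert row.aic == pytest.approx(2 * row.k - 2 * row.lnl)
        # data simulated under JC: JC within 2 AIC units of the winner
        jc_aic = table.loc[table.model == "JC", "aic"].iloc[0]
        assert jc_aic - table.aic.min() < 2.0
        # nesting: richer models never fit worse
        lnl = table.set_index("model")["lnl"]
        assert lnl["GTR+G4"] >= lnl["JC"] - 1e-3

    def test_gamma_shape_recovery_within_thirty_percent(self):
        true_alpha = 0.5
        hits = 0
        for seed in range(3):
            model = SubstitutionModel.gtr(
                [0.3, 0.2, 0.2, 0.3],
                [1.0, 2.5, 0.8, 1.2, 2.5, 1.0],
                alpha=true_alpha,
                ncat=4,
            )
            tree = simulate_tree(8, seed=seed).scale(0.3)
            aln = simulate_region_alignment(tree, 3000, 1.0, model,
                                            seed=seed + 70)
            result = optimize_ml_tree(
                aln, MLSearchConfig(n_nni_rounds=0), model=model.with_params(alpha=1.0)
            )
            if abs(result.model.alpha - true_alpha) / true_alpha < 0.3:
                hits += 1
        assert hits >= 2


class TestUltrametricization:
    def test_already_ultrametric_tree_is_a_fixed_point(self):
        tree = simulate_tree(6, seed=8)
        out = make_ultrametric(tree)
        before = tree.tip_depths()
        after = out.tip_depths()
        for tip in before:
            assert after[tip] == pytest.approx(before[tip], abs=1e-6)

    def test_two_tip_mean_path_length(self):
        out = make_ultrametric(PhyloTree.from_newick("(a:1,b:3);"))
        assert out.tip_depths() == pytest.approx({"a": 2.0, "b": 2.0})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_tip_depths_equalized(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree([f"t{i}" for i in range(7)], rng)
        out = make_ultrametric(tree)
        depths = list(out.tip_depths().values())
        assert max(depths) - min(depths) < 1e-6
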