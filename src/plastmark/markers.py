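"""Exhaustive marker-combination screening against a reference tree.

Every non-empty subset of candidate regions is concatenated, a tree is
inferred (fast mode by default: neighbor joining on JC distances), and
the tree is scored against the whole-plastome reference under two
congruence metrics: classic Robinson-Foulds similarity and the
clustering-information similarity recommended by the generalized-RF
literature (mutual clustering information between splits under an
optimal split matching).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .phylo import (
    MLSearchConfig,
    fast_jc_distance_matrix,
    neighbor_joining,
    optimize_ml_tree,
    pairwise_differences,
)
from .records import RegionAlignment, concatenate_alignments
from .trees import PhyloTree

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 20


# --------------------------------------------------------------- enumeration


def enumerate_combinations(candidates: list[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    k = len(candidates)
    if k < 1:
        raise ValueError("need at least one candidate region")
    if k > MAX_CANDIDATES:
        raise ValueError(
            f"{k} candidates would give {2**k - 1} subsets; pre-filter "
            f"to at most {MAX_CANDIDATES} (e.g. via PI/pi ranking)"
        )
    out: list[tuple[str, ...]] = []
    for size in range(1, k + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            out.append(combo)
    return out


# -------------------------------------------------------------------- splits


def _check_leaf_sets(tree1: PhyloTree, tree2: PhyloTree) -> frozenset[str]:
    s1, s2 = set(tree1.tip_names()), set(tree2.tip_names())
    if s1 != s2:
        raise ValueError(f"leaf sets differ: {sorted(s1 ^ s2)}")
    return frozenset(s1)


def robinson_foulds(
    tree1: PhyloTree, tree2: PhyloTree
) -> tuple[int, float]:
    """Symmetric-difference RF distance, raw and normalized to [0, 1].

    normalized = raw / (|S1| + |S2|); two identical binary trees score
    (0, 0.0), maximally different ones (.., 1.0).
    """
    _check_leaf_sets(tree1, tree2)
    s1, s2 = tree1.splits(), tree2.splits()
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return raw, (raw / denom if denom else 0.0)


def _split_entropy(size_a: int, size_b: int) -> float:
    n = size_a + size_b
    h = 0.0
    for s in (size_a, size_b):
        if s:
            p = s / n
            h -= p * math.log(p)
    return h


def _mutual_information(
    split1: frozenset[str], split2: frozenset[str], all_tips: frozenset[str]
) -> float:
    n = len(all_tips)
    a, b = split1, all_tips - split1
    c, d = split2, all_tips - split2
    mi = 0.0
    for block1 in (a, b):
        for block2 in (c, d):
            nij = len(block1 & block2)
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((len(block1) / n) * (len(block2) / n)))
    return max(mi, 0.0)


def clustering_info_similarity(tree1: PhyloTree, tree2: PhyloTree) -> float:
    """Clustering-information similarity in [0, 1].

    Each split is a two-block clustering of the leaves with entropy
    H(S); shared information between the trees is the maximum-weight
    matching of pairwise mutual clustering information; similarity =
    2*shared / (H(T1) + H(T2)).  Trees without nontrivial splits score
    0 against anything (and 0 with each other, by convention).
    """
    all_tips = _check_leaf_sets(tree1, tree2)
    if len(all_tips) < 4:
        raise ValueError("clustering-information similarity needs >= 4 leaves")
    splits1 = sorted(tree1.splits(), key=sorted)
    splits2 = sorted(tree2.splits(), key=sorted)
    n = len(all_tips)
    h1 = sum(_split_entropy(len(s), n - len(s)) for s in splits1)
    h2 = sum(_split_entropy(len(s), n - len(s)) for s in splits2)
    if h1 + h2 == 0.0:
        return 0.0
    if not splits1 or not splits2:
        return 0.0
    weights = np.array(
        [
            [_mutual_information(s1, s2, all_tips) for s2 in splits2]
            for s1 in splits1
        ]
    )
    rows, cols = linear_sum_assignment(weights, maximize=True)
    shared = weights[rows, cols].sum()
    return float(2.0 * shared / (h1 + h2))


# ------------------------------------------------------------------- results


@dataclass
class CombinationResult:
    subset: tuple[str, ...]
    concat_length: int
    tree: PhyloTree
    score_rf_normalized: float  # similarity, 1 - normalized RF distance
    score_cis: float
    rank: int = 0

    def score(self, metric: str) -> float:
        return self.score_cis if metric == "cis" else self.score_rf_normalized


@dataclass
class ScreenConfig:
    metric: str = "cis"  # cis | rf
    fast_mode: bool = True
    seed: int = 0
    full_search_top: int = 0  # re-infer the top-k subsets with full NNI ML
    strict: bool = False


def _fast_tree(
    alignments: list[RegionAlignment],
    diff_cache: dict[str, tuple[np.ndarray, np.ndarray]],
    taxa: list[str],
) -> PhyloTree:
    diffs = sum(diff_cache[a.region_name][0] for a in alignments)
    shared = sum(diff_cache[a.region_name][1] for a in alignments)
    dmat = fast_jc_distance_matrix(diffs, np.clip(shared, 1.0, None))
    return neighbor_joining(pd.DataFrame(dmat, index=taxa, columns=taxa))


def screen_combinations(
    region_alignments: dict[str, RegionAlignment],
    candidates: list[str],
    reference_tree: PhyloTree,
    config: ScreenConfig | None = None,
) -> list[CombinationResult]:
    """Score every candidate subset against the reference tree.

    Fast mode infers each subset's tree by neighbor joining on JC
    distances computed from the concatenation (sufficient for ranking);
    ``full_search_top`` optionally re-infers the best subsets with the
    full NNI maximum-likelihood search.  Ties rank by fewer regions,
    then shorter concatenation, then subset name.
    """
    config = config or ScreenConfig()
    ref_taxa = set(reference_tree.tip_names())
    usable: dict[str, RegionAlignment] = {}
    for name in candidates:
        aln = region_alignments.get(name)
        if aln is None or set(aln.taxa) != ref_taxa:
            msg = f"candidate region {name!r} missing taxa or absent"
            if config.strict:
                raise ValueError(msg)
            logger.warning("%s; dropped from the screen", msg)
            continue
        usable[name] = aln
    subsets = enumerate_combinations(list(usable))
    taxa = sorted(ref_taxa)
    diff_cache = {
        name: pairwise_differences(aln.reorder(taxa))
        for name, aln in usable.items()
    }
    results: list[CombinationResult] = []
    for subset in subsets:
        alns = [usable[name] for name in subset]
        length = sum(a.n_columns for a in alns)
        if config.fast_mode:
            tree = _fast_tree(alns, diff_cache, taxa)
        else:
            concat, _ = concatenate_alignments(
                [a.reorder(taxa) for a in alns], name="+".join(subset)
            )
            tree = optimize_ml_tree(
                concat, MLSearchConfig(seed=config.seed)
            ).tree
        _, rf_norm = robinson_foulds(tree, reference_tree)
        cis = clustering_info_similarity(tree, reference_tree)
        results.append(
            CombinationResult(
                subset=subset,
                concat_length=length,
                tree=tree,
                score_rf_normalized=1.0 - rf_norm,
                score_cis=cis,
            )
        )

    results.sort(
        key=lambda r: (
            -r.score(config.metric),
            len(r.subset),
            r.concat_length,
            r.subset,
        )
    )
    if config.full_search_top > 0:
        for res in results[: config.full_search_top]:
            concat, _ = concatenate_alignments(
                [usable[name].reorder(taxa) for name in res.subset],
                name="+".join(res.subset),
            )
            ml = optimize_ml_tree(concat, MLSearchConfig(seed=config.seed))
            res.tree = ml.tree
            _, rf_norm = robinson_foulds(ml.tree, reference_tree)
            res.score_rf_normalized = 1.0 - rf_norm
            res.score_cis = clustering_info_similarity(ml.tree, reference_tree)
        results.sort(
            key=lambda r: (
                -r.score(config.metric),
                len(r.subset),
                r.concat_length,
                r.subset,
            )
        )
    for i, res in enumerate(results, start=1):
        res.rank = i
    return results


def export_tanglegram(
    tree1: PhyloTree,
    tree2: PhyloTree,
    out_dir,
    names: tuple[str, str] = ("reference", "subset"),
) -> None:
    """Write the side-by-side comparison inputs: two newicks plus a
    shared-leaf map TSV (for tanglegram rendering by external tools)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shared = sorted(set(tree1.tip_names()) & set(tree2.tip_names()))
    (out / f"{names[0]}.nwk").write_text(tree1.to_newick() + "\n")
    (out / f"{names[1]}.nwk").write_text(tree2.to_newick() + "\n")
    pd.DataFrame({"leaf_left": shared, "leaf_right": shared}).to_csv(
        out / "leaf_map.tsv", sep="\t", index=False
    )


def ranking_table(results: list[CombinationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "subset": "+".join(r.subset),
                "n_regions": len(r.subset),
                "length": r.concat_length,
                "score_cis": r.score_cis,
                "score_rf": r.score_rf_normalized,
            }
            for r in results
        ]
    )
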