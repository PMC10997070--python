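"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (regex scans, full-diagonal
enumeration, exhaustive state sums, exhaustive matchings) and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np


# ------------------------------------------------------- nucleotide diversity


def pi_bruteforce(rows: list[str]) -> float:
    """Complete-deletion pi over all pairs, by direct looping."""
    n = len(rows)
    length = len(rows[0])
    keep = [
        i
        for i in range(length)
        if all(row[i] in "ACGT" for row in rows)
    ]
    if not keep:
        raise ValueError("no columns retained")
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sum(1 for c in keep if rows[i][c] != rows[j][c])
            total += diffs / len(keep)
            pairs += 1
    return total / pairs


# ---------------------------------------------------------------------- SSRs


def _primitive(motif: str) -> bool:
    u = len(motif)
    return not any(
        u % p == 0 and motif == motif[:p] * (u // p) for p in range(1, u)
    )


def ssr_regex_oracle(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """Maximal perfect tandem repeats via overlapping regex scan.

    Returns {(motif, unit, count, start, end)}.
    """
    out: set[tuple] = set()
    n = len(seq)
    for u, min_reps in thresholds.items():
        pattern = re.compile(r"(?=((.{%d})\2+))" % u, re.DOTALL)
        for m in pattern.finditer(seq):
            a = m.start()
            motif = m.group(2)
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality of the periodic tract
            if a >= 1 and a - 1 + u < n and seq[a - 1] == seq[a - 1 + u]:
                continue
            count = len(m.group(1)) // u
            if count < min_reps:
                continue
            out.add((motif, u, count, a, a + u * count))
    return out


# ---------------------------------------------------------- dispersed repeats

_RC = str.maketrans("ACGT", "TGCA")
_C = str.maketrans("ACGT", "TGCA")


def repeats_bruteforce(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    kinds: tuple[str, ...] = ("forward", "palindromic"),
) -> set[tuple]:
    """All maximal repeat pairs by full O(n^2) diagonal enumeration.

    Returns {(kind, pos1, pos2, length, mismatches)}.
    """
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    transforms = {
        "forward": s,
        "palindromic": s.translate(_RC)[::-1],
        "reverse": s[::-1],
        "complement": s.translate(_C),
    }
    out: set[tuple] = set()
    for kind in kinds:
        t = transforms[kind]
        tarr = np.frombuffer(t.encode(), dtype="S1")
        d_values = (
            range(1, n) if kind == "forward" else range(-(n - 1), n)
        )
        for d in d_values:
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            segment_mm = arr[lo:hi] != tarr[lo + d : hi + d]
            mism = (np.flatnonzero(segment_mm) + lo).tolist()
            sentinels = [lo - 1] + mism + [hi]
            if len(mism) <= max_mismatch:
                windows = [(lo, hi, len(mism))]
            else:
                windows = []
                for i in range(len(mism) - max_mismatch + 1):
                    w_lo = sentinels[i] + 1
                    w_hi = sentinels[i + max_mismatch + 1]
                    windows.append((w_lo, w_hi, max_mismatch))
            for w_lo, w_hi, mm in windows:
                length = w_hi - w_lo
                if length < min_len:
                    continue
                g1 = w_lo
                if kind in ("palindromic", "reverse"):
                    g2 = n - (w_lo + d) - length
                else:
                    g2 = w_lo + d
                p1, p2 = sorted((g1, g2))
                if p2 < p1 + length:
                    continue
                out.add((kind, p1, p2, length, mm))
    return out


# ----------------------------------------------------------------- likelihood


def exhaustive_log_likelihood(tree, alignment, model) -> float:
    """Sum over every internal-state assignment, site by site."""
    from plastmark._seq import encode_states

    tip_states = {
        name: encode_states(alignment.row(name)) for name in alignment.taxa
    }
    nodes = tree.postorder()
    internals = [node for node in nodes if not node.is_leaf]
    cat_rates = model.category_rates()
    n_sites = alignment.n_columns
    lnl = 0.0
    edge_mats = {}
    for cat, rate in enumerate(cat_rates):
        for node in nodes:
            if node is not tree.root:
                edge_mats[(cat, id(node))] = model.transition_matrix(
                    node.length * rate
                )
    parent_of = tree.parent_map()
    for site in range(n_sites):
        site_like = 0.0
        for cat in range(len(cat_rates)):
            cat_sum = 0.0
            for assignment in itertools.product(range(4), repeat=len(internals)):
                state_of = {
                    id(node): s for node, s in zip(internals, assignment)
                }
                for node in nodes:
                    if node.is_leaf:
                        state_of[id(node)] = tip_states[node.name][site]
                prob = model.freqs[state_of[id(tree.root)]]
                for node in nodes:
                    if node is tree.root:
                        continue
                    child_state = state_of[id(node)]
                    parent_state = state_of[id(parent_of[id(node)])]
                    if child_state == 4:  # missing tip: marginalizes to 1
                        continue
                    prob *= edge_mats[(cat, id(node))][parent_state, child_state]
                cat_sum += prob
            site_like += cat_sum / len(cat_rates)
        lnl += math.log(site_like)
    return lnl


# --------------------------------------------------- clustering info matching


def _entropy(a: int, n: int) -> float:
    h = 0.0
    for s in (a, n - a):
        if s:
            h -= (s / n) * math.log(s / n)
    return h


def _mi(s1: frozenset, s2: frozenset, tips: frozenset) -> float:
    n = len(tips)
    mi = 0.0
    for b1 in (s1, tips - s1):
        for b2 in (s2, tips - s2):
            k = len(b1 & b2)
            if k:
                mi += (k / n) * math.log(
                    (k / n) / ((len(b1) / n) * (len(b2) / n))
                )
    return max(mi, 0.0)


def cis_bruteforce(tree1, tree2) -> float:
    """Clustering-information similarity with the split matching found
    by exhaustive enumeration of all injective pairings."""
    tips = frozenset(tree1.tip_names())
    s1 = sorted(tree1.splits(), key=sorted)
    s2 = sorted(tree2.splits(), key=sorted)
    n = len(tips)
    h1 = sum(_entropy(len(s), n) for s in s1)
    h2 = sum(_entropy(len(s), n) for s in s2)
    if h1 + h2 == 0 or not s1 or not s2:
        return 0.0
    small, large = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
    best = 0.0
    for perm in itertools.permutations(range(len(large)), len(small)):
        score = sum(_mi(small[i], large[j], tips) for i, j in enumerate(perm))
        best = max(best, score)
    return 2.0 * best / (h1 + h2)


# ------------------------------------------------------------- random trees


def random_binary_tree(labels: list[str], rng: np.random.Generator, scale=1.0):
    """Random topology by sequential edge insertion; random lengths."""
    from plastmark.trees import Node, PhyloTree

    nodes = [Node(lab, float(rng.uniform(0.1, 1.0)) * scale) for lab in labels]
    root = Node(None, 0.0, [nodes[0], nodes[1], nodes[2]])
    for tip in nodes[3:]:
        tree = PhyloTree(root)
        candidates = [n for n in tree.postorder() if n is not root]
        target = candidates[int(rng.integers(len(candidates)))]
        parents = tree.parent_map()
        parent = parents[id(target)]
        split = float(rng.uniform(0.2, 0.8))
        mid = Node(None, target.length * (1 - split), [target, tip])
        idx = parent.children.index(target)
        target.length *= split
        parent.children[idx] = mid
        root = tree.root
    return PhyloTree(root)


def all_unrooted_topologies(labels: list[str]):
    """Every unrooted binary topology over the labels (15 for 5 tips)."""
    from plastmark.trees import Node, PhyloTree

    def expand(root, remaining):
        if not remaining:
            yield PhyloTree(root).copy()
            return
        label = remaining[0]
        tree = PhyloTree(root)
        edges = [n for n in tree.postorder() if n is not root]
        for i in range(len(edges)):
            work = PhyloTree(root).copy()
            work_edges = [n for n in work.postorder() if n is not work.root]
            target = work_edges[i]
            parent = work.parent_map()[id(target)]
            mid = Node(None, 1.0, [target, Node(label, 1.0)])
            parent.children[parent.children.index(target)] = mid
            yield from expand(work.root, remaining[1:])

    base = Node(
        None,
        0.0,
        [Node(labels[0], 1.0), Node(labels[1], 1.0), Node(labels[2], 1.0)],
    )
    yield from expand(base, list(labels[3:]))
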