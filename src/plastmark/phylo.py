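"""Tree inference: pairwise distances, neighbor joining, maximum
likelihood under reversible models with discrete-gamma rates, bootstrap
support, AIC model choice and mean-path-length ultrametricization.

The ML search is a desk-scale reimplementation of the usual pipeline:
a neighbor-joining starting tree, per-edge Brent branch-length
optimization, model-parameter fitting, and first-improvement NNI
hill-climbing.  The search is deterministic; randomness enters only
through bootstrap resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from ._seq import encode_states
from .models import SubstitutionModel
from .records import RegionAlignment
from .trees import Node, PhyloTree

_MIN_BRANCH = 1e-9
_MAX_BRANCH = 10.0


class SaturatedDistanceError(ValueError):
    pass


# ----------------------------------------------------------------- distances


def _pair_counts(seq_i: str, seq_j: str) -> tuple[np.ndarray, int]:
    """4x4 site-pattern counts over shared unambiguous columns."""
    a = encode_states(seq_i)
    b = encode_states(seq_j)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    mask = (a < 4) & (b < 4)
    counts = np.zeros((4, 4), dtype=float)
    np.add.at(counts, (a[mask], b[mask]), 1.0)
    return counts, int(mask.sum())


def ml_distance(
    seq_i: str,
    seq_j: str,
    model: SubstitutionModel | str = "JC",
    cap_saturated: bool = False,
) -> float:
    """Model-based evolutionary distance between two aligned rows.

    JC and K2P use their closed forms; HKY and GTR maximize the
    two-sequence likelihood over the single branch length numerically.
    A JC-saturated pair (p >= 3/4) raises unless ``cap_saturated``.
    """
    kind = model if isinstance(model, str) else model.kind
    counts, n_shared = _pair_counts(seq_i, seq_j)
    if n_shared == 0:
        raise ValueError("no shared unambiguous columns")
    p = (counts.sum() - np.trace(counts)) / n_shared

    if kind == "JC":
        if p >= 0.75 - 1e-12:
            if cap_saturated:
                p = 0.75 - 1.0 / (2 * n_shared)
            else:
                raise SaturatedDistanceError(
                    f"JC distance undefined: p-distance {p:.4f} >= 0.75"
                )
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    if kind == "K2P":
        transitions = (counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1])
        ts = transitions / n_shared
        tv = p - ts
        w1 = 1.0 - 2.0 * ts - tv
        w2 = 1.0 - 2.0 * tv
        if w1 <= 0 or w2 <= 0:
            if cap_saturated:
                return ml_distance(seq_i, seq_j, "JC", cap_saturated=True)
            raise SaturatedDistanceError("K2P distance undefined (saturated pair)")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)

    if not isinstance(model, SubstitutionModel):
        raise ValueError(f"{kind}: pass a fitted SubstitutionModel instance")
    rates = model.category_rates()
    freqs = model.freqs

    def neg_lnl(t: float) -> float:
        like = np.zeros((4, 4))
        for r in rates:
            like += freqs[:, None] * model.transition_matrix(t * r)
        like /= len(rates)
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(np.clip(like, 1e-300, None)), 0.0)
        return -(counts * logs).sum()

    res = minimize_scalar(
        neg_lnl, bounds=(_MIN_BRANCH, _MAX_BRANCH), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def distance_matrix(
    alignment: RegionAlignment,
    model: SubstitutionModel | str = "JC",
    cap_saturated: bool = True,
) -> pd.DataFrame:
    n = alignment.n_taxa
    rows = ["".join(r) for r in alignment.matrix]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_distance(rows[i], rows[j], model, cap_saturated=cap_saturated)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=alignment.taxa, columns=alignment.taxa)


def fast_jc_distance_matrix(
    diff_counts: np.ndarray, n_sites: float | np.ndarray
) -> np.ndarray:
    """Vectorized JC transform of a pairwise difference-count matrix."""
    p = diff_counts / n_sites
    p = np.minimum(p, 0.75 - 1e-6)
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def pairwise_differences(alignment: RegionAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise mismatch counts and comparable-site counts (pairwise
    deletion over gap/N columns)."""
    states = np.stack([encode_states("".join(r)) for r in alignment.matrix])
    valid = states < 4
    n = states.shape[0]
    diffs = np.zeros((n, n))
    shared = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diffs[i] = ((states[i] != states) & both).sum(axis=1)
        shared[i] = both.sum(axis=1)
    np.fill_diagonal(diffs, 0.0)
    return diffs, shared


# ----------------------------------------------------------- neighbor joining


def neighbor_joining(dist: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei agglomeration.

    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sister edge.  For n == 3 the unique unrooted
    tree follows from the three-point formulas.
    """
    labels = list(dist.index)
    mat = dist.values.astype(float)
    if mat.shape[0] != mat.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[Node] = [Node(name) for name in labels]
    if n == 2:
        d = mat[0, 1]
        nodes[0].length = nodes[1].length = d / 2.0
        return PhyloTree(Node(None, 0.0, nodes))
    active = list(range(n))
    dmat = mat.copy()

    while len(active) > 3:
        m = len(active)
        sub = dmat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) index pair
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = sub[fi, fj]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        new_node = Node(None, 0.0, [nodes[i], nodes[j]])
        new_dists = 0.5 * (
            dmat[i, active] + dmat[j, active] - dij
        )
        dmat = np.pad(dmat, ((0, 1), (0, 1)))
        k = dmat.shape[0] - 1
        dmat[k, active] = new_dists
        dmat[active, k] = new_dists
        nodes.append(new_node)
        active = [a for a in active if a not in (i, j)] + [k]

    a, b, c = active
    la = 0.5 * (dmat[a, b] + dmat[a, c] - dmat[b, c])
    lb = 0.5 * (dmat[a, b] + dmat[b, c] - dmat[a, c])
    lc = 0.5 * (dmat[a, c] + dmat[b, c] - dmat[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(ln, 0.0)
    return PhyloTree(Node(None, 0.0, [nodes[a], nodes[b], nodes[c]]))


# ----------------------------------------------------------------- likelihood


class TreeLikelihood:
    """Felsenstein pruning over compressed site patterns.

    Gaps and N are missing data (all-ones tip partials); columns that
    are missing in every row are dropped.
    """

    def __init__(
        self,
        tree: PhyloTree,
        alignment: RegionAlignment,
        model: SubstitutionModel,
    ) -> None:
        tip_names = tree.tip_names()
        if set(tip_names) != set(alignment.taxa):
            raise ValueError(
                "tree tips and alignment taxa differ: "
                f"{sorted(set(tip_names) ^ set(alignment.taxa))}"
            )
        self.tree = tree
        self.model = model
        states = np.stack(
            [encode_states(alignment.row(name)) for name in tip_names]
        )
        keep = (states < 4).any(axis=0)
        states = states[:, keep]
        patterns, inverse, weights = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (ntaxa, npat)
        self.pattern_of_column = inverse
        self.weights = weights.astype(float)
        self.tip_index = {name: i for i, name in enumerate(tip_names)}
        self.cat_rates = model.category_rates()
        self.ncat = len(self.cat_rates)
        self.npat = self.patterns.shape[1]
        # tip partials, shared across categories
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        self._tip_partials = {
            name: eye5[self.patterns[i]] for name, i in self.tip_index.items()
        }

    # -- message passing

    def _edge_matrices(self, node: Node) -> np.ndarray:
        return np.stack(
            [
                self.model.transition_matrix(max(node.length, 0.0) * r)
                for r in self.cat_rates
            ]
        )

    def _down_messages(self) -> dict[int, np.ndarray]:
        """(ncat, npat, 4) conditional likelihoods below each node."""
        down: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                tip = self._tip_partials[node.name]
                down[id(node)] = np.broadcast_to(
                    tip, (self.ncat, self.npat, 4)
                ).copy()
            else:
                acc = np.ones((self.ncat, self.npat, 4))
                for child in node.children:
                    pmats = self._edge_matrices(child)
                    acc *= np.einsum("cij,cpj->cpi", pmats, down[id(child)])
                down[id(node)] = acc
        return down

    def _messages(self) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        """Down messages plus outside messages B for every non-root node.

        ``B[c]`` lives at c's parent: the likelihood flux from everything
        outside c's subtree, including the root prior.  The per-site
        likelihood factorizes as B[c] . P(t_c) . down[c] on any edge.
        """
        down = self._down_messages()
        b_msgs: dict[int, np.ndarray] = {}
        freqs = self.model.freqs
        # contribution of each child edge at its parent
        lifted = {
            id(c): np.einsum(
                "cij,cpj->cpi", self._edge_matrices(c), down[id(c)]
            )
            for node in self.tree.preorder()
            for c in node.children
        }
        above: dict[int, np.ndarray] = {
            id(self.tree.root): np.broadcast_to(
                freqs, (self.ncat, self.npat, 4)
            ).copy()
        }
        for node in self.tree.preorder():
            for child in node.children:
                b = above[id(node)].copy()
                for sib in node.children:
                    if sib is not child:
                        b *= lifted[id(sib)]
                b_msgs[id(child)] = b
                above[id(child)] = np.einsum(
                    "cpi,cij->cpj", b, self._edge_matrices(child)
                )
        return down, b_msgs

    # -- likelihood values

    def _site_likelihoods(self) -> np.ndarray:
        down = self._down_messages()
        root = down[id(self.tree.root)]
        return np.einsum("cpi,i->cp", root, self.model.freqs)

    def lnl(self) -> float:
        site = self._site_likelihoods().mean(axis=0)
        return float(self.weights @ np.log(np.clip(site, 1e-300, None)))

    def column_category_posteriors(self) -> np.ndarray:
        """(ncolumns, ncat) posterior over rate categories per column."""
        cat_like = self._site_likelihoods()  # (ncat, npat)
        post = cat_like / np.clip(cat_like.sum(axis=0, keepdims=True), 1e-300, None)
        return post.T[self.pattern_of_column]

    # -- branch-length optimization

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_passes: int = 3
    ) -> float:
        """Per-edge Brent optimization; returns the final lnL.

        Messages are refreshed before each edge so every 1-D problem is
        exact; the loop stops when a pass improves lnL by < ``tol``.
        """
        last = self.lnl()
        for _ in range(max_passes):
            for node in self.tree.postorder():
                if node is self.tree.root:
                    continue
                down, b_msgs = self._messages()
                d = down[id(node)]
                b = b_msgs[id(node)]

                def neg_lnl(t: float) -> float:
                    pmats = np.stack(
                        [
                            self.model.transition_matrix(t * r)
                            for r in self.cat_rates
                        ]
                    )
                    site = np.einsum("cpi,cij,cpj->cp", b, pmats, d).mean(axis=0)
                    return -(
                        self.weights @ np.log(np.clip(site, 1e-300, None))
                    )

                res = minimize_scalar(
                    neg_lnl,
                    bounds=(_MIN_BRANCH, _MAX_BRANCH),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
                if -res.fun >= -neg_lnl(node.length):
                    node.length = float(res.x)
            current = self.lnl()
            if current - last < tol:
                last = max(current, last)
                break
            last = current
        return last


def log_likelihood(
    tree: PhyloTree, alignment: RegionAlignment, model: SubstitutionModel
) -> float:
    """Natural-log likelihood of the alignment on the tree."""
    return TreeLikelihood(tree, alignment, model).lnl()


# ------------------------------------------------------------------ ML search


@dataclass
class MLSearchConfig:
    starting_tree: str = "nj"
    n_nni_rounds: int = 10
    bl_tol: float = 1e-4
    n_bootstrap: int = 0
    seed: int = 0
    fast_mode: bool = False
    fit_model: bool = True
    bl_passes: int = 2


@dataclass
class MLResult:
    tree: PhyloTree
    model: SubstitutionModel
    lnl: float
    lnl_history: list[float] = field(default_factory=list)


def _empirical_freqs(alignment: RegionAlignment) -> np.ndarray:
    states = np.stack([encode_states("".join(r)) for r in alignment.matrix])
    counts = np.array([(states == i).sum() for i in range(4)], dtype=float) + 1.0
    return counts / counts.sum()


def _fit_model_params(
    tree: PhyloTree, alignment: RegionAlignment, model: SubstitutionModel
) -> SubstitutionModel:
    """Optimize alpha (if present) and exchangeabilities on a fixed tree."""
    if model.alpha is not None and model.ncat > 1:

        def neg_alpha(log_a: float) -> float:
            m = model.with_params(alpha=float(np.exp(log_a)))
            return -TreeLikelihood(tree, alignment, m).lnl()

        res = minimize_scalar(
            neg_alpha, bounds=(np.log(0.05), np.log(50.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        model = model.with_params(alpha=float(np.exp(res.x)))

    if model.kind in ("K2P", "HKY"):

        def neg_kappa(log_k: float) -> float:
            kappa = float(np.exp(log_k))
            ex = np.ones(6)
            ex[[1, 4]] = kappa
            m = model.with_params(exchangeabilities=ex)
            return -TreeLikelihood(tree, alignment, m).lnl()

        res = minimize_scalar(
            neg_kappa, bounds=(np.log(0.05), np.log(100.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        ex = np.ones(6)
        ex[[1, 4]] = float(np.exp(res.x))
        model = model.with_params(exchangeabilities=ex)

    elif model.kind == "GTR":

        def neg_rates(log_r: np.ndarray) -> float:
            ex = np.ones(6)
            ex[:5] = np.exp(log_r)
            m = model.with_params(exchangeabilities=ex)
            return -TreeLikelihood(tree, alignment, m).lnl()

        x0 = np.log(np.clip(model.exchangeabilities[:5], 1e-3, None))
        res = minimize(
            neg_rates, x0, method="L-BFGS-B",
            bounds=[(np.log(1e-3), np.log(1e3))] * 5,
            options={"maxiter": 40, "ftol": 1e-8},
        )
        ex = np.ones(6)
        ex[:5] = np.exp(res.x)
        model = model.with_params(exchangeabilities=ex)

    return model


def _unrooted_internal_edges(tree: PhyloTree) -> list[frozenset[str]]:
    """Internal edges as canonical splits, in fixed postorder."""
    all_tips = frozenset(tree.tip_names())
    ref = min(all_tips)
    n = len(all_tips)
    below = tree.below_sets()
    seen: list[frozenset[str]] = []
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = below[id(node)]
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2 and side not in seen:
            seen.append(side)
    return seen


def _nni_neighbors(tree: PhyloTree, split: frozenset[str]):
    """The two NNI rearrangements around one internal edge."""
    rerooted = tree.reroot_at_split(split)
    c_side, p_side = rerooted.root.children
    if c_side.is_leaf or p_side.is_leaf:
        return
    for swap_idx in range(len(p_side.children)):
        variant = rerooted.copy()
        c2, p2 = variant.root.children
        b = c2.children[-1]
        partner = p2.children[swap_idx]
        c2.children[-1] = partner
        p2.children[swap_idx] = b
        yield variant


def optimize_ml_tree(
    alignment: RegionAlignment,
    config: MLSearchConfig | None = None,
    model: SubstitutionModel | None = None,
) -> MLResult:
    """NJ start, then alternate branch-length/model optimization with
    first-improvement NNI sweeps until no move gains more than
    ``config.bl_tol`` log units."""
    config = config or MLSearchConfig()
    if alignment.n_taxa < 4:
        raise ValueError("ML search needs at least 4 taxa")
    if model is None:
        model = SubstitutionModel.gtr(
            _empirical_freqs(alignment), np.ones(6), alpha=1.0, ncat=4
        )

    diffs, shared = pairwise_differences(alignment)
    dmat = fast_jc_distance_matrix(diffs, np.clip(shared, 1.0, None))
    tree = neighbor_joining(
        pd.DataFrame(dmat, index=alignment.taxa, columns=alignment.taxa)
    )

    engine = TreeLikelihood(tree, alignment, model)
    lnl = engine.optimize_branch_lengths(tol=config.bl_tol, max_passes=config.bl_passes)
    if config.fit_model and not config.fast_mode:
        model = _fit_model_params(tree, alignment, model)
        engine = TreeLikelihood(tree, alignment, model)
        lnl = engine.optimize_branch_lengths(
            tol=config.bl_tol, max_passes=config.bl_passes
        )
    history = [lnl]

    if not config.fast_mode:
        for _ in range(config.n_nni_rounds):
            improved = False
            for split in _unrooted_internal_edges(tree):
                for variant in _nni_neighbors(tree, split):
                    cand = TreeLikelihood(variant, alignment, model)
                    cand_lnl = cand.optimize_branch_lengths(
                        tol=config.bl_tol, max_passes=1
                    )
                    if cand_lnl > lnl + config.bl_tol:
                        tree, lnl, improved = variant, cand_lnl, True
                        break
                if improved:
                    break
            if not improved:
                break
            engine = TreeLikelihood(tree, alignment, model)
            lnl = max(lnl, engine.optimize_branch_lengths(
                tol=config.bl_tol, max_passes=config.bl_passes
            ))
            if config.fit_model:
                model = _fit_model_params(tree, alignment, model)
                engine = TreeLikelihood(tree, alignment, model)
                lnl = engine.optimize_branch_lengths(
                    tol=config.bl_tol, max_passes=1
                )
            history.append(lnl)

    return MLResult(tree=tree, model=model, lnl=lnl, lnl_history=history)


# ------------------------------------------------------------------ bootstrap


def bootstrap_support(
    alignment: RegionAlignment,
    best_tree: PhyloTree,
    config: MLSearchConfig | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap; split frequencies (%) are mapped
    onto a copy of the best tree.  Replicate trees are inferred in fast
    mode (NJ on JC distances)."""
    config = config or MLSearchConfig()
    out = best_tree.copy()
    if config.n_bootstrap <= 0:
        return out
    rng = np.random.default_rng(config.seed)
    ncols = alignment.n_columns
    split_counts: dict[frozenset[str], int] = {}
    for _ in range(config.n_bootstrap):
        cols = rng.integers(0, ncols, size=ncols)
        res_aln = RegionAlignment(
            alignment.region_name,
            alignment.region_kind,
            alignment.taxa,
            alignment.matrix[:, cols],
        )
        diffs, shared = pairwise_differences(res_aln)
        dmat = fast_jc_distance_matrix(diffs, np.clip(shared, 1.0, None))
        rep = neighbor_joining(
            pd.DataFrame(dmat, index=res_aln.taxa, columns=res_aln.taxa)
        )
        for split in rep.splits():
            split_counts[split] = split_counts.get(split, 0) + 1

    all_tips = frozenset(out.tip_names())
    ref = min(all_tips)
    n = len(all_tips)
    below = out.below_sets()
    for node in out.postorder():
        if node.is_leaf or node is out.root:
            continue
        side = below[id(node)]
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2:
            node.support = 100.0 * split_counts.get(side, 0) / config.n_bootstrap
    return out


# -------------------------------------------------------------- model choice


def default_model_candidates() -> list[SubstitutionModel]:
    flat = [
        SubstitutionModel.jc(),
        SubstitutionModel.k2p(),
        SubstitutionModel.hky(np.full(4, 0.25)),
        SubstitutionModel.gtr(np.full(4, 0.25), np.ones(6)),
    ]
    gamma = [m.with_params(alpha=1.0, ncat=4) for m in flat]
    return flat + gamma


def select_model_aic(
    alignment: RegionAlignment,
    tree: PhyloTree,
    candidates: list[SubstitutionModel] | None = None,
) -> tuple[SubstitutionModel, pd.DataFrame]:
    """Fit each candidate on the fixed topology and return the AIC
    winner plus the full comparison table (AIC = 2k - 2 lnL)."""
    candidates = candidates or default_model_candidates()
    rows = []
    best: tuple[float, SubstitutionModel] | None = None
    for cand in candidates:
        if cand.kind in ("HKY", "GTR"):
            cand = cand.with_params(freqs=_empirical_freqs(alignment))
        work = tree.copy()
        engine = TreeLikelihood(work, alignment, cand)
        engine.optimize_branch_lengths(max_passes=1)
        fitted = _fit_model_params(work, alignment, cand)
        engine = TreeLikelihood(work, alignment, fitted)
        lnl = engine.optimize_branch_lengths(max_passes=1)
        k = fitted.n_free_parameters()
        aic = 2.0 * k - 2.0 * lnl
        rows.append(
            {"model": fitted.short_name(), "k": k, "lnl": lnl, "aic": aic}
        )
        if best is None or aic < best[0]:
            best = (aic, fitted)
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    assert best is not None
    return best[1], table


# ----------------------------------------------------------- ultrametricizing


def make_ultrametric(tree: PhyloTree, tol: float = 1e-9) -> PhyloTree:
    """Mean-path-length ultrametricization.

    Each internal node's age is the mean of its root-to-tip path
    lengths measured below it; parent >= child is enforced bottom-up,
    then branch lengths are rewritten as age differences so all tips
    end at depth zero.
    """
    work = tree.copy()
    if len(work.root.children) != 2:
        work = work.midpoint_root()
    ages: dict[int, float] = {}
    sums: dict[int, tuple[float, int]] = {}
    for node in work.postorder():
        if node.is_leaf:
            sums[id(node)] = (0.0, 1)
            ages[id(node)] = 0.0
        else:
            total, count = 0.0, 0
            for child in node.children:
                s, c = sums[id(child)]
                total += s + c * child.length
                count += c
            sums[id(node)] = (total, count)
            age = total / count
            max_child = max(ages[id(c)] for c in node.children)
            ages[id(node)] = max(age, max_child + tol)
    for node in work.preorder():
        for child in node.children:
            child.length = max(ages[id(node)] - ages[id(child)], 0.0)
    return work
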