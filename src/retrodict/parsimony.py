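"""Wagner (ordered-character) maximum parsimony on rooted trees.

Trees are nested 2-tuples: a leaf is a taxon label (str), an internal node
is a pair of subtrees.  Rooting is Lundberg-style: the hypothetical
ancestor ANC participates in the search as an ordinary leaf and the root is
its attachment edge, so optimal trees are reported as ``(ANC, ingroup)``.

Tree length under linearly ordered states (cost |i - j|) is computed with
the Farris interval algorithm, which is exact on binary trees and runs
vectorised over characters.  Exhaustive and branch-and-bound searches are
provably optimal; a stepwise-addition + NNI heuristic scales to hundreds of
taxa.  Fit statistics follow the classical definitions:

  CI = M / s     (M = sum of per-character state ranges, s = tree length)
  RI = (G - s) / (G - M)   (G = sum of per-character star-tree lengths)
  RC = CI * RI
  g1 = skewness of the tree-length distribution over uniformly sampled
       rooted topologies (complete enumeration up to 7 taxa); strongly
       negative g1 indicates phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats as sps

from .coding import ANCESTOR_LABEL, CharacterMatrix

Tree = object  # str (leaf) or 2-tuple of Tree

EXHAUSTIVE_CAP = 9
BNB_TAXA_CAP = 60
MAX_RETAINED_TREES = 1000
DEFAULT_G1_SAMPLES = 10_000
G1_ENUMERATION_CAP = 7
HEURISTIC_RESTARTS_LARGE = 25


class ParsimonyError(ValueError):
    """Raised for taxon mismatches, size refusals, and invalid trees."""


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def is_leaf(t: Tree) -> bool:
    return isinstance(t, str)


def leaves(t: Tree) -> list[str]:
    if is_leaf(t):
        return [t]
    return [x for child in t for x in leaves(child)]


def canonical(t: Tree) -> Tree:
    """Order-independent canonical form (children sorted by min leaf)."""
    if is_leaf(t):
        return t
    kids = tuple(canonical(c) for c in t)
    return tuple(sorted(kids, key=lambda c: min(leaves(c))))


def to_newick(t: Tree) -> str:
    def rec(x: Tree) -> str:
        if is_leaf(x):
            return x
        return "(" + ",".join(rec(c) for c in x) + ")"

    return rec(canonical(t)) + ";"


def clades(t: Tree) -> set[frozenset[str]]:
    """All non-trivial clades (leaf sets of internal nodes, excluding root)."""
    out: set[frozenset[str]] = set()

    def rec(x: Tree) -> frozenset[str]:
        if is_leaf(x):
            return frozenset([x])
        s = frozenset().union(*(rec(c) for c in x))
        out.add(s)
        return s

    rec(t)
    out.discard(frozenset(leaves(t)))
    return out


def bipartitions(t: Tree) -> set[frozenset[str]]:
    """Unrooted bipartitions, each encoded by the side not containing the
    lexicographically smallest taxon; trivial splits excluded."""
    all_taxa = frozenset(leaves(t))
    ref = min(all_taxa)
    out: set[frozenset[str]] = set()
    for c in clades(t):
        side = c if ref not in c else all_taxa - c
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(side)
    return out


def robinson_foulds(t1: Tree, t2: Tree, normalized: bool = True) -> float:
    """Symmetric-difference (RF) distance between unrooted topologies."""
    if sorted(leaves(t1)) != sorted(leaves(t2)):
        raise ParsimonyError("trees must share the same taxa")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    n = len(leaves(t1))
    denom = 2 * (n - 3)
    return rf / denom if denom > 0 else 0.0


def reroot_at_leaf(t: Tree, leaf: str) -> Tree:
    """Re-hang a binary tree so ``leaf`` is a child of the root.

    The unrooted topology is unchanged; the degree-2 node left at the old
    root is suppressed.  Walks from the old root toward ``leaf``, folding
    the siblings passed along the way into the new root-side subtree.
    """
    if is_leaf(t) or leaf not in leaves(t):
        raise ParsimonyError(f"cannot reroot at {leaf!r}")

    def build(x: Tree, carry: Tree | None) -> Tree:
        if is_leaf(x):
            assert x == leaf
            return carry  # type: ignore[return-value]
        a, b = x
        down, sib = (a, b) if leaf in leaves(a) else (b, a)
        new_carry = sib if carry is None else (carry, sib)
        return build(down, new_carry)

    return (leaf, build(t, None))


def insert_at_edges(t: Tree, new_leaf: str) -> Iterator[Tree]:
    """Yield every tree obtained by attaching ``new_leaf`` on an edge of
    ``t`` (including the edge above the root)."""

    def rec(x: Tree) -> Iterator[Tree]:
        yield (x, new_leaf)  # attach on the edge above x
        if not is_leaf(x):
            a, b = x
            for na in rec(a):
                yield (na, b)
            for nb in rec(b):
                yield (a, nb)

    return rec(t)


def all_rooted_trees(taxa: Sequence[str]) -> Iterator[Tree]:
    """Enumerate all rooted binary topologies on ``taxa`` ((2n-3)!! trees)."""
    taxa = list(taxa)
    if not taxa:
        return
    if len(taxa) == 1:
        yield taxa[0]
        return

    def rec(i: int, t: Tree) -> Iterator[Tree]:
        if i == len(taxa):
            yield t
            return
        for nt in insert_at_edges(t, taxa[i]):
            yield from rec(i + 1, nt)

    yield from rec(1, taxa[0])


def random_rooted_tree(taxa: Sequence[str], rng: np.random.Generator) -> Tree:
    """Uniform random rooted binary topology by sequential edge insertion."""
    taxa = list(taxa)
    if len(taxa) == 0:
        raise ParsimonyError("need at least one taxon")
    t: Tree = taxa[0]
    for i, leaf in enumerate(taxa[1:], start=1):
        options = list(insert_at_edges(t, leaf))
        t = options[rng.integers(len(options))]
    return t


def nni_neighbors(t: Tree) -> Iterator[Tree]:
    """Nearest-neighbour-interchange neighbours of a rooted tree."""

    def rec(x: Tree) -> Iterator[Tree]:
        if is_leaf(x):
            return
        a, b = x
        if not is_leaf(b):
            c, d = b
            yield (c, (a, d))
            yield (d, (a, c))
        if not is_leaf(a):
            c, d = a
            yield (c, (b, d))
            yield (d, (b, c))
        for na in rec(a):
            yield (na, b)
        for nb in rec(b):
            yield (a, nb)

    seen: set[str] = set()
    for nt in rec(t):
        key = to_newick(nt)
        if key not in seen:
            seen.add(key)
            yield nt


# ---------------------------------------------------------------------------
# Tree length (Farris intervals, vectorised over characters)
# ---------------------------------------------------------------------------

def _check_taxa(tree: Tree, m: CharacterMatrix) -> None:
    tl = sorted(leaves(tree))
    ml = sorted(m.taxa)
    if tl != ml:
        raise ParsimonyError(f"tree taxa {tl} != matrix taxa {ml}")


def wagner_length(tree: Tree, m: CharacterMatrix) -> int:
    """Minimal total steps under ordered cost |i-j|, summed over characters."""
    _check_taxa(tree, m)
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    return _wagner_length_rows(tree, rows)


def _wagner_length_rows(tree: Tree, rows: dict[str, np.ndarray]) -> int:
    total = 0

    def rec(x: Tree) -> tuple[np.ndarray, np.ndarray]:
        nonlocal total
        if is_leaf(x):
            r = rows[x]
            return r, r
        lo1, hi1 = rec(x[0])
        lo2, hi2 = rec(x[1])
        L = np.maximum(lo1, lo2)
        H = np.minimum(hi1, hi2)
        gap = L - H
        np.clip(gap, 0, None, out=gap)
        total += int(gap.sum())
        lo = np.where(L <= H, L, H)
        hi = np.where(L <= H, H, L)
        return lo, hi

    rec(tree)
    return total


def sankoff_length(tree: Tree, m: CharacterMatrix) -> int:
    """Independent check: Sankoff DP over explicit states with cost |i-j|.

    The min-plus convolution with a linear metric is computed by forward
    and backward cumulative passes in O(k) per node.
    """
    _check_taxa(tree, m)
    k = m.k
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    nchar = m.states.shape[1]

    def leaf_cost(r: np.ndarray) -> np.ndarray:
        c = np.full((nchar, k), np.inf)
        c[np.arange(nchar), r] = 0.0
        return c

    def transmit(c: np.ndarray) -> np.ndarray:
        # m(j) = min_i c(i) + |i - j|
        out = c.copy()
        for j in range(1, k):
            out[:, j] = np.minimum(out[:, j], out[:, j - 1] + 1)
        for j in range(k - 2, -1, -1):
            out[:, j] = np.minimum(out[:, j], out[:, j + 1] + 1)
        return out

    def rec(x: Tree) -> np.ndarray:
        if is_leaf(x):
            return leaf_cost(rows[x])
        return transmit(rec(x[0])) + transmit(rec(x[1]))

    return int(rec(tree).min(axis=1).sum())


def min_conceivable_steps(m: CharacterMatrix) -> int:
    """M: sum over characters of the state range (steps on a perfect tree)."""
    return int((m.states.max(axis=0) - m.states.min(axis=0)).sum())


def max_conceivable_steps(m: CharacterMatrix) -> int:
    """G: sum over characters of the star-tree length, the maximum steps
    any binary tree can require; for an ordered character this is
    ``min_a sum_t |x_t - a|`` (a at the state median)."""
    total = 0
    for c in range(m.states.shape[1]):
        col = m.states[:, c]
        best = min(
            int(np.abs(col - a).sum()) for a in range(col.min(), col.max() + 1)
        )
        total += best
    return total


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitStats:
    """Tree length with homoplasy and signal statistics."""

    length: int
    CI: float
    RI: float
    RC: float
    g1: float | None
    g1_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "length": self.length,
            "CI": self.CI,
            "RI": self.RI,
            "RC": self.RC,
            "g1": self.g1,
            "g1_samples": self.g1_samples,
        }


@dataclass
class ParsimonyResult:
    """Optimal trees plus fit statistics and search metadata."""

    trees: list[Tree]
    length: int
    stats: FitStats | None = None
    method: str = ""
    seed: int | None = None
    trees_examined: int = 0

    @property
    def best(self) -> Tree:
        return self.trees[0]

    def consensus(self) -> Tree:
        return strict_consensus(self.trees)


def tree_length_distribution(
    m: CharacterMatrix, samples: int = DEFAULT_G1_SAMPLES, seed: int | None = 0
) -> np.ndarray:
    """Lengths of uniformly sampled rooted topologies (complete enumeration
    when the matrix has at most 7 taxa)."""
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    taxa = sorted(m.taxa)
    if len(taxa) <= G1_ENUMERATION_CAP:
        return np.array(
            [_wagner_length_rows(t, rows) for t in all_rooted_trees(taxa)]
        )
    rng = np.random.default_rng(seed)
    out = np.empty(samples)
    for i in range(samples):
        out[i] = _wagner_length_rows(random_rooted_tree(taxa, rng), rows)
    return out


def g1_statistic(lengths: np.ndarray) -> float | None:
    """Adjusted Fisher-Pearson skewness; None when the distribution is flat."""
    if len(lengths) < 3 or np.ptp(lengths) == 0:
        return None
    return float(sps.skew(lengths, bias=False))


def fit_stats(
    tree: Tree,
    m: CharacterMatrix,
    g1_samples: int = DEFAULT_G1_SAMPLES,
    seed: int | None = 0,
    compute_g1: bool = True,
) -> FitStats:
    s = wagner_length(tree, m)
    M = min_conceivable_steps(m)
    G = max_conceivable_steps(m)
    CI = M / s if s > 0 else 1.0
    RI = (G - s) / (G - M) if G > M else 1.0
    RC = CI * RI
    g1 = None
    n_used = 0
    if compute_g1:
        lengths = tree_length_distribution(m, samples=g1_samples, seed=seed)
        n_used = len(lengths)
        g1 = g1_statistic(lengths)
    return FitStats(length=s, CI=CI, RI=RI, RC=RC, g1=g1, g1_samples=n_used)


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------

def _split_ancestor(m: CharacterMatrix) -> tuple[list[str], bool]:
    ingroup = [t for t in m.taxa if t != ANCESTOR_LABEL]
    return ingroup, m.has_ancestor


def _rooted_result_tree(t: Tree, has_anc: bool) -> Tree:
    """Report trees with ANC as a child of the root (Lundberg rooting)."""
    if has_anc and ANCESTOR_LABEL in leaves(t):
        t = reroot_at_leaf(t, ANCESTOR_LABEL)
    return canonical(t)


def exhaustive_search(m: CharacterMatrix) -> ParsimonyResult:
    """Global optimum over all rooted topologies; ANC, when present, is the
    outgroup and ingroup root placement is exhausted.  Refuses more than
    9 non-ANC taxa (use :func:`branch_and_bound`)."""
    ingroup, has_anc = _split_ancestor(m)
    if len(ingroup) > EXHAUSTIVE_CAP:
        raise ParsimonyError(
            f"{len(ingroup)} taxa exceed the exhaustive cap of {EXHAUSTIVE_CAP}; "
            "use branch_and_bound"
        )
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    best_len = None
    best: list[Tree] = []
    examined = 0
    for ing in all_rooted_trees(sorted(ingroup)):
        t = (ANCESTOR_LABEL, ing) if has_anc else ing
        examined += 1
        L = _wagner_length_rows(t, rows)
        if best_len is None or L < best_len:
            best_len, best = L, [t]
        elif L == best_len and len(best) < MAX_RETAINED_TREES:
            best.append(t)
    trees = sorted(
        (_rooted_result_tree(t, has_anc) for t in best), key=to_newick
    )
    return ParsimonyResult(
        trees=trees, length=int(best_len), method="exhaustive", trees_examined=examined
    )


def heuristic_search(
    m: CharacterMatrix,
    seed: int = 0,
    restarts: int = 10,
) -> ParsimonyResult:
    """Random-addition stepwise insertion followed by NNI hill climbing.

    Deterministic given ``seed``; ties during stepwise insertion and NNI
    are broken in canonical traversal order.
    """
    rng = np.random.default_rng(seed)
    ingroup, has_anc = _split_ancestor(m)
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    best_len: int | None = None
    best: dict[str, Tree] = {}
    examined = 0

    for _ in range(max(1, restarts)):
        order = list(ingroup)
        rng.shuffle(order)
        if has_anc:
            order = [ANCESTOR_LABEL] + order
        t: Tree = order[0]
        if len(order) > 1:
            t = (order[0], order[1])
        for leaf in order[2:]:
            cand_best = None
            cand_len = None
            for nt in insert_at_edges(t, leaf):
                examined += 1
                L = _wagner_length_rows(nt, rows)
                if cand_len is None or L < cand_len:
                    cand_len, cand_best = L, nt
            t = cand_best
        # NNI hill climbing (first-improvement sweeps)
        cur_len = _wagner_length_rows(t, rows)
        improved = True
        while improved:
            improved = False
            for nt in nni_neighbors(t):
                examined += 1
                L = _wagner_length_rows(nt, rows)
                if L < cur_len:
                    t, cur_len = nt, L
                    improved = True
                    break
        if best_len is None or cur_len < best_len:
            best_len = cur_len
            best = {to_newick(_rooted_result_tree(t, has_anc)): _rooted_result_tree(t, has_anc)}
        elif cur_len == best_len:
            rt = _rooted_result_tree(t, has_anc)
            if len(best) < MAX_RETAINED_TREES:
                best[to_newick(rt)] = rt
    trees = [best[k] for k in sorted(best)]
    return ParsimonyResult(
        trees=trees,
        length=int(best_len),
        method="heuristic",
        seed=seed,
        trees_examined=examined,
    )


def branch_and_bound(
    m: CharacterMatrix,
    taxa_cap: int = BNB_TAXA_CAP,
    seed: int = 0,
) -> ParsimonyResult:
    """Provably minimal trees by depth-first branch and bound.

    The initial upper bound comes from :func:`heuristic_search`; taxa are
    added in order of decreasing state variance; partial trees are pruned
    when their length plus a per-character remaining-range bound exceeds
    the best length found.  Above ``taxa_cap`` taxa the search falls back
    to the heuristic with a warning.
    """
    ingroup, has_anc = _split_ancestor(m)
    if len(ingroup) > taxa_cap:
        import warnings

        warnings.warn(
            f"{len(ingroup)} taxa exceed the branch-and-bound cap ({taxa_cap}); "
            "falling back to heuristic search",
            stacklevel=2,
        )
        res = heuristic_search(m, seed=seed, restarts=HEURISTIC_RESTARTS_LARGE)
        res.method = "heuristic-fallback"
        return res

    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
    # addition order: decreasing variance of the taxon's state vector
    variances = {t: float(np.var(rows[t])) for t in ingroup}
    order = sorted(ingroup, key=lambda t: (-variances[t], t))
    if has_anc:
        order = [ANCESTOR_LABEL] + order

    upper = heuristic_search(m, seed=seed, restarts=5)
    ub = upper.length
    examined = 0
    best: dict[str, Tree] = {}
    best_len = ub
    for t in upper.trees:
        best[to_newick(t)] = t

    # Per-character min/max over the taxa not yet placed, by addition depth.
    nchar = m.states.shape[1]
    suffix_min = np.full((len(order) + 1, nchar), np.iinfo(np.int64).max)
    suffix_max = np.full((len(order) + 1, nchar), np.iinfo(np.int64).min)
    for i in range(len(order) - 1, -1, -1):
        r = rows[order[i]]
        suffix_min[i] = np.minimum(suffix_min[i + 1], r)
        suffix_max[i] = np.maximum(suffix_max[i + 1], r)

    def lower_bound(t: Tree, depth: int) -> int:
        nonlocal examined
        examined += 1
        L = _wagner_length_rows(t, rows)
        if depth >= len(order):
            return L
        placed = [rows[x] for x in leaves(t)]
        pmin = np.min(placed, axis=0)
        pmax = np.max(placed, axis=0)
        rmin = suffix_min[depth]
        rmax = suffix_max[depth]
        extra = np.clip(pmin - rmin, 0, None) + np.clip(rmax - pmax, 0, None)
        return L + int(extra.sum())

    start: Tree = (order[0], order[1]) if len(order) >= 2 else order[0]

    def dfs(t: Tree, depth: int) -> None:
        nonlocal best_len, best
        if depth == len(order):
            L = _wagner_length_rows(t, rows)
            if L < best_len:
                best_len = L
                best = {}
            if L == best_len and len(best) < MAX_RETAINED_TREES:
                rt = _rooted_result_tree(t, has_anc)
                best[to_newick(rt)] = rt
            return
        leaf = order[depth]
        for nt in insert_at_edges(t, leaf):
            if lower_bound(nt, depth + 1) <= best_len:
                dfs(nt, depth + 1)

    if len(order) < 2:
        only: Tree = order[0]
        return ParsimonyResult(trees=[only], length=0, method="branch-and-bound")
    dfs(start, 2)
    trees = [best[k] for k in sorted(best)]
    return ParsimonyResult(
        trees=trees,
        length=int(best_len),
        method="branch-and-bound",
        seed=seed,
        trees_examined=examined,
    )


# ---------------------------------------------------------------------------
# Consensus and node distances
# ---------------------------------------------------------------------------

def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Strict consensus of rooted trees (clades present in every tree).

    The result may be multifurcating; it is represented with nested tuples
    where internal nodes can have more than two children.
    """
    if not trees:
        raise ParsimonyError("no trees")
    taxa = sorted(leaves(trees[0]))
    common = set.intersection(*(clades(t) for t in trees))
    common.add(frozenset(taxa))
    # build by nesting clades (they are mutually compatible)
    ordered = sorted(common, key=len)

    def build(clade: frozenset[str]) -> Tree:
        children_clades: list[frozenset[str]] = []
        for c in sorted((c for c in ordered if c < clade), key=len, reverse=True):
            if not any(c < cc for cc in children_clades):
                children_clades.append(c)
        covered = set().union(*children_clades) if children_clades else set()
        parts: list[Tree] = [build(c) for c in children_clades]
        parts.extend(sorted(clade - covered))
        parts.sort(key=lambda x: min(leaves(x)) if not is_leaf(x) else x)
        if len(parts) == 1:
            return parts[0]
        return tuple(parts)

    return build(frozenset(taxa))


def node_distances(tree: Tree, exclude: Iterable[str] = (ANCESTOR_LABEL,)) -> dict:
    """Node distance (internal nodes on the root-to-leaf path, root
    included) and relative age ``1 - nd/nd_max`` per leaf.

    Relative age 1 marks the most basal (ancient) taxa.  Leaves named in
    ``exclude`` (the hypothetical ancestor by default) are dropped from
    both the output and the nd_max computation.
    """
    if is_leaf(tree):
        raise ParsimonyError("node distances need a rooted tree with >= 2 leaves")
    nd: dict[str, int] = {}

    def rec(x: Tree, depth: int) -> None:
        if is_leaf(x):
            nd[x] = depth
            return
        for child in x:
            rec(child, depth + 1)

    rec(tree, 0)
    excl = set(exclude)
    nd = {t: d for t, d in nd.items() if t not in excl}
    nd_max = max(nd.values())
    rel = {t: 1.0 - d / nd_max if nd_max > 0 else 0.0 for t, d in nd.items()}
    return {"nd": nd, "relative_age": rel, "nd_max": nd_max}
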