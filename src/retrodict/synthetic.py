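"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

* a tRNA family evolved along a known reference tree from a 76-nt
  cloverleaf scaffold, with compensatory stem mutations that preserve base
  pairing (so leaves remain valid cloverleafs when the compensatory
  probability is 1);
* a domain-abundance census produced by an accretion process: domains are
  born once at tree nodes and their abundance grows multiplicatively along
  every subsequent edge with lognormal noise, so birth order is the true
  age rank and root-born domains occur in every proteome.

A direct ordered-character simulator is also provided for recovery
experiments on the parsimony engine itself: each character activates at a
tree node and drifts toward higher states inside that clade, matching the
polarization model (order increases in evolution) that roots the trees.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronology import InteractionRecord
from .coding import CharacterMatrix
from .parsimony import Tree, is_leaf, leaves
from .structure import (
    SecondaryStructure,
    StructureError,
    decompose_cloverleaf,
    parse_dotbracket,
)

# ---------------------------------------------------------------------------
# Scaffold: a 76-nt consensus cloverleaf consistent with the default template
# ---------------------------------------------------------------------------
# acceptor stem 1-7 : 66-72, D stem 10-13 : 22-25, anticodon stem 27-31 :
# 39-43, T stem 49-53 : 61-65; anticodon at 34-36; 3' NCCA tail 73-76.

SCAFFOLD_SEQUENCE = (
    "GCGGAUU"      # 1-7    acceptor 5'
    "UA"           # 8-9
    "GCUC"         # 10-13  D stem 5'
    "AGUUGGGA"     # 14-21  D loop
    "GAGC"         # 22-25  D stem 3'
    "G"            # 26
    "CCAGA"        # 27-31  anticodon stem 5'
    "CU"           # 32-33
    "GAA"          # 34-36  anticodon
    "UA"           # 37-38
    "UCUGG"        # 39-43  anticodon stem 3'
    "AGGUC"        # 44-48  variable loop
    "CUGUG"        # 49-53  T stem 5'
    "UUCGAUC"      # 54-60  T loop
    "CACAG"        # 61-65  T stem 3'
    "AAUUCGC"      # 66-72  acceptor 3'
    "ACCA"         # 73-76
)

SCAFFOLD_STRUCTURE = (
    "((((((("       # 1-7
    ".."
    "(((("          # 10-13
    "........"
    "))))"          # 22-25
    "."
    "((((("         # 27-31
    ".."
    "..."
    ".."
    ")))))"         # 39-43
    "....."
    "((((("         # 49-53
    "......."
    ")))))"         # 61-65
    ")))))))"       # 66-72
    "...."
)

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = "ACGU"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic generators.

    Defaults define the study conditions: moderate divergence with mostly
    compensatory stem evolution for the tRNA family, and a gentle
    multiplicative accretion process for the census.
    """

    n_taxa: int = 8
    seed: int = 0
    substitution_prob: float = 0.03       # per site per edge
    compensatory_prob: float = 1.0        # stem mutations preserve pairing
    # character accretion-drift model
    n_characters: int = 40
    k_states: int = 24
    drift_per_edge: float = 1.0           # mean state increase per edge once active
    drift_sd: float = 0.5                 # spread of heritable increments
    drift_noise_sd: float = 0.25          # leaf measurement noise (low-noise condition)
    # accretion / census model
    birth_prob: float = 0.75              # domain birth probability per node
    growth_factor: float = 1.5            # abundance growth per edge
    noise_sigma: float = 0.2              # lognormal sigma (log-growth ~2x noise)
    initial_abundance: float = 1.0
    root_age_gy: float = 3.8              # age assigned to root-born domains

    def __post_init__(self) -> None:
        for p in (self.substitution_prob, self.compensatory_prob, self.birth_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.growth_factor < 1.0:
            raise ValueError("growth factor must be >= 1")


def scaffold_structure() -> SecondaryStructure:
    return parse_dotbracket(SCAFFOLD_SEQUENCE, SCAFFOLD_STRUCTURE, name="scaffold")


# ---------------------------------------------------------------------------
# Reference trees
# ---------------------------------------------------------------------------

def simulate_reference_tree(
    n_taxa: int, seed: int, prefix: str = "T"
) -> Tree:
    """Random rooted binary tree over ``n_taxa`` labelled leaves.

    Uniform sequential edge attachment; deterministic per seed.  Labels are
    ``T001, T002, ...``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    from .parsimony import random_rooted_tree

    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1:03d}" for i in range(n_taxa)]
    return random_rooted_tree(labels, rng)


# ---------------------------------------------------------------------------
# tRNA family evolution
# ---------------------------------------------------------------------------

def evolve_trna_family(
    tree: Tree, cfg: SimulationConfig | None = None
) -> dict[str, str]:
    """Evolve the scaffold along the tree; returns leaf name -> sequence.

    Substitutions hit each site independently per edge.  A substitution at
    a stem position is compensatory with probability
    ``cfg.compensatory_prob``: the site changes and its partner follows to
    restore Watson-Crick pairing, so the cloverleaf survives.  Loop
    substitutions are uniform over the three alternative bases.  No indels
    are introduced, keeping the template numbering valid.
    """
    cfg = cfg or SimulationConfig()
    scaffold = scaffold_structure()
    try:
        decompose_cloverleaf(scaffold)
    except StructureError as exc:  # pragma: no cover - scaffold is fixed
        raise ValueError(f"scaffold fails cloverleaf decomposition: {exc}")
    rng = np.random.default_rng(cfg.seed)
    partner: dict[int, int] = {}
    for i, j in scaffold.pairs:
        partner[i] = j
        partner[j] = i

    def mutate(seq: list[str]) -> list[str]:
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < cfg.substitution_prob)[0]
        for pos0 in hits:
            pos = int(pos0) + 1
            old = out[pos0]
            alts = [b for b in _BASES if b != old]
            new = alts[rng.integers(3)]
            out[pos0] = new
            if pos in partner and rng.random() < cfg.compensatory_prob:
                out[partner[pos] - 1] = _WC[new]
        return out

    result: dict[str, str] = {}

    def rec(x: Tree, seq: list[str]) -> None:
        if is_leaf(x):
            result[x] = "".join(seq)
            return
        for child in x:
            rec(child, mutate(seq))

    rec(tree, list(SCAFFOLD_SEQUENCE))
    return result


# ---------------------------------------------------------------------------
# Ordered-character drift (direct recovery experiments)
# ---------------------------------------------------------------------------

def simulate_character_drift(
    tree: Tree, cfg: SimulationConfig | None = None
) -> CharacterMatrix:
    """Ordered characters accreting and drifting toward higher states.

    Each character *activates* at a node drawn uniformly from the tree
    (root, internal nodes and leaves alike): outside the activation clade
    the character keeps the ancestral state 0, inside it the state
    increases by ``round(N(drift, drift_sd))`` per edge (negative draws
    model reversals), clamped to ``0..k-1``.  Leaves finally receive
    non-heritable measurement noise ``round(N(0, noise))``.

    This is the generality-criterion picture that justifies ancestor
    rooting: conformational order is gained clade-wise as structures
    canalise, so primitive lineages genuinely retain low states and the
    all-zero hypothetical ancestor attaches at the base.  Activations at
    internal nodes are the shared-derived characters carrying the
    topological signal; the matching ancestral polarity is state 0 for
    every character.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    k, nchar = cfg.k_states, cfg.n_characters

    n_nodes = _count_nodes(tree)
    activation_node = rng.integers(0, n_nodes, size=nchar)
    states: dict[str, np.ndarray] = {}
    counter = [0]

    def rec(x: Tree, cur: np.ndarray, active: np.ndarray) -> None:
        my_id = counter[0]
        active = active | (activation_node == my_id)
        if is_leaf(x):
            noise = np.round(rng.normal(0.0, cfg.drift_noise_sd, nchar)).astype(int)
            states[x] = np.clip(cur + noise, 0, k - 1)
            return
        for child in x:
            counter[0] += 1
            step = np.round(rng.normal(cfg.drift_per_edge, cfg.drift_sd, nchar)).astype(int)
            rec(child, np.clip(cur + np.where(active, step, 0), 0, k - 1), active)

    rec(tree, np.zeros(nchar, dtype=int), np.zeros(nchar, dtype=bool))
    taxa = tuple(sorted(states))
    chars = tuple(f"c{i + 1:03d}" for i in range(nchar))
    mat = np.vstack([states[t] for t in taxa])
    return CharacterMatrix(
        taxa=taxa,
        characters=chars,
        states=mat,
        k=k,
        uninformative=tuple(bool(len(np.unique(mat[:, c])) <= 1) for c in range(nchar)),
        polarity={c: 0 for c in chars},
    )


def _count_nodes(tree: Tree) -> int:
    if is_leaf(tree):
        return 1
    return 1 + sum(_count_nodes(c) for c in tree)


# ---------------------------------------------------------------------------
# Domain-abundance census (accretion process)
# ---------------------------------------------------------------------------

@dataclass
class CensusTruth:
    """Census with the ground truth needed to score reconstructions."""

    census: pd.DataFrame                     # domains x proteomes
    ages: dict[str, float]                   # true age (Gy) per domain
    birth_order: dict[str, int]              # 0 = oldest (root-born)
    interactions: list[InteractionRecord]    # faithful domain-substructure map


def simulate_domain_census(
    tree: Tree, cfg: SimulationConfig | None = None
) -> CensusTruth:
    """Accretion process along the tree: each node may birth one domain.

    The root always births the first domain, so at least one domain is
    present in every proteome.  Abundance starts at
    ``cfg.initial_abundance`` and is multiplied by
    ``growth_factor * LogNormal(0, sigma)`` along every edge below the
    birth node.  Leaves are proteomes; the census holds rounded integer
    counts.  True ages decrease linearly with the birth node's depth, from
    ``root_age_gy`` at the root to 0 at the deepest node; the faithful
    interaction map pairs the five cloverleaf regions with domains in true
    age order (acceptor oldest, anticodon arm youngest).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # enumerate internal nodes in preorder with depths
    nodes: list[tuple[int, int]] = [(0, 0)]  # (node id, depth)
    node_children: dict[int, list[tuple[int, Tree]]] = {}
    counter = [0]

    def index(x: Tree, my_id: int, depth: int) -> None:
        node_children[my_id] = []
        if is_leaf(x):
            return
        for child in x:
            counter[0] += 1
            cid = counter[0]
            nodes.append((cid, depth + 1))
            node_children[my_id].append((cid, child))
            index(child, cid, depth + 1)

    index(tree, 0, 0)
    leaf_of_node: dict[int, str] = {}

    def map_leaves(x: Tree, my_id: int) -> None:
        if is_leaf(x):
            leaf_of_node[my_id] = x
            return
        for cid, child in node_children[my_id]:
            map_leaves(child, cid)

    map_leaves(tree, 0)

    depth_of = dict(nodes)
    max_depth = max(depth_of.values()) or 1
    births: list[tuple[str, int]] = []  # (domain, birth node)
    d_idx = 0
    for nid, _depth in nodes:
        if nid == 0 or rng.random() < cfg.birth_prob:
            d_idx += 1
            births.append((f"D{d_idx:03d}", nid))

    proteomes = sorted(leaves(tree))
    counts = pd.DataFrame(
        0, index=[d for d, _ in births], columns=proteomes, dtype=int
    )

    def descend(nid: int, x: Tree, abundances: dict[str, float]) -> None:
        # domains born at this node start accumulating here
        for d, b in births:
            if b == nid:
                abundances = {**abundances, d: cfg.initial_abundance}
        if is_leaf(x):
            for d, a in abundances.items():
                counts.loc[d, x] = max(1, int(round(a)))
            return
        for cid, child in node_children[nid]:
            grown = {
                d: a
                * cfg.growth_factor
                * rng.lognormal(mean=0.0, sigma=cfg.noise_sigma)
                for d, a in abundances.items()
            }
            descend(cid, child, grown)

    descend(0, tree, {})

    ages = {
        d: cfg.root_age_gy * (1.0 - depth_of[b] / max_depth) for d, b in births
    }
    birth_order = {d: i for i, (d, _) in enumerate(births)}

    # faithful interaction map: oldest domains partner the oldest regions
    region_order = ["acceptor", "t_arm", "d_arm", "variable_loop", "anticodon_arm"]
    by_age = sorted(ages, key=lambda d: -ages[d])
    interactions = [
        InteractionRecord(domain=by_age[i % len(by_age)], substructure=region)
        for i, region in enumerate(region_order)
        if by_age
    ]
    return CensusTruth(
        census=counts, ages=ages, birth_order=birth_order, interactions=interactions
    )
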