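"""Boltzmann-ensemble statistics of RNA secondary structure.

The module computes, for each sequence, the base-pairing probability matrix
(from a partition function over all nested canonical structures), a
minimum-free-energy structure, and the three morphospace statistics used as
phylogenetic characters:

* ``Q`` — Shannon entropy of the base-pairing probability matrix, in bits
  per nucleotide.  A sharp ensemble (one dominant structure) has Q near 0; a
  diffuse, conformationally disordered ensemble has large Q.
* ``P`` — base-pairing propensity: the fraction of nucleotides paired in the
  MFE structure.
* ``S`` — mean stem length: average number of stacked pairs per helix of
  the MFE structure.

The energy model is deliberately transparent: additive per-pair energies
(GC/AU/GU, in kT) plus a bonus per stacked adjacency and a minimum hairpin
loop length.  It is exact against brute-force enumeration, which is kept as
an oracle (``enumerate_ensemble``).  The engine is an interface: any object
with the same fields can be swapped in for a nearest-neighbour backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .structure import RNA_ALPHABET, SecondaryStructure, StructureError, find_helices

_CANONICAL = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class EnergyModel:
    """Additive pair + stacking energy model in thermal units (kT).

    ``pair_energies`` are per pair type and must be non-positive;
    ``stack`` is the bonus added for each stacked adjacency
    ``(i,j),(i+1,j-1)``; ``min_loop`` is the minimum hairpin loop length.
    """

    pair_energies: dict[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack: float = -1.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if any(e > 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be <= 0 (kT)")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing bases ``a``:``b``; None if non-canonical."""
        if (a, b) not in _CANONICAL:
            return None
        if {a, b} == {"G", "C"}:
            return self.pair_energies["GC"]
        if {a, b} == {"A", "U"}:
            return self.pair_energies["AU"]
        return self.pair_energies["GU"]


@dataclass(frozen=True)
class BasePairMatrix:
    """Ensemble pairing probabilities ``p[i,j]`` and unpaired ``q[i]``.

    Matrices are 0-based internally; ``p`` is symmetric with zero diagonal
    and ``q[i] + sum_j p[i,j] = 1`` for every position.
    """

    n: int
    p: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class StatTriple:
    """The three morphospace statistics of one sequence or region."""

    Q: float
    P: float
    S: float
    context_pairs: int = 0  # MFE pairs crossing the region boundary (diagnostic)


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise StructureError(f"invalid RNA characters: {sorted(bad)!r}")


def structure_energy(s: SecondaryStructure, model: EnergyModel) -> float:
    """Total energy: sum of pair energies plus stacking bonuses."""
    e = 0.0
    pair_set = s.pairs
    for i, j in pair_set:
        pe = model.pair_energy(s.sequence[i - 1], s.sequence[j - 1])
        if pe is None:
            raise StructureError(f"non-canonical pair at ({i},{j})")
        e += pe
        if (i + 1, j - 1) in pair_set:
            e += model.stack
    return e


# ---------------------------------------------------------------------------
# Exhaustive enumeration (oracle)
# ---------------------------------------------------------------------------

ENUMERATION_CAP = 25


def _pairable(sequence: str, model: EnergyModel) -> np.ndarray:
    n = len(sequence)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            if (sequence[i], sequence[j]) in _CANONICAL:
                ok[i, j] = True
    return ok


def enumerate_structures(
    sequence: str, model: EnergyModel
) -> Iterator[frozenset[tuple[int, int]]]:
    """Yield every nested, canonical, min_loop-respecting pair set once."""
    ok = _pairable(sequence, model)
    n = len(sequence)

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        # all structures on the closed 0-based interval [i, j]
        if i > j:
            yield ()
            return
        # case: i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # case: i paired to k
        for k in range(i + model.min_loop + 1, j + 1):
            if ok[i, k]:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i + 1, k + 1),) + inner + outer

    for pairs in rec(0, n - 1):
        yield frozenset(pairs)


def count_structures(sequence: str, model: EnergyModel) -> int:
    """Independent count of nested structures by a plain recursion."""
    ok = _pairable(sequence, model)
    n = len(sequence)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        if i > j:
            return 1
        total = c(i + 1, j)
        for k in range(i + model.min_loop + 1, j + 1):
            if ok[i, k]:
                total += c(i + 1, k - 1) * c(k + 1, j)
        return total

    return c(0, n - 1)


def enumerate_ensemble(
    sequence: str, model: EnergyModel | None = None, cap: int = ENUMERATION_CAP
) -> list[tuple[SecondaryStructure, float, float]]:
    """All structures with energies and Boltzmann weights ``exp(-E)``.

    Brute-force oracle; refuses sequences longer than ``cap`` nucleotides.
    """
    model = model or EnergyModel()
    _check_sequence(sequence)
    if len(sequence) > cap:
        raise ValueError(
            f"enumeration is an oracle for short sequences (n <= {cap}); "
            "use partition_bpp for longer inputs"
        )
    out = []
    for pairs in enumerate_structures(sequence, model):
        s = SecondaryStructure(name="", sequence=sequence, pairs=pairs)
        e = structure_energy(s, model)
        out.append((s, e, math.exp(-e)))
    return out


def bpp_by_enumeration(sequence: str, model: EnergyModel | None = None) -> BasePairMatrix:
    """Base-pairing probabilities from the exhaustive ensemble (oracle)."""
    model = model or EnergyModel()
    ensemble = enumerate_ensemble(sequence, model)
    n = len(sequence)
    z = sum(w for _, _, w in ensemble)
    p = np.zeros((n, n))
    for s, _, w in ensemble:
        for i, j in s.pairs:
            p[i - 1, j - 1] += w
    p /= z
    p = p + p.T
    q = 1.0 - p.sum(axis=1)
    return BasePairMatrix(n=n, p=p, q=q)


# ---------------------------------------------------------------------------
# Partition function (inside/outside dynamic programme)
# ---------------------------------------------------------------------------

def _pair_weights(sequence: str, model: EnergyModel) -> np.ndarray:
    """w[i,j] = exp(-E_pair) for allowed pairs, else 0 (0-based)."""
    n = len(sequence)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            e = model.pair_energy(sequence[i], sequence[j])
            if e is not None:
                w[i, j] = math.exp(-e)
    return w


def partition_bpp(sequence: str, model: EnergyModel | None = None) -> BasePairMatrix:
    """Base-pairing probability matrix from the partition function.

    Inside pass (0-based, closed intervals):

      Qb[i,j] = w[i,j] * ( Q[i+1,j-1] + (b-1) * Qb[i+1,j-1] )
      Q[i,j]  = Q[i+1,j] + sum_k Qb[i,k] * Q[k+1,j]

    where ``b = exp(-stack)`` applies when the enclosed interval is exactly
    the pair ``(i+1, j-1)`` (a stacked adjacency).  Outside pass: the weight
    of everything surrounding a pair ``(i,j)``, accumulating over its
    innermost enclosing pair, gives ``p[i,j] = Qb[i,j] * Zout[i,j] / Q``.
    """
    model = model or EnergyModel()
    _check_sequence(sequence)
    n = len(sequence)
    p = np.zeros((n, n))
    if n == 0:
        return BasePairMatrix(n=0, p=p, q=np.zeros(0))
    w = _pair_weights(sequence, model)
    b = math.exp(-model.stack)

    # Q over closed intervals; Qfull[i][j] with empty interval = 1.
    def Q(i: int, j: int) -> float:
        if i > j:
            return 1.0
        return Qm[i, j]

    def Qb_(i: int, j: int) -> float:
        if i > j or not (0 <= i < n and 0 <= j < n):
            return 0.0
        return Qb[i, j]

    Qm = np.ones((n, n))
    Qb = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if w[i, j] > 0.0:
                Qb[i, j] = w[i, j] * (Q(i + 1, j - 1) + (b - 1.0) * Qb_(i + 1, j - 1))
            total = Q(i + 1, j)
            for k in range(i + model.min_loop + 1, j + 1):
                if Qb[i, k] > 0.0:
                    total += Qb[i, k] * Q(k + 1, j)
            Qm[i, j] = total
    Z = Q(0, n - 1)

    # Outside: process pairs by decreasing span.  T[k,l] accumulates
    # Zout[k,l] * w[k,l] for already-processed (larger-span) pairs.
    pairs_by_span = sorted(
        ((i, j) for i in range(n) for j in range(n) if w[i, j] > 0.0),
        key=lambda ij: ij[1] - ij[0],
        reverse=True,
    )
    T = np.zeros((n, n))
    # Qleft[k][i] = Q(k+1, i-1); precompute helper closure
    for i, j in pairs_by_span:
        zout = Q(0, i - 1) * Q(j + 1, n - 1)
        if i > 0 and j < n - 1:
            # sum over enclosing pairs (k,l), k<i, l>j:
            #   T[k,l] * Q(k+1, i-1) * Q(j+1, l-1)
            u = np.array([Q(k + 1, i - 1) for k in range(i)])
            v = np.array([Q(j + 1, l - 1) for l in range(j + 1, n)])
            M = T[:i, j + 1 :]
            if M.any():
                zout += float(u @ M @ v)
                # stacked enclosing pair gets the bonus instead of weight 1
                if T[i - 1, j + 1] > 0.0:
                    zout += (b - 1.0) * T[i - 1, j + 1]
        T[i, j] = zout * w[i, j]
        p[i, j] = Qb[i, j] * zout / Z

    p = p + p.T
    q = 1.0 - p.sum(axis=1)
    return BasePairMatrix(n=n, p=p, q=q)


# ---------------------------------------------------------------------------
# Minimum-free-energy structure
# ---------------------------------------------------------------------------

_INF = (math.inf, math.inf)


def _add(a: tuple[float, float], b: tuple[float, float]) -> tuple[float, float]:
    return (a[0] + b[0], a[1] + b[1])


def mfe_structure(
    sequence: str, model: EnergyModel | None = None, name: str = ""
) -> SecondaryStructure:
    """A minimum-energy structure with deterministic tie-breaking.

    The DP optimises the tuple ``(energy, pair count)`` lexicographically,
    so among minimum-energy structures one with fewest pairs is returned;
    the traceback then prefers pairing the leftmost position to its
    smallest admissible partner, which selects the lexicographically
    smallest pair set among the remaining ties.
    """
    model = model or EnergyModel()
    _check_sequence(sequence)
    n = len(sequence)
    if n == 0:
        return SecondaryStructure(name=name, sequence=sequence, pairs=frozenset())
    w_ok = _pair_weights(sequence, model) > 0.0
    pe = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if w_ok[i, j]:
                e = model.pair_energy(sequence[i], sequence[j])
                pe[i, j] = e if e is not None else 0.0

    V: dict[tuple[int, int], tuple[float, float]] = {}
    Vb: dict[tuple[int, int], tuple[float, float]] = {}

    def getV(i: int, j: int) -> tuple[float, float]:
        if i > j:
            return (0.0, 0.0)
        return V[(i, j)]

    def getVb(i: int, j: int) -> tuple[float, float]:
        if i > j or not w_ok[i, j]:
            return _INF
        return Vb[(i, j)]

    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            if w_ok[i, j]:
                base = (pe[i, j], 1.0)
                # interior where (i+1, j-1) is NOT paired together
                cand = _add(base, _vnb(i + 1, j - 1, getV, getVb, w_ok, model))
                inner = getVb(i + 1, j - 1)
                if inner is not _INF and math.isfinite(inner[0]):
                    stacked = _add(_add(base, (model.stack, 0.0)), inner)
                    cand = min(cand, stacked)
                Vb[(i, j)] = cand
            best = getV(i + 1, j)
            for k in range(i + model.min_loop + 1, j + 1):
                if w_ok[i, k]:
                    c = _add(getVb(i, k), getV(k + 1, j))
                    if c < best:
                        best = c
            V[(i, j)] = best

    pairs: set[tuple[int, int]] = set()

    def trace_V(i: int, j: int) -> None:
        # Reconstruct an optimum of V[i,j], preferring to pair the leftmost
        # position to its smallest admissible partner (lex-smallest pairs).
        while i <= j:
            target = getV(i, j)
            chosen = None
            for k in range(i + model.min_loop + 1, j + 1):
                if w_ok[i, k] and _close(_add(getVb(i, k), getV(k + 1, j)), target):
                    chosen = k
                    break
            if chosen is None:
                i += 1  # i unpaired; V[i,j] == V[i+1,j]
            else:
                trace_Vb(i, chosen)
                i = chosen + 1

    def trace_Vb(i: int, j: int) -> None:
        pairs.add((i + 1, j + 1))
        target = _sub(Vb[(i, j)], (pe[i, j], 1.0))
        l, r = i + 1, j - 1
        if l > r:
            return
        # Ascending k keeps the pair set lexicographically smallest; the
        # full-span stacked pair (l,r) is naturally the last k tried.
        for k in range(l + model.min_loop + 1, r + 1):
            if not w_ok[l, k]:
                continue
            if k < r:
                c = _add(getVb(l, k), getV(k + 1, r))
            else:
                c = _add((model.stack, 0.0), getVb(l, r))
            if _close(c, target):
                if k < r:
                    trace_Vb(l, k)
                    trace_V(k + 1, r)
                else:
                    trace_Vb(l, r)
                return
        trace_V(l + 1, r)  # l unpaired inside the loop

    trace_V(0, n - 1)
    return SecondaryStructure(name=name, sequence=sequence, pairs=frozenset(pairs))


def _vnb(l, r, getV, getVb, w_ok, model) -> tuple[float, float]:
    """Best (energy, npairs) over interval [l,r] with (l,r) not paired together."""
    if l > r:
        return (0.0, 0.0)
    best = getV(l + 1, r)
    for k in range(l + model.min_loop + 1, r):
        if w_ok[l, k]:
            c = _add(getVb(l, k), getV(k + 1, r))
            if c < best:
                best = c
    return best


def _sub(a: tuple[float, float], b: tuple[float, float]) -> tuple[float, float]:
    return (a[0] - b[0], a[1] - b[1])


def _close(a: tuple[float, float], b: tuple[float, float], tol: float = 1e-9) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


# ---------------------------------------------------------------------------
# Morphospace statistics
# ---------------------------------------------------------------------------

def _xlog2x(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out


def ensemble_entropy(bpm: BasePairMatrix, indices: set[int] | None = None) -> float:
    """Shannon entropy of the pairing matrix, bits per nucleotide.

    ``Q = -(1/n) [ sum_{i<j} p_ij log2 p_ij + sum_i q_i log2 q_i ]`` with
    the convention ``0 log 0 = 0``.  With ``indices`` (1-based) the sums are
    restricted to positions inside the region; pairs crossing the boundary
    are excluded.
    """
    if bpm.n == 0:
        return 0.0
    if indices is None:
        iu = np.triu_indices(bpm.n, k=1)
        pair_term = float(_xlog2x(bpm.p[iu]).sum())
        unpaired_term = float(_xlog2x(bpm.q).sum())
        n_eff = bpm.n
    else:
        idx = sorted(i - 1 for i in indices)
        pair_term = 0.0
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 :]:
                pair_term += float(_xlog2x(np.array([bpm.p[a, b]]))[0])
        unpaired_term = float(_xlog2x(bpm.q[idx]).sum())
        n_eff = len(idx)
    if n_eff == 0:
        return 0.0
    return max(0.0, -(pair_term + unpaired_term) / n_eff)


def pairing_propensity(
    s: SecondaryStructure, indices: set[int] | None = None
) -> tuple[float, int]:
    """Fraction of positions paired (within the region); returns (P, crossing)."""
    if indices is None:
        indices = set(range(1, s.n + 1))
    inside = {(i, j) for i, j in s.pairs if i in indices and j in indices}
    crossing = sum(
        1 for i, j in s.pairs if (i in indices) != (j in indices)
    )
    paired = len(inside) * 2
    return (paired / len(indices) if indices else 0.0, crossing)


def mean_stem_length(s: SecondaryStructure, indices: set[int] | None = None) -> float:
    """Mean helix length (pairs per maximal stacked run); 0 when unpaired."""
    if indices is not None:
        sub = SecondaryStructure(
            name=s.name,
            sequence=s.sequence,
            pairs=frozenset((i, j) for i, j in s.pairs if i in indices and j in indices),
        )
    else:
        sub = s
    helices = find_helices(sub)
    if not helices:
        return 0.0
    return sum(h.length for h in helices) / len(helices)


def morphospace_stats(
    sequence: str,
    model: EnergyModel | None = None,
    indices: set[int] | None = None,
    bpm: BasePairMatrix | None = None,
    mfe: SecondaryStructure | None = None,
) -> StatTriple:
    """Compute the (Q, P, S) statistic triple for a sequence or region.

    ``bpm``/``mfe`` may be passed in to avoid refolding when several regions
    of one molecule are scored.
    """
    model = model or EnergyModel()
    if bpm is None:
        bpm = partition_bpp(sequence, model)
    if mfe is None:
        mfe = mfe_structure(sequence, model)
    q = ensemble_entropy(bpm, indices)
    p, crossing = pairing_propensity(mfe, indices)
    s = mean_stem_length(mfe, indices)
    return StatTriple(Q=q, P=p, S=s, context_pairs=crossing)
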