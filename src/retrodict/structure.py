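"""RNA secondary structures, dot-bracket I/O, and cloverleaf decomposition.

Coordinates are 1-based and ranges are closed on both ends throughout,
matching the biological tRNA numbering convention.  Structures are nested
(pseudoknot-free); pseudoknotted inputs are rejected rather than silently
pruned, because every downstream ensemble statistic assumes nestedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

RNA_ALPHABET = frozenset("ACGU")

#: Canonical tRNA cloverleaf coordinates on a 76-nt numbering.  Each region
#: maps to one or more closed 1-based ranges; the acceptor stem is split
#: between the 5' and 3' ends of the molecule.
DEFAULT_TEMPLATE_REGIONS: dict[str, tuple[tuple[int, int], ...]] = {
    "acceptor": ((1, 7), (66, 72)),
    "d_arm": ((10, 25),),
    "anticodon_arm": ((27, 43),),
    "variable_loop": ((44, 48),),
    "t_arm": ((49, 65),),
}

CANONICAL_REGIONS = ("acceptor", "d_arm", "anticodon_arm", "variable_loop", "t_arm")

#: Variable loops longer than this many nucleotides mark a type II tRNA.
TYPE_II_THRESHOLD = 10


class StructureError(ValueError):
    """Raised for malformed structures or inconsistent inputs."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence with a nested set of base pairs.

    Parameters
    ----------
    name:
        Label carried through to writers.
    sequence:
        RNA string over ``{A, C, G, U}``.
    pairs:
        1-based ``(i, j)`` pairs with ``i < j``.
    """

    name: str
    sequence: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise StructureError(f"invalid RNA characters: {sorted(bad)!r}")
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise StructureError(f"pair ({i},{j}) out of bounds for length {n}")
            if i in seen or j in seen:
                raise StructureError(f"index reused across pairs near ({i},{j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1 :]:
                if k >= j:
                    break
                if k > i and l > j:
                    raise StructureError(
                        f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross"
                    )

    @property
    def n(self) -> int:
        return len(self.sequence)

    def to_dotbracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def paired_indices(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.update((i, j))
        return out


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs (i,j), (i+1,j-1), ..."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CloverleafTemplate:
    """Index ranges assigning cloverleaf regions on a canonical numbering.

    ``regions`` maps each of the five canonical region names to closed
    1-based ranges; ``anticodon`` gives the anticodon triplet positions.
    """

    regions: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_REGIONS)
    )
    anticodon: tuple[int, int, int] = (34, 35, 36)
    type_ii_threshold: int = TYPE_II_THRESHOLD

    def __post_init__(self) -> None:
        names = set(self.regions)
        if names != set(CANONICAL_REGIONS):
            raise StructureError(
                f"template regions must be exactly {CANONICAL_REGIONS}, got {sorted(names)}"
            )
        covered: set[int] = set()
        for name, ranges in self.regions.items():
            for lo, hi in ranges:
                if lo > hi or lo < 1:
                    raise StructureError(f"bad range ({lo},{hi}) for region {name}")
                span = set(range(lo, hi + 1))
                if covered & span:
                    raise StructureError(f"region {name} overlaps another region")
                covered |= span

    def max_index(self) -> int:
        return max(hi for ranges in self.regions.values() for _, hi in ranges)

    def indices(self, region: str) -> set[int]:
        return {
            x for lo, hi in self.regions[region] for x in range(lo, hi + 1)
        }


@dataclass(frozen=True)
class SubstructureSet:
    """Cloverleaf regions of one molecule with presence/type flags."""

    regions: Mapping[str, tuple[tuple[int, int], ...]]
    present: Mapping[str, bool]
    type_ii: bool


# ---------------------------------------------------------------------------
# Parsing and writing
# ---------------------------------------------------------------------------

def parse_dotbracket(sequence: str, structure: str, name: str = "") -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises :class:`StructureError` on length mismatch, characters outside
    ``.()`` or unbalanced brackets.
    """
    if len(sequence) != len(structure):
        raise StructureError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    if not set(structure) <= {".", "(", ")"}:
        raise StructureError("structure may contain only '.', '(' and ')'")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(name=name, sequence=sequence, pairs=frozenset(pairs))


def write_vienna(structures: Iterable[SecondaryStructure]) -> str:
    """Vienna-style records: ``>name`` / sequence / dot-bracket, LF endings."""
    lines: list[str] = []
    for s in structures:
        lines.append(f">{s.name}")
        lines.append(s.sequence)
        lines.append(s.to_dotbracket())
    return "\n".join(lines) + "\n"


def read_vienna(text: str) -> list[SecondaryStructure]:
    records: list[SecondaryStructure] = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise StructureError("truncated Vienna record")
        name, seq, db = lines[i][1:], lines[i + 1], lines[i + 2]
        records.append(parse_dotbracket(seq, db, name=name))
        i += 3
    return records


def write_fasta(sequences: Mapping[str, str]) -> str:
    import io

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    buf = io.StringIO()
    seqio_write(
        (SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()),
        buf,
        "fasta",
    )
    return buf.getvalue()


def read_fasta(text: str) -> dict[str, str]:
    import io

    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq) for rec in seqio_parse(io.StringIO(text), "fasta")}


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def find_helices(s: SecondaryStructure) -> list[Helix]:
    """Split the pair set into maximal stacked runs.

    Every pair belongs to exactly one helix; a helix extends while the next
    pair inward is ``(i+1, j-1)``.
    """
    remaining = sorted(s.pairs)
    pair_set = set(remaining)
    helices: list[Helix] = []
    used: set[tuple[int, int]] = set()
    for i, j in remaining:
        if (i, j) in used:
            continue
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its run
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        used.update(run)
        helices.append(Helix(pairs=tuple(run)))
    return helices


def decompose_cloverleaf(
    s: SecondaryStructure, template: CloverleafTemplate | None = None
) -> SubstructureSet:
    """Assign a structure's pairs to cloverleaf regions via a template.

    A region is *present* when at least one pair lies entirely inside its
    index ranges.  The variable loop is additionally classified type II when
    its template span exceeds the template's length threshold (long variable
    loops mark serine/leucine-type cognate tRNAs).
    """
    template = template or CloverleafTemplate()
    if template.max_index() > s.n:
        raise StructureError(
            f"template spans position {template.max_index()} but sequence has {s.n} nt"
        )
    present: dict[str, bool] = {}
    for region in CANONICAL_REGIONS:
        idx = template.indices(region)
        present[region] = any(i in idx and j in idx for i, j in s.pairs)
    vl_len = sum(
        hi - lo + 1 for lo, hi in template.regions["variable_loop"]
    )
    return SubstructureSet(
        regions={r: template.regions[r] for r in CANONICAL_REGIONS},
        present=present,
        type_ii=vl_len > template.type_ii_threshold,
    )
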