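"""Ordered multistate character matrices from continuous statistics.

Continuous morphospace statistics (or genomic abundance counts) are binned
into k linearly ordered states; matrices can be transposed (molecules as
taxa vs substructures as taxa) and receive a hypothetical ancestor row that
polarizes character change and roots the parsimony trees (Lundberg
rooting).  Polarization follows the convention that conformational order
increases in evolution: entropy-like characters are maximal in the
ancestor, order-like characters (pairing propensity, stem length) minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Parsimony state alphabet: 24 states written 0-9 then A-N.
STATE_SYMBOLS = "0123456789ABCDEFGHIJKLMN"
MAX_STATES = len(STATE_SYMBOLS)
DEFAULT_K = 24

ANCESTOR_LABEL = "ANC"

#: Which extreme of each statistic is ancestral under the
#: order-increases-in-evolution model.  "max" = highest state ancestral.
STAT_POLARITY: dict[str, str] = {"Q": "max", "P": "min", "S": "min"}

#: Ancestral convention for genomic-abundance characters.  The most
#: abundant, most widely spread domains are taken as the most ancient,
#: so the hypothetical ancestor carries the maximal state.  The opposite
#: convention is available via ``polarity="min"`` in :func:`code_abundance`
#: ancestor attachment; results should always report which was used.
ABUNDANCE_POLARITY_DEFAULT = "max"


class CodingError(ValueError):
    """Raised for invalid values, shapes or polarity configuration."""


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x ordered-multistate characters.

    ``states`` holds integers in ``0..k-1``; ``uninformative`` flags
    zero-range characters that are retained so matrix dimensions match the
    input; ``polarity`` maps each character to its ancestral state.
    """

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    states: np.ndarray
    k: int
    ordered: bool = True
    uninformative: tuple[bool, ...] = ()
    polarity: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.k > MAX_STATES or self.k < 2:
            raise CodingError(f"k must be in 2..{MAX_STATES}")
        st = np.asarray(self.states)
        if st.shape != (len(self.taxa), len(self.characters)):
            raise CodingError(
                f"state matrix shape {st.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if st.size and (st.min() < 0 or st.max() > self.k - 1):
            raise CodingError("state out of range 0..k-1")

    @property
    def has_ancestor(self) -> bool:
        return ANCESTOR_LABEL in self.taxa

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def transpose(self) -> "CharacterMatrix":
        """Swap taxa and characters (an involution, cell-preserving)."""
        if self.has_ancestor:
            raise CodingError("transpose the matrix before attaching the ancestor")
        return CharacterMatrix(
            taxa=self.characters,
            characters=self.taxa,
            states=self.states.T.copy(),
            k=self.k,
            ordered=self.ordered,
            uninformative=tuple(
                bool(len(set(col)) <= 1) for col in self.states
            ),
            polarity=None,
        )

    def drop_taxon(self, taxon: str) -> "CharacterMatrix":
        idx = [t for t in self.taxa if t != taxon]
        rows = [self.taxa.index(t) for t in idx]
        return replace(self, taxa=tuple(idx), states=self.states[rows])


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(values: Sequence[float], k: int = DEFAULT_K) -> tuple[np.ndarray, bool]:
    """Bin real values into ``k`` equal-width ordered states over [min, max].

    Values exactly on a bin boundary go to the lower state.  Returns the
    state vector and an *uninformative* flag (True for constant columns,
    which map to state 0).
    """
    if k < 2:
        raise CodingError("k must be >= 2")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CodingError("non-finite value in character column")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(len(arr), dtype=int), True
    t = (arr - lo) / (hi - lo)
    states = np.ceil(t * k).astype(int) - 1
    states = np.clip(states, 0, k - 1)
    return states, False


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def build_matrix(
    stats: pd.DataFrame,
    mode: str = "ToM",
    k: int = DEFAULT_K,
    stat: str | None = None,
) -> CharacterMatrix:
    """Build a character matrix from a long-format statistics table.

    ``stats`` must have columns ``name`` (molecule), ``region``, ``stat``
    and ``value``.  In ``ToM`` mode taxa are molecules and characters are
    region:stat combinations; in ``ToS`` mode the matrix is transposed so
    taxa are substructure regions.  ``stat`` restricts the table to one
    statistic (required shape for a classic substructure tree).
    """
    required = {"name", "region", "stat", "value"}
    if not required <= set(stats.columns):
        raise CodingError(f"stats table must have columns {sorted(required)}")
    if mode not in ("ToM", "ToS"):
        raise CodingError(f"mode must be ToM or ToS, got {mode!r}")
    df = stats if stat is None else stats[stats["stat"] == stat]
    if df.empty:
        raise CodingError(f"no rows for stat {stat!r}")
    wide = df.pivot_table(
        index="name", columns=["region", "stat"], values="value", aggfunc="first"
    )
    if wide.isna().any().any():
        missing = [
            f"{m}/{r}:{s}"
            for (r, s) in wide.columns
            for m in wide.index[wide[(r, s)].isna()]
        ]
        raise CodingError(f"missing cells: {missing}")
    char_labels = tuple(f"{r}:{s}" for r, s in wide.columns)
    char_stats = tuple(s for _, s in wide.columns)
    if mode == "ToS":
        # taxa are regions (region:stat labels when several stats kept)
        mat = wide.to_numpy().T
        taxa = char_labels
        characters = tuple(str(m) for m in wide.index)
        col_stats = tuple(None for _ in characters)
    else:
        mat = wide.to_numpy()
        taxa = tuple(str(m) for m in wide.index)
        characters = char_labels
        col_stats = char_stats

    states = np.zeros(mat.shape, dtype=int)
    flags: list[bool] = []
    for c in range(mat.shape[1]):
        col, flag = discretize(mat[:, c], k)
        states[:, c] = col
        flags.append(flag)

    if mode == "ToS":
        # every character derives from the single selected statistic
        if stat in STAT_POLARITY:
            anc = _ancestral_state(STAT_POLARITY[stat], k)
            polarity = {ch: anc for ch in characters}
        else:
            polarity = None
    else:
        if all(st_ in STAT_POLARITY for st_ in col_stats):
            polarity = {
                ch: _ancestral_state(STAT_POLARITY[st_], k)
                for ch, st_ in zip(characters, col_stats)
            }
        else:
            polarity = None
    return CharacterMatrix(
        taxa=taxa,
        characters=characters,
        states=states,
        k=k,
        uninformative=tuple(flags),
        polarity=polarity,
    )


def _ancestral_state(direction: str | None, k: int) -> int:
    if direction == "max":
        return k - 1
    if direction == "min":
        return 0
    raise CodingError("undefined polarity")


def attach_ancestor(
    m: CharacterMatrix, polarity: Mapping[str, int] | None = None
) -> CharacterMatrix:
    """Append the hypothetical ancestor row ANC carrying polarized states.

    ``polarity`` maps character label to ancestral state; it defaults to
    the matrix's own polarity annotation.  Entropy-derived characters are
    ancestrally maximal (disorder), propensity/stem-length characters
    ancestrally minimal.
    """
    if m.has_ancestor:
        raise CodingError(f"matrix already contains a taxon named {ANCESTOR_LABEL}")
    pol = polarity if polarity is not None else m.polarity
    if pol is None:
        raise CodingError("no polarity defined; supply ancestral states per character")
    missing = [c for c in m.characters if c not in pol]
    if missing:
        raise CodingError(f"polarity undefined for characters: {missing}")
    anc = np.array([pol[c] for c in m.characters], dtype=int)
    if anc.size and (anc.min() < 0 or anc.max() > m.k - 1):
        raise CodingError("ancestral state out of range")
    return CharacterMatrix(
        taxa=m.taxa + (ANCESTOR_LABEL,),
        characters=m.characters,
        states=np.vstack([m.states, anc[None, :]]),
        k=m.k,
        ordered=m.ordered,
        uninformative=m.uninformative,
        polarity=dict(pol),
    )


def code_abundance(
    census: pd.DataFrame,
    k: int = DEFAULT_K,
    polarity: str = ABUNDANCE_POLARITY_DEFAULT,
) -> CharacterMatrix:
    """Code a domain x proteome abundance census into ordered states.

    State for count ``g`` in a proteome with column maximum ``g_max`` is
    ``round_half_up((k-1) * ln(g+1) / ln(g_max+1))``; the logarithm
    compresses the heavy-tailed abundance distribution so states spread
    across the whole ordered series.  Taxa are domains, characters are
    proteomes.
    """
    counts = census.to_numpy()
    if counts.size and (counts < 0).any():
        raise CodingError("negative abundance count")
    if not np.allclose(counts, np.round(counts)):
        raise CodingError("abundance counts must be integers")
    counts = counts.astype(float)
    states = np.zeros(counts.shape, dtype=int)
    flags: list[bool] = []
    for c in range(counts.shape[1]):
        gmax = counts[:, c].max() if counts.shape[0] else 0.0
        if gmax <= 0:
            flags.append(True)
            continue
        states[:, c] = _round_half_up(
            (k - 1) * np.log(counts[:, c] + 1.0) / math.log(gmax + 1.0)
        )
        flags.append(len(np.unique(states[:, c])) <= 1)
    anc_state = _ancestral_state(polarity, k)
    characters = tuple(str(c) for c in census.columns)
    return CharacterMatrix(
        taxa=tuple(str(t) for t in census.index),
        characters=characters,
        states=states,
        k=k,
        uninformative=tuple(flags),
        polarity={ch: anc_state for ch in characters},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_census_tsv(path_or_buf) -> pd.DataFrame:
    """Census TSV: header row = proteome labels, first column = domains."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    return df


def to_nexus(m: CharacterMatrix) -> str:
    """NEXUS DATA block with ordered (Wagner) characters.

    States use symbols 0-9A-N; the ancestor, when present, is written as an
    ordinary taxon; an ASSUMPTIONS block declares every character ORD.
    """
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(
        f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.characters)};"
    )
    lines.append(
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{STATE_SYMBOLS[: m.k]}" MISSING=? GAP=-;'
    )
    lines.append("  MATRIX")
    width = max(len(t) for t in m.taxa) + 2
    for t, row in zip(m.taxa, m.states):
        codes = "".join(STATE_SYMBOLS[s] for s in row)
        lines.append(f"    {t:<{width}}{codes}")
    lines.append("  ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN ASSUMPTIONS;")
    lines.append(f"  TYPESET * wagner = ORD: 1-{len(m.characters)};")
    lines.append("END;")
    return "\n".join(lines) + "\n"
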