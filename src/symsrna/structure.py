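"""Compensatory basepair changes and shared pairs in consensus structures.

A consensus base pair of an aligned sRNA region is *compensatory* when at
least two distinct canonical pair types (AU, UA, GC, CG, GU, UG) are
realized across the aligned sequences — joint substitution of both
partners that preserves pairing, the classic evidence that a structure
is under selection.  Rows gapped at either partner are ignored; pairs
with no canonical realization at all are reported separately as
inconsistent rather than counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import DotBracketStructure

logger = logging.getLogger(__name__)

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
_GAPS = frozenset("-.")


@dataclass(frozen=True)
class StructureAlignment:
    """≥2 equal-length aligned RNA sequences plus a consensus structure."""

    sequences: tuple[str, ...]
    consensus: DotBracketStructure

    def __post_init__(self) -> None:
        seqs = tuple(s.upper().replace("T", "U") for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if len(seqs) < 2:
            raise ValueError("need at least 2 aligned sequences")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("aligned sequences must have equal length")
        if len(seqs[0]) != self.consensus.length:
            raise ValueError("alignment length must equal structure length")


@dataclass(frozen=True)
class CovariationReport:
    n_pairs: int
    n_compensatory: int
    n_inconsistent: int
    pair_classes: dict[tuple[int, int], frozenset[tuple[str, str]]]


def count_compensatory(alignment: StructureAlignment) -> CovariationReport:
    """Count consensus pairs showing ≥2 distinct canonical pair types."""
    classes: dict[tuple[int, int], frozenset[tuple[str, str]]] = {}
    n_comp = n_incons = 0
    for (i, j) in sorted(alignment.consensus.pairs):
        types = set()
        for seq in alignment.sequences:
            a, b = seq[i - 1], seq[j - 1]
            if a in _GAPS or b in _GAPS:
                continue
            if (a, b) in CANONICAL_PAIRS:
                types.add((a, b))
        classes[(i, j)] = frozenset(types)
        if len(types) >= 2:
            n_comp += 1
        elif len(types) == 0:
            n_incons += 1
    return CovariationReport(
        len(alignment.consensus.pairs), n_comp, n_incons, classes
    )


def shared_pairs(
    pairwise_structure: DotBracketStructure,
    multi_structure: DotBracketStructure,
    column_map: dict[int, int],
) -> tuple[int, float]:
    """Pairs of the pairwise structure also present (as mapped column
    pairs) in the multi-genome structure, and that count as a fraction of
    the pairwise structure's pairs (0.0 when it has none).

    ``column_map`` translates pairwise-alignment columns (1-based) to
    multi-alignment columns; unmappable columns skip the pair with a log
    message.
    """
    multi = set(multi_structure.pairs)
    shared = 0
    for (i, j) in pairwise_structure.pairs:
        if i not in column_map or j not in column_map:
            logger.info("pair (%d, %d) skipped: unmappable column", i, j)
            continue
        mi, mj = column_map[i], column_map[j]
        if (min(mi, mj), max(mi, mj)) in multi:
            shared += 1
    n = len(pairwise_structure.pairs)
    return shared, (shared / n if n else 0.0)
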