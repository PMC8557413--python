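"""Conserved-asRNA calling between two lineages and the proportion test.

Two asRNAs are called orthologous ("conserved") when, after translating
lineage A's coordinates onto lineage B through the whole-genome alignment
offset map, both the start and the end coordinates agree within a
threshold (default 15 nt) and — when per-base coverage is supplied —
every base of each transcript has continuous read coverage (depth ≥ 1 by
default).  Candidate pairs are resolved one-to-one by greedy matching on
the smallest total coordinate offset, ties broken by id, so the pairing
is deterministic.

Whether conservation exceeds expectation is assessed by a one-sided
z-proportion test comparing the conserved fraction of asRNAs with the
asRNAs-per-CDS fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OffsetMap, SrnaTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappedInterval:
    start: int
    end: int
    flipped: bool           # True when mapped through a reverse-orientation block
    straddled: bool = False  # True when the interval spanned >1 block


def map_coordinates(
    offset_map: OffsetMap,
    interval: tuple[int, int],
    direction: str = "a2b",
    min_cover_frac: float = 0.5,
) -> MappedInterval | None:
    """Translate a 1-based inclusive interval through the offset map.

    The covering block is the one overlapping the largest share of the
    interval; ``None`` when no block covers at least ``min_cover_frac`` of
    it.  Reverse-orientation blocks flip the interval (and the strand of
    whatever it carries).  An interval straddling several blocks is mapped
    via the majority block and flagged.
    """
    if direction == "b2a":
        offset_map = offset_map.inverted()
    elif direction != "a2b":
        raise ValueError(f"direction must be 'a2b' or 'b2a', got {direction!r}")
    s, e = interval
    if s > e:
        raise ValueError(f"invalid interval {interval}")
    covering = [
        (min(e, b.a_end) - max(s, b.a_start) + 1, b)
        for b in offset_map.blocks
        if b.a_start <= e and b.a_end >= s
    ]
    if not covering:
        return None
    covering.sort(key=lambda t: (-t[0], t[1].a_start))
    cover, block = covering[0]
    if cover < min_cover_frac * (e - s + 1):
        return None
    straddled = len(covering) > 1
    if straddled:
        logger.info(
            "interval %s straddles %d blocks; mapped via majority block",
            interval, len(covering),
        )
        s, e = max(s, block.a_start), min(e, block.a_end)
    if block.orientation == "+":
        ms, me = block.b_start + (s - block.a_start), block.b_start + (e - block.a_start)
        return MappedInterval(ms, me, False, straddled)
    ms = block.b_end - (e - block.a_start)
    me = block.b_end - (s - block.a_start)
    return MappedInterval(ms, me, True, straddled)


# ---------------------------------------------------------------------------
# Conserved-pair calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologPairing:
    srna_a: str
    srna_b: str
    start_offset: int
    end_offset: int
    coverage_ok_a: bool
    coverage_ok_b: bool
    verdict: str  # "conserved" | "not_conserved"


def _continuous(coverage: np.ndarray | None, start: int, end: int, min_depth: float) -> bool:
    if coverage is None:
        return True
    return bool((np.asarray(coverage)[start - 1 : end] >= min_depth).all())


def call_conserved(
    srna_table_a: SrnaTable,
    srna_table_b: SrnaTable,
    offset_map: OffsetMap,
    coverage_a: np.ndarray | None = None,
    coverage_b: np.ndarray | None = None,
    nt_threshold: int = 15,
    min_depth: float = 1.0,
    require_both_ends: bool = True,
    min_cover_frac: float = 0.5,
) -> list[OrthologPairing]:
    """Call one-to-one conserved asRNA pairs between two lineages.

    A pair qualifies iff after mapping A onto B both |Δstart| and |Δend|
    are ≤ ``nt_threshold`` (start only when ``require_both_ends`` is
    False) and both transcripts pass the coverage-continuity check.
    Qualifying candidates are paired greedily by smallest |Δstart|+|Δend|,
    ties by (srna_a, srna_b) id order; each sRNA joins at most one pair.
    """
    candidates = []
    b_rows = list(srna_table_b.df.itertuples())
    for ra in srna_table_a.df.itertuples():
        mapped = map_coordinates(
            offset_map, (ra.start, ra.end), "a2b", min_cover_frac=min_cover_frac
        )
        if mapped is None:
            continue
        for rb in b_rows:
            ds, de = abs(mapped.start - rb.start), abs(mapped.end - rb.end)
            if mapped.flipped and ra.strand == rb.strand:
                continue  # orientation flip must flip the strand too
            if not mapped.flipped and ra.strand != rb.strand:
                continue
            ok = ds <= nt_threshold and (de <= nt_threshold or not require_both_ends)
            if not ok:
                continue
            cov_a = _continuous(coverage_a, ra.start, ra.end, min_depth)
            cov_b = _continuous(coverage_b, rb.start, rb.end, min_depth)
            if not (cov_a and cov_b):
                logger.info(
                    "pair (%s, %s) rejected: coverage gap", ra.srna_id, rb.srna_id
                )
                continue
            candidates.append((ds + de, ra.srna_id, rb.srna_id, ds, de, cov_a, cov_b))

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for total, a_id, b_id, ds, de, ca, cb in candidates:
        if a_id in used_a or b_id in used_b:
            continue
        used_a.add(a_id)
        used_b.add(b_id)
        pairs.append(OrthologPairing(a_id, b_id, ds, de, ca, cb, "conserved"))
    return pairs


def pairing_report(pairs: list[OrthologPairing]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "srna_a": p.srna_a,
                "srna_b": p.srna_b,
                "start_offset": p.start_offset,
                "end_offset": p.end_offset,
                "coverage_ok_a": p.coverage_ok_a,
                "coverage_ok_b": p.coverage_ok_b,
                "verdict": p.verdict,
            }
            for p in pairs
        ],
        columns=[
            "srna_a", "srna_b", "start_offset", "end_offset",
            "coverage_ok_a", "coverage_ok_b", "verdict",
        ],
    )


# ---------------------------------------------------------------------------
# z-proportion test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionTestResult:
    p_hat: float
    p0: float
    n: int
    z: float
    p_value: float


def z_proportion_test(n_conserved: int, n_srna: int, n_cds: int) -> ProportionTestResult:
    """One-sided z-test of the conserved asRNA fraction against the
    asRNAs-per-CDS fraction.

    ``p_hat = n_conserved/n_srna`` is tested against the null proportion
    ``p0 = n_srna/n_cds`` with ``z = (p_hat - p0)/sqrt(p0(1-p0)/n_srna)``;
    the P value is the upper tail of the standard normal (no continuity
    correction).
    """
    if n_conserved > n_srna:
        raise ValueError("n_conserved exceeds n_srna")
    if n_srna <= 0 or n_cds <= 0:
        raise ValueError("n_srna and n_cds must be positive")
    p0 = n_srna / n_cds
    if p0 >= 1:
        raise ValueError(f"degenerate null proportion p0={p0:.3f} >= 1")
    p_hat = n_conserved / n_srna
    z = (p_hat - p0) / np.sqrt(p0 * (1 - p0) / n_srna)
    return ProportionTestResult(p_hat, p0, n_srna, float(z), float(stats.norm.sf(z)))
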