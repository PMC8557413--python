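"""Promoter-region composition analysis of 61-nt upstream regions.

Strand-aware extraction of the 61 nt immediately 5' of each transcript or
CDS start, 7-nt/1-nt-step sliding windows of GC percent and GC skew
((C − G)/(C + G)), a 100× mononucleotide-reshuffle permutation null with
per-window paired t-tests for GC percent, and qualitative asRNA-vs-CDS
GC-skew profile comparison.

Position convention (fixed here and used everywhere): position 1 is the
nucleotide immediately upstream of the start, position 61 the farthest
upstream.  The region string reads 5'→3' on the feature's strand, so its
*last* character is position 1.  Window ``w`` (1..55) covers positions
``w..w+6``; a 61-nt region therefore yields exactly 55 windows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeRecord, SrnaTable
from .synthetic import IUPAC

logger = logging.getLogger(__name__)

WINDOW = 7
UPSTREAM_LEN = 61

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class UpstreamRegion:
    """One extracted upstream region (or an exclusion record)."""

    source_id: str
    sequence: str  # 5'->3' on the feature strand; last char = position 1
    excluded: bool = False
    reason: str = ""

    def position(self, p: int) -> str:
        """Nucleotide at upstream position ``p`` (1 = adjacent to start)."""
        return self.sequence[len(self.sequence) - p]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_upstream(
    genome: GenomeRecord,
    source_id: str,
    start: int,
    end: int,
    strand: str,
    length: int = UPSTREAM_LEN,
    own_cds_ids: frozenset[str] | set[str] = frozenset(),
    check_cds_overlap: bool = True,
    circular: bool = False,
) -> UpstreamRegion:
    """Extract the ``length`` nt immediately 5' of a feature's start.

    Excluded with reason ``"genome_edge"`` when truncated by the genome
    end (unless ``circular`` permits wrap-around) and with
    ``"cds_overlap"`` when the region intersects any CDS other than
    those in ``own_cds_ids`` (an asRNA's upstream region lies inside its
    own target CDS by construction, so the target is exempted).
    """
    L = len(genome)
    if strand == "+":
        g_lo, g_hi = start - length, start - 1
    elif strand == "-":
        g_lo, g_hi = end + 1, end + length
    else:
        raise ValueError(f"bad strand {strand!r}")

    wrapped = g_lo < 1 or g_hi > L
    if wrapped and not circular:
        return UpstreamRegion(source_id, "", True, "genome_edge")

    if check_cds_overlap:
        for f in genome.features:
            if f.feature_id in own_cds_ids:
                continue
            lo, hi = g_lo, g_hi
            if not wrapped and f.start <= hi and f.end >= lo:
                return UpstreamRegion(source_id, "", True, "cds_overlap")
            if wrapped:
                for s2, e2 in _wrap_intervals(lo, hi, L):
                    if f.start <= e2 and f.end >= s2:
                        return UpstreamRegion(source_id, "", True, "cds_overlap")

    if wrapped:
        seq = "".join(genome.sequence[s - 1 : e] for s, e in _wrap_intervals(g_lo, g_hi, L))
        if strand == "-":
            from .io_formats import revcomp

            seq = revcomp(seq)
    else:
        seq = genome.subseq(g_lo, g_hi, strand)
    return UpstreamRegion(source_id, seq)


def _wrap_intervals(lo: int, hi: int, L: int) -> list[tuple[int, int]]:
    """Split a possibly out-of-range 1..L interval into wrapped pieces."""
    out = []
    for g in range(lo, hi + 1):
        gg = ((g - 1) % L) + 1
        if out and out[-1][1] == gg - 1:
            out[-1] = (out[-1][0], gg)
        else:
            out.append((gg, gg))
    return out


def extract_asrna_upstreams(
    genome: GenomeRecord,
    srna_table: SrnaTable,
    length: int = UPSTREAM_LEN,
    circular: bool = False,
) -> tuple[list[UpstreamRegion], list[UpstreamRegion]]:
    """Upstream regions of all antisense (or unclassified) sRNAs.

    A region overlapping any CDS other than the asRNA's own target is
    dropped — the literal any-CDS rule would exclude every asRNA in a
    gene-dense genome, since an asRNA sits inside its target.
    Returns (kept, excluded).
    """
    kept, excluded = [], []
    df = srna_table.df
    for row in df.itertuples():
        own = set()
        if "target_cds" in df.columns and isinstance(row.target_cds, str):
            own.add(row.target_cds)
        r = extract_upstream(
            genome, row.srna_id, row.start, row.end, row.strand,
            length=length, own_cds_ids=own, circular=circular,
        )
        (excluded if r.excluded else kept).append(r)
    return kept, excluded


def extract_cds_upstreams(
    genome: GenomeRecord, length: int = UPSTREAM_LEN, circular: bool = False
) -> tuple[list[UpstreamRegion], list[UpstreamRegion]]:
    """Upstream regions of all CDSs; dropped when overlapping an adjacent
    CDS on either strand.  Returns (kept, excluded)."""
    kept, excluded = [], []
    for f in genome.features:
        r = extract_upstream(
            genome, f.feature_id, f.start, f.end, f.strand,
            length=length, own_cds_ids={f.feature_id}, circular=circular,
        )
        (excluded if r.excluded else kept).append(r)
    return kept, excluded


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def _check_seq(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if not seq or bad:
        raise ValueError(f"invalid nucleotide string (bad characters: {sorted(bad)})")


def gc_percent(seq: str) -> float:
    """100 · (#G + #C) / length."""
    _check_seq(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def gc_skew(seq: str) -> float:
    """(#C − #G) / (#C + #G); 0 by convention when the window has no G or C
    (common in an ~84%-AT genome; dropping such windows would bias profiles)."""
    _check_seq(seq)
    c, g = seq.count("C"), seq.count("G")
    return 0.0 if c + g == 0 else (c - g) / (c + g)


def window_scan(
    region: UpstreamRegion | str,
    stat: Callable[[str], float],
    window: int = WINDOW,
    expected_length: int | None = UPSTREAM_LEN,
) -> np.ndarray:
    """Per-window statistic, index w-1 holding window ``w`` (positions
    ``w..w+6``); a 61-nt region gives exactly 55 values."""
    seq = region.sequence if isinstance(region, UpstreamRegion) else region
    U = len(seq)
    if expected_length is not None and U != expected_length:
        raise ValueError(f"region length {U} != expected {expected_length}")
    if U < window:
        raise ValueError("region shorter than the window")
    return np.array(
        [stat(seq[U - w - window + 1 : U - w + 1]) for w in range(1, U - window + 2)]
    )


# ---------------------------------------------------------------------------
# Permutation null for GC percent
# ---------------------------------------------------------------------------

def _encode(regions: Sequence[UpstreamRegion | str]) -> np.ndarray:
    seqs = [r.sequence if isinstance(r, UpstreamRegion) else r for r in regions]
    for s in seqs:
        _check_seq(s)
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("regions must have equal length")
    return np.array([[_BASE_CODE[c] for c in s] for s in seqs], dtype=np.int8)


def _window_gc_matrix(codes: np.ndarray, window: int = WINDOW) -> np.ndarray:
    """GC% per window from base-code arrays (..., U) → (..., U-window+1),
    output index w-1 = window w (positions w..w+6)."""
    gc = ((codes == 1) | (codes == 2)).astype(float)
    csum = np.cumsum(gc, axis=-1)
    csum = np.concatenate([np.zeros((*gc.shape[:-1], 1)), csum], axis=-1)
    sums = csum[..., window:] - csum[..., :-window]  # ascending string windows
    return 100.0 * sums[..., ::-1] / window  # reverse → ascending position windows


def shuffle_codes(
    codes: np.ndarray, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """``(R, U)`` base codes → ``(R, n_shuffles, U)`` uniform permutations
    (Fisher–Yates via random-key argsort); each permutation preserves the
    region's base multiset exactly."""
    R, U = codes.shape
    keys = rng.random((R, n_shuffles, U))
    order = np.argsort(keys, axis=-1)
    return np.take_along_axis(
        np.broadcast_to(codes[:, None, :], (R, n_shuffles, U)), order, axis=-1
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erikson): the sequence is
    viewed as an Eulerian walk on the base multigraph and a uniform random
    Eulerian walk with the same start and end is regenerated."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(set(edges) | {last})
    while True:  # sample last-edges until they form an arborescence into `last`
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last and edges.get(v)
        }
        ok = True
        for v in last_edge:
            seen, u = set(), v
            while u != last:
                if u in seen or u not in last_edge:
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break
    walk_edges = {}
    for v in vertices:
        rest = list(edges.get(v, []))
        if v in last_edge:
            rest.remove(last_edge[v])
        rest = [rest[k] for k in rng.permutation(len(rest))]
        if v in last_edge:
            rest.append(last_edge[v])
        walk_edges[v] = rest
    out, ptr, v = [seq[0]], {u: 0 for u in vertices}, seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def gc_permutation_test(
    regions: Sequence[UpstreamRegion | str],
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    window: int = WINDOW,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-window paired t-test of observed GC% against each region's
    permutation-null mean.

    Each region's 61-mer is uniformly re-shuffled ``n_shuffles`` times
    (composition-preserving); the per-window GC% of the shuffles is
    averaged into that region's null mean; across regions a paired,
    two-sided t-test compares observed vs null-mean GC% per window.
    Returns a profile DataFrame with columns ``window, n, mean, se,
    null_mean, t, p, significant, direction``; ``direction`` is the sign
    of (observed − null) mean.  No multiple-testing correction by
    default; Benjamini-Hochberg behind ``bh_correct``.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions for the paired t-test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _encode(regions)
    obs = _window_gc_matrix(codes, window)  # (R, W)
    perm = shuffle_codes(codes, n_shuffles, rng)  # (R, S, U)
    null_mean = _window_gc_matrix(perm, window).mean(axis=1)  # (R, W)

    R, W = obs.shape
    t_stat, p_val = stats.ttest_rel(obs, null_mean, axis=0)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    p_use = p_val
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p_use = multipletests(p_val, alpha=alpha, method="fdr_bh")[1]
    diff = (obs - null_mean).mean(axis=0)
    return pd.DataFrame(
        {
            "window": np.arange(1, W + 1),
            "n": R,
            "mean": obs.mean(axis=0),
            "se": obs.std(axis=0, ddof=1) / np.sqrt(R),
            "null_mean": null_mean.mean(axis=0),
            "t": t_stat,
            "p": p_use,
            "significant": p_use < alpha,
            "direction": np.sign(diff).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# GC-skew profiles (qualitative asRNA-vs-CDS comparison)
# ---------------------------------------------------------------------------

def _window_skew_matrix(codes: np.ndarray, window: int = WINDOW) -> np.ndarray:
    c = (codes == 1).astype(float)
    g = (codes == 2).astype(float)

    def wsum(x):
        csum = np.concatenate([np.zeros((*x.shape[:-1], 1)), np.cumsum(x, axis=-1)], axis=-1)
        return (csum[..., window:] - csum[..., :-window])[..., ::-1]

    cs, gs = wsum(c), wsum(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(cs + gs > 0, (cs - gs) / (cs + gs), 0.0)
    return skew


def skew_profile(regions: Sequence[UpstreamRegion | str], window: int = WINDOW) -> pd.DataFrame:
    """Per-window mean ± SE GC skew across a region set (no test: the
    whole qualifying population is profiled, not a sample)."""
    if not regions:
        raise ValueError("empty region set")
    skew = _window_skew_matrix(_encode(regions), window)
    R, W = skew.shape
    se = skew.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(W)
    return pd.DataFrame(
        {"window": np.arange(1, W + 1), "n": R, "mean": skew.mean(axis=0), "se": se}
    )


def skew_profiles(
    asrna_regions: Sequence[UpstreamRegion | str],
    cds_regions: Sequence[UpstreamRegion | str],
    window: int = WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GC-skew profiles of the asRNA and CDS upstream sets, for side-by-side
    plotting."""
    return skew_profile(asrna_regions, window), skew_profile(cds_regions, window)


# ---------------------------------------------------------------------------
# Motif export and scanning
# ---------------------------------------------------------------------------

def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC nucleotide motif into a regex."""
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"malformed IUPAC motif: bad characters {sorted(bad)}")
    return re.compile(
        "".join(f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch] for ch in motif)
    )


def motif_fraction(regions: Sequence[UpstreamRegion | str], motif: str) -> float:
    """Fraction of regions containing ≥1 match of the IUPAC motif."""
    if not regions:
        raise ValueError("empty region set")
    pat = iupac_regex(motif)
    seqs = [r.sequence if isinstance(r, UpstreamRegion) else r for r in regions]
    return sum(bool(pat.search(s)) for s in seqs) / len(seqs)


def motif_site_export(
    regions: Sequence[UpstreamRegion],
    fasta_path: str | Path,
    position_interval: tuple[int, int] | None = None,
    motif: str | None = None,
) -> float | None:
    """Write regions (or the stated upstream-position sub-interval of each)
    as FASTA for external motif discovery; optionally report the fraction
    of regions matching a user motif."""
    with open(fasta_path, "w") as fh:
        for r in regions:
            seq = r.sequence
            if position_interval is not None:
                lo, hi = position_interval
                U = len(seq)
                seq = seq[U - hi : U - lo + 1]
            fh.write(f">{r.source_id}\n{seq}\n")
    if motif is not None:
        return motif_fraction(regions, motif)
    return None
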