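"""Selection signatures on the protein regions encoding conserved asRNAs.

In strongly reduced, AT-rich symbiont genomes synonymous divergence
between lineages is saturated (dS >> 3), so the usable signal of
purifying selection on an asRNA footprint is amino-acid divergence: if
the protein region complementary to a conserved asRNA evolves more
slowly than the rest of the protein, the asRNA footprint is under
selective constraint.

Three pieces implement that test:

* :func:`aa_ml_distance` — pairwise maximum-likelihood amino-acid
  distance under the 20-state equal-rates model, which has the closed
  form ``d = -(19/20) * ln(1 - (20/19) * p)`` for mismatch fraction
  ``p`` over comparable (ungapped) columns.
* :func:`estimate_synonymous_divergence` — a counting (NG86-style) dS
  used purely as a saturation screen.
* :func:`sliding_window_conservation_test` — the asRNA footprint
  (transcript overlap plus 15-nt flanks, converted to whole codons) is
  compared against the distribution of equally long windows slid over
  the rest of the alignment at a 1-codon step, with a one-tailed t-test
  of the single region value against that distribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import STOP_CODONS, translate_codon

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped CDS nucleotide sequences aligned codon-wise.

    The frame is anchored to the CDS start: column i of the amino-acid
    alignment is nucleotide columns 3i..3i+2.  Codon columns containing a
    gap are treated as missing; internal stop codons draw a warning but
    do not fail (annotation slippage is common in degraded genomes).
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length must be a multiple of 3")
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> list[tuple[str, str] | None]:
        """Per codon column: the (a, b) codon pair, or None when gapped."""
        out: list[tuple[str, str] | None] = []
        for i in range(self.n_codons):
            ca = self.seq_a[3 * i : 3 * i + 3]
            cb = self.seq_b[3 * i : 3 * i + 3]
            if set(ca) & GAP_CHARS or set(cb) & GAP_CHARS:
                out.append(None)
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                if i < self.n_codons - 1:
                    logger.warning("internal stop codon at codon column %d", i + 1)
                out.append(None)
                continue
            out.append((ca, cb))
        return out

    def aa_pair(self) -> tuple[str, str]:
        """Amino-acid translation of both rows, '-' where gapped/stop."""
        a, b = [], []
        for i, pair in enumerate(self.codon_pairs()):
            if pair is None:
                a.append("-")
                b.append("-")
            else:
                a.append(translate_codon(pair[0]))
                b.append(translate_codon(pair[1]))
        return "".join(a), "".join(b)


# ---------------------------------------------------------------------------
# Amino-acid ML distance (20-state equal-rates model)
# ---------------------------------------------------------------------------

SATURATION_P = 19.0 / 20.0


def aa_ml_distance(aa_a: str, aa_b: str) -> tuple[float, bool]:
    """Pairwise ML amino-acid distance; returns ``(d, saturated)``.

    Under the 20-state equal-rates substitution model the ML estimate is
    ``d = -(19/20) ln(1 - (20/19) p)`` with ``p`` the mismatch fraction
    over comparable columns (both non-gap).  ``p >= 19/20`` makes the
    log argument nonpositive: the distance is infinite and flagged
    saturated.
    """
    if len(aa_a) != len(aa_b):
        raise ValueError("amino-acid sequences must have equal length")
    comparable = mismatch = 0
    for x, y in zip(aa_a, aa_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        mismatch += x != y
    if comparable == 0:
        raise ValueError("no comparable columns")
    p = mismatch / comparable
    if p >= SATURATION_P:
        return math.inf, True
    return -SATURATION_P * math.log1p(-p / SATURATION_P), False


# ---------------------------------------------------------------------------
# Synonymous divergence (NG86-style counting, saturation screen)
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractions of the codon's 3 sites that are synonymous/nonsynonymous."""
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pairwise_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = ca, 0.0, 0.0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_counts.append((sd, nd))
    if not path_counts:  # every pathway passes through a stop; count all paths
        path_counts = []
        for order in itertools.permutations(diff_pos):
            cur, sd, nd = ca, 0.0, 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS or translate_codon(nxt) != translate_codon(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            path_counts.append((sd, nd))
    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return sd, nd


_FOURFOLD_PREFIXES = frozenset(
    {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}  # third position fully degenerate
)


@dataclass(frozen=True)
class SynonymousDivergence:
    ds: float
    ps: float
    syn_sites: float
    syn_diffs: float
    ps_ceiling: float
    saturated: bool


def estimate_synonymous_divergence(
    alignment: CodonAlignment,
    saturation_ds: float = 3.0,
    ceiling_frac: float = 0.85,
) -> SynonymousDivergence:
    """Counting-method dS with the Jukes-Cantor multiple-hit correction
    ``dS = -(3/4) ln(1 - (4/3) ps)``, used purely as a saturation screen.

    Saturation is flagged when the correction is undefined (ps ≥ 3/4),
    when dS exceeds ``saturation_ds``, or when ps reaches
    ``ceiling_frac`` of its composition ceiling ``1 - Σ f_i²`` (f_i =
    pooled base frequencies at fourfold-degenerate third positions).  The
    last criterion matters in extremely AT-rich genomes: with biased
    composition the expected mismatch fraction at saturation is well
    below 3/4, so the uncorrected JC threshold alone would never fire
    even on fully randomized synonymous sites.
    """
    S = Sd = 0.0
    four_counts = {b: 0 for b in "ACGT"}
    for pair in alignment.codon_pairs():
        if pair is None:
            continue
        ca, cb = pair
        S += (_codon_site_counts(ca)[0] + _codon_site_counts(cb)[0]) / 2.0
        Sd += _pairwise_diff_counts(ca, cb)[0]
        for c in (ca, cb):
            if c[:2] in _FOURFOLD_PREFIXES:
                four_counts[c[2]] += 1
    if S == 0:
        raise ValueError("no synonymous sites in alignment")
    ps = Sd / S
    n4 = sum(four_counts.values())
    ceiling = (
        1.0 - sum((v / n4) ** 2 for v in four_counts.values()) if n4 else 0.75
    )
    if ps >= 0.75:
        return SynonymousDivergence(math.inf, ps, S, Sd, ceiling, True)
    ds = -0.75 * math.log1p(-ps / 0.75)
    saturated = ds > saturation_ds or (ceiling > 0 and ps >= ceiling_frac * ceiling)
    return SynonymousDivergence(ds, ps, S, Sd, ceiling, saturated)


# ---------------------------------------------------------------------------
# Sliding-window conservation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceWindowResult:
    srna_region_distance: float
    window_distances: tuple[float, ...]
    t_stat: float
    p_value: float
    region_bounds: tuple[int, int]  # codon interval, 1-based inclusive
    significant: bool
    untestable: bool
    reason: str = ""


def _region_codons(
    srna_interval: tuple[int, int], flank_nt: int, n_codons: int
) -> tuple[int, int]:
    """asRNA overlap (gene-local nt, 1-based) + flanks, as whole codons."""
    s_nt = max(1, srna_interval[0] - flank_nt)
    e_nt = min(3 * n_codons, srna_interval[1] + flank_nt)
    return (s_nt + 2) // 3, (e_nt + 2) // 3


def _window_distance(mismatch: np.ndarray, comparable: np.ndarray) -> np.ndarray:
    """Vector of equal-rates ML distances from per-window mismatch and
    comparable-column counts; NaN where no comparable columns, +inf when
    saturated."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mismatch / comparable
        arg = 1.0 - p / SATURATION_P
        d = np.where(arg > 0, -SATURATION_P * np.log(np.maximum(arg, 1e-300)), np.inf)
        d = np.where(comparable > 0, d, np.nan)
    return d


def sliding_window_conservation_test(
    alignment: CodonAlignment,
    srna_interval: tuple[int, int],
    flank_nt: int = 15,
    step_codons: int = 1,
    exclude_overlap_frac: float = 0.0,
    alpha: float = 0.01,
) -> DivergenceWindowResult:
    """Test whether the asRNA-encoding protein region is more conserved
    than the rest of the protein.

    The region is the transcript overlap extended ``flank_nt`` each side,
    converted to whole codons; a window of the same codon length slides
    over the full alignment at ``step_codons``; windows overlapping the
    region by more than ``exclude_overlap_frac`` of their length are
    excluded from the null distribution (default: any overlap excludes —
    windows sharing codons with the region would leak it into its own
    null).  The region's distance is then
    compared with the null windows by a one-tailed t-test of a single
    observation against a sample (alternative: region < window mean).
    The standard error uses ``s * sqrt(L/n + 1)`` — the single-observation
    form with a Bartlett-type inflation of the window-mean variance that
    accounts for the autocorrelation of overlapping windows (L = window
    length in steps).
    """
    n = alignment.n_codons
    rs, re = _region_codons(srna_interval, flank_nt, n)
    if not (1 <= rs <= re <= n):
        raise ValueError(f"sRNA region {srna_interval} outside the gene")
    aa_a, aa_b = alignment.aa_pair()
    comp = np.array([x != "-" and y != "-" for x, y in zip(aa_a, aa_b)], dtype=float)
    mism = np.array(
        [c and x != y for x, y, c in zip(aa_a, aa_b, comp.astype(bool))], dtype=float
    )

    L = re - rs + 1
    region_d = _window_distance(
        np.array([mism[rs - 1 : re].sum()]), np.array([comp[rs - 1 : re].sum()])
    )[0]

    starts = np.arange(0, n - L + 1, step_codons)
    csum_m = np.concatenate([[0.0], np.cumsum(mism)])
    csum_c = np.concatenate([[0.0], np.cumsum(comp)])
    wm = csum_m[starts + L] - csum_m[starts]
    wc = csum_c[starts + L] - csum_c[starts]
    wd = _window_distance(wm, wc)

    # overlap of each window [start+1, start+L] with the region [rs, re]
    ov = np.minimum(starts + L, re) - np.maximum(starts + 1, rs) + 1
    null_mask = (ov <= exclude_overlap_frac * L) & np.isfinite(wd)
    null_d = wd[null_mask]

    if not np.isfinite(region_d):
        return DivergenceWindowResult(
            region_d, tuple(null_d), math.nan, math.nan, (rs, re),
            False, True, "region distance saturated or undefined",
        )
    if null_d.size < 3:
        return DivergenceWindowResult(
            region_d, tuple(null_d), math.nan, math.nan, (rs, re),
            False, True, f"only {null_d.size} usable null windows",
        )

    mean = float(null_d.mean())
    # Delta-method standard error for (window mean - region distance).
    # Overlapping windows make the naive window-sample sd nearly useless
    # (a handful of effective degrees of freedom), but the underlying
    # information is one mismatch indicator per codon: with pooled null
    # mismatch fraction q over N non-region codons and a region of Lc
    # comparable codons, var(d) = d'(q)^2 q(1-q) (1/Lc + 1/N) with
    # d'(q) = 1/(1 - q/(19/20)).
    region_mask = np.zeros(n, dtype=bool)
    region_mask[rs - 1 : re] = True
    null_codons = comp.astype(bool) & ~region_mask
    N = int(null_codons.sum())
    Lc = int(comp[rs - 1 : re].sum())
    q = float(mism[null_codons].sum() / N) if N else 0.0
    if q < SATURATION_P and N and Lc:
        dprime = 1.0 / (1.0 - q / SATURATION_P)
        se = dprime * math.sqrt(max(q * (1.0 - q), 0.0) * (1.0 / Lc + 1.0 / N))
    else:
        se = math.nan
    df = max(3, N + Lc - 2)
    if not math.isfinite(se):
        return DivergenceWindowResult(
            region_d, tuple(null_d), math.nan, math.nan, (rs, re),
            False, True, "null mismatch fraction saturated",
        )
    if se == 0.0:
        t = 0.0 if region_d == mean else math.copysign(math.inf, mean - region_d)
        p = 0.5 if t == 0.0 else (0.0 if t > 0 else 1.0)
    else:
        t = (mean - region_d) / se
        p = float(stats.t.sf(t, df=df))
    return DivergenceWindowResult(
        float(region_d), tuple(null_d), float(t), p, (rs, re), p < alpha, False
    )
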