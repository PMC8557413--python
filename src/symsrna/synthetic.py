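"""Synthetic paired symbiont-like genomes with known ground truth.

The generator emulates the comparative setting this package analyses: two
gene-dense, extremely AT-rich (default 16% GC) bacterial genomes whose
orthologous CDSs diverged by amino-acid-changing substitutions while
synonymous sites saturated; antisense sRNAs (asRNAs) embedded inside CDSs,
a subset orthologous between the two lineages with small coordinate
jitter; lowered substitution rates inside conserved asRNA footprints; and
61-nt upstream regions carrying planted GC-percent dips, GC-skew bumps,
and a promoter-like motif.

Every source of randomness flows from one seed through named
``numpy.random.SeedSequence`` sub-streams, so an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io_formats import (
    CdsFeature,
    GenomeRecord,
    OffsetBlock,
    OffsetMap,
    SrnaTable,
    revcomp,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The bacterial/archaeal/plant-plastid code; identical to the standard code
#: on all 61 sense codons (it differs only in permitted start codons).
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TABLE.forward_table))

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def translate_codon(codon: str) -> str:
    """Amino acid (or '*' for stop) of one codon under the bacterial code."""
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def _nonsyn_neighbors() -> dict[str, tuple[str, ...]]:
    out = {}
    for codon in SENSE_CODONS:
        aa = translate_codon(codon)
        nb = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut not in STOP_CODONS and translate_codon(mut) != aa:
                    nb.append(mut)
        out[codon] = tuple(nb)
    return out


def _synonyms() -> dict[str, tuple[str, ...]]:
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(translate_codon(codon), []).append(codon)
    return {c: tuple(by_aa[translate_codon(c)]) for c in SENSE_CODONS}


NONSYN_NEIGHBORS = _nonsyn_neighbors()
SYNONYMS = _synonyms()


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated genome pair.

    Defaults mirror the survey this package targets: a ~165-kb genome of
    196 non-overlapping CDSs at 16% GC, 36 asRNAs in lineage A and 32 in
    lineage B of which 11 are orthologous (coordinate jitter sd 5 nt),
    amino-acid divergence 0.4 substitutions/site outside conserved asRNA
    footprints versus 0.05 inside, saturated synonymous sites, a GC-percent
    dip planted in upstream windows 33-48, a GC-skew bump in windows 46-54,
    and a Pribnow-style TANAAT motif ~8 nt upstream of the start.
    """

    seed: int = 0
    n_cds: int = 196
    mean_cds_len: int = 800          # nt, incl. stop codon
    genome_gc: float = 0.16
    spacer_mean: int = 25            # nt between consecutive CDSs
    n_asrna: int = 36
    n_asrna_b: int | None = 32
    frac_conserved: float = 11.0 / 36.0
    n_conserved: int | None = None   # overrides frac_conserved when set
    coord_jitter_sd: float = 5.0
    asrna_len_range: tuple[int, int] = (60, 200)
    aa_div_outside: float = 0.4      # expected aa substitutions/site
    aa_div_inside: float = 0.05      # inside conserved asRNA footprints
    syn_sat_prob: float = 0.7        # per-codon synonymous replacement prob
    footprint_flank_nt: int = 15
    upstream_len: int = 61
    dip_band: tuple[int, int] = (33, 48)   # 7-nt window indices
    dip_depth: float = 0.10                # GC-fraction decrement
    skew_band: tuple[int, int] = (46, 54)  # 7-nt window indices
    skew_height: float = 0.5               # target (C-G)/(C+G) in band
    motif: str = "TANAAT"
    motif_prob: float = 0.6
    motif_offset: int = 8            # upstream position of the motif's 3' end
    coverage_depth: float = 50.0
    genome_length: int | None = None  # optional cap; error if CDSs don't fit

    def __post_init__(self) -> None:
        for name in ("genome_gc", "frac_conserved", "syn_sat_prob", "motif_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.aa_div_inside > self.aa_div_outside:
            raise ValueError("aa_div_inside must not exceed aa_div_outside")
        if self.dip_depth > self.genome_gc:
            raise ValueError("dip_depth exceeds genome_gc")

    @property
    def resolved_n_conserved(self) -> int:
        if self.n_conserved is not None:
            return self.n_conserved
        return int(round(self.frac_conserved * self.n_asrna))

    @property
    def resolved_n_asrna_b(self) -> int:
        return self.n_asrna if self.n_asrna_b is None else self.n_asrna_b


@dataclass
class GroundTruth:
    """Oracle record of everything the generator planted."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    host_cds: dict[str, str] = field(default_factory=dict)
    footprints: dict[str, tuple[int, int]] = field(default_factory=dict)
    upstream_flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def conserved_a_ids(self) -> set[str]:
        return {a for a, _ in self.pairs}

    def conserved_b_ids(self) -> set[str]:
        return {b for _, b in self.pairs}


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=length, p=_base_probs(gc))])


def random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random non-stop codons + TAA, sampled at the target composition."""
    p = _base_probs(gc)
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(_BASES[rng.choice(4, size=3, p=p)])
            if c not in STOP_CODONS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _weighted_choice(rng: np.random.Generator, items: Sequence[str], weights: np.ndarray) -> str:
    w = weights / weights.sum()
    return items[rng.choice(len(items), p=w)]


def _codon_weight(codon: str, gc: float) -> float:
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    return p[codon[0]] * p[codon[1]] * p[codon[2]]


def evolve_cds(
    rng: np.random.Generator,
    cds_seq: str,
    aa_div: float | np.ndarray,
    syn_sat_prob: float,
    gc: float,
) -> str:
    """Derive a lineage-B CDS from lineage A by codon-level substitution.

    Each codon independently receives an amino-acid-changing single-nt
    substitution with probability ``1 - exp(-d)`` where ``d`` is that
    codon's expected aa divergence, and (independently) a synonymous
    replacement with probability ``syn_sat_prob`` — deliberately high, so
    synonymous divergence is saturated and only amino-acid divergence is
    informative, matching the regime in strongly reduced genomes.
    Synonyms are drawn with composition-weighted probabilities so the
    AT bias is preserved.  Start and stop codons are left untouched.
    """
    n = len(cds_seq) // 3
    d = np.broadcast_to(np.asarray(aa_div, dtype=float), (n,))
    p_ns = 1.0 - np.exp(-d)
    ns_hit = rng.random(n) < p_ns
    syn_hit = rng.random(n) < syn_sat_prob
    out = []
    for i in range(n):
        codon = cds_seq[3 * i : 3 * i + 3]
        if i == 0 or codon in STOP_CODONS:
            out.append(codon)
            continue
        if ns_hit[i]:
            nb = NONSYN_NEIGHBORS[codon]
            if nb:
                # composition-weighted so the AT bias survives substitution
                w = np.array([_codon_weight(c, gc) for c in nb])
                codon = _weighted_choice(rng, nb, w)
        if syn_hit[i]:
            syns = SYNONYMS[codon]
            if len(syns) > 1:
                w = np.array([_codon_weight(c, gc) for c in syns])
                codon = _weighted_choice(rng, syns, w)
        out.append(codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome-pair simulation
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "layout", "cds", "evolve", "asrna", "jitter",
        "upstream", "coverage", "expression",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _mean_expression(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.round(rng.lognormal(mean=3.0, sigma=1.0, size=n), 2)


def _asrna_rows(
    genome_id: str,
    prefix: str,
    placements: Iterable[tuple[str, int, int, str]],
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for k, (host, start, end, strand) in enumerate(placements, start=1):
        e = _mean_expression(rng, 3)
        rows.append(
            {
                "srna_id": f"{prefix}{k:03d}",
                "genome": genome_id,
                "start": start,
                "end": end,
                "strand": strand,
                "category": "unset",
                "expr_1": e[0],
                "expr_2": e[1],
                "expr_3": e[2],
                "_host": host,
            }
        )
    return rows


def simulate_genome_pair(
    config: SimulationConfig,
) -> tuple[GenomeRecord, GenomeRecord, SrnaTable, SrnaTable, OffsetMap, GroundTruth]:
    """Simulate two syntenic genomes, their asRNA tables, the exact offset
    map between them, and the ground truth of everything planted."""
    rngs = _streams(config.seed)
    lay, cds_rng, evo, asr, jit = (
        rngs["layout"], rngs["cds"], rngs["evolve"], rngs["asrna"], rngs["jitter"],
    )

    mean_codons = max(60, config.mean_cds_len // 3)
    n_codons = np.maximum(
        60, np.round(lay.gamma(shape=8.0, scale=mean_codons / 8.0, size=config.n_cds))
    ).astype(int)
    strands = np.where(lay.random(config.n_cds) < 0.5, "+", "-")
    spacers_a = lay.poisson(config.spacer_mean, size=config.n_cds + 1) + 2
    spacers_b = lay.poisson(config.spacer_mean, size=config.n_cds + 1) + 2

    if config.genome_length is not None:
        need = int(3 * n_codons.sum() + spacers_a.sum())
        if need > config.genome_length:
            raise ValueError(
                f"infeasible packing: {config.n_cds} CDSs need {need} bp "
                f"> genome_length {config.genome_length}"
            )

    cds_seqs_a = [random_cds(cds_rng, int(k), config.genome_gc) for k in n_codons]

    # --- place asRNAs in lineage A -------------------------------------
    up, flank = config.upstream_len, config.footprint_flank_nt
    lo_len, hi_len = config.asrna_len_range
    # margin on the asRNA's 5' side keeps its 61-nt upstream region inside
    # the host CDS; margin on both sides absorbs jitter and the footprint flank
    side = flank + 1
    eligible = [
        i for i in range(config.n_cds) if 3 * n_codons[i] >= hi_len + up + 2 * side + 6
    ]
    n_b_extra = config.resolved_n_asrna_b - config.resolved_n_conserved
    hosts_needed = config.n_asrna + n_b_extra
    if len(eligible) < hosts_needed:
        raise ValueError(
            f"infeasible packing: need {hosts_needed} host CDSs, only "
            f"{len(eligible)} are long enough"
        )
    host_idx = asr.choice(len(eligible), size=hosts_needed, replace=False)
    hosts_a = [eligible[i] for i in host_idx[: config.n_asrna]]
    hosts_b_extra = [eligible[i] for i in host_idx[config.n_asrna :]]

    def place_in_cds(rng, cds_i, cds_start, cds_end, cds_strand):
        """Pick an asRNA interval inside the CDS honoring all margins."""
        length = int(rng.integers(lo_len, hi_len + 1))
        # on the asRNA strand (opposite the CDS), upstream lies toward the
        # CDS 3' end in genomic coordinates iff the CDS is on '+'
        lo = cds_start + (side if cds_strand == "+" else side + up)
        hi = cds_end - length + 1 - (side + up if cds_strand == "+" else side)
        start = int(rng.integers(lo, hi + 1))
        strand = "-" if cds_strand == "+" else "+"
        return start, start + length - 1, strand

    # --- assemble genome A ---------------------------------------------
    parts, feats_a, cursor = [], [], 0
    cds_coords_a = []
    for i in range(config.n_cds):
        parts.append(random_dna(lay, int(spacers_a[i]), config.genome_gc))
        cursor += int(spacers_a[i])
        start = cursor + 1
        seq = cds_seqs_a[i]
        parts.append(seq if strands[i] == "+" else revcomp(seq))
        cursor += len(seq)
        cds_coords_a.append((start, cursor))
        feats_a.append(CdsFeature(f"cdsA_{i + 1:03d}", start, cursor, strands[i]))
    parts.append(random_dna(lay, int(spacers_a[-1]), config.genome_gc))
    genome_a = GenomeRecord("simA", "".join(parts), tuple(feats_a))

    placements_a = []
    for i in hosts_a:
        s, e, st = place_in_cds(asr, i, *cds_coords_a[i], strands[i])
        placements_a.append((f"cdsA_{i + 1:03d}", s, e, st))

    truth = GroundTruth()
    order = asr.permutation(config.n_asrna)
    conserved_pos = set(order[: config.resolved_n_conserved].tolist())

    # --- evolve CDSs into lineage B -------------------------------------
    host_of_a = {hosts_a[k]: placements_a[k] for k in range(config.n_asrna)}
    conserved_hosts = {
        hosts_a[k]: placements_a[k] for k in range(config.n_asrna) if k in conserved_pos
    }
    cds_seqs_b = []
    for i in range(config.n_cds):
        div = np.full(int(n_codons[i]), config.aa_div_outside)
        if i in conserved_hosts:
            _, s, e, _ = conserved_hosts[i]
            cs, ce = cds_coords_a[i]
            if strands[i] == "+":
                off5, off3 = s - cs, ce - e
            else:
                off5, off3 = ce - e, s - cs
            lo_nt = max(0, off5 - flank)
            hi_nt = (ce - cs + 1) - max(0, off3 - flank)  # exclusive, CDS-local nt
            div[lo_nt // 3 : (hi_nt + 2) // 3] = config.aa_div_inside
        cds_seqs_b.append(
            evolve_cds(evo, cds_seqs_a[i], div, config.syn_sat_prob, config.genome_gc)
        )

    # --- assemble genome B (same gene order and strands, new spacers) ---
    parts, feats_b, cursor = [], [], 0
    cds_coords_b = []
    for i in range(config.n_cds):
        parts.append(random_dna(lay, int(spacers_b[i]), config.genome_gc))
        cursor += int(spacers_b[i])
        start = cursor + 1
        seq = cds_seqs_b[i]
        parts.append(seq if strands[i] == "+" else revcomp(seq))
        cursor += len(seq)
        cds_coords_b.append((start, cursor))
        feats_b.append(CdsFeature(f"cdsB_{i + 1:03d}", start, cursor, strands[i]))
    parts.append(random_dna(lay, int(spacers_b[-1]), config.genome_gc))
    genome_b = GenomeRecord("simB", "".join(parts), tuple(feats_b))

    offset_map = OffsetMap(
        tuple(
            OffsetBlock(a[0], a[1], b[0], b[1], "+")
            for a, b in zip(cds_coords_a, cds_coords_b)
        )
    )

    # --- lineage-B asRNAs: conserved counterparts + lineage-specific ----
    placements_b, pair_of_b = [], []
    for k in sorted(conserved_pos):
        host, s, e, st = placements_a[k]
        i = int(host.split("_")[1]) - 1
        shift = cds_coords_b[i][0] - cds_coords_a[i][0]
        max_jit = min(3.0 * config.coord_jitter_sd, 15.0)
        js = int(np.clip(round(jit.normal(0, config.coord_jitter_sd)), -max_jit, max_jit))
        je = int(np.clip(round(jit.normal(0, config.coord_jitter_sd)), -max_jit, max_jit))
        bs, be = s + shift + js, e + shift + je
        cs, ce = cds_coords_b[i]
        bs = max(cs + 1, bs)
        be = min(ce - 1, be)
        placements_b.append((f"cdsB_{i + 1:03d}", bs, be, st))
        pair_of_b.append(k)
    for i in hosts_b_extra:
        s, e, st = place_in_cds(asr, i, *cds_coords_b[i], strands[i])
        placements_b.append((f"cdsB_{i + 1:03d}", s, e, st))
        pair_of_b.append(None)

    rows_a = _asrna_rows("simA", "sA_", placements_a, rngs["expression"])
    rows_b = _asrna_rows("simB", "sB_", placements_b, rngs["expression"])

    for k, row in enumerate(rows_a):
        truth.host_cds[row["srna_id"]] = row.pop("_host")
        truth.footprints[row["srna_id"]] = (row["start"], row["end"])
    for j, row in enumerate(rows_b):
        truth.host_cds[row["srna_id"]] = row.pop("_host")
        truth.footprints[row["srna_id"]] = (row["start"], row["end"])
        if pair_of_b[j] is not None:
            truth.pairs.append((rows_a[pair_of_b[j]]["srna_id"], row["srna_id"]))

    table_a = SrnaTable.from_records(rows_a)
    table_b = SrnaTable.from_records(rows_b)
    return genome_a, genome_b, table_a, table_b, offset_map, truth


# ---------------------------------------------------------------------------
# Upstream signal planting
# ---------------------------------------------------------------------------

def _band_positions(band: tuple[int, int], window: int = 7) -> range:
    """Upstream positions covered by 7-nt windows ``band[0]..band[1]``."""
    return range(band[0], band[1] + window)


def plant_upstream_signals(
    genome: GenomeRecord,
    srna_table: SrnaTable,
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
) -> GenomeRecord:
    """Rewrite each asRNA's 61-nt upstream region to carry the configured
    GC dip, GC-skew bump, and motif; all edits stay inside those regions.

    Upstream position ``p`` (1 = nt adjacent to the transcript start,
    61 = farthest upstream) maps to genomic coordinate ``start - p`` for a
    plus-strand feature and ``end + p`` (complemented) for minus-strand.
    """
    if config.dip_depth > config.genome_gc:
        raise ValueError("dip_depth exceeds genome_gc")
    rng = _streams(config.seed)["upstream"]
    seq = bytearray(genome.sequence, "ascii")
    dip_pos = set(_band_positions(config.dip_band))
    skew_pos = set(_band_positions(config.skew_band))
    up = config.upstream_len
    motif = config.motif.upper()
    m_hi = config.motif_offset + len(motif) - 1  # motif spans positions offset..m_hi

    for row in srna_table.df.itertuples():
        if row.strand == "+":
            if row.start - up < 1:
                continue
        else:
            if row.end + up > len(genome):
                continue
        has_motif = bool(rng.random() < config.motif_prob)
        motif_inst = "".join(
            IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in motif
        )
        for p in range(1, up + 1):
            # a zero-effect band is left untouched, not resampled
            in_dip = p in dip_pos and config.dip_depth > 0
            in_skew = p in skew_pos and config.skew_height != 0
            base: str | None = None
            if has_motif and config.motif_offset <= p <= m_hi:
                # motif written 5'->3': position m_hi holds its first char
                base = motif_inst[m_hi - p]
            elif in_dip or in_skew:
                p_gc = config.genome_gc - (config.dip_depth if in_dip else 0.0)
                p_c = (1.0 + config.skew_height) / 2.0 if in_skew else 0.5
                if rng.random() < p_gc:
                    base = "C" if rng.random() < p_c else "G"
                else:
                    base = "A" if rng.random() < 0.5 else "T"
            if base is None:
                continue
            if row.strand == "+":
                g = row.start - p
                seq[g - 1] = ord(base)
            else:
                g = row.end + p
                seq[g - 1] = ord(base.translate(_COMPLEMENT))
        if ground_truth is not None:
            ground_truth.upstream_flags[row.srna_id] = {
                "dip": config.dip_depth > 0,
                "skew": config.skew_height > 0,
                "motif": has_motif and config.motif_prob > 0,
            }
    return genome.with_sequence(seq.decode("ascii"))


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    genome: GenomeRecord,
    srna_table: SrnaTable,
    depth: float,
    background: float = 0.0,
    gap_srnas: Sequence[str] = (),
    gap_len: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Poisson(depth) per-base read counts over sRNA intervals, Poisson
    (background) elsewhere.  ``gap_srnas`` get a zero-coverage gap punched
    into their middle — negative controls for the continuity check."""
    if depth < 0 or background < 0:
        raise ValueError("depth and background must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cov = (
        rng.poisson(background, size=len(genome)).astype(float)
        if background > 0
        else np.zeros(len(genome))
    )
    for row in srna_table.df.itertuples():
        cov[row.start - 1 : row.end] = rng.poisson(depth, size=row.end - row.start + 1)
    for sid in gap_srnas:
        sub = srna_table.df[srna_table.df.srna_id == sid]
        if sub.empty:
            raise KeyError(f"unknown sRNA id {sid!r}")
        row = sub.iloc[0]
        mid = (int(row.start) + int(row.end)) // 2
        half = max(1, gap_len // 2)
        cov[mid - half : mid - half + gap_len] = 0.0
    return cov
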