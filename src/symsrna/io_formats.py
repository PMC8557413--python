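"""Readers and writers for every external representation the pipeline touches.

All genomic intervals are 1-based and inclusive at every I/O boundary (the
GFF3 dialect).  Sequences are uppercase DNA over ``{A, C, G, T}``; IUPAC
ambiguity codes are rejected by default or, optionally, masked to ``A``
(the sensible prior for an ~84%-AT symbiont genome) with a warning.

Formats handled here: FASTA (via Biopython), GFF3 CDS features (via
gffutils), the sRNA coordinate table (TSV), dot-bracket secondary
structures, blockwise offset maps between two genomes, and per-base
coverage vectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_AMBIGUITY = frozenset("RYSWKMBDHVN")

#: Fixed leading column order of the sRNA table TSV; expression columns
#: (``expr_*``) follow in the order given.
SRNA_TABLE_COLUMNS = ["srna_id", "genome", "start", "end", "strand", "category"]

CATEGORIES = ("antisense", "utr", "intergenic", "unset")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsFeature:
    """One CDS annotation: 1-based inclusive ``start..end`` on ``strand``."""

    feature_id: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"feature {self.feature_id!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeRecord:
    """A genome sequence plus its strand-aware CDS annotation set."""

    genome_id: str
    sequence: str
    features: tuple[CdsFeature, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome {self.genome_id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "features", tuple(self.features))
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.genome_id!r}: non-ACGT characters {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise FormatError(
                    f"feature out of bounds: {f.feature_id!r} "
                    f"({f.start}..{f.end} on {len(self.sequence)}-bp genome)"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``start..end`` (1-based inclusive); minus strand is
        reverse-complemented so the result reads 5'→3' on that strand."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(f"interval {start}..{end} outside genome {self.genome_id!r}")
        s = self.sequence[start - 1 : end]
        return s if strand == "+" else revcomp(s)

    def with_sequence(self, sequence: str) -> "GenomeRecord":
        return replace(self, sequence=sequence)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    ambiguity: str = "reject",
) -> GenomeRecord:
    """Load a genome FASTA plus its GFF3 CDS annotation into a GenomeRecord.

    The GFF3 seqid must match the FASTA record id.  ``ambiguity`` is either
    ``"reject"`` (default) or ``"mask"`` (replace ambiguity codes with ``A``
    and log a warning).
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    for p in (fasta_path, gff_path):
        if not p.exists():
            raise FileNotFoundError(str(p))

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    rec = records[0]
    seq = str(rec.seq).upper()
    ambig = set(seq) & _AMBIGUITY
    if ambig:
        if ambiguity == "mask":
            logger.warning(
                "genome %s: masking ambiguity codes %s to A", rec.id, sorted(ambig)
            )
            seq = re.sub(f"[{''.join(sorted(_AMBIGUITY))}]", "A", seq)
        else:
            raise FormatError(
                f"genome {rec.id}: ambiguity codes {sorted(ambig)} present "
                "(use ambiguity='mask' to replace with A)"
            )

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features = []
    for f in db.features_of_type("CDS", order_by="start"):
        if f.seqid != rec.id:
            raise FormatError(
                f"{gff_path}: seqid {f.seqid!r} does not match FASTA header {rec.id!r}"
            )
        fid = f.attributes.get("ID", [f.id])[0]
        product = f.attributes.get("product", [None])[0]
        feat = CdsFeature(fid, f.start, f.end, f.strand, product)
        if feat.end > len(seq):
            raise FormatError(
                f"feature out of bounds: {fid!r} ({feat.start}..{feat.end} "
                f"on {len(seq)}-bp genome)"
            )
        features.append(feat)
    return GenomeRecord(rec.id, seq, tuple(features))


def write_genome(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write a GenomeRecord back out as FASTA + GFF3 (CDS features)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for f in genome.features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "symsrna",
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sRNA tables
# ---------------------------------------------------------------------------

@dataclass
class SrnaTable:
    """Predicted sRNA transcripts for one genome, as a validated DataFrame.

    Columns: ``srna_id, genome, start, end, strand, category`` plus zero or
    more ``expr_*`` expression columns, plus (after classification)
    ``target_cds`` and ``overlap_len``.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.df.empty and not len(self.df.columns):
            self.df = pd.DataFrame(columns=SRNA_TABLE_COLUMNS)
        missing = [c for c in SRNA_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"sRNA table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        for i, row in self.df.iterrows():
            if not (1 <= int(row.start) <= int(row.end)):
                raise FormatError(
                    f"sRNA {row.srna_id!r} (row {i}): invalid interval "
                    f"{row.start}..{row.end}"
                )
            if row.strand not in ("+", "-"):
                raise FormatError(f"sRNA {row.srna_id!r}: bad strand {row.strand!r}")
            if row.category not in CATEGORIES:
                raise FormatError(f"sRNA {row.srna_id!r}: bad category {row.category!r}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SrnaTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def expr_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("expr_")]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SrnaTable":
        df = pd.DataFrame(list(records))
        if df.empty:
            return cls()
        extra = [c for c in df.columns if c not in SRNA_TABLE_COLUMNS]
        return cls(df[SRNA_TABLE_COLUMNS + extra])


def read_srna_table(tsv_path: str | Path) -> SrnaTable:
    """Read a tab-separated sRNA table; malformed rows raise with their line number."""
    tsv_path = Path(tsv_path)
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in SRNA_TABLE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{tsv_path}: header missing columns {missing}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{tsv_path}:{lineno}: expected {len(header)} fields")
            row = dict(zip(header, parts))
            try:
                row["start"], row["end"] = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise FormatError(f"{tsv_path}:{lineno}: non-integer coordinate") from exc
            if row["start"] > row["end"] or row["start"] < 1:
                raise FormatError(
                    f"{tsv_path}:{lineno}: invalid interval {row['start']}..{row['end']}"
                )
            for c in header:
                if c.startswith("expr_") or c == "overlap_len":
                    row[c] = float(row[c])
            rows.append(row)
    df = pd.DataFrame(rows, columns=header)
    if not rows:
        df = pd.DataFrame(columns=header)
        df = df.astype({"start": int, "end": int})
    return SrnaTable(df)


def write_srna_table(table: SrnaTable, tsv_path: str | Path) -> None:
    """Write an sRNA table with a byte-stable column order (round-trips losslessly)."""
    extra = [c for c in table.df.columns if c not in SRNA_TABLE_COLUMNS]
    cols = SRNA_TABLE_COLUMNS + extra
    table.df[cols].to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dot-bracket structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotBracketStructure:
    """A secondary structure in dot-bracket notation with its base-pair table."""

    structure: str
    pairs: frozenset[tuple[int, int]] = field(default=frozenset())

    @property
    def length(self) -> int:
        return len(self.structure)


def parse_dot_bracket(text: str) -> DotBracketStructure:
    """Parse dot-bracket text into a structure with a 1-based pair table.

    Pairs are extracted by stack matching; unbalanced parentheses or
    characters outside ``(``, ``)``, ``.`` are rejected.
    """
    text = text.strip()
    bad = set(text) - set("().")
    if bad:
        raise FormatError(f"illegal dot-bracket characters: {sorted(bad)}")
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return DotBracketStructure(text, frozenset(pairs))


# ---------------------------------------------------------------------------
# Offset maps (blockwise coordinate correspondence between two genomes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffsetBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str = "+"  # '-' means the block maps with a strand flip

    def __post_init__(self) -> None:
        if self.a_end < self.a_start or self.b_end < self.b_start:
            raise FormatError("offset block with inverted interval")
        if (self.a_end - self.a_start) != (self.b_end - self.b_start):
            raise FormatError("offset block with unequal spans (indels unsupported)")
        if self.orientation not in ("+", "-"):
            raise FormatError(f"bad block orientation {self.orientation!r}")


@dataclass(frozen=True)
class OffsetMap:
    """Ordered non-overlapping alignment blocks mapping genome A onto genome B."""

    blocks: tuple[OffsetBlock, ...]

    def __post_init__(self) -> None:
        blocks = tuple(sorted(self.blocks, key=lambda b: b.a_start))
        object.__setattr__(self, "blocks", blocks)
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.a_start <= prev.a_end:
                raise FormatError("offset blocks overlap in genome A")
        for prev, cur in zip(
            sorted(blocks, key=lambda b: b.b_start), sorted(blocks, key=lambda b: b.b_start)[1:]
        ):
            if cur.b_start <= prev.b_end:
                raise FormatError("offset blocks overlap in genome B")

    def inverted(self) -> "OffsetMap":
        """The same correspondence read B→A."""
        return OffsetMap(
            tuple(
                OffsetBlock(b.b_start, b.b_end, b.a_start, b.a_end, b.orientation)
                for b in self.blocks
            )
        )


def read_offset_map(tsv_path: str | Path) -> OffsetMap:
    df = pd.read_csv(tsv_path, sep="\t")
    blocks = tuple(
        OffsetBlock(
            int(r.a_start), int(r.a_end), int(r.b_start), int(r.b_end), str(r.orientation)
        )
        for r in df.itertuples()
    )
    return OffsetMap(blocks)


def write_offset_map(omap: OffsetMap, tsv_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "a_start": b.a_start,
                "a_end": b.a_end,
                "b_start": b.b_start,
                "b_end": b.b_end,
                "orientation": b.orientation,
            }
            for b in omap.blocks
        ],
        columns=["a_start", "a_end", "b_start", "b_end", "orientation"],
    ).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage vectors
# ---------------------------------------------------------------------------

def read_coverage(tsv_path: str | Path, genome_length: int | None = None) -> np.ndarray:
    """Read a (pos, depth) TSV into a depth array indexed 0..L-1 for positions 1..L."""
    df = pd.read_csv(tsv_path, sep="\t")
    if not {"pos", "depth"} <= set(df.columns):
        raise FormatError(f"{tsv_path}: coverage TSV needs 'pos' and 'depth' columns")
    length = genome_length or int(df["pos"].max())
    cov = np.zeros(length, dtype=float)
    cov[df["pos"].to_numpy(int) - 1] = df["depth"].to_numpy(float)
    return cov


def write_coverage(coverage: Sequence[float], tsv_path: str | Path) -> None:
    cov = np.asarray(coverage)
    pd.DataFrame({"pos": np.arange(1, len(cov) + 1), "depth": cov}).to_csv(
        tsv_path, sep="\t", index=False
    )
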