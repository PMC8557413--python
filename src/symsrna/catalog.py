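"""Categorize predicted sRNAs against the annotation and tally pathways.

sRNAs fall into exactly one of three categories: *antisense* (≥1 nt
overlap with a CDS on the opposite strand), *UTR* (within a configurable
flank, default 50 nt, of a same-strand CDS without overlapping it), and
*intergenic* (everything else).  The antisense target is the
opposite-strand CDS with maximal overlap; ties break to the
lexicographically smallest feature id.

Also here: upper-quantile normalization of count libraries, the
differential-expression candidate filter (q ≤ 0.05 and a mean of ≥9 raw
reads across replicates — the DE test itself is consumed, not computed),
and pathway tallies of asRNA-targeted CDSs from a pathway map table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import FormatError, GenomeRecord, SrnaTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_srnas(
    srna_table: SrnaTable,
    genome: GenomeRecord,
    utr_flank: int = 50,
) -> SrnaTable:
    """Return a copy of the table with category, target_cds and overlap_len set."""
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for f in genome.features:
        trees[f.strand][f.start : f.end + 1] = f  # half-open internal, 1-based ends
    opposite = {"+": "-", "-": "+"}

    df = srna_table.df.copy()
    cats, targets, overlaps = [], [], []
    for row in df.itertuples():
        if row.end > len(genome) or row.start < 1:
            raise FormatError(
                f"sRNA {row.srna_id!r} outside genome bounds "
                f"({row.start}..{row.end} on {len(genome)} bp)"
            )
        anti = trees[opposite[row.strand]][row.start : row.end + 1]
        if anti:
            best = min(
                anti,
                key=lambda iv: (
                    -(min(row.end, iv.data.end) - max(row.start, iv.data.start) + 1),
                    # tie-break: lexicographically smallest id wins
                    iv.data.feature_id,
                ),
            )
            ov = min(row.end, best.data.end) - max(row.start, best.data.start) + 1
            ties = [
                iv.data.feature_id
                for iv in anti
                if min(row.end, iv.data.end) - max(row.start, iv.data.start) + 1 == ov
            ]
            if len(ties) > 1:
                logger.info(
                    "sRNA %s: target tie among %s, keeping %s",
                    row.srna_id, sorted(ties), best.data.feature_id,
                )
            cats.append("antisense")
            targets.append(best.data.feature_id)
            overlaps.append(ov)
            continue
        same = trees[row.strand]
        if not same[row.start : row.end + 1] and same[
            max(1, row.start - utr_flank) : row.end + utr_flank + 1
        ]:
            cats.append("utr")
            targets.append(None)
            overlaps.append(0)
        else:
            cats.append("intergenic")
            targets.append(None)
            overlaps.append(0)
    df["category"] = cats
    df["target_cds"] = targets
    df["overlap_len"] = overlaps
    return SrnaTable(df)


# ---------------------------------------------------------------------------
# Upper-quantile normalization
# ---------------------------------------------------------------------------

def upper_quantile_normalize(
    counts: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Scale each sample (column) so its 75th percentile of nonzero counts
    equals the across-sample reference (the mean of those percentiles).

    Returns the normalized matrix and the per-sample scaling factors.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("counts must be a 2-D matrix (features x samples)")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    uq = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        nz = arr[:, j][arr[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {j}: all-zero counts, cannot normalize")
        uq[j] = np.percentile(nz, 75)
    ref = uq.mean()
    factors = ref / uq
    logger.info("upper-quantile factors: %s", np.round(factors, 4).tolist())
    out = arr * factors
    if isinstance(counts, pd.DataFrame):
        out = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out, factors


# ---------------------------------------------------------------------------
# DE candidate filter
# ---------------------------------------------------------------------------

def filter_de_candidates(
    srna_table: SrnaTable,
    counts: pd.DataFrame,
    qvalues: pd.Series,
    q_max: float = 0.05,
    min_mean_reads: float = 9.0,
) -> SrnaTable:
    """Keep sRNAs with q ≤ 0.05 AND a mean of ≥9 raw reads across replicates.

    ``counts`` is indexed by srna_id with one column per replicate;
    ``qvalues`` is indexed by srna_id (the DE test is external).
    """
    ids = srna_table.df["srna_id"]
    missing = set(ids) - set(counts.index)
    if missing or counts.shape[1] < 1:
        raise ValueError(f"replicate counts missing for sRNAs: {sorted(missing)}")
    mean_reads = counts.loc[ids].mean(axis=1).to_numpy()
    q = qvalues.loc[ids].to_numpy(float)
    keep = (q <= q_max) & (mean_reads >= min_mean_reads)
    logger.info("DE filter: %d of %d sRNAs kept", int(keep.sum()), len(ids))
    return SrnaTable(srna_table.df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Pathway tallies
# ---------------------------------------------------------------------------

@dataclass
class PathwayTally:
    n_pathways: int
    n_essential_aa: int
    per_pathway: dict[str, list[str]]


def load_pathway_map(path: str | Path | None = None, genome: str | None = None) -> pd.DataFrame:
    """Load a pathway map TSV (cds_id, pathway, essential_aa), optionally
    filtered to one genome column of the packaged table."""
    if path is None:
        src = resources.files("symsrna.data").joinpath("panther_pathways.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if genome is not None:
        df = df[df["genome"] == genome].reset_index(drop=True)
    dup = df.duplicated(subset=["cds_id", "pathway"])
    if dup.any():
        raise FormatError("pathway map has duplicate (cds_id, pathway) pairs")
    return df


def tally_pathways(srna_table: SrnaTable, pathway_map: pd.DataFrame) -> PathwayTally:
    """Distinct pathways with ≥1 asRNA-targeted CDS, and the essential-amino-
    acid subset counted from the map's ``essential_aa`` flag."""
    df = srna_table.df
    if "target_cds" not in df.columns:
        targets: set = set()
    else:
        targets = set(df.loc[df["category"] == "antisense", "target_cds"].dropna())
    unmapped = targets - set(pathway_map["cds_id"])
    if unmapped:
        logger.info("CDSs without pathway annotation: %s", sorted(unmapped))
    hit = pathway_map[pathway_map["cds_id"].isin(targets)]
    per_pathway = {
        pw: sorted(g["cds_id"]) for pw, g in hit.groupby("pathway", sort=True)
    }
    essential = hit.loc[hit["essential_aa"] == 1, "pathway"].nunique()
    return PathwayTally(len(per_pathway), int(essential), per_pathway)
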