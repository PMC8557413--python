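"""End-to-end orchestration: simulate → classify → conserve → divergence →
covary → upstream, with per-stage TSV outputs, structured logging of
record counts at every filter, and a run manifest for reproducibility.

Every stage is also runnable standalone (see :mod:`symsrna.cli`) with
identical results; the pipeline only sequences them and carries one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import classify_srnas
from .conservation import call_conserved, pairing_report, z_proportion_test
from .divergence import CodonAlignment, sliding_window_conservation_test
from .io_formats import (
    DotBracketStructure,
    GenomeRecord,
    SrnaTable,
    read_genome,
    read_offset_map,
    read_srna_table,
    write_genome,
    write_offset_map,
    write_srna_table,
)
from .structure import StructureAlignment, count_compensatory
from .synthetic import (
    SimulationConfig,
    plant_upstream_signals,
    simulate_coverage,
    simulate_genome_pair,
)
from .upstream import (
    extract_asrna_upstreams,
    extract_cds_upstreams,
    gc_permutation_test,
    motif_site_export,
    skew_profiles,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, at their canonical defaults."""

    seed: int = 0
    conservation_nt: int = 15      # |coordinate offset| allowed for orthologs
    flank_nt: int = 15             # footprint extension for the selection test
    q_max: float = 0.05            # DE candidate q-value cutoff
    min_mean_reads: float = 9.0    # DE candidate mean raw reads
    alpha_window: float = 0.05     # per-window GC% significance
    alpha_selection: float = 0.01  # sliding-window conservation significance
    n_shuffles: int = 100          # permutation null size
    window_nt: int = 7
    step_nt: int = 1
    upstream_nt: int = 61
    utr_flank: int = 50
    min_depth: float = 1.0
    motif: str = "TANAAT"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _synthetic_consensus(seq: str) -> DotBracketStructure:
    """A synthetic hairpin-style consensus for a region: outermost positions
    pair inward while the reference bases are complementary (stand-in for an
    externally folded consensus when only simulated data exist)."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    L = len(seq)
    struct = ["."] * L
    pairs = []
    i, j = 0, L - 1
    while j - i > 3:
        if comp[seq[i]] == seq[j]:
            struct[i], struct[j] = "(", ")"
            pairs.append((i + 1, j + 1))
            i, j = i + 1, j - 1
        else:
            i += 1
    return DotBracketStructure("".join(struct), frozenset(pairs))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    simulate: bool = True,
    inputs: dict | None = None,
) -> dict:
    """Run every stage; returns a dict of summary numbers.

    With ``simulate=True`` all inputs come from the synthetic generator
    under ``config.simulation``; otherwise ``inputs`` must name
    fasta/gff/srna-table/offset-map paths for both lineages.
    A stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # -- stage: inputs ---------------------------------------------------
    stage = "simulate" if simulate else "load"
    try:
        if simulate:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            ga, gb, ta, tb, omap, truth = simulate_genome_pair(sim)
            ga = plant_upstream_signals(ga, ta, sim, ground_truth=truth)
            cov_a = simulate_coverage(ga, ta, sim.coverage_depth, seed=sim.seed)
            cov_b = simulate_coverage(gb, tb, sim.coverage_depth, seed=sim.seed + 1)
            write_genome(ga, outdir / "genomeA.fasta", outdir / "genomeA.gff3")
            write_genome(gb, outdir / "genomeB.fasta", outdir / "genomeB.gff3")
            write_offset_map(omap, outdir / "offset_map.tsv")
        else:
            if not inputs:
                raise StageError("load", "no inputs provided and simulate=False")
            for key in ("fasta_a", "gff_a", "fasta_b", "gff_b", "srna_a", "srna_b", "offset_map"):
                if key not in inputs:
                    raise StageError("load", f"missing input {key!r}")
                if not Path(inputs[key]).exists():
                    raise StageError("load", f"missing file {inputs[key]}")
            ga = read_genome(inputs["fasta_a"], inputs["gff_a"])
            gb = read_genome(inputs["fasta_b"], inputs["gff_b"])
            ta = read_srna_table(inputs["srna_a"])
            tb = read_srna_table(inputs["srna_b"])
            omap = read_offset_map(inputs["offset_map"])
            cov_a = cov_b = None
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage: classify -------------------------------------------------
    try:
        ta = classify_srnas(ta, ga, utr_flank=config.utr_flank)
        tb = classify_srnas(tb, gb, utr_flank=config.utr_flank)
        write_srna_table(ta, outdir / "srnaA.classified.tsv")
        write_srna_table(tb, outdir / "srnaB.classified.tsv")
        for name, t in (("A", ta), ("B", tb)):
            counts = t.df["category"].value_counts().to_dict()
            summary[f"categories_{name}"] = counts
            logger.info("classify %s: %s", name, counts)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    # -- stage: conserve -------------------------------------------------
    try:
        pairs = call_conserved(
            ta, tb, omap, cov_a, cov_b,
            nt_threshold=config.conservation_nt, min_depth=config.min_depth,
        )
        pairing_report(pairs).to_csv(outdir / "conserved_pairs.tsv", sep="\t", index=False)
        n_cds_a, n_cds_b = len(ga.features), len(gb.features)
        zt_a = z_proportion_test(len(pairs), len(ta), n_cds_a)
        zt_b = z_proportion_test(len(pairs), len(tb), n_cds_b)
        summary["n_conserved"] = len(pairs)
        summary["z_a"], summary["p_a"] = round(zt_a.z, 3), round(zt_a.p_value, 5)
        summary["z_b"], summary["p_b"] = round(zt_b.z, 3), round(zt_b.p_value, 5)
    except Exception as exc:
        raise StageError("conserve", str(exc)) from exc

    # -- stage: divergence -----------------------------------------------
    try:
        feats_a = {f.feature_id: f for f in ga.features}
        feats_b = {f.feature_id: f for f in gb.features}
        rows = []
        ta_by_id = ta.df.set_index("srna_id")
        tb_by_id = tb.df.set_index("srna_id")
        for p in pairs:
            ra, rb = ta_by_id.loc[p.srna_a], tb_by_id.loc[p.srna_b]
            if not isinstance(ra.target_cds, str) or not isinstance(rb.target_cds, str):
                continue
            fa, fb = feats_a[ra.target_cds], feats_b[rb.target_cds]
            aln = CodonAlignment(
                ga.subseq(fa.start, fa.end, fa.strand),
                gb.subseq(fb.start, fb.end, fb.strand),
            )
            if fa.strand == "+":
                local = (ra.start - fa.start + 1, ra.end - fa.start + 1)
            else:
                local = (fa.end - ra.end + 1, fa.end - ra.start + 1)
            res = sliding_window_conservation_test(
                aln, local, flank_nt=config.flank_nt, alpha=config.alpha_selection
            )
            rows.append(
                {
                    "srna_a": p.srna_a,
                    "gene": ra.target_cds,
                    "region_start_codon": res.region_bounds[0],
                    "region_end_codon": res.region_bounds[1],
                    "region_d": res.srna_region_distance,
                    "mean_window_d": float(np.mean(res.window_distances))
                    if res.window_distances else float("nan"),
                    "t": res.t_stat,
                    "p": res.p_value,
                    "significant": res.significant,
                    "untestable": res.untestable,
                }
            )
        div_df = pd.DataFrame(rows)
        div_df.to_csv(outdir / "divergence_windows.tsv", sep="\t", index=False)
        summary["n_selection_significant"] = int(div_df["significant"].sum()) if len(div_df) else 0
        summary["n_selection_tested"] = int((~div_df["untestable"]).sum()) if len(div_df) else 0
    except Exception as exc:
        raise StageError("divergence", str(exc)) from exc

    # -- stage: covary ----------------------------------------------------
    try:
        rows = []
        for p in pairs:
            ra, rb = ta_by_id.loc[p.srna_a], tb_by_id.loc[p.srna_b]
            from .conservation import map_coordinates

            mapped = map_coordinates(omap, (int(ra.start), int(ra.end)))
            if mapped is None:
                continue
            seq_a = ga.subseq(int(ra.start), int(ra.end), ra.strand)
            seq_b = gb.subseq(mapped.start, mapped.end, ra.strand)
            consensus = _synthetic_consensus(seq_a)
            rep = count_compensatory(StructureAlignment((seq_a, seq_b), consensus))
            rows.append(
                {
                    "srna_a": p.srna_a,
                    "srna_b": p.srna_b,
                    "n_pairs": rep.n_pairs,
                    "n_compensatory": rep.n_compensatory,
                    "n_inconsistent": rep.n_inconsistent,
                }
            )
        cov_df = pd.DataFrame(rows)
        cov_df.to_csv(outdir / "covariation.tsv", sep="\t", index=False)
        summary["n_structures"] = len(cov_df)
    except Exception as exc:
        raise StageError("covary", str(exc)) from exc

    # -- stage: upstream ---------------------------------------------------
    try:
        as_kept, as_drop = extract_asrna_upstreams(ga, ta, length=config.upstream_nt)
        cds_kept, cds_drop = extract_cds_upstreams(ga, length=config.upstream_nt)
        logger.info(
            "upstream: asRNA %d kept / %d dropped; CDS %d kept / %d dropped",
            len(as_kept), len(as_drop), len(cds_kept), len(cds_drop),
        )
        summary["n_upstream_asrna"] = len(as_kept)
        summary["n_upstream_cds"] = len(cds_kept)
        profile = gc_permutation_test(
            as_kept, n_shuffles=config.n_shuffles, alpha=config.alpha_window,
            seed=config.seed, window=config.window_nt,
        )
        profile.to_csv(outdir / "gc_profile.tsv", sep="\t", index=False)
        summary["n_windows_significant"] = int(profile["significant"].sum())
        if cds_kept:
            sp_as, sp_cds = skew_profiles(as_kept, cds_kept, window=config.window_nt)
            sp_as.assign(set="asRNA").pipe(
                lambda d: pd.concat([d, sp_cds.assign(set="CDS")])
            ).to_csv(outdir / "skew_profiles.tsv", sep="\t", index=False)
        frac = motif_site_export(
            as_kept, outdir / "upstream_regions.fasta", motif=config.motif
        )
        summary["motif_fraction"] = round(float(frac), 4) if frac is not None else None
    except Exception as exc:
        raise StageError("upstream", str(exc)) from exc

    # -- manifest + summary ------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg_dict,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("symsrna run summary\n")
        for k, v in summary.items():
            fh.write(f"{k}: {v}\n")
    return summary
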