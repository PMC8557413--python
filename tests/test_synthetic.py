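"""Generator contracts: determinism, composition control, planted signals."""

import dataclasses

import numpy as np
import pytest

from symsrna.conservation import map_coordinates
from symsrna.synthetic import (
    SimulationConfig,
    plant_upstream_signals,
    simulate_coverage,
    simulate_genome_pair,
    translate_codon,
    _band_positions,
)


def test_same_seed_gives_byte_identical_outputs(small_config):
    ga1, gb1, ta1, tb1, om1, tr1 = simulate_genome_pair(small_config)
    ga2, gb2, ta2, tb2, om2, tr2 = simulate_genome_pair(small_config)
    assert ga1.sequence == ga2.sequence and gb1.sequence == gb2.sequence
    assert ta1 == ta2 and tb1 == tb2
    assert om1 == om2 and tr1.pairs == tr2.pairs


def test_different_seed_changes_sequence(small_config):
    ga1, *_ = simulate_genome_pair(small_config)
    ga2, *_ = simulate_genome_pair(dataclasses.replace(small_config, seed=43))
    assert ga1.sequence != ga2.sequence


def test_gc_composition_within_one_point_of_target():
    cfg = SimulationConfig(seed=5, n_cds=80, mean_cds_len=800, n_asrna=5,
                           n_asrna_b=5, n_conserved=2)
    ga, gb, *_ = simulate_genome_pair(cfg)
    assert len(ga) >= 50_000
    for g in (ga, gb):
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert abs(gc - cfg.genome_gc) < 0.01


def test_no_noise_limit_maps_exactly(small_config):
    cfg = dataclasses.replace(
        small_config, n_asrna_b=None, n_conserved=None, frac_conserved=1.0,
        coord_jitter_sd=0.0,
    )
    ga, gb, ta, tb, omap, truth = simulate_genome_pair(cfg)
    assert len(truth.pairs) == cfg.n_asrna
    b_rows = tb.df.set_index("srna_id")
    a_rows = ta.df.set_index("srna_id")
    for a_id, b_id in truth.pairs:
        ra, rb = a_rows.loc[a_id], b_rows.loc[b_id]
        mapped = map_coordinates(omap, (int(ra.start), int(ra.end)))
        assert (mapped.start, mapped.end) == (int(rb.start), int(rb.end))


def test_cds_sequences_stay_in_frame_without_internal_stops(small_pair):
    ga, gb, *_ = small_pair
    for g in (ga, gb):
        for f in g.features:
            cds = g.subseq(f.start, f.end, f.strand)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG" and cds[-3:] == "TAA"
            aas = [translate_codon(cds[i : i + 3]) for i in range(3, len(cds) - 3, 3)]
            assert "*" not in aas


def test_conserved_footprints_diverge_less(small_pair):
    """Amino-acid mismatch inside planted conserved footprints is far below
    the genome-wide level (0.05 vs 0.4 expected substitutions/site)."""
    ga, gb, ta, tb, omap, truth = small_pair
    feats_a = {f.feature_id: f for f in ga.features}
    feats_b = {f.feature_id: f for f in gb.features}
    inside = outside = in_n = out_n = 0
    for a_id, _ in truth.pairs:
        host = truth.host_cds[a_id]
        fa = feats_a[host]
        fb = feats_b["cdsB_" + host.split("_")[1]]
        ca = ga.subseq(fa.start, fa.end, fa.strand)
        cb = gb.subseq(fb.start, fb.end, fb.strand)
        s, e = truth.footprints[a_id]
        if fa.strand == "+":
            lo, hi = s - fa.start, e - fa.start
        else:
            lo, hi = fa.end - e, fa.end - s
        for i in range(1, len(ca) // 3 - 1):
            diff = translate_codon(ca[3 * i : 3 * i + 3]) != translate_codon(cb[3 * i : 3 * i + 3])
            if lo // 3 <= i <= hi // 3:
                inside += diff
                in_n += 1
            else:
                outside += diff
                out_n += 1
    assert inside / in_n < 0.15
    assert outside / out_n > 0.25


class TestPlantUpstreamSignals:
    def test_zero_signals_leave_genome_unchanged(self, small_pair, small_config):
        ga, _, ta, *_ = small_pair
        cfg = dataclasses.replace(
            small_config, dip_depth=0.0, skew_height=0.0, motif_prob=0.0
        )
        assert plant_upstream_signals(ga, ta, cfg).sequence == ga.sequence

    def test_dip_depth_exceeding_gc_rejected(self, small_pair, small_config):
        ga, _, ta, *_ = small_pair
        with pytest.raises(ValueError):
            dataclasses.replace(small_config, dip_depth=0.5)

    def test_planted_dip_lowers_band_gc_by_ten_points(self):
        cfg = SimulationConfig(
            seed=9, n_cds=220, mean_cds_len=700, n_asrna=200, n_asrna_b=0,
            n_conserved=0, dip_depth=0.10, skew_height=0.0, motif_prob=0.0,
        )
        ga, _, ta, *_ = simulate_genome_pair(cfg)
        ga2 = plant_upstream_signals(ga, ta, cfg)
        band = set(_band_positions(cfg.dip_band))
        in_gc, in_n, out_gc, out_n = 0, 0, 0, 0
        for row in ta.df.itertuples():
            for p in range(1, 62):
                g = row.start - p if row.strand == "+" else row.end + p
                is_gc = ga2.sequence[g - 1] in "GC"
                if p in band:
                    in_gc += is_gc
                    in_n += 1
                elif p not in set(_band_positions(cfg.skew_band)):
                    out_gc += is_gc
                    out_n += 1
        assert abs((out_gc / out_n) - (in_gc / in_n) - cfg.dip_depth) < 0.02

    def test_motif_prob_one_plants_motif_at_fixed_offset(self, small_pair, small_config):
        from symsrna.upstream import extract_upstream, iupac_regex

        ga, _, ta, *_ = small_pair
        cfg = dataclasses.replace(
            small_config, dip_depth=0.0, skew_height=0.0, motif_prob=1.0
        )
        ga2 = plant_upstream_signals(ga, ta, cfg)
        pat = iupac_regex(cfg.motif)
        lo = cfg.motif_offset
        hi = cfg.motif_offset + len(cfg.motif) - 1
        for row in ta.df.itertuples():
            r = extract_upstream(
                ga2, row.srna_id, row.start, row.end, row.strand,
                check_cds_overlap=False,
            )
            site = "".join(r.position(p) for p in range(hi, lo - 1, -1))
            assert pat.fullmatch(site)

    def test_edits_confined_to_upstream_regions(self, small_pair, small_config):
        ga, _, ta, *_ = small_pair
        ga2 = plant_upstream_signals(ga, ta, small_config)
        allowed = set()
        for row in ta.df.itertuples():
            for p in range(1, 62):
                allowed.add(row.start - p if row.strand == "+" else row.end + p)
        changed = {
            i + 1 for i, (a, b) in enumerate(zip(ga.sequence, ga2.sequence)) if a != b
        }
        assert changed <= allowed


class TestSimulateCoverage:
    def test_zero_depth_gives_all_zero(self, small_pair):
        ga, _, ta, *_ = small_pair
        assert not simulate_coverage(ga, ta, 0.0).any()

    def test_poisson_mean_within_sampling_error(self, small_pair):
        ga, _, ta, *_ = small_pair
        cov = simulate_coverage(ga, ta, 50.0, seed=3)
        row = ta.df.iloc[0]
        vals = cov[row.start - 1 : row.end]
        n = len(vals)
        assert abs(vals.mean() - 50.0) < 3 * np.sqrt(50.0 / n)

    def test_gap_punches_zero_coverage(self, small_pair):
        ga, _, ta, *_ = small_pair
        sid = ta.df.iloc[0].srna_id
        cov = simulate_coverage(ga, ta, 50.0, gap_srnas=[sid], seed=3)
        row = ta.df.iloc[0]
        assert (cov[row.start - 1 : row.end] == 0).any()

    def test_background_only_outside_srnas(self, small_pair):
        ga, _, ta, *_ = small_pair
        cov = simulate_coverage(ga, ta, 50.0, seed=3)
        mask = np.ones(len(ga), dtype=bool)
        for row in ta.df.itertuples():
            mask[row.start - 1 : row.end] = False
        assert not cov[mask].any()
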