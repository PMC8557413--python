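"""Upstream extraction, window statistics, permutation null, motif scan."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symsrna.io_formats import CdsFeature, revcomp
from symsrna.synthetic import random_dna
from symsrna.upstream import (
    UPSTREAM_LEN,
    dinucleotide_shuffle,
    extract_asrna_upstreams,
    extract_upstream,
    gc_percent,
    gc_permutation_test,
    gc_skew,
    iupac_regex,
    motif_fraction,
    motif_site_export,
    shuffle_codes,
    skew_profile,
    skew_profiles,
    window_scan,
    _encode,
)
from tests.conftest import make_genome, make_srna_table


class TestExtractUpstream:
    def test_plus_strand_start_100_gives_39_to_99_forward(self):
        seq = "".join("ACGT"[(i // 1) % 4] for i in range(200))
        g = make_genome(seq)
        r = extract_upstream(g, "s1", 100, 150, "+", check_cds_overlap=False)
        assert not r.excluded
        assert r.sequence == seq[38:99]
        assert r.position(1) == seq[98]  # genomic 99, adjacent to the start

    def test_minus_strand_end_500_gives_501_to_561_revcomp(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 700, 0.25)
        g = make_genome(seq)
        r = extract_upstream(g, "s1", 450, 500, "-", check_cds_overlap=False)
        assert r.sequence == revcomp(seq[500:561])
        assert r.position(1) == revcomp(seq[500])  # genomic 501

    def test_truncated_region_excluded_as_genome_edge(self):
        g = make_genome("A" * 200)
        r = extract_upstream(g, "s1", 30, 90, "+", check_cds_overlap=False)
        assert r.excluded and r.reason == "genome_edge"

    def test_circular_flag_wraps_instead_of_excluding(self):
        g = make_genome("ACGT" * 50)
        r = extract_upstream(g, "s1", 30, 90, "+", circular=True, check_cds_overlap=False)
        assert not r.excluded
        assert len(r.sequence) == 61

    def test_overlap_with_foreign_cds_excluded(self):
        g = make_genome("A" * 300, [CdsFeature("c1", 50, 120, "+")])
        r = extract_upstream(g, "s1", 150, 200, "+")
        assert r.excluded and r.reason == "cds_overlap"
        # exempting the overlapping CDS as the asRNA's own target keeps it
        r2 = extract_upstream(g, "s1", 150, 200, "+", own_cds_ids={"c1"})
        assert not r2.excluded


class TestWindowStats:
    def test_gc_percent_example(self):
        assert gc_percent("CCGGAAT") == pytest.approx(400 / 7)

    def test_gc_skew_examples(self):
        assert gc_skew("CCGGAAT") == 0.0
        assert gc_skew("CCCAAAA") == 1.0
        assert gc_skew("AAAATTT") == 0.0  # zero-denominator convention

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            gc_percent("ACGX")

    def test_scan_yields_exactly_55_windows(self):
        vals = window_scan("A" * 61, gc_percent)
        assert len(vals) == 61 - 7 + 1 == 55

    def test_constant_sequence_gives_identical_values(self):
        vals = window_scan("C" * 61, gc_percent)
        assert (vals == 100.0).all()

    def test_single_c_at_position_1_hits_only_window_1(self):
        # position 1 = nt adjacent to the start = LAST character of the string
        seq = "A" * 60 + "C"
        vals = window_scan(seq, gc_skew)
        assert vals[0] == 1.0
        assert (vals[1:] == 0.0).all()

    def test_scan_matches_direct_recomputation_on_random_regions(self, rng):
        for _ in range(100):
            seq = random_dna(rng, 61, float(rng.uniform(0.1, 0.9)))
            for stat in (gc_percent, gc_skew):
                vals = window_scan(seq, stat)
                for w in (1, 7, 23, 40, 55):
                    # positions w..w+6; position p is string index 61-p
                    window = "".join(seq[61 - p] for p in range(w, w + 7))
                    assert vals[w - 1] == pytest.approx(stat(window))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            window_scan("ACGT", gc_percent)

    def test_gc_plus_at_is_always_100(self, rng):
        seq = random_dna(rng, 61, 0.3)
        gc = window_scan(seq, gc_percent)
        at = window_scan(seq, lambda s: 100.0 - gc_percent(s))
        np.testing.assert_allclose(gc + at, 100.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=7, max_size=61))
def test_gc_skew_sign_flips_under_cg_exchange(seq):
    swapped = seq.translate(str.maketrans("CG", "GC"))
    assert gc_skew(swapped) == pytest.approx(-gc_skew(seq))
    assert -1.0 <= gc_skew(seq) <= 1.0


class TestPermutationTest:
    def test_permutations_preserve_base_multisets(self, rng):
        codes = _encode([random_dna(rng, 61, 0.3) for _ in range(5)])
        perms = shuffle_codes(codes, 100, rng)
        for r in range(5):
            expect = np.bincount(codes[r], minlength=4)
            for s in range(100):
                np.testing.assert_array_equal(
                    np.bincount(perms[r, s], minlength=4), expect
                )

    def test_fixed_seed_reproducible_bit_for_bit(self, rng):
        regions = [random_dna(rng, 61, 0.2) for _ in range(10)]
        p1 = gc_permutation_test(regions, seed=7)
        p2 = gc_permutation_test(regions, seed=7)
        assert p1.equals(p2)

    def test_fewer_than_three_regions_rejected(self):
        with pytest.raises(ValueError):
            gc_permutation_test(["A" * 61, "C" * 61])

    def test_profile_shape_and_columns(self, rng):
        prof = gc_permutation_test([random_dna(rng, 61, 0.2) for _ in range(8)], seed=1)
        assert list(prof.window) == list(range(1, 56))
        assert (prof.n == 8).all()
        assert {"mean", "se", "null_mean", "t", "p", "significant", "direction"} <= set(prof.columns)
        assert (prof.se >= 0).all()

    def test_null_flag_rate_near_alpha(self, rng):
        """Composition-uniform random regions should trigger ≈5% of windows."""
        flags = total = 0
        for _ in range(60):
            regions = [random_dna(rng, 61, 0.16) for _ in range(30)]
            prof = gc_permutation_test(regions, seed=int(rng.integers(2**31)))
            flags += int(prof.significant.sum())
            total += len(prof)
        assert 0.02 < flags / total < 0.08

    def test_dinucleotide_shuffle_preserves_dinucleotides(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 61, 0.3)
            out = dinucleotide_shuffle(seq, rng)
            count = lambda s: sorted((a + b) for a, b in zip(s, s[1:]))
            assert count(out) == count(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]


class TestSkewProfiles:
    def test_planted_skew_bump_raises_asrna_profile_in_band_only(self):
        """A C-over-G excess planted in windows 46-54 of asRNA upstream
        regions shows up in their skew profile but not in an unplanted
        (CDS-like) region set."""
        import dataclasses

        from symsrna.catalog import classify_srnas
        from symsrna.synthetic import (
            SimulationConfig,
            plant_upstream_signals,
            simulate_genome_pair,
        )
        from symsrna.upstream import extract_asrna_upstreams

        cfg = SimulationConfig(
            seed=13, n_cds=80, mean_cds_len=700, n_asrna=40, n_asrna_b=0,
            n_conserved=0, dip_depth=0.0, skew_height=0.5, motif_prob=0.0,
        )
        ga, _, ta, *_ = simulate_genome_pair(cfg)
        planted = plant_upstream_signals(ga, ta, cfg)
        t = classify_srnas(ta, planted)
        kept, _ = extract_asrna_upstreams(planted, t)
        plain_kept, _ = extract_asrna_upstreams(ga, classify_srnas(ta, ga))
        prof, plain = skew_profiles(kept, plain_kept)
        band = prof.window.between(*cfg.skew_band)
        assert prof.loc[band, "mean"].mean() > 0.25
        assert abs(plain.loc[band, "mean"].mean()) < 0.15
        out = prof.window < 40  # windows free of the planted band
        assert abs(prof.loc[out, "mean"].mean()) < 0.15

    def test_identical_sets_give_identical_profiles(self, rng):
        regions = [random_dna(rng, 61, 0.3) for _ in range(10)]
        pa, pc = skew_profiles(regions, list(regions))
        assert pa.equals(pc)

    def test_all_at_regions_give_flat_zero_profile(self):
        prof = skew_profile(["AT" * 30 + "A"] * 5)
        assert (prof["mean"] == 0.0).all()
        assert (prof["se"] == 0.0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            skew_profile([])


class TestMotifScan:
    def test_iupac_n_matches_any_base(self):
        assert motif_fraction(["T" * 30 + "TACAAT" + "T" * 25], "TANAAT") == 1.0

    def test_fraction_counts_regions_with_any_match(self):
        regions = ["A" * 61, "G" * 27 + "TATAAT" + "G" * 28]
        assert motif_fraction(regions, "TANAAT") == 0.5

    def test_malformed_motif_rejected(self):
        with pytest.raises(ValueError):
            iupac_regex("TAZAAT")

    def test_matches_bruteforce_iupac_expansion(self, rng):
        from symsrna.synthetic import IUPAC

        motif = "TAWAVT"
        expansions = [
            "".join(choice)
            for choice in itertools.product(*[IUPAC[c] for c in motif])
        ]
        regions = [random_dna(rng, 61, 0.35) for _ in range(50)]
        expect = sum(
            any(e in r for e in expansions) for r in regions
        ) / len(regions)
        assert motif_fraction(regions, motif) == pytest.approx(expect)

    def test_export_writes_fasta_and_subinterval(self, tmp_path, rng):
        regions, _ = _regions_fixture(rng)
        out = tmp_path / "up.fasta"
        frac = motif_site_export(regions, out, motif="TANAAT")
        text = out.read_text()
        assert text.count(">") == len(regions)
        assert frac is not None
        # sub-interval export: positions 33..48 -> 16-nt sequences
        motif_site_export(regions, out, position_interval=(33, 48))
        seqs = [l for l in out.read_text().splitlines() if not l.startswith(">")]
        assert all(len(s) == 16 for s in seqs)


def _regions_fixture(rng):
    from symsrna.upstream import UpstreamRegion

    regions = [
        UpstreamRegion(f"r{i}", random_dna(rng, UPSTREAM_LEN, 0.2)) for i in range(6)
    ]
    return regions, None
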