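"""Categorization, normalization, DE filtering and pathway tallies."""

import numpy as np
import pandas as pd
import pytest

from symsrna.catalog import (
    classify_srnas,
    filter_de_candidates,
    load_pathway_map,
    tally_pathways,
    upper_quantile_normalize,
)
from symsrna.io_formats import CdsFeature, FormatError, GenomeRecord, SrnaTable
from tests.conftest import make_genome, make_srna_table


def _genome_with(features, length=1000):
    return make_genome("A" * length, features)


class TestClassify:
    def test_srna_inside_opposite_strand_cds_is_antisense(self):
        g = _genome_with([CdsFeature("c1", 100, 400, "-")])
        t = classify_srnas(make_srna_table([("s1", "g1", 150, 250, "+")]), g)
        row = t.df.iloc[0]
        assert row.category == "antisense"
        assert row.target_cds == "c1"
        assert row.overlap_len == 101

    def test_srna_far_from_everything_is_intergenic(self):
        g = _genome_with([CdsFeature("c1", 100, 200, "+"), CdsFeature("c2", 700, 800, "+")])
        t = classify_srnas(make_srna_table([("s1", "g1", 400, 450, "+")]), g)
        assert t.df.iloc[0].category == "intergenic"

    def test_utr_within_flank_of_same_strand_cds(self):
        g = _genome_with([CdsFeature("c1", 100, 200, "+")])
        t = classify_srnas(make_srna_table([("s1", "g1", 220, 240, "+")]), g, utr_flank=50)
        assert t.df.iloc[0].category == "utr"
        t = classify_srnas(make_srna_table([("s1", "g1", 300, 320, "+")]), g, utr_flank=50)
        assert t.df.iloc[0].category == "intergenic"

    def test_target_is_cds_with_maximal_overlap(self):
        g = _genome_with(
            [CdsFeature("c1", 100, 209, "-"), CdsFeature("c2", 210, 400, "-")]
        )
        # overlaps c1 by 10 nt and c2 by 40 nt
        t = classify_srnas(make_srna_table([("s1", "g1", 200, 249, "+")]), g)
        assert t.df.iloc[0].target_cds == "c2"
        assert t.df.iloc[0].overlap_len == 40

    def test_equal_overlap_tie_breaks_to_smallest_id(self):
        g = _genome_with(
            [CdsFeature("cB", 100, 219, "-"), CdsFeature("cA", 220, 400, "-")]
        )
        t = classify_srnas(make_srna_table([("s1", "g1", 200, 239, "+")]), g)
        assert t.df.iloc[0].target_cds == "cA"

    def test_out_of_bounds_srna_rejected(self):
        g = _genome_with([CdsFeature("c1", 100, 200, "+")], length=300)
        with pytest.raises(FormatError, match="outside genome"):
            classify_srnas(make_srna_table([("s1", "g1", 290, 310, "+")]), g)

    def test_every_srna_gets_exactly_one_category(self, small_pair):
        ga, _, ta, *_ = small_pair
        t = classify_srnas(ta, ga)
        assert set(t.df.category) <= {"antisense", "utr", "intergenic"}
        assert t.df.category.notna().all()

    def test_matches_exhaustive_overlap_oracle_on_random_instances(self, rng):
        """Brute-force interval arithmetic over all (sRNA, CDS) pairs must
        agree with the tree-based classifier on 100 random small genomes."""
        flank = 50
        for _ in range(100):
            n_cds = int(rng.integers(1, 6))
            feats = []
            for k in range(n_cds):
                s = int(rng.integers(1, 4950))
                e = s + int(rng.integers(10, 200))
                feats.append(CdsFeature(f"c{k}", s, min(e, 5000), "+" if rng.random() < 0.5 else "-"))
            g = make_genome("A" * 5000, feats)
            s = int(rng.integers(1, 4950))
            e = s + int(rng.integers(5, 100))
            strand = "+" if rng.random() < 0.5 else "-"
            t = classify_srnas(make_srna_table([("s1", "g1", s, min(e, 5000), strand)]), g)
            got = t.df.iloc[0]

            # independent oracle
            e = min(e, 5000)
            anti = [
                (min(e, f.end) - max(s, f.start) + 1, f.feature_id)
                for f in feats
                if f.strand != strand and f.start <= e and f.end >= s
            ]
            same_overlap = any(
                f.strand == strand and f.start <= e and f.end >= s for f in feats
            )
            same_near = any(
                f.strand == strand and f.start <= e + flank and f.end >= s - flank
                for f in feats
            )
            if anti:
                ov, tid = max(anti, key=lambda x: (x[0], tuple(-ord(c) for c in x[1])))
                best = min([a for a in anti if a[0] == ov], key=lambda x: x[1])
                assert got.category == "antisense"
                assert got.target_cds == best[1]
                assert got.overlap_len == ov
            elif not same_overlap and same_near:
                assert got.category == "utr"
            else:
                assert got.category == "intergenic"


class TestUpperQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [10.0, 10.0], [0.0, 0.0]])
        out, factors = upper_quantile_normalize(m)
        np.testing.assert_allclose(out, m)
        np.testing.assert_allclose(factors, [1.0, 1.0])

    def test_scaled_column_recovers_equality(self):
        c1 = np.array([2.0, 8.0, 14.0, 0.0, 6.0])
        m = np.column_stack([c1, 2 * c1])
        out, _ = upper_quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_factors_match_direct_percentile_computation(self, rng):
        m = rng.poisson(30, size=(50, 4)).astype(float)
        _, factors = upper_quantile_normalize(m)
        uq = np.array([np.percentile(m[:, j][m[:, j] > 0], 75) for j in range(4)])
        np.testing.assert_allclose(factors, uq.mean() / uq)

    def test_idempotent(self, rng):
        m = rng.poisson(30, size=(40, 3)).astype(float)
        once, _ = upper_quantile_normalize(m)
        twice, _ = upper_quantile_normalize(once)
        np.testing.assert_allclose(once, twice)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            upper_quantile_normalize(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestDeFilter:
    @pytest.mark.parametrize(
        "q,reads,kept",
        [
            (0.04, (9, 9, 9), True),     # at both thresholds -> kept
            (0.05, (9, 9, 9), True),     # q boundary inclusive
            (0.04, (8, 8, 8), False),    # mean 8 < 9
            (0.06, (100, 100, 100), False),
            (0.04, (27, 0, 0), True),    # mean 9 across replicates
        ],
    )
    def test_thresholds(self, q, reads, kept):
        t = make_srna_table([("s1", "g", 1, 50, "+")])
        counts = pd.DataFrame([reads], index=["s1"])
        qv = pd.Series({"s1": q})
        out = filter_de_candidates(t, counts, qv)
        assert (len(out) == 1) is kept

    def test_missing_replicates_rejected(self):
        t = make_srna_table([("s1", "g", 1, 50, "+")])
        with pytest.raises(ValueError):
            filter_de_candidates(t, pd.DataFrame([[9]], index=["other"]), pd.Series({"s1": 0.01}))


class TestPathwayTally:
    def _table_for(self, genome_label):
        pm = load_pathway_map(genome=genome_label)
        rows = []
        for k, cds in enumerate(sorted(set(pm["cds_id"]))):
            rows.append(
                {
                    "srna_id": f"s{k}", "genome": genome_label, "start": 1 + 10 * k,
                    "end": 5 + 10 * k, "strand": "+", "category": "antisense",
                    "target_cds": cds,
                }
            )
        return SrnaTable.from_records(rows), pm

    def test_first_lineage_column_gives_13_pathways_7_essential(self):
        t, pm = self._table_for("BC")
        tally = tally_pathways(t, pm)
        assert (tally.n_pathways, tally.n_essential_aa) == (13, 7)

    def test_second_lineage_column_gives_10_pathways_7_essential(self):
        t, pm = self._table_for("DC")
        tally = tally_pathways(t, pm)
        assert (tally.n_pathways, tally.n_essential_aa) == (10, 7)

    def test_empty_table_gives_zero(self):
        tally = tally_pathways(make_srna_table([]), load_pathway_map(genome="BC"))
        assert (tally.n_pathways, tally.n_essential_aa) == (0, 0)
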