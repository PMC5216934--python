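"""Six-category lncRNA classification and cis nearby-gene logic."""

import numpy as np
import pandas as pd
import pytest

from netkit.dataio import TranscriptRecord
from netkit.genomics import (
    build_cis_network,
    class_counts,
    classify_lncrna,
    nearby_coding_genes,
)


def gene(gid, start, end, strand="+", chrom="chr1", exons=None):
    return TranscriptRecord(id=gid, transcript_class="mRNA", chrom=chrom,
                            start=start, end=end, strand=strand,
                            gene_symbol=gid,
                            exons=tuple(exons) if exons else ((start, end),))


def lnc(lid, start, end, strand="+", chrom="chr1"):
    return TranscriptRecord(id=lid, transcript_class="lncRNA", chrom=chrom,
                            start=start, end=end, strand=strand,
                            gene_symbol=lid, exons=((start, end),))


GENE = gene("G", 10_000, 20_000,
            exons=[(10_000, 10_800), (15_000, 15_700), (19_400, 20_000)])


class TestClassify:
    def test_no_coding_gene_anywhere_is_intergenic(self):
        c = classify_lncrna(lnc("L", 100, 500), [])
        assert c.categories == {"intergenic"}

    def test_exon_overlap_same_strand(self):
        c = classify_lncrna(lnc("L", 15_200, 15_900), [GENE])
        assert "exon_sense_overlapping" in c.categories

    def test_intron_containment_same_strand(self):
        c = classify_lncrna(lnc("L", 11_000, 14_000), [GENE])
        assert c.categories == {"intron_sense_overlapping"}

    def test_antisense_overlap(self):
        c = classify_lncrna(lnc("L", 15_200, 15_900, strand="-"), [GENE])
        assert c.categories == {"natural_antisense"}

    def test_intronic_antisense(self):
        c = classify_lncrna(lnc("L", 11_000, 14_000, strand="-"), [GENE])
        assert c.categories == {"intronic_antisense"}

    def test_bidirectional_within_gap(self):
        c = classify_lncrna(lnc("L", 8_500, 9_500, strand="-"), [GENE])
        assert c.categories == {"bidirectional"}  # TSS gap 500 <= 1000

    def test_bidirectional_gap_boundary(self):
        near = classify_lncrna(lnc("L", 8_000, 9_000, strand="-"), [GENE])
        far = classify_lncrna(lnc("L", 7_000, 8_900, strand="-"), [GENE])
        assert near.categories == {"bidirectional"}   # gap exactly 1000
        assert far.categories == {"intergenic"}       # gap 1100

    def test_missing_strand_is_unknown(self):
        c = classify_lncrna(lnc("L", 15_200, 15_900, strand="."), [GENE])
        assert c.categories == {"unknown"}

    def test_strand_flip_preserves_category(self):
        flipped_gene = gene("G", 10_000, 20_000, strand="-",
                            exons=[(10_000, 10_800), (15_000, 15_700),
                                   (19_400, 20_000)])
        for start, end, strand in [(15_200, 15_900, "+"),
                                   (11_000, 14_000, "+"),
                                   (15_200, 15_900, "-"),
                                   (11_000, 14_000, "-")]:
            orig = classify_lncrna(lnc("L", start, end, strand), [GENE])
            other = "-" if strand == "+" else "+"
            both = classify_lncrna(lnc("L", start, end, other), [flipped_gene])
            assert orig.categories == both.categories

    def test_templates_classified_to_planted_labels(self, small_bundle):
        coding = [r for r in small_bundle.annotation
                  if r.transcript_class == "mRNA"]
        records = {r.id: r for r in small_bundle.annotation}
        for lnc_id, label in small_bundle.truth.class_labels.items():
            c = classify_lncrna(records[lnc_id], coding)
            assert c.categories == {label}, lnc_id


class TestClassCounts:
    def test_single_category_is_hundred_percent(self):
        cls = [classify_lncrna(lnc(f"L{i}", 100 + 10_000 * i,
                                   500 + 10_000 * i), [])
               for i in range(10)]
        excl, multi, _ = class_counts(cls)
        row = excl.set_index("category").loc["intergenic"]
        assert row["count"] == 10 and row["percent"] == pytest.approx(100.0)

    def test_empty_input_gives_empty_table(self):
        excl, multi, chrom = class_counts([])
        assert excl["count"].sum() == 0 and chrom.empty

    def test_exclusive_percentages_sum_to_hundred(self, small_bundle):
        coding = [r for r in small_bundle.annotation
                  if r.transcript_class == "mRNA"]
        cls = [classify_lncrna(r, coding) for r in small_bundle.annotation
               if r.transcript_class == "lncRNA"]
        excl, _, _ = class_counts(cls)
        assert excl["percent"].sum() == pytest.approx(100.0, abs=1e-9)


class TestNearbyGenes:
    def test_gap_of_exactly_window_excluded(self):
        g = gene("G", 400_000, 410_000)
        hit = nearby_coding_genes(lnc("L", 90_000, 100_000), [g],
                                  window=300_000)
        assert hit == []  # gap exactly 300,000: strict bound

    def test_gap_one_below_window_included(self):
        g = gene("G", 399_999, 410_000)
        hit = nearby_coding_genes(lnc("L", 90_000, 100_000), [g],
                                  window=300_000)
        assert hit == [("G", 299_999)]

    def test_overlap_gives_distance_zero(self):
        g = gene("G", 95_000, 105_000)
        assert nearby_coding_genes(lnc("L", 90_000, 100_000), [g]) == [("G", 0)]

    def test_upstream_sign_respects_strand(self):
        g = gene("G", 10_000, 20_000)
        plus = nearby_coding_genes(lnc("L", 30_000, 31_000, strand="+"), [g])
        minus = nearby_coding_genes(lnc("L", 30_000, 31_000, strand="-"), [g])
        assert plus == [("G", -10_000)]   # gene 5' of a + lncRNA: upstream
        assert minus == [("G", 10_000)]   # same gene is downstream on -

    def test_matches_brute_force_gap_scan(self, rng):
        genes = [gene(f"G{i}", int(s), int(s) + 5_000)
                 for i, s in enumerate(rng.integers(0, 2_000_000, size=40))]
        query = lnc("L", 900_000, 905_000)
        got = dict(nearby_coding_genes(query, genes, window=300_000))
        for g in genes:
            if g.start >= query.end:
                gap = g.start - query.end
            elif g.end <= query.start:
                gap = query.start - g.end
            else:
                gap = 0
            if gap < 300_000:
                assert abs(got[g.id]) == gap
            else:
                assert g.id not in got

    def test_gap_is_symmetric(self):
        from netkit.genomics import _gap_bp

        a, b = gene("A", 0, 100), gene("B", 5_000, 5_100)
        assert _gap_bp(a, b) == _gap_bp(b, a) == 4_900


class TestCisNetwork:
    EDGES = pd.DataFrame(
        [("L1", "G1", 0.95, 1e-5, 1e-4, "positive"),
         ("L2", "G2", 0.93, 1e-5, 1e-4, "positive")],
        columns=["id_a", "id_b", "pcc", "p_value", "fdr", "sign"])

    def test_window_violation_excluded(self):
        ann = [lnc("L1", 0, 1_000), gene("G1", 501_000, 510_000)]
        out = build_cis_network({"L1"}, {"G1"}, self.EDGES, ann)
        assert out.empty  # 500 kb away

    def test_pair_without_edge_excluded(self):
        ann = [lnc("L9", 0, 1_000), gene("G9", 5_000, 10_000)]
        out = build_cis_network({"L9"}, {"G9"}, self.EDGES, ann)
        assert out.empty

    def test_members_must_be_differentially_expressed(self):
        ann = [lnc("L1", 0, 1_000), gene("G1", 5_000, 10_000)]
        assert build_cis_network(set(), {"G1"}, self.EDGES, ann).empty
        out = build_cis_network({"L1"}, {"G1"}, self.EDGES, ann)
        assert list(out["lnc_id"]) == ["L1"]
        assert out.loc[0, "distance"] == 4_000

    def test_planted_pairs_recovered_with_correct_distances(self, small_bundle):
        truth = small_bundle.truth
        edges = pd.DataFrame(
            [(l, g, 0.95, 1e-6, 1e-5, "positive")
             for l, g, _d in truth.cis_pairs],
            columns=["id_a", "id_b", "pcc", "p_value", "fdr", "sign"])
        out = build_cis_network({l for l, _g, _d in truth.cis_pairs},
                                {g for _l, g, _d in truth.cis_pairs},
                                edges, small_bundle.annotation)
        got = {(r.lnc_id, r.gene_id): r.distance for r in out.itertuples()}
        for l, g, d in truth.cis_pairs:
            assert got[(l, g)] == d
            assert abs(d) < 300_000
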