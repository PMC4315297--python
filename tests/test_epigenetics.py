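"""DMR calling, D2/C2 classification, quartiles, normalization, marks."""

import numpy as np
import pandas as pd
import pytest

from p4rna.epigenetics import (
    call_chh_dmrs,
    classify_d2_c2,
    mark_overlap_windows,
    quartile_table,
    relative_sirna_abundance,
    tile_regions,
)
from p4rna.intervals import LibraryReads
from p4rna.model import AlignedRead, GenomicInterval, Library


def meth_table(sites):
    """sites: list of (chrom, pos, mc, total)."""
    return pd.DataFrame(
        {
            "chrom": [s[0] for s in sites],
            "pos": [s[1] for s in sites],
            "strand": "+",
            "context": "CHH",
            "mc_count": [s[2] for s in sites],
            "total_count": [s[3] for s in sites],
        }
    )


class TestCallChhDmrs:
    def test_clear_loss_called(self):
        wt = meth_table([("c", 10 * i, 3, 10) for i in range(10)])
        mut = meth_table([("c", 10 * i, 0, 10) for i in range(10)])
        dmrs = call_chh_dmrs(wt, mut)
        assert dmrs == [GenomicInterval("c", 0, 100)]

    def test_unchanged_methylation_not_called(self):
        wt = meth_table([("c", 10 * i, 3, 10) for i in range(10)])
        assert call_chh_dmrs(wt, wt.copy()) == []

    def test_low_wt_level_not_called(self):
        wt = meth_table([("c", 10 * i, 0, 10) for i in range(10)])
        mut = meth_table([("c", 10 * i, 0, 10) for i in range(10)])
        assert call_chh_dmrs(wt, mut) == []

    def test_too_few_sites_not_called(self):
        wt = meth_table([("c", 10 * i, 5, 10) for i in range(3)])
        mut = meth_table([("c", 10 * i, 0, 10) for i in range(3)])
        assert call_chh_dmrs(wt, mut, min_sites=4) == []

    def test_empty_chh_table_raises(self):
        empty = meth_table([]).assign(context=pd.Series(dtype=str))
        wt = meth_table([("c", 1, 3, 10)])
        with pytest.raises(ValueError):
            call_chh_dmrs(empty, wt)

    def test_planted_dmrs_recover_d2_loci(self, sim, pipeline):
        from p4rna.intervals import build_interval_index, overlaps_any

        idx = build_interval_index(pipeline.drm2_dmrs)
        d2_hit = np.mean(
            [overlaps_any(iv, idx) for iv in sim.truth.loci_of_class("D2")]
        )
        c2_hit = np.mean(
            [overlaps_any(iv, idx) for iv in sim.truth.loci_of_class("C2")]
        )
        assert d2_hit >= 0.95 and c2_hit <= 0.05


class TestClassifyD2C2:
    LOCUS = GenomicInterval("c", 100, 300)

    def test_single_class_overlap(self):
        d2 = [GenomicInterval("c", 150, 200)]
        out = classify_d2_c2([self.LOCUS], d2, [])
        assert out == [(self.LOCUS, "D2")]
        out = classify_d2_c2([self.LOCUS], [], d2)
        assert out == [(self.LOCUS, "C2")]

    def test_no_overlap_is_other(self):
        assert classify_d2_c2([self.LOCUS], [], [])[0][1] == "other"

    def test_both_classes_longer_overlap_wins(self):
        d2 = [GenomicInterval("c", 100, 250)]  # 150 bp
        c2 = [GenomicInterval("c", 250, 300)]  # 50 bp
        assert classify_d2_c2([self.LOCUS], d2, c2)[0][1] == "D2"

    def test_exact_tie_is_other(self):
        d2 = [GenomicInterval("c", 100, 150)]
        c2 = [GenomicInterval("c", 200, 250)]
        assert classify_d2_c2([self.LOCUS], d2, c2)[0][1] == "other"

    def test_partition_covers_all_loci(self, pipeline):
        assert len(pipeline.locus_classes) == len(pipeline.p4sirna_loci)
        assert {k for _, k in pipeline.locus_classes} <= {"D2", "C2", "other"}


class TestQuartileTable:
    def test_worked_example(self):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "start": range(8),
                "value": [8, 7, 6, 5, 4, 3, 2, 1],
                "hit": [True] * 4 + [False] * 4,
            }
        )
        out = quartile_table(df, "value", "hit")
        assert out["value"].tolist() == [100.0, 100.0, 0.0, 0.0]
        assert out["n"].tolist() == [2, 2, 2, 2]

    def test_quartile_sizes_near_equal_and_disjoint(self, rng):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "start": range(103),
                "value": rng.random(103),
                "hit": rng.random(103) < 0.5,
            }
        )
        out = quartile_table(df, "value", "hit")
        assert out["n"].sum() == 103
        assert out["n"].max() - out["n"].min() <= 3

    def test_ties_broken_by_genomic_order(self):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "start": [30, 10, 20, 40],
                "value": [1.0] * 4,
                "hit": [False, True, False, False],
            }
        )
        out = quartile_table(df, "value", "hit")
        # locus at start 10 sorts first, so quartile 1 contains the hit
        assert out["value"].tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_numeric_summary_uses_mean(self):
        df = pd.DataFrame(
            {"chrom": "c", "start": range(4), "value": [4.0, 3, 2, 1],
             "level": [0.4, 0.3, 0.2, 0.1]}
        )
        out = quartile_table(df, "value", "level")
        assert out["value"].tolist() == [0.4, 0.3, 0.2, 0.1]

    def test_too_few_loci_raises(self):
        df = pd.DataFrame({"chrom": "c", "start": [0], "value": [1.0]})
        with pytest.raises(ValueError):
            quartile_table(df, "value", "value")

    def test_planted_monotone_dependence_recovered(self, rng):
        """When precursor detection probability increases with siRNA
        abundance, quartile detection percentages are non-increasing from
        the top quartile down."""
        n = 400
        abundance = np.sort(rng.lognormal(0, 1, size=n))[::-1]
        prob = np.interp(
            np.arange(n), [0, n // 4, n // 2, 3 * n // 4, n - 1],
            [0.95, 0.9, 0.6, 0.35, 0.2],
        )
        detected = rng.random(n) < prob
        df = pd.DataFrame(
            {"chrom": "c", "start": range(n), "sirna_rpm_wt": abundance,
             "p4rna_detected": detected}
        )
        out = quartile_table(df, "sirna_rpm_wt", "p4rna_detected")
        vals = out["value"].tolist()
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def srna_lib(p4_reads, bg_reads, library_id="wt"):
    reads = [
        AlignedRead(GenomicInterval("c", 10, 34, "+")) for _ in range(p4_reads)
    ] + [
        AlignedRead(GenomicInterval("c", 5000, 5024, "+"))
        for _ in range(bg_reads)
    ]
    lib = Library(library_id, "sRNA", "WT", 1, max(1, p4_reads + bg_reads))
    return LibraryReads(lib, reads)


P4_SET = [GenomicInterval("c", 0, 100)]


class TestRelativeSirnaAbundance:
    def test_identity_is_exactly_one(self):
        wt = srna_lib(400, 600)
        assert relative_sirna_abundance(wt, wt, P4_SET) == 1.0

    def test_zero_mutant_p4_reads_gives_zero(self):
        wt = srna_lib(400, 600)
        mut = srna_lib(0, 600, "mut")
        assert relative_sirna_abundance(mut, wt, P4_SET) == 0.0

    def test_fourfold_depletion_recovered(self):
        wt = srna_lib(400, 600)
        mut = srna_lib(100, 600, "mut")
        assert relative_sirna_abundance(mut, wt, P4_SET) == pytest.approx(0.25)

    def test_zero_background_raises(self):
        wt = srna_lib(400, 0)
        with pytest.raises(ValueError):
            relative_sirna_abundance(wt, wt, P4_SET)

    def test_class_filter_restricts_numerator(self):
        wt = srna_lib(400, 600)
        mut = srna_lib(100, 600, "mut")
        val = relative_sirna_abundance(
            mut, wt, P4_SET, classes=["D2"], class_filter="D2"
        )
        assert val == pytest.approx(0.25)
        with pytest.raises(ValueError):
            relative_sirna_abundance(mut, wt, P4_SET, class_filter="D2")


class TestMarkOverlapWindows:
    def test_single_window_hit_fraction(self):
        marks = {"k9": [GenomicInterval("c", 0, 1500)], "k27": []}
        loci = [GenomicInterval("c", 600, 650)]  # inside window 2 of 3
        wt, lt = mark_overlap_windows(marks, loci)
        k9_row = wt[wt["mark"] == "k9"].iloc[0]
        assert k9_row.n_windows == 3
        assert k9_row.pct_with_loci == pytest.approx(100 / 3)

    def test_no_loci_all_zero(self):
        marks = {"k9": [GenomicInterval("c", 0, 1500)],
                 "k27": [GenomicInterval("c", 0, 1000)]}
        wt, lt = mark_overlap_windows(marks, [])
        assert (wt["pct_with_loci"] == 0).all()

    def test_tile_regions_keeps_partial_window(self):
        tiles = tile_regions([GenomicInterval("c", 0, 1200)], 500)
        assert [t.length for t in tiles] == [500, 500, 200]

    def test_percentages_bounded_and_both_is_intersection(self, sim):
        loci = sim.truth.p4_intervals()
        classes = [p.klass for p in sim.truth.p4_loci]
        marks = {"k9": sim.marks["h3k9me2"], "k27": sim.marks["h3k27me1"]}
        wt, lt = mark_overlap_windows(marks, loci, classes)
        assert ((wt["pct_with_loci"] >= 0) & (wt["pct_with_loci"] <= 100)).all()
        for _, row in lt.iterrows():
            assert row.pct_both <= min(row.pct_k9, row.pct_k27) + 1e-9

    def test_c2_loci_carry_both_marks_far_more_than_d2(self, sim):
        loci = sim.truth.p4_intervals()
        classes = [p.klass for p in sim.truth.p4_loci]
        marks = {"k9": sim.marks["h3k9me2"], "k27": sim.marks["h3k27me1"]}
        _, lt = mark_overlap_windows(marks, loci, classes)
        c2 = lt[lt["group"] == "C2"].iloc[0].pct_both
        d2 = lt[lt["group"] == "D2"].iloc[0].pct_both
        assert c2 > 80 and d2 < 40 and c2 > 2 * d2
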