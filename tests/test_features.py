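"""Naive splice scan, intron-coverage filter, strand classification."""

import numpy as np
import pytest

from p4rna.features import (
    SpliceCandidate,
    classify_strandedness,
    filter_junctions_by_coverage,
    find_spliced_reads,
    polya_dependence_contrast,
    revcomp,
)
from p4rna.intervals import LibraryReads
from p4rna.model import AlignedRead, GenomicInterval, Library


def _random_genome(rng, n=4000, name="g"):
    return {name: "".join(rng.choice(list("ACGT"), size=n))}


class TestFindSplicedReads:
    def test_constructed_positive_watson(self, rng):
        g = _random_genome(rng)
        read = g["g"][100:115] + g["g"][300:315]
        res = find_spliced_reads([("r1", read)], g)
        (c,) = res.candidates
        assert c.left_segment == GenomicInterval("g", 100, 115, "+")
        assert c.right_segment == GenomicInterval("g", 300, 315, "+")
        assert c.gap_interval == GenomicInterval("g", 115, 300, "+")

    def test_constructed_positive_crick(self, rng):
        g = _random_genome(rng)
        read = revcomp(g["g"][100:115] + g["g"][300:315])
        res = find_spliced_reads([("r1", read)], g)
        (c,) = res.candidates
        assert c.strand == "-"
        assert c.gap_interval.start == 115 and c.gap_interval.end == 300

    def test_span_beyond_limit_rejected(self, rng):
        g = _random_genome(rng)
        read = g["g"][100:115] + g["g"][1300:1315]  # span 1215 > 1000
        res = find_spliced_reads([("r1", read)], g)
        assert res.candidates == [] and res.n_no_placement == 1

    def test_contiguous_reads_yield_no_candidates(self, sim, rng):
        """Perfectly mapping reads are never splice candidates, whether
        pre-filtered by id or re-detected by exact matching."""
        chrom = sorted(sim.genome)[0]
        reads = []
        for i, s in enumerate(rng.integers(0, 400_000, size=50)):
            reads.append((f"cont{i}", sim.genome[chrom][int(s) : int(s) + 40]))
        res = find_spliced_reads(reads, sim.genome)
        assert res.candidates == []
        assert res.n_perfect_match == 50
        res2 = find_spliced_reads(
            reads, sim.genome, already_mapped_ids={r[0] for r in reads}
        )
        assert res2.candidates == [] and res2.n_perfect_match == 0

    def test_short_reads_skipped_and_counted(self, rng):
        g = _random_genome(rng)
        res = find_spliced_reads([("r1", g["g"][0:20])], g, seed_len=15)
        assert res.n_short_skipped == 1 and res.candidates == []

    def test_ambiguous_anchor_pairs_discarded(self):
        rng = np.random.default_rng(4)
        core = "".join(rng.choice(list("ACGT"), size=400))
        head = core[0:15]
        tail = core[200:215]
        # head occurs twice, both placements pair with the tail within range
        genome = {"g": head + core[15:100] + head + core[115:]}
        read = head + "ACGTACGTAC" + tail
        res = find_spliced_reads([("r1", read)], genome)
        assert res.candidates == [] and res.n_ambiguous == 1

    def test_planted_junction_recall(self, sim):
        reads = sorted(sim.spliced_sequences.items())[:800]
        res = find_spliced_reads(reads, sim.genome)
        found = {c.read_id for c in res.candidates}
        wanted = {rid for rid, _ in reads}
        assert len(found & wanted) / len(wanted) >= 0.95

    def test_candidate_anchors_match_genome(self, sim):
        """No emitted candidate may carry an anchor that mismatches the
        genome (post-hoc substring verification)."""
        reads = sorted(sim.spliced_sequences.items())[:200]
        res = find_spliced_reads(reads, sim.genome)
        for c in res.candidates:
            seq = sim.spliced_sequences[c.read_id]
            if c.strand == "-":
                seq = revcomp(seq)
            L, R = c.left_segment, c.right_segment
            assert sim.genome[L.chrom][L.start : L.end] == seq[:15]
            assert sim.genome[R.chrom][R.start : R.end] == seq[-15:]


def coverage_lib(depth_spec, chrom="g"):
    """depth_spec: list of (start, end, depth) blocks of 50-nt reads."""
    reads = []
    for s, e, d in depth_spec:
        for _ in range(d):
            reads.append(AlignedRead(GenomicInterval(chrom, s, e, "+")))
    return reads


class TestJunctionCoverageFilter:
    def _cand(self, gap_start=200, gap_end=300):
        return SpliceCandidate(
            "x",
            GenomicInterval("g", gap_start - 15, gap_start, "+"),
            GenomicInterval("g", gap_end, gap_end + 15, "+"),
            GenomicInterval("g", gap_start, gap_end, "+"),
            "+",
        )

    def test_fivefold_drop_retained(self):
        reads = coverage_lib([(100, 200, 10), (300, 400, 10), (200, 300, 1)])
        kept, removed = filter_junctions_by_coverage([self._cand()], reads)
        assert len(kept) == 1 and removed == []

    def test_insufficient_drop_removed(self):
        reads = coverage_lib([(100, 200, 10), (300, 400, 10), (200, 300, 3)])
        kept, removed = filter_junctions_by_coverage([self._cand()], reads)
        assert kept == [] and removed[0][1] == pytest.approx(10 / 3)

    def test_zero_flank_coverage_removed(self):
        kept, removed = filter_junctions_by_coverage([self._cand()], [])
        assert kept == [] and removed[0][1] == 0.0

    def test_raising_min_ratio_is_monotone(self):
        reads = coverage_lib([(100, 200, 12), (300, 400, 12), (200, 300, 2)])
        for lo, hi in ((3, 5), (5, 7), (7, 20)):
            k_lo, _ = filter_junctions_by_coverage(
                [self._cand()], reads, min_ratio=lo
            )
            k_hi, _ = filter_junctions_by_coverage(
                [self._cand()], reads, min_ratio=hi
            )
            assert len(k_hi) <= len(k_lo)

    def test_true_junctions_kept_decoys_removed(self, sim):
        """Real intron junctions survive (introns are uncovered) while decoy
        junctions inside uniformly covered P4 loci are all removed."""
        reads = sorted(sim.spliced_sequences.items())[:300]
        cands = find_spliced_reads(reads, sim.genome).candidates
        genic_idx = sim.reads["polyA_plus_dcl234_r1"].index()
        kept, _ = filter_junctions_by_coverage(cands, genic_idx)
        assert len(kept) == len(cands) > 0

        ds_idx = sim.reads["dsRNA_dcl234_r1"].index()
        decoys = []
        for p in sim.truth.p4_loci:
            iv = p.interval
            if iv.length >= 200:
                mid = iv.start + iv.length // 2
                decoys.append(
                    SpliceCandidate(
                        "decoy",
                        GenomicInterval(iv.chrom, mid - 60, mid - 45),
                        GenomicInterval(iv.chrom, mid + 45, mid + 60),
                        GenomicInterval(iv.chrom, mid - 45, mid + 45),
                        "+",
                    )
                )
        kept_d, removed_d = filter_junctions_by_coverage(decoys, ds_idx)
        assert kept_d == [] and len(removed_d) == len(decoys) > 0


def strand_lib(watson, crick, total=1000, stranded=True):
    reads = [
        AlignedRead(GenomicInterval("c", 10, 34, "+")) for _ in range(watson)
    ] + [AlignedRead(GenomicInterval("c", 10, 34, "-")) for _ in range(crick)]
    lib = Library("s", "polyA_plus", "dcl234", 1, total, stranded)
    return LibraryReads(lib, reads)


LOCUS = [GenomicInterval("c", 0, 100)]


class TestStrandedness:
    def test_nine_to_one_boundary_single_stranded(self):
        (r,) = classify_strandedness(strand_lib(90, 10), LOCUS, min_rpm=1)
        assert r.ratio_major_minor == 9.0 and r.single_stranded

    def test_balanced_is_double_stranded(self):
        (r,) = classify_strandedness(strand_lib(50, 50), LOCUS, min_rpm=1)
        assert r.ratio_major_minor == 1.0 and not r.single_stranded

    def test_zero_minor_strand_is_single(self):
        (r,) = classify_strandedness(strand_lib(30, 0), LOCUS, min_rpm=1)
        assert np.isinf(r.ratio_major_minor) and r.single_stranded

    def test_low_expression_loci_excluded(self):
        assert classify_strandedness(strand_lib(0, 0), LOCUS) == []

    def test_unstranded_library_rejected(self):
        with pytest.raises(ValueError):
            classify_strandedness(strand_lib(5, 5, stranded=False), LOCUS)

    def test_strand_swap_symmetry(self, rng):
        for _ in range(20):
            w, c = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            if w + c == 0:
                continue
            (a,) = classify_strandedness(strand_lib(w, c), LOCUS, min_rpm=0)
            (b,) = classify_strandedness(strand_lib(c, w), LOCUS, min_rpm=0)
            assert a.single_stranded == b.single_stranded
            assert a.ratio_major_minor == b.ratio_major_minor

    def test_simulated_libraries_classify_as_planted(self, sim):
        pol2 = [p.interval for p in sim.truth.pol2_loci]
        res = classify_strandedness(
            sim.library_reads("polyA_plus_dcl234_r1"), pol2
        )
        assert np.mean([r.single_stranded for r in res]) >= 0.95
        p4 = sim.truth.p4_intervals()
        res2 = classify_strandedness(sim.library_reads("dsRNA_dcl234_r1"), p4)
        assert np.mean([not r.single_stranded for r in res2]) >= 0.95


class TestPolyaDependence:
    def _libs(self, plus_counts, minus_counts):
        def mk(counts, assay, genotype):
            reads = [
                AlignedRead(GenomicInterval("c", 10, 60, "+"))
                for _ in range(counts)
            ]
            lib = Library(
                f"{assay}_{genotype}", assay, genotype, 1, 10**6, True
            )
            return {genotype: [LibraryReads(lib, reads)]}

        plus = {**mk(plus_counts[0], "polyA_plus", "dcl234"),
                **mk(plus_counts[1], "polyA_plus", "dcl234_nrpd1")}
        minus = {**mk(minus_counts[0], "polyA_minus", "dcl234"),
                 **mk(minus_counts[1], "polyA_minus", "dcl234_nrpd1")}
        return plus, minus

    def test_minus_fraction_dependence_flagged(self):
        plus, minus = self._libs((3, 3), (40, 5))
        df = polya_dependence_contrast(plus, minus, LOCUS)
        row = df.iloc[0]
        assert row.dependent_minus and not row.dependent_plus

    def test_silent_locus_excluded(self):
        plus, minus = self._libs((0, 0), (0, 0))
        assert polya_dependence_contrast(plus, minus, LOCUS).empty

    def test_simulated_p4_loci_minus_only(self, sim):
        plus = {
            g: sim.libraries_for("polyA_plus", g)
            for g in ("dcl234", "dcl234_nrpd1")
        }
        minus = {
            g: sim.libraries_for("polyA_minus", g)
            for g in ("dcl234", "dcl234_nrpd1")
        }
        df = polya_dependence_contrast(
            plus, minus, sim.truth.p4_intervals()
        )
        frac = (df.dependent_minus & ~df.dependent_plus).mean()
        assert frac >= 0.9
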