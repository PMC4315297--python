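"""Generator contracts: determinism, planted composition, planted truth."""

import math

import numpy as np
import pytest

from p4rna.intervals import count_reads
from p4rna.model import GenomicInterval
from p4rna.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_genome,
    simulate,
)

TINY = dict(
    genome_size=60_000,
    n_p4_loci=20,
    n_pol2_loci=5,
    n_genes=8,
    default_depth=20_000,
)


class TestGenome:
    def test_same_seed_identical_fasta(self):
        cfg = SimulationConfig(seed=5, **TINY)
        g1, _ = generate_genome(cfg)
        g2, _ = generate_genome(cfg)
        assert g1 == g2

    def test_pure_at_flanks(self):
        cfg = SimulationConfig(seed=5, flank_at_enrichment=1.0, **TINY)
        genome, truth = generate_genome(cfg)
        for locus in truth.p4_loci:
            iv = locus.interval
            seq = genome[iv.chrom]
            flank = seq[max(0, iv.start - 50) : iv.start] + seq[iv.end : iv.end + 50]
            assert set(flank) <= {"A", "T"}

    def test_body_gc_within_binomial_ci(self):
        cfg = SimulationConfig(seed=5, body_gc=0.5, **TINY)
        genome, truth = generate_genome(cfg)
        bases = "".join(
            genome[p.interval.chrom][p.interval.start : p.interval.end]
            for p in truth.p4_loci
        )
        n = len(bases)
        gc = sum(1 for b in bases if b in "GC")
        # 99% binomial CI around the planted proportion
        half = 2.576 * math.sqrt(0.25 * n)
        assert abs(gc - 0.5 * n) < half

    def test_genes_have_introns(self):
        _, truth = generate_genome(SimulationConfig(seed=5, **TINY))
        assert all(len(g.exons) >= 2 for g in truth.genes)
        assert all(i.length > 0 for g in truth.genes for i in g.introns)

    def test_c2_pericentromeric_d2_on_arms(self):
        _, truth = generate_genome(SimulationConfig(seed=5, **TINY))
        for p in truth.p4_loci:
            peri = truth.pericentromere(p.interval.chrom)
            inside = p.interval.overlaps(peri)
            assert inside == (p.klass == "C2")

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(seed=5, genome_size=5_000, n_p4_loci=40,
                               n_pol2_loci=0, n_genes=0, default_depth=1000)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(cfg)

    def test_d2_c2_disjoint(self, sim):
        d2 = sim.truth.loci_of_class("D2")
        c2 = sim.truth.loci_of_class("C2")
        assert len(d2) + len(c2) == len(sim.truth.p4_loci)
        for a in d2:
            for b in c2:
                assert not a.overlaps(b)


class TestLibraries:
    def test_full_determinism(self):
        cfg = SimulationConfig(seed=7, **TINY)
        s1, s2 = simulate(cfg), simulate(cfg)
        assert s1.genome == s2.genome
        for lib_id in s1.reads:
            a, b = s1.reads[lib_id], s2.reads[lib_id]
            assert np.array_equal(a.starts, b.starts)
            assert np.array_equal(a.ends, b.ends)
            assert np.array_equal(a.strands, b.strands)
        assert s1.truth.to_json() == s2.truth.to_json()

    def test_manifest_totals_match_read_counts(self, sim):
        for lib_id, lib in sim.libraries.items():
            assert lib.total_mapped_reads == len(sim.reads[lib_id])

    def test_infinite_fold_change_empties_mutant_loci(self):
        cfg = SimulationConfig(seed=7, p4_fold_change=float("inf"), **TINY)
        s = simulate(cfg)
        idx = s.reads["sRNA_nrpd1_r1"].index()
        for p in s.truth.p4_loci:
            assert idx.count(p.interval) == 0

    def test_poisson_locus_mean_within_clt_bound(self):
        # equal weights: planted per-locus mean = depth * share / n_loci = 100
        cfg = SimulationConfig(
            seed=9,
            genome_size=300_000,
            n_p4_loci=200,
            n_pol2_loci=5,
            n_genes=8,
            default_depth=40_000,
            noise_model="poisson",
            expression_sigma=0.0,
        )
        s = simulate(cfg)
        idx = s.reads["sRNA_WT_r1"].index()
        counts = [idx.count(p.interval) for p in s.truth.p4_loci]
        mean = np.mean(counts)
        se = math.sqrt(100 / len(counts))
        # slack for background reads that happen to overlap locus edges
        assert abs(mean - 100) < 3 * se + 1.0

    def test_polya_plus_strand_skew(self, sim):
        hits = tot = 0
        idx = sim.reads["polyA_plus_dcl234_r1"].index()
        for p in sim.truth.pol2_loci:
            w, c = idx.count_per_strand(p.interval)
            major = w if p.interval.strand == "+" else c
            hits += major
            tot += w + c
        assert tot > 0 and hits / tot >= 0.9

    def test_spliced_reads_emitted_as_segment_pairs(self, sim):
        lib = sim.reads["polyA_plus_dcl234_r1"]
        seen: dict[str, int] = {}
        for n in lib.names:
            if n.startswith("spliced_"):
                seen[n] = seen.get(n, 0) + 1
        assert seen and set(seen.values()) == {2}
        assert set(seen) == sim.truth.spliced_read_ids
        assert set(seen) == set(sim.spliced_sequences)


class TestEpigenome:
    def test_planted_methylation_differences(self, sim):
        wt = sim.methylomes["WT"]
        drm12 = sim.methylomes["drm12"]

        def locus_level(df, iv):
            sel = df[
                (df["chrom"] == iv.chrom)
                & (df["pos"] >= iv.start)
                & (df["pos"] < iv.end)
            ]
            return sel["mc_count"].sum() / max(1, sel["total_count"].sum())

        d2 = sim.truth.loci_of_class("D2")[:40]
        c2 = sim.truth.loci_of_class("C2")[:40]
        drops = [locus_level(wt, iv) - locus_level(drm12, iv) for iv in d2]
        assert np.mean([d >= 0.25 for d in drops]) >= 0.95
        stable = [abs(locus_level(wt, iv) - locus_level(drm12, iv)) for iv in c2]
        assert np.mean([d <= 0.05 for d in stable]) >= 0.95

    def test_flank_nucleosomes_depleted(self, sim):
        from p4rna.intervals import ReadIndex
        from p4rna.model import AlignedRead

        calls = [AlignedRead(GenomicInterval(iv.chrom, iv.start, iv.end, "+"))
                 for iv in sim.nucleosomes]
        idx = ReadIndex.build(calls)
        flank_hits = body_hits = flank_bp = body_bp = 0
        for p in sim.truth.p4_loci:
            iv = p.interval
            left = GenomicInterval(iv.chrom, max(0, iv.start - 50), iv.start)
            right = GenomicInterval(iv.chrom, iv.end, iv.end + 50)
            flank_hits += idx.count(left) + idx.count(right)
            flank_bp += left.length + right.length
            body_hits += idx.count(iv)
            body_bp += iv.length
        assert flank_hits / flank_bp < body_hits / body_bp

    def test_marks_cover_pericentromere(self, sim):
        from p4rna.intervals import build_interval_index, overlaps_any

        k9 = build_interval_index(sim.marks["h3k9me2"])
        c2_hit = np.mean(
            [overlaps_any(iv, k9) for iv in sim.truth.loci_of_class("C2")]
        )
        d2_hit = np.mean(
            [overlaps_any(iv, k9) for iv in sim.truth.loci_of_class("D2")]
        )
        assert c2_hit > 0.9 > d2_hit


class TestTruthSerialization:
    def test_json_round_trip(self, sim):
        text = sim.truth.to_json()
        back = GroundTruth.from_json(text)
        assert back.to_json() == text
        assert back.chrom_sizes == sim.truth.chrom_sizes
        assert len(back.p4_loci) == len(sim.truth.p4_loci)
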