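"""Synthetic genome, sequencing libraries, methylomes and chromatin tracks
with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* Pol IV-dependent (P4) loci whose dsRNA-seq and sRNA-seq signal collapses
  in ``nrpd1`` / ``rdr2`` genotypes (near-complete loss by default);
* two-strand dsRNA coverage at P4 loci versus one-strand poly(A)+ coverage
  at Pol II-transcribed loci;
* GC-rich locus bodies with A/T-rich, nucleosome-depleted ~50-nt flanks;
* D2 (DRM2-dependent, chromosome arms) versus C2 (CMT2-dependent,
  pericentromeric) CHH-methylation geography, with matching H3K9me2 /
  H3K27me1 domains;
* genes with introns, whose poly(A)+ reads include exon-exon spliced reads
  emitted as two BED segments sharing a read id plus a sidecar sequence
  table for the seed-anchored splice scan.

Everything is deterministic under a fixed config + seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as pio
from .intervals import LibraryReads, ReadIndex
from .model import GenomicInterval, Library

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# relative input-mass fractions per library component in the control
# genotype. Libraries are sequenced to a fixed depth, so when the P4
# component collapses in a mutant the remaining components absorb the
# reads (the usual composition effect of library-size normalization).
_SRNA_MIX = {"p4": 0.5, "background": 0.5}
_DSRNA_MIX = {"p4": 0.5, "genic": 0.5}
_POLYA_PLUS_MIX = {"pol2": 0.6, "genic": 0.25, "p4": 0.15}
_POLYA_MINUS_MIX = {"p4": 0.5, "genic": 0.5}
_SPLICED_FRACTION = 0.1  # of genic poly(A)+ reads
_SRNA_LENGTHS = np.array([20, 21, 22, 23, 24, 25])
_SRNA_LENGTH_P = np.array([0.05, 0.10, 0.10, 0.15, 0.50, 0.10])
_LONG_READ_LEN = 50
_SPLICE_SEG_LEN = 20


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults are a desk-scale genome (2 x 500 kb) with 300 P4 loci; the
    Pol IV/RDR2 mutants retain 1/``p4_fold_change`` of the wild-type P4
    signal (``inf`` plants a complete loss).
    """

    genome_size: int = 500_000  # per chromosome
    n_chroms: int = 2
    n_p4_loci: int = 300
    n_pol2_loci: int = 50
    n_genes: int = 100
    p4_locus_length: tuple = (100, 500)
    p4_fold_change: float = 20.0
    library_depths: dict | None = None  # library_id -> expected read count
    default_depth: int = 200_000
    flank_at_enrichment: float = 0.8  # A/T proportion in 50-nt flanks
    body_gc: float = 0.5
    background_at: float = 0.64  # genome-wide A/T away from planted loci
    flank_width: int = 50
    d2_fraction: float = 0.4
    noise_model: str = "negbin"  # "poisson" | "negbin"
    negbin_dispersion: float = 0.1
    polya_strand_skew: float = 0.95  # P(read strand == planted strand)
    expression_sigma: float = 0.6  # lognormal spread of per-locus expression
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank_at_enrichment", "body_gc", "background_at", "d2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p4_fold_change < 1:
            raise ValueError("p4_fold_change must be >= 1")
        if self.noise_model not in ("poisson", "negbin"):
            raise ValueError("noise_model must be poisson or negbin")
        if self.negbin_dispersion <= 0:
            raise ValueError("negbin_dispersion must be > 0")

    def depth(self, library_id: str) -> int:
        if self.library_depths and library_id in self.library_depths:
            return int(self.library_depths[library_id])
        return self.default_depth


@dataclass
class PlantedLocus:
    interval: GenomicInterval
    klass: str = ""  # "D2" | "C2" for P4 loci
    weight: float = 0.0  # share of the component read mass
    pol2_strand: str = "+"  # strand of residual Pol II transcription


@dataclass
class PlantedGene:
    interval: GenomicInterval
    exons: list  # list[GenomicInterval]
    weight: float = 0.0

    @property
    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons[:-1], self.exons[1:]):
            out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out


@dataclass
class GroundTruth:
    """Planted features and read-level truth used as the acceptance oracle."""

    p4_loci: list = field(default_factory=list)  # PlantedLocus, klass D2/C2
    pol2_loci: list = field(default_factory=list)  # PlantedLocus
    genes: list = field(default_factory=list)  # PlantedGene
    p4_fold_change: float = 1.0
    chrom_sizes: dict = field(default_factory=dict)
    spliced_read_ids: set = field(default_factory=set)
    junctions: dict = field(default_factory=dict)  # read_id -> gap GenomicInterval

    def p4_intervals(self) -> list:
        return [p.interval for p in self.p4_loci]

    def loci_of_class(self, klass: str) -> list:
        return [p.interval for p in self.p4_loci if p.klass == klass]

    def pericentromere(self, chrom: str) -> GenomicInterval:
        size = self.chrom_sizes[chrom]
        return GenomicInterval(chrom, size // 3, 2 * size // 3)

    def to_json(self) -> str:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end, i.strand]

        obj = {
            "p4_fold_change": self.p4_fold_change,
            "chrom_sizes": self.chrom_sizes,
            "p4_loci": [
                {"iv": iv(p.interval), "class": p.klass, "weight": p.weight,
                 "pol2_strand": p.pol2_strand}
                for p in self.p4_loci
            ],
            "pol2_loci": [
                {"iv": iv(p.interval), "weight": p.weight} for p in self.pol2_loci
            ],
            "genes": [
                {"iv": iv(g.interval), "weight": g.weight,
                 "exons": [iv(e) for e in g.exons]}
                for g in self.genes
            ],
            "spliced_read_ids": sorted(self.spliced_read_ids),
            "junctions": {k: iv(v) for k, v in sorted(self.junctions.items())},
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)

        def iv(x: list) -> GenomicInterval:
            return GenomicInterval(x[0], x[1], x[2], x[3])

        return cls(
            p4_loci=[
                PlantedLocus(iv(p["iv"]), p["class"], p["weight"], p["pol2_strand"])
                for p in obj["p4_loci"]
            ],
            pol2_loci=[
                PlantedLocus(iv(p["iv"]), "", p["weight"]) for p in obj["pol2_loci"]
            ],
            genes=[
                PlantedGene(iv(g["iv"]), [iv(e) for e in g["exons"]], g["weight"])
                for g in obj["genes"]
            ],
            p4_fold_change=obj["p4_fold_change"],
            chrom_sizes=obj["chrom_sizes"],
            spliced_read_ids=set(obj["spliced_read_ids"]),
            junctions={k: iv(v) for k, v in obj["junctions"].items()},
        )


@dataclass
class SimReads:
    """Reads of one simulated library as parallel arrays."""

    chrom_of: np.ndarray  # int codes into chrom_names
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray  # int8: 1 = +, 0 = -
    names: list  # read names; "" for anonymous reads
    chrom_names: list

    def __len__(self) -> int:
        return len(self.starts)

    def index(self) -> ReadIndex:
        return ReadIndex.from_arrays(
            self.chrom_of, self.starts, self.ends, self.strands, self.chrom_names
        )

    def to_frame(self) -> pd.DataFrame:
        strand = np.where(self.strands == 1, "+", "-")
        names = [n if n else "." for n in self.names] if self.names else "."
        df = pd.DataFrame(
            {
                "chrom": [self.chrom_names[c] for c in self.chrom_of],
                "start": self.starts,
                "end": self.ends,
                "name": names,
                "score": 0,
                "strand": strand,
            }
        )
        return df.sort_values(
            ["chrom", "start", "end", "strand", "name"], kind="stable"
        ).reset_index(drop=True)


@dataclass
class Simulation:
    """Complete synthetic dataset held in memory."""

    config: SimulationConfig
    genome: dict  # chrom -> sequence string
    truth: GroundTruth
    libraries: dict  # library_id -> Library
    reads: dict  # library_id -> SimReads
    spliced_sequences: dict  # read_id -> sequence (unaligned records)
    methylomes: dict  # genotype -> DataFrame (methylation table)
    nucleosomes: list  # list[GenomicInterval]
    marks: dict  # "h3k9me2"/"h3k27me1" -> list[GenomicInterval]

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def library_reads(self, library_id: str) -> LibraryReads:
        return LibraryReads.from_index(
            self.libraries[library_id], self.reads[library_id].index()
        )

    def libraries_for(self, assay: str, genotype: str) -> list:
        out = []
        for lib_id in sorted(self.libraries):
            lib = self.libraries[lib_id]
            if lib.assay == assay and lib.genotype == genotype:
                out.append(self.library_reads(lib_id))
        return out

    def write(self, outdir: str) -> None:
        """Write the dataset in the plain-text exchange formats."""
        pio.ensure_dir(outdir)
        pio.write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
            fh.write(annotation_gff3(self.truth))
        reads_dir = pio.ensure_dir(os.path.join(outdir, "reads"))
        for lib_id in sorted(self.reads):
            df = self.reads[lib_id].to_frame()
            df.to_csv(
                os.path.join(reads_dir, f"{lib_id}.bed"),
                sep="\t", header=False, index=False,
            )
        pio.write_manifest(
            [self.libraries[k] for k in sorted(self.libraries)],
            os.path.join(outdir, "manifest.tsv"),
        )
        with open(os.path.join(reads_dir, "spliced_sequences.tsv"), "w") as fh:
            for rid in sorted(self.spliced_sequences):
                fh.write(f"{rid}\t{self.spliced_sequences[rid]}\n")
        meth_dir = pio.ensure_dir(os.path.join(outdir, "methylation"))
        for genotype in sorted(self.methylomes):
            pio.write_methylation(
                self.methylomes[genotype],
                os.path.join(meth_dir, f"{genotype}.tsv"),
            )
        pio.write_bed(self.nucleosomes, os.path.join(outdir, "nucleosomes.bed"))
        marks_dir = pio.ensure_dir(os.path.join(outdir, "marks"))
        for mark in sorted(self.marks):
            pio.write_bed(self.marks[mark], os.path.join(marks_dir, f"{mark}.bed"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(BASES, size=n, p=p)


def _place_lengths(
    rng: np.random.Generator, region: tuple, lengths: list, min_gap: int
) -> list:
    """Place features of given lengths into [region[0], region[1]) without
    overlap, separated by at least ``min_gap``; random slack between them."""
    n = len(lengths)
    if n == 0:
        return []
    span = region[1] - region[0]
    need = sum(lengths) + (n + 1) * min_gap
    if need > span:
        raise ValueError(
            f"infeasible packing: need {need} bp but region has {span} bp"
        )
    slack = span - need
    fracs = rng.dirichlet(np.ones(n + 1)) * slack
    out = []
    cursor = float(region[0])
    for i, L in enumerate(lengths):
        cursor += min_gap + fracs[i]
        s = int(cursor)
        out.append((s, s + L))
        cursor = float(s + L)
    return out


def _split_count(n: int, k: int) -> list:
    return [n // k + (1 if i < n % k else 0) for i in range(k)]


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict, GroundTruth]:
    """Build the toy genome and planted annotation.

    C2 loci are packed into the middle ("pericentromeric") third of each
    chromosome; D2 loci, Pol II loci and genes into the arms. P4 locus
    bodies are GC-rich (``body_gc``) with ``flank_width``-nt A/T-rich
    flanks (``flank_at_enrichment``); genes always carry >= 1 intron.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_d2 = int(round(config.n_p4_loci * config.d2_fraction))
    n_c2 = config.n_p4_loci - n_d2
    d2_per = _split_count(n_d2, config.n_chroms)
    c2_per = _split_count(n_c2, config.n_chroms)
    pol2_per = _split_count(config.n_pol2_loci, config.n_chroms)
    gene_per = _split_count(config.n_genes, config.n_chroms)

    genome: dict[str, str] = {}
    truth = GroundTruth(p4_fold_change=config.p4_fold_change)
    lo, hi = config.p4_locus_length

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.genome_size
        seq = _random_sequence(rng, L, config.background_at)
        truth.chrom_sizes[chrom] = L

        # --- arms: D2 loci, pol2 loci, genes -------------------------------
        arm_items: list[tuple[str, object]] = []
        for _ in range(d2_per[ci]):
            arm_items.append(("D2", int(rng.integers(lo, hi + 1))))
        for _ in range(pol2_per[ci]):
            arm_items.append(("pol2", int(rng.integers(400, 1001))))
        for _ in range(gene_per[ci]):
            n_ex = int(rng.integers(2, 4))
            ex_lens = rng.integers(150, 401, size=n_ex)
            in_lens = rng.integers(80, 301, size=n_ex - 1)
            arm_items.append(("gene", (ex_lens.tolist(), in_lens.tolist())))
        order = rng.permutation(len(arm_items))
        arm_items = [arm_items[i] for i in order]

        def item_len(item) -> int:
            kind, payload = item
            if kind == "gene":
                ex, intr = payload
                return sum(ex) + sum(intr)
            return payload

        n_arm1 = len(arm_items) // 2
        arms = [(0, L // 3), (2 * L // 3, L)]
        groups = [arm_items[:n_arm1], arm_items[n_arm1:]]
        for arm, items in zip(arms, groups):
            placed = _place_lengths(
                rng, arm, [item_len(it) for it in items], min_gap=300
            )
            for (kind, payload), (s, e) in zip(items, placed):
                if kind == "D2":
                    strand = "+" if rng.random() < 0.5 else "-"
                    truth.p4_loci.append(
                        PlantedLocus(
                            GenomicInterval(chrom, s, e), "D2", pol2_strand=strand
                        )
                    )
                elif kind == "pol2":
                    strand = "+" if rng.random() < 0.5 else "-"
                    truth.pol2_loci.append(
                        PlantedLocus(GenomicInterval(chrom, s, e, strand))
                    )
                else:
                    ex_lens, in_lens = payload
                    strand = "+" if rng.random() < 0.5 else "-"
                    exons = []
                    cursor = s
                    for i, xl in enumerate(ex_lens):
                        exons.append(GenomicInterval(chrom, cursor, cursor + xl, strand))
                        cursor += xl
                        if i < len(in_lens):
                            cursor += in_lens[i]
                    truth.genes.append(
                        PlantedGene(GenomicInterval(chrom, s, e, strand), exons)
                    )

        # --- pericentromere: C2 loci ---------------------------------------
        peri = (L // 3, 2 * L // 3)
        c2_lens = [int(rng.integers(lo, hi + 1)) for _ in range(c2_per[ci])]
        for s, e in _place_lengths(rng, peri, c2_lens, min_gap=300):
            strand = "+" if rng.random() < 0.5 else "-"
            truth.p4_loci.append(
                PlantedLocus(GenomicInterval(chrom, s, e), "C2", pol2_strand=strand)
            )

        # --- overwrite P4 locus bodies and flanks with planted composition --
        for locus in truth.p4_loci:
            iv = locus.interval
            if iv.chrom != chrom:
                continue
            body_at = 1.0 - config.body_gc
            seq[iv.start : iv.end] = _random_sequence(rng, iv.length, body_at)
            w = config.flank_width
            fl = _random_sequence(rng, w, config.flank_at_enrichment)
            fr = _random_sequence(rng, w, config.flank_at_enrichment)
            seq[max(0, iv.start - w) : iv.start] = fl[: iv.start - max(0, iv.start - w)]
            seq[iv.end : min(L, iv.end + w)] = fr[: min(L, iv.end + w) - iv.end]

        genome[chrom] = seq.tobytes().decode("ascii")

    # per-locus expression weights (shared across assays/genotypes)
    for group in (truth.p4_loci, truth.pol2_loci, truth.genes):
        if not group:
            continue
        raw = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=len(group))
        w = raw / raw.sum()
        for item, wi in zip(group, w):
            item.weight = float(wi)
    return genome, truth


def annotation_gff3(truth: GroundTruth) -> str:
    """GFF3 text for the planted genes/exons (1-based inclusive on write)."""
    lines = ["##gff-version 3"]
    genes = sorted(truth.genes, key=lambda g: (g.interval.chrom, g.interval.start))
    for gi, g in enumerate(genes, start=1):
        iv = g.interval
        gid = f"gene{gi:04d}"
        lines.append(
            f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
            f"ID={gid}"
        )
        for xi, ex in enumerate(g.exons, start=1):
            lines.append(
                f"{ex.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t"
                f"ID={gid}.exon{xi};Parent={gid}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequencing libraries
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    if config.noise_model == "poisson":
        return rng.poisson(means)
    disp = config.negbin_dispersion
    n = 1.0 / disp
    out = np.zeros(len(means), dtype=np.int64)
    pos = means > 0
    p = n / (n + means[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


class _ReadBuffer:
    def __init__(self, chrom_names: list) -> None:
        self.chrom_names = chrom_names
        self.codes = {c: i for i, c in enumerate(chrom_names)}
        self.chrom_of: list = []
        self.starts: list = []
        self.ends: list = []
        self.strands: list = []
        self.names: list = []

    def add(self, chrom, starts, ends, strands, names=None) -> None:
        n = len(starts)
        if n == 0:
            return
        code = self.codes[chrom]
        self.chrom_of.append(np.full(n, code, dtype=np.int32))
        self.starts.append(np.asarray(starts, dtype=np.int64))
        self.ends.append(np.asarray(ends, dtype=np.int64))
        self.strands.append(np.asarray(strands, dtype=np.int8))
        self.names.extend(names if names is not None else [""] * n)

    def finish(self) -> SimReads:
        if not self.starts:
            empty = np.array([], dtype=np.int64)
            return SimReads(
                np.array([], dtype=np.int32), empty, empty.copy(),
                np.array([], dtype=np.int8), [], self.chrom_names,
            )
        return SimReads(
            np.concatenate(self.chrom_of),
            np.concatenate(self.starts),
            np.concatenate(self.ends),
            np.concatenate(self.strands),
            self.names,
            self.chrom_names,
        )


def _locus_reads(
    rng: np.random.Generator,
    buf: _ReadBuffer,
    locus: GenomicInterval,
    count: int,
    read_len,
    strand_mode: str,
    skew: float = 0.5,
    planted_strand: str = "+",
) -> None:
    """Place ``count`` reads uniformly within a locus.

    ``strand_mode``: "both" draws strands 50/50; "skewed" draws the planted
    strand with probability ``skew``.
    """
    if count <= 0:
        return
    if callable(read_len):
        rlens = read_len(count)
    else:
        rlens = np.full(count, read_len, dtype=np.int64)
    rlens = np.minimum(rlens, locus.length)
    span = locus.length - rlens + 1
    starts = locus.start + (rng.random(count) * span).astype(np.int64)
    ends = starts + rlens
    if strand_mode == "both":
        strands = (rng.random(count) < 0.5).astype(np.int8)
    else:
        planted = 1 if planted_strand == "+" else 0
        hit = rng.random(count) < skew
        strands = np.where(hit, planted, 1 - planted).astype(np.int8)
    buf.add(locus.chrom, starts, ends, strands)


def _srna_lengths(rng: np.random.Generator):
    def draw(n: int) -> np.ndarray:
        return rng.choice(_SRNA_LENGTHS, size=n, p=_SRNA_LENGTH_P)

    return draw


def _uniform_background(
    rng: np.random.Generator,
    buf: _ReadBuffer,
    truth: GroundTruth,
    total: int,
    read_len,
    exclude: list | None = None,
) -> None:
    """Reads placed uniformly over the genome, optionally rejecting any that
    overlap ``exclude`` intervals (e.g. Pol IV-independent small RNAs are
    drawn from outside the planted P4 loci)."""
    sizes = truth.chrom_sizes
    chrom_names = sorted(sizes)
    lens = np.array([sizes[c] for c in chrom_names], dtype=float)
    per_chrom = rng.multinomial(total, lens / lens.sum())
    excl_by_chrom: dict[str, list] = {c: [] for c in chrom_names}
    for iv in exclude or []:
        excl_by_chrom[iv.chrom].append(iv)
    for chrom, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        ex = sorted(excl_by_chrom[chrom], key=lambda iv: iv.start)
        ex_starts = np.array([iv.start for iv in ex], dtype=np.int64)
        ex_ends = np.array([iv.end for iv in ex], dtype=np.int64)
        got_s: list = []
        remaining = int(n)
        while remaining > 0:
            if callable(read_len):
                rlens = read_len(remaining)
            else:
                rlens = np.full(remaining, read_len, dtype=np.int64)
            starts = (rng.random(remaining) * (sizes[chrom] - rlens)).astype(np.int64)
            ends = starts + rlens
            if len(ex_starts):
                idx = np.searchsorted(ex_starts, starts, side="right") - 1
                bad = np.zeros(remaining, dtype=bool)
                ok = idx >= 0
                bad[ok] = ex_ends[idx[ok]] > starts[ok]
                nxt = idx + 1
                ok2 = nxt < len(ex_starts)
                bad[ok2] |= ex_starts[nxt[ok2]] < ends[ok2]
                starts, ends = starts[~bad], ends[~bad]
            got_s.append((starts, ends))
            remaining = int(n) - sum(len(s) for s, _ in got_s)
        starts = np.concatenate([s for s, _ in got_s])[: int(n)]
        ends = np.concatenate([e for _, e in got_s])[: int(n)]
        strands = (rng.random(int(n)) < 0.5).astype(np.int8)
        buf.add(chrom, starts, ends, strands)


def _exonic_background(
    rng: np.random.Generator,
    buf: _ReadBuffer,
    truth: GroundTruth,
    total: int,
    stranded_to_gene: bool,
    skew: float,
    both_strands: bool = False,
    read_len=None,
) -> None:
    """Reads drawn from exons, genes weighted by expression, position
    uniform within the exon."""
    exons = []
    weights = []
    for g in truth.genes:
        for ex in g.exons:
            exons.append((ex, g))
            weights.append(g.weight * ex.length / g.interval.length)
    if not exons:
        return
    rlen = read_len if read_len is not None else _LONG_READ_LEN
    w = np.array(weights)
    counts = rng.multinomial(total, w / w.sum())
    for (ex, g), c in zip(exons, counts):
        if c == 0:
            continue
        if both_strands:
            _locus_reads(rng, buf, ex, int(c), rlen, "both")
        else:
            _locus_reads(
                rng, buf, ex, int(c), rlen, "skewed",
                skew=skew, planted_strand=ex.strand,
            )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_libraries(
    truth: GroundTruth,
    config: SimulationConfig,
    genome: dict,
    rng: np.random.Generator,
) -> tuple[dict, dict, dict]:
    """Generate all sequencing libraries.

    Returns ``(libraries, reads, spliced_sequences)`` where ``libraries``
    maps library_id -> :class:`Library` with ``total_mapped_reads`` equal to
    the number of reads actually emitted, ``reads`` maps library_id ->
    :class:`SimReads` and ``spliced_sequences`` maps spliced read ids to
    their (unaligned) sequences.
    """
    chrom_names = sorted(truth.chrom_sizes)
    fold = config.p4_fold_change
    depleted = 0.0 if math.isinf(fold) else 1.0 / fold
    p4 = truth.p4_loci
    p4_w = np.array([p.weight for p in p4])
    pol2 = truth.pol2_loci
    pol2_w = np.array([p.weight for p in pol2])

    libraries: dict[str, Library] = {}
    reads: dict[str, SimReads] = {}
    spliced_sequences: dict[str, str] = {}

    def register(lib_id, assay, genotype, rep, buf, stranded=True):
        sim = buf.finish()
        libraries[lib_id] = Library(
            library_id=lib_id,
            assay=assay,
            genotype=genotype,
            replicate=rep,
            total_mapped_reads=max(1, len(sim)),
            stranded=stranded,
        )
        reads[lib_id] = sim

    # ---- sRNA-seq: WT and nrpd1, 3 replicates each -----------------------
    for genotype, scale in (("WT", 1.0), ("nrpd1", depleted)):
        for rep in (1, 2, 3):
            lib_id = f"sRNA_{genotype}_r{rep}"
            depth = config.depth(lib_id)
            p4_mass = _SRNA_MIX["p4"] * scale
            factor = depth / (p4_mass + _SRNA_MIX["background"])
            buf = _ReadBuffer(chrom_names)
            means = factor * p4_mass * p4_w
            counts = _draw_counts(rng, means, config)
            for locus, c in zip(p4, counts):
                _locus_reads(
                    rng, buf, locus.interval, int(c), _srna_lengths(rng), "both"
                )
            # Pol IV-independent small RNAs: mostly genic (miRNA-like and
            # degradation products of expressed mRNAs), a thin uniform
            # layer elsewhere; none originates from the P4 loci themselves
            n_bg = int(rng.poisson(factor * _SRNA_MIX["background"]))
            n_genic = int(round(n_bg * 0.8))
            _exonic_background(
                rng, buf, truth, n_genic, False, 0.5, both_strands=True,
                read_len=_srna_lengths(rng),
            )
            _uniform_background(
                rng, buf, truth, n_bg - n_genic, _srna_lengths(rng),
                exclude=truth.p4_intervals(),
            )
            register(lib_id, "sRNA", genotype, rep, buf)

    # ---- dsRNA-seq: dcl234 / dcl234 nrpd1 / dcl234 rdr2, 3 reps ----------
    for genotype, scale in (
        ("dcl234", 1.0),
        ("dcl234_nrpd1", depleted),
        ("dcl234_rdr2", depleted),
    ):
        for rep in (1, 2, 3):
            lib_id = f"dsRNA_{genotype}_r{rep}"
            depth = config.depth(lib_id)
            p4_mass = _DSRNA_MIX["p4"] * scale
            factor = depth / (p4_mass + _DSRNA_MIX["genic"])
            buf = _ReadBuffer(chrom_names)
            means = factor * p4_mass * p4_w
            counts = _draw_counts(rng, means, config)
            for locus, c in zip(p4, counts):
                _locus_reads(rng, buf, locus.interval, int(c), _LONG_READ_LEN, "both")
            # RNase-protected structured background derives from genic RNA
            n_bg = int(rng.poisson(factor * _DSRNA_MIX["genic"]))
            _exonic_background(rng, buf, truth, n_bg, False, 0.5, both_strands=True)
            register(lib_id, "dsRNA", genotype, rep, buf)

    # ---- stranded poly(A)+ : dcl234 and dcl234 nrpd1 ----------------------
    for genotype in ("dcl234", "dcl234_nrpd1"):
        lib_id = f"polyA_plus_{genotype}_r1"
        depth = config.depth(lib_id)
        buf = _ReadBuffer(chrom_names)
        means = depth * _POLYA_PLUS_MIX["pol2"] * pol2_w
        counts = _draw_counts(rng, means, config)
        for locus, c in zip(pol2, counts):
            _locus_reads(
                rng, buf, locus.interval, int(c), _LONG_READ_LEN, "skewed",
                skew=config.polya_strand_skew, planted_strand=locus.interval.strand,
            )
        # residual Pol II transcription at P4 loci: one strand, Pol IV-independent
        means = depth * _POLYA_PLUS_MIX["p4"] * p4_w
        counts = _draw_counts(rng, means, config)
        for locus, c in zip(p4, counts):
            _locus_reads(
                rng, buf, locus.interval, int(c), _LONG_READ_LEN, "skewed",
                skew=config.polya_strand_skew, planted_strand=locus.pol2_strand,
            )
        n_genic = int(rng.poisson(depth * _POLYA_PLUS_MIX["genic"]))
        n_spliced = int(round(n_genic * _SPLICED_FRACTION))
        _exonic_background(
            rng, buf, truth, n_genic - n_spliced, True, config.polya_strand_skew
        )
        if genotype == "dcl234":  # splice truth tracked for the scan's oracle
            _spliced_reads(rng, buf, truth, genome, n_spliced, spliced_sequences)
        else:
            _spliced_reads(rng, buf, truth, genome, n_spliced, None)
        register(lib_id, "polyA_plus", genotype, 1, buf)

    # ---- stranded poly(A)- : dcl234 and dcl234 nrpd1 ----------------------
    for genotype, scale in (("dcl234", 1.0), ("dcl234_nrpd1", depleted)):
        lib_id = f"polyA_minus_{genotype}_r1"
        depth = config.depth(lib_id)
        p4_mass = _POLYA_MINUS_MIX["p4"] * scale
        factor = depth / (p4_mass + _POLYA_MINUS_MIX["genic"])
        buf = _ReadBuffer(chrom_names)
        means = factor * p4_mass * p4_w
        counts = _draw_counts(rng, means, config)
        for locus, c in zip(p4, counts):
            _locus_reads(rng, buf, locus.interval, int(c), _LONG_READ_LEN, "both")
        n_bg = int(rng.poisson(factor * _POLYA_MINUS_MIX["genic"]))
        _exonic_background(rng, buf, truth, n_bg, False, 0.5, both_strands=True)
        register(lib_id, "polyA_minus", genotype, 1, buf)

    return libraries, reads, spliced_sequences


def _spliced_reads(
    rng: np.random.Generator,
    buf: _ReadBuffer,
    truth: GroundTruth,
    genome: dict,
    total: int,
    sequences: dict | None,
) -> None:
    """Exon-exon junction reads: two BED segments sharing a read id, plus
    (optionally) the unaligned sequence record and junction truth."""
    junctions = []
    weights = []
    for gi, g in enumerate(truth.genes):
        for ji, intron in enumerate(g.introns):
            junctions.append((gi, ji, g, intron))
            weights.append(g.weight / max(1, len(g.introns)))
    if not junctions:
        return
    w = np.array(weights)
    counts = rng.multinomial(total, w / w.sum())
    k = _SPLICE_SEG_LEN
    for (gi, ji, g, intron), c in zip(junctions, counts):
        left_exon = g.exons[ji]
        right_exon = g.exons[ji + 1]
        if left_exon.length < k or right_exon.length < k:
            continue
        chrom = g.interval.chrom
        for i in range(int(c)):
            rid = f"spliced_g{gi:04d}_j{ji}_{i:04d}"
            ls, le = left_exon.end - k, left_exon.end
            rs, re = right_exon.start, right_exon.start + k
            code = 1 if g.interval.strand == "+" else 0
            buf.add(chrom, [ls], [le], [code], names=[rid])
            buf.add(chrom, [rs], [re], [code], names=[rid])
            if sequences is not None:
                seq = genome[chrom][ls:le] + genome[chrom][rs:re]
                if g.interval.strand == "-":
                    seq = _revcomp(seq)
                sequences[rid] = seq
                truth.spliced_read_ids.add(rid)
                truth.junctions[rid] = GenomicInterval(
                    chrom, intron.start, intron.end, g.interval.strand
                )


# ---------------------------------------------------------------------------
# epigenome
# ---------------------------------------------------------------------------

_LEVELS = {
    # genotype -> (level at D2 loci, level at C2 loci, background level)
    "WT": (0.30, 0.30, 0.02),
    "drm12": (0.02, 0.30, 0.02),
    "cmt2": (0.30, 0.02, 0.02),
    "nrpd1": (0.02, 0.30, 0.02),  # Pol IV-dependent CHH is mainly DRM2-placed
}


def simulate_epigenome(
    truth: GroundTruth,
    config: SimulationConfig,
    genome: dict,
    rng: np.random.Generator,
) -> tuple[dict, list, dict]:
    """Methylomes per genotype, nucleosome calls and histone-mark domains.

    CHH methylation is high at P4 loci in WT, lost at D2 loci in ``drm12``
    (and ``nrpd1``) and at C2 loci in ``cmt2``. Nucleosome calls avoid the
    planted A/T-rich flanks and are anchored just inside locus ends. Both
    H3K9me2 and H3K27me1 cover most of the pericentromeric third, with
    sparse correlated islands in the arms.
    """
    methylomes = {
        g: _methylome(truth, config, genome, rng, g) for g in sorted(_LEVELS)
    }
    nucleosomes = _nucleosomes(truth, config, rng)
    marks = _mark_domains(truth, rng)
    return methylomes, nucleosomes, marks


def _methylome(
    truth: GroundTruth,
    config: SimulationConfig,
    genome: dict,
    rng: np.random.Generator,
    genotype: str,
) -> pd.DataFrame:
    d2_level, c2_level, bg_level = _LEVELS[genotype]
    rows = {k: [] for k in ("chrom", "pos", "strand", "context", "mc", "total")}
    for chrom in sorted(truth.chrom_sizes):
        seq = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        c_pos = np.flatnonzero(seq == ord("C"))  # CHH on Watson
        g_pos = np.flatnonzero(seq == ord("G"))  # CHH on Crick
        loci = sorted(
            (p for p in truth.p4_loci if p.interval.chrom == chrom),
            key=lambda p: p.interval.start,
        )
        starts = np.array([p.interval.start for p in loci], dtype=np.int64)
        ends = np.array([p.interval.end for p in loci], dtype=np.int64)
        is_d2 = np.array([p.klass == "D2" for p in loci])
        for pos_all, strand in ((c_pos, "+"), (g_pos, "-")):
            idx = np.searchsorted(starts, pos_all, side="right") - 1
            in_locus = (idx >= 0) & (pos_all < ends[np.clip(idx, 0, None)])
            keep_p = np.where(in_locus, 0.5, 0.02)
            keep = rng.random(len(pos_all)) < keep_p
            pos = pos_all[keep]
            inl = in_locus[keep]
            lidx = idx[keep]
            level = np.full(len(pos), bg_level)
            level[inl] = np.where(is_d2[lidx[inl]], d2_level, c2_level)
            total = rng.poisson(19, size=len(pos)) + 1
            mc = rng.binomial(total, level)
            rows["chrom"].extend([chrom] * len(pos))
            rows["pos"].extend(pos.tolist())
            rows["strand"].extend([strand] * len(pos))
            rows["context"].extend(["CHH"] * len(pos))
            rows["mc"].extend(mc.tolist())
            rows["total"].extend(total.tolist())
    df = pd.DataFrame(
        {
            "chrom": rows["chrom"],
            "pos": rows["pos"],
            "strand": rows["strand"],
            "context": rows["context"],
            "mc_count": rows["mc"],
            "total_count": rows["total"],
        }
    )
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )


def _nucleosomes(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> list:
    """Background nucleosome array minus the planted flank depletion, plus
    a well-positioned nucleosome just inside each locus end."""
    calls: list[GenomicInterval] = []
    w = config.flank_width
    for chrom in sorted(truth.chrom_sizes):
        L = truth.chrom_sizes[chrom]
        loci = sorted(
            (p.interval for p in truth.p4_loci if p.interval.chrom == chrom),
            key=lambda iv: iv.start,
        )
        fl_starts = np.array(
            [max(0, iv.start - w) for iv in loci]
            + [iv.end for iv in loci],
            dtype=np.int64,
        )
        fl_ends = np.array(
            [iv.start for iv in loci] + [min(L, iv.end + w) for iv in loci],
            dtype=np.int64,
        )
        order = np.argsort(fl_starts)
        fl_starts, fl_ends = fl_starts[order], fl_ends[order]
        pos = 10
        while pos + 147 < L:
            if rng.random() < 0.75:
                s, e = pos, pos + 147
                i = int(np.searchsorted(fl_ends, s, side="right"))
                overlaps_flank = i < len(fl_starts) and fl_starts[i] < e
                if not overlaps_flank:
                    calls.append(GenomicInterval(chrom, s, e))
            pos += 147 + int(rng.integers(10, 60))
        for iv in loci:  # phased nucleosome just inside each end
            if iv.length >= 310:
                calls.append(GenomicInterval(chrom, iv.start + 3, iv.start + 150))
                calls.append(GenomicInterval(chrom, iv.end - 150, iv.end - 3))
            else:
                s = iv.start + 3
                e = min(iv.end - 3, s + 147)
                if e > s:
                    calls.append(GenomicInterval(chrom, s, e))
    return sorted(calls, key=lambda iv: (iv.chrom, iv.start))


def _tile_domains(
    rng: np.random.Generator,
    chrom: str,
    region: tuple,
    len_range: tuple,
    gap_range: tuple,
) -> list:
    out = []
    pos = region[0] + int(rng.integers(*gap_range))
    while pos < region[1]:
        dl = int(rng.integers(*len_range))
        end = min(pos + dl, region[1])
        if end > pos:
            out.append(GenomicInterval(chrom, pos, end))
        pos = end + int(rng.integers(*gap_range))
    return out


def _mark_domains(truth: GroundTruth, rng: np.random.Generator) -> dict:
    k9: list[GenomicInterval] = []
    k27: list[GenomicInterval] = []
    for chrom in sorted(truth.chrom_sizes):
        L = truth.chrom_sizes[chrom]
        peri = (L // 3, 2 * L // 3)
        k9 += _tile_domains(rng, chrom, peri, (3000, 8000), (100, 400))
        k27 += _tile_domains(rng, chrom, peri, (3000, 8000), (100, 400))
        # correlated heterochromatic islands on the arms
        for arm in ((0, L // 3), (2 * L // 3, L)):
            pos = arm[0] + int(rng.integers(2000, 15000))
            while pos < arm[1]:
                il = int(rng.integers(2000, 5001))
                end = min(pos + il, arm[1])
                if rng.random() < 0.8:
                    k9.append(GenomicInterval(chrom, pos, end))
                if rng.random() < 0.8:
                    k27.append(GenomicInterval(chrom, pos, end))
                pos = end + int(rng.integers(8000, 25000))
    key = lambda iv: (iv.chrom, iv.start)  # noqa: E731
    return {"h3k9me2": sorted(k9, key=key), "h3k27me1": sorted(k27, key=key)}


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig | None = None) -> Simulation:
    """Run the full generator under ``config`` (deterministic per seed)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome, truth = generate_genome(config, rng)
    libraries, reads, spliced = simulate_libraries(truth, config, genome, rng)
    methylomes, nucleosomes, marks = simulate_epigenome(truth, config, genome, rng)
    return Simulation(
        config=config,
        genome=genome,
        truth=truth,
        libraries=libraries,
        reads=reads,
        spliced_sequences=spliced,
        methylomes=methylomes,
        nucleosomes=nucleosomes,
        marks=marks,
    )


def simulate_null_differential(
    n_windows: int = 2000,
    window: int = 300,
    mean_count: float = 20.0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list, list, list]:
    """A no-effect dataset for error-control checks: the same per-window
    negative-binomial mean in both genotypes.

    Returns ``(control_libs, mutant_libs, windows)`` ready for the
    differential caller.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrN"
    windows = [
        GenomicInterval(chrom, i * window, (i + 1) * window) for i in range(n_windows)
    ]
    cfg = SimulationConfig(seed=seed, negbin_dispersion=dispersion)

    def make(side: str, rep: int) -> LibraryReads:
        counts = _draw_counts(
            rng, np.full(n_windows, mean_count), cfg
        )
        buf = _ReadBuffer([chrom])
        for win, c in zip(windows, counts):
            _locus_reads(rng, buf, win, int(c), 24, "both")
        sim = buf.finish()
        genotype = "WT" if side == "control" else "nrpd1"
        lib = Library(
            library_id=f"null_{side}_r{rep}",
            assay="sRNA",
            genotype=genotype,
            replicate=rep,
            total_mapped_reads=max(1, len(sim)),
        )
        return LibraryReads.from_index(lib, sim.index())

    control = [make("control", r) for r in range(1, n_replicates + 1)]
    mutant = [make("mutant", r) for r in range(1, n_replicates + 1)]
    return control, mutant, windows


def load_simulation_dir(path: str) -> dict:
    """Load a written simulation directory back into analysis-ready objects.

    Returns a dict with genome, truth, manifest, per-library LibraryReads,
    methylomes, nucleosomes and marks.
    """
    genome = pio.read_fasta(os.path.join(path, "genome.fa"))
    with open(os.path.join(path, "truth.json")) as fh:
        truth = GroundTruth.from_json(fh.read())
    manifest = pio.read_manifest(os.path.join(path, "manifest.tsv"))
    libs: dict[str, LibraryReads] = {}
    for lib_id, lib in manifest.items():
        reads = pio.read_bed_reads(
            os.path.join(path, "reads", f"{lib_id}.bed"), lib_id
        )
        libs[lib_id] = LibraryReads(library=lib, reads=reads)
    methylomes = {}
    meth_dir = os.path.join(path, "methylation")
    for fn in sorted(os.listdir(meth_dir)):
        methylomes[fn[: -len(".tsv")]] = pio.read_methylation(
            os.path.join(meth_dir, fn)
        )
    nucleosomes = pio.read_bed(os.path.join(path, "nucleosomes.bed"))
    marks = {
        "h3k9me2": pio.read_bed(os.path.join(path, "marks", "h3k9me2.bed")),
        "h3k27me1": pio.read_bed(os.path.join(path, "marks", "h3k27me1.bed")),
    }
    return {
        "genome": genome,
        "truth": truth,
        "manifest": manifest,
        "libraries": libs,
        "methylomes": methylomes,
        "nucleosomes": nucleosomes,
        "marks": marks,
    }
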