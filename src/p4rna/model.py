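"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read. Strand is one of ``+``, ``-`` or ``.`` (strandless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")
ASSAYS = ("sRNA", "dsRNA", "RNAseq", "polyA_plus", "polyA_minus")
GENOTYPES = ("WT", "nrpd1", "dcl234", "dcl234_nrpd1", "dcl234_rdr2", "other")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap_bp

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read. ``name`` carries the read id where one exists
    (spliced reads share a name across their two segments)."""

    interval: GenomicInterval
    library_id: str = ""
    name: str = ""


@dataclass(frozen=True)
class Library:
    """Metadata for one sequencing library; ``total_mapped_reads`` is the
    RPM denominator and comes from the manifest, not from counting the
    (possibly subsetted) read file."""

    library_id: str
    assay: str
    genotype: str
    replicate: int = 1
    total_mapped_reads: int = 1
    stranded: bool = True

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")


@dataclass(frozen=True)
class MethylationRecord:
    """Per-cytosine methylation evidence: ``mc_count`` methylated calls out
    of ``total_count`` reads covering the position."""

    chrom: str
    pos: int
    strand: str
    context: str
    mc_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 <= self.mc_count <= self.total_count):
            raise ValueError("require 0 <= mc_count <= total_count")

    @property
    def level(self) -> float:
        return self.mc_count / self.total_count if self.total_count else 0.0


@dataclass(frozen=True)
class NucleosomeCall:
    """A called nucleosome footprint (strandless)."""

    interval: GenomicInterval


@dataclass
class LocusRecord:
    """A P4siRNA locus annotated through the pipeline: expression,
    precursor detection, methylation, methyltransferase class
    (D2 = DRM2-dependent, C2 = CMT2-dependent), quartiles, histone marks."""

    interval: GenomicInterval
    sirna_rpm_wt: float = 0.0
    p4rna_detected: bool = False
    chh_wt: float = 0.0
    chh_dcl234: float = 0.0
    klass: str = "other"  # D2 | C2 | other
    sirna_quartile: int = 0
    chh_quartile: int = 0
    has_k9: bool = False
    has_k27: bool = False


@dataclass
class MetageneProfile:
    """Anchored per-position signal averaged over many regions.

    ``offsets[i]`` is the signed distance from the anchor (0 = anchor base);
    ``values[i]`` is the mean signal there, in [0, 1]; ``n[i]`` the number of
    sequences contributing to that position (sequences whose window runs off
    a chromosome are excluded position by position).
    """

    anchor: str  # "start" | "end"
    offsets: "list[int] | object"
    values: "list[float] | object"
    n: "list[int] | object" = field(default_factory=list)
    n_sequences: int = 0
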