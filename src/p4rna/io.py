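"""Reading and writing the pipeline's exchange formats.

BED3/BED6 for intervals and reads, GFF3 for annotation (converted to
0-based half-open on read), FASTA for the genome, a tab-delimited
per-cytosine methylation table, and a tab-delimited library manifest.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .model import AlignedRead, GenomicInterval, Library, NucleosomeCall

MANIFEST_COLUMNS = [
    "library_id",
    "assay",
    "genotype",
    "replicate",
    "total_mapped_reads",
    "stranded",
]

METH_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count"]


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_bed(path: str, stranded: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals (0-based half-open, as stored).

    Malformed lines raise ``ValueError`` naming the 1-based line number.
    With ``stranded`` a missing/invalid strand column is an error instead of
    defaulting to ``"."``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno)
            if stranded and iv.strand == ".":
                raise ValueError(f"line {lineno}: strand required for stranded input")
            out.append(iv)
    return out


def read_bed_reads(path: str, library_id: str) -> list[AlignedRead]:
    """Read aligned reads from BED6; column 4 is kept as the read name
    (spliced reads appear as two lines sharing a name)."""
    out: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno)
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) >= 4 else ""
            out.append(AlignedRead(iv, library_id=library_id, name=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED6 (name ``.``, score 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_bed_reads(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            name = r.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_sam_reads(path: str, library_id: str) -> list[AlignedRead]:
    """Read mapped reads from a SAM file (read-only convenience path)."""
    import pysam  # local import: optional input path

    out: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            out.append(AlignedRead(iv, library_id=library_id, name=aln.query_name))
    return out


def read_gff3(path: str, feature_types: Sequence[str] | None = None) -> dict:
    """Read a GFF3 annotation into ``{feature_type: [GenomicInterval, ...]}``.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open
    (start - 1). Only ``feature_types`` are kept when given.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feature_types is not None and feat.featuretype not in feature_types:
            continue
        strand = feat.strand if feat.strand in ("+", "-") else "."
        out.setdefault(feat.featuretype, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        )
    return out


def read_fasta(path: str) -> dict:
    """Load a genome FASTA into ``{chrom: sequence string}`` (uppercased)."""
    from pyfaidx import Fasta

    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_methylation(path: str) -> pd.DataFrame:
    """Read a per-cytosine methylation table.

    Tab-delimited columns: chrom, pos (0-based), strand, context, mc_count,
    total_count; a header line starting with ``#`` is skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=METH_COLUMNS)
    if ((df["mc_count"] < 0) | (df["mc_count"] > df["total_count"])).any():
        raise ValueError("methylation table violates 0 <= mc_count <= total_count")
    return df


def write_methylation(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(METH_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_manifest(path: str) -> dict:
    """Read a library manifest TSV into ``{library_id: Library}``."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out: dict[str, Library] = {}
    for row in df.itertuples(index=False):
        lib = Library(
            library_id=str(row.library_id),
            assay=str(row.assay),
            genotype=str(row.genotype),
            replicate=int(row.replicate),
            total_mapped_reads=int(row.total_mapped_reads),
            stranded=bool(row.stranded),
        )
        out[lib.library_id] = lib
    return out


def write_manifest(libraries: Sequence[Library], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "library_id": lib.library_id,
                "assay": lib.assay,
                "genotype": lib.genotype,
                "replicate": lib.replicate,
                "total_mapped_reads": lib.total_mapped_reads,
                "stranded": lib.stranded,
            }
            for lib in libraries
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_nucleosomes(path: str) -> list[NucleosomeCall]:
    return [NucleosomeCall(iv) for iv in read_bed(path)]


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
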