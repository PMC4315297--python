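"""Transcript-feature analyses distinguishing Pol II from Pol IV products.

* A naive, motif-agnostic spliced-read scan: a read not mapping
  contiguously is a splice candidate if its first and last 15 nt each map
  perfectly to the same strand nearby (genomic footprint <= 1000 nt).
* An intron-coverage filter: a candidate junction survives only if its
  gap ("intron") is covered at least five times less than its flanks.
* Strand-ratio classification of stranded libraries at loci (the 9:1
  single-strand rule) and the poly(A)+/poly(A)- dependence contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import LibraryReads, ReadIndex, base_coverage
from .model import GenomicInterval
from .regions import fold_change

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SpliceCandidate:
    """A potential splicing event: two perfectly matching seed segments on
    one strand with an unmatched gap between them."""

    read_id: str
    left_segment: GenomicInterval
    right_segment: GenomicInterval
    gap_interval: GenomicInterval
    strand: str


@dataclass
class SpliceScanResult:
    candidates: list
    n_reads: int = 0
    n_short_skipped: int = 0
    n_perfect_match: int = 0
    n_ambiguous: int = 0
    n_no_placement: int = 0


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _placements(genome: dict, seq: str) -> list[tuple[str, str, int]]:
    """All exact matches of ``seq``: (chrom, strand, genomic start)."""
    rc = revcomp(seq)
    out = []
    for chrom in sorted(genome):
        for pos in _find_all(genome[chrom], seq):
            out.append((chrom, "+", pos))
        for pos in _find_all(genome[chrom], rc):
            out.append((chrom, "-", pos))
    return out


def find_spliced_reads(
    reads_with_sequence: Iterable[tuple],
    genome: dict,
    already_mapped_ids: "set | frozenset" = frozenset(),
    seed_len: int = 15,
    max_span: int = 1000,
) -> SpliceScanResult:
    """Seed-anchored spliced-read discovery.

    ``reads_with_sequence`` yields ``(read_id, sequence)`` records of reads
    that failed contiguous mapping (ids in ``already_mapped_ids`` are
    skipped; reads whose full sequence still matches the genome exactly are
    treated as mapped and skipped too). A candidate requires the first and
    last ``seed_len`` nt to match the genome perfectly on one strand of one
    chromosome, in splice orientation with a positive gap, with the
    anchor-to-anchor genomic footprint at most ``max_span``. Reads with
    more than one compatible anchor pairing are discarded as ambiguous.
    """
    result = SpliceScanResult(candidates=[])
    cache: dict[str, list] = {}  # many reads share junction sequences

    def placements(seq: str) -> list:
        hits = cache.get(seq)
        if hits is None:
            hits = cache[seq] = _placements(genome, seq)
        return hits

    for read_id, seq in reads_with_sequence:
        result.n_reads += 1
        if read_id in already_mapped_ids:
            continue
        seq = seq.upper()
        if len(seq) < 2 * seed_len:
            result.n_short_skipped += 1
            continue
        if placements(seq):
            result.n_perfect_match += 1
            continue
        head = seq[:seed_len]
        tail = seq[-seed_len:]
        head_hits = placements(head)
        tail_hits = placements(tail)
        pairs = []
        for hc, hs, hp in head_hits:
            for tc, ts, tp in tail_hits:
                if hc != tc or hs != ts:
                    continue
                if hs == "+":
                    left, right = hp, tp  # head upstream of tail
                else:
                    left, right = tp, hp  # read 5' end is genomically right
                gap = right - (left + seed_len)
                span = (right + seed_len) - left
                if gap > 0 and span <= max_span:
                    pairs.append((hc, hs, left, right))
        if len(pairs) == 1:
            chrom, strand, left, right = pairs[0]
            result.candidates.append(
                SpliceCandidate(
                    read_id=read_id,
                    left_segment=GenomicInterval(chrom, left, left + seed_len, strand),
                    right_segment=GenomicInterval(
                        chrom, right, right + seed_len, strand
                    ),
                    gap_interval=GenomicInterval(chrom, left + seed_len, right, strand),
                    strand=strand,
                )
            )
        elif len(pairs) > 1:
            result.n_ambiguous += 1
        else:
            result.n_no_placement += 1
    return result


def filter_junctions_by_coverage(
    candidates: Sequence[SpliceCandidate],
    coverage_reads: "ReadIndex | Sequence",
    flank_width: int | None = None,
    min_ratio: float = 5.0,
) -> tuple[list, list]:
    """Keep junctions whose gap coverage is >= ``min_ratio`` times lower
    than the mean coverage of the two adjacent flanks.

    ``flank_width`` defaults to the gap length capped at 100 bp. A
    candidate whose flanks carry no coverage is removed (a coverage drop
    cannot be demonstrated). Returns ``(retained, removed)`` where removed
    entries are ``(candidate, flank_mean / gap_mean ratio)`` with ``inf``
    for a zero gap mean.
    """
    idx = (
        coverage_reads
        if isinstance(coverage_reads, ReadIndex)
        else ReadIndex.build(coverage_reads)
    )
    retained, removed = [], []
    for cand in candidates:
        gap = cand.gap_interval
        w = flank_width if flank_width is not None else min(gap.length, 100)
        w = max(1, w)
        left = GenomicInterval(gap.chrom, max(0, gap.start - w), gap.start)
        right = GenomicInterval(gap.chrom, gap.end, gap.end + w)
        gap_mean = float(np.mean(base_coverage(idx, gap)))
        flank_depths = np.concatenate(
            [base_coverage(idx, left), base_coverage(idx, right)]
        )
        flank_mean = float(np.mean(flank_depths)) if len(flank_depths) else 0.0
        if flank_mean <= 0:
            removed.append((cand, 0.0))
            continue
        ratio = np.inf if gap_mean == 0 else flank_mean / gap_mean
        if ratio >= min_ratio:
            retained.append(cand)
        else:
            removed.append((cand, ratio))
    return retained, removed


@dataclass
class StrandClassification:
    locus: GenomicInterval
    watson_reads: int
    crick_reads: int
    rpm_total: float
    ratio_major_minor: float
    single_stranded: bool


def classify_strandedness(
    stranded_reads: LibraryReads,
    loci: Sequence[GenomicInterval],
    min_rpm: float = 1.0,
    min_ratio: float = 9.0,
) -> list[StrandClassification]:
    """Classify loci as single- or double-stranded by their read strand
    ratio.

    Loci with total signal below ``min_rpm`` are excluded as unexpressed.
    The ratio is major/minor strand counts, with a zero minor strand
    treated as infinite; a locus is single-stranded iff the ratio is at
    least ``min_ratio`` (the 9:1 rule).
    """
    if not stranded_reads.library.stranded:
        raise ValueError("strandedness classification requires a stranded library")
    out = []
    for locus in loci:
        w, c = stranded_reads.index.count_per_strand(locus)
        total_rpm = stranded_reads.rpm(w + c)
        if total_rpm <= min_rpm:
            continue
        major, minor = max(w, c), min(w, c)
        ratio = np.inf if minor == 0 else major / minor
        out.append(
            StrandClassification(
                locus=locus,
                watson_reads=w,
                crick_reads=c,
                rpm_total=total_rpm,
                ratio_major_minor=float(ratio),
                single_stranded=bool(ratio >= min_ratio),
            )
        )
    return out


def polya_dependence_contrast(
    polya_plus: dict,
    polya_minus: dict,
    loci: Sequence[GenomicInterval],
    control_genotype: str = "dcl234",
    mutant_genotype: str = "dcl234_nrpd1",
    min_fold: float = 4.0,
) -> pd.DataFrame:
    """Per-locus Pol IV dependence tested separately in the poly(A)+ and
    poly(A)- fractions.

    ``polya_plus`` / ``polya_minus`` map genotype -> list[LibraryReads].
    Loci with no reads in any fraction are excluded. The returned frame
    has RPM per fraction x genotype, the control/mutant fold per fraction,
    and dependence flags (fold >= ``min_fold``).
    """
    for name, group in (("polya_plus", polya_plus), ("polya_minus", polya_minus)):
        for g in (control_genotype, mutant_genotype):
            if g not in group:
                raise ValueError(f"{name} lacks genotype {g}")

    def group_rpm(libs: Sequence[LibraryReads], locus: GenomicInterval) -> tuple:
        count = sum(lr.index.count(locus) for lr in libs)
        total = sum(lr.library.total_mapped_reads for lr in libs)
        return count, count * 1e6 / total

    rows = []
    for locus in loci:
        cp, rpm_pc = group_rpm(polya_plus[control_genotype], locus)
        mp, rpm_pm = group_rpm(polya_plus[mutant_genotype], locus)
        cm, rpm_mc = group_rpm(polya_minus[control_genotype], locus)
        mm, rpm_mm = group_rpm(polya_minus[mutant_genotype], locus)
        if cp + mp + cm + mm == 0:
            continue
        fold_plus = fold_change(rpm_pc, rpm_pm)
        fold_minus = fold_change(rpm_mc, rpm_mm)
        rows.append(
            {
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "rpm_plus_control": rpm_pc,
                "rpm_plus_mutant": rpm_pm,
                "rpm_minus_control": rpm_mc,
                "rpm_minus_mutant": rpm_mm,
                "fold_plus": fold_plus,
                "fold_minus": fold_minus,
                "dependent_plus": fold_plus >= min_fold,
                "dependent_minus": fold_minus >= min_fold,
            }
        )
    return pd.DataFrame(rows)
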