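"""Transcript assembly from dsRNA-seq reads.

Reads from all ``dcl234`` replicates falling in P4RNA regions are combined
and neighbouring reads no more than 60 nt apart are joined into
transcripts. Four filters are then applied, each recorded as a flag:
length > 60 nt, combined expression > 1 RPM, at least fourfold more signal
than in ``dcl234 nrpd1``, and overlap with a P4siRNA locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import (
    LibraryReads,
    build_interval_index,
    mask_overlapping,
    merge_coordinate_arrays,
    overlaps_any,
)
from .model import GenomicInterval
from .regions import fold_change


@dataclass
class AssembledTranscript:
    """One merged transcript with its filter evidence. Transcripts are
    strandless; the 5' end is taken as the Watson-strand start."""

    interval: GenomicInterval
    length: int
    count_dcl234: int
    count_nrpd1: int
    rpm_dcl234_combined: float
    rpm_nrpd1: float
    fold_vs_nrpd1: float
    overlaps_p4sirna: bool
    pass_length: bool
    pass_rpm: bool
    pass_fold: bool
    passed_filters: bool


def assemble(
    dcl234_libs: Sequence[LibraryReads],
    nrpd1_libs: Sequence[LibraryReads],
    p4rna_regions: Sequence[GenomicInterval],
    p4sirna_loci: Sequence[GenomicInterval],
    max_gap: int = 60,
    min_length: int = 60,
    min_rpm: float = 1.0,
    min_fold: float = 4.0,
    keep_all: bool = False,
) -> list[AssembledTranscript]:
    """Assemble and filter P4RNA transcripts.

    Only reads overlapping ``p4rna_regions`` participate. By default only
    transcripts passing all four filters are returned; ``keep_all`` retains
    every merged transcript with its flags.
    """
    if not dcl234_libs:
        raise ValueError("need >= 1 dcl234 library")
    n_dcl = sum(lr.library.total_mapped_reads for lr in dcl234_libs)
    n_mut = sum(lr.library.total_mapped_reads for lr in nrpd1_libs) or 1

    region_idx = build_interval_index(p4rna_regions)
    sirna_idx = build_interval_index(p4sirna_loci)

    # merge in-region reads per chromosome across all control replicates
    transcripts: list[GenomicInterval] = []
    chroms = sorted(region_idx)
    for chrom in chroms:
        rs, re = region_idx[chrom]
        parts_s, parts_e = [], []
        for lr in dcl234_libs:
            s, e, _ = lr.index.chrom_arrays(chrom)
            if len(s) == 0:
                continue
            keep = mask_overlapping(s, e, rs, re)
            parts_s.append(s[keep])
            parts_e.append(e[keep])
        if not parts_s:
            continue
        s = np.concatenate(parts_s)
        e = np.concatenate(parts_e)
        order = np.argsort(s, kind="stable")
        ms, me = merge_coordinate_arrays(s[order], e[order], max_gap=max_gap)
        transcripts.extend(
            GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me)
        )

    out: list[AssembledTranscript] = []
    for t in transcripts:
        c_dcl = sum(lr.index.count(t) for lr in dcl234_libs)
        c_mut = sum(lr.index.count(t) for lr in nrpd1_libs)
        rpm_dcl = c_dcl * 1e6 / n_dcl
        rpm_mut = c_mut * 1e6 / n_mut
        fold = fold_change(rpm_dcl, rpm_mut)
        has_sirna = overlaps_any(t, sirna_idx)
        pass_len = t.length > min_length
        pass_rpm = rpm_dcl > min_rpm
        pass_fold = fold >= min_fold
        passed = pass_len and pass_rpm and pass_fold and has_sirna
        rec = AssembledTranscript(
            interval=t,
            length=t.length,
            count_dcl234=c_dcl,
            count_nrpd1=c_mut,
            rpm_dcl234_combined=rpm_dcl,
            rpm_nrpd1=rpm_mut,
            fold_vs_nrpd1=fold,
            overlaps_p4sirna=has_sirna,
            pass_length=pass_len,
            pass_rpm=pass_rpm,
            pass_fold=pass_fold,
            passed_filters=passed,
        )
        if keep_all or passed:
            out.append(rec)
    return out


def transcript_length_distribution(
    transcripts: Sequence[AssembledTranscript],
    bin_width: int = 100,
    max_length: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of transcript lengths.

    Bins are ``[0, bin_width), [bin_width, 2*bin_width), ...`` up to
    ``max_length`` with a final open-ended bin, so counts always sum to the
    number of transcripts.
    """
    if not transcripts:
        raise ValueError("no transcripts to histogram")
    lengths = np.array([t.length for t in transcripts])
    edges = np.append(np.arange(0, max_length + bin_width, bin_width), np.inf)
    counts, _ = np.histogram(lengths, bins=edges)
    return edges, counts
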