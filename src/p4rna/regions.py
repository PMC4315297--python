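"""Differential locus calling.

P4siRNA loci are genomic windows whose small-RNA signal drops at least
fourfold in ``nrpd1`` relative to wild type with Fisher P < 0.01; P4RNA
regions apply the same rule to dsRNA-seq/RNA-seq of ``dcl234`` versus
``dcl234 nrpd1`` (Pol IV dependence) or ``dcl234 rdr2`` (RDR2 dependence).
Replicate counts are pooled per genotype before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import LibraryReads, merge_intervals
from .model import GenomicInterval

#: RPM-equivalent pseudocount applied to both sides of the fold ratio so a
#: 0/0 window has fold 1 and a finite fold is always defined.
PSEUDOCOUNT_RPM = 0.5


@dataclass
class DifferentialRegion:
    """One tested window/region with pooled counts and the decision."""

    interval: GenomicInterval
    count_control: int
    count_mutant: int
    rpm_control: float
    rpm_mutant: float
    fold_change: float
    p_value: float
    significant: bool


def fold_change(rpm_control: float, rpm_mutant: float) -> float:
    """Control/mutant RPM ratio with a symmetric pseudocount."""
    return (rpm_control + PSEUDOCOUNT_RPM) / (rpm_mutant + PSEUDOCOUNT_RPM)


def _pooled_counts(libs: Sequence[LibraryReads], windows, chrom_groups) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=np.int64)
    for lr in libs:
        for chrom, (sl, starts, ends) in chrom_groups.items():
            counts[sl] += lr.index.count_many(chrom, starts, ends)
    return counts


def _group_windows(windows: Sequence[GenomicInterval]) -> dict:
    """Group window positions by chromosome, keeping original indices."""
    groups: dict[str, tuple] = {}
    order: dict[str, list] = {}
    for i, w in enumerate(windows):
        order.setdefault(w.chrom, []).append(i)
    for chrom, idxs in order.items():
        idx = np.array(idxs, dtype=np.int64)
        starts = np.array([windows[i].start for i in idxs], dtype=np.int64)
        ends = np.array([windows[i].end for i in idxs], dtype=np.int64)
        groups[chrom] = (idx, starts, ends)
    return groups


def call_differential_regions(
    control_libs: Sequence[LibraryReads],
    mutant_libs: Sequence[LibraryReads],
    windows: Sequence[GenomicInterval],
    min_fold: float = 4.0,
    alpha: float = 0.01,
    min_rpm_control: float = 1.0,
    bh_correct: bool = False,
) -> list[DifferentialRegion]:
    """Test each window for reduced signal in the mutant.

    Replicate counts are summed per side and normalized against the summed
    library sizes. Significance requires fold >= ``min_fold`` (control over
    mutant RPM, pseudocounted), a two-sided Fisher exact P < ``alpha`` on
    the (window count, library remainder) x (control, mutant) table, and
    control RPM >= ``min_rpm_control``. ``bh_correct`` applies
    Benjamini-Hochberg to the P-values before thresholding (off by default:
    the selection rule is a raw P-value cut).
    """
    if not control_libs or not mutant_libs:
        raise ValueError("need >= 1 library per side")
    n_control = sum(lr.library.total_mapped_reads for lr in control_libs)
    n_mutant = sum(lr.library.total_mapped_reads for lr in mutant_libs)
    if n_control <= 0 or n_mutant <= 0:
        raise ValueError("zero total library size")
    for w in windows:
        if w.length <= 0:
            raise ValueError(f"degenerate window {w}")

    groups = _group_windows(windows)
    c_counts = _pooled_counts(control_libs, windows, groups)
    m_counts = _pooled_counts(mutant_libs, windows, groups)
    rpm_c = c_counts * 1e6 / n_control
    rpm_m = m_counts * 1e6 / n_mutant
    folds = (rpm_c + PSEUDOCOUNT_RPM) / (rpm_m + PSEUDOCOUNT_RPM)

    pvals = np.ones(len(windows))
    for i in range(len(windows)):
        c, m = int(c_counts[i]), int(m_counts[i])
        if c == 0 and m == 0:
            continue
        table = [[c, n_control - c], [m, n_mutant - m]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    p_for_cut = _bh_adjust(pvals) if bh_correct else pvals
    out = []
    for i, w in enumerate(windows):
        sig = (
            folds[i] >= min_fold
            and p_for_cut[i] < alpha
            and rpm_c[i] >= min_rpm_control
        )
        out.append(
            DifferentialRegion(
                interval=w,
                count_control=int(c_counts[i]),
                count_mutant=int(m_counts[i]),
                rpm_control=float(rpm_c[i]),
                rpm_mutant=float(rpm_m[i]),
                fold_change=float(folds[i]),
                p_value=float(pvals[i]),
                significant=bool(sig),
            )
        )
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def tile_genome(chrom_sizes: dict, window_size: int = 300) -> list[GenomicInterval]:
    """Non-overlapping tiling; the final partial window is kept."""
    windows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for s in range(0, size, window_size):
            windows.append(GenomicInterval(chrom, s, min(s + window_size, size)))
    return windows


def merge_significant(regions: Sequence[DifferentialRegion]) -> list[GenomicInterval]:
    """Merge adjacent significant windows (gap 0) into loci."""
    return merge_intervals(
        [r.interval for r in regions if r.significant], max_gap=0
    )


def define_p4sirna_loci(
    wt_libs: Sequence[LibraryReads],
    nrpd1_libs: Sequence[LibraryReads],
    chrom_sizes: dict,
    window_size: int = 300,
    min_fold: float = 4.0,
    alpha: float = 0.01,
    min_rpm_control: float = 1.0,
) -> list[GenomicInterval]:
    """Genome-wide P4siRNA locus calling: tile, test WT vs ``nrpd1``, merge
    significant windows."""
    windows = tile_genome(chrom_sizes, window_size)
    regions = call_differential_regions(
        wt_libs, nrpd1_libs, windows, min_fold, alpha, min_rpm_control
    )
    return merge_significant(regions)


@dataclass
class LocusSetPartition:
    both: list  # members of A overlapping B
    a_only: list
    b_only: list  # members of B not overlapping A


def intersect_locus_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> LocusSetPartition:
    """Partition two locus sets by mutual overlap (>= ``min_overlap_bp``)."""
    from .intervals import build_interval_index, overlaps_any

    b_idx = build_interval_index(b)
    a_idx = build_interval_index(a)
    both = [iv for iv in a if overlaps_any(iv, b_idx, min_overlap_bp)]
    a_only = [iv for iv in a if not overlaps_any(iv, b_idx, min_overlap_bp)]
    b_only = [iv for iv in b if not overlaps_any(iv, a_idx, min_overlap_bp)]
    return LocusSetPartition(both=both, a_only=a_only, b_only=b_only)


def require_both_dependencies(
    pol_iv_regions: Sequence[GenomicInterval],
    rdr2_regions: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[GenomicInterval]:
    """Regions significant in both the Pol IV and the RDR2 comparison."""
    return intersect_locus_sets(pol_iv_regions, rdr2_regions, min_overlap_bp).both
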