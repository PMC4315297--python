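"""Interval arithmetic and read-counting primitives.

These are the workhorses behind every stage: joining neighbouring reads
into transcripts, counting reads per window for differential calling,
and per-base coverage for the intron filter. Reads are held as sorted
coordinate arrays so that window counting is O(log n) per query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import AlignedRead, GenomicInterval, Library

logger = logging.getLogger(__name__)


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Join intervals whose gap is at most ``max_gap`` bases.

    Neighbouring intervals separated by ``next.start - prev.end <= max_gap``
    are joined (a gap of exactly ``max_gap`` joins; ``max_gap + 1`` does
    not). Strand is ignored; merged intervals are strandless. The result is
    sorted and idempotent under re-merging.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def merge_coordinate_arrays(
    starts: np.ndarray, ends: np.ndarray, max_gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Array analogue of :func:`merge_intervals` for one chromosome.

    ``starts`` must be sorted ascending with ``ends`` aligned to it.
    Returns merged (starts, ends).
    """
    if len(starts) == 0:
        return starts.copy(), ends.copy()
    run_end = np.maximum.accumulate(ends)
    new_group = np.empty(len(starts), dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] - run_end[:-1] > max_gap
    group_first = np.flatnonzero(new_group)
    m_starts = starts[group_first]
    m_ends = np.maximum.reduceat(ends, group_first)
    return m_starts, m_ends


class ReadIndex:
    """Sorted coordinate arrays of aligned reads, per chromosome.

    Counting rule: a read overlaps a region iff it shares >= 1 bp with it,
    and is counted once per region (no fractional assignment).
    """

    def __init__(self) -> None:
        self.chroms: list[str] = []
        self._start_sorted: dict[str, np.ndarray] = {}
        self._end_aligned: dict[str, np.ndarray] = {}  # aligned to start order
        self._strand_aligned: dict[str, np.ndarray] = {}  # int8: 1 = +, 0 = -
        self._end_sorted: dict[str, np.ndarray] = {}
        self._per_strand: dict[tuple, tuple] = {}  # (chrom, strand) -> (S, Esorted)
        self.n_reads: int = 0

    # -- construction -------------------------------------------------
    @classmethod
    def build(cls, reads: Iterable[AlignedRead]) -> "ReadIndex":
        per: dict[str, list[tuple[int, int, int]]] = {}
        for r in reads:
            iv = r.interval
            per.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, 1 if iv.strand == "+" else 0)
            )
        idx = cls()
        for chrom in sorted(per):
            rows = per[chrom]
            s = np.array([a for a, _, _ in rows], dtype=np.int64)
            e = np.array([b for _, b, _ in rows], dtype=np.int64)
            st = np.array([c for _, _, c in rows], dtype=np.int8)
            idx._add_chrom(chrom, s, e, st)
        return idx

    @classmethod
    def from_arrays(
        cls,
        chrom_of: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
        chrom_names: Sequence[str],
    ) -> "ReadIndex":
        """Build from parallel arrays; ``chrom_of`` holds integer codes into
        ``chrom_names`` and ``strands`` holds 1 (Watson) / 0 (Crick)."""
        idx = cls()
        for code, chrom in enumerate(chrom_names):
            mask = chrom_of == code
            if not mask.any():
                continue
            idx._add_chrom(
                chrom,
                np.asarray(starts[mask], dtype=np.int64),
                np.asarray(ends[mask], dtype=np.int64),
                np.asarray(strands[mask], dtype=np.int8),
            )
        return idx

    def _add_chrom(
        self, chrom: str, s: np.ndarray, e: np.ndarray, st: np.ndarray
    ) -> None:
        order = np.argsort(s, kind="stable")
        s, e, st = s[order], e[order], st[order]
        self.chroms.append(chrom)
        self._start_sorted[chrom] = s
        self._end_aligned[chrom] = e
        self._strand_aligned[chrom] = st
        self._end_sorted[chrom] = np.sort(e)
        for strand, code in (("+", 1), ("-", 0)):
            m = st == code
            self._per_strand[(chrom, strand)] = (s[m], np.sort(e[m]))
        self.n_reads += len(s)

    # -- queries -------------------------------------------------------
    @staticmethod
    def _count_arrays(
        S: np.ndarray, Esorted: np.ndarray, start: int, end: int
    ) -> int:
        # reads with start < end minus reads with end <= start
        return int(
            np.searchsorted(S, end, side="left")
            - np.searchsorted(Esorted, start, side="right")
        )

    def count(self, region: GenomicInterval) -> int:
        if region.chrom not in self._start_sorted:
            logger.warning("unknown chromosome %s in count query", region.chrom)
            return 0
        return self._count_arrays(
            self._start_sorted[region.chrom],
            self._end_sorted[region.chrom],
            region.start,
            region.end,
        )

    def count_per_strand(self, region: GenomicInterval) -> tuple[int, int]:
        if (region.chrom, "+") not in self._per_strand:
            logger.warning("unknown chromosome %s in count query", region.chrom)
            return (0, 0)
        sw, ew = self._per_strand[(region.chrom, "+")]
        sc, ec = self._per_strand[(region.chrom, "-")]
        return (
            self._count_arrays(sw, ew, region.start, region.end),
            self._count_arrays(sc, ec, region.start, region.end),
        )

    def count_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized overlap counts for many regions on one chromosome."""
        if chrom not in self._start_sorted:
            return np.zeros(len(starts), dtype=np.int64)
        S = self._start_sorted[chrom]
        E = self._end_sorted[chrom]
        return np.searchsorted(S, ends, side="left") - np.searchsorted(
            E, starts, side="right"
        )

    def intervals_overlapping(
        self, region: GenomicInterval
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, strand codes) of reads overlapping ``region``."""
        if region.chrom not in self._start_sorted:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.int8)
        S = self._start_sorted[region.chrom]
        E = self._end_aligned[region.chrom]
        ST = self._strand_aligned[region.chrom]
        hi = int(np.searchsorted(S, region.end, side="left"))
        mask = E[:hi] > region.start
        return S[:hi][mask], E[:hi][mask], ST[:hi][mask]

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All reads on ``chrom`` sorted by start: (starts, ends, strands)."""
        if chrom not in self._start_sorted:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.int8)
        return (
            self._start_sorted[chrom],
            self._end_aligned[chrom],
            self._strand_aligned[chrom],
        )


def count_reads(
    reads: "ReadIndex | Sequence[AlignedRead]",
    region: GenomicInterval,
    per_strand: bool = False,
):
    """Count reads overlapping ``region`` by at least one base.

    ``reads`` may be a prebuilt :class:`ReadIndex` or a sequence of
    :class:`AlignedRead` (indexed on the fly). With ``per_strand`` a
    ``(watson, crick)`` pair is returned.
    """
    idx = reads if isinstance(reads, ReadIndex) else ReadIndex.build(reads)
    return idx.count_per_strand(region) if per_strand else idx.count(region)


def base_coverage(
    reads: "ReadIndex | Sequence[AlignedRead]", region: GenomicInterval
) -> np.ndarray:
    """Per-base read depth over ``region`` (length ``region.length`` vector).

    ``depth[i]`` is the number of reads covering base ``region.start + i``.
    """
    idx = reads if isinstance(reads, ReadIndex) else ReadIndex.build(reads)
    diff = np.zeros(region.length + 1, dtype=np.int64)
    if region.chrom in idx._start_sorted:
        starts = idx._start_sorted[region.chrom]
        ends = idx._end_sorted[region.chrom]
        # reads entirely outside clip to (0,0) or (L,L): net zero contribution
        s = np.clip(starts - region.start, 0, region.length)
        e = np.clip(ends - region.start, 0, region.length)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1])


def rpm(count: float, library: Library) -> float:
    """Reads per million mapped reads: ``count * 1e6 / total_mapped_reads``."""
    if library.total_mapped_reads <= 0:
        raise ValueError("library total_mapped_reads must be > 0")
    return count * 1e6 / library.total_mapped_reads


@dataclass
class LibraryReads:
    """A library together with its aligned reads.

    Reads may be given as :class:`AlignedRead` objects (small inputs) or as
    a prebuilt :class:`ReadIndex` (simulation-scale inputs).
    """

    library: Library
    reads: list = field(default_factory=list)
    _index: ReadIndex | None = None

    @classmethod
    def from_index(cls, library: Library, index: ReadIndex) -> "LibraryReads":
        return cls(library=library, reads=[], _index=index)

    @property
    def index(self) -> ReadIndex:
        if self._index is None:
            self._index = ReadIndex.build(self.reads)
        return self._index

    def rpm(self, count: float) -> float:
        return rpm(count, self.library)


def build_interval_index(intervals: Iterable[GenomicInterval]) -> dict:
    """Index a set of intervals for overlap membership queries.

    Intervals are merged (gap 0) per chromosome first, so the stored starts
    and ends are jointly sorted and disjoint.
    """
    merged = merge_intervals(intervals, max_gap=0)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    per: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        per.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in per.items():
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def overlaps_any(
    query: GenomicInterval, interval_index: dict, min_overlap_bp: int = 1
) -> bool:
    """True iff ``query`` overlaps an indexed interval by >= ``min_overlap_bp``."""
    entry = interval_index.get(query.chrom)
    if entry is None:
        return False
    starts, ends = entry
    n = len(starts)
    i = int(np.searchsorted(ends, query.start, side="right"))
    while i < n and starts[i] < query.end:
        ov = min(int(ends[i]), query.end) - max(int(starts[i]), query.start)
        if ov >= min_overlap_bp:
            return True
        i += 1
    return False


def mask_overlapping(
    starts: np.ndarray,
    ends: np.ndarray,
    region_starts: np.ndarray,
    region_ends: np.ndarray,
) -> np.ndarray:
    """Boolean mask of intervals overlapping any of a set of disjoint,
    sorted regions (all on one chromosome). Vectorized."""
    if len(region_starts) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(region_starts, starts, side="right") - 1
    left = np.zeros(len(starts), dtype=bool)
    ok = idx >= 0
    left[ok] = region_ends[idx[ok]] > starts[ok]
    nxt = idx + 1
    right = np.zeros(len(starts), dtype=bool)
    ok2 = nxt < len(region_starts)
    right[ok2] = region_starts[nxt[ok2]] < ends[ok2]
    return left | right
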