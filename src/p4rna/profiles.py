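"""Anchored metagene profiles and chromosomal density tracks.

Profiles align many regions at a common anchor (transcription start or
end; position 0 = the anchor base) and average a per-base signal over
them: A/T composition from the genome sequence, or the fraction of regions
covered by a nucleosome call. Windows that run off a chromosome drop out
of the affected positions' denominators rather than being padded.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import GenomicInterval, MetageneProfile, NucleosomeCall

_AT = frozenset(b"AT")


def _anchor_position(iv: GenomicInterval, which_end: str) -> int:
    """Anchor base, strand-aware: for a minus-strand region the biological
    start is the last covered base. The end anchor of an interval is
    ``end - 1`` (last covered base), not the half-open bound."""
    if which_end not in ("start", "end"):
        raise ValueError("which_end must be 'start' or 'end'")
    if iv.strand == "-":
        return iv.end - 1 if which_end == "start" else iv.start
    return iv.start if which_end == "start" else iv.end - 1


def at_composition_profile(
    genome: dict,
    anchors: Sequence[GenomicInterval],
    which_end: str = "start",
    flank: int = 1000,
    min_length: int = 200,
) -> MetageneProfile:
    """Proportion of A/T among A/T/G/C at each offset around the anchors.

    Regions shorter than ``min_length`` are excluded. Offsets are oriented
    along the region (positive = into the body at a start anchor); for
    minus-strand regions the window is reflected. Ambiguity codes (N) count
    in neither numerator nor denominator.
    """
    anchors_used = [iv for iv in anchors if iv.length >= min_length]
    if not anchors_used:
        raise ValueError(f"no anchor regions of length >= {min_length}")
    width = 2 * flank + 1
    at = np.zeros(width, dtype=np.int64)
    total = np.zeros(width, dtype=np.int64)
    for iv in anchors_used:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom} absent from genome")
        seq = genome[iv.chrom]
        pos = _anchor_position(iv, which_end)
        lo = pos - flank
        hi = pos + flank + 1
        s = max(0, lo)
        e = min(len(seq), hi)
        window = np.frombuffer(seq[s:e].encode(), dtype=np.uint8)
        is_at = (window == ord("A")) | (window == ord("T"))
        is_base = is_at | (window == ord("G")) | (window == ord("C"))
        off0 = s - lo
        if iv.strand == "-":
            sl = slice(width - off0 - len(window), width - off0)
            at[sl] += is_at[::-1]
            total[sl] += is_base[::-1]
        else:
            at[off0 : off0 + len(window)] += is_at
            total[off0 : off0 + len(window)] += is_base
    values = np.divide(at, total, out=np.zeros(width), where=total > 0)
    return MetageneProfile(
        anchor=which_end,
        offsets=np.arange(-flank, flank + 1),
        values=values,
        n=total,
        n_sequences=len(anchors_used),
    )


def nucleosome_occupancy_profile(
    nucleosomes: "Sequence[NucleosomeCall] | Sequence[GenomicInterval]",
    anchors: Sequence[GenomicInterval],
    chrom_sizes: dict,
    which_end: str = "start",
    flank: int = 1000,
    min_length: int = 0,
) -> MetageneProfile:
    """Fraction of anchor regions covered by a nucleosome call, per offset.

    Coverage uses the call intervals exactly as given (no smoothing).
    """
    anchors_used = [iv for iv in anchors if iv.length >= min_length]
    if not anchors_used:
        raise ValueError("no anchor regions after length filter")
    covered: dict[str, np.ndarray] = {
        c: np.zeros(size, dtype=bool) for c, size in chrom_sizes.items()
    }
    for call in nucleosomes:
        iv = call.interval if isinstance(call, NucleosomeCall) else call
        if iv.chrom in covered:
            covered[iv.chrom][iv.start : iv.end] = True

    width = 2 * flank + 1
    hit = np.zeros(width, dtype=np.int64)
    n = np.zeros(width, dtype=np.int64)
    for iv in anchors_used:
        mask = covered[iv.chrom]
        pos = _anchor_position(iv, which_end)
        lo, hi = pos - flank, pos + flank + 1
        s, e = max(0, lo), min(len(mask), hi)
        if e <= s:
            continue
        window = mask[s:e]
        off0 = s - lo
        if iv.strand == "-":
            sl = slice(width - off0 - len(window), width - off0)
            hit[sl] += window[::-1]
            n[sl] += 1
        else:
            hit[off0 : off0 + len(window)] += window
            n[off0 : off0 + len(window)] += 1
    values = np.divide(hit, n, out=np.zeros(width), where=n > 0)
    return MetageneProfile(
        anchor=which_end,
        offsets=np.arange(-flank, flank + 1),
        values=values,
        n=n,
        n_sequences=len(anchors_used),
    )


def chromosomal_density(
    features: Sequence[GenomicInterval],
    chrom_sizes: dict,
    bin_size: int = 100_000,
) -> dict:
    """Per-chromosome feature counts in fixed bins; each feature falls in
    the bin of its midpoint, so bin totals conserve the feature count."""
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        n_bins = int(np.ceil(chrom_sizes[chrom] / bin_size)) or 1
        out[chrom] = np.zeros(n_bins, dtype=np.int64)
    for iv in features:
        if iv.chrom not in out:
            continue
        b = min(iv.midpoint // bin_size, len(out[iv.chrom]) - 1)
        out[iv.chrom][b] += 1
    return out
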