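"""Shared helpers for the test suite (oracles and random inputs)."""

import numpy as np

from p4rna.model import AlignedRead, GenomicInterval


def random_interval_set(rng, n, span=3000, max_len=150, chroms=("c1", "c2")):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        out.append(
            GenomicInterval(str(rng.choice(chroms)), s, s + int(rng.integers(1, max_len)))
        )
    return out


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def best_reciprocal(target, candidates) -> float:
    return max(
        (reciprocal_overlap(target, c) for c in candidates if c.chrom == target.chrom),
        default=0.0,
    )
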