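"""CHH methylation context of siRNA loci.

DMR calling between genotypes, classification of P4siRNA loci into D2
(DRM2-dependent) and C2 (CMT2-dependent) by DMR overlap, quartile
summaries linking siRNA abundance / CHH methylation / precursor
discovery, mutant-vs-WT relative siRNA abundance normalized against
non-P4siRNA small RNAs, and histone-mark window overlap.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    LibraryReads,
    build_interval_index,
    merge_intervals,
    overlaps_any,
)
from .model import GenomicInterval


def _chh_window_levels(df: pd.DataFrame, window: int) -> pd.DataFrame:
    chh = df[df["context"] == "CHH"]
    if chh.empty:
        raise ValueError("empty CHH table")
    g = chh.assign(win=chh["pos"] // window).groupby(["chrom", "win"])
    out = g.agg(
        n_sites=("pos", "size"),
        mc=("mc_count", "sum"),
        total=("total_count", "sum"),
    )
    out["level"] = out["mc"] / out["total"]
    return out


def call_chh_dmrs(
    wt: pd.DataFrame,
    mutant: pd.DataFrame,
    window: int = 100,
    min_sites: int = 4,
    min_wt_level: float = 0.1,
    min_drop: float = 0.5,
) -> list[GenomicInterval]:
    """Windows losing CHH methylation in the mutant, merged into DMRs.

    A ``window``-bp window qualifies when it holds >= ``min_sites`` CHH
    positions in WT, its WT weighted methylation level (sum mC / sum
    coverage) is >= ``min_wt_level``, and the mutant level has dropped by
    at least the fraction ``min_drop`` of the WT level. Adjacent qualifying
    windows are merged (gap 0).
    """
    wt_lv = _chh_window_levels(wt, window)
    mut_lv = _chh_window_levels(mutant, window)
    joined = wt_lv.join(mut_lv, how="inner", lsuffix="_wt", rsuffix="_mut")
    ok = (
        (joined["n_sites_wt"] >= min_sites)
        & (joined["level_wt"] >= min_wt_level)
        & (joined["level_mut"] <= (1.0 - min_drop) * joined["level_wt"])
    )
    hits = [
        GenomicInterval(chrom, int(win) * window, (int(win) + 1) * window)
        for (chrom, win) in joined.index[ok]
    ]
    return merge_intervals(hits, max_gap=0)


def classify_d2_c2(
    p4sirna_loci: Sequence[GenomicInterval],
    drm2_dmrs: Sequence[GenomicInterval],
    cmt2_dmrs: Sequence[GenomicInterval],
) -> list[tuple]:
    """Assign each locus to D2 / C2 / other by DMR overlap.

    A locus overlapping only DRM2-dependent DMRs is D2; only
    CMT2-dependent DMRs, C2. A locus overlapping both is assigned to the
    class with greater overlapped length; an exact tie falls back to
    "other" (the two classes are expected to be largely nonoverlapping).
    Returns ``[(locus, klass), ...]`` covering every input locus.
    """
    d2_merged = merge_intervals(drm2_dmrs, 0)
    c2_merged = merge_intervals(cmt2_dmrs, 0)

    def total_overlap(locus: GenomicInterval, dmrs: list) -> int:
        return sum(locus.overlap_bp(d) for d in dmrs if d.chrom == locus.chrom)

    out = []
    for locus in p4sirna_loci:
        od = total_overlap(locus, d2_merged)
        oc = total_overlap(locus, c2_merged)
        if od > 0 and od > oc:
            klass = "D2"
        elif oc > 0 and oc > od:
            klass = "C2"
        else:
            klass = "other"
        out.append((locus, klass))
    return out


def quartile_table(
    loci: pd.DataFrame,
    rank_by: str,
    summarize: "str | Callable",
) -> pd.DataFrame:
    """Quartile summary of a locus table.

    Loci are sorted descending by ``rank_by`` (quartile 1 = highest
    values; ties broken by genomic order for determinism) and split into
    four near-equal groups. ``summarize`` is a column name — a boolean
    column yields the percentage true per quartile, a numeric column the
    mean — or a callable mapping the quartile sub-frame to a number.
    """
    if len(loci) < 4:
        raise ValueError("need >= 4 loci for quartiles")
    if rank_by not in loci.columns:
        raise KeyError(rank_by)
    tie_cols = [c for c in ("chrom", "start") if c in loci.columns]
    df = loci.sort_values(
        [rank_by] + tie_cols,
        ascending=[False] + [True] * len(tie_cols),
        kind="stable",
    ).reset_index(drop=True)
    bounds = np.array_split(np.arange(len(df)), 4)
    parts = [df.iloc[b] for b in bounds]
    rows = []
    for q, part in enumerate(parts, start=1):
        if callable(summarize):
            value = float(summarize(part))
        else:
            col = part[summarize]
            if col.dtype == bool:
                value = 100.0 * col.mean()
            else:
                value = float(col.mean())
        rows.append({"quartile": q, "n": len(part), "value": value})
    return pd.DataFrame(rows)


def relative_sirna_abundance(
    mutant_lib: LibraryReads,
    wt_lib: LibraryReads,
    p4_loci: Sequence[GenomicInterval],
    classes: "Sequence[str] | None" = None,
    class_filter: str = "all",
) -> float:
    """Mutant/WT siRNA abundance at P4 loci, normalized against small RNAs
    from non-P4siRNA loci.

    value = (mutant P4 reads / mutant non-P4 reads)
          / (WT P4 reads / WT non-P4 reads)

    so WT vs WT is exactly 1. ``class_filter`` ("D2", "C2" or "all")
    restricts the numerator loci (``classes`` aligns with ``p4_loci``);
    the non-P4 denominator always excludes the full P4 locus set.
    """
    if class_filter != "all":
        if classes is None:
            raise ValueError("class_filter needs per-locus classes")
        selected = [
            iv for iv, k in zip(p4_loci, classes) if k == class_filter
        ]
    else:
        selected = list(p4_loci)
    all_idx = build_interval_index(p4_loci)
    sel_idx = build_interval_index(selected) if selected else {}

    def split_counts(lib: LibraryReads) -> tuple[int, int]:
        in_sel = 0
        in_any = 0
        total = 0
        for chrom in lib.index.chroms:
            starts, ends, _ = lib.index.chrom_arrays(chrom)
            total += len(starts)
            from .intervals import mask_overlapping

            if chrom in all_idx:
                m_any = mask_overlapping(starts, ends, *all_idx[chrom])
                in_any += int(m_any.sum())
            if chrom in sel_idx:
                m_sel = mask_overlapping(starts, ends, *sel_idx[chrom])
                in_sel += int(m_sel.sum())
        return in_sel, total - in_any

    mut_p4, mut_bg = split_counts(mutant_lib)
    wt_p4, wt_bg = split_counts(wt_lib)
    if mut_bg == 0 or wt_bg == 0 or wt_p4 == 0:
        raise ValueError("zero normalization counts (non-P4 or WT P4 reads)")
    return (mut_p4 / mut_bg) / (wt_p4 / wt_bg)


def tile_regions(
    regions: Sequence[GenomicInterval], window: int = 500
) -> list[GenomicInterval]:
    """Cut regions into fixed windows; the final partial window is kept."""
    out = []
    for iv in regions:
        for s in range(iv.start, iv.end, window):
            out.append(GenomicInterval(iv.chrom, s, min(s + window, iv.end)))
    return out


def _intersect_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two interval sets."""
    a_m = merge_intervals(a, 0)
    b_m = merge_intervals(b, 0)
    out = []
    by_chrom: dict[str, list] = {}
    for iv in b_m:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in a_m:
        for other in by_chrom.get(iv.chrom, []):
            s = max(iv.start, other.start)
            e = min(iv.end, other.end)
            if e > s:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def mark_overlap_windows(
    mark_regions: dict,
    p4sirna_loci: Sequence[GenomicInterval],
    classes: "Sequence[str] | None" = None,
    window: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way overlap between histone-mark domains and siRNA loci.

    ``mark_regions`` maps ``"k9"``/``"k27"`` to domain interval lists.
    Returns ``(window_table, locus_table)``:

    * window_table — mark domains (k9, k27, and their base-level
      intersection "both") tiled into ``window``-bp windows; the
      percentage of windows containing >= 1 siRNA locus.
    * locus_table — percentage of loci (total and per class when
      ``classes`` is given) overlapping k9, k27, or both marks.
    """
    k9 = mark_regions["k9"]
    k27 = mark_regions["k27"]
    locus_idx = build_interval_index(p4sirna_loci) if p4sirna_loci else {}

    window_rows = []
    for name, regions in (
        ("k9", k9),
        ("k27", k27),
        ("both", _intersect_sets(k9, k27)),
    ):
        wins = tile_regions(regions, window)
        hit = sum(1 for w in wins if overlaps_any(w, locus_idx))
        pct = 100.0 * hit / len(wins) if wins else 0.0
        window_rows.append(
            {"mark": name, "n_windows": len(wins), "n_with_loci": hit,
             "pct_with_loci": pct}
        )

    k9_idx = build_interval_index(k9) if k9 else {}
    k27_idx = build_interval_index(k27) if k27 else {}
    has_k9 = np.array([overlaps_any(iv, k9_idx) for iv in p4sirna_loci])
    has_k27 = np.array([overlaps_any(iv, k27_idx) for iv in p4sirna_loci])
    groups = {"total": np.ones(len(p4sirna_loci), dtype=bool)}
    if classes is not None:
        cls = np.array(list(classes))
        for k in ("D2", "C2"):
            groups[k] = cls == k
    locus_rows = []
    for name, mask in groups.items():
        n = int(mask.sum())
        if n == 0:
            locus_rows.append(
                {"group": name, "n_loci": 0, "pct_k9": 0.0, "pct_k27": 0.0,
                 "pct_both": 0.0}
            )
            continue
        locus_rows.append(
            {
                "group": name,
                "n_loci": n,
                "pct_k9": 100.0 * has_k9[mask].mean(),
                "pct_k27": 100.0 * has_k27[mask].mean(),
                "pct_both": 100.0 * (has_k9[mask] & has_k27[mask]).mean(),
            }
        )
    return pd.DataFrame(window_rows), pd.DataFrame(locus_rows)
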