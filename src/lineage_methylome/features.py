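"""TSS-centered windowed profiling of repeats, conservation and lincRNAs.

Windows are laid out in transcription-direction coordinates (window +1 is
immediately downstream of the TSS, -1 immediately upstream), tiled
non-overlapping across a symmetric span; minus-strand genes have their
genomic coordinates mirrored about the TSS. All interval arithmetic is
0-based half-open; a zero-length overlap does not count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_2x2, rank_sum_test

__all__ = [
    "WindowProfile",
    "make_tss_windows",
    "repeat_presence_profile",
    "repeat_density_test",
    "conservation_profile",
    "indel_coverage_profile",
    "feature_wilcoxon",
    "lincrna_neighbor_fraction",
    "regional_feature_scores",
]

DEFAULT_SPAN = 5000
TEST_FLANK = 2000
REPEAT_CLASSES = ("LINE", "SINE", "LTR")


@dataclass
class WindowProfile:
    """Windowed per-gene values and their set-level summary.

    ``per_gene``: genes x window offsets (offset -k..-1, +1..+k in
    transcription direction); ``summary``: offset-indexed set-level value
    (presence frequency, mean score, or percent coverage).
    """

    per_gene: pd.DataFrame
    summary: pd.Series | pd.DataFrame
    width: int
    span: int
    kind: str


def make_tss_windows(tss: pd.DataFrame, width: int, span: int) -> pd.DataFrame:
    """Non-overlapping windows tiling [-span, +span) around each TSS.

    Returns one row per gene and offset with genomic ``start``/``end``;
    offsets are transcription-direction labels, so for minus-strand genes the
    genomic intervals are mirrored about the TSS.
    """
    if span == 0:
        return pd.DataFrame(columns=["gene", "chrom", "offset", "start", "end"])
    if span % width != 0:
        raise ValueError("span must be a multiple of the window width")
    k = span // width
    offsets = np.array([o for o in range(-k, k + 1) if o != 0])
    # plus-strand genomic interval for offset o
    rel_start = np.where(offsets > 0, (offsets - 1) * width, offsets * width)
    rows = []
    for g, row in tss.iterrows():
        t = int(row["tss"])
        if row["strand"] == "-":
            starts = t - rel_start - width
        else:
            starts = t + rel_start
        for o, s in zip(offsets, starts):
            rows.append((g, row["chrom"], int(o), int(s), int(s) + width))
    return pd.DataFrame(rows, columns=["gene", "chrom", "offset", "start", "end"])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly overlapping intervals into a disjoint sorted set."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def _window_track_stats(windows: pd.DataFrame, track: pd.DataFrame,
                        value_col: str | None = None):
    """Per-window (weighted sum, covered length) against a disjoint track.

    The track must be non-overlapping within each chromosome (merge first
    for element tracks). Windows are half-open; partial overlaps are clipped.
    """
    wsum = np.zeros(len(windows))
    cov = np.zeros(len(windows))
    for chrom, tr in track.groupby("chrom", sort=False):
        sel = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        order = np.argsort(tr["start"].to_numpy(), kind="stable")
        s = tr["start"].to_numpy(dtype=np.int64)[order]
        e = tr["end"].to_numpy(dtype=np.int64)[order]
        v = (tr[value_col].to_numpy(dtype=float)[order]
             if value_col else np.ones(len(tr)))
        seg = v * (e - s)
        pref_w = np.concatenate([[0.0], np.cumsum(seg)])
        pref_l = np.concatenate([[0.0], np.cumsum(e - s)])
        a = windows["start"].to_numpy(dtype=np.int64)[sel]
        b = windows["end"].to_numpy(dtype=np.int64)[sel]
        lo = np.searchsorted(e, a, side="right")
        hi = np.searchsorted(s, b, side="left")
        full_w = pref_w[hi] - pref_w[lo]
        full_l = pref_l[hi] - pref_l[lo]
        has = hi > lo
        loc = np.clip(lo, 0, len(s) - 1)
        hic = np.clip(hi - 1, 0, len(s) - 1)
        head = np.where(has, np.maximum(0, a - s[loc]), 0)
        tail = np.where(has, np.maximum(0, e[hic] - b), 0)
        wsum[sel] = full_w - head * v[loc] - tail * v[hic]
        cov[sel] = full_l - head - tail
    return wsum, cov


def repeat_presence_profile(gene_set, windows: pd.DataFrame,
                            repeats: pd.DataFrame,
                            classes=REPEAT_CLASSES) -> WindowProfile:
    """Fraction of genes with >= 1 overlapping repeat, per class and window."""
    gene_set = sorted(set(gene_set))
    win = windows[windows["gene"].isin(gene_set)].reset_index(drop=True)
    per_gene_frames = {}
    summary = {}
    for cl in classes:
        tr = repeats[repeats["class"] == cl]
        merged_parts = []
        for chrom, sub in tr.groupby("chrom", sort=False):
            ms, me = _merge_intervals(sub["start"].to_numpy(dtype=np.int64),
                                      sub["end"].to_numpy(dtype=np.int64))
            merged_parts.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
        merged = (pd.concat(merged_parts, ignore_index=True) if merged_parts
                  else pd.DataFrame(columns=["chrom", "start", "end"]))
        _, cov = _window_track_stats(win, merged)
        present = pd.DataFrame({
            "gene": win["gene"], "offset": win["offset"], "present": cov > 0})
        mat = present.pivot(index="gene", columns="offset", values="present")
        mat = mat.reindex(gene_set)
        per_gene_frames[cl] = mat
        summary[cl] = mat.mean(axis=0)
    per_gene = pd.concat(per_gene_frames, axis=1)  # columns: (class, offset)
    summary_df = pd.DataFrame(summary)             # offsets x classes
    width = int(win["end"].iloc[0] - win["start"].iloc[0]) if len(win) else 0
    return WindowProfile(per_gene=per_gene, summary=summary_df, width=width,
                         span=0, kind="repeat_presence")


def _genes_with_repeat_near_tss(genes, tss, repeats, flank):
    region = pd.DataFrame({
        "gene": list(genes),
        "chrom": tss.loc[list(genes), "chrom"].to_numpy(),
        "offset": 0,
        "start": tss.loc[list(genes), "tss"].to_numpy(dtype=np.int64) - flank,
        "end": tss.loc[list(genes), "tss"].to_numpy(dtype=np.int64) + flank,
    })
    _, cov = _window_track_stats(region, repeats.sort_values(["chrom", "start"]))
    return pd.Series(cov > 0, index=region["gene"].to_numpy())


def repeat_density_test(set_a, set_b, repeats: pd.DataFrame, tss: pd.DataFrame,
                        flank: int = TEST_FLANK,
                        classes=REPEAT_CLASSES) -> pd.DataFrame:
    """Per-class Fisher test of repeat presence near the TSS between gene sets.

    The 2x2 unit is genes: [>=1 repeat of the class within +-flank vs none]
    x [set A vs set B]; two-sided p and odds ratio per class.
    """
    set_a, set_b = sorted(set(set_a)), sorted(set(set_b))
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("gene sets overlap")
    rows = []
    for cl in classes:
        tr = repeats[repeats["class"] == cl]
        merged_parts = []
        for chrom, sub in tr.groupby("chrom", sort=False):
            ms, me = _merge_intervals(sub["start"].to_numpy(dtype=np.int64),
                                      sub["end"].to_numpy(dtype=np.int64))
            merged_parts.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
        merged = (pd.concat(merged_parts, ignore_index=True) if merged_parts
                  else pd.DataFrame(columns=["chrom", "start", "end"]))
        pres_a = _genes_with_repeat_near_tss(set_a, tss, merged, flank)
        pres_b = _genes_with_repeat_near_tss(set_b, tss, merged, flank)
        table = [[int(pres_a.sum()), int((~pres_a).sum())],
                 [int(pres_b.sum()), int((~pres_b).sum())]]
        res = fisher_2x2(table)
        rows.append((cl, pres_a.mean(), pres_b.mean(), res.statistic, res.pvalue))
    return pd.DataFrame(rows, columns=["class", "freq_a", "freq_b",
                                       "odds_ratio", "pvalue"]).set_index("class")


def conservation_profile(gene_set, windows: pd.DataFrame,
                         score_track: pd.DataFrame) -> WindowProfile:
    """Length-weighted mean conservation score per gene and window.

    Windows with no covered base are missing for that gene; the set-level
    profile is the mean over genes with data.
    """
    gene_set = sorted(set(gene_set))
    win = windows[windows["gene"].isin(gene_set)].reset_index(drop=True)
    wsum, cov = _window_track_stats(win, score_track, value_col="score")
    with np.errstate(invalid="ignore"):
        mean = np.where(cov > 0, wsum / np.maximum(cov, 1e-300), np.nan)
    df = pd.DataFrame({"gene": win["gene"], "offset": win["offset"], "value": mean})
    per_gene = df.pivot(index="gene", columns="offset", values="value").reindex(gene_set)
    width = int(win["end"].iloc[0] - win["start"].iloc[0]) if len(win) else 0
    return WindowProfile(per_gene=per_gene, summary=per_gene.mean(axis=0),
                         width=width, span=0, kind="conservation")


def indel_coverage_profile(gene_set, windows: pd.DataFrame,
                           elements: pd.DataFrame) -> WindowProfile:
    """Percent of each window covered by indel-purified elements.

    Overlapping elements are merged before measuring, so bases are not
    double-counted.
    """
    gene_set = sorted(set(gene_set))
    win = windows[windows["gene"].isin(gene_set)].reset_index(drop=True)
    merged_parts = []
    for chrom, sub in elements.groupby("chrom", sort=False):
        ms, me = _merge_intervals(sub["start"].to_numpy(dtype=np.int64),
                                  sub["end"].to_numpy(dtype=np.int64))
        merged_parts.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    merged = (pd.concat(merged_parts, ignore_index=True) if merged_parts
              else pd.DataFrame(columns=["chrom", "start", "end"]))
    _, cov = _window_track_stats(win, merged)
    width = (win["end"] - win["start"]).to_numpy()
    pct = 100.0 * cov / np.maximum(width, 1)
    df = pd.DataFrame({"gene": win["gene"], "offset": win["offset"], "value": pct})
    per_gene = df.pivot(index="gene", columns="offset", values="value").reindex(gene_set)
    w = int(width[0]) if len(win) else 0
    return WindowProfile(per_gene=per_gene, summary=per_gene.mean(axis=0),
                         width=w, span=0, kind="indel_coverage")


def regional_feature_scores(tss: pd.DataFrame, genes, track: pd.DataFrame,
                            flank: int = TEST_FLANK,
                            value_col: str | None = "score",
                            merge: bool = False) -> pd.Series:
    """Per-gene length-weighted mean (or percent coverage) over TSS +- flank."""
    genes = sorted(set(genes))
    region = pd.DataFrame({
        "gene": genes,
        "chrom": tss.loc[genes, "chrom"].to_numpy(),
        "offset": 0,
        "start": tss.loc[genes, "tss"].to_numpy(dtype=np.int64) - flank,
        "end": tss.loc[genes, "tss"].to_numpy(dtype=np.int64) + flank,
    })
    use = track
    if merge:
        parts = []
        for chrom, sub in track.groupby("chrom", sort=False):
            ms, me = _merge_intervals(sub["start"].to_numpy(dtype=np.int64),
                                      sub["end"].to_numpy(dtype=np.int64))
            parts.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
        use = (pd.concat(parts, ignore_index=True) if parts
               else pd.DataFrame(columns=["chrom", "start", "end"]))
        value_col = None
    wsum, cov = _window_track_stats(region, use, value_col=value_col)
    if value_col is None:
        values = 100.0 * cov / (2 * flank)
    else:
        with np.errstate(invalid="ignore"):
            values = np.where(cov > 0, wsum / np.maximum(cov, 1e-300), np.nan)
    return pd.Series(values, index=genes)


def feature_wilcoxon(scores_a, scores_b, alternative: str = "two-sided") -> TestResult:
    """Rank-sum comparison of per-gene regional feature scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return TestResult.not_testable("empty side")
    return rank_sum_test(a, b, alternative=alternative)


def lincrna_neighbor_fraction(tss: pd.DataFrame, lincrnas: pd.DataFrame,
                              set_a, set_b):
    """Fraction of genes that are some lincRNA's nearest genic neighbor.

    Each lincRNA is assigned to the gene whose TSS is closest to the lincRNA
    midpoint; a gene is flagged when >= 1 lincRNA picks it. Returns the two
    per-set fractions and a two-sided Fisher test of flagged status between
    the sets.
    """
    set_a, set_b = sorted(set(set_a)), sorted(set(set_b))
    flagged: set = set()
    for chrom, sub in lincrnas.groupby("chrom", sort=False):
        genes_c = tss[tss["chrom"] == chrom]
        if genes_c.empty:
            continue
        pos = genes_c["tss"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids = genes_c.index.to_numpy()[order]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64)
        right = np.searchsorted(pos_sorted, mid, side="left")
        left = np.clip(right - 1, 0, len(pos_sorted) - 1)
        right_c = np.clip(right, 0, len(pos_sorted) - 1)
        d_left = np.abs(mid - pos_sorted[left])
        d_right = np.abs(mid - pos_sorted[right_c])
        nearest = np.where(d_left <= d_right, left, right_c)
        flagged.update(ids[nearest])
    fa = np.array([g in flagged for g in set_a])
    fb = np.array([g in flagged for g in set_b])
    frac_a = float(fa.mean()) if len(fa) else float("nan")
    frac_b = float(fb.mean()) if len(fb) else float("nan")
    table = [[int(fa.sum()), int((~fa).sum())],
             [int(fb.sum()), int((~fb).sum())]]
    res = fisher_2x2(table)
    return frac_a, frac_b, res
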