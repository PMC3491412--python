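"""Probe-to-gene mapping and qualifying CGI-promoter probe selection.

Array probes are assigned to the gene with the nearest TSS; probes equidistant
to two or more genes are dropped as ambiguous. A probe qualifies for the
hypermethylation analysis when it lies inside a CpG island and within 200 bp
of its gene's TSS. Entries failing the array detection p-value threshold are
masked to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "map_probes_to_genes",
    "flag_qualifying_probes",
    "apply_detection_filter",
]

DEFAULT_MAX_TSS_DIST = 200
DEFAULT_DETECTION_P = 0.01


@dataclass
class GenomeAnnotation:
    """TSS records, CGI intervals and probe positions on shared chromosomes.

    ``tss``: indexed by gene id with columns chrom, strand, tss (0-based).
    ``cgi``: columns chrom, start, end (0-based half-open).
    ``probes``: indexed by probe id with columns chrom, pos.
    """

    tss: pd.DataFrame
    cgi: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self):
        if self.tss.index.has_duplicates:
            raise ValueError("gene ids in the TSS table must be unique")
        if (self.cgi["start"] >= self.cgi["end"]).any():
            raise ValueError("CGI intervals must satisfy start < end")
        if (self.tss["tss"] < 0).any() or (self.probes["pos"] < 0).any():
            raise ValueError("positions must be nonnegative")


def map_probes_to_genes(ann: GenomeAnnotation) -> pd.DataFrame:
    """Assign each probe to the gene with the minimal |probe - TSS| distance.

    Returns a frame indexed by probe id with columns ``gene`` (or None when
    the probe's chromosome carries no TSS), strand-aware signed ``distance``
    (negative = upstream of the TSS in transcription direction) and
    ``dropped_ambiguous`` (equidistant to >= 2 genes).
    """
    out = pd.DataFrame(index=ann.probes.index.copy())
    out["gene"] = None
    out["distance"] = np.nan
    out["dropped_ambiguous"] = False

    for chrom, probes_c in ann.probes.groupby("chrom", sort=False):
        genes_c = ann.tss[ann.tss["chrom"] == chrom]
        if genes_c.empty:
            continue
        tss_pos = genes_c["tss"].to_numpy(dtype=np.int64)
        order = np.argsort(tss_pos, kind="stable")
        tss_sorted = tss_pos[order]
        gene_ids = genes_c.index.to_numpy()[order]
        strands = genes_c["strand"].to_numpy()[order]

        pos = probes_c["pos"].to_numpy(dtype=np.int64)
        right = np.searchsorted(tss_sorted, pos, side="left")
        left = right - 1
        right_c = np.clip(right, 0, len(tss_sorted) - 1)
        left_c = np.clip(left, 0, len(tss_sorted) - 1)
        d_left = np.abs(pos - tss_sorted[left_c])
        d_right = np.abs(pos - tss_sorted[right_c])
        d_left[left < 0] = np.iinfo(np.int64).max
        d_right[right > len(tss_sorted) - 1] = np.iinfo(np.int64).max

        use_left = d_left < d_right
        nearest = np.where(use_left, left_c, right_c)
        # ambiguity: two distinct TSS positions at the same minimal distance,
        # or several genes sharing the chosen TSS coordinate
        tie = (d_left == d_right) & (tss_sorted[left_c] != tss_sorted[right_c])
        chosen_tss = tss_sorted[nearest]
        _, counts = np.unique(tss_sorted, return_counts=True)
        dup_pos = {p for p, c in zip(np.unique(tss_sorted), counts) if c > 1}
        shared = np.array([p in dup_pos for p in chosen_tss]) if dup_pos else np.zeros(len(pos), bool)
        ambiguous = tie | shared

        signed = pos - chosen_tss
        minus = strands[nearest] == "-"
        signed = np.where(minus, -signed, signed)

        idx = probes_c.index
        out.loc[idx, "gene"] = np.where(ambiguous, None, gene_ids[nearest])
        out.loc[idx, "distance"] = np.where(ambiguous, np.nan, signed)
        out.loc[idx, "dropped_ambiguous"] = ambiguous
    return out


def _in_any_interval(chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of points in 0-based half-open intervals, per chromosome.

    A point p is covered iff some interval has start <= p < end; with
    start-sorted intervals and a running maximum of ends this reduces to one
    binary search per point, overlapping intervals included.
    """
    inside = np.zeros(len(pos), dtype=bool)
    for c, iv in intervals.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        s = iv["start"].to_numpy(dtype=np.int64)
        e = iv["end"].to_numpy(dtype=np.int64)
        order = np.argsort(s, kind="stable")
        s = s[order]
        e_cummax = np.maximum.accumulate(e[order])
        p = pos[sel]
        j = np.searchsorted(s, p, side="right") - 1
        ok = (j >= 0) & (p < e_cummax[np.clip(j, 0, len(s) - 1)])
        inside[sel] = ok
    return inside


def flag_qualifying_probes(probe_map: pd.DataFrame, ann: GenomeAnnotation,
                           max_dist: int = DEFAULT_MAX_TSS_DIST) -> pd.DataFrame:
    """Flag probes inside a CGI and within ``max_dist`` bp of their TSS.

    The distance bound is inclusive (|distance| <= max_dist). Returns a copy
    of the map with ``in_cgi`` and ``qualifying`` columns filled.
    """
    out = probe_map.copy()
    chrom = ann.probes.loc[out.index, "chrom"].to_numpy()
    pos = ann.probes.loc[out.index, "pos"].to_numpy(dtype=np.int64)
    out["in_cgi"] = _in_any_interval(chrom, pos, ann.cgi)
    dist_ok = out["distance"].abs() <= max_dist
    out["qualifying"] = (
        out["in_cgi"] & dist_ok.fillna(False) & ~out["dropped_ambiguous"]
        & out["gene"].notna()
    )
    return out


def apply_detection_filter(beta: pd.DataFrame, detection_p: pd.DataFrame,
                           threshold: float = DEFAULT_DETECTION_P) -> pd.DataFrame:
    """Mask beta entries whose detection p-value is >= ``threshold``.

    Strictly smaller p-values pass; everything else becomes NaN (missing).
    """
    if not beta.index.equals(detection_p.index) or not beta.columns.equals(detection_p.columns):
        missing_rows = beta.index.symmetric_difference(detection_p.index).tolist()[:5]
        missing_cols = beta.columns.symmetric_difference(detection_p.columns).tolist()[:5]
        raise ValueError(
            "beta and detection-p matrices are not aligned; offending probes "
            f"{missing_rows}, samples {missing_cols}"
        )
    return beta.where(detection_p.to_numpy() < threshold)
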