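"""Sequencing-based (MBD-seq / WGBS-style) CGI methylation calling.

Three published calling rules over CGI read counts:

* paired elevation — among CGIs unmethylated in all normals, frequent when
  the tumor RPKM strictly exceeds the matched normal in >= 2 pairs,
  resistant when in no pair;
* one-sided rank test — frequent when a one-sided Wilcoxon rank-sum test
  finds significantly more reads in tumors than normals (no resistant set
  is defined under this rule);
* region overlap — genes called by the class of pre-defined prone/resistant
  regions containing their CGI TSS.

Counts are normalized to RPKM (reads / kb of CGI / million mapped reads),
with replicate lanes of a sample averaged first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "CgiCountMatrix",
    "cgi_rpkm",
    "normal_unmethylated_cgis",
    "call_paired_elevation",
    "call_wilcoxon_cgis",
    "assign_regions_to_genes",
]


@dataclass
class CgiCountMatrix:
    """CGI x sample read counts with normalization metadata.

    ``counts``: integer reads per CGI per sequencing lane; ``lengths``: CGI
    lengths in bp; ``samples``: indexed by lane id with columns ``role``
    (tumor/normal), ``pair_id``, ``source_sample`` (replicate grouping: lanes
    sharing a source are averaged) and ``total_reads``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        if (self.lengths <= 0).any():
            raise ValueError("CGI lengths must be positive")
        if (self.samples["total_reads"] <= 0).any():
            raise ValueError("total mapped reads must be positive")

    @classmethod
    def from_frames(cls, counts_with_length: pd.DataFrame, samples: pd.DataFrame):
        lengths = counts_with_length["length"].astype(float)
        counts = counts_with_length.drop(columns=["length"])
        return cls(counts=counts, lengths=lengths, samples=samples)


def cgi_rpkm(data: CgiCountMatrix) -> pd.DataFrame:
    """Length- and depth-normalized CGI methylation signal per sample.

    RPKM = count / (CGI length in kb x total mapped reads in millions);
    replicate lanes of one source sample are averaged into a single column.
    """
    data.validate()
    totals = data.samples.loc[data.counts.columns, "total_reads"].astype(float)
    per_lane = data.counts.div(data.lengths / 1000.0, axis=0).div(totals / 1e6, axis=1)
    source = data.samples.loc[data.counts.columns, "source_sample"]
    rpkm = per_lane.T.groupby(source).mean().T
    return rpkm


def _sample_meta(samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse lane metadata to one row per source sample."""
    return samples.groupby("source_sample").first()


def normal_unmethylated_cgis(rpkm: pd.DataFrame, normal_ids, q: float = 0.25) -> pd.Index:
    """CGIs unmethylated in every normal sample.

    The published analyses give no numeric rule; here a CGI qualifies when
    its maximum RPKM across normals does not exceed the ``q`` quantile of
    that max-statistic over all CGIs (so roughly a fraction ``q`` of CGIs,
    the consistently lowest ones, qualify).
    """
    stat = rpkm[list(normal_ids)].max(axis=1)
    thr = stat.quantile(q)
    return rpkm.index[stat <= thr]


def call_paired_elevation(rpkm: pd.DataFrame, samples: pd.DataFrame,
                          unmeth_cgis, tss: pd.DataFrame | None = None,
                          cgi: pd.DataFrame | None = None,
                          min_pairs_elevated: int = 2) -> pd.DataFrame:
    """Paired tumor-vs-matched-normal elevation caller.

    Restricted to CGIs unmethylated in all normals. A CGI is frequently
    hypermethylated when its tumor RPKM is strictly greater than the matched
    normal's in >= ``min_pairs_elevated`` pairs, resistant when in no pair;
    ties do not count as elevation. When ``tss``/``cgi`` are supplied, calls
    are lifted to genes whose TSS lies in the CGI, and genes reached by both
    a frequent and a resistant CGI are ``excluded_ambiguous``.
    """
    meta = _sample_meta(samples)
    pairs = []
    for pid, sub in meta.groupby("pair_id"):
        t = sub.index[sub["role"] == "tumor"]
        n = sub.index[sub["role"] == "normal"]
        if len(t) == 1 and len(n) == 1:
            pairs.append((t[0], n[0]))
    if len(pairs) < 2:
        raise ValueError("paired-elevation rule needs at least two tumor/normal pairs")
    sub = rpkm.loc[list(unmeth_cgis)]
    elevated = sum((sub[t] > sub[n]).astype(int) for t, n in pairs)
    status = pd.Series("neither", index=sub.index, name="status")
    status[elevated >= min_pairs_elevated] = "frequent"
    status[elevated == 0] = "resistant"
    out = pd.DataFrame({"status": status, "n_pairs_elevated": elevated})
    out["method"] = "paired"
    if tss is not None and cgi is not None:
        return _lift_to_genes(out, tss, cgi)
    return out


def call_wilcoxon_cgis(rpkm: pd.DataFrame, tumor_ids, normal_ids,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum caller: CGIs with significantly more reads in tumors.

    One-sided (tumor > normal) Wilcoxon rank-sum per CGI; frequent when
    p < ``alpha``. No resistant set is produced under this rule.
    """
    tumor_ids, normal_ids = list(tumor_ids), list(normal_ids)
    if not tumor_ids or not normal_ids:
        raise ValueError("need at least one sample per group")
    pvals = np.empty(len(rpkm))
    T = rpkm[tumor_ids].to_numpy()
    N = rpkm[normal_ids].to_numpy()
    for i in range(len(rpkm)):
        pvals[i] = rank_sum_test(T[i], N[i], alternative="greater").pvalue
    out = pd.DataFrame({"pvalue": pvals}, index=rpkm.index)
    out["status"] = np.where(out["pvalue"] < alpha, "frequent", "neither")
    out["method"] = "wilcoxon"
    return out


def _tss_in_intervals(tss: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """For each gene, whether its TSS lies in any interval (half-open)."""
    from .annotation import _in_any_interval

    return pd.Series(
        _in_any_interval(tss["chrom"].to_numpy(), tss["tss"].to_numpy(dtype=np.int64),
                         intervals),
        index=tss.index,
    )


def _lift_to_genes(cgi_calls: pd.DataFrame, tss: pd.DataFrame,
                   cgi: pd.DataFrame) -> pd.DataFrame:
    """Assign CGI-level calls to genes whose TSS falls inside the CGI."""
    cgi_idx = cgi.set_index("name") if "name" in cgi.columns else cgi
    rows = []
    for status_wanted in ("frequent", "resistant"):
        named = cgi_calls.index[cgi_calls["status"] == status_wanted]
        iv = cgi_idx.loc[cgi_idx.index.intersection(named)]
        if iv.empty:
            continue
        hit = _tss_in_intervals(tss, iv[["chrom", "start", "end"]])
        for g in tss.index[hit]:
            rows.append((g, status_wanted))
    calls = pd.DataFrame(rows, columns=["gene", "status"])
    both = set(calls.loc[calls["status"] == "frequent", "gene"]) & \
        set(calls.loc[calls["status"] == "resistant", "gene"])
    out = calls.drop_duplicates().set_index("gene")["status"]
    out.loc[list(both)] = "excluded_ambiguous"
    out = out[~out.index.duplicated()]
    result = pd.DataFrame({"status": out})
    result["method"] = "paired"
    return result


def assign_regions_to_genes(prone_regions: pd.DataFrame,
                            resistant_regions: pd.DataFrame,
                            tss: pd.DataFrame) -> pd.DataFrame:
    """Region-overlap caller (whole-genome bisulfite style).

    A gene is frequent/resistant when its TSS lies inside a region of that
    class; genes inside both region classes are ``excluded_ambiguous``.
    """
    in_prone = _tss_in_intervals(tss, prone_regions)
    in_res = _tss_in_intervals(tss, resistant_regions)
    status = np.select(
        [in_prone & in_res, in_prone, in_res],
        ["excluded_ambiguous", "frequent", "resistant"],
        default="neither",
    )
    return pd.DataFrame({"status": status, "method": "region_overlap"}, index=tss.index)
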