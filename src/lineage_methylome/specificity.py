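"""Tissue-specificity scoring and expression-vs-susceptibility tests.

The specificity score of a gene over N tissues is the information content of
its normalized expression profile: with p_t = x_t / sum_u x_u and Shannon
entropy H = -sum_t p_t log2 p_t, the score is S = log2(N) - H, in bits. A
uniformly expressed gene scores 0; a gene expressed in a single tissue
scores log2 N. Differential expression between two tissues uses Welch's t
with Benjamini-Hochberg FDR control; set comparisons use Wilcoxon rank-sum
tests and a Spearman correlation links specificity to the number of tumor
types in which a gene is frequently hypermethylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import TestResult, bh_adjust, rank_sum_test

__all__ = [
    "drop_unexpressed",
    "specificity_scores",
    "assign_quintiles",
    "compare_score_sets",
    "welch_bh_de",
    "define_active_repressed",
    "susceptibility_expression_test",
    "specificity_vs_ntypes_correlation",
    "TissueSpecificityScorer",
]


def drop_unexpressed(expr: pd.DataFrame, presence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Remove genes with no evidence of expression in any tissue.

    With ``presence`` calls (array mode) a gene is dropped when called absent
    in every sample; without (sequencing mode) when its expression is zero in
    all tissues.
    """
    if presence is not None:
        keep = presence.eq("P").any(axis=1)
        return expr.loc[keep[keep].index.intersection(expr.index)]
    return expr.loc[(expr != 0).any(axis=1)]


def specificity_scores(expr: pd.DataFrame) -> pd.Series:
    """Information-theoretic tissue-specificity score S, in bits.

    Requires nonnegative expression with no all-zero rows (apply
    :func:`drop_unexpressed` first); 0 * log2(0) is taken as 0.
    """
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero genes present; apply drop_unexpressed first")
    p = x / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    s = np.log2(expr.shape[1]) - entropy
    return pd.Series(s, index=expr.index, name="specificity")


def assign_quintiles(scores: pd.Series, n_groups: int = 5) -> pd.Series:
    """Split genes into equally sized groups of increasing specificity.

    Rank-based with stable tie-breaking by gene id; group sizes differ by at
    most one, with the remainder going to the lowest-specificity groups.
    Groups are labeled 1 (least specific) .. ``n_groups`` (most specific).
    """
    if len(scores) < n_groups:
        raise ValueError(f"need at least {n_groups} genes")
    # stable two-key sort: primary ascending score, ties by gene id
    ordered = scores.sort_index(kind="stable").sort_values(kind="stable").index
    n = len(scores)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    labels = np.repeat(np.arange(1, n_groups + 1), sizes)
    return pd.Series(labels, index=ordered, name="quintile").reindex(scores.index)


def compare_score_sets(scores: pd.Series, set_a, set_b,
                       alternative: str = "two-sided") -> TestResult:
    """Rank-sum comparison of specificity scores between two disjoint gene sets.

    ``alternative`` follows scipy: 'greater' tests set A > set B.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    if set_a & set_b:
        raise ValueError("gene sets overlap")
    a = scores.loc[scores.index.intersection(sorted(set_a))]
    b = scores.loc[scores.index.intersection(sorted(set_b))]
    return rank_sum_test(a.to_numpy(), b.to_numpy(), alternative=alternative)


@dataclass
class DEResult:
    """Per-gene Welch-t differential expression between two tissue groups."""

    table: pd.DataFrame  # mean_diff, t, pvalue, qvalue, direction, significant
    fdr: float

    @property
    def active_in_a(self) -> set:
        t = self.table
        return set(t.index[t["significant"] & (t["direction"] == "active_in_A")])

    @property
    def repressed_in_a(self) -> set:
        t = self.table
        return set(t.index[t["significant"] & (t["direction"] == "repressed_in_A")])


def welch_bh_de(expr_a: pd.DataFrame, expr_b: pd.DataFrame, fdr: float = 0.05) -> DEResult:
    """Welch's unequal-variance t-test per gene with BH FDR control.

    ``expr_a``/``expr_b`` are gene x replicate matrices over a shared gene
    index; genes with zero variance in both groups and equal means get p = 1.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("gene indexes of the two groups differ")
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    A, B = expr_a.to_numpy(dtype=float), expr_b.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    mean_diff = A.mean(axis=1) - B.mean(axis=1)
    degenerate = np.isnan(p)
    p = np.where(degenerate, np.where(mean_diff == 0, 1.0, 0.0), p)
    t = np.where(np.isnan(t), 0.0, t)
    q = bh_adjust(p)
    table = pd.DataFrame({
        "mean_diff": mean_diff,
        "t": t,
        "pvalue": p,
        "qvalue": q,
        "direction": np.where(mean_diff >= 0, "active_in_A", "repressed_in_A"),
        "significant": q < fdr,
    }, index=expr_a.index)
    return DEResult(table=table, fdr=fdr)


def define_active_repressed(de: DEResult, qualifying_unmeth_genes) -> tuple[set, set]:
    """Tissue-A-active and -repressed CGI gene sets.

    Significant DE genes intersected with the genes that have qualifying CGI
    promoter probes unmethylated in the tissue-A normals.
    """
    qual = set(qualifying_unmeth_genes)
    return de.active_in_a & qual, de.repressed_in_a & qual


def susceptibility_expression_test(vm_susceptibility: pd.DataFrame,
                                   vm_status: pd.DataFrame,
                                   expr: pd.DataFrame,
                                   type_to_tissue: dict[str, str]) -> pd.DataFrame:
    """Per-type test that VM genes prone in the type are repressed in its tissue.

    For each cancer type, a one-sided rank-sum test that matched-tissue
    expression of VM genes frequently hypermethylated in that type is lower
    than that of VM genes never methylated in that type. Types with an empty
    side are flagged not testable.
    """
    rows = []
    for t, tissue in type_to_tissue.items():
        frequent = vm_susceptibility.index[vm_susceptibility[t]]
        never = vm_status.index[vm_status[t] == "never"]
        never = never.intersection(vm_susceptibility.index)
        frequent = frequent.intersection(expr.index)
        never = never.intersection(expr.index)
        if len(frequent) == 0 or len(never) == 0:
            res = TestResult.not_testable("empty gene group")
        else:
            res = rank_sum_test(expr.loc[frequent, tissue].to_numpy(),
                                expr.loc[never, tissue].to_numpy(),
                                alternative="less")
        rows.append((t, tissue, len(frequent), len(never),
                     res.pvalue, res.testable))
    return pd.DataFrame(rows, columns=["cancer_type", "tissue", "n_frequent",
                                       "n_never", "pvalue", "testable"])


def specificity_vs_ntypes_correlation(scores: pd.Series,
                                      n_types_frequent: pd.Series) -> TestResult:
    """Spearman correlation of specificity with the count of susceptible types."""
    common = scores.index.intersection(n_types_frequent.index)
    s = scores.loc[common].to_numpy()
    k = n_types_frequent.loc[common].to_numpy(dtype=float)
    if len(common) < 3 or np.all(k == k[0]) or np.all(s == s[0]):
        return TestResult.not_testable("constant input vector")
    rho, p = sps.spearmanr(s, k)
    return TestResult(statistic=float(rho), pvalue=float(p))


class TissueSpecificityScorer(BaseEstimator, TransformerMixin):
    """Transformer computing specificity scores and quantile groups.

    ``fit`` records the tissue panel; ``transform`` maps a gene x tissue
    expression matrix to a frame with the score (bits) and its group
    (1 = least specific .. n_groups = most specific). Unexpressed genes must
    be removed beforehand.
    """

    def __init__(self, n_groups: int = 5):
        self.n_groups = n_groups

    def fit(self, expr: pd.DataFrame, y=None):
        self.tissues_ = list(expr.columns)
        self.n_tissues_ = expr.shape[1]
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        scores = specificity_scores(expr)
        groups = assign_quintiles(scores, n_groups=self.n_groups)
        return pd.DataFrame({"specificity": scores, "group": groups})
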