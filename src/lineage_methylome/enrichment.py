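"""GO-term Fisher enrichment and PCA of tumor methylomes.

Enrichment compares term membership of a gene set against an array
background with Fisher's exact test, dropping terms carried by fewer than 10
background genes. The methylome PCA treats samples as observations and
gene-level methylation values (per-gene maximum qualifying-probe beta) as
variables, centered but not scaled; the first component is then correlated
with each sample's median methylation over the designated gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .stats import TestResult, fisher_2x2

__all__ = [
    "go_fisher",
    "gene_level_beta",
    "MethylomePCA",
    "pca_methylation",
    "pc1_median_correlation",
]


def go_fisher(gene_set, background, term_map: dict[str, list[str]],
              min_term_size: int = 10) -> pd.DataFrame:
    """Fisher enrichment of terms in ``gene_set`` against ``background``.

    Terms with fewer than ``min_term_size`` background genes are excluded.
    ``pct_change`` is the signed percent change of the in-set term percentage
    relative to the background percentage (ratio form); the percentage-point
    difference is also reported as ``pct_point_diff``.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    gene_set = set(gene_set) & background
    rows = []
    n_bg = len(background)
    n_set = len(gene_set)
    for term in sorted(term_map):
        members = set(term_map[term]) & background
        k_bg = len(members)
        if k_bg < min_term_size:
            continue
        k_set = len(members & gene_set)
        table = [[k_set, n_set - k_set],
                 [k_bg - k_set, n_bg - n_set - (k_bg - k_set)]]
        res = fisher_2x2(table)
        pct_set = 100.0 * k_set / n_set if n_set else 0.0
        pct_bg = 100.0 * k_bg / n_bg
        change = 100.0 * (pct_set - pct_bg) / pct_bg
        rows.append((term, k_set, pct_set, k_bg, pct_bg, change,
                     pct_set - pct_bg, res.pvalue))
    return pd.DataFrame(rows, columns=[
        "term", "set_count", "set_pct", "background_count", "background_pct",
        "pct_change", "pct_point_diff", "pvalue"]).set_index("term")


def gene_level_beta(beta: pd.DataFrame, probe_map: pd.DataFrame,
                    genes=None) -> pd.DataFrame:
    """Per-gene methylation per sample: max over qualifying probes.

    Matches the classifier's gene-level aggregation; rows are genes, columns
    samples. ``genes`` optionally restricts/orders the output.
    """
    qual = probe_map[probe_map["qualifying"].astype(bool)]
    qual = qual[qual.index.isin(beta.index)]
    grouped = beta.loc[qual.index].groupby(qual["gene"]).max()
    grouped.index.name = "gene"
    if genes is not None:
        grouped = grouped.reindex(sorted(set(genes) & set(grouped.index)))
    return grouped


class MethylomePCA(BaseEstimator):
    """PCA of sample methylomes over a designated gene set.

    ``fit`` takes a gene x sample methylation matrix; samples are the
    observations, genes the variables (centered, not scaled; SVD). Fitted
    attributes: ``coordinates_`` (samples x components),
    ``variance_fraction_`` (per component), ``median_methylation_``
    (per-sample median over the designated genes, computed before
    imputation). Missing entries are imputed with the per-gene median.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, gene_beta: pd.DataFrame, y=None):
        if gene_beta.shape[0] < 1:
            raise ValueError("need at least one gene")
        if gene_beta.shape[1] < 2:
            raise ValueError("need at least two samples")
        X = gene_beta.T  # samples x genes
        self.median_methylation_ = X.median(axis=1, skipna=True)
        med = gene_beta.median(axis=1, skipna=True)
        X = X.fillna(med)
        k = min(self.n_components, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(X.to_numpy())
        self.pca_ = pca
        self.coordinates_ = pd.DataFrame(
            coords, index=X.index,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
        self.variance_fraction_ = pd.Series(
            pca.explained_variance_ratio_,
            index=self.coordinates_.columns)
        return self

    def pc1_median_correlation(self) -> TestResult:
        return pc1_median_correlation(self)


def pca_methylation(gene_beta: pd.DataFrame, n_components: int = 4) -> MethylomePCA:
    """Fit a :class:`MethylomePCA` on a gene x sample methylation matrix."""
    return MethylomePCA(n_components=n_components).fit(gene_beta)


def pc1_median_correlation(pca: MethylomePCA) -> TestResult:
    """Pearson correlation of PC1 with per-sample median methylation.

    The component sign is arbitrary, so the magnitude |r| is the meaningful
    quantity; the signed r is returned as the statistic.
    """
    pc1 = pca.coordinates_["PC1"].to_numpy()
    med = pca.median_methylation_.to_numpy()
    if np.all(med == med[0]) or np.all(pc1 == pc1[0]):
        return TestResult.not_testable("constant vector")
    r, p = sps.pearsonr(pc1, med)
    return TestResult(statistic=float(r), pvalue=float(p))
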