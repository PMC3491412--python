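"""Independent brute-force oracles and small builders used across tests.

These implementations are deliberately naive (full enumeration, literal
step-up definition) and independent of the package code paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def hypergeom_prob(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins (r1, r2 row sums; c1 col sum)."""
    n = r1 + r2
    return comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by summing all tables as or less probable."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_prob(a, r1, r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom_prob(k, r1, r2, c1)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def wilcoxon_one_sided_oracle(x, y) -> float:
    """Exact one-sided (x > y) rank-sum p = P(U >= u_obs) by full enumeration.

    Assumes no ties; enumerates every assignment of pooled ranks to group x.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    m = len(x)
    u_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2
    n_total = 0
    n_ge = 0
    for idx in combinations(range(len(pooled)), m):
        u = sum(i + 1 for i in idx) - m * (m + 1) / 2
        n_total += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    return n_ge / n_total


def bh_oracle(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def binom_interval(n: int, p: float, alpha: float):
    """Exact central binomial interval [lo, hi] covering >= 1 - alpha."""
    from scipy.stats import binom

    lo = int(binom.ppf(alpha / 2, n, p))
    hi = int(binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


def make_beta(probe_rows: dict, samples: list[tuple[str, str, str]]):
    """Tiny beta matrix + sample sheet + probe map builder.

    ``probe_rows``: probe id -> (gene, [values per sample]);
    ``samples``: list of (sample_id, role, cancer_type).
    """
    sample_ids = [s[0] for s in samples]
    beta = pd.DataFrame(
        {pid: vals for pid, (_, vals) in probe_rows.items()},
        index=sample_ids).T
    sheet = pd.DataFrame(samples, columns=["sample_id", "role", "cancer_type"]
                         ).set_index("sample_id")
    pmap = pd.DataFrame({
        "gene": [g for (g, _) in probe_rows.values()],
        "qualifying": True,
        "dropped_ambiguous": False,
    }, index=pd.Index(list(probe_rows), name="probe"))
    return beta, sheet, pmap
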