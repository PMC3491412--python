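"""Hypermethylation-prone / -resistant gene calling from beta matrices.

Per cancer type, a qualifying probe is evaluable when it is unmethylated
(beta < 0.3) in every available normal of that tissue; a tumor is methylated
at a probe when beta > 0.3. A gene is frequently hypermethylated in a type
when at least 20% of evaluable tumors are methylated, never methylated when
no tumor is. Across types: prone = frequently hypermethylated in >= 1 type,
resistant = never methylated in any tumor of any type (requiring
evaluability in every type); genes landing on both lists via different
probes are excluded as ambiguous. Prone genes split into consistently
methylated (CM: >= 5% of tumors of every type) and variably methylated
(VM: never methylated in >= 1 type).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import TestResult, fisher_2x2

__all__ = [
    "ClassifierParams",
    "TypeCallTable",
    "GeneSets",
    "HypermethylationCaller",
    "classify_gene_by_type",
    "derive_pan_sets",
    "derive_cm_vm",
    "sweep_frequency_threshold",
    "consensus_lists",
]

STATUS_FREQUENT = "frequent"
STATUS_NEVER = "never"
STATUS_INTERMEDIATE = "intermediate"
STATUS_NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the calling rules.

    ``unmeth_thr``/``meth_thr``: probes are unmethylated strictly below /
    methylated strictly above beta 0.3 (a beta of exactly 0.3 is neither);
    ``freq_thr``: 'frequent' needs a methylated fraction >= 20%;
    ``cm_thr``: CM needs >= 5% in every type; ``mean_beta_thr``: the
    mean-beta rule variant calls a gene methylated in a tumor when the mean
    qualifying-probe beta exceeds 0.5.
    """

    unmeth_thr: float = 0.3
    meth_thr: float = 0.3
    freq_thr: float = 0.20
    cm_thr: float = 0.05
    mean_beta_thr: float = 0.5
    mode: str = "probe_binary"
    min_normals: int = 1

    def validate(self) -> None:
        for name in ("unmeth_thr", "meth_thr", "mean_beta_thr"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0.0 < self.freq_thr <= 1.0):
            raise ValueError("freq_thr must lie in (0, 1]")
        if not (0.0 < self.cm_thr <= 1.0):
            raise ValueError("cm_thr must lie in (0, 1]")
        if self.mode not in ("probe_binary", "mean_beta"):
            raise ValueError("mode must be 'probe_binary' or 'mean_beta'")
        if self.min_normals < 1:
            raise ValueError("min_normals must be >= 1")


@dataclass
class TypeCallTable:
    """Per-(gene, type) methylation calls.

    ``gene`` has one row per gene and type with ``n_evaluable_tumors``,
    ``methylated_fraction`` (max over evaluable probes) and ``status``.
    ``probe`` (probe_binary mode) keeps the per-probe fractions used for the
    any-probe prone/resistant list construction.
    """

    gene: pd.DataFrame
    probe: pd.DataFrame | None
    types: list[str]

    def status_matrix(self) -> pd.DataFrame:
        return self.gene.pivot(index="gene", columns="cancer_type", values="status")

    def fraction_matrix(self) -> pd.DataFrame:
        return self.gene.pivot(index="gene", columns="cancer_type",
                               values="methylated_fraction")


@dataclass
class GeneSets:
    prone: set = field(default_factory=set)
    resistant: set = field(default_factory=set)
    ambiguous: set = field(default_factory=set)
    cm: set = field(default_factory=set)
    vm: set = field(default_factory=set)
    vm_susceptibility: pd.DataFrame | None = None  # vm genes x types, bool

    def check_invariants(self) -> None:
        assert not (self.prone & self.resistant), "prone and resistant overlap"
        assert not (self.cm & self.vm), "cm and vm overlap"
        assert (self.cm | self.vm) <= self.prone, "cm/vm outside prone"

    def to_dict(self) -> dict:
        d = {k: sorted(getattr(self, k)) for k in
             ("prone", "resistant", "ambiguous", "cm", "vm")}
        if self.vm_susceptibility is not None:
            d["vm_susceptibility"] = {
                g: sorted(r.index[r]) for g, r in self.vm_susceptibility.iterrows()
            }
        return d


def _split_samples(samples: pd.DataFrame, cancer_type: str):
    if cancer_type not in set(samples["cancer_type"]):
        raise ValueError(f"cancer type '{cancer_type}' absent from sample sheet")
    sel = samples["cancer_type"] == cancer_type
    normals = samples.index[sel & (samples["role"] == "normal")]
    tumors = samples.index[sel & (samples["role"] == "tumor")]
    return tumors, normals


def _probe_calls_one_type(beta, qual_map, params, tumors, normals):
    """Per-probe evaluability and methylated tumor fraction for one type."""
    B = beta.loc[qual_map.index]
    Bn = B[normals]
    Bt = B[tumors]
    n_norm = Bn.notna().sum(axis=1)
    unmeth_in_normals = (Bn.lt(params.unmeth_thr) | Bn.isna()).all(axis=1)
    n_tum = Bt.notna().sum(axis=1)
    evaluable = unmeth_in_normals & (n_norm >= params.min_normals) & (n_tum >= 1)
    n_meth = Bt.gt(params.meth_thr).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n_meth / n_tum.replace(0, np.nan)
    return pd.DataFrame({
        "gene": qual_map["gene"],
        "evaluable": evaluable,
        "methylated_fraction": frac.where(evaluable),
        "n_evaluable_tumors": n_tum.where(evaluable),
    })


def _gene_rows_from_probes(probe_calls: pd.DataFrame, params, cancer_type: str):
    all_genes = sorted(probe_calls["gene"].unique())
    ev = probe_calls[probe_calls["evaluable"]].reset_index(drop=True)
    rows = []
    if not ev.empty:
        best = ev.loc[ev.groupby("gene")["methylated_fraction"].idxmax()]
        for g, frac, n_t in zip(best["gene"], best["methylated_fraction"],
                                best["n_evaluable_tumors"]):
            rows.append((g, cancer_type, int(n_t), float(frac),
                         _status(float(frac), params)))
    covered = {r[0] for r in rows}
    for g in all_genes:
        if g not in covered:
            rows.append((g, cancer_type, 0, np.nan, STATUS_NOT_EVALUABLE))
    rows.sort(key=lambda r: r[0])
    return rows


def _status(frac: float, params: ClassifierParams) -> str:
    if frac >= params.freq_thr:
        return STATUS_FREQUENT
    if frac == 0.0:
        return STATUS_NEVER
    return STATUS_INTERMEDIATE


def _mean_beta_gene_calls(beta, qual_map, params, tumors, normals, cancer_type):
    rows = []
    for g, sub in qual_map.groupby("gene", sort=True):
        Bn = beta.loc[sub.index, normals]
        Bt = beta.loc[sub.index, tumors]
        n_norm = int(Bn.notna().any(axis=0).sum())
        # any qualifying probe methylated in any normal disqualifies the gene
        if bool(Bn.gt(params.unmeth_thr).any().any()) or n_norm < params.min_normals:
            rows.append((g, cancer_type, 0, np.nan, STATUS_NOT_EVALUABLE))
            continue
        means = Bt.mean(axis=0, skipna=True)
        n_tum = int(means.notna().sum())
        if n_tum == 0:
            rows.append((g, cancer_type, 0, np.nan, STATUS_NOT_EVALUABLE))
            continue
        frac = float((means > params.mean_beta_thr).sum() / n_tum)
        rows.append((g, cancer_type, n_tum, frac, _status(frac, params)))
    return rows


def classify_gene_by_type(beta: pd.DataFrame, probe_map: pd.DataFrame,
                          samples: pd.DataFrame, params: ClassifierParams,
                          cancer_type: str) -> TypeCallTable:
    """Call per-gene methylation status against one cancer type's normals.

    ``beta`` must already be detection-filtered; ``probe_map`` must carry the
    ``qualifying`` flag. Genes without a qualifying probe, or whose probes
    fail the unmethylated-in-all-normals requirement, are ``not_evaluable``.
    """
    params.validate()
    tumors, normals = _split_samples(samples, cancer_type)
    qual = probe_map[probe_map["qualifying"].astype(bool)]
    qual = qual[qual.index.isin(beta.index)]
    if params.mode == "mean_beta":
        rows = _mean_beta_gene_calls(beta, qual, params, tumors, normals, cancer_type)
        probe_calls = None
    else:
        probe_calls = _probe_calls_one_type(beta, qual, params, tumors, normals)
        probe_calls.insert(1, "cancer_type", cancer_type)
        rows = _gene_rows_from_probes(probe_calls, params, cancer_type)
    gene = pd.DataFrame(rows, columns=["gene", "cancer_type", "n_evaluable_tumors",
                                       "methylated_fraction", "status"])
    return TypeCallTable(gene=gene, probe=probe_calls, types=[cancer_type])


def classify_all_types(beta, probe_map, samples, params) -> TypeCallTable:
    types = sorted(samples["cancer_type"].unique())
    parts = [classify_gene_by_type(beta, probe_map, samples, params, t) for t in types]
    gene = pd.concat([p.gene for p in parts], ignore_index=True)
    probe = (pd.concat([p.probe for p in parts], ignore_index=False)
             if parts[0].probe is not None else None)
    return TypeCallTable(gene=gene, probe=probe, types=types)


def derive_pan_sets(calls: TypeCallTable, params: ClassifierParams,
                    freq_thr: float | None = None) -> GeneSets:
    """Pan-cancer prone/resistant sets with the ambiguity exclusion.

    List membership is probe-wise, as in probe-level array analyses: a gene
    joins the frequent list through any evaluable probe reaching the
    frequency threshold, and the never list through any probe evaluable in
    every type with zero methylated tumors everywhere. Genes on both lists
    (possible only with multiple probes) are excluded as ambiguous.
    """
    thr = params.freq_thr if freq_thr is None else freq_thr
    status = calls.status_matrix()
    if status.isna().any().any():
        missing = status.columns[status.isna().any()].tolist()
        raise ValueError(f"type coverage incomplete for {missing}")

    if calls.probe is not None:
        pr = calls.probe
        frequent_any = set(pr.loc[pr["evaluable"] &
                                  (pr["methylated_fraction"] >= thr), "gene"])
        ev = pr.pivot_table(index=[pr.index, "gene"], columns="cancer_type",
                            values="evaluable", aggfunc="first").fillna(False)
        fr = pr.pivot_table(index=[pr.index, "gene"], columns="cancer_type",
                            values="methylated_fraction", aggfunc="first")
        all_ev = ev.all(axis=1)
        never_everywhere = all_ev & fr.eq(0.0).all(axis=1)
        never_all = {g for (_, g) in never_everywhere.index[never_everywhere]}
    else:
        frac = calls.fraction_matrix()
        frequent_any = set(frac.index[(frac >= thr).any(axis=1)])
        evaluable_all = status.ne(STATUS_NOT_EVALUABLE).all(axis=1)
        never_all = set(frac.index[evaluable_all & frac.eq(0.0).all(axis=1)])

    ambiguous = frequent_any & never_all
    sets = GeneSets(prone=frequent_any - ambiguous,
                    resistant=never_all - ambiguous,
                    ambiguous=ambiguous)
    sets.check_invariants()
    return sets


def derive_cm_vm(calls: TypeCallTable, sets: GeneSets,
                 params: ClassifierParams) -> GeneSets:
    """Split prone genes into consistently and variably methylated subsets."""
    frac = calls.fraction_matrix()
    status = calls.status_matrix()
    prone_idx = frac.index.intersection(sorted(sets.prone))
    f = frac.loc[prone_idx]
    s = status.loc[prone_idx]
    cm_mask = s.ne(STATUS_NOT_EVALUABLE).all(axis=1) & f.ge(params.cm_thr).all(axis=1)
    vm_mask = s.eq(STATUS_NEVER).any(axis=1)
    sets.cm = set(prone_idx[cm_mask])
    sets.vm = set(prone_idx[vm_mask])
    vm_idx = prone_idx[vm_mask]
    sets.vm_susceptibility = s.loc[vm_idx].eq(STATUS_FREQUENT)
    sets.check_invariants()
    return sets


def sweep_frequency_threshold(beta, probe_map, samples, params,
                              thresholds) -> dict[float, GeneSets]:
    """Re-derive gene sets across a sweep of 'frequent' thresholds.

    Fractions are computed once; prone sets are nested nonincreasing in the
    threshold.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    calls = classify_all_types(beta, probe_map, samples, params)
    out = {}
    for thr in thresholds:
        calls_t = _recalled(calls, params, thr)
        sets = derive_pan_sets(calls_t, params, freq_thr=thr)
        out[thr] = derive_cm_vm(calls_t, sets, params)
    return out


def _recalled(calls: TypeCallTable, params: ClassifierParams, thr: float) -> TypeCallTable:
    gene = calls.gene.copy()
    ev = gene["status"] != STATUS_NOT_EVALUABLE
    frac = gene["methylated_fraction"]
    gene.loc[ev, "status"] = np.where(
        frac[ev] >= thr, STATUS_FREQUENT,
        np.where(frac[ev] == 0.0, STATUS_NEVER, STATUS_INTERMEDIATE))
    return TypeCallTable(gene=gene, probe=calls.probe, types=calls.types)


def consensus_lists(per_dataset_frequent: list[set], background: set,
                    reference: set | None = None):
    """Cross-study consensus of frequently hypermethylated gene lists.

    The consensus is the intersection across datasets. When a ``reference``
    list is supplied, returns the fraction of consensus genes found in the
    reference and a two-sided Fisher exact test of the 2x2 membership table
    over the background universe.
    """
    if len(per_dataset_frequent) < 2:
        raise ValueError("need at least two datasets for a consensus")
    if not background:
        raise ValueError("background universe is empty")
    consensus = set.intersection(*[set(s) for s in per_dataset_frequent])
    if reference is None:
        return consensus, None, None
    consensus &= background
    reference = set(reference) & background
    a = len(consensus & reference)
    table = [[a, len(consensus) - a],
             [len(reference) - a, len(background - consensus - reference)]]
    res = fisher_2x2(table)
    overlap = a / len(consensus) if consensus else float("nan")
    return consensus, overlap, res


class HypermethylationCaller(BaseEstimator):
    """Estimator wrapper around the beta-matrix gene classifier.

    Parameters mirror :class:`ClassifierParams`. ``fit`` takes the
    detection-filtered probe x sample beta matrix plus the sample sheet and
    probe-gene map, and exposes the derived sets as fitted attributes
    (``prone_``, ``resistant_``, ``ambiguous_``, ``cm_``, ``vm_``,
    ``type_calls_``, ``gene_sets_``).
    """

    def __init__(self, unmeth_thr=0.3, meth_thr=0.3, freq_thr=0.20, cm_thr=0.05,
                 mean_beta_thr=0.5, mode="probe_binary", min_normals=1):
        self.unmeth_thr = unmeth_thr
        self.meth_thr = meth_thr
        self.freq_thr = freq_thr
        self.cm_thr = cm_thr
        self.mean_beta_thr = mean_beta_thr
        self.mode = mode
        self.min_normals = min_normals

    def _params(self) -> ClassifierParams:
        return ClassifierParams(
            unmeth_thr=self.unmeth_thr, meth_thr=self.meth_thr,
            freq_thr=self.freq_thr, cm_thr=self.cm_thr,
            mean_beta_thr=self.mean_beta_thr, mode=self.mode,
            min_normals=self.min_normals)

    def fit(self, beta: pd.DataFrame, y=None, *, samples: pd.DataFrame,
            probe_map: pd.DataFrame):
        params = self._params()
        params.validate()
        calls = classify_all_types(beta, probe_map, samples, params)
        sets = derive_pan_sets(calls, params)
        sets = derive_cm_vm(calls, sets, params)
        self.type_calls_ = calls
        self.gene_sets_ = sets
        self.prone_ = sets.prone
        self.resistant_ = sets.resistant
        self.ambiguous_ = sets.ambiguous
        self.cm_ = sets.cm
        self.vm_ = sets.vm
        self.vm_susceptibility_ = sets.vm_susceptibility
        return self
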