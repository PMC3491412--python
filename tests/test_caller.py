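"""Gene classification rules: per-type calls, pan-cancer sets, CM/VM split,
threshold sweep and consensus overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from helpers import make_beta
from lineage_methylome.caller import (ClassifierParams, HypermethylationCaller,
                                      classify_all_types, classify_gene_by_type,
                                      consensus_lists, derive_cm_vm,
                                      derive_pan_sets, sweep_frequency_threshold)

PARAMS = ClassifierParams()


def _samples(n_tumors=10, n_normals=2, cancer_type="A"):
    return ([(f"{cancer_type}_t{i}", "tumor", cancer_type) for i in range(n_tumors)]
            + [(f"{cancer_type}_n{i}", "normal", cancer_type) for i in range(n_normals)])


class TestPerType:
    def test_three_of_ten_tumors_is_frequent(self):
        vals = [0.5, 0.6, 0.7] + [0.1] * 7 + [0.1, 0.2]  # 10 tumors, 2 normals
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        row = calls.gene.iloc[0]
        assert row["methylated_fraction"] == pytest.approx(0.3)
        assert row["status"] == "frequent"

    def test_methylated_normal_blocks_evaluation(self):
        vals = [0.5] * 10 + [0.35, 0.1]
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        assert calls.gene.iloc[0]["status"] == "not_evaluable"

    def test_zero_methylated_tumors_is_never(self):
        vals = [0.1] * 10 + [0.1, 0.2]
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        assert calls.gene.iloc[0]["status"] == "never"

    def test_beta_exactly_at_threshold_is_neither(self):
        # 0.3 in a normal does not disqualify (not >0.3 is irrelevant: rule is
        # <0.3 for unmethylated) -> a normal at exactly 0.3 blocks evaluability;
        # a tumor at exactly 0.3 is not methylated
        vals = [0.3] * 10 + [0.1, 0.1]
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        assert calls.gene.iloc[0]["status"] == "never"
        vals = [0.5] * 10 + [0.3, 0.1]
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        assert calls.gene.iloc[0]["status"] == "not_evaluable"

    def test_missing_entries_excluded_from_fractions(self):
        vals = [0.5, np.nan, np.nan, 0.1, 0.1, 0.1, np.nan, np.nan, np.nan, np.nan,
                0.1, np.nan]
        beta, sheet, pmap = make_beta({"p1": ("g1", vals)}, _samples())
        calls = classify_gene_by_type(beta, pmap, sheet, PARAMS, "A")
        row = calls.gene.iloc[0]
        assert row["n_evaluable_tumors"] == 4
        assert row["methylated_fraction"] == pytest.approx(0.25)

    def test_unknown_type_raises(self):
        beta, sheet, pmap = make_beta({"p1": ("g1", [0.1] * 12)}, _samples())
        with pytest.raises(ValueError, match="cancer type"):
            classify_gene_by_type(beta, pmap, sheet, PARAMS, "B")

    def test_mean_beta_mode(self):
        # two probes; tumor mean crosses 0.5 for 3 of 10 tumors
        tumor_p1 = [0.8, 0.7, 0.9] + [0.1] * 7
        tumor_p2 = [0.6, 0.5, 0.4] + [0.1] * 7
        beta, sheet, pmap = make_beta({
            "p1": ("g1", tumor_p1 + [0.1, 0.1]),
            "p2": ("g1", tumor_p2 + [0.1, 0.1]),
        }, _samples())
        params = ClassifierParams(mode="mean_beta")
        calls = classify_gene_by_type(beta, pmap, sheet, params, "A")
        row = calls.gene.iloc[0]
        assert row["methylated_fraction"] == pytest.approx(0.3)
        assert row["status"] == "frequent"


class TestPanSets:
    def _two_type_calls(self, probe_rows):
        samples = _samples(10, 2, "A") + _samples(10, 2, "B")
        beta, sheet, pmap = make_beta(probe_rows, samples)
        return classify_all_types(beta, pmap, sheet, PARAMS)

    def test_frequent_in_one_type_is_prone(self):
        vals_a = [0.5] * 10 + [0.1, 0.1]
        vals_b = [0.1] * 10 + [0.1, 0.1]
        calls = self._two_type_calls({"p1": ("g1", vals_a + vals_b)})
        sets = derive_pan_sets(calls, PARAMS)
        assert sets.prone == {"g1"} and not sets.resistant

    def test_never_everywhere_is_resistant(self):
        calls = self._two_type_calls({"p1": ("g1", [0.1] * 24)})
        sets = derive_pan_sets(calls, PARAMS)
        assert sets.resistant == {"g1"} and not sets.prone

    def test_conflicting_probes_excluded_ambiguous(self):
        # probe q1 frequent in type A; probe q2 evaluable everywhere, never
        q1 = [0.5] * 10 + [0.1, 0.1] + [0.1] * 10 + [0.1, 0.1]
        q2 = [0.1] * 24
        calls = self._two_type_calls({"q1": ("g1", q1), "q2": ("g1", q2)})
        sets = derive_pan_sets(calls, PARAMS)
        assert sets.ambiguous == {"g1"}
        assert not sets.prone and not sets.resistant

    def test_not_evaluable_everywhere_in_neither_set(self):
        calls = self._two_type_calls({"p1": ("g1", [0.9] * 24)})
        sets = derive_pan_sets(calls, PARAMS)
        assert not sets.prone and not sets.resistant and not sets.ambiguous


class TestCmVm:
    def _calls(self, fractions):
        """Build a three-type gene table directly from per-type fractions."""
        rows = []
        for t, f in zip("ABC", fractions):
            status = ("not_evaluable" if f is None else
                      "frequent" if f >= 0.2 else "never" if f == 0 else "intermediate")
            rows.append(("g1", t, 10, np.nan if f is None else f, status))
        gene = pd.DataFrame(rows, columns=["gene", "cancer_type",
                                           "n_evaluable_tumors",
                                           "methylated_fraction", "status"])
        from lineage_methylome.caller import TypeCallTable
        return TypeCallTable(gene=gene, probe=None, types=list("ABC"))

    def test_cm_rule(self):
        from lineage_methylome.caller import GeneSets
        sets = GeneSets(prone={"g1"})
        sets = derive_cm_vm(self._calls([0.3, 0.1, 0.06]), sets, PARAMS)
        assert sets.cm == {"g1"} and not sets.vm

    def test_vm_rule(self):
        from lineage_methylome.caller import GeneSets
        sets = GeneSets(prone={"g1"})
        sets = derive_cm_vm(self._calls([0.3, 0.0, 0.2]), sets, PARAMS)
        assert sets.vm == {"g1"} and not sets.cm
        assert sets.vm_susceptibility.loc["g1"].tolist() == [True, False, True]

    def test_cm_vm_disjoint_by_construction(self, fitted_caller):
        sets = fitted_caller.gene_sets_
        assert not (sets.cm & sets.vm)
        assert (sets.cm | sets.vm) <= sets.prone


class TestSweepAndConsensus:
    def test_prone_sets_nested_in_threshold(self, default_bundle, annotated):
        pmap, beta = annotated
        sweep = sweep_frequency_threshold(beta, pmap, default_bundle.samples,
                                          PARAMS, [0.1, 0.2, 0.3, 0.4, 0.5])
        thresholds = sorted(sweep)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert sweep[hi].prone <= sweep[lo].prone

    def test_sweep_rejects_unsorted(self, default_bundle, annotated):
        pmap, beta = annotated
        with pytest.raises(ValueError):
            sweep_frequency_threshold(beta, pmap, default_bundle.samples,
                                      PARAMS, [0.5, 0.1])

    def test_planted_freq_visible_at_20_gone_at_50(self, default_bundle, annotated):
        pmap, beta = annotated
        sweep = sweep_frequency_threshold(beta, pmap, default_bundle.samples,
                                          PARAMS, [0.2, 0.5])
        prone_true = default_bundle.truth.prone_genes
        recall_20 = len(sweep[0.2].prone & prone_true) / len(prone_true)
        recall_50 = len(sweep[0.5].prone & prone_true) / len(prone_true)
        assert recall_20 > 0.95
        assert recall_50 < 0.05

    def test_consensus_intersection(self):
        consensus, _, _ = consensus_lists([{"g1", "g2"}, {"g1"}, {"g1", "g3"}],
                                          background={"g1", "g2", "g3", "g4"})
        assert consensus == {"g1"}

    def test_consensus_overlap_fraction_and_fisher(self):
        bg = {f"g{i}" for i in range(4)}
        consensus, overlap, res = consensus_lists(
            [{"g0", "g1"}, {"g0", "g1"}], background=bg, reference={"g0", "g1"})
        assert overlap == 1.0
        # membership table [[2,0],[0,2]] -> two-sided Fisher p = 1/3
        assert res.pvalue == pytest.approx(1 / 3, abs=1e-12)

    def test_consensus_requires_two_datasets_and_background(self):
        with pytest.raises(ValueError):
            consensus_lists([{"g1"}], background={"g1"})
        with pytest.raises(ValueError):
            consensus_lists([{"g1"}, {"g1"}], background=set())


class TestInvariants:
    def test_sample_permutation_invariance(self, default_bundle, annotated):
        pmap, beta = annotated
        rng = np.random.default_rng(0)
        perm = rng.permutation(beta.columns)
        caller_a = HypermethylationCaller().fit(
            beta, samples=default_bundle.samples, probe_map=pmap)
        caller_b = HypermethylationCaller().fit(
            beta[perm], samples=default_bundle.samples.loc[perm], probe_map=pmap)
        assert caller_a.prone_ == caller_b.prone_
        assert caller_a.resistant_ == caller_b.resistant_
        assert caller_a.vm_ == caller_b.vm_

    @given(data=st.data())
    def test_set_algebra_on_random_matrices(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n_genes = data.draw(st.integers(2, 6))
        probe_rows = {}
        samples = _samples(5, 2, "A") + _samples(5, 2, "B")
        for i in range(n_genes):
            for j in range(data.draw(st.integers(1, 2))):
                probe_rows[f"p{i}_{j}"] = (f"g{i}",
                                           list(rng.uniform(size=len(samples))))
        beta, sheet, pmap = make_beta(probe_rows, samples)
        calls = classify_all_types(beta, pmap, sheet, PARAMS)
        sets = derive_cm_vm(calls, derive_pan_sets(calls, PARAMS), PARAMS)
        assert not (sets.prone & sets.resistant)
        assert not (sets.cm & sets.vm)
        assert (sets.cm | sets.vm) <= sets.prone

    def test_estimator_get_set_params_roundtrip(self):
        c = HypermethylationCaller(freq_thr=0.25)
        params = c.get_params()
        assert params["freq_thr"] == 0.25
        c.set_params(freq_thr=0.5)
        assert c.freq_thr == 0.5
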