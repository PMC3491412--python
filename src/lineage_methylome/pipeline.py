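"""End-to-end orchestration: simulate -> annotate -> classify -> specificity
-> features -> enrichment -> PCA, with a machine-readable report.

A fixed configuration and seed produce a byte-identical ``report.json``.
When run on synthetic input the report includes recovery metrics against the
planted ground truth.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .annotation import (GenomeAnnotation, apply_detection_filter,
                         flag_qualifying_probes, map_probes_to_genes)
from .caller import ClassifierParams, HypermethylationCaller, sweep_frequency_threshold
from .enrichment import MethylomePCA, gene_level_beta, go_fisher, pc1_median_correlation
from .features import (conservation_profile, feature_wilcoxon,
                       indel_coverage_profile, lincrna_neighbor_fraction,
                       make_tss_windows, regional_feature_scores,
                       repeat_density_test, repeat_presence_profile)
from .specificity import (TissueSpecificityScorer, compare_score_sets,
                          define_active_repressed, drop_unexpressed,
                          specificity_vs_ntypes_correlation,
                          susceptibility_expression_test, welch_bh_de)
from .stats import rank_sum_test
from .synthetic import SynthConfig, SyntheticBundle, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis", "recovery_metrics"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    outdir: str | Path = "lineage_methylome_out"
    seed: int = 0
    synth: SynthConfig | None = None          # simulate inline when set
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    repeat_window: int = 1000
    conservation_window: int = 500
    profile_span: int = 5000
    test_flank: int = 2000
    alpha: float = 0.05
    sweep_thresholds: tuple = (0.10, 0.20, 0.30, 0.40, 0.50)
    n_pcs: int = 4

    def resolved_synth(self) -> SynthConfig:
        cfg = self.synth or SynthConfig()
        if cfg.seed != self.seed:
            cfg = SynthConfig(**{**cfg.__dict__, "seed": self.seed})
        return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def recovery_metrics(gene_sets, vm_susceptibility, truth) -> dict:
    """Precision/recall/F1 of recovered sets against planted classes."""

    def f1(pred: set, true: set) -> dict:
        tp = len(pred & true)
        precision = tp / len(pred) if pred else float("nan")
        recall = tp / len(true) if true else float("nan")
        denom = len(pred) + len(true)
        return {
            "precision": precision,
            "recall": recall,
            "f1": 2 * tp / denom if denom else float("nan"),
        }

    true_prone = truth.prone_genes
    true_res = truth.gene_set("resistant")
    true_vm = truth.gene_set("vm")
    recovered_vm = gene_sets.vm & true_vm
    matches = 0
    for g in recovered_vm:
        called = set(vm_susceptibility.columns[vm_susceptibility.loc[g]])
        if called == truth.susceptible_types(g):
            matches += 1
    return {
        "prone": f1(gene_sets.prone, true_prone),
        "resistant": f1(gene_sets.resistant, true_res),
        "cm": f1(gene_sets.cm, truth.gene_set("cm")),
        "vm": f1(gene_sets.vm, true_vm),
        "vm_sensitivity": len(recovered_vm) / len(true_vm) if true_vm else float("nan"),
        "vm_type_match_fraction": matches / len(recovered_vm) if recovered_vm else float("nan"),
    }


def run_full_analysis(config: PipelineConfig,
                      bundle: SyntheticBundle | None = None) -> dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Returns the report dict. Any stage failure removes the partial outputs
    and raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        if bundle is None:
            bundle = generate_dataset(config.resolved_synth())
        report["n_genes"] = int(len(bundle.truth.genes))
        report["types"] = bundle.config.type_names

        stage = "annotate"
        ann = GenomeAnnotation(tss=bundle.tss, cgi=bundle.cgi,
                               probes=bundle.probes[["chrom", "pos"]])
        pmap = map_probes_to_genes(ann)
        pmap = flag_qualifying_probes(pmap, ann)
        beta = apply_detection_filter(bundle.beta, bundle.detection_p)
        lio.write_matrix(pmap, outdir / "probe_gene_map.tsv", index_label="probe")

        stage = "classify"
        caller = HypermethylationCaller(**{
            k: getattr(config.classifier, k) for k in
            ("unmeth_thr", "meth_thr", "freq_thr", "cm_thr",
             "mean_beta_thr", "mode", "min_normals")})
        caller.fit(beta, samples=bundle.samples, probe_map=pmap)
        sets = caller.gene_sets_
        sets.check_invariants()
        lio.write_json(sets.to_dict(), outdir / "gene_sets.json")
        caller.type_calls_.gene.to_csv(outdir / "type_calls.tsv", sep="\t",
                                       index=False, float_format=lio.FLOAT_FMT)
        report["set_sizes"] = {k: len(getattr(sets, k)) for k in
                               ("prone", "resistant", "ambiguous", "cm", "vm")}
        status = caller.type_calls_.status_matrix()
        report["single_type_prone"] = int(
            (status.loc[sorted(sets.prone)].eq("frequent").sum(axis=1) == 1).sum())
        sweep = sweep_frequency_threshold(beta, pmap, bundle.samples,
                                          config.classifier, config.sweep_thresholds)
        report["sweep_prone_sizes"] = {f"{thr:g}": len(s.prone)
                                       for thr, s in sweep.items()}

        stage = "specificity"
        expr = drop_unexpressed(bundle.expression, bundle.presence)
        scorer = TissueSpecificityScorer().fit(expr)
        spec = scorer.transform(expr)
        lio.write_matrix(spec, outdir / "specificity.tsv", index_label="gene")
        scores = spec["specificity"]
        in_scores = lambda s: set(s) & set(scores.index)  # noqa: E731
        tests = {}
        if sets.prone and sets.resistant:
            res = compare_score_sets(scores, in_scores(sets.prone),
                                     in_scores(sets.resistant), alternative="greater")
            tests["specificity_prone_gt_resistant"] = {"p": res.pvalue,
                                                       "U": res.statistic}
        if sets.cm and sets.vm:
            res = compare_score_sets(scores, in_scores(sets.cm), in_scores(sets.vm),
                                     alternative="greater")
            tests["specificity_cm_gt_vm"] = {"p": res.pvalue, "U": res.statistic}
        type_to_tissue = {t: f"tissue_{t}" for t in bundle.config.type_names}
        vm_status = status.loc[status.index.intersection(sorted(sets.vm))]
        vm_susc = (sets.vm_susceptibility if sets.vm_susceptibility is not None
                   else pd.DataFrame(columns=status.columns))
        vm_susc = vm_susc.reindex(columns=status.columns, fill_value=False)
        vm_status = vm_status.reindex(columns=status.columns)
        susc = susceptibility_expression_test(vm_susc, vm_status,
                                              bundle.expression, type_to_tissue)
        tests["susceptibility_expression"] = [
            {"type": r.cancer_type, "p": (None if not r.testable else r.pvalue),
             "testable": bool(r.testable), "n_frequent": int(r.n_frequent),
             "n_never": int(r.n_never)}
            for r in susc.itertuples()]
        n_freq_types = status.eq("frequent").sum(axis=1)
        prone_res = sorted((sets.prone | sets.resistant) & set(scores.index))
        corr = specificity_vs_ntypes_correlation(
            scores.loc[prone_res], n_freq_types.reindex(prone_res).fillna(0))
        tests["specificity_vs_ntypes"] = (
            {"rho": corr.statistic, "p": corr.pvalue} if corr.testable
            else {"rho": None, "p": None})

        # differential expression: first matched tissue vs reference tissue
        tissues = bundle.config.tissue_names
        t0, ref = tissues[0], tissues[-1]
        reps_a = bundle.expression_reps.filter(regex=f"^{t0}_rep")
        reps_b = bundle.expression_reps.filter(regex=f"^{ref}_rep")
        if reps_a.shape[1] >= 2 and reps_b.shape[1] >= 2 and t0 != ref:
            de = welch_bh_de(reps_a, reps_b, fdr=config.alpha)
            de.table.to_csv(outdir / "de_results.tsv", sep="\t",
                            index_label="gene", float_format=lio.FLOAT_FMT)
            type0 = bundle.config.type_names[0]
            evaluable0 = status.index[status[type0] != "not_evaluable"]
            active, repressed = define_active_repressed(de, set(evaluable0))
            gb = gene_level_beta(beta, pmap)
            tumors0 = bundle.samples.index[
                (bundle.samples["role"] == "tumor")
                & (bundle.samples["cancer_type"] == type0)]
            mean_meth = gb[tumors0].mean(axis=1)
            a = mean_meth.reindex(sorted(active & set(gb.index))).dropna()
            r = mean_meth.reindex(sorted(repressed & set(gb.index))).dropna()
            rr = (rank_sum_test(r.to_numpy(), a.to_numpy(), alternative="greater")
                  if len(a) and len(r) else None)
            tests["repressed_more_methylated"] = {
                "n_active": int(len(a)), "n_repressed": int(len(r)),
                "p": (rr.pvalue if rr is not None and rr.testable else None)}
        report["expression_tests"] = tests

        stage = "features"
        feature_tests = {}
        if sets.prone and sets.resistant:
            prone, resistant = sets.prone, sets.resistant
            rep_windows = make_tss_windows(bundle.tss, config.repeat_window,
                                           config.profile_span)
            prof_prone = repeat_presence_profile(prone, rep_windows, bundle.repeats)
            prof_res = repeat_presence_profile(resistant, rep_windows, bundle.repeats)
            profiles = pd.concat({
                "prone": prof_prone.summary, "resistant": prof_res.summary}, axis=1)
            lio.write_matrix(profiles, outdir / "profiles.tsv", index_label="offset")
            dens = repeat_density_test(prone, resistant, bundle.repeats,
                                       bundle.tss, flank=config.test_flank)
            feature_tests["repeats"] = {
                cl: {"p": row["pvalue"], "odds_ratio": row["odds_ratio"],
                     "freq_prone": row["freq_a"], "freq_resistant": row["freq_b"]}
                for cl, row in dens.iterrows()}
            cons_prone = regional_feature_scores(bundle.tss, prone,
                                                 bundle.conservation,
                                                 flank=config.test_flank)
            cons_res = regional_feature_scores(bundle.tss, resistant,
                                               bundle.conservation,
                                               flank=config.test_flank)
            res = feature_wilcoxon(cons_prone, cons_res, alternative="greater")
            feature_tests["conservation"] = {"p": res.pvalue if res.testable else None}
            ind_prone = regional_feature_scores(bundle.tss, prone,
                                                bundle.indel_purified,
                                                flank=config.test_flank, merge=True)
            ind_res = regional_feature_scores(bundle.tss, resistant,
                                              bundle.indel_purified,
                                              flank=config.test_flank, merge=True)
            res = feature_wilcoxon(ind_prone, ind_res, alternative="greater")
            feature_tests["indel_purified"] = {"p": res.pvalue if res.testable else None}
            fr_a, fr_b, fish = lincrna_neighbor_fraction(bundle.tss, bundle.lincrna,
                                                         prone, resistant)
            feature_tests["lincrna"] = {"frac_prone": fr_a, "frac_resistant": fr_b,
                                        "p": fish.pvalue}
        report["feature_tests"] = feature_tests

        stage = "enrich"
        background = set(pmap.loc[pmap["qualifying"], "gene"].dropna())
        enr = go_fisher(sets.prone & background, background, bundle.terms)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format=lio.FLOAT_FMT)
        report["enrichment_top"] = [
            {"term": t, "pct_change": row["pct_change"], "p": row["pvalue"]}
            for t, row in enr.sort_values("pvalue").head(5).iterrows()]

        stage = "pca"
        tumors = bundle.samples.index[bundle.samples["role"] == "tumor"]
        gb_prone = gene_level_beta(beta, pmap, genes=sets.prone)
        if len(gb_prone) >= 1 and len(tumors) >= 2:
            pca = MethylomePCA(n_components=config.n_pcs).fit(gb_prone[tumors])
            pca.coordinates_.to_csv(outdir / "pca.tsv", sep="\t",
                                    index_label="sample",
                                    float_format=lio.FLOAT_FMT)
            corr = pc1_median_correlation(pca)
            report["pca"] = {
                "variance_fraction": [float(v) for v in pca.variance_fraction_],
                "pc1_median_r": corr.statistic if corr.testable else None,
                "pc1_median_abs_r": abs(corr.statistic) if corr.testable else None,
            }

        stage = "report"
        report["recovery"] = recovery_metrics(sets, sets.vm_susceptibility,
                                              bundle.truth)
        payload = _round_floats(report)
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return payload
    except Exception as exc:  # noqa: BLE001 - abort cleanly, naming the stage
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob("*"):
                if f.is_file():
                    f.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
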