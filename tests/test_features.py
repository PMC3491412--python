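"""Window construction, interval profiling and the promoter-feature tests."""

import numpy as np
import pandas as pd
import pytest

from lineage_methylome.features import (conservation_profile, feature_wilcoxon,
                                        indel_coverage_profile,
                                        lincrna_neighbor_fraction, make_tss_windows,
                                        regional_feature_scores, repeat_density_test,
                                        repeat_presence_profile)


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"]
                        ).set_index("gene")


PLUS = _tss([("g1", "chr1", "+", 10_000)])
MINUS = _tss([("g1", "chr1", "-", 10_000)])


class TestWindows:
    def test_plus_strand_layout(self):
        w = make_tss_windows(PLUS, width=1000, span=2000)
        got = {o: (s, e) for o, s, e in zip(w["offset"], w["start"], w["end"])}
        assert got == {-2: (8000, 9000), -1: (9000, 10000),
                       1: (10000, 11000), 2: (11000, 12000)}

    def test_minus_strand_mirrored(self):
        w = make_tss_windows(MINUS, width=1000, span=2000)
        got = {o: (s, e) for o, s, e in zip(w["offset"], w["start"], w["end"])}
        assert got[1] == (9000, 10000)
        assert got[-1] == (10000, 11000)
        assert got[2] == (8000, 9000)

    def test_zero_span_empty(self):
        assert make_tss_windows(PLUS, width=500, span=0).empty

    def test_span_must_divide(self):
        with pytest.raises(ValueError):
            make_tss_windows(PLUS, width=300, span=1000)


def _repeats(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])


class TestRepeatPresence:
    def test_single_overlap_counted_once(self):
        w = make_tss_windows(PLUS, width=1000, span=2000)
        prof = repeat_presence_profile(["g1"], w, _repeats(
            [("chr1", 10_100, 10_200, "SINE")]))
        assert prof.summary.loc[1, "SINE"] == 1.0
        assert prof.summary.loc[2, "SINE"] == 0.0
        assert prof.summary["LINE"].sum() == 0.0

    def test_empty_track_all_zero(self):
        w = make_tss_windows(PLUS, width=1000, span=2000)
        prof = repeat_presence_profile(["g1"], w, _repeats([]))
        assert (prof.summary.to_numpy() == 0).all()

    def test_abutting_repeat_not_counted(self):
        # repeat [11000, 11200) abuts window +1 = [10000, 11000): no overlap
        w = make_tss_windows(PLUS, width=1000, span=2000)
        prof = repeat_presence_profile(["g1"], w, _repeats(
            [("chr1", 11_000, 11_200, "LINE")]))
        assert prof.summary.loc[1, "LINE"] == 0.0
        assert prof.summary.loc[2, "LINE"] == 1.0

    def test_monotone_under_adding_repeats(self):
        w = make_tss_windows(PLUS, width=1000, span=2000)
        base = repeat_presence_profile(["g1"], w, _repeats(
            [("chr1", 10_100, 10_200, "SINE")]))
        more = repeat_presence_profile(["g1"], w, _repeats(
            [("chr1", 10_100, 10_200, "SINE"), ("chr1", 8_100, 8_200, "SINE")]))
        assert (more.summary["SINE"] >= base.summary["SINE"]).all()


class TestRepeatDensity:
    def test_balanced_table(self):
        tss = _tss([(f"g{i}", "chr1", "+", 100_000 * (i + 1)) for i in range(4)])
        reps = _repeats([("chr1", 100_000, 100_200, "SINE"),
                         ("chr1", 200_000, 200_200, "SINE")])
        out = repeat_density_test({"g0", "g1"}, {"g2", "g3"}, reps, tss)
        assert out.loc["SINE", "pvalue"] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_composition_p_one(self):
        tss = _tss([(f"g{i}", "chr1", "+", 100_000 * (i + 1)) for i in range(4)])
        reps = _repeats([("chr1", 100_000, 100_200, "LTR"),
                         ("chr1", 300_000, 300_200, "LTR")])
        out = repeat_density_test({"g0", "g1"}, {"g2", "g3"}, reps, tss)
        assert out.loc["LTR", "pvalue"] == 1.0

    def test_planted_depletion_detected(self, default_bundle):
        truth = default_bundle.truth
        out = repeat_density_test(truth.prone_genes, truth.gene_set("resistant"),
                                  default_bundle.repeats, default_bundle.tss)
        assert (out["pvalue"] < 0.05).all()
        assert (out["odds_ratio"] < 1).all()  # depletion at prone promoters


class TestConservation:
    def _track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])

    def test_constant_track(self):
        w = make_tss_windows(PLUS, width=500, span=2000)
        prof = conservation_profile(["g1"], w, self._track(
            [("chr1", 0, 20_000, 0.5)]))
        assert np.allclose(prof.summary.to_numpy(), 0.5)

    def test_weighted_mean_half_half(self):
        w = make_tss_windows(PLUS, width=500, span=500)
        track = self._track([("chr1", 10_000, 10_250, 1.0),
                             ("chr1", 10_250, 10_500, 0.0)])
        prof = conservation_profile(["g1"], w, track)
        assert prof.per_gene.loc["g1", 1] == pytest.approx(0.5)

    def test_empty_track_all_missing(self):
        w = make_tss_windows(PLUS, width=500, span=1000)
        prof = conservation_profile(["g1"], w, self._track([]))
        assert prof.per_gene.isna().all().all()

    def test_partial_coverage_uses_covered_bases_only(self):
        w = make_tss_windows(PLUS, width=500, span=500)
        track = self._track([("chr1", 10_000, 10_100, 0.8)])
        prof = conservation_profile(["g1"], w, track)
        assert prof.per_gene.loc["g1", 1] == pytest.approx(0.8)


class TestIndelCoverage:
    def test_half_covered(self):
        w = make_tss_windows(PLUS, width=500, span=500)
        elements = pd.DataFrame([("chr1", 10_000, 10_250)],
                                columns=["chrom", "start", "end"])
        prof = indel_coverage_profile(["g1"], w, elements)
        assert prof.per_gene.loc["g1", 1] == pytest.approx(50.0)

    def test_overlapping_elements_merged(self):
        w = make_tss_windows(PLUS, width=500, span=500)
        elements = pd.DataFrame([("chr1", 10_000, 10_200), ("chr1", 10_100, 10_250)],
                                columns=["chrom", "start", "end"])
        prof = indel_coverage_profile(["g1"], w, elements)
        assert prof.per_gene.loc["g1", 1] == pytest.approx(50.0)

    def test_no_elements_zero(self):
        w = make_tss_windows(PLUS, width=500, span=500)
        prof = indel_coverage_profile(
            ["g1"], w, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert prof.per_gene.loc["g1", 1] == 0.0


class TestStrandSymmetry:
    def test_mirrored_minus_strand_profile_matches(self):
        """Reflecting the track about the TSS of a minus-strand gene
        reproduces the plus-strand profile."""
        w_plus = make_tss_windows(PLUS, width=500, span=2000)
        w_minus = make_tss_windows(MINUS, width=500, span=2000)
        track_plus = pd.DataFrame([("chr1", 10_600, 10_900, 0.9)],
                                  columns=["chrom", "start", "end", "score"])
        # reflection of [10600, 10900) about 10000 is [9100, 9400)
        track_minus = pd.DataFrame([("chr1", 9_100, 9_400, 0.9)],
                                   columns=["chrom", "start", "end", "score"])
        p_plus = conservation_profile(["g1"], w_plus, track_plus)
        p_minus = conservation_profile(["g1"], w_minus, track_minus)
        pd.testing.assert_series_equal(p_plus.per_gene.loc["g1"],
                                       p_minus.per_gene.loc["g1"])


class TestFeatureWilcoxon:
    def test_exact_small_case(self):
        res = feature_wilcoxon([0.9, 0.8], [0.1, 0.2], alternative="greater")
        assert res.pvalue == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_multisets_p_one(self):
        res = feature_wilcoxon([0.4, 0.4], [0.4, 0.4])
        assert res.pvalue == 1.0

    def test_planted_conservation_elevation_detected(self, default_bundle):
        b = default_bundle
        truth = b.truth
        prone = regional_feature_scores(b.tss, truth.prone_genes, b.conservation)
        res_set = regional_feature_scores(b.tss, truth.gene_set("resistant"),
                                          b.conservation)
        res = feature_wilcoxon(prone, res_set, alternative="greater")
        assert res.pvalue < 0.05


class TestLincRNA:
    def test_fraction_single_neighbor(self):
        tss = _tss([("g1", "chr1", "+", 1000), ("g2", "chr1", "+", 100_000)])
        linc = pd.DataFrame([("chr1", 1_900, 2_100, "l1")],
                            columns=["chrom", "start", "end", "name"])
        fa, fb, res = lincrna_neighbor_fraction(tss, linc, {"g1"}, {"g2"})
        assert fa == 1.0 and fb == 0.0

    def test_no_lincrnas(self):
        tss = _tss([("g1", "chr1", "+", 1000), ("g2", "chr1", "+", 100_000)])
        linc = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        fa, fb, res = lincrna_neighbor_fraction(tss, linc, {"g1"}, {"g2"})
        assert fa == 0.0 and fb == 0.0 and res.pvalue == 1.0

    def test_planted_adjacency_detected(self, default_bundle):
        b = default_bundle
        truth = b.truth
        fa, fb, res = lincrna_neighbor_fraction(
            b.tss, b.lincrna, truth.prone_genes, truth.gene_set("resistant"))
        assert fa > fb
        assert res.pvalue < 0.05
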