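"""Locus annotation rules, Firth locus scan, Bonferroni and BMI models."""

import numpy as np
import pytest

from rarecnv.calls import CnvCall
from rarecnv.loci import (LocusDefinition, annotate_locus, bmi_linear,
                          carrier_vector, locus_scan, read_locus_list,
                          write_locus_list)
from conftest import make_callset


def call(chrom, start, end, cnv_type="DEL"):
    return CnvCall("S1", str(chrom), start, end, cnv_type, 10)


class TestSyndromicRule:
    LOCUS = LocusDefinition("syn", "1", 1_000_000, 2_100_000, "DEL")  # 1.1 Mb

    def test_small_call_inside_large_locus_annotated(self):
        # 40 kb deletion fully inside: ov/len(call) = 1 >= 0.5
        assert annotate_locus(call("1", 1_500_000, 1_540_000), self.LOCUS)

    def test_large_call_covering_half_the_locus_annotated(self):
        # ov/len(locus) = 0.5 via the locus denominator
        assert annotate_locus(call("1", 450_000, 1_550_000), self.LOCUS)

    def test_marginal_overlap_not_annotated(self):
        # 300 kb call overlapping by 100 kb: 100/1100 and 100/300 both < 0.5
        assert not annotate_locus(call("1", 800_000, 1_100_000), self.LOCUS)

    def test_type_mismatch_short_circuits(self):
        assert not annotate_locus(call("1", 1_500_000, 1_540_000, "DUP"), self.LOCUS)


class TestPleiotropicRule:
    SEG = LocusDefinition("seg", "1", 1_000_000, 1_200_000, "DEL",
                          rule="pleiotropic_seg")  # 200 kb

    def test_25_percent_of_segment_clause(self):
        # 60 kb call overlapping by 55 kb: 55/200 = 0.275 >= 0.25
        assert annotate_locus(call("1", 995_000, 1_055_000), self.SEG)

    def test_large_call_50_percent_clause(self):
        big = LocusDefinition("seg6", "1", 1_000_000, 1_600_000, "DEL",
                              rule="pleiotropic_seg")  # 600 kb
        # 150 kb call with 80 kb inside: >= 100 kb and ov >= 0.5*len(call)... 80<75? 80>=75 yes
        assert annotate_locus(call("1", 930_000, 1_080_000), big)
        # 90 kb call fully inside: < 100 kb and 90/600 = 0.15 < 0.25 -> no
        assert not annotate_locus(call("1", 1_010_000, 1_100_000), big)

    def test_below_both_clauses_not_annotated(self):
        assert not annotate_locus(call("1", 990_000, 1_030_000), self.SEG)  # 40/200 = 0.2


class TestExonRule:
    EXONS = [(1_050_000, 1_052_000), (1_080_000, 1_081_500)]
    LOCUS = LocusDefinition("nrxn1_like", "1", 1_000_000, 1_100_000, "DEL",
                            rule="exon_1bp", exon_intervals=EXONS)

    def test_one_bp_exon_overlap_counts(self):
        assert annotate_locus(call("1", 1_051_999, 1_060_000), self.LOCUS)

    def test_intronic_call_not_annotated(self):
        # overlaps the locus but no exon: the intron-only deletion case
        assert not annotate_locus(call("1", 1_053_000, 1_079_000), self.LOCUS)

    def test_exon_intervals_required_iff_exon_rule(self):
        with pytest.raises(ValueError):
            LocusDefinition("bad", "1", 0, 1000, "DEL", rule="exon_1bp")
        with pytest.raises(ValueError):
            LocusDefinition("bad", "1", 0, 1000, "DEL", rule="syndromic_50",
                            exon_intervals=[(0, 10)])


def test_all_rules_agree_on_exact_locus_call():
    c = call("1", 1_000_000, 1_100_000)
    for rule, exons in (("syndromic_50", None), ("pleiotropic_seg", None),
                        ("exon_1bp", [(1_000_000, 1_002_000)])):
        locus = LocusDefinition("x", "1", 1_000_000, 1_100_000, "DEL",
                                rule=rule, exon_intervals=exons)
        assert annotate_locus(c, locus)


class TestLocusScan:
    def test_carrier_is_sample_level_indicator(self):
        cs = make_callset([("S1", "1", 1_000_000, 1_100_000, "DEL"),
                           ("S1", "1", 1_010_000, 1_090_000, "DEL"),
                           ("S2", "1", 1_000_000, 1_100_000, "DEL")],
                          sample_ids=["S1", "S2", "S3", "S4"])
        locus = LocusDefinition("l", "1", 1_000_000, 1_100_000, "DEL")
        assert carrier_vector(cs, locus).tolist() == [1, 1, 0, 0]

    def test_unobserved_locus_not_tested(self, small_sim):
        loci = [LocusDefinition("empty", "9", 50_000_000, 51_000_000, "DUP")]
        out = locus_scan(small_sim.callset, loci)
        assert out.iloc[0]["status"] == "unobserved"
        assert not out.iloc[0]["significant"]

    def test_bonferroni_uses_full_list_length(self, small_sim):
        loci = [LocusDefinition("plant", "1", 20_000_000, 20_100_000, "DEL"),
                LocusDefinition("empty", "9", 50_000_000, 51_000_000, "DUP")]
        out = locus_scan(small_sim.callset, loci, n_bonferroni=67)
        assert np.allclose(out["bonferroni_alpha"], 0.05 / 67)
        tested = out[out.status == "tested"]
        assert (tested["significant"]
                == (tested["p_sided"] < 0.05 / 67)).all()

    def test_sidedness_identity(self, small_sim):
        loci_two = [LocusDefinition("p2", "1", 20_000_000, 20_100_000, "DEL",
                                    sided="two")]
        loci_one = [LocusDefinition("p1", "1", 20_000_000, 20_100_000, "DEL",
                                    sided="one")]
        r2 = locus_scan(small_sim.callset, loci_two).iloc[0]
        r1 = locus_scan(small_sim.callset, loci_one).iloc[0]
        assert r1["OR"] == pytest.approx(r2["OR"])
        if r1["OR"] > 1:
            assert r1["p_sided"] == pytest.approx(r2["p_sided"] / 2)


class TestBmiLinear:
    def test_planted_negative_bmi_effect_recovered(self):
        from rarecnv.simulate import SimConfig, PlantedLocus, simulate
        locus = PlantedLocus("1", 10_000_000, 10_100_000, "DEL", 0.01,
                             odds_ratio=1.0, bmi_effect=-2.0)
        res = simulate(SimConfig(n_cases=2500, n_controls=2500, seed=31,
                                 chrom_lengths={"1": 50_000_000},
                                 planted_loci=[locus]))
        ld = LocusDefinition("l", "1", 10_000_000, 10_100_000, "DEL")
        out = bmi_linear(res.callset, [ld], stratum="controls")
        row = out.iloc[0]
        assert row["status"] == "tested"
        assert row["ci_low"] < -2.0 < row["ci_high"]

    def test_zero_carriers_unobserved(self, small_sim):
        ld = LocusDefinition("none", "9", 50_000_000, 50_500_000, "DUP")
        out = bmi_linear(small_sim.callset, [ld], stratum="cases")
        assert out.iloc[0]["status"] == "unobserved"

    def test_invalid_stratum_raises(self, small_sim):
        with pytest.raises(ValueError):
            bmi_linear(small_sim.callset, [], stratum="everyone")


def test_locus_list_round_trip(tmp_path):
    loci = [LocusDefinition("a", "1", 0, 1_000_000, "DEL"),
            LocusDefinition("b", "2", 5_000, 400_000, "DUP",
                            rule="pleiotropic_seg", sided="one"),
            LocusDefinition("c", "1", 0, 100_000, "DEL", rule="exon_1bp",
                            exon_intervals=[(10, 20), (50, 80)])]
    path = tmp_path / "loci.tsv"
    write_locus_list(loci, path)
    back = read_locus_list(path)
    assert [l.locus_id for l in back] == ["a", "b", "c"]
    assert back[2].exon_intervals == [(10, 20), (50, 80)]
    assert back[1].sided == "one" and back[1].rule == "pleiotropic_seg"
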