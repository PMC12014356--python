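"""Breakpoint enumeration, one-type encodings, r^2, CNVR clumping, mirrors."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.calls import ProbeMap
from rarecnv.breakpoints import (BreakpointMatrix, breakpoint_frequency,
                                 clump_and_define_cnvrs, encode,
                                 enumerate_breakpoints,
                                 filter_rare_breakpoints, ld_r2, mirror_scan,
                                 scan, cnvr_table)
from conftest import make_callset


class TestEnumerate:
    def test_identical_calls_deduplicate(self):
        cs = make_callset([("S1", "1", 100, 200, "DEL"),
                           ("S2", "1", 100, 200, "DEL")])
        bps = enumerate_breakpoints(cs)
        assert len(bps) == 2
        assert list(bps["pos"]) == [100, 200]

    def test_overlapping_calls_give_four_breakpoints(self):
        cs = make_callset([("S1", "1", 100, 200, "DEL"),
                           ("S2", "1", 150, 250, "DUP")])
        bps = enumerate_breakpoints(cs)
        assert list(bps["pos"]) == [100, 150, 200, 250]

    def test_shared_position_marked_both(self):
        cs = make_callset([("S1", "1", 100, 200, "DEL"),
                           ("S2", "1", 200, 300, "DEL")])
        bps = enumerate_breakpoints(cs)
        assert bps.loc[bps["pos"] == 200, "origin"].iloc[0] == "both"

    def test_empty_callset(self):
        cs = make_callset([("S1", "1", 100, 200, "DEL")])
        assert len(enumerate_breakpoints(cs.subset(np.zeros(1, bool)))) == 0


def truth_table_callset():
    # S1: DUP only; S2: DEL only; S3: both types covering [100, 200); S4: none
    return make_callset([("S1", "1", 100, 200, "DUP"),
                         ("S2", "1", 100, 200, "DEL"),
                         ("S3", "1", 100, 200, "DUP"),
                         ("S3", "1", 120, 180, "DEL")],
                        sample_ids=["S1", "S2", "S3", "S4"])


class TestEncoding:
    def test_truth_table(self):
        cs = truth_table_callset()
        bps = enumerate_breakpoints(cs)
        dup = encode(cs, bps, "dup_only")
        del_ = encode(cs, bps, "del_only")
        i = list(bps["pos"]).index(120)
        # hand-enumerated: DUP carrier is ALT in dup model, MISSING in del model;
        # a sample with both types is ALT in both (model type takes precedence)
        assert dup.entry(0, i) == "ALT" and del_.entry(0, i) == "MISSING"
        assert dup.entry(1, i) == "MISSING" and del_.entry(1, i) == "ALT"
        assert dup.entry(2, i) == "ALT" and del_.entry(2, i) == "ALT"
        assert dup.entry(3, i) == "REF" and del_.entry(3, i) == "REF"

    def test_call_covers_both_its_endpoints(self):
        cs = make_callset([("S1", "1", 100, 200, "DUP")], sample_ids=["S1", "S2"])
        bps = enumerate_breakpoints(cs)
        dup = encode(cs, bps, "dup_only")
        for i in range(2):   # positions 100 and 200 (closed right end)
            assert dup.entry(0, i) == "ALT"

    def test_complementarity_on_random_callsets(self):
        rng = np.random.default_rng(7)
        ids = [f"S{i}" for i in range(30)]
        rows = []
        for _ in range(60):
            s = int(rng.integers(0, 5_000))
            rows.append((ids[int(rng.integers(30))], "1", s,
                         s + int(rng.integers(100, 2_000)),
                         "DEL" if rng.random() < 0.5 else "DUP"))
        cs = make_callset(rows, sample_ids=ids)
        bps = enumerate_breakpoints(cs)
        dup = encode(cs, bps, "dup_only")
        del_ = encode(cs, bps, "del_only")
        for i in range(len(bps)):
            for s in range(30):
                e_dup, e_del = dup.entry(s, i), del_.entry(s, i)
                covered_dup = e_dup == "ALT"
                covered_del = e_del == "ALT"
                # REF in both iff covered by no call of either type
                if e_dup == "REF":
                    assert e_del in ("REF", "ALT")
                if e_dup == "MISSING":
                    assert covered_del and not covered_dup
                if e_del == "MISSING":
                    assert covered_dup and not covered_del


class TestFrequency:
    def test_frequency_arithmetic(self):
        ids = [f"S{i}" for i in range(1000)]
        rows = [(f"S{i}", "1", 100, 20_000, "DUP") for i in range(10)]
        rows += [(f"S{i}", "1", 90, 20_010, "DEL") for i in range(10, 14)]
        cs = make_callset(rows, sample_ids=ids)
        bps = enumerate_breakpoints(cs)
        freq = breakpoint_frequency(encode(cs, bps, "dup_only"))
        row = freq[freq["pos"] == 100].iloc[0]
        # 10 ALT among 1000 - 4 missing = 996 non-missing
        assert row["alt_count"] == 10 and row["n_nonmissing"] == 996
        assert row["freq"] == pytest.approx(10 / 996)

    def test_rare_filter_bounds(self):
        ids = [f"S{i}" for i in range(100)]
        rows = [(f"S{i}", "1", 100, 20_000, "DUP") for i in range(2)]        # 2%: out
        rows += [("S50", "1", 100_000, 120_000, "DUP")]                      # 1%: out (strict)
        rows += [("S60", "2", 100, 20_000, "DEL")]                           # dup model: 0 ALT
        cs = make_callset(rows, sample_ids=ids)
        bps = enumerate_breakpoints(cs)
        mat, rec = filter_rare_breakpoints(encode(cs, bps, "dup_only"), max_freq=0.02)
        kept = set(mat.breakpoints["pos"])
        assert kept == {100_000, 120_000}
        assert rec.removed == rec.n_before - rec.n_after


class TestLdR2:
    def make_matrix(self, alt_sets, miss_sets=None, positions=None, n=5):
        ids = [f"S{i}" for i in range(n)]
        cs = make_callset([("S0", "1", 0, 100, "DEL")], sample_ids=ids)
        k = len(alt_sets)
        positions = positions or [100 * (i + 1) for i in range(k)]
        bps = pd.DataFrame({"chrom": "1", "pos": positions, "origin": "start"})
        alt = [np.asarray(a, dtype=np.int64) for a in alt_sets]
        miss = ([np.asarray(m, dtype=np.int64) for m in miss_sets]
                if miss_sets else [np.empty(0, np.int64)] * k)
        return BreakpointMatrix("del_only", bps, alt, miss, cs)

    def test_hand_value(self):
        # x=(1,1,0,0,0), y=(1,0,0,0,0): r^2 = 9/24 = 0.375
        m = self.make_matrix([[0, 1], [0]])
        assert ld_r2(m, 0, 1) == pytest.approx(0.375)

    def test_identical_columns(self):
        m = self.make_matrix([[1, 3], [1, 3]])
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_constant_on_shared_support_flagged_zero(self):
        # column j is ALT only for a sample that is missing in column i
        m = self.make_matrix([[0], [1]], miss_sets=[[1], []])
        assert ld_r2(m, 0, 1) == 0.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        n = 4000
        a = np.sort(rng.choice(n, 400, replace=False))
        b = np.sort(rng.choice(n, 400, replace=False))
        ids = [f"S{i}" for i in range(n)]
        cs = make_callset([("S0", "1", 0, 100, "DEL")], sample_ids=ids)
        bps = pd.DataFrame({"chrom": "1", "pos": [100, 200], "origin": "start"})
        m = BreakpointMatrix("del_only", bps, [a, b],
                             [np.empty(0, np.int64)] * 2, cs)
        assert ld_r2(m, 0, 1) < 0.01


def clump_fixture(lead_or=3.0, partner_shift=40_000, partner_overlap=8,
                  probe_spacing=2_000, n=400):
    """A lead breakpoint at 1,000,000 with one correlated partner."""
    ids = [f"S{i}" for i in range(n)]
    statuses = [1 if i < n // 2 else 0 for i in range(n)]
    lead_alt = np.arange(10)
    partner_alt = np.arange(partner_overlap)
    cs = make_callset([("S0", "1", 900_000, 1_100_000, "DEL")],
                      sample_ids=ids, statuses=statuses)
    positions = [1_000_000, 1_000_000 + partner_shift, 2_000_000]
    bps = pd.DataFrame({"chrom": "1", "pos": positions, "origin": "start"})
    far_alt = np.array([n - 1])
    mat = BreakpointMatrix("del_only", bps, [lead_alt, partner_alt, far_alt],
                           [np.empty(0, np.int64)] * 3, cs)
    scan_df = pd.DataFrame({
        "chrom": "1", "pos": positions, "origin": "start", "model": "del_only",
        "alt_case": [9, 7, 1], "alt_control": [1, 1, 0],
        "n_eff": n, "beta": [np.log(lead_or), 0.5, 0.2],
        "se": 0.5, "OR": [lead_or, 1.6, 1.2],
        "p_two_sided": [0.001, 0.2, 0.6], "p_one_sided": [0.0005, 0.1, 0.3],
        "converged": True})
    probes = ProbeMap({"1": np.arange(0, 3_000_000, probe_spacing)})
    return scan_df, mat, probes


class TestClump:
    def test_hand_trace_span(self):
        scan_df, mat, probes = clump_fixture()
        assert ld_r2(mat, 0, 1) >= 0.5
        regions = clump_and_define_cnvrs(scan_df, mat, probes, ci=False)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1_000_000, 1_040_000)
        assert r.length == 40_000 and r.lead_pos == 1_000_000
        assert r.n_case_carriers == 1 and r.n_control_carriers == 0

    def test_partner_outside_window_excluded(self):
        scan_df, mat, probes = clump_fixture(partner_shift=301_000)
        regions = clump_and_define_cnvrs(scan_df, mat, probes, ci=False)
        assert regions == []   # lone lead: zero-length span fails >= 20 kb

    def test_protective_lead_not_emitted(self):
        scan_df, mat, probes = clump_fixture()
        scan_df.loc[0, ["OR", "beta"]] = [0.4, np.log(0.4)]
        assert clump_and_define_cnvrs(scan_df, mat, probes, ci=False) == []

    def test_min_probe_filter(self):
        scan_df, mat, probes = clump_fixture(probe_spacing=5_000)  # 9 probes in 40 kb
        assert clump_and_define_cnvrs(scan_df, mat, probes, ci=False) == []

    def test_min_length_filter(self):
        scan_df, mat, probes = clump_fixture(partner_shift=19_000)
        assert clump_and_define_cnvrs(scan_df, mat, probes, ci=False) == []

    def test_carrier_recount_matches_bruteforce(self, small_sim):
        from rarecnv.calls import qc_filter, filter_rare
        cs, _ = qc_filter(small_sim.callset)
        cs, _ = filter_rare(cs)
        bps = enumerate_breakpoints(cs)
        full = encode(cs, bps, "del_only")
        mat, _ = filter_rare_breakpoints(full)
        res = scan(mat, region=("1", 19_800_000, 20_300_000))
        regions = clump_and_define_cnvrs(res, full, small_sim.probe_map, ci=False)
        for r in regions:
            calls = cs.calls
            sel = ((calls["cnv_type"] == "DEL") & (calls["chrom"] == r.chrom)
                   & (calls["start"] <= r.end) & (calls["end"] > r.start))
            carriers = calls.loc[sel, "sample_id"].unique()
            status = cs.samples.loc[carriers, "status"]
            assert r.n_case_carriers == int((status == 1).sum())
            assert r.n_control_carriers == int((status == 0).sum())

    def test_table_columns(self):
        scan_df, mat, probes = clump_fixture()
        regions = clump_and_define_cnvrs(scan_df, mat, probes, ci=False)
        tab = cnvr_table(regions)
        for col in ("genotype", "length_kb", "n_probes", "OR", "p", "genes"):
            assert col in tab.columns


def mirror_frame(chrom, pos, or_, p):
    return pd.DataFrame({"chrom": [chrom], "pos": [pos], "origin": "start",
                         "model": "x", "alt_case": 5, "alt_control": 5,
                         "n_eff": 100, "beta": [np.log(or_)], "se": 0.3,
                         "OR": [or_], "p_two_sided": [p], "p_one_sided": [p / 2],
                         "converged": True})


class TestMirror:
    def test_opposite_directions_flagged(self):
        dup = mirror_frame("5", 1_000_000, 0.5, 0.03)
        del_ = mirror_frame("5", 1_020_000, 2.0, 0.04)
        out = mirror_scan(dup, del_)
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "del_risk_dup_protective"

    def test_same_direction_not_flagged(self):
        dup = mirror_frame("5", 1_000_000, 2.0, 0.03)
        del_ = mirror_frame("5", 1_020_000, 2.0, 0.04)
        assert len(mirror_scan(dup, del_)) == 0

    def test_nominal_filter_applies(self):
        dup = mirror_frame("5", 1_000_000, 0.5, 0.06)
        del_ = mirror_frame("5", 1_020_000, 2.0, 0.04)
        assert len(mirror_scan(dup, del_)) == 0

    def test_window_bound(self):
        dup = mirror_frame("5", 1_000_000, 0.5, 0.03)
        del_ = mirror_frame("5", 1_400_000, 2.0, 0.04)
        assert len(mirror_scan(dup, del_, window=300_000)) == 0


class TestScan:
    def test_planted_risk_breakpoints_rank_top(self, small_sim):
        from rarecnv.calls import qc_filter, filter_rare
        cs, _ = qc_filter(small_sim.callset)
        cs, _ = filter_rare(cs)
        bps = enumerate_breakpoints(cs)
        mat, _ = filter_rare_breakpoints(encode(cs, bps, "del_only"))
        res = scan(mat, region=("1", 19_000_000, 21_000_000))
        assert res.attrs["model"] == "del_only"
        best = res.nsmallest(3, "p_two_sided")
        # the planted locus [20.0, 20.1] Mb dominates the del-only scan
        assert ((best["pos"] >= 19_900_000) & (best["pos"] <= 20_200_000)).all()
        assert (best["OR"] > 1).all()
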