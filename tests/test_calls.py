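"""CNV data model: PLINK I/O, reciprocal overlap, frequency and filters."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rarecnv.calls import (CnvCall, CnvParseError, ValidationError,
                           cnv_frequency, call_frequencies, filter_rare,
                           qc_filter, read_plink_cnv, reciprocal_overlap,
                           write_plink_cnv)
from conftest import make_callset

HEADER = "FID IID CHR BP1 BP2 TYPE SCORE SITES\n"


class TestPlinkIO:
    def test_coordinates_convert_to_half_open(self):
        f = io.StringIO(HEADER + "F1 S1 2 50730001 50770000 1 20 17\n")
        cs = read_plink_cnv(f)
        row = cs.calls.iloc[0]
        assert (row.start, row.end) == (50730000, 50770000)
        assert row.cnv_type == "DEL"
        assert row.n_probes == 17
        assert row.end - row.start == 40_000

    @pytest.mark.parametrize("cn,expected", [(0, "DEL"), (1, "DEL"),
                                             (3, "DUP"), (4, "DUP")])
    def test_copy_number_collapses_to_del_dup(self, cn, expected):
        f = io.StringIO(HEADER + f"F1 S1 1 1001 60000 {cn} 5 12\n")
        assert read_plink_cnv(f).calls.iloc[0].cnv_type == expected

    def test_copy_neutral_rejected(self):
        f = io.StringIO(HEADER + "F1 S1 1 1001 60000 2 5 12\n")
        with pytest.raises(ValidationError, match="copy-neutral"):
            read_plink_cnv(f)

    def test_zero_length_rejected(self):
        f = io.StringIO(HEADER + "F1 S1 1 5000 5000 1 5 12\n")
        with pytest.raises(ValidationError, match="zero-length"):
            read_plink_cnv(f)

    def test_malformed_row_reports_line_number(self):
        f = io.StringIO(HEADER + "F1 S1 1 1001 60000 1 5 12\nF2 S2 1 oops\n")
        with pytest.raises(CnvParseError, match="line 3"):
            read_plink_cnv(f)

    def test_round_trip_is_exact(self, small_sim):
        buf1 = io.StringIO()
        write_plink_cnv(small_sim.callset, buf1)
        buf1.seek(0)
        cs = read_plink_cnv(buf1, samples=small_sim.callset.samples)
        buf2 = io.StringIO()
        write_plink_cnv(cs, buf2)
        assert buf1.getvalue() == buf2.getvalue()


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 100), (0, 100), 1.0),      # identity
        ((0, 100), (100, 200), 0.0),    # touching half-open intervals disjoint
        ((0, 100), (50, 150), 0.5),     # ov=50, min(50/100, 50/100)
        ((0, 1000), (0, 100), 0.1),     # nested: min over both denominators
    ])
    def test_hand_values(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_different_chromosomes_give_zero(self):
        a = CnvCall("S1", "1", 0, 100, "DEL", 1)
        b = CnvCall("S2", "2", 0, 100, "DEL", 1)
        assert reciprocal_overlap(a, b) == 0.0

    @given(st.integers(0, 10_000), st.integers(1, 10_000),
           st.integers(0, 10_000), st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = (s1, s1 + l1), (s2, s2 + l2)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0
        assert (ro == 1.0) == (a == b)


class TestFrequency:
    def test_singleton_counts_only_itself(self):
        ids = [f"S{i}" for i in range(1000)]
        cs = make_callset([("S0", "1", 0, 100_000, "DEL")], sample_ids=ids)
        call = next(cs.iter_calls())
        count, freq = cnv_frequency(call, cs)
        assert (count, freq) == (1, 0.001)

    def test_identical_calls_in_13_of_12458_samples_are_rare(self):
        # 13/12458 ~= 0.00104 < 0.01, so such a call stays in the rare set
        ids = [f"S{i}" for i in range(200)]
        rows = [(f"S{i}", "1", 0, 100_000, "DUP") for i in range(13)]
        cs = make_callset(rows, sample_ids=ids)
        count, freq = cnv_frequency(next(cs.iter_calls()), cs)
        assert count == 13
        assert freq == pytest.approx(13 / 200)
        assert 13 / 12458 == pytest.approx(0.00104, abs=5e-5)

    def test_overlap_below_threshold_not_counted(self):
        # reciprocal overlap 0.4: each call counts only its own carrier
        cs = make_callset([("S1", "1", 0, 100, "DEL"),
                           ("S2", "1", 60, 160, "DEL")])
        for call in cs.iter_calls():
            assert cnv_frequency(call, cs)[0] == 1

    def test_type_mismatch_not_counted(self):
        cs = make_callset([("S1", "1", 0, 100, "DEL"), ("S2", "1", 0, 100, "DUP")])
        for call in cs.iter_calls():
            assert cnv_frequency(call, cs)[0] == 1

    def test_vectorized_matches_scalar(self, small_sim):
        cs = small_sim.callset
        counts, freqs = call_frequencies(cs)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(cs), 25, replace=False):
            row = cs.calls.iloc[i]
            call = CnvCall(row.sample_id, row.chrom, row.start, row.end,
                           row.cnv_type, row.n_probes)
            assert cnv_frequency(call, cs)[0] == counts[i]

    def test_same_sample_counts_once(self):
        cs = make_callset([("S1", "1", 0, 100_000, "DEL"),
                           ("S1", "1", 1_000, 99_000, "DEL"),
                           ("S2", "1", 0, 100_000, "DEL")])
        count, _ = cnv_frequency(next(cs.iter_calls()), cs)
        assert count == 2  # two distinct samples, not three calls


class TestFilters:
    def test_qc_length_boundary_is_strict(self):
        cs = make_callset([("S1", "1", 0, 20_000, "DEL", 15),     # exactly 20 kb: out
                           ("S2", "1", 0, 25_000, "DEL", 9),      # probe rule: out
                           ("S3", "1", 0, 25_000, "DEL", 10)])    # boundary passes
        out, rec = qc_filter(cs)
        assert list(out.calls["sample_id"]) == ["S3"]
        assert (rec.n_before, rec.n_after, rec.removed) == (3, 1, 2)

    def test_rare_filter_is_strict_at_threshold(self):
        ids = [f"S{i}" for i in range(100)]
        common = [(f"S{i}", "1", 0, 100_000, "DEL") for i in range(5)]   # freq 0.05
        rare = [("S99", "2", 0, 100_000, "DEL")]                         # freq 0.01? no: 1/100=0.01
        cs = make_callset(common + rare, sample_ids=ids)
        out, _ = filter_rare(cs, max_freq=0.05)   # 0.05 exactly: removed (strict <)
        assert set(out.calls["sample_id"]) == {"S99"}
        out2, _ = filter_rare(cs, max_freq=0.01)  # 1/100 == 0.01: removed too
        assert len(out2) == 0

    def test_filters_idempotent(self, small_sim):
        cs, _ = qc_filter(small_sim.callset)
        cs2, rec = qc_filter(cs)
        assert rec.removed == 0 and cs2.calls.equals(cs.calls)
        cs3, _ = filter_rare(cs)
        cs4, rec2 = filter_rare(cs3)
        assert rec2.removed == 0 and cs4.calls.equals(cs3.calls)

    def test_empty_callset_passes_through(self):
        cs = make_callset([("S1", "1", 0, 100, "DEL")])
        empty = cs.subset(np.zeros(1, dtype=bool))
        out, rec = filter_rare(empty)
        assert len(out) == 0 and rec.n_before == 0


class TestInvariants:
    def test_zero_length_call_rejected(self):
        with pytest.raises(ValidationError):
            CnvCall("S1", "1", 100, 100, "DEL", 5)

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError, match="unknown samples"):
            make_callset([("S1", "1", 0, 100, "DEL")], sample_ids=["S2"])
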