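import pytest

from smsmap import (
    EvalConfig,
    MappingRecord,
    TruthRecord,
    agreement_matrix,
    classify_correct_read,
    count_correct_bases,
    count_sv_spanning,
    covers,
    real_metrics,
    simulated_metrics,
)
from smsmap.evaluation import truth_spanning_reads


def mapped(read_id="r", ref_id="g", strand="+", ref_start=0,
           cigar=((100, "M"),), read_length=None, score=0):
    cigar = [tuple(c) for c in cigar]
    if read_length is None:
        read_length = sum(n for n, op in cigar if op in "MIS")
    return MappingRecord(read_id=read_id, mapped=True,
                         read_length=read_length, ref_id=ref_id,
                         strand=strand, ref_start=ref_start, cigar=cigar,
                         score=score)


def unmapped(read_id="r", read_length=100):
    return MappingRecord(read_id=read_id, mapped=False,
                         read_length=read_length)


class TestClassifyCorrectRead:
    def test_overlap_at_boundary(self):
        truth = TruthRecord("r", "g", "+", 0, 100, "100=")
        rec = mapped(ref_start=5, cigar=[(95, "M"), (5, "S")])
        assert rec.read_length == 100
        # overlap [5,100) = 95 >= 0.9 * 100
        assert classify_correct_read(rec, truth)

    def test_below_boundary(self):
        truth = TruthRecord("r", "g", "+", 0, 100, "100=")
        rec = mapped(ref_start=11, cigar=[(89, "M"), (11, "S")])
        assert not classify_correct_read(rec, truth)

    def test_wrong_strand(self):
        truth = TruthRecord("r", "g", "-", 0, 100, "100=")
        assert not classify_correct_read(mapped(), truth)

    def test_wrong_reference(self):
        truth = TruthRecord("r", "g2", "+", 0, 100, "100=")
        assert not classify_correct_read(mapped(), truth)

    def test_unmapped(self):
        truth = TruthRecord("r", "g", "+", 0, 100, "100=")
        assert not classify_correct_read(unmapped(), truth)


class TestCountCorrectBases:
    def test_identical_alignment(self):
        truth = TruthRecord("r", "g", "+", 10, 110, "100=")
        rec = mapped(ref_start=10)
        assert count_correct_bases(rec, truth) == (100, 100)

    def test_shift_six_all_wrong(self):
        truth = TruthRecord("r", "g", "+", 10, 110, "100=")
        rec = mapped(ref_start=16)
        assert count_correct_bases(rec, truth) == (100, 0)

    def test_shift_five_inclusive(self):
        truth = TruthRecord("r", "g", "+", 10, 110, "100=")
        rec = mapped(ref_start=15)
        assert count_correct_bases(rec, truth) == (100, 100)

    def test_inserted_truth_bases_never_correct(self):
        truth = TruthRecord("r", "g", "+", 0, 50, "50=50I")
        rec = mapped(ref_start=0, cigar=[(100, "M")])
        assert count_correct_bases(rec, truth) == (100, 50)

    def test_length_mismatch_raises(self):
        truth = TruthRecord("r", "g", "+", 0, 50, "50=")
        rec = mapped(ref_start=0, cigar=[(100, "M")])
        with pytest.raises(ValueError):
            count_correct_bases(rec, truth)


class TestSimulatedMetrics:
    def test_half_correct_cfar(self):
        truths = [TruthRecord(f"r{i}", "g", "+", 0, 100, "100=")
                  for i in range(4)]
        records = [
            mapped("r0"), mapped("r1"),
            unmapped("r2"), unmapped("r3"),
        ]
        rep = simulated_metrics(records, truths)
        assert rep.cFAR == 50.0

    def test_perfect_alignment_is_100_everywhere(self):
        truths = [TruthRecord(f"r{i}", "g", "+", i * 200, i * 200 + 100,
                              "100=") for i in range(3)]
        records = [mapped(f"r{i}", ref_start=i * 200) for i in range(3)]
        rep = simulated_metrics(records, truths)
        assert rep.cFAR == rep.cFAB == rep.cACR == 100.0
        assert rep.sensitivity == rep.precision == 100.0

    def test_three_read_toy(self):
        """(M, M^c) = (100,100), (100,50), unaligned ->
        cFAR 66.67, cFAB 75, cACR 75."""
        truths = [
            TruthRecord("r1", "g", "+", 0, 100, "100="),
            TruthRecord("r2", "g", "+", 200, 300, "50=50D50I"),
            TruthRecord("r3", "g", "+", 400, 500, "100="),
        ]
        records = [
            mapped("r1", ref_start=0),
            mapped("r2", ref_start=200),  # 100M: 50 correct, 50 on inserts
            unmapped("r3"),
        ]
        rep = simulated_metrics(records, truths)
        assert rep.cFAR == pytest.approx(66.67, abs=0.005)
        assert rep.cFAB == 75.0
        assert rep.cACR == 75.0

    def test_missing_truth_errors(self):
        with pytest.raises(ValueError, match="no truth"):
            simulated_metrics([mapped("rX")], [])

    def test_identity_cfar_times_n(self):
        truths = [TruthRecord(f"r{i}", "g", "+", 0, 100, "100=")
                  for i in range(7)]
        records = [mapped(f"r{i}") for i in range(5)] + \
                  [unmapped(f"r{i}") for i in range(5, 7)]
        rep = simulated_metrics(records, truths)
        assert rep.cFAR * rep.n_reads / 100 == pytest.approx(rep.n_correct)


class TestRealMetrics:
    def test_all_fully_matched(self):
        records = [mapped(f"r{i}") for i in range(3)]
        rep = real_metrics(records)
        assert rep.FAR == rep.FAB == rep.ACR == 100.0
        assert rep.ACR_std == 0.0

    def test_half_aligned_far(self):
        records = [mapped("r0"), mapped("r1"),
                   unmapped("r2"), unmapped("r3")]
        assert real_metrics(records).FAR == 50.0

    def test_toy_fab_acr(self):
        records = [
            mapped("r0", cigar=[(90, "M"), (10, "S")]),
            mapped("r1", cigar=[(100, "M")]),
            unmapped("r2"), unmapped("r3"),
        ]
        rep = real_metrics(records)
        assert rep.FAB == 47.5  # 190 / 400
        assert rep.ACR == pytest.approx(95.0)

    def test_acr_std_population(self):
        records = [
            mapped("r0", cigar=[(80, "M"), (20, "S")]),
            mapped("r1", cigar=[(100, "M")]),
        ]
        rep = real_metrics(records)
        # ratios 0.8 and 1.0 -> population std 0.1, on the ratio scale
        assert rep.ACR_std == pytest.approx(0.1)


class TestCovers:
    def test_identical_mutual(self):
        x = mapped("r", ref_start=0)
        y = mapped("r", ref_start=0)
        assert covers(x, y) and covers(y, x)

    def test_boundary_inclusive(self):
        x = mapped("r", ref_start=0, cigar=[(1000, "M")])
        y = mapped("r", ref_start=50, cigar=[(900, "M")])
        assert covers(x, y)  # 900/900
        assert covers(y, x)  # 900/1000 = 0.9 exactly, inclusive

    def test_disjoint(self):
        x = mapped("r", ref_start=0, cigar=[(100, "M")])
        y = mapped("r", ref_start=500, cigar=[(100, "M")])
        assert not covers(x, y) and not covers(y, x)

    def test_agreement_matrix_diagonal_and_asymmetry(self):
        a = {f"r{i}": mapped(f"r{i}", ref_start=0, cigar=[(1000, "M")])
             for i in range(4)}
        b = {f"r{i}": mapped(f"r{i}", ref_start=100, cigar=[(800, "M")])
             for i in range(4)}
        matrix = agreement_matrix({"A": list(a.values()),
                                   "B": list(b.values())})
        assert matrix["A"]["A"] == 100.0
        assert matrix["B"]["B"] == 100.0
        assert matrix["A"]["B"] == 100.0  # A covers all of B's intervals
        assert matrix["B"]["A"] == 0.0  # 800/1000 < 0.9


class TestSvSpanning:
    def test_spans_interior_breakpoint(self):
        rec = mapped("r", ref_start=100, cigar=[(4900, "M")])
        assert count_sv_spanning([rec], [2000]) == 1

    def test_half_open_end_does_not_span(self):
        rec = mapped("r", ref_start=100, cigar=[(4900, "M")])  # [100, 5000)
        assert count_sv_spanning([rec], [5000]) == 0

    def test_no_mapped_reads(self):
        assert count_sv_spanning([unmapped("r")], [2000]) == 0

    def test_truth_restriction(self):
        rec = mapped("r", ref_start=100, cigar=[(4900, "M")])
        truth_far = [TruthRecord("r", "g", "+", 6000, 7000, "1000=")]
        truth_near = [TruthRecord("r", "g", "+", 100, 5000, "4900=")]
        assert count_sv_spanning([rec], [2000], truth_far) == 0
        assert count_sv_spanning([rec], [2000], truth_near) == 1

    def test_truth_spanning_reads_strict(self):
        truths = [
            TruthRecord("a", "g", "+", 0, 100, "100="),
            TruthRecord("b", "g", "+", 100, 200, "100="),
        ]
        assert [t.read_id for t in truth_spanning_reads(truths, [100])] == []
        assert [t.read_id for t in truth_spanning_reads(truths, [150])] == ["b"]


class TestDoubleEntryOracle:
    def test_naive_recomputation_matches(self):
        """Independent per-read bookkeeping reproduces simulated_metrics."""
        truths = [
            TruthRecord("r1", "g", "+", 0, 100, "100="),
            TruthRecord("r2", "g", "+", 200, 300, "40=10D10I50="),
            TruthRecord("r3", "g", "-", 400, 500, "100="),
            TruthRecord("r4", "g", "+", 600, 700, "100="),
        ]
        records = [
            mapped("r1", ref_start=0),
            mapped("r2", ref_start=203, cigar=[(100, "M")]),
            mapped("r3", strand="-", ref_start=400),
            unmapped("r4"),
        ]
        rep = simulated_metrics(records, truths)

        cfg = EvalConfig()
        per_read = []
        for rec, truth in zip(records, truths):
            ok = classify_correct_read(rec, truth, cfg)
            m, mc = count_correct_bases(rec, truth, cfg)
            per_read.append((ok, m, mc, rec.read_length))
        n_correct = sum(ok for ok, *_ in per_read)
        assert rep.cFAR == pytest.approx(100 * n_correct / len(records))
        m_total = sum(m for ok, m, _, _ in per_read if ok)
        mc_total = sum(mc for ok, _, mc, _ in per_read if ok)
        assert rep.cFAB == pytest.approx(100 * mc_total / m_total)
        ratios = [mc / m for ok, m, mc, _ in per_read if ok and m]
        assert rep.cACR == pytest.approx(100 * sum(ratios) / n_correct)
        all_mc = sum(mc for _, _, mc, _ in per_read)
        assert rep.sensitivity == pytest.approx(
            100 * all_mc / sum(L for *_, L in per_read)
        )
        assert rep.precision == pytest.approx(
            100 * all_mc / sum(m for _, m, _, _ in per_read)
        )
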