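"""Mapping evaluation: truth-based and truth-free metrics, alignment
agreement between mappers, and structural-variant spanning counts.

Truth-based (simulated data): a read is correctly aligned when it maps
to the right reference and strand and its aligned reference interval
overlaps the truth interval by at least p = p_coeff * read length;
a matched base (read base in an M op) is correct when its reference
coordinate lies within base_tolerance of the truth coordinate of that
read base. cFAR / cFAB / cACR, sensitivity and precision follow.

Truth-free (real data): FAR / FAB / ACR over aligned reads, where a
read's matched bases are its M-op bases and its coverage ratio divides
by the read length; ACR_std is the population standard deviation of the
per-read ratios (reported on the ratio scale, not percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io_formats import MappingRecord, TruthRecord


@dataclass(frozen=True)
class EvalConfig:
    p_coeff: float = 0.9
    base_tolerance: int = 5
    cover_fraction: float = 0.9


@dataclass
class EvaluationReport:
    n_reads: int = 0
    n_correct: int = 0
    n_aligned: int = 0
    cFAR: float | None = None
    cFAB: float | None = None
    cACR: float | None = None
    sensitivity: float | None = None
    precision: float | None = None
    FAR: float | None = None
    FAB: float | None = None
    ACR: float | None = None
    ACR_std: float | None = None

    def as_dict(self) -> dict[str, float | int | None]:
        return dict(self.__dict__)


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_correct_read(record: MappingRecord, truth: TruthRecord,
                          config: EvalConfig = EvalConfig()) -> bool:
    if not record.mapped:
        return False
    if record.ref_id != truth.ref_id or record.strand != truth.strand:
        return False
    p = config.p_coeff * record.read_length
    overlap = _interval_overlap(
        record.aligned_interval(), (truth.ref_start, truth.ref_end)
    )
    return overlap >= p


def _truth_base_coords(truth: TruthRecord) -> list[int | None]:
    """Reference coordinate of each read base (forward orientation).

    Inserted read bases get None.
    """
    coords: list[int | None] = []
    ref = truth.ref_start
    for n, op in truth.ops():
        if op in "=X":
            coords.extend(range(ref, ref + n))
            ref += n
        elif op == "I":
            coords.extend([None] * n)
        elif op == "D":
            ref += n
    return coords


def _record_base_coords(record: MappingRecord) -> list[int | None]:
    """Reference coordinate of each read base from the CIGAR walk.

    The walk is in forward-genome orientation (minus-strand records
    store their CIGAR that way already). I and S bases get None.
    """
    coords: list[int | None] = []
    ref = record.ref_start
    for n, op in record.cigar:
        if op == "M":
            coords.extend(range(ref, ref + n))
            ref += n
        elif op in "IS":
            coords.extend([None] * n)
        elif op == "D":
            ref += n
    return coords


def count_correct_bases(record: MappingRecord, truth: TruthRecord,
                        config: EvalConfig = EvalConfig()
                        ) -> tuple[int, int]:
    """(matched bases, correct matched bases) for one mapped read."""
    if not record.mapped:
        return 0, 0
    got = _record_base_coords(record)
    want = _truth_base_coords(truth)
    if len(got) != len(want):
        raise ValueError(
            f"{record.read_id!r}: CIGAR walks {len(got)} read bases but "
            f"truth script has {len(want)}"
        )
    matched = 0
    correct = 0
    tol = config.base_tolerance
    for g, w in zip(got, want):
        if g is None:
            continue
        matched += 1
        if w is not None and abs(g - w) <= tol:
            correct += 1
    return matched, correct


def simulated_metrics(records: Sequence[MappingRecord],
                      truths: Sequence[TruthRecord],
                      config: EvalConfig = EvalConfig()
                      ) -> EvaluationReport:
    """cFAR/cFAB/cACR plus base sensitivity and precision.

    Every record must have a truth with the same read id.
    """
    truth_by_id = {t.read_id: t for t in truths}
    n = len(records)
    n_correct = 0
    sum_correct_over_correct_reads = 0  # numerator of cFAB
    sum_matched_over_correct_reads = 0  # M in cFAB / denominators
    ratio_sum = 0.0
    total_read_bases = 0
    total_mapped_bases = 0
    total_correct_bases = 0
    for rec in records:
        truth = truth_by_id.get(rec.read_id)
        if truth is None:
            raise ValueError(f"no truth record for read {rec.read_id!r}")
        total_read_bases += rec.read_length
        if not rec.mapped:
            continue
        m_tau, m_tau_c = count_correct_bases(rec, truth, config)
        total_mapped_bases += m_tau
        total_correct_bases += m_tau_c
        if classify_correct_read(rec, truth, config):
            n_correct += 1
            sum_correct_over_correct_reads += m_tau_c
            sum_matched_over_correct_reads += m_tau
            if m_tau:
                ratio_sum += m_tau_c / m_tau
    report = EvaluationReport(n_reads=n, n_correct=n_correct)
    if n:
        report.cFAR = 100.0 * n_correct / n
    if sum_matched_over_correct_reads:
        report.cFAB = (100.0 * sum_correct_over_correct_reads
                       / sum_matched_over_correct_reads)
    if n_correct:
        report.cACR = 100.0 * ratio_sum / n_correct
    if total_read_bases:
        report.sensitivity = 100.0 * total_correct_bases / total_read_bases
    if total_mapped_bases:
        report.precision = 100.0 * total_correct_bases / total_mapped_bases
    return report


def real_metrics(records: Sequence[MappingRecord],
                 read_lengths: dict[str, int] | None = None
                 ) -> EvaluationReport:
    """FAR/FAB/ACR without truth; read lengths default to the records'."""
    n = len(records)
    lengths = read_lengths or {}
    total_bases = 0
    matched_sum = 0
    ratios: list[float] = []
    n_aligned = 0
    for rec in records:
        read_len = lengths.get(rec.read_id, rec.read_length)
        total_bases += read_len
        if not rec.mapped:
            continue
        n_aligned += 1
        m_a = sum(k for k, op in rec.cigar if op == "M")
        matched_sum += m_a
        ratios.append(m_a / read_len if read_len else 0.0)
    report = EvaluationReport(n_reads=n, n_aligned=n_aligned)
    if n:
        report.FAR = 100.0 * n_aligned / n
    if total_bases:
        report.FAB = 100.0 * matched_sum / total_bases
    if n_aligned:
        mean = sum(ratios) / n_aligned
        report.ACR = 100.0 * mean
        report.ACR_std = math.sqrt(
            sum((r - mean) ** 2 for r in ratios) / n_aligned
        )
    return report


def covers(x: MappingRecord, y: MappingRecord,
           cover_fraction: float = 0.9) -> bool:
    """x covers y when their overlap is >= cover_fraction of y's interval."""
    if not (x.mapped and y.mapped) or x.ref_id != y.ref_id:
        return False
    y_span = y.ref_span()
    if y_span == 0:
        return False
    overlap = _interval_overlap(x.aligned_interval(), y.aligned_interval())
    return overlap >= cover_fraction * y_span


def agreement_matrix(record_sets: dict[str, Sequence[MappingRecord]],
                     cover_fraction: float = 0.9
                     ) -> dict[str, dict[str, float | None]]:
    """matrix[A][B] = % of B's alignments (reads aligned by both A and
    B) that A's alignments cover. Asymmetric by construction; the
    diagonal is 100 (every alignment covers itself). Pairs sharing no
    aligned read get None.
    """
    by_method = {
        name: {r.read_id: r for r in recs if r.mapped}
        for name, recs in record_sets.items()
    }
    matrix: dict[str, dict[str, float | None]] = {}
    for a, a_recs in by_method.items():
        matrix[a] = {}
        for b, b_recs in by_method.items():
            shared = sorted(set(a_recs) & set(b_recs))
            if not shared:
                matrix[a][b] = None
                continue
            covered = sum(
                covers(a_recs[rid], b_recs[rid], cover_fraction)
                for rid in shared
            )
            matrix[a][b] = 100.0 * covered / len(shared)
    return matrix


def count_sv_spanning(records: Sequence[MappingRecord],
                      breakpoints: Sequence[int],
                      truths: Sequence[TruthRecord] | None = None) -> int:
    """Number of mapped reads whose alignment brackets a breakpoint.

    A read counts once when its alignment's reference start < bp and
    end > bp for at least one breakpoint; when ``truths`` is given, only
    breakpoints strictly inside the read's truth interval qualify.
    """
    truth_by_id = {t.read_id: t for t in truths} if truths else None
    count = 0
    for rec in records:
        if not rec.mapped:
            continue
        start, end = rec.aligned_interval()
        eligible = breakpoints
        if truth_by_id is not None:
            truth = truth_by_id.get(rec.read_id)
            if truth is None:
                continue
            eligible = [
                bp for bp in breakpoints
                if truth.ref_start < bp < truth.ref_end
            ]
        if any(start < bp < end for bp in eligible):
            count += 1
    return count


def truth_spanning_reads(truths: Sequence[TruthRecord],
                         breakpoints: Sequence[int]) -> list[TruthRecord]:
    """Truth records whose interval strictly contains a breakpoint."""
    return [
        t for t in truths
        if any(t.ref_start < bp < t.ref_end for bp in breakpoints)
    ]
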