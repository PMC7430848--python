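"""Orchestration: index -> anchor -> split -> banded align -> SAM.

One best record per read. Anchoring runs on the read and its reverse
complement against the forward index of every reference sequence; the
highest credibility wins (ties: forward strand, then first reference in
file order, then the anchor tie-breaks). Minus-strand reads are aligned
as their reverse complement, so CIGARs always walk the forward genome.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import Sequence

from .anchor_locator import LocatorConfig, StartAnchor, locate_start
from .banded_aligner import (
    BandParams,
    align_banded_low_column,
    combine_alignments,
    split_segments,
)
from .io_formats import (
    MappingRecord,
    SequenceRecord,
    read_sequences,
    reverse_complement,
    write_sam,
)
from .reference_index import (
    DEFAULT_K,
    DEFAULT_OCCURRENCE_CAP,
    WordIndex,
    build_index,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapperConfig:
    k: int = DEFAULT_K
    word_step: int = 1
    tolerance_coefficient: float = 0.2
    alpha: float = 0.1
    match: int = 2
    mismatch: int = -2
    gap: int = 2
    occurrence_cap: int | None = DEFAULT_OCCURRENCE_CAP
    threads: int = 1

    def locator(self) -> LocatorConfig:
        return LocatorConfig(self.word_step, self.tolerance_coefficient)

    def band(self) -> BandParams:
        return BandParams(alpha=self.alpha, match=self.match,
                          mismatch=self.mismatch, gap=self.gap)


def build_indexes(references: Sequence[SequenceRecord],
                  config: MapperConfig) -> list[WordIndex]:
    return [
        build_index(ref, k=config.k, occurrence_cap=config.occurrence_cap)
        for ref in references
    ]


def map_read(read: SequenceRecord,
             indexes: Sequence[WordIndex],
             references: Sequence[SequenceRecord],
             config: MapperConfig = MapperConfig()) -> MappingRecord:
    """Map one read; unmapped (never an error) when no anchor exists."""
    unmapped = MappingRecord(
        read_id=read.id, mapped=False, read_length=len(read),
        seq=read.bases, quality=read.quality,
    )
    if len(read) < config.k:
        return unmapped

    loc_cfg = config.locator()
    rc = reverse_complement(read.bases)
    best: tuple[tuple, StartAnchor, int, str] | None = None
    for ref_i, index in enumerate(indexes):
        for strand, seq in (("+", read.bases), ("-", rc)):
            anchor = locate_start(seq, index, loc_cfg, strand)
            if anchor is None:
                continue
            # maximize credibility; ties: forward strand, file order,
            # then the locator's own (position, offset) tie-break
            key = (
                -anchor.credibility,
                0 if strand == "+" else 1,
                ref_i,
                anchor.genome_position,
                anchor.read_offset,
            )
            if best is None or key < best[0]:
                best = (key, anchor, ref_i, seq)
    if best is None:
        return unmapped

    _, anchor, ref_i, oriented = best
    reference = references[ref_i]
    band_params = config.band()
    b = band_params.bandwidth(len(read))

    split = split_segments(len(read), anchor, len(reference),
                           band_params.slope)
    r_u = oriented[split.r_u[0] : split.r_u[1]]
    r_d = oriented[split.r_d[0] : split.r_d[1]]
    g_u = reference.bases[split.g_u[0] : split.g_u[1]]
    g_d = reference.bases[split.g_d[0] : split.g_d[1]]

    up = align_banded_low_column(r_u[::-1], g_u[::-1], band_params, band=b)
    down = align_banded_low_column(r_d, g_d, band_params, band=b)
    ref_start, cigar, score = combine_alignments(
        up, down, split, anchor, len(reference)
    )
    record = MappingRecord(
        read_id=read.id,
        mapped=True,
        read_length=len(read),
        ref_id=reference.id,
        strand=anchor.strand,
        ref_start=ref_start,
        cigar=cigar,
        score=score,
        seq=read.bases,
        quality=read.quality,
        credibility=anchor.credibility,
    )
    record.validate(len(reference))
    return record


def map_records(reads: Sequence[SequenceRecord],
                references: Sequence[SequenceRecord],
                config: MapperConfig = MapperConfig(),
                indexes: Sequence[WordIndex] | None = None
                ) -> list[MappingRecord]:
    if indexes is None:
        indexes = build_indexes(references, config)
    out = []
    for i, read in enumerate(reads, 1):
        out.append(map_read(read, indexes, references, config))
        if i % 1000 == 0:
            logger.info("mapped %d/%d reads", i, len(reads))
    return out


def map_all(reads_path: str, ref_path: str,
            config: MapperConfig = MapperConfig(),
            out_sam_path: str = "out.sam") -> dict[str, int]:
    """Map a reads file against a reference FASTA; write SAM in read order.

    Returns summary counts. Output content is independent of
    ``config.threads`` (threading affects wall time only; the current
    implementation is serial).
    """
    references = read_sequences(ref_path, "fasta")
    if not references:
        raise ValueError(f"no reference sequences in {ref_path}")
    reads = read_sequences(reads_path, "auto")
    records = map_records(reads, references, config)
    write_sam(records, references, out_sam_path)
    mapped = sum(r.mapped for r in records)
    summary = {"reads": len(records), "mapped": mapped,
               "unmapped": len(records) - mapped}
    print(
        f"[smsmap] {summary['mapped']}/{summary['reads']} reads mapped",
        file=sys.stderr,
    )
    return summary
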