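"""Readers/writers for FASTA, FASTQ, SAM and the truth sidecar table.

All coordinates inside the package are 0-based half-open; the single
conversion to SAM's 1-based POS happens in :func:`write_sam`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: CIGAR ops that consume read bases / reference bases.
READ_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MD=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class ParseError(ValueError):
    """Malformed input file; message carries file path and line number."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One FASTA/FASTQ record; bases uppercase over {A,C,G,T,N}."""

    id: str
    bases: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class TruthRecord:
    """Ground-truth placement of one simulated read.

    ``edit_script`` is a CIGAR-like string over ``=`` (match run), ``X``
    (substitution), ``I`` (base inserted into the read) and ``D`` (genome
    base deleted from the read), always written in forward-genome
    orientation (for minus-strand reads it describes the
    reverse-complemented read).
    """

    read_id: str
    ref_id: str
    strand: str
    ref_start: int
    ref_end: int
    edit_script: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"truth {self.read_id!r}: empty/inverted interval "
                f"[{self.ref_start}, {self.ref_end})"
            )
        ref_span = sum(
            n for n, op in parse_cigar(self.edit_script) if op in "=XD"
        )
        if ref_span != self.ref_end - self.ref_start:
            raise ValueError(
                f"truth {self.read_id!r}: edit script consumes {ref_span} "
                f"reference bases but interval has "
                f"{self.ref_end - self.ref_start}"
            )

    @property
    def read_length(self) -> int:
        return sum(n for n, op in parse_cigar(self.edit_script) if op in "=XI")

    def ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.edit_script)


@dataclass
class MappingRecord:
    """One end-to-end alignment (or an unmapped read).

    ``cigar`` uses M/I/D/S; ``seq`` holds the read in its original
    orientation (the SAM writer reverse-complements minus-strand reads).
    """

    read_id: str
    mapped: bool
    read_length: int
    ref_id: str = "*"
    strand: str = "+"
    ref_start: int = 0
    cigar: list[tuple[int, str]] = field(default_factory=list)
    score: int = 0
    seq: str = ""
    quality: list[int] | None = None
    credibility: int = 0

    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in REF_OPS)

    def ref_end(self) -> int:
        return self.ref_start + self.ref_span()

    def aligned_interval(self) -> tuple[int, int]:
        return self.ref_start, self.ref_end()

    def validate(self, ref_length: int | None = None) -> None:
        """Check CIGAR conservation; raise ValueError when violated."""
        if not self.mapped:
            return
        read_sum = sum(n for n, op in self.cigar if op in READ_OPS)
        if read_sum != self.read_length:
            raise ValueError(
                f"{self.read_id!r}: CIGAR consumes {read_sum} read bases, "
                f"read has {self.read_length}"
            )
        if self.ref_start < 0:
            raise ValueError(f"{self.read_id!r}: negative ref_start")
        if ref_length is not None and self.ref_end() > ref_length:
            raise ValueError(
                f"{self.read_id!r}: alignment end {self.ref_end()} exceeds "
                f"reference length {ref_length}"
            )


def cigar_to_string(cigar: Sequence[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cigar) if cigar else "*"


def parse_cigar(text: str) -> list[tuple[int, str]]:
    if text in ("", "*"):
        return []
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(text)]
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR string {text!r}")
    return ops


def merge_cigar(ops: Iterable[tuple[int, str]]) -> list[tuple[int, str]]:
    """Merge adjacent same-op runs and drop zero-length runs."""
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if n == 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return merged


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _check_bases(raw: str, path: str, lineno: int) -> str:
    bases = raw.upper()
    bad = set(bases) - VALID_BASES
    if bad:
        raise ParseError(
            f"{path}:{lineno}: invalid base(s) {sorted(bad)!r}"
        )
    return bases


def _read_fasta(lines: list[str], path: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        records.append(SequenceRecord(name, "".join(chunks)))

    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise ParseError(f"{path}:{lineno}: empty FASTA header")
            chunks = []
        else:
            if name is None:
                raise ParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            chunks.append(_check_bases(line, path, lineno))
    flush()
    return records


def _read_fastq(lines: list[str], path: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    stripped = [ln.rstrip("\n") for ln in lines]
    while stripped and stripped[-1] == "":
        stripped.pop()
    if len(stripped) % 4 != 0:
        raise ParseError(
            f"{path}:{len(stripped)}: truncated FASTQ (records are 4 lines)"
        )
    for i in range(0, len(stripped), 4):
        lineno = i + 1
        head, seq, plus, qual = stripped[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' header")
        name = head[1:].split()[0] if len(head) > 1 else ""
        if not name:
            raise ParseError(f"{path}:{lineno}: empty FASTQ header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: expected '+' separator")
        bases = _check_bases(seq, path, lineno + 1)
        if len(qual) != len(bases):
            raise ParseError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(bases)}"
            )
        quality = [ord(c) - 33 for c in qual]
        if any(q < 0 for q in quality):
            raise ParseError(
                f"{path}:{lineno + 3}: quality characters below '!'"
            )
        records.append(SequenceRecord(name, bases, quality))
    return records


def read_sequences(path: str | Path, format: str = "auto") -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into SequenceRecords, in file order."""
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    if format == "auto":
        first = next((ln for ln in lines if ln.strip()), "")
        format = "fastq" if first.startswith("@") else "fasta"
    if format == "fasta":
        return _read_fasta(lines, str(path))
    if format == "fastq":
        return _read_fastq(lines, str(path))
    raise ValueError(f"unknown format {format!r}")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [30] * len(rec)
            fh.write(
                f"@{rec.id}\n{rec.bases}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(records: Iterable[MappingRecord],
              references: Sequence[SequenceRecord],
              path: str | Path) -> None:
    """Write mapping records as SAM v1.6.

    Minus-strand records get flag 0x10 with SEQ reverse-complemented;
    unmapped records get flag 0x4, POS 0 and CIGAR '*'. The alignment
    score goes into AS:i and the anchor credibility into XC:i; MAPQ is
    255 (unavailable).
    """
    ref_lengths = {r.id: len(r) for r in references}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for rec in records:
            if rec.mapped:
                if rec.ref_id not in ref_lengths:
                    raise ValueError(
                        f"{rec.read_id!r}: unknown reference {rec.ref_id!r}"
                    )
                rec.validate(ref_lengths[rec.ref_id])
                flag = 16 if rec.strand == "-" else 0
                seq = (reverse_complement(rec.seq) if rec.strand == "-"
                       else rec.seq) or "*"
                qual = rec.quality
                if qual is not None and rec.strand == "-":
                    qual = qual[::-1]
                qstr = ("".join(chr(q + 33) for q in qual)
                        if qual is not None else "*")
                fh.write(
                    "\t".join(
                        [
                            rec.read_id,
                            str(flag),
                            rec.ref_id,
                            str(rec.ref_start + 1),
                            "255",
                            cigar_to_string(rec.cigar),
                            "*", "0", "0",
                            seq,
                            qstr,
                            f"AS:i:{rec.score}",
                            f"XC:i:{rec.credibility}",
                        ]
                    )
                    + "\n"
                )
            else:
                seq = rec.seq or "*"
                qstr = ("".join(chr(q + 33) for q in rec.quality)
                        if rec.quality is not None else "*")
                fh.write(
                    "\t".join(
                        [rec.read_id, "4", "*", "0", "0", "*",
                         "*", "0", "0", seq, qstr]
                    )
                    + "\n"
                )


_PYSAM_OPS = "MIDNSHP=X"


def read_sam(path: str | Path) -> list[MappingRecord]:
    """Parse a SAM file (this tool's or another mapper's) into records."""
    records: list[MappingRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            seq = aln.query_sequence or ""
            if aln.is_unmapped:
                records.append(
                    MappingRecord(
                        read_id=aln.query_name,
                        mapped=False,
                        read_length=len(seq),
                        seq=seq,
                    )
                )
                continue
            cigar = [(n, _PYSAM_OPS[code]) for code, n in aln.cigartuples]
            strand = "-" if aln.is_reverse else "+"
            # store the read in its original orientation
            if strand == "-":
                seq = reverse_complement(seq)
            read_len = sum(n for n, op in cigar if op in READ_OPS)
            records.append(
                MappingRecord(
                    read_id=aln.query_name,
                    mapped=True,
                    read_length=read_len,
                    ref_id=aln.reference_name,
                    strand=strand,
                    ref_start=aln.reference_start,
                    cigar=cigar,
                    score=(aln.get_tag("AS") if aln.has_tag("AS") else 0),
                    seq=seq,
                    credibility=(aln.get_tag("XC") if aln.has_tag("XC") else 0),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Truth sidecar (TSV): read_id, ref_id, strand, ref_start, ref_end, edit_script
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "read_id\tref_id\tstrand\tref_start\tref_end\tedit_script"


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + _TRUTH_HEADER + "\n")
        for rec in records:
            fh.write(
                f"{rec.read_id}\t{rec.ref_id}\t{rec.strand}\t"
                f"{rec.ref_start}\t{rec.ref_end}\t{rec.edit_script}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            rec = TruthRecord(
                read_id=fields[0],
                ref_id=fields[1],
                strand=fields[2],
                ref_start=int(fields[3]),
                ref_end=int(fields[4]),
                edit_script=fields[5],
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


# Breakpoint sidecar (TSV): sv_id, sv_type, position (variant-genome coord)

def write_breakpoints(rows: Iterable[tuple[str, str, int]],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sv_id\tsv_type\tposition\n")
        for sv_id, sv_type, pos in rows:
            fh.write(f"{sv_id}\t{sv_type}\t{pos}\n")


def read_breakpoints(path: str | Path) -> list[tuple[str, str, int]]:
    rows: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields"
            )
        rows.append((fields[0], fields[1], int(fields[2])))
    return rows
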