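"""Synthetic genomes, structural variants and error-bearing long reads.

Stands in for an external long-read simulator so every test is
self-contained: each simulated read carries an exact truth record whose
edit script reconstructs the read from its genome template. The error
model is a flat per-base rate with a configurable substitution /
insertion / deletion mix, indel-dominated by default as is typical of
single-molecule sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord, TruthRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_ERROR_MIX = (0.2, 0.5, 0.3)  # substitution, insertion, deletion


@dataclass(frozen=True)
class SimulatorConfig:
    genome_length: int = 100_000
    gc_content: float = 0.5
    depth: float = 10.0
    read_length_mean: float = 10_000.0
    read_length_sd: float = 1_000.0
    error_rate: float = 0.0
    error_mix: tuple[float, float, float] = DEFAULT_ERROR_MIX
    min_read_length: int = 50
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class SVSpec:
    """One structural variant on the base genome.

    ``breakpoints`` is filled by :func:`inject_svs` with the junction
    coordinate(s) on the variant genome.
    """

    sv_type: str  # insertion | deletion | inversion
    position: int
    length: int
    breakpoints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sv_type not in ("insertion", "deletion", "inversion"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.length <= 0 or self.position < 0:
            raise ValueError("SV needs position >= 0 and length > 0")

    def base_interval(self) -> tuple[int, int]:
        """Footprint on the base genome (insertions are a point)."""
        if self.sv_type == "insertion":
            return (self.position, self.position)
        return (self.position, self.position + self.length)


def generate_genome(length: int, gc_content: float = 0.5,
                    seed: int | np.random.Generator = 0) -> SequenceRecord:
    """Random genome with i.i.d. bases, P(G or C) = gc_content."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = _rng(seed)
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    codes = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return SequenceRecord("genome", codes.tobytes().decode("ascii"))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def inject_svs(genome: SequenceRecord, svs: list[SVSpec],
               seed: int | np.random.Generator = 0
               ) -> tuple[SequenceRecord, list[SVSpec]]:
    """Apply SVs to a base genome; return variant genome and resolved SVs.

    Insertions splice random donor sequence before ``position``;
    deletions remove [position, position+length); inversions
    reverse-complement the interval in place. Returned SVSpecs carry
    variant-genome breakpoint coordinates. Overlapping SVs are rejected.
    """
    rng = _rng(seed)
    for sv in svs:
        lo, hi = sv.base_interval()
        if hi > len(genome):
            raise ValueError(f"SV {sv.sv_type}@{sv.position} exceeds genome")
    ordered = sorted(svs, key=lambda s: s.base_interval())
    for a, b in zip(ordered, ordered[1:]):
        if a.base_interval()[1] > b.base_interval()[0]:
            raise ValueError(
                f"overlapping SVs at {a.position} and {b.position}"
            )

    parts: list[str] = []
    resolved: list[SVSpec] = []
    cursor = 0  # on base genome
    out_len = 0
    for sv in ordered:
        lo, hi = sv.base_interval()
        parts.append(genome.bases[cursor:lo])
        out_len += lo - cursor
        if sv.sv_type == "insertion":
            donor = _random_seq(rng, sv.length)
            parts.append(donor)
            bps = [out_len, out_len + sv.length]
            out_len += sv.length
        elif sv.sv_type == "deletion":
            bps = [out_len]
        else:  # inversion
            parts.append(reverse_complement(genome.bases[lo:hi]))
            bps = [out_len, out_len + (hi - lo)]
            out_len += hi - lo
        resolved.append(
            SVSpec(sv.sv_type, sv.position, sv.length, breakpoints=bps)
        )
        cursor = hi
    parts.append(genome.bases[cursor:])
    out_len += len(genome) - cursor
    variant = SequenceRecord(genome.id + "_sv", "".join(parts))
    assert len(variant) == out_len
    return variant, resolved


def _apply_errors(template: str, rng: np.random.Generator,
                  error_rate: float,
                  error_mix: tuple[float, float, float]
                  ) -> tuple[str, str]:
    """Corrupt a template; return (read sequence, edit script).

    The script is over ``=``/``X``/``I``/``D`` in template orientation:
    substitutions emit a base different from the template's, insertions
    add a random base before the current template base.
    """
    if error_rate == 0:
        return template, f"{len(template)}="
    p_sub, p_ins, p_del = error_mix
    t = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    n = len(t)
    err = rng.random(n) < error_rate
    kinds = np.zeros(n, dtype=np.int8)  # 0 none, 1 sub, 2 ins, 3 del
    n_err = int(err.sum())
    if n_err:
        kinds[err] = rng.choice([1, 2, 3], size=n_err,
                                p=[p_sub, p_ins, p_del])

    # pre-draw replacement/inserted bases vectorized (N templates get a
    # random base on substitution, like any non-identical draw)
    t_idx = np.searchsorted(_BASES, t)  # ACGT are sorted ASCII codes
    t_idx[t == ord("N")] = 0
    sub_base = _BASES[(t_idx + rng.integers(1, 4, size=n)) % 4]
    ins_base = _BASES[rng.integers(0, 4, size=n)]

    out = bytearray()
    script: list[str] = []
    run_eq = 0

    def flush() -> None:
        nonlocal run_eq
        if run_eq:
            script.append(f"{run_eq}=")
            run_eq = 0

    for i in range(n):
        kind = kinds[i]
        if kind == 0:
            out.append(t[i])
            run_eq += 1
        elif kind == 1:
            out.append(sub_base[i])
            flush()
            script.append("1X")
        elif kind == 2:
            out.append(ins_base[i])
            out.append(t[i])
            flush()
            script.append("1I")
            run_eq = 1
        else:
            flush()
            script.append("1D")
    flush()
    return out.decode("ascii"), _compact_script(script)


def _compact_script(parts: list[str]) -> str:
    """Merge adjacent same-op runs of a piecewise script."""
    merged: list[tuple[int, str]] = []
    for part in parts:
        n, op = int(part[:-1]), part[-1]
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


def apply_edit_script(template: str, script_ops: list[tuple[int, str]],
                      read: str) -> str:
    """Independent reconstruction of a read from template + script.

    For ``X`` and ``I`` ops the emitted bases are taken from the read
    itself (the script records only structure); used to verify truth
    consistency.
    """
    out: list[str] = []
    ti = ri = 0
    for n, op in script_ops:
        if op == "=":
            out.append(template[ti : ti + n])
            ti += n
            ri += n
        elif op == "X":
            out.append(read[ri : ri + n])
            ti += n
            ri += n
        elif op == "I":
            out.append(read[ri : ri + n])
            ri += n
        elif op == "D":
            ti += n
        else:
            raise ValueError(f"bad edit op {op!r}")
    return "".join(out)


def simulate_reads(genome: SequenceRecord,
                   config: SimulatorConfig
                   ) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Draw strand-random reads from uniform template placements.

    Truth edit scripts are in forward-genome orientation: for a minus
    strand read the script describes reverse_complement(read).
    """
    L = len(genome)
    if L <= config.read_length_mean:
        raise ValueError("genome shorter than mean read length")
    rng = _rng(config.seed)
    n_reads = max(1, round(config.depth * L / config.read_length_mean))
    lo = max(config.min_read_length, 1)

    reads: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for idx in range(n_reads):
        tlen = 0
        while not lo <= tlen <= L:
            tlen = int(round(rng.normal(config.read_length_mean,
                                        config.read_length_sd)))
        start = int(rng.integers(0, L - tlen + 1))
        template = genome.bases[start : start + tlen]
        fwd_read, script = _apply_errors(
            template, rng, config.error_rate, config.error_mix
        )
        strand = "+" if rng.random() < 0.5 else "-"
        bases = fwd_read if strand == "+" else reverse_complement(fwd_read)
        read_id = f"read{idx:06d}"
        reads.append(
            SequenceRecord(read_id, bases,
                           [config.base_quality] * len(bases))
        )
        truths.append(
            TruthRecord(
                read_id=read_id,
                ref_id=genome.id,
                strand=strand,
                ref_start=start,
                ref_end=start + tlen,
                edit_script=script,
            )
        )
    return reads, truths
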