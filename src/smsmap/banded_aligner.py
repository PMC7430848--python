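"""Banded global-in-read alignment on a low-column score matrix.

The anchor splits read and genome into upstream/downstream segment
pairs. Each pair is aligned with a banded dynamic program whose matrix
stores only the 2b+1 in-band columns per row, so storage is
Theta((n+1)*(2b+1)) regardless of genome segment length. The read
segment must be consumed entirely; genome beyond the best last-row cell
is free (the extra slope*|r| genome slack is deliberate and unpenalized).

Band geometry: row u's stored columns start at max(u - b, 0) (clamped to
the genome segment length), i.e. the band is centered on the unit
diagonal with half-width b = ceil(alpha * full read length). Centering
on the slope-1.2 rectangle diagonal instead (:func:`band_start_column`)
would lose any alignment path whose read segment exceeds half the read:
a path consuming ~1 genome base per read base sits 0.2*u below that
center line and leaves the band once 0.2*u > b. The 1.2 factor is kept
where it belongs — sizing the genome segment so deletion-rich paths
have slack to consume extra genome.

Moves inside a cell prefer diagonal, then up (read base vs gap), then
left (genome base vs gap); the final-cell tie goes to the earliest
genome column. Upstream segments are aligned reversed with the same
routine and their ops reversed when combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anchor_locator import StartAnchor
from .io_formats import merge_cigar

DEFAULT_ALPHA = 0.1
DEFAULT_SLOPE = 1.2

# traceback move codes
INVALID, DIAG, UP, LEFT, START = 0, 1, 2, 3, 4

_N = ord("N")


@dataclass(frozen=True)
class BandParams:
    alpha: float = DEFAULT_ALPHA
    slope: float = DEFAULT_SLOPE
    match: int = 2
    mismatch: int = -2
    gap: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap <= 0:
            raise ValueError("need match > 0, mismatch < 0, gap > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def bandwidth(self, read_length: int) -> int:
        """b = ceil(alpha * full read length), at least 1."""
        return max(1, math.ceil(self.alpha * read_length))


@dataclass(frozen=True)
class SegmentSplit:
    """Read/genome intervals upstream and downstream of the anchor."""

    r_u: tuple[int, int]
    r_d: tuple[int, int]
    g_u: tuple[int, int]
    g_d: tuple[int, int]


@dataclass
class LowColumnMatrix:
    """Filled DP state: (n+1) x (2b+1) scores plus traceback moves."""

    scores: np.ndarray
    moves: np.ndarray
    sci: np.ndarray
    bandwidth: int
    genome_length: int


@dataclass
class SegmentAlignment:
    score: int
    ops: list[tuple[int, str]] = field(default_factory=list)
    genome_consumed: int = 0


def band_start_column(u: int, b: int, slope: float = DEFAULT_SLOPE) -> int:
    """Band start along the rectangle diagonal: max(floor(slope*u - b), 0).

    This is the column-extraction rule for a band drawn around the main
    diagonal of the n x ceil(slope*n) segment rectangle. The DP matrix
    itself uses unit-diagonal centering (see module docstring): with
    free genome suffix the true path consumes roughly one genome base
    per read base, and this rule would strand it below the band for
    segments longer than half the read.
    """
    return max(math.floor(slope * u - b), 0)


def row_band_start(u: int, b: int, genome_length: int) -> int:
    """Starting genome column actually used for row u's band."""
    return min(max(u - b, 0), genome_length)


def split_segments(read_length: int, anchor: StartAnchor, genome_length: int,
                   slope: float = DEFAULT_SLOPE) -> SegmentSplit:
    """Split read and genome at the anchor.

    Genome segments take ceil(slope * read-segment length) bases, clipped
    at the genome boundaries.
    """
    i = anchor.read_offset
    g = anchor.genome_position
    if not 0 <= i <= read_length:
        raise ValueError("anchor read offset outside read")
    if not 0 <= g <= genome_length:
        raise ValueError("anchor genome position outside genome")
    len_ru, len_rd = i, read_length - i
    g_u_start = max(0, g - math.ceil(slope * len_ru))
    g_d_end = min(genome_length, g + math.ceil(slope * len_rd))
    return SegmentSplit(
        r_u=(0, i), r_d=(i, read_length),
        g_u=(g_u_start, g), g_d=(g, g_d_end),
    )


def fill_low_column_matrix(r_seg: str, g_seg: str,
                           params: BandParams = BandParams(),
                           band: int | None = None) -> LowColumnMatrix:
    """Fill the banded DP matrix for one segment pair.

    ``band`` overrides the half-width b (the pipeline passes
    ceil(alpha * full read length)). Row band starts follow
    :func:`row_band_start`: unit-diagonal centering, clamped to the
    genome segment length so boundary-truncated segments keep a
    reachable terminal column.
    """
    n, m = len(r_seg), len(g_seg)
    b = band if band is not None else params.bandwidth(n)
    W = 2 * b + 1
    d = params.gap
    sci = np.minimum(np.maximum(np.arange(n + 1) - b, 0), m)
    F = np.full((n + 1, W), -np.inf)
    moves = np.zeros((n + 1, W), dtype=np.int8)
    cols = np.arange(W)

    lim = min(W - 1, m)  # row 0: genome prefix gap-penalized within band
    F[0, : lim + 1] = -d * cols[: lim + 1].astype(float)
    moves[0, 0] = START
    moves[0, 1 : lim + 1] = LEFT

    if n == 0:
        return LowColumnMatrix(F, moves, sci, b, m)

    g_codes = np.frombuffer(g_seg.encode("ascii"), dtype=np.uint8)
    r_codes = np.frombuffer(r_seg.encode("ascii"), dtype=np.uint8)

    for u in range(1, n + 1):
        shift = int(sci[u] - sci[u - 1])
        prev = F[u - 1]
        up = _shifted(prev, shift)
        diag = _shifted(prev, shift - 1)

        c = cols + sci[u]
        valid = c <= m

        sub = np.full(W, -np.inf)
        has_g = (c >= 1) & valid
        rb = int(r_codes[u - 1])
        if has_g.any():
            gb = g_codes[c[has_g] - 1]
            eq = (gb == rb) & (gb != _N) & (rb != _N)
            sub[has_g] = np.where(eq, params.match, params.mismatch)

        diag_tot = diag + sub
        up_tot = up - d
        du = np.maximum(diag_tot, up_tot)
        mv = np.where(diag_tot >= up_tot, DIAG, UP).astype(np.int8)

        # left moves within the row are a running max along the band
        ramp = d * cols.astype(float)
        run = np.maximum.accumulate(du + ramp)
        row = run - ramp
        from_left = run > du + ramp
        row = np.where(valid, row, -np.inf)
        mv = np.where(from_left, LEFT, mv).astype(np.int8)
        mv[~(np.isfinite(row))] = INVALID
        F[u] = row
        moves[u] = mv

    return LowColumnMatrix(F, moves, sci, b, m)


def _shifted(prev: np.ndarray, t: int) -> np.ndarray:
    """out[v] = prev[v + t], padding out-of-range with -inf."""
    W = len(prev)
    out = np.full(W, -np.inf)
    if t >= 0:
        if t < W:
            out[: W - t] = prev[t:]
    else:
        out[-t:] = prev[: W + t]
    return out


def align_banded_low_column(r_seg: str, g_seg: str,
                            params: BandParams = BandParams(),
                            band: int | None = None) -> SegmentAlignment:
    """Align a read segment to a prefix of its genome segment.

    The read is consumed entirely (ops over M/I/D); the reported score
    is the best last-row cell, genome beyond it unpenalized. Empty read
    segment yields an empty alignment with score 0.
    """
    if len(r_seg) == 0:
        return SegmentAlignment(score=0)
    mat = fill_low_column_matrix(r_seg, g_seg, params, band)
    return traceback(mat)


def traceback(mat: LowColumnMatrix) -> SegmentAlignment:
    F, moves, sci = mat.scores, mat.moves, mat.sci
    n = F.shape[0] - 1
    last = F[n]
    v = int(np.argmax(last))
    if not np.isfinite(last[v]):
        raise RuntimeError("no valid cell in final row; band unusable")
    score = int(last[v])
    genome_consumed = v + int(sci[n])

    ops_rev: list[str] = []
    u = n
    while True:
        mv = int(moves[u, v])
        if mv == START:
            break
        if mv == DIAG:
            ops_rev.append("M")
            v = v + int(sci[u] - sci[u - 1]) - 1
            u -= 1
        elif mv == UP:
            ops_rev.append("I")
            v = v + int(sci[u] - sci[u - 1])
            u -= 1
        elif mv == LEFT:
            ops_rev.append("D")
            v -= 1
        else:
            raise RuntimeError("traceback entered an invalid cell")

    runs: list[tuple[int, str]] = []
    for op in reversed(ops_rev):
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + 1, op)
        else:
            runs.append((1, op))
    return SegmentAlignment(score=score, ops=runs,
                            genome_consumed=genome_consumed)


def combine_alignments(upstream: SegmentAlignment,
                       downstream: SegmentAlignment,
                       split: SegmentSplit,
                       anchor: StartAnchor,
                       genome_length: int
                       ) -> tuple[int, list[tuple[int, str]], int]:
    """Join the two segment alignments into (ref_start, cigar, score).

    ``upstream`` was computed on reversed(r_u) vs reversed(g_u), so its
    ops reverse back into forward orientation. Read bases that ran past
    a genome boundary (alignment flush against position 0 or the genome
    end, trailing into I ops) become soft clips.
    """
    ref_start = anchor.genome_position - upstream.genome_consumed
    if ref_start < 0:
        raise RuntimeError("upstream alignment consumed past genome start")
    cigar = merge_cigar(list(reversed(upstream.ops)) + list(downstream.ops))
    score = upstream.score + downstream.score

    if cigar and cigar[0][1] == "I" and ref_start == 0:
        cigar[0] = (cigar[0][0], "S")
    if cigar and cigar[-1][1] == "I":
        ref_end = ref_start + sum(n for n, op in cigar if op in "MD")
        if ref_end == genome_length:
            cigar[-1] = (cigar[-1][0], "S")
    return ref_start, cigar, score
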