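"""Anchor selection by diagonal credibility voting.

Every sampled read word contributes its exact genome matches as
"modified positions" o = p - i (genome position minus read offset),
constant along a gap-free alignment diagonal. The credibility of a
candidate is the number of modified positions — its own included —
within the error-tolerant window L(r) = tolerance_coefficient * read
length. The maximizer fixes the alignment starting position on read
and genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_index import WordIndex

DEFAULT_TOLERANCE_COEFFICIENT = 0.2


@dataclass(frozen=True)
class LocatorConfig:
    word_step: int = 1
    tolerance_coefficient: float = DEFAULT_TOLERANCE_COEFFICIENT

    def __post_init__(self) -> None:
        if self.word_step < 1:
            raise ValueError("word_step must be >= 1")
        if self.tolerance_coefficient <= 0:
            raise ValueError("tolerance_coefficient must be > 0")


@dataclass
class WordMatchSet:
    """Genome occurrences of the read word starting at ``read_offset``."""

    read_offset: int
    positions: np.ndarray
    modified_positions: np.ndarray

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CandidateScore:
    read_offset: int
    list_index: int
    modified_position: int
    credibility: int


@dataclass(frozen=True)
class StartAnchor:
    read_offset: int
    genome_position: int
    strand: str
    credibility: int


def collect_word_matches(read, index: WordIndex,
                         config: LocatorConfig = LocatorConfig()
                         ) -> list[WordMatchSet]:
    """One WordMatchSet per sampled read offset with >= 1 unmasked hit.

    Words containing N are skipped. A read shorter than k yields [].
    """
    seq = read.bases if hasattr(read, "bases") else read
    k = index.k
    out: list[WordMatchSet] = []
    for i in range(0, len(seq) - k + 1, config.word_step):
        word = seq[i : i + k]
        if "N" in word:
            continue
        positions = index.locate(word)
        if len(positions) == 0:
            continue
        out.append(
            WordMatchSet(
                read_offset=i,
                positions=positions,
                modified_positions=positions - i,
            )
        )
    return out


def credibility_scores(match_sets: list[WordMatchSet], read_length: int,
                       config: LocatorConfig = LocatorConfig()
                       ) -> list[CandidateScore]:
    """Credibility of every candidate (read offset, occurrence) pair.

    The window half-width L(r) = tolerance_coefficient * read_length is
    used as a real number; counting is done once over the sorted pool of
    all modified positions, which is exactly the double sum over all
    match sets (self-term included).
    """
    if not match_sets:
        return []
    tol = config.tolerance_coefficient * read_length
    pool = np.sort(
        np.concatenate([ms.modified_positions for ms in match_sets])
    )
    out: list[CandidateScore] = []
    for ms in match_sets:
        mods = ms.modified_positions
        lo = np.searchsorted(pool, mods - tol, side="left")
        hi = np.searchsorted(pool, mods + tol, side="right")
        counts = hi - lo
        for l, (o, s) in enumerate(zip(mods.tolist(), counts.tolist())):
            out.append(CandidateScore(ms.read_offset, l, o, s))
    return out


def select_anchor(candidates: list[CandidateScore],
                  strand: str = "+") -> StartAnchor | None:
    """Highest-credibility candidate as a StartAnchor; None when empty.

    Ties break toward the smaller genome position, then the smaller
    read offset, for determinism.
    """
    best: CandidateScore | None = None
    best_key: tuple[int, int, int] | None = None
    for cand in candidates:
        genome_pos = cand.modified_position + cand.read_offset
        key = (-cand.credibility, genome_pos, cand.read_offset)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None:
        return None
    return StartAnchor(
        read_offset=best.read_offset,
        genome_position=best.modified_position + best.read_offset,
        strand=strand,
        credibility=best.credibility,
    )


def locate_start(read, index: WordIndex,
                 config: LocatorConfig = LocatorConfig(),
                 strand: str = "+") -> StartAnchor | None:
    """Convenience: collect matches, score, select — for one strand."""
    match_sets = collect_word_matches(read, index, config)
    seq = read.bases if hasattr(read, "bases") else read
    candidates = credibility_scores(match_sets, len(seq), config)
    return select_anchor(candidates, strand)
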