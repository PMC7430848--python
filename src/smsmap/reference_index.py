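"""Exact-match word index over the forward strand of one reference sequence.

A plain hash table of k-mer -> sorted positions satisfies the locate
contract at the scales this package targets; compressed full-text
indexing is deliberately out of scope. Words occurring more often than
``occurrence_cap`` are masked: they stay in the table but locate to
nothing, bounding anchor collection on repeats.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_K = 14
DEFAULT_OCCURRENCE_CAP = 512

_MAGIC = "smsmap-word-index"
_VERSION = 1


class IndexLoadError(RuntimeError):
    pass


@dataclass
class WordIndex:
    k: int
    ref_id: str
    ref_length: int
    occurrence_cap: int
    table: dict[str, np.ndarray] = field(repr=False)
    masked: frozenset[str] = field(default_factory=frozenset, repr=False)

    def locate(self, word: str) -> np.ndarray:
        """All forward-strand occurrence positions of ``word``, ascending.

        Empty for absent or masked words. ``word`` must have length k.
        """
        if len(word) != self.k:
            raise ValueError(
                f"query word length {len(word)} != index k {self.k}"
            )
        hits = self.table.get(word)
        if hits is None:
            return np.empty(0, dtype=np.int64)
        return hits


def locate_word(index: WordIndex, word: str) -> np.ndarray:
    return index.locate(word)


def build_index(reference, k: int = DEFAULT_K,
                occurrence_cap: int | None = DEFAULT_OCCURRENCE_CAP) -> WordIndex:
    """Index every N-free k-length word of ``reference``.

    ``occurrence_cap=None`` disables masking.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = reference.bases
    if len(seq) < k:
        raise ValueError(
            f"reference {reference.id!r} shorter ({len(seq)}) than k ({k})"
        )

    positions: dict[str, list[int]] = {}
    # positions of N bases let us skip words overlapping them
    next_n = _next_n_table(seq)
    i = 0
    last = len(seq) - k
    while i <= last:
        n_at = next_n[i]
        if n_at is not None and n_at < i + k:
            i = n_at + 1  # no N-free word can start before past this N
            continue
        positions.setdefault(seq[i : i + k], []).append(i)
        i += 1

    table: dict[str, np.ndarray] = {}
    masked: set[str] = set()
    for word, pos in positions.items():
        if occurrence_cap is not None and len(pos) > occurrence_cap:
            masked.add(word)
            table[word] = np.empty(0, dtype=np.int64)
        else:
            table[word] = np.asarray(pos, dtype=np.int64)
    return WordIndex(
        k=k,
        ref_id=reference.id,
        ref_length=len(seq),
        occurrence_cap=occurrence_cap if occurrence_cap is not None else -1,
        table=table,
        masked=frozenset(masked),
    )


def _next_n_table(seq: str) -> list[int | None]:
    """next_n[i] = smallest j >= i with seq[j] == 'N', or None."""
    out: list[int | None] = [None] * (len(seq) + 1)
    nxt: int | None = None
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


def save_index(index: WordIndex, path: str | Path) -> None:
    payload = {
        "magic": _MAGIC,
        "version": _VERSION,
        "k": index.k,
        "ref_id": index.ref_id,
        "ref_length": index.ref_length,
        "occurrence_cap": index.occurrence_cap,
        "table": {w: p.tolist() for w, p in index.table.items()},
        "masked": sorted(index.masked),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_index(path: str | Path) -> WordIndex:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (OSError, pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise IndexLoadError(f"cannot read index file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
        raise IndexLoadError(f"{path} is not a word-index file")
    if payload.get("version") != _VERSION:
        raise IndexLoadError(
            f"{path}: unsupported index version {payload.get('version')!r}"
        )
    return WordIndex(
        k=payload["k"],
        ref_id=payload["ref_id"],
        ref_length=payload["ref_length"],
        occurrence_cap=payload["occurrence_cap"],
        table={
            w: np.asarray(p, dtype=np.int64)
            for w, p in payload["table"].items()
        },
        masked=frozenset(payload["masked"]),
    )
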