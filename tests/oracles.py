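"""Independent reference implementations used only by tests.

Deliberately naive (full matrices, double loops, exhaustive
enumeration) and written without reusing the package's DP or scoring
code paths.
"""

from __future__ import annotations

NEG = float("-inf")


def _sub(a: str, b: str, match: int, mismatch: int) -> int:
    if a == b and a != "N" and b != "N":
        return match
    return mismatch


def full_dp_matrix(r: str, g: str, match: int = 2, mismatch: int = -2,
                   gap: int = 2) -> list[list[float]]:
    """Unbanded global-in-read DP table F[u][c] (genome prefix alignment)."""
    n, m = len(r), len(g)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for c in range(m + 1):
        F[0][c] = -gap * c
    for u in range(1, n + 1):
        for c in range(m + 1):
            best = F[u - 1][c] - gap
            if c > 0:
                best = max(
                    best,
                    F[u][c - 1] - gap,
                    F[u - 1][c - 1] + _sub(r[u - 1], g[c - 1],
                                          match, mismatch),
                )
            F[u][c] = best
    return F


def full_dp_score(r: str, g: str, match: int = 2, mismatch: int = -2,
                  gap: int = 2) -> float:
    """Best score aligning all of r to any prefix of g (suffix free)."""
    return max(full_dp_matrix(r, g, match, mismatch, gap)[len(r)])


def banded_full_matrix(r: str, g: str, b: int, match: int = 2,
                       mismatch: int = -2, gap: int = 2
                       ) -> list[list[float]]:
    """Full-size matrix with out-of-band cells fixed at -inf.

    The band of row u is [start(u), start(u) + 2b] with
    start(u) = min(max(u - b, 0), len(g)).
    """
    n, m = len(r), len(g)

    def start(u: int) -> int:
        return min(max(u - b, 0), m)

    def in_band(u: int, c: int) -> bool:
        return start(u) <= c <= start(u) + 2 * b

    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for c in range(m + 1):
        if in_band(0, c):
            F[0][c] = -gap * c
    for u in range(1, n + 1):
        for c in range(m + 1):
            if not in_band(u, c):
                continue
            best = F[u - 1][c] - gap
            if c > 0:
                best = max(
                    best,
                    F[u][c - 1] - gap,
                    F[u - 1][c - 1] + _sub(r[u - 1], g[c - 1],
                                          match, mismatch),
                )
            F[u][c] = best
    return F


def enumerate_alignments(r: str, g: str, match: int = 2, mismatch: int = -2,
                         gap: int = 2) -> tuple[int, set[str]]:
    """Exhaustive enumeration of all read-consuming alignments.

    Returns (best score, set of op strings like 'MIMM' achieving it).
    The genome suffix after the alignment end is free. Only usable for
    tiny inputs.
    """
    best: dict[str, int] = {}

    def rec(i: int, j: int, score: int, ops: str) -> None:
        if i == len(r):
            if ops not in best or best[ops] < score:
                best[ops] = score
            return
        if j < len(g):
            rec(i + 1, j + 1,
                score + _sub(r[i], g[j], match, mismatch), ops + "M")
            rec(i, j + 1, score - gap, ops + "D")
        rec(i + 1, j, score - gap, ops + "I")

    rec(0, 0, 0, "")
    top = max(best.values())
    return top, {ops for ops, s in best.items() if s == top}


def credibility_double_loop(match_sets, read_length: int,
                            tol_coeff: float = 0.2) -> dict[tuple[int, int], int]:
    """Literal double-sum credibility: for every candidate (i, l), count
    all (j, k) pairs with |o_j^k - o_i^l| <= tol_coeff * read_length."""
    tol = tol_coeff * read_length
    pool = [
        int(o) for ms in match_sets for o in ms.modified_positions
    ]
    out: dict[tuple[int, int], int] = {}
    for ms in match_sets:
        for l, o in enumerate(int(x) for x in ms.modified_positions):
            out[(ms.read_offset, l)] = sum(
                1 for o2 in pool if abs(o2 - o) <= tol
            )
    return out


def find_all_occurrences(genome: str, word: str) -> list[int]:
    """Linear-scan substring search (index oracle)."""
    return [
        i for i in range(len(genome) - len(word) + 1)
        if genome[i : i + len(word)] == word
    ]
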