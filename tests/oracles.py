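"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most direct method available
(exhaustive recursion, ancestor-set intersection, per-site scans) and never
shares code with the module it checks.
"""

from __future__ import annotations

from functools import lru_cache


def oracle_global_affine_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive recursion over the
    three-state (match / gap-in-b / gap-in-a) space; a gap of length L
    costs gap_open + L * gap_extend."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "D" else gap_open + gap_extend
            options.append(-cost + best(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend if state == "I" else gap_open + gap_extend
            options.append(-cost + best(i, j + 1, "I"))
        return max(options)

    result = best(0, 0, "start")
    best.cache_clear()
    return result


def oracle_lca(parent_of: dict[str, str | None], a: str, b: str) -> str:
    """LCA by ancestor-set intersection on a parent map."""
    ancestors = []
    node: str | None = a
    while node is not None:
        ancestors.append(node)
        node = parent_of[node]
    ancestor_set = set(ancestors)
    node = b
    while node is not None:
        if node in ancestor_set:
            return node
        node = parent_of[node]
    raise ValueError("no common ancestor")


def oracle_weighted_fraction(
    verdict_similar: list[bool], missense_counts: list[int]
) -> float:
    """Independent recount of the mutation-weighted conservation fraction."""
    total = sum(missense_counts)
    if total == 0:
        return 0.0
    carried = sum(c for ok, c in zip(verdict_similar, missense_counts) if ok)
    return carried / total


def oracle_sites_in_regions(
    positions: list[int], intervals: list[tuple[int, int]]
) -> int:
    """Per-site inclusive interval membership scan."""
    n = 0
    for p in positions:
        if any(s <= p <= e for s, e in intervals):
            n += 1
    return n


def oracle_scan_best(sequence_scores: list[list[float]], profile_len: int) -> tuple[int, float]:
    """Best ungapped window by explicit re-summation.

    ``sequence_scores[i][k]`` is the score of sequence position i against
    profile column k (precomputed by the caller from first principles).
    """
    n = len(sequence_scores)
    best = (0, float("-inf"))
    for off in range(n - profile_len + 1):
        total = sum(sequence_scores[off + k][k] for k in range(profile_len))
        if total > best[1]:
            best = (off, total)
    return best
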