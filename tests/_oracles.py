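"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by direct enumeration, deliberately
avoiding the vectorized algorithms in the package.
"""

from __future__ import annotations

from functools import lru_cache

from ssrkit.dna import VALID_BASES, is_primitive

MIN_UNITS = {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}


def brute_force_ssrs(seq: str, min_units: dict[int, int] | None = None):
    """Every maximal perfect SSR tract by direct per-position enumeration.

    A tract anchored at i with period p is reported when the position is a
    run start (no same-period match immediately to the left), the leading
    p bases form a primitive ACGT motif, and the number of complete motif
    copies reaches the period's minimum. Returns (start, end, motif) tuples
    sorted by (start, period).
    """
    min_units = min_units or MIN_UNITS
    n = len(seq)
    out = []
    for p, need in min_units.items():
        for i in range(n - p * need + 1):
            if i > 0 and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                continue  # not a run start
            motif = seq[i : i + p]
            if set(motif) - VALID_BASES or not is_primitive(motif):
                continue
            k = 0
            while seq[i + k * p : i + (k + 1) * p] == motif:
                k += 1
            if k >= need:
                out.append((i, i + k * p, motif))
    return sorted(out, key=lambda t: (t[0], len(t[2])))


def window_alignments(pattern: str, window: str, max_gaps: int, anchor: int):
    """All (mismatches, gaps) outcomes of globally aligning pattern to window.

    Gaps are counted per inserted/deleted base and are forbidden (as are
    mismatches) within the last ``anchor`` pattern positions. Plain
    recursion over (pattern index, window index, gaps used).
    """
    m, n = len(pattern), len(window)
    results: set[tuple[int, int]] = set()

    def go(i: int, j: int, g: int, mm: int) -> None:
        if i == m and j == n:
            results.add((mm, g))
            return
        anchored = i >= m - anchor
        if i < m and j < n:
            if pattern[i] == window[j]:
                go(i + 1, j + 1, g, mm)
            elif not anchored:
                go(i + 1, j + 1, g, mm + 1)
        if g < max_gaps and not anchored:
            if i < m:
                go(i + 1, j, g + 1, mm)
            if j < n:
                go(i, j + 1, g + 1, mm)

    go(0, 0, 0, 0)
    return results


def brute_force_candidate_ends(
    pattern: str, text: str, max_mm: int, max_gaps: int, anchor: int
):
    """Minimum candidate cost per alignment end position, by enumeration.

    For every end position and every window length reachable under the gap
    budget, enumerates all global alignments and keeps the cheapest
    (cost, gaps, start) whose cost stays within max_mm + 2*max_gaps.
    Mirrors the site-search contract; the search itself is exhaustive.
    """
    m = len(pattern)
    bound = max_mm + 2 * max_gaps
    best: dict[int, tuple[int, int, int]] = {}  # end -> (cost, gaps, start)
    for end in range(1, len(text) + 1):
        for wlen in range(max(1, m - max_gaps), min(end, m + max_gaps) + 1):
            start = end - wlen
            for mm, g in window_alignments(
                pattern, text[start:end], max_gaps, anchor
            ):
                cost = mm + 2 * g
                if cost > bound:
                    continue
                cand = (cost, g, start)
                if end not in best or cand < best[end]:
                    best[end] = cand
    return best


def nussinov_count(seq: str, min_loop: int = 3) -> int:
    """Maximum number of base pairs by memoized recursion (independent of
    the iterative implementation)."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        top = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in pairs:
                left = best(i, k - 1) if k > i else 0
                top = max(top, left + 1 + best(k + 1, j - 1))
        return top

    result = best(0, len(seq) - 1)
    best.cache_clear()
    return result


def hamming_hits(pattern: str, text: str, max_mm: int):
    """All (offset, mismatches) of an ungapped full-length slide."""
    m = len(pattern)
    out = []
    for off in range(len(text) - m + 1):
        mm = sum(1 for a, b in zip(pattern, text[off : off + m]) if a != b)
        if mm <= max_mm:
            out.append((off, mm))
    return out
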