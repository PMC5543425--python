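"""Independent oracles used by the tests; none share code with the package."""

from __future__ import annotations

import functools
import sys


def oracle_best_chain_score(a: str, b: str, min_len: int) -> int:
    """Exhaustive best co-linear gapless chain score (blocks >= min_len)."""
    sys.setrecursionlimit(200000)

    @functools.lru_cache(maxsize=None)
    def run(i: int, j: int) -> int:
        r = 0
        while i + r < len(a) and j + r < len(b) and a[i + r] == b[j + r]:
            r += 1
        return r

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i >= len(a) or j >= len(b):
            return 0
        best = max(f(i + 1, j), f(i, j + 1))
        for ln in range(min_len, run(i, j) + 1):
            best = max(best, ln + f(i + ln, j + ln))
        return best

    return f(0, 0)


def oracle_best_local_match(a: str, b: str) -> tuple[int, int, int]:
    """Longest exact gapless match by full enumeration (ties: smallest q, t)."""
    best = (0, 0, 0)
    for q in range(len(a)):
        for t in range(len(b)):
            ln = 0
            while q + ln < len(a) and t + ln < len(b) and a[q + ln] == b[t + ln]:
                ln += 1
            if ln > best[2]:
                best = (q, t, ln)
    return best


def admits_interval_chain(transcript: str, reference: str) -> bool:
    """Can ``transcript`` be spelled as in-order non-overlapping intervals of
    ``reference``?  Equivalent to a character-subsequence check, done by an
    independent two-pointer DP."""
    i = 0
    for c in reference:
        if i < len(transcript) and transcript[i] == c:
            i += 1
    return i == len(transcript)


def boundary_set(paths: dict[str, list[tuple[int, int]]], length: int) -> set[int]:
    """Brute-force block boundary enumeration from path endpoints."""
    b = {0, length}
    for path in paths.values():
        for s, e in path:
            b.update((s, e))
    return b
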