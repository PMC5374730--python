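"""Independent recursive Smith-Waterman oracle used to cross-check the DP.

Deliberately implemented as a plain recursion over the local-alignment
recurrence with its own substitution rules (no shared code with the package
beyond the tie conventions it must reproduce): the best score ending at
(i, j) is max(0, end(i-1, j-1) + s, end(i-1, j) + gap, end(i, j-1) + gap),
the overall optimum is the row-major-first maximal cell, and traceback
prefers DIAG over UP over LEFT.  Only suitable for short sequences.
"""

from __future__ import annotations

from typing import Dict, List, Tuple


def subst(read_base: str, ref_base: str, match: int, mismatch: int, mode: str) -> int:
    if read_base == "N" or ref_base == "N":
        return mismatch
    if read_base == ref_base:
        return match
    if mode == "c_to_t" and read_base == "T" and ref_base == "C":
        return match
    if mode == "g_to_a" and read_base == "A" and ref_base == "G":
        return match
    return mismatch


def best_ending_at(
    read: str,
    window: str,
    i: int,
    j: int,
    match: int,
    mismatch: int,
    gap: int,
    mode: str,
    memo: Dict[Tuple[int, int], int] = None,
) -> int:
    if memo is None:
        memo = {}
    if i == 0 or j == 0:
        return 0
    if (i, j) in memo:
        return memo[(i, j)]
    diag = best_ending_at(read, window, i - 1, j - 1, match, mismatch, gap, mode, memo) + subst(
        read[i - 1], window[j - 1], match, mismatch, mode
    )
    up = best_ending_at(read, window, i - 1, j, match, mismatch, gap, mode, memo) + gap
    left = best_ending_at(read, window, i, j - 1, match, mismatch, gap, mode, memo) + gap
    value = max(0, diag, up, left)
    memo[(i, j)] = value
    return value


def oracle_align(
    read: str, window: str, match: int, mismatch: int, gap: int, mode: str
):
    """Best local score, its row-major-first end cell, and the traceback pairs.

    Returns (score, (end_i, end_j), pairs, (read_start, window_start)) with
    pairs listed left to right like the package's Alignment.pairs.
    """
    memo: Dict[Tuple[int, int], int] = {}
    n, m = len(read), len(window)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = best_ending_at(read, window, i, j, match, mismatch, gap, mode, memo)
            if v > best:
                best, bi, bj = v, i, j

    pairs: List[Tuple[str, str]] = []
    i, j = bi, bj
    while True:
        v = best_ending_at(read, window, i, j, match, mismatch, gap, mode, memo)
        if v == 0:
            break
        diag = best_ending_at(read, window, i - 1, j - 1, match, mismatch, gap, mode, memo) + subst(
            read[i - 1], window[j - 1], match, mismatch, mode
        )
        up = best_ending_at(read, window, i - 1, j, match, mismatch, gap, mode, memo) + gap
        left = best_ending_at(read, window, i, j - 1, match, mismatch, gap, mode, memo) + gap
        if v == diag:
            pairs.append((read[i - 1], window[j - 1]))
            i, j = i - 1, j - 1
        elif v == up:
            pairs.append((read[i - 1], "-"))
            i -= 1
        else:
            assert v == left
            pairs.append(("-", window[j - 1]))
            j -= 1
    pairs.reverse()
    return best, (bi, bj), pairs, (i, j)
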