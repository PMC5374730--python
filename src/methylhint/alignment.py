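"""Windowed Smith-Waterman local alignment with bisulfite-aware scoring.

Bisulfite treatment converts unmethylated cytosines to uracil, read as T
after amplification.  A read from the converted forward strand therefore
legitimately shows T where the reference has C, and a read representing the
opposite strand shows A where the forward reference has G.  Penalizing those
positions as mismatches is what makes naive mapping of treated reads
inaccurate, so the substitution function here is *asymmetric*: under the
``c_to_t`` mode a read-T against a reference-C scores as a match while a
read-C against a reference-T stays a mismatch (and mirrored for ``g_to_a``).

The dynamic program records, for every cell, which predecessor attained the
maximum (the direction pointer), so traceback is a pure pointer walk with no
re-evaluation of the recurrence.  Tie order is DIAG > UP > LEFT > STOP and
the alignment endpoint is the first maximal cell in row-major order; both
rules exist solely to make results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

# direction-pointer codes
STOP, DIAG, UP, LEFT = 0, 1, 2, 3

_BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASES)}

CONVERSION_MODES = ("none", "c_to_t", "g_to_a")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/linear-gap scores plus the bisulfite conversion mode.

    ``conversion_mode``:
      * ``none``   — plain symmetric matching (untreated anchor reads);
      * ``c_to_t`` — read T vs reference C also matches (treated reads from
        the forward strand);
      * ``g_to_a`` — read A vs reference G also matches (treated reads
        representing the reverse strand, compared against the forward
        reference).

    Any comparison involving N scores as a mismatch.
    """

    match: int = 2
    mismatch: int = -3
    gap: int = -2
    conversion_mode: str = "none"

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError(f"match score must be positive, got {self.match}")
        if self.mismatch >= 0:
            raise ValueError(f"mismatch score must be negative, got {self.mismatch}")
        if self.gap >= 0:
            raise ValueError(f"gap penalty must be negative, got {self.gap}")
        if self.conversion_mode not in CONVERSION_MODES:
            raise ValueError(
                f"conversion_mode must be one of {CONVERSION_MODES}, got {self.conversion_mode!r}"
            )

    def substitution_table(self) -> np.ndarray:
        """5x5 int32 table over (read code, reference code)."""
        table = np.full((5, 5), self.mismatch, dtype=np.int32)
        for i in range(4):  # N (code 4) never matches, not even N/N
            table[i, i] = self.match
        if self.conversion_mode == "c_to_t":
            table[_CODE["T"], _CODE["C"]] = self.match
        elif self.conversion_mode == "g_to_a":
            table[_CODE["A"], _CODE["G"]] = self.match
        return table

    def with_mode(self, conversion_mode: str) -> "ScoringScheme":
        return ScoringScheme(self.match, self.mismatch, self.gap, conversion_mode)


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as int8 codes; any other base is an error."""
    try:
        return np.fromiter((_CODE[b] for b in sequence), dtype=np.int8, count=len(sequence))
    except KeyError as exc:
        raise AlignmentError(f"illegal base {exc.args[0]!r} in sequence") from None


def substitution_score(read_base: str, ref_base: str, scheme: ScoringScheme) -> int:
    """Score one read base against one reference base under the scheme's mode."""
    for b in (read_base, ref_base):
        if b not in _CODE:
            raise AlignmentError(f"illegal base {b!r}")
    return int(scheme.substitution_table()[_CODE[read_base], _CODE[ref_base]])


def _fill_py(read: np.ndarray, window: np.ndarray, table: np.ndarray, gap: int):
    n, m = read.size, window.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    D = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = H[i - 1, j - 1] + table[read[i - 1], window[j - 1]]
            d = DIAG
            up = H[i - 1, j] + gap
            if up > s:
                s, d = up, UP
            left = H[i, j - 1] + gap
            if left > s:
                s, d = left, LEFT
            if s <= 0:
                s, d = 0, STOP
            H[i, j] = s
            D[i, j] = d
            if s > best:
                best, bi, bj = s, i, j
    return H, D, bi, bj


try:  # numba accelerates the O(n*m) fill; the pure-Python fill is the reference
    import numba

    _fill_jit = numba.njit(cache=True, nogil=True)(_fill_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _fill_jit = _fill_py


@dataclass
class DPMatrices:
    """Score grid H, direction-pointer grid, and the traceback start cell.

    Invariants: the zeroth row/column are 0, every score is >= 0, a cell's
    pointer is STOP exactly when its score is 0, and following pointers from
    any cell reaches a STOP cell in at most i+j steps.
    """

    score: np.ndarray
    direction: np.ndarray
    argmax: Tuple[int, int]
    read: str
    window: str
    scheme: ScoringScheme


@dataclass
class Alignment:
    """A local alignment of a read inside a reference window.

    Spans are 0-based half-open; ``pairs`` lists aligned columns left to
    right as (read base or '-', window base or '-').  ``genome_start`` /
    ``genome_end`` are the window span lifted to 1-based inclusive genome
    coordinates, set by :func:`align_in_window`.
    """

    score: int
    read_start: int
    read_end: int
    window_start: int
    window_end: int
    pairs: List[Tuple[str, str]] = field(default_factory=list)
    genome_start: Optional[int] = None
    genome_end: Optional[int] = None

    @property
    def n_aligned(self) -> int:
        return sum(1 for r, w in self.pairs if r != "-" and w != "-")


def build_matrices(read: str, window: str, scheme: ScoringScheme) -> DPMatrices:
    """Run the local-alignment dynamic program, recording direction pointers.

    H(i,j) = max(0, H(i-1,j-1)+s(read_i, window_j), H(i-1,j)+gap, H(i,j-1)+gap)
    with ties resolved DIAG > UP > LEFT > STOP; the traceback start is the
    first maximal cell in row-major order.
    """
    if not read or not window:
        raise AlignmentError("read and window must be non-empty")
    H, D, bi, bj = _fill_jit(encode(read), encode(window), scheme.substitution_table(), scheme.gap)
    return DPMatrices(H, D, (int(bi), int(bj)), read, window, scheme)


def traceback(matrices: DPMatrices) -> Alignment:
    """Walk direction pointers from the argmax cell back to the first STOP.

    No scores are recomputed and no branch of the recurrence is re-evaluated;
    the pointer stored during the fill fully determines each step.  As a
    corruption check the emitted pairs are re-summed and must equal the score
    at the argmax cell.
    """
    H, D = matrices.score, matrices.direction
    i, j = matrices.argmax
    read, window = matrices.read, matrices.window
    end_i, end_j = i, j
    pairs: List[Tuple[str, str]] = []
    max_steps = i + j
    steps = 0
    while D[i, j] != STOP:
        steps += 1
        if steps > max_steps:
            raise AlignmentError("corrupted direction grid: traceback did not terminate")
        d = D[i, j]
        if d == DIAG:
            pairs.append((read[i - 1], window[j - 1]))
            i, j = i - 1, j - 1
        elif d == UP:
            pairs.append((read[i - 1], "-"))
            i -= 1
        elif d == LEFT:
            pairs.append(("-", window[j - 1]))
            j -= 1
        else:
            raise AlignmentError(f"corrupted direction grid: pointer {d} at ({i},{j})")
    pairs.reverse()

    table = matrices.scheme.substitution_table()
    resum = 0
    for rb, wb in pairs:
        if rb == "-" or wb == "-":
            resum += matrices.scheme.gap
        else:
            resum += int(table[_CODE[rb], _CODE[wb]])
    score = int(H[end_i, end_j])
    if resum != score:
        raise AlignmentError(
            f"corrupted matrices: traceback re-sum {resum} != score {score}"
        )
    return Alignment(
        score=score,
        read_start=i,
        read_end=end_i,
        window_start=j,
        window_end=end_j,
        pairs=pairs,
    )


def align_in_window(
    read: str, window: str, window_offset: int, scheme: ScoringScheme
) -> Alignment:
    """Align a read inside a reference window and lift coordinates to the genome.

    ``window_offset`` is the 1-based genome coordinate of the window's first
    base; the alignment's ``genome_start``/``genome_end`` become 1-based
    inclusive genome coordinates of the consumed window span.
    """
    aln = traceback(build_matrices(read, window, scheme))
    aln.genome_start = window_offset + aln.window_start
    aln.genome_end = window_offset + aln.window_end - 1
    return aln


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
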