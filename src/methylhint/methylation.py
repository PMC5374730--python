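"""Per-cytosine methylation calling and genome-wide aggregation.

A bisulfite-treated read reports, at each reference cytosine it covers,
whether that cytosine was protected (methylated, base retained) or converted
(unmethylated, C read as T on the forward strand, G read as A for reads
representing the reverse strand).  Calls carry the standard trinucleotide
context (CpG / CHG / CHH, H = A, C or T).  Reverse-strand cytosines are
reported at the forward-reference G coordinate with strand '-', matching
common cytosine-report practice.

Aggregation into :class:`MethylationCounts` is a pure counter increment:
associative and commutative, so the final counts are independent of how the
calls were batched or ordered across workers — the property that lets the
parallel pipeline write back per-group buffers in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .alignment import Alignment
from .io_formats import FlatReference, TargetRecord

CONTEXTS = ("CpG", "CHG", "CHH")

Key = Tuple[str, int, str]  # (chrom, 1-based position, strand)


class CallError(ValueError):
    pass


@dataclass(frozen=True)
class MethylationCall:
    """One read-level observation at one reference cytosine."""

    chrom: str
    position: int  # 1-based forward-reference coordinate
    strand: str  # '+' (reference C) or '-' (reference G)
    context: str
    methylated: bool


class MethylationCounts:
    """Sparse per-(chrom, position, strand) methylated/unmethylated counters."""

    def __init__(self) -> None:
        self._counts: Dict[Key, List[int]] = {}

    def add(self, call: MethylationCall) -> None:
        pair = self._counts.setdefault((call.chrom, call.position, call.strand), [0, 0])
        pair[0 if call.methylated else 1] += 1

    def add_many(self, calls: Iterable[MethylationCall]) -> None:
        for call in calls:
            self.add(call)

    def add_counts(self, chrom: str, position: int, strand: str, m: int, u: int) -> None:
        if m < 0 or u < 0:
            raise ValueError("counts must be non-negative")
        pair = self._counts.setdefault((chrom, position, strand), [0, 0])
        pair[0] += m
        pair[1] += u

    def get(self, chrom: str, position: int, strand: str) -> Tuple[int, int]:
        m, u = self._counts.get((chrom, position, strand), (0, 0))
        return m, u

    def items(self) -> Iterator[Tuple[Key, Tuple[int, int]]]:
        for key in sorted(self._counts):
            m, u = self._counts[key]
            yield key, (m, u)

    def merge(self, other: "MethylationCounts") -> None:
        for (chrom, pos, strand), (m, u) in other.items():
            self.add_counts(chrom, pos, strand, m, u)

    def total_observations(self) -> int:
        return sum(m + u for m, u in self._counts.values())

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationCounts):
            return NotImplemented
        return self._counts == other._counts


def classify_context(ref: FlatReference, chrom: str, position: int, strand: str) -> str:
    """Trinucleotide context of the cytosine at (chrom, position, strand).

    On '+' the reference base must be C: C,G,* -> CpG; C,H,G -> CHG; else CHH.
    On '-' the reference base must be G and the rule is mirrored on the
    reverse complement (the neighbours are at position-1, position-2).
    A trinucleotide truncated by the chromosome end defaults to CHH, except
    that a complete CpG dinucleotide is still CpG.
    """
    length = ref.chrom_length(chrom)
    base = ref.base(chrom, position)
    if strand == "+":
        if base != "C":
            raise CallError(f"{chrom}:{position}:+ is {base}, not a cytosine")
        nxt = ref.base(chrom, position + 1) if position + 1 <= length else None
        nxt2 = ref.base(chrom, position + 2) if position + 2 <= length else None
        if nxt == "G":
            return "CpG"
        if nxt is not None and nxt2 == "G":
            return "CHG"
        return "CHH"
    if strand == "-":
        if base != "G":
            raise CallError(f"{chrom}:{position}:- is {base}, not a reverse-strand cytosine")
        prv = ref.base(chrom, position - 1) if position - 1 >= 1 else None
        prv2 = ref.base(chrom, position - 2) if position - 2 >= 1 else None
        if prv == "C":
            return "CpG"
        if prv is not None and prv2 == "C":
            return "CHG"
        return "CHH"
    raise CallError(f"strand must be '+' or '-', got {strand!r}")


def call_methylation(
    alignment: Alignment, record: TargetRecord, ref: FlatReference
) -> List[MethylationCall]:
    """Convert an accepted treated-read alignment into per-cytosine calls.

    Only substitution columns (both sides non-gap) can emit a call; gapped
    columns are skipped.  On '+' fragments a reference C covered by read C is
    methylated and by read T unmethylated; on '-' fragments a reference G
    covered by read G is methylated and by read A unmethylated.  Any other
    read base at a cytosine column emits no call (sequencing-error guard).
    A disagreement between the aligned window base and the reference at the
    lifted coordinate is a hard error — it means the window was extracted
    from the wrong place.
    """
    if not record.treated:
        raise CallError(f"group {record.group_id}: methylation calls require a treated read")
    if alignment.genome_start is None:
        raise CallError("alignment lacks genome coordinates; use align_in_window")
    if record.strand == "+":
        ref_cytosine, kept, converted = "C", "C", "T"
    else:
        ref_cytosine, kept, converted = "G", "G", "A"

    calls: List[MethylationCall] = []
    pos = alignment.genome_start
    for read_base, window_base in alignment.pairs:
        if read_base != "-" and window_base != "-":
            actual = ref.base(record.chrom, pos)
            if actual != window_base:
                raise CallError(
                    f"window/reference mismatch at {record.chrom}:{pos}: "
                    f"window {window_base}, reference {actual}"
                )
            if window_base == ref_cytosine:
                if read_base == kept:
                    status = True
                elif read_base == converted:
                    status = False
                else:
                    status = None
                if status is not None:
                    calls.append(
                        MethylationCall(
                            chrom=record.chrom,
                            position=pos,
                            strand=record.strand,
                            context=classify_context(ref, record.chrom, pos, record.strand),
                            methylated=status,
                        )
                    )
            pos += 1
        elif window_base != "-":  # read gap: window advances
            pos += 1
        # window gap: genome position unchanged
    return calls


def aggregate_calls(
    calls: Iterable[MethylationCall], counts: MethylationCounts
) -> MethylationCounts:
    """Increment ``counts`` with ``calls`` and return it.

    Pure increments, so aggregation is associative and commutative across
    batches: any partition of the calls in any order yields equal counts.
    """
    counts.add_many(calls)
    return counts


def methylation_level(
    counts: MethylationCounts, chrom: str, position: int, strand: str
) -> Optional[float]:
    """m/(m+u) at a site, or None when the site has no observations."""
    m, u = counts.get(chrom, position, strand)
    if m + u == 0:
        return None
    return m / (m + u)
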