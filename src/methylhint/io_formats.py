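"""Readers and writers for every external representation used by the pipeline.

Four formats cross the package boundary:

* a multi-FASTA reference genome, flattened on load into one contiguous
  in-memory string per chromosome (``FlatReference``) so that any 1-based
  coordinate can be resolved with plain indexing;
* the flattened-reference dialect itself (ordinary FASTA with exactly one
  sequence line per record), written so a later run can re-load it without
  re-flattening;
* the five/six-column whitespace-separated target file: one read per line
  carrying a group ID, the read sequence, the genomic strand of the source
  fragment, the chromosome, a 1-based coordinate hint, and optionally a
  ``T``/``U`` flag marking the bisulfite-treated or untreated end;
* methylation reports: a CX-style TSV of per-cytosine counts and a bedGraph
  of methylation levels.

Coordinates are 1-based inclusive everywhere in this module except bedGraph
output, which is 0-based half-open per that format's convention.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, Iterator, List, Optional, Tuple, Union

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

PathOrHandle = Union[str, os.PathLike, IO[str]]


class ReferenceFormatError(ValueError):
    """Malformed FASTA input (empty, headerless sequence, duplicate name)."""


class TargetParseError(ValueError):
    """Malformed target-file line; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class GroupTooLargeError(ValueError):
    """A single ID group exceeds the chunk size, so chunking cannot avoid splitting it."""


@dataclass
class FlatReference:
    """A reference genome held as one whitespace-free string per chromosome.

    Chromosome order is the order of appearance in the source FASTA and is
    preserved by all writers (reports are sorted in this order).
    """

    chrom_names: List[str] = field(default_factory=list)
    sequences: Dict[str, str] = field(default_factory=dict)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.sequences

    def base(self, chrom: str, position: int) -> str:
        """Base at a 1-based coordinate."""
        return self.sequences[chrom][position - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases for the 1-based inclusive interval [start, end]."""
        return self.sequences[chrom][start - 1 : end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlatReference):
            return NotImplemented
        return self.chrom_names == other.chrom_names and self.sequences == other.sequences


@dataclass
class TargetRecord:
    """One line of the target file.

    ``treated`` is ``None`` when the optional sixth column was absent; it is
    resolved by file order within the group (first record = untreated anchor,
    the rest treated) when records are grouped or chunk-read.
    """

    group_id: int
    sequence: str
    strand: str  # '+' or '-'
    chrom: str
    coord: int  # 1-based coordinate hint
    treated: Optional[bool] = None
    line_number: Optional[int] = None

    def serialize(self) -> str:
        fields = [str(self.group_id), self.sequence, self.strand, self.chrom, str(self.coord)]
        if self.treated is not None:
            fields.append("T" if self.treated else "U")
        return " ".join(fields)


def _open_for_read(source: PathOrHandle) -> Tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(os.fspath(source), "r"), True


def _open_for_write(dest: PathOrHandle) -> Tuple[IO[str], bool]:
    if hasattr(dest, "write"):
        return dest, False  # type: ignore[return-value]
    return open(os.fspath(dest), "w"), True


def _normalize_seq(raw: str, where: str) -> str:
    seq = raw.upper()
    cleaned = _NON_ACGTN.sub("N", seq)
    if cleaned != seq:
        n_mapped = sum(1 for a, b in zip(seq, cleaned) if a != b)
        log.warning("%s: mapped %d non-ACGTN character(s) to N", where, n_mapped)
    return cleaned


def flatten_reference(source: PathOrHandle) -> FlatReference:
    """Load a multi-FASTA and flatten each record into a single string.

    Line breaks inside a record are removed so that the base at 1-based
    coordinate ``p`` of the flattened chromosome equals the base at ``p`` in
    the original record (coordinate preservation).  Any line width is
    accepted.  Lowercase is uppercased and characters outside A/C/G/T/N are
    mapped to N with a logged warning.

    Raises
    ------
    ReferenceFormatError
        on empty input, sequence appearing before the first ``>`` header, or
        a duplicate chromosome name.
    """
    handle, own = _open_for_read(source)
    try:
        ref = FlatReference()
        name: Optional[str] = None
        parts: List[str] = []

        def commit() -> None:
            if name is None:
                return
            ref.chrom_names.append(name)
            ref.sequences[name] = _normalize_seq("".join(parts), f"reference record {name!r}")

        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                commit()
                new_name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not new_name:
                    raise ReferenceFormatError("FASTA header with empty record name")
                if new_name in ref.sequences or new_name == name:
                    raise ReferenceFormatError(f"duplicate chromosome name {new_name!r}")
                name = new_name
                parts = []
            else:
                if name is None:
                    raise ReferenceFormatError(
                        f"sequence data before first FASTA header: {line[:30]!r}"
                    )
                parts.append(line)
        commit()
    finally:
        if own:
            handle.close()
    if not ref.chrom_names:
        raise ReferenceFormatError("empty FASTA input: no records found")
    return ref


def load_flat_reference(source: PathOrHandle) -> FlatReference:
    """Load a reference written by :func:`write_flat_reference`.

    The flattened dialect is valid FASTA, so this accepts any FASTA and is an
    alias for :func:`flatten_reference`.
    """
    return flatten_reference(source)


def write_flat_reference(ref: FlatReference, destination: PathOrHandle) -> None:
    """Write one header line plus one unbroken sequence line per chromosome."""
    handle, own = _open_for_write(destination)
    try:
        for name in ref.chrom_names:
            handle.write(f">{name}\n{ref.sequences[name]}\n")
    finally:
        if own:
            handle.close()


def parse_target_line(line: str, line_number: Optional[int] = None) -> TargetRecord:
    """Parse one whitespace-separated target line into a :class:`TargetRecord`.

    Columns: ID, sequence, strand (+/-), chromosome, 1-based coordinate hint,
    and an optional sixth column ``T`` (bisulfite-treated) / ``U`` (untreated).
    When the sixth column is absent ``treated`` is left ``None`` for later
    resolution by pair order within the group.
    """
    fields = line.split()
    if len(fields) not in (5, 6):
        raise TargetParseError(
            f"expected 5 or 6 whitespace-separated columns, got {len(fields)}", line_number
        )
    try:
        group_id = int(fields[0])
    except ValueError:
        raise TargetParseError(f"non-integer ID {fields[0]!r}", line_number) from None
    sequence = _normalize_seq(fields[1], f"target line {line_number}")
    if not sequence:
        raise TargetParseError("empty sequence", line_number)
    strand = fields[2].replace("−", "-")  # tolerate unicode minus
    if strand not in ("+", "-"):
        raise TargetParseError(f"illegal strand symbol {fields[2]!r}", line_number)
    chrom = fields[3]
    try:
        coord = int(fields[4])
    except ValueError:
        raise TargetParseError(f"non-integer coordinate {fields[4]!r}", line_number) from None
    if coord < 1:
        raise TargetParseError(f"coordinate must be >= 1, got {coord}", line_number)
    treated: Optional[bool] = None
    if len(fields) == 6:
        flag = fields[5].upper()
        if flag not in ("T", "U"):
            raise TargetParseError(f"illegal treated flag {fields[5]!r} (expected T or U)", line_number)
        treated = flag == "T"
    return TargetRecord(group_id, sequence, strand, chrom, coord, treated, line_number)


def resolve_treated_defaults(records: List[TargetRecord]) -> None:
    """Fill in ``treated`` for records lacking the explicit column, in place.

    Within each maximal run of equal group IDs, the first record in file
    order is the untreated anchor and every subsequent record is treated.
    Explicit T/U flags are never overridden.
    """
    prev_id: Optional[int] = None
    idx_in_group = 0
    for rec in records:
        idx_in_group = idx_in_group + 1 if rec.group_id == prev_id else 0
        if rec.treated is None:
            rec.treated = idx_in_group > 0
        prev_id = rec.group_id


def _iter_records(handle: IO[str]) -> Iterator[TargetRecord]:
    for line_number, line in enumerate(handle, start=1):
        if not line.strip():
            continue
        yield parse_target_line(line, line_number)


def read_target_chunks(
    source: PathOrHandle, chunk_size: int = 2_000_000
) -> Iterator[List[TargetRecord]]:
    """Stream the target file as lists of records of roughly ``chunk_size``.

    Each iteration reads ``chunk_size`` records; if the file continues with
    the same group ID as the chunk's last record, that trailing run is
    deferred to the next chunk so no group is ever split across a boundary.
    The default chunk size is two million records, matching the pipeline's
    concentrated-IO design.  A group larger than ``chunk_size`` is a hard
    error.  ``treated`` defaults are resolved per group before a chunk is
    yielded.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    handle, own = _open_for_read(source)
    try:
        records = _iter_records(handle)
        deferred: List[TargetRecord] = []
        lookahead: Optional[TargetRecord] = next(records, None)
        while deferred or lookahead is not None:
            buf = deferred
            deferred = []
            taken = 0  # deferred records ride on top of the chunk_size new reads
            while lookahead is not None and taken < chunk_size:
                buf.append(lookahead)
                taken += 1
                lookahead = next(records, None)
            if lookahead is not None and lookahead.group_id == buf[-1].group_id:
                tail_id = buf[-1].group_id
                cut = len(buf)
                while cut > 0 and buf[cut - 1].group_id == tail_id:
                    cut -= 1
                if cut == 0:
                    raise GroupTooLargeError(
                        f"group {tail_id} has more than chunk_size={chunk_size} records"
                    )
                deferred = buf[cut:]
                buf = buf[:cut]
            resolve_treated_defaults(buf)
            yield buf
    finally:
        if own:
            handle.close()


def read_targets(source: PathOrHandle) -> List[TargetRecord]:
    """Read the whole target file as one list (treated defaults resolved)."""
    handle, own = _open_for_read(source)
    try:
        records = list(_iter_records(handle))
    finally:
        if own:
            handle.close()
    resolve_treated_defaults(records)
    return records


CX_HEADER = "#chrom\tposition\tstrand\tcontext\tcount_methylated\tcount_unmethylated"


def write_methylation_report(
    counts,
    ref: FlatReference,
    cx_dest: PathOrHandle,
    bedgraph_dest: PathOrHandle,
) -> None:
    """Serialize aggregated counts as a CX-style TSV and a bedGraph.

    The TSV has one row per covered cytosine (chrom, 1-based position, strand,
    trinucleotide context, methylated count, unmethylated count), sorted by
    reference chromosome order then position then strand.  The bedGraph holds
    the level m/(m+u) over 0-based half-open single-base intervals, only for
    covered positions.  A count at a position outside the reference is a hard
    error: it indicates an upstream coordinate bug.
    """
    from .methylation import classify_context  # deferred: avoids an import cycle

    order = {name: i for i, name in enumerate(ref.chrom_names)}
    rows = []
    for (chrom, position, strand), (m, u) in counts.items():
        if chrom not in order:
            raise ValueError(f"counts refer to unknown chromosome {chrom!r}")
        if not (1 <= position <= ref.chrom_length(chrom)):
            raise ValueError(
                f"counts position {chrom}:{position} outside reference "
                f"(length {ref.chrom_length(chrom)})"
            )
        rows.append((order[chrom], position, strand, chrom, m, u))
    rows.sort()

    cx_handle, own_cx = _open_for_write(cx_dest)
    bg_handle, own_bg = _open_for_write(bedgraph_dest)
    try:
        cx_handle.write(CX_HEADER + "\n")
        for _, position, strand, chrom, m, u in rows:
            context = classify_context(ref, chrom, position, strand)
            cx_handle.write(f"{chrom}\t{position}\t{strand}\t{context}\t{m}\t{u}\n")
            if m + u > 0:
                level = m / (m + u)
                bg_handle.write(f"{chrom}\t{position - 1}\t{position}\t{level:.6g}\n")
    finally:
        if own_cx:
            cx_handle.close()
        if own_bg:
            bg_handle.close()


def read_cx_report(source: PathOrHandle):
    """Load a CX-style TSV written by :func:`write_methylation_report`."""
    from .methylation import MethylationCounts

    counts = MethylationCounts()
    handle, own = _open_for_read(source)
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, position, strand, _context, m, u = line.split("\t")
            counts.add_counts(chrom, int(position), strand, int(m), int(u))
    finally:
        if own:
            handle.close()
    return counts
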