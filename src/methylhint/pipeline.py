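"""End-to-end driver: grouping, windowed alignment, filtering, dedup, aggregation.

Each target read carries a coordinate hint from an upstream locator; instead
of searching the whole genome, the pipeline re-aligns the read with
Smith-Waterman inside a window of ``window_radius`` bases (default 1000) on
either side of the hint.  Records sharing an ID form a group — the two ends
of one fragment, one bisulfite-treated and one untreated anchor.  The anchor
aligns with plain scoring and validates the locus; the treated end aligns
with the strand-appropriate asymmetric mode.  A group is accepted only when
every member reaches ``min_score_fraction`` of its maximal possible score;
PCR duplicates among accepted groups (same treated-end coordinates) are
collapsed to the single best-scoring group before the treated ends'
methylation calls are aggregated genome-wide.

Parallel contract: groups are partitioned contiguously across workers,
groups are never split, and results are merged in partition order, so the
written reports are byte-identical for any worker count and any legal chunk
size — parallel execution is an optimization, never a source of
nondeterminism.
"""

from __future__ import annotations

import json
import logging
import math
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .alignment import Alignment, ScoringScheme, align_in_window
from .io_formats import (
    FlatReference,
    TargetRecord,
    load_flat_reference,
    read_target_chunks,
    write_methylation_report,
)
from .methylation import MethylationCall, MethylationCounts, aggregate_calls, call_methylation

log = logging.getLogger(__name__)


class GroupingError(ValueError):
    pass


class WindowError(ValueError):
    """Record-level window-extraction failure; rejects the group, never the run."""


@dataclass
class PipelineConfig:
    window_radius: int = 1000
    chunk_size: int = 2_000_000
    min_score_fraction: float = 0.6
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError(f"window_radius must be >= 1, got {self.window_radius}")
        if self.chunk_size < 1:
            raise ValueError(f"chunk_size must be >= 1, got {self.chunk_size}")
        if not (0 < self.min_score_fraction <= 1):
            raise ValueError(
                f"min_score_fraction must be in (0, 1], got {self.min_score_fraction}"
            )
        if self.n_workers < 1:
            raise ValueError(f"n_workers must be >= 1, got {self.n_workers}")


DedupKey = Tuple[str, int, int, str]


@dataclass
class GroupResult:
    """Outcome of aligning and gating one ID group."""

    group_id: int
    records: List[TargetRecord]
    alignments: List[Alignment]
    combined_score: int
    accepted: bool
    dedup_key: Optional[DedupKey] = None
    calls: List[MethylationCall] = field(default_factory=list)
    reject_reason: Optional[str] = None


def group_records(records: Sequence[TargetRecord]) -> List[List[TargetRecord]]:
    """Split an ordered record list into maximal runs of equal group ID.

    The target format orders records by ID, so equal IDs must be contiguous;
    a duplicate ID reappearing after a different one is a hard error (both
    line numbers cited).  All members of a group must name one chromosome.
    """
    groups: List[List[TargetRecord]] = []
    first_line: Dict[int, Optional[int]] = {}
    prev_id: Optional[int] = None
    for rec in records:
        if rec.group_id != prev_id:
            if rec.group_id in first_line:
                raise GroupingError(
                    f"group ID {rec.group_id} is not contiguous: seen at line "
                    f"{first_line[rec.group_id]} and again at line {rec.line_number}"
                )
            first_line[rec.group_id] = rec.line_number
            groups.append([rec])
            prev_id = rec.group_id
        else:
            if rec.chrom != groups[-1][0].chrom:
                raise GroupingError(
                    f"group ID {rec.group_id} spans chromosomes "
                    f"{groups[-1][0].chrom!r} and {rec.chrom!r}"
                )
            groups[-1].append(rec)
    return groups


def extract_window(
    ref: FlatReference, chrom: str, coord: int, radius: int
) -> Tuple[str, int]:
    """Reference bases within ``radius`` of a 1-based hint, with their offset.

    Returns the substring covering [max(1, coord-radius), min(length,
    coord+radius)] inclusive and the 1-based genome coordinate of its first
    base.  Truncation at chromosome ends is silent.
    """
    if not ref.has_chrom(chrom):
        raise WindowError(f"unknown chromosome {chrom!r}")
    length = ref.chrom_length(chrom)
    if not (1 <= coord <= length):
        raise WindowError(f"hint {chrom}:{coord} outside chromosome (length {length})")
    lo = max(1, coord - radius)
    hi = min(length, coord + radius)
    return ref.fetch(chrom, lo, hi), lo


def _mode_for(record: TargetRecord) -> str:
    if not record.treated:
        return "none"
    return "c_to_t" if record.strand == "+" else "g_to_a"


def process_group(
    group: Sequence[TargetRecord], ref: FlatReference, config: PipelineConfig
) -> GroupResult:
    """Align every member of a group in its own window and gate the group.

    Acceptance requires *every* member to reach ``min_score_fraction`` of its
    maximal score (read length x match): a failed untreated anchor means the
    hint itself is unreliable, so the treated end's calls would be
    untrustworthy.  Methylation calls are emitted only from accepted groups'
    treated members.  The dedup key is the treated end's mapped span.
    """
    if not group:
        raise ValueError("process_group requires a non-empty group")
    gid = group[0].group_id
    alignments: List[Alignment] = []
    accepted = True
    reason: Optional[str] = None
    for rec in group:
        try:
            window, offset = extract_window(ref, rec.chrom, rec.coord, config.window_radius)
        except WindowError as exc:
            return GroupResult(
                group_id=gid,
                records=list(group),
                alignments=[],
                combined_score=0,
                accepted=False,
                reject_reason=str(exc),
            )
        scheme = config.scheme.with_mode(_mode_for(rec))
        aln = align_in_window(rec.sequence, window, offset, scheme)
        alignments.append(aln)
        threshold = config.min_score_fraction * len(rec.sequence) * config.scheme.match
        if aln.score < threshold:
            accepted = False
            reason = (
                f"member at {rec.chrom}:{rec.coord} scored {aln.score} "
                f"< threshold {threshold:g}"
            )

    combined = sum(a.score for a in alignments)
    treated_idx = next((i for i, r in enumerate(group) if r.treated), 0)
    key_aln = alignments[treated_idx]
    dedup_key: DedupKey = (
        group[treated_idx].chrom,
        int(key_aln.genome_start),
        int(key_aln.genome_end),
        group[treated_idx].strand,
    )

    calls: List[MethylationCall] = []
    if accepted:
        for rec, aln in zip(group, alignments):
            if rec.treated:
                calls.extend(call_methylation(aln, rec, ref))
    return GroupResult(
        group_id=gid,
        records=list(group),
        alignments=alignments,
        combined_score=combined,
        accepted=accepted,
        dedup_key=dedup_key,
        calls=calls,
        reject_reason=reason,
    )


def remove_duplicates(results: Sequence[GroupResult]) -> List[GroupResult]:
    """Collapse accepted groups sharing a dedup key to the best-scoring one.

    Ties on combined score are broken by the smallest group ID.  Output
    preserves input order; the operation is deterministic and idempotent.
    """
    best: Dict[DedupKey, GroupResult] = {}
    for res in results:
        cur = best.get(res.dedup_key)
        if cur is None or (res.combined_score, -res.group_id) > (
            cur.combined_score,
            -cur.group_id,
        ):
            best[res.dedup_key] = res
    return [res for res in results if best[res.dedup_key] is res]


def partition_groups(
    groups: Sequence[List[TargetRecord]], n_workers: int
) -> List[List[List[TargetRecord]]]:
    """Split groups into ``n_workers`` contiguous partitions, balanced by records.

    Greedy rule: each partition takes whole groups until its record count
    reaches ceil(remaining records / remaining workers).  Groups are never
    split and concatenating the partitions reproduces the input order;
    trailing partitions may be empty when workers outnumber groups.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    partitions: List[List[List[TargetRecord]]] = []
    remaining = sum(len(g) for g in groups)
    idx = 0
    for worker in range(n_workers):
        part: List[List[TargetRecord]] = []
        workers_left = n_workers - worker
        target = math.ceil(remaining / workers_left) if remaining else 0
        count = 0
        while idx < len(groups) and count < target:
            part.append(groups[idx])
            count += len(groups[idx])
            idx += 1
        remaining -= count
        partitions.append(part)
    return partitions


def _process_partition(
    part: Sequence[List[TargetRecord]], ref: FlatReference, config: PipelineConfig
) -> List[GroupResult]:
    return [process_group(g, ref, config) for g in part]


def process_chunk(
    records: Sequence[TargetRecord], ref: FlatReference, config: PipelineConfig
) -> List[GroupResult]:
    """Group, partition and align one chunk; results in original group order."""
    groups = group_records(records)
    parts = partition_groups(groups, config.n_workers)
    if config.n_workers == 1:
        per_part = [_process_partition(parts[0], ref, config)]
    else:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            per_part = list(pool.map(lambda p: _process_partition(p, ref, config), parts))
    return [res for part in per_part for res in part]


def run(
    config: PipelineConfig,
    reference_path: str,
    targets_path: str,
    output_dir: str,
) -> Dict[str, int]:
    """Run the whole pipeline and write reports plus a run summary.

    Per chunk: group, partition across workers, align and gate.  Accepted
    results are collected across chunks and deduplicated once over the whole
    run (so the survivor set — and therefore every report byte — is invariant
    to chunk size and worker count), then the surviving treated-end calls are
    aggregated into the global counters and serialized.  Per-group failures
    are logged and counted; they never abort the run.
    """
    ref = load_flat_reference(reference_path)
    os.makedirs(output_dir, exist_ok=True)

    accepted: List[GroupResult] = []
    summary = {
        "records_read": 0,
        "groups_seen": 0,
        "groups_accepted": 0,
        "groups_rejected": 0,
        "duplicates_removed": 0,
        "calls_emitted": 0,
        "sites_covered": 0,
    }
    for chunk_idx, chunk in enumerate(read_target_chunks(targets_path, config.chunk_size)):
        results = process_chunk(chunk, ref, config)
        summary["records_read"] += len(chunk)
        summary["groups_seen"] += len(results)
        for res in results:
            if res.accepted:
                accepted.append(res)
            else:
                summary["groups_rejected"] += 1
                log.info("group %d rejected: %s", res.group_id, res.reject_reason)
        log.info(
            "chunk %d: %d records, %d groups (%d accepted so far)",
            chunk_idx,
            len(chunk),
            len(results),
            len(accepted),
        )
    summary["groups_accepted"] = len(accepted)

    survivors = remove_duplicates(accepted)
    summary["duplicates_removed"] = len(accepted) - len(survivors)

    counts = MethylationCounts()
    for res in survivors:
        aggregate_calls(res.calls, counts)
        summary["calls_emitted"] += len(res.calls)
    summary["sites_covered"] = len(counts)

    write_methylation_report(
        counts,
        ref,
        os.path.join(output_dir, "methylation_cx.tsv"),
        os.path.join(output_dir, "methylation.bedGraph"),
    )
    with open(os.path.join(output_dir, "summary.json"), "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    log.info("run summary: %s", summary)
    return summary
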