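"""Synthetic bisulfite-sequencing fixtures with full ground truth.

The generator emulates the hybrid-pair experimental design the pipeline
consumes: for each fragment it emits an *untreated anchor* end (an exact
reference substring plus optional sequencing errors) and a *bisulfite-
treated* end in which each covered cytosine is independently methylated with
its site's true level; unmethylated cytosines are converted with probability
``conversion_rate`` (C->T for '+' fragments, G->A for '-' fragments, both
rendered against the forward reference since all reads are emitted in
forward-reference orientation).  Coordinate hints are the true start
positions perturbed by uniform jitter, mimicking an imprecise upstream
locator.  A configurable fraction of groups are PCR duplicates: re-emissions
of a prior group's molecules with fresh sequencing errors.

Everything is driven by one integer seed through independent named
sub-streams, so every artifact is byte-reproducible.  The truth table
records, per cytosine, the realized methylated/total read counts over
non-duplicate molecules — exactly what an error-free caller should recover —
and, per group, the true loci and duplicate links.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import FlatReference, TargetRecord, write_flat_reference
from .methylation import classify_context

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the package's standard conditions.

    ``genome_length`` is the total length split evenly across
    ``n_chromosomes``.  ``pair_gap`` is the mean gap between the two ends of
    a fragment, varied uniformly by ±``pair_gap_jitter`` (insert-size
    variation; with a rigid geometry, independent fragments at high coverage
    would collide on identical coordinates far more often than in real
    libraries).  Per-context levels are the per-read methylation
    probabilities of every cytosine in that context.  ``hint_jitter`` must
    stay below window_radius - read_length or the truth becomes
    unrecoverable.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.5
    n_groups: int = 100
    read_length: int = 50
    pair_gap: int = 100
    pair_gap_jitter: int = 20
    level_cpg: float = 0.8
    level_chg: float = 0.02
    level_chh: float = 0.02
    sequencing_error_rate: float = 0.0
    conversion_rate: float = 1.0
    duplicate_fraction: float = 0.0
    hint_jitter: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "level_cpg",
            "level_chg",
            "level_chh",
            "sequencing_error_rate",
            "conversion_rate",
            "duplicate_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {value}")
        if self.n_chromosomes < 1 or self.n_groups < 1 or self.read_length < 1:
            raise SimulationError("n_chromosomes, n_groups and read_length must be >= 1")
        if self.pair_gap < 0 or self.pair_gap_jitter < 0 or self.hint_jitter < 0:
            raise SimulationError("pair_gap, pair_gap_jitter and hint_jitter must be >= 0")
        if self.pair_gap_jitter > self.pair_gap:
            raise SimulationError("pair_gap_jitter must not exceed pair_gap")
        chrom_len = self.genome_length // self.n_chromosomes
        span = 2 * self.read_length + self.pair_gap + self.pair_gap_jitter
        if chrom_len < span:
            raise SimulationError(
                f"chromosomes of {chrom_len} bp cannot hold a fragment of {span} bp"
            )

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    def level_for(self, context: str) -> float:
        return {"CpG": self.level_cpg, "CHG": self.level_chg, "CHH": self.level_chh}[context]


@dataclass
class CytosineTruth:
    context: str
    level: float
    realized_methylated: int = 0
    realized_total: int = 0


@dataclass
class GroupTruth:
    chrom: str
    strand: str
    untreated_start: int  # 1-based start of the anchor end
    treated_start: int  # 1-based start of the treated end
    duplicate_of: Optional[int] = None


@dataclass
class TruthTable:
    """Ground truth for a simulated fixture.

    ``cytosines`` maps (chrom, 1-based position, strand) to the site's
    context, true level and realized counts over the treated reads of
    non-duplicate groups.  ``groups`` maps group ID to the fragment's true
    loci and its duplicate-of link (None for originals).
    """

    cytosines: Dict[Tuple[str, int, str], CytosineTruth] = field(default_factory=dict)
    groups: Dict[int, GroupTruth] = field(default_factory=dict)

    def realized_fraction(self, chrom: str, position: int, strand: str) -> Optional[float]:
        truth = self.cytosines.get((chrom, position, strand))
        if truth is None or truth.realized_total == 0:
            return None
        return truth.realized_methylated / truth.realized_total

    def write_tsv(self, cytosine_path: str, group_path: str) -> None:
        with open(cytosine_path, "w") as handle:
            handle.write(
                "#chrom\tposition\tstrand\tcontext\tlevel\trealized_methylated\trealized_total\n"
            )
            for (chrom, pos, strand) in sorted(self.cytosines):
                t = self.cytosines[(chrom, pos, strand)]
                handle.write(
                    f"{chrom}\t{pos}\t{strand}\t{t.context}\t{t.level:g}\t"
                    f"{t.realized_methylated}\t{t.realized_total}\n"
                )
        with open(group_path, "w") as handle:
            handle.write("#group_id\tchrom\tstrand\tuntreated_start\ttreated_start\tduplicate_of\n")
            for gid in sorted(self.groups):
                g = self.groups[gid]
                dup = "." if g.duplicate_of is None else str(g.duplicate_of)
                handle.write(
                    f"{gid}\t{g.chrom}\t{g.strand}\t{g.untreated_start}\t{g.treated_start}\t{dup}\n"
                )

    @classmethod
    def read_tsv(cls, cytosine_path: str, group_path: str) -> "TruthTable":
        table = cls()
        with open(cytosine_path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, strand, context, level, m, total = line.rstrip("\n").split("\t")
                table.cytosines[(chrom, int(pos), strand)] = CytosineTruth(
                    context, float(level), int(m), int(total)
                )
        with open(group_path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                gid, chrom, strand, u_start, t_start, dup = line.rstrip("\n").split("\t")
                table.groups[int(gid)] = GroupTruth(
                    chrom,
                    strand,
                    int(u_start),
                    int(t_start),
                    None if dup == "." else int(dup),
                )
        return table


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent named sub-streams; all derived state stays a function of the seed
    return np.random.default_rng([int(params.seed), stream])


def simulate_reference(params: SimulationParams) -> FlatReference:
    """Seeded i.i.d. reference at the requested GC fraction."""
    rng = _rng(params, 0)
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    ref = FlatReference()
    for i in range(params.n_chromosomes):
        name = f"chr{i + 1}"
        draws = rng.choice(4, size=params.chrom_length, p=probs)
        ref.chrom_names.append(name)
        ref.sequences[name] = "".join(_BASES[draws])
    return ref


def assign_methylation_states(
    ref: FlatReference, params: SimulationParams
) -> Dict[Tuple[str, int, str], float]:
    """True per-read methylation probability for every cytosine on both strands.

    The level is a deterministic function of the site's trinucleotide
    context; randomness enters later, per read, when molecules are drawn.
    """
    states: Dict[Tuple[str, int, str], float] = {}
    for chrom in ref.chrom_names:
        seq = ref.sequences[chrom]
        for idx, base in enumerate(seq):
            pos = idx + 1
            if base == "C":
                context = classify_context(ref, chrom, pos, "+")
                states[(chrom, pos, "+")] = params.level_for(context)
            elif base == "G":
                context = classify_context(ref, chrom, pos, "-")
                states[(chrom, pos, "-")] = params.level_for(context)
    return states


def _apply_errors(sequence: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return sequence
    seq = list(sequence)
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for idx in hits:
        alternatives = [b for b in "ACGT" if b != seq[idx]]
        seq[idx] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def _treat_end(
    ref: FlatReference,
    states: Dict[Tuple[str, int, str], float],
    chrom: str,
    start: int,
    length: int,
    strand: str,
    params: SimulationParams,
    rng: np.random.Generator,
    truth: Optional[TruthTable],
) -> str:
    """Draw one bisulfite-treated molecule over [start, start+length).

    Returns the pre-sequencing-error read (forward orientation).  When
    ``truth`` is given, realized counts are recorded: a cytosine whose base
    survives treatment (methylated, or a conversion failure) counts as
    methylated — that is what any caller can observe.
    """
    cytosine, converted = ("C", "T") if strand == "+" else ("G", "A")
    out = []
    for pos in range(start, start + length):
        base = ref.base(chrom, pos)
        if base == cytosine:
            level = states[(chrom, pos, strand)]
            methylated = bool(rng.random() < level)
            if methylated or not (rng.random() < params.conversion_rate):
                emitted = base  # protected, or conversion failure
                observed_methylated = True
            else:
                emitted = converted
                observed_methylated = False
            if truth is not None:
                site = truth.cytosines[(chrom, pos, strand)]
                site.realized_total += 1
                site.realized_methylated += int(observed_methylated)
            out.append(emitted)
        else:
            out.append(base)
    return "".join(out)


def simulate_read_pairs(
    ref: FlatReference,
    states: Dict[Tuple[str, int, str], float],
    params: SimulationParams,
) -> Tuple[List[TargetRecord], TruthTable]:
    """Emit ID-sorted hybrid read pairs plus their ground truth.

    Each group holds two records: the untreated anchor first, then the
    treated end ``pair_gap`` (± jitter) bases downstream, both as forward-
    reference substrings with explicit U/T flags.  The last
    ``floor(duplicate_fraction * n_groups)`` groups re-emit a uniformly
    chosen earlier group's molecules with fresh sequencing errors.
    """
    rng = _rng(params, 1)
    truth = TruthTable()
    for (chrom, pos, strand), level in states.items():
        truth.cytosines[(chrom, pos, strand)] = CytosineTruth(
            context=classify_context(ref, chrom, pos, strand), level=level
        )

    n_dup = int(params.duplicate_fraction * params.n_groups)
    n_orig = params.n_groups - n_dup
    if n_dup > 0 and n_orig == 0:
        raise SimulationError("duplicate_fraction leaves no original groups")

    records: List[TargetRecord] = []
    L = params.read_length
    # pre-error sequences of originals, kept so duplicates re-emit the same molecules
    molecules: Dict[int, Tuple[str, str]] = {}

    def emit(gid: int, chrom: str, strand: str, s1: int, s2: int, untreated: str, treated: str):
        for start, seq, flag in ((s1, untreated, False), (s2, treated, True)):
            read = _apply_errors(seq, rng, params.sequencing_error_rate)
            jitter = int(rng.integers(-params.hint_jitter, params.hint_jitter + 1)) if params.hint_jitter else 0
            hint = min(max(1, start + jitter), ref.chrom_length(chrom))
            records.append(TargetRecord(gid, read, strand, chrom, hint, flag))

    for gid in range(1, n_orig + 1):
        chrom = ref.chrom_names[int(rng.integers(len(ref.chrom_names)))]
        strand = "+" if rng.random() < 0.5 else "-"
        gap = params.pair_gap + (
            int(rng.integers(-params.pair_gap_jitter, params.pair_gap_jitter + 1))
            if params.pair_gap_jitter
            else 0
        )
        span = 2 * L + gap
        s1 = int(rng.integers(1, ref.chrom_length(chrom) - span + 2))
        s2 = s1 + L + gap
        untreated = ref.fetch(chrom, s1, s1 + L - 1)
        treated = _treat_end(ref, states, chrom, s2, L, strand, params, rng, truth)
        molecules[gid] = (untreated, treated)
        truth.groups[gid] = GroupTruth(chrom, strand, s1, s2, None)
        emit(gid, chrom, strand, s1, s2, untreated, treated)

    for gid in range(n_orig + 1, params.n_groups + 1):
        source = int(rng.integers(1, n_orig + 1))
        src = truth.groups[source]
        untreated, treated = molecules[source]
        truth.groups[gid] = GroupTruth(
            src.chrom, src.strand, src.untreated_start, src.treated_start, duplicate_of=source
        )
        emit(gid, src.chrom, src.strand, src.untreated_start, src.treated_start, untreated, treated)

    return records, truth


def write_fixture(params: SimulationParams, output_dir: str) -> Dict[str, str]:
    """Materialize a complete fixture directory; byte-deterministic per seed.

    Writes the flattened reference, the target file, the two truth TSVs and
    the parameters used; returns the paths keyed by role.
    """
    os.makedirs(output_dir, exist_ok=True)
    ref = simulate_reference(params)
    states = assign_methylation_states(ref, params)
    records, truth = simulate_read_pairs(ref, states, params)

    paths = {
        "reference": os.path.join(output_dir, "reference.flat.fa"),
        "targets": os.path.join(output_dir, "targets.txt"),
        "truth_cytosines": os.path.join(output_dir, "truth_cytosines.tsv"),
        "truth_groups": os.path.join(output_dir, "truth_groups.tsv"),
        "params": os.path.join(output_dir, "params.json"),
    }
    write_flat_reference(ref, paths["reference"])
    with open(paths["targets"], "w") as handle:
        for rec in records:
            handle.write(rec.serialize() + "\n")
    truth.write_tsv(paths["truth_cytosines"], paths["truth_groups"])
    with open(paths["params"], "w") as handle:
        json.dump(dataclasses.asdict(params), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths
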