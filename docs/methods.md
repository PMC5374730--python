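# Methods

## Model and procedure

`methylhint` calls cytosine methylation from bisulfite sequencing reads that
arrive with approximate genomic locations. The input is a whitespace-
separated target file — one read per line: integer group ID, sequence,
strand, chromosome, 1-based coordinate hint, optional `T`/`U` treated flag —
and a reference genome. Records sharing an ID are one group: the two ends
of one fragment, one end bisulfite-treated and one untreated. When the
sixth column is absent, the first record of a group in file order is taken
as the untreated anchor and the rest as treated; a single parsed line
therefore carries `treated = None` until its group is assembled.

Per group the pipeline:

1. extracts, for each member, the reference window within `window_radius`
   (default 1000 bp) of its hint, truncated silently at chromosome ends;
2. aligns the member in its window with Smith–Waterman (linear gaps),
   using plain symmetric scoring for the untreated anchor and the
   strand-appropriate asymmetric mode for the treated end: C→T mode adds
   read-T/reference-C to the match set (converted unmethylated cytosine)
   while keeping read-C/reference-T a mismatch; G→A mode mirrors this for
   reads representing the reverse strand, compared in forward-reference
   orientation. Any comparison involving N is a mismatch (a conservative
   choice: ambiguity never manufactures score);
3. accepts the group iff **every** member scores at least
   `min_score_fraction × read_length × match` (default 0.6). The anchor is
   part of the gate deliberately: a failed anchor means the hint itself is
   unreliable, so the treated end's calls would be untrustworthy;
4. collapses PCR duplicates among accepted groups — identical treated-end
   mapped span and strand — keeping the highest combined score, ties to the
   smallest group ID;
5. scans surviving treated-end alignments column by column: at a reference
   C on '+' (or G on '−'), read C/G ⇒ methylated, read T/A ⇒ unmethylated,
   any other base ⇒ no call; gap columns emit nothing. Calls carry the
   CpG/CHG/CHH trinucleotide context; reverse-strand cytosines are reported
   at the forward G coordinate with strand '−'. Counts accumulate in a
   sparse per-(chrom, position, strand) map and serialize as a CX-style TSV
   and a bedGraph of `m/(m+u)`.

### Alignment details

The DP records, per cell, which argument of the recurrence attained the
maximum (DIAG/UP/LEFT, or STOP exactly when the score is 0), so traceback
is a pointer walk with no branch re-evaluation. Determinism requires fixed
tie rules: DIAG > UP > LEFT within a cell, and the first maximal cell in
row-major order as the alignment endpoint. As a corruption check the
traceback re-sums its emitted columns and must reproduce the cell score.
The fill is a numba `njit(nogil=True)` kernel (a pure-Python fallback with
identical semantics is selected if numba is unavailable); the DP is full,
not banded — the windowing already bounds the problem to
`read × (2·radius+1)` cells.

### Parallel execution contract

Within each input chunk, groups are partitioned contiguously across
`n_workers` threads by a greedy rule (each partition takes whole groups
until its record count reaches ⌈remaining records / remaining workers⌉),
which bounds the largest partition by ⌈total/n⌉ + (largest group − 1).
Groups are never split; per-partition results are concatenated in partition
order; aggregation is a commutative counter increment. Consequently the
reports are byte-identical for any worker count and chunk size — the
package's testable statement of serial/parallel correctness. Workers are
threads (the DP kernel releases the GIL); the contract, not the mechanism,
is the specified behaviour.

### Chunked IO

Targets stream in chunks of `chunk_size` records (default 2,000,000). Each
iteration reads `chunk_size` new records; if the file continues with the
same group ID, that trailing run is deferred to the next chunk, so a chunk
boundary never splits a group. A group larger than the chunk size is a hard
error. The reference is pre-flattened (line breaks removed, coordinates
preserved) so it loads in one pass; the flattened dialect is itself valid
FASTA.

### Duplicate-removal scope

Duplicates are resolved once over the whole run rather than per input
chunk: accepted group results are held (group IDs, scores, keys and their
calls — memory linear in accepted groups, small at the scales this package
targets) and the best-per-key selection happens before aggregation. A
per-chunk scope would make the survivor set — and therefore the output —
depend on where chunk boundaries fall whenever a duplicate lands in a
different chunk than its original, violating the output contract above.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_radius` | 1000 bp | half-width of the re-alignment window around the hint; must exceed hint error + read length |
| `chunk_size` | 2,000,000 records | records imported per IO cycle; bounds memory, never changes output |
| `min_score_fraction` | 0.6 | per-member acceptance gate as a fraction of the maximal score |
| `match`, `mismatch`, `gap` | +2, −3, −2 | Smith–Waterman scores (linear gap); all configurable |
| `n_workers` | 1 | worker threads; output invariant by contract |

The scoring defaults are conventional short-read local-alignment values;
with them a 50-mer must retain ≈ 40 of 50 aligned matches to pass the 0.6
gate, rejecting scrambled or mis-hinted reads (random 50-mers score far
below threshold in a 2 kb window) while tolerating a few sequencing errors.

## The simulator

`methylhint.simulate` generates the study conditions: an i.i.d. reference
at a given GC fraction (default 100 kb over 2 chromosomes, GC 0.5); a true
methylation level per cytosine, deterministic by context (defaults CpG
0.80, CHG 0.02, CHH 0.02 — mammalian-like); and per group an untreated
anchor (exact substring) plus a treated end `pair_gap` (100 ± 20 bp,
uniform) downstream, in which each cytosine is methylated per-read with its
site's level, unmethylated cytosines convert with `conversion_rate`
(default 1.0), and sequencing errors substitute uniformly at
`sequencing_error_rate`. Hints are true starts ± uniform jitter. A
`duplicate_fraction` of groups re-emit a prior group's molecules with fresh
errors. The insert-size variation exists because with rigid fragment
geometry, independent fragments at high coverage would collide on identical
coordinates far more often than in real libraries, inflating duplicate
removal. All reads are emitted in forward-reference orientation; the strand
column records the fragment's chemistry ('−' fragments show G→A against the
forward reference), one documented convention among the possible ones.

The truth table records per cytosine the realized methylated/total counts
over non-duplicate molecules *as observable after treatment* — a conversion
failure counts as methylated, because no caller can distinguish it — and
per group the true loci and duplicate links.

What the simulator does **not** model: read-length and quality
distributions, PCR amplification errors, SNPs/CNVs, M-bias, non-uniform
coverage, adapter contamination. Passing recovery tests therefore show the
*computational* chain (window → asymmetric alignment → gate → dedup → call
→ aggregate) is correct and deterministic, not that real-library artifacts
are handled; on real data, conversion failures bias levels upward by
roughly `(1 − conversion_rate) · (1 − level)`, which the simulator's
conversion knob makes measurable.

## Numerical and degenerate-input choices

- Coordinates: 1-based inclusive externally (target hints, CX report),
  0-based half-open internally and in bedGraph.
- Non-ACGTN reference or read characters map to N with a logged warning
  (real references contain IUPAC codes); N never matches.
- A read whose best local score is 0 yields an empty alignment and is
  rejected by the gate.
- Cytosines whose trinucleotide is truncated by a chromosome end classify
  as CHH unless the CpG dinucleotide is complete.
- Window extraction at chromosome ends truncates silently; an unknown
  chromosome or out-of-range hint rejects the group with a logged reason
  and never aborts the run.
- Methylation level at an uncovered site is undefined (`None`), distinct
  from 0.

## Verification sizes

The test-suite and acceptance-script fixtures use 100-group genomes of
100 kb for exact-regime, parallel-equivalence and duplicate checks, a
6,000-group single 3 kb chromosome (~50× per-strand cytosine coverage,
0.5% error, ±200 bp jitter) for noisy recovery, and ≥200 random instances
of length ≤ 12 for the alignment oracle; these sizes give stable
percentages while keeping a full run in seconds.

## Known limitations

- Linear (not affine) gap penalties; no banding, SIMD or seed-and-extend —
  the window bounds the cost instead.
- Group scoring treats all members as one unit; re-pairing ends within a
  group (best treated/untreated combination) is not attempted.
- Quality scores do not exist in the target format and are not modelled.
- Coordinate-keyed duplicate removal cannot distinguish genuinely
  independent fragments that coincide exactly; at extreme coverage with
  short fixed-length fragments this removes real observations (the
  estimates remain unbiased, the effective coverage drops).
- The whole accepted-group set is held in memory for run-global dedup;
  genome-scale throughput engineering is out of scope.
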