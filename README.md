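# methylhint

Whole-genome DNA methylation calling from bisulfite sequencing data by
**hinted, windowed re-alignment**. `methylhint` is for epigenomics analysts
who have bisulfite-treated reads with approximate genomic locations attached
(from an upstream locator) and want accurate per-cytosine methylation calls
without paying for genome-wide mapping of converted reads.

## The method

Bisulfite treatment converts unmethylated cytosines to uracil (read as T);
methylated cytosines stay C. Mapping treated reads directly against the
reference is error-prone precisely because the reads have been changed.
`methylhint` addresses this two ways:

1. **Hybrid read pairs.** Each fragment contributes an *untreated anchor*
   end, which aligns unambiguously and validates the locus, and a *treated*
   end, which carries the methylation signal. Records sharing an ID form one
   group and are always processed together.
2. **Hinted windows with asymmetric scoring.** Each read is re-aligned only
   within ±1000 bp of its coordinate hint using Smith–Waterman local
   alignment,

   `H(i,j) = max(0, H(i−1,j−1) + s(rᵢ, wⱼ), H(i−1,j) + g, H(i,j−1) + g)`,

   where the substitution function `s` is *asymmetric* for treated reads:
   under C→T mode a read-T against reference-C scores as a match (a
   converted cytosine) while read-C against reference-T stays a mismatch;
   G→A mode mirrors this for reads representing the reverse strand. During
   the fill, the best source direction of every cell is recorded, so
   traceback is a pure pointer walk with no re-evaluation of the recurrence.

Groups whose members all reach a score threshold are accepted; PCR
duplicates (accepted groups whose treated ends map to identical coordinates)
are collapsed to the best-scoring one; the surviving treated-end alignments
are scanned per reference cytosine — read C at reference C ⇒ methylated,
read T ⇒ unmethylated (mirrored on the reverse strand) — and aggregated into
genome-wide counters. The per-site methylation level is `m / (m + u)`.

**Parallel contract.** Groups are partitioned contiguously and whole across
workers, and results are merged in partition order, so the reports are
byte-identical for any worker count and any chunk size: parallelism is an
optimization, never a source of nondeterminism.

A fully ground-truthed simulator (`methylhint simulate` /
`methylhint.simulate`) generates references, methylation states and hybrid
read pairs with configurable error, conversion, duplicate and hint-jitter
rates, so every claim above is testable without external data.

## Worked example

```sh
methylhint simulate --out fx --seed 7 --n-groups 20
methylhint run --reference fx/reference.flat.fa --targets fx/targets.txt --out out
```

prints

```
calls_emitted: 245
duplicates_removed: 0
groups_accepted: 20
groups_rejected: 0
groups_seen: 20
records_read: 40
sites_covered: 245
```

All 20 simulated groups (40 records: one untreated anchor plus one treated
end each) aligned above threshold, none were duplicates, and their treated
ends yielded 245 read-level cytosine observations over 245 distinct sites.
The per-site report begins

```
#chrom  position  strand  context  count_methylated  count_unmethylated
chr1    2773      +       CpG      0                 1
chr1    2775      +       CpG      1                 0
```

— the cytosine at chr1:2773 (CpG context, forward strand) was covered by one
treated read and observed converted (unmethylated, level 0), while chr1:2775
was observed retained (methylated, level 1). `out/methylation.bedGraph`
holds the same levels over 0-based single-base intervals. Other
subcommands: `methylhint flatten-ref` (pre-process a multi-FASTA into the
one-line-per-chromosome dialect the pipeline loads quickly) and
`methylhint report` (regenerate reports from a CX TSV).

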