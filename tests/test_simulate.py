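import filecmp

import pytest

from methylhint.io_formats import load_flat_reference, read_targets
from methylhint.simulate import (
    SimulationError,
    SimulationParams,
    TruthTable,
    assign_methylation_states,
    simulate_read_pairs,
    simulate_reference,
    write_fixture,
)


class TestSimulateReference:
    def test_same_seed_same_sequence(self):
        params = SimulationParams(seed=1, genome_length=10_000, n_chromosomes=1)
        assert simulate_reference(params) == simulate_reference(params)

    def test_degenerate_gc_one_yields_only_gc(self):
        params = SimulationParams(seed=2, genome_length=5_000, n_chromosomes=1, gc_fraction=1.0)
        ref = simulate_reference(params)
        assert set(ref.sequences["chr1"]) <= {"G", "C"}

    def test_empirical_gc_tracks_parameter(self):
        params = SimulationParams(seed=3, genome_length=100_000, n_chromosomes=1, gc_fraction=0.4)
        seq = simulate_reference(params).sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4) < 0.01

    def test_infeasible_geometry_is_an_error(self):
        with pytest.raises(SimulationError):
            SimulationParams(genome_length=100, n_chromosomes=1)


class TestAssignMethylationStates:
    def test_levels_follow_context(self):
        params = SimulationParams(seed=4, level_cpg=1.0, level_chg=0.25, level_chh=0.0)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        truth = TruthTable()
        from methylhint.methylation import classify_context

        for (chrom, pos, strand), level in states.items():
            context = classify_context(ref, chrom, pos, strand)
            assert level == {"CpG": 1.0, "CHG": 0.25, "CHH": 0.0}[context]

    def test_every_cytosine_both_strands_is_assigned(self):
        params = SimulationParams(seed=5, genome_length=10_000, n_chromosomes=1)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        seq = ref.sequences["chr1"]
        n_c = seq.count("C")
        n_g = seq.count("G")
        assert len(states) == n_c + n_g


class TestSimulateReadPairs:
    def test_unmethylated_error_free_limit_converts_every_cytosine(self):
        params = SimulationParams(seed=6, level_cpg=0.0, level_chg=0.0, level_chh=0.0)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        records, truth = simulate_read_pairs(ref, states, params)
        for rec in records:
            if not rec.treated:
                continue
            g = truth.groups[rec.group_id]
            region = ref.fetch(g.chrom, g.treated_start, g.treated_start + params.read_length - 1)
            expected = region.replace("C", "T") if g.strand == "+" else region.replace("G", "A")
            assert rec.sequence == expected

    def test_fully_methylated_limit_emits_the_reference_substring(self):
        params = SimulationParams(seed=6, level_cpg=1.0, level_chg=1.0, level_chh=1.0)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        records, truth = simulate_read_pairs(ref, states, params)
        for rec in records:
            if rec.treated:
                g = truth.groups[rec.group_id]
                assert rec.sequence == ref.fetch(
                    g.chrom, g.treated_start, g.treated_start + params.read_length - 1
                )

    def test_error_free_reads_differ_from_reference_only_at_cytosines(self):
        params = SimulationParams(seed=8)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        records, truth = simulate_read_pairs(ref, states, params)
        cytosine = {"+": "C", "-": "G"}
        for rec in records:
            g = truth.groups[rec.group_id]
            start = g.treated_start if rec.treated else g.untreated_start
            region = ref.fetch(g.chrom, start, start + params.read_length - 1)
            if not rec.treated:
                assert rec.sequence == region
            else:
                for read_base, ref_base in zip(rec.sequence, region):
                    if read_base != ref_base:
                        assert ref_base == cytosine[g.strand]

    def test_realized_counts_match_emitted_reads(self):
        params = SimulationParams(seed=9, n_groups=50)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        records, truth = simulate_read_pairs(ref, states, params)
        observed = {}
        for rec in records:
            if not rec.treated:
                continue
            g = truth.groups[rec.group_id]
            cytosine, kept = ("C", "C") if g.strand == "+" else ("G", "G")
            for i, read_base in enumerate(rec.sequence):
                pos = g.treated_start + i
                if ref.base(g.chrom, pos) == cytosine:
                    m, total = observed.get((g.chrom, pos, g.strand), (0, 0))
                    observed[(g.chrom, pos, g.strand)] = (m + (read_base == kept), total + 1)
        for key, (m, total) in observed.items():
            site = truth.cytosines[key]
            assert (site.realized_methylated, site.realized_total) == (m, total)

    def test_duplicate_groups_link_to_their_source(self):
        params = SimulationParams(seed=10, n_groups=100, duplicate_fraction=0.1)
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        records, truth = simulate_read_pairs(ref, states, params)
        dups = {gid: g for gid, g in truth.groups.items() if g.duplicate_of is not None}
        assert len(dups) == 10
        for gid, g in dups.items():
            src = truth.groups[g.duplicate_of]
            assert src.duplicate_of is None
            assert (g.chrom, g.strand, g.untreated_start, g.treated_start) == (
                src.chrom,
                src.strand,
                src.untreated_start,
                src.treated_start,
            )


class TestWriteFixture:
    def test_same_seed_twice_is_byte_identical(self, tmp_path):
        params = SimulationParams(seed=12, n_groups=20)
        a = write_fixture(params, str(tmp_path / "a"))
        b = write_fixture(params, str(tmp_path / "b"))
        for role in a:
            assert filecmp.cmp(a[role], b[role], shallow=False), role

    def test_two_records_per_group(self, tmp_path):
        params = SimulationParams(seed=12, n_groups=100)
        paths = write_fixture(params, str(tmp_path / "fx"))
        records = read_targets(paths["targets"])
        assert len(records) == 200
        assert load_flat_reference(paths["reference"]).chrom_names == ["chr1", "chr2"]

    def test_truth_tsv_round_trips(self, tmp_path):
        params = SimulationParams(seed=15, n_groups=30, duplicate_fraction=0.1)
        paths = write_fixture(params, str(tmp_path / "fx"))
        ref = simulate_reference(params)
        states = assign_methylation_states(ref, params)
        _, truth = simulate_read_pairs(ref, states, params)
        loaded = TruthTable.read_tsv(paths["truth_cytosines"], paths["truth_groups"])
        assert loaded.groups == truth.groups
        assert loaded.cytosines == truth.cytosines
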