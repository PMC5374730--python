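import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylhint.alignment import (
    STOP,
    AlignmentError,
    ScoringScheme,
    align_in_window,
    build_matrices,
    reverse_complement,
    substitution_score,
    traceback,
)
from sw_oracle import oracle_align

SCHEMES = {mode: ScoringScheme(conversion_mode=mode) for mode in ("none", "c_to_t", "g_to_a")}


class TestSubstitutionScore:
    @pytest.mark.parametrize(
        "read_base, ref_base, mode, expected",
        [
            ("A", "A", "none", 2),
            ("A", "G", "none", -3),
            ("T", "C", "c_to_t", 2),  # converted unmethylated cytosine must not be penalized
            ("C", "T", "c_to_t", -3),  # the asymmetry: reference T is not a convertible C
            ("A", "G", "g_to_a", 2),
            ("G", "A", "g_to_a", -3),
            ("N", "N", "none", -3),
            ("A", "N", "c_to_t", -3),
        ],
    )
    def test_bisulfite_aware_asymmetric_scores(self, read_base, ref_base, mode, expected):
        assert substitution_score(read_base, ref_base, SCHEMES[mode]) == expected

    def test_plain_mode_is_symmetric(self):
        for a in "ACGTN":
            for b in "ACGTN":
                assert substitution_score(a, b, SCHEMES["none"]) == substitution_score(
                    b, a, SCHEMES["none"]
                )

    def test_illegal_base_is_an_error(self):
        with pytest.raises(AlignmentError, match="illegal base"):
            substitution_score("X", "A", SCHEMES["none"])

    @pytest.mark.parametrize("field, value", [("match", 0), ("mismatch", 1), ("gap", 0)])
    def test_scheme_sign_constraints(self, field, value):
        kwargs = {"match": 2, "mismatch": -3, "gap": -2, field: value}
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)


class TestBuildMatrices:
    def test_perfect_match_scores_length_times_match(self):
        m = build_matrices("ACGT", "ACGT", SCHEMES["none"])
        assert m.score[m.argmax] == 8

    def test_converted_read_scores_as_perfect_under_c_to_t(self):
        m = build_matrices("ATGT", "ACGT", SCHEMES["c_to_t"])
        assert m.score[m.argmax] == 8

    def test_empty_sequences_are_an_error(self):
        with pytest.raises(AlignmentError):
            build_matrices("", "ACGT", SCHEMES["none"])

    def test_matrix_invariants_on_random_instances(self):
        """Zero borders, non-negative scores, STOP exactly at zero cells."""
        rng = random.Random(21)
        for _ in range(50):
            read = "".join(rng.choice("ACGTN") for _ in range(rng.randrange(1, 13)))
            window = "".join(rng.choice("ACGTN") for _ in range(rng.randrange(1, 13)))
            m = build_matrices(read, window, SCHEMES[rng.choice(list(SCHEMES))])
            assert not m.score[0, :].any() and not m.score[:, 0].any()
            assert (m.score >= 0).all()
            assert ((m.direction == STOP) == (m.score == 0)).all()


class TestTraceback:
    def test_perfect_match_traceback(self):
        aln = traceback(build_matrices("ACGT", "ACGT", SCHEMES["none"]))
        assert aln.pairs == [("A", "A"), ("C", "C"), ("G", "G"), ("T", "T")]
        assert (aln.read_start, aln.read_end) == (0, 4)
        assert (aln.window_start, aln.window_end) == (0, 4)

    def test_tie_resolution_prefers_the_stated_rules(self):
        # two optimal local alignments of score 4 end at the same cell; the
        # DIAG>UP>LEFT fill pointers select the gapless GT match
        aln = traceback(build_matrices("AGT", "ACGT", SCHEMES["none"]))
        assert aln.score == 4
        assert aln.pairs == [("G", "G"), ("T", "T")]

    def test_pairs_resum_to_the_argmax_score(self):
        rng = random.Random(33)
        for _ in range(200):
            read = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 13)))
            window = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 13)))
            scheme = SCHEMES[rng.choice(list(SCHEMES))]
            m = build_matrices(read, window, scheme)
            aln = traceback(m)  # traceback itself asserts the re-sum identity
            table = scheme.substitution_table()
            resum = sum(
                scheme.gap
                if "-" in (rb, wb)
                else int(substitution_score(rb, wb, scheme))
                for rb, wb in aln.pairs
            )
            assert resum == aln.score == m.score[m.argmax]


class TestOracleEquivalence:
    def test_scores_and_tracebacks_match_recursive_oracle(self):
        rng = random.Random(77)
        for _ in range(60):
            read = "".join(rng.choice("ACGTN") for _ in range(rng.randrange(1, 13)))
            window = "".join(rng.choice("ACGTN") for _ in range(rng.randrange(1, 13)))
            mode = rng.choice(list(SCHEMES))
            m = build_matrices(read, window, SCHEMES[mode])
            aln = traceback(m)
            score, end, pairs, start = oracle_align(read, window, 2, -3, -2, mode)
            assert aln.score == score
            assert m.argmax == end
            assert aln.pairs == pairs
            assert (aln.read_start, aln.window_start) == start

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        read=st.text(alphabet="ACGT", min_size=1, max_size=10),
        window=st.text(alphabet="ACGT", min_size=1, max_size=10),
        mode=st.sampled_from(["none", "c_to_t", "g_to_a"]),
    )
    def test_score_equals_oracle_property(self, read, window, mode):
        m = build_matrices(read, window, SCHEMES[mode])
        score, _, _, _ = oracle_align(read, window, 2, -3, -2, mode)
        assert int(m.score[m.argmax]) == score

    def test_converting_reference_matched_cytosines_never_lowers_c_to_t_score(self):
        rng = random.Random(13)
        for _ in range(40):
            window = "".join(rng.choice("ACGT") for _ in range(12))
            read = window  # read matching the window exactly
            converted = read.replace("C", "T")
            s_read = int(build_matrices(read, window, SCHEMES["c_to_t"]).score.max())
            s_conv = int(build_matrices(converted, window, SCHEMES["c_to_t"]).score.max())
            assert s_conv >= s_read


class TestAlignInWindow:
    def test_window_span_lifts_to_genome_coordinates(self):
        # place the read at window offset 3 of a window starting at genome 1001
        window = "TTTACGTTTT"
        aln = align_in_window("ACGT", window, 1001, SCHEMES["none"])
        assert (aln.window_start, aln.window_end) == (3, 7)
        assert (aln.genome_start, aln.genome_end) == (1004, 1007)

    def test_planted_read_recovers_its_offset(self):
        rng = random.Random(55)
        window = "".join(rng.choice("ACGT") for _ in range(300))
        for _ in range(10):
            k = rng.randrange(0, 250)
            read = window[k : k + 40]
            aln = align_in_window(read, window, 5001, SCHEMES["none"])
            assert aln.score == 80
            assert aln.genome_start == 5001 + k

    def test_wrong_orientation_scores_much_lower(self):
        rng = random.Random(66)
        window = "".join(rng.choice("ACGT") for _ in range(200))
        read = window[60:110]
        forward = align_in_window(read, window, 1, SCHEMES["none"]).score
        flipped = align_in_window(reverse_complement(read), window, 1, SCHEMES["none"]).score
        assert forward == 100
        assert flipped < 0.5 * forward
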