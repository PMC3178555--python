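"""Feature-incorporated alignment: position scoring, Gotoh DP, traceback."""

import random

import pytest

from cbmfia.core import GAP, ProteinSequence, TemplateRecord, ValidationError
from cbmfia.fia import (
    AlignmentParams,
    PairwiseAlignment,
    ResidueFeatures,
    align_all,
    align_pair,
    position_score,
    substitution_score,
)

from conftest import brute_force_affine, make_ann, random_protein

NO_BONUS = AlignmentParams(har_bonus=0.0, ss_bonus=0.0)


class TestPositionScore:
    def test_har_and_strand_bonuses_stack(self):
        s = position_score(
            "W", "W",
            ResidueFeatures(har=True, state="E"),
            ResidueFeatures(har=True, state="E"),
        )
        assert s == 11 + 5 + 2

    def test_plain_tryptophan_pair(self):
        s = position_score(
            "W", "W",
            ResidueFeatures(har=False, state="L"),
            ResidueFeatures(har=False, state="L"),
        )
        assert s == 11

    def test_loop_match_earns_no_bonus(self):
        s = position_score(
            "A", "A",
            ResidueFeatures(har=False, state="L"),
            ResidueFeatures(har=False, state="L"),
        )
        assert s == substitution_score("A", "A")

    def test_zero_bonuses_reduce_to_matrix(self):
        for a, b in [("W", "Y"), ("A", "G"), ("D", "E")]:
            s = position_score(
                a, b,
                ResidueFeatures(har=True, state="E"),
                ResidueFeatures(har=True, state="E"),
                NO_BONUS,
            )
            assert s == substitution_score(a, b)

    def test_unknown_residue_uses_x_row(self):
        s = position_score(
            "B", "W",
            ResidueFeatures(har=False, state="L"),
            ResidueFeatures(har=False, state="L"),
            NO_BONUS,
        )
        assert s == substitution_score("X", "W")

    def test_gap_rejected(self):
        with pytest.raises(ValidationError):
            position_score(
                "-", "W",
                ResidueFeatures(har=False, state="L"),
                ResidueFeatures(har=False, state="L"),
            )


class TestAlignPair:
    def test_self_alignment_is_gapless(self):
        aln = align_pair(make_ann("GSWNP"), make_ann("GSWNP", seq_id="p"))
        assert (aln.ident, aln.gap_openings, aln.n_columns) == (5, 0, 5)
        assert aln.t_row == aln.p_row == "GSWNP"

    def test_single_terminal_gap(self):
        aln = align_pair(make_ann("W"), make_ann("WA", seq_id="p"))
        assert aln.n_columns == 2
        assert aln.gap_openings == 1
        assert aln.t_row == "W-"
        assert aln.p_row == "WA"
        # BLOSUM62(W,W)=11 minus one gap opening of 11
        assert aln.score == 0

    def test_rows_recover_inputs(self):
        rng = random.Random(7)
        for _ in range(20):
            t, p = random_protein(rng, 1, 15), random_protein(rng, 1, 15)
            aln = align_pair(make_ann(t), make_ann(p, seq_id="p"))
            assert aln.t_row.replace(GAP, "") == t
            assert aln.p_row.replace(GAP, "") == p
            assert not any(
                a == GAP and b == GAP for a, b in zip(aln.t_row, aln.p_row)
            )

    def test_matches_bruteforce_on_small_pairs(self):
        rng = random.Random(42)
        for _ in range(40):
            t, p = random_protein(rng, 1, 5), random_protein(rng, 1, 5)
            aln = align_pair(make_ann(t), make_ann(p, seq_id="p"), NO_BONUS)
            expected = brute_force_affine(
                t, p, substitution_score, NO_BONUS.gap_open, NO_BONUS.gap_extend
            )
            assert aln.score == pytest.approx(expected)

    def test_har_bonus_never_decreases_score(self):
        t = make_ann("AAGSWNPAA", har_flags=[False] * 4 + [True] + [False] * 4)
        p = make_ann("GSWNP", har_flags=[False, False, True, False, False],
                     seq_id="p")
        base = align_pair(t, p, AlignmentParams(har_bonus=0.0, ss_bonus=0.0)).score
        bonus = align_pair(t, p, AlignmentParams(har_bonus=5.0, ss_bonus=0.0)).score
        assert bonus >= base

    def test_score_symmetric_under_swap(self):
        rng = random.Random(3)
        for _ in range(10):
            t = make_ann(random_protein(rng, 2, 10), seq_id="a")
            p = make_ann(random_protein(rng, 2, 10), seq_id="b")
            assert align_pair(t, p).score == align_pair(p, t).score

    def test_gap_openings_counts_runs_in_both_rows(self):
        rng = random.Random(5)
        for _ in range(20):
            t = make_ann(random_protein(rng, 1, 12))
            p = make_ann(random_protein(rng, 1, 12), seq_id="p")
            aln = align_pair(t, p)

            def runs(row):
                return sum(
                    1 for i, c in enumerate(row)
                    if c == GAP and (i == 0 or row[i - 1] != GAP)
                )

            assert aln.gap_openings == runs(aln.t_row) + runs(aln.p_row)
            if aln.gap_openings == 0:
                assert len(t) == len(p) and GAP not in aln.t_row

    def test_free_end_gaps_leave_overhangs_unpenalized(self):
        t = make_ann("AAAGSWNPAAA")
        p = make_ann("GSWNP", seq_id="p")
        free = align_pair(t, p, AlignmentParams(free_end_gaps=True))
        penalized = align_pair(t, p)
        assert free.score >= penalized.score
        assert free.p_row.strip(GAP) == "GSWNP"

    def test_secondary_structure_steers_register(self):
        # two equally scoring tryptophans; shared strand state disambiguates
        t = make_ann("AWAAAWA", states="LELLLLL")
        p = make_ann("AWA", states="LEL", seq_id="p")
        aln = align_pair(t, p, AlignmentParams(free_end_gaps=True, ss_bonus=2.0))
        pairs = [x for x in aln.aligned_pairs() if x[0] and x[1]]
        assert (2, 2) in pairs  # strand W aligned to strand W


class TestAlignAll:
    def test_one_alignment_per_template_in_order(self, tiny_benchmark):
        target = tiny_benchmark.targets[0]
        pool = align_all(target, tiny_benchmark.templates)
        assert [a.template_id for a in pool] == [
            t.template_id for t in tiny_benchmark.templates
        ]
        assert all(a.template is not None for a in pool)

    def test_single_template(self, tiny_benchmark):
        pool = align_all(tiny_benchmark.targets[0], tiny_benchmark.templates[:1])
        assert len(pool) == 1

    def test_empty_template_set_rejected(self, tiny_benchmark):
        with pytest.raises(ValidationError):
            align_all(tiny_benchmark.targets[0], [])


class TestAlignmentParams:
    def test_extend_must_not_exceed_open(self):
        with pytest.raises(ValidationError):
            AlignmentParams(gap_open=1.0, gap_extend=2.0)

    def test_negative_bonus_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentParams(har_bonus=-1.0)


def test_pairwise_alignment_rejects_gap_in_both_column():
    with pytest.raises(ValidationError):
        PairwiseAlignment(
            target_id="t", template_id="p", t_row="A-A", p_row="A-A", score=0.0
        )
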