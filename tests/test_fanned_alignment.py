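"""Fanned multi-reference alignment: fill rules, strand choice, backtrack,
scoring, and the concatenation-oracle equivalence."""
import random

import numpy as np
import pytest

from fusionlens import (ReadSequence, Reference, ReferencePanel, align_read,
                        alignment_score, backtrack, choose_strand,
                        fill_breakpoint_column, fill_fanned, fill_left_stack,
                        fill_right_stack, reverse_complement)

from .conftest import random_panel, random_seq
from .oracles import concat_best, concat_pair_scores


def panel_of(left, right):
    return ReferencePanel(
        [Reference(f"L{k}", "custom", s) for k, s in enumerate(left)],
        [Reference(f"R{k}", "custom", s) for k, s in enumerate(right)])


# ---------------------------------------------------------------- fill rules

def test_left_stack_hand_filled_cell(scheme):
    """Read AC vs left ref AC: only column 1 (base A) is scored; H(1,1)=1."""
    panel = panel_of(["AC"], ["GG"])
    left = fill_left_stack(ReadSequence("r", "AC"), panel, scheme)
    assert left[0].shape == (3, 2)
    assert left[0][1, 1] == 1


def test_left_stack_local_initialization_is_zero(scheme):
    panel = panel_of(["ACGTA", "TT"], ["GG"])
    left = fill_left_stack(ReadSequence("r", "GATC"), panel, scheme)
    for H in left:
        assert (H[0, :] == 0).all() and (H[:, 0] == 0).all()


def test_left_stack_semiglobal_column0_is_gap_ramp(scheme):
    panel = panel_of(["ACGTA"], ["GG"])
    left = fill_left_stack(ReadSequence("r", "AAA"), panel, scheme,
                           mode="semiglobal")
    assert left[0][3, 0] == -3
    assert list(left[0][:, 0]) == [0, -1, -2, -3]


def test_length1_left_reference_contributes_via_breakpoint_column(scheme):
    """A 1-base left reference has only its initialized column, yet its single
    base still feeds the breakpoint column diagonal."""
    panel = panel_of(["A"], ["CCC"])
    read = ReadSequence("r", "AC")
    left = fill_left_stack(read, panel, scheme)
    assert left[0].shape == (3, 1)
    bk = fill_breakpoint_column(read, left, panel, scheme)
    assert bk[1] == 1  # read base A matched against the lone left base


def test_breakpoint_column_hand_filled(scheme):
    """Read AC, left ref AC: diagonal from H_left(1,1)=1 plus match on C."""
    panel = panel_of(["AC"], ["GG"])
    read = ReadSequence("r", "AC")
    left = fill_left_stack(read, panel, scheme)
    bk = fill_breakpoint_column(read, left, panel, scheme)
    assert bk[0] == 0
    assert bk[2] == 2


def test_breakpoint_column_floor_dominates_without_matches(scheme):
    panel = panel_of(["AAAA"], ["AAAA"])
    read = ReadSequence("r", "CCCC")
    left = fill_left_stack(read, panel, scheme)
    bk = fill_breakpoint_column(read, left, panel, scheme)
    assert (bk == 0).all()


def test_breakpoint_column_pairs_each_matrix_with_its_own_last_base(scheme):
    """Two left refs differing only in the last base: the column must realize
    its value through the reference whose last base the read matches, which a
    per-reference single-left computation confirms."""
    read = ReadSequence("r", "GGAT")
    both = panel_of(["GGAC", "GGAT"], ["CCCC"])
    left = fill_left_stack(read, both, scheme)
    bk_both = fill_breakpoint_column(read, left, both, scheme)
    singles = []
    for seq in ("GGAC", "GGAT"):
        single = panel_of([seq], ["CCCC"])
        bk = fill_breakpoint_column(
            read, fill_left_stack(read, single, scheme), single, scheme)
        singles.append(bk)
    assert (bk_both == np.maximum(singles[0], singles[1])).all()
    assert bk_both[4] == 4  # realized only through the GGAT reference
    assert singles[0][4] < 4


def test_right_stack_column0_equals_breakpoint_column(scheme):
    panel = panel_of(["AC"], ["GATTACA", "CCC"])
    read = ReadSequence("r", "ACG")
    left = fill_left_stack(read, panel, scheme)
    bk = fill_breakpoint_column(read, left, panel, scheme)
    right = fill_right_stack(read, panel, bk, scheme)
    for H in right:
        assert (H[:, 0] == bk).all()


def test_right_stack_perfect_match_reaches_ref_length(scheme):
    panel = panel_of(["TT"], ["GATTACA"])
    read = ReadSequence("r", "GATTACA")
    mats = fill_fanned(read, panel, scheme)
    assert max(int(H.max()) for H in mats.right) == 7


# ------------------------------------------------------------- strand choice

def test_reverse_complement_read_selects_minus_strand(scheme):
    ref = "ACGTACGTACGTTGCAACGT"
    panel = panel_of([ref], ["GGGGG"])
    read = ReadSequence("r", reverse_complement(ref))
    res = align_read(read, panel, scheme)
    assert res.strand == "-"
    assert res.alpha == 100.0


def test_palindromic_read_ties_to_forward(scheme):
    read = ReadSequence("r", "ACGT")  # its own reverse complement
    panel = panel_of(["ACGT"], ["ACGT"])
    _, _, strand = choose_strand(read, panel, scheme)
    assert strand == "+"


def test_chosen_orientation_maximum_matches_independent_recomputation(scheme):
    rng = random.Random(5)
    for _ in range(40):
        panel = random_panel(rng)
        read = random_seq(rng, rng.randint(1, 12))
        fwd = concat_best(read, [r.sequence for r in panel.left_refs],
                          [r.sequence for r in panel.right_refs])
        rev = concat_best(reverse_complement(read),
                          [r.sequence for r in panel.left_refs],
                          [r.sequence for r in panel.right_refs])
        res = align_read(ReadSequence("r", read), panel, scheme)
        assert res.score_raw == max(fwd, rev)


# ------------------------------------------------------------------ backtrack

def test_junction_crossing_read_is_spanning_with_chosen_pair(scheme):
    left = ["AAAAAAACGTAC", "TTTTTTTGGCAT"]
    right = ["GATTCCAGGA", "CCCCCCCCCC"]
    read = ReadSequence("r", left[1][-6:] + right[0][:6])
    res = align_read(read, panel_of(left, right), scheme)
    assert res.spanning
    assert res.left_ref_index == 1
    assert res.right_ref_index == 0
    assert res.alpha == 100.0


def test_read_contained_in_right_reference_is_not_spanning(scheme):
    panel = panel_of(["TTTTTTTT"], ["GATTACAGGC"])
    read = ReadSequence("r", "TACAGG")
    res = align_read(read, panel, scheme)
    assert not res.spanning
    assert res.left_ref_index is None
    assert res.right_ref_index == 0
    assert res.alpha == 100.0


def test_random_instances_match_concatenation_oracle(scheme):
    """Score equality with max-over-pairs classic SW; the chosen pair must
    achieve that maximum when the alignment spans."""
    rng = random.Random(99)
    for _ in range(150):
        panel = random_panel(rng)
        read_str = random_seq(rng, rng.randint(1, 12))
        read = ReadSequence("r", read_str)
        mats = fill_fanned(read, panel, scheme)
        res = backtrack(mats, panel, read, scheme)
        pairs = concat_pair_scores(read_str,
                                   [r.sequence for r in panel.left_refs],
                                   [r.sequence for r in panel.right_refs])
        best = max(s for s, _, _ in pairs)
        assert res.score_raw == best, (read_str, panel)
        if res.spanning:
            chosen = [s for s, fl, fr in pairs
                      if fl == res.left_ref_index and fr == res.right_ref_index]
            assert chosen[0] == best


# -------------------------------------------------------------------- scoring

def test_perfect_thirty_base_read_scores_100(scheme):
    rng = random.Random(1)
    ref = random_seq(rng, 60)
    panel = panel_of([ref], [random_seq(rng, 40)])
    read = ReadSequence("r", ref[10:40])
    res = align_read(read, panel, scheme)
    assert res.alpha == 100.0


def test_zero_raw_score_gives_alpha_zero(scheme):
    res = align_read(ReadSequence("r", "NNNNNN"),
                     panel_of(["ACGT"], ["ACGT"]), scheme)
    assert res.score_raw == 0 and res.alpha == 0.0
    assert res.aligned_read == ""


def test_single_internal_mismatch_costs_ten_points_on_20mer(scheme):
    rng = random.Random(3)
    ref = random_seq(rng, 50)
    read = list(ref[10:30])
    read[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[10]]
    res = align_read(ReadSequence("r", "".join(read)),
                     panel_of([ref], ["GGGGGGGG"]), scheme)
    assert res.score_raw == 18
    assert res.alpha == 90.0


def test_alignment_score_rejects_empty_read():
    with pytest.raises(ValueError, match="cannot score empty read"):
        alignment_score(5, 0)


def test_empty_read_aligns_empty(scheme):
    res = align_read(ReadSequence("r", ""), panel_of(["ACGT"], ["ACGT"]), scheme)
    assert res.score_raw == 0 and res.aligned_read == ""


# ------------------------------------------------------------------ invariants

def test_local_alpha_bounded_and_matrices_nonnegative(scheme):
    rng = random.Random(12)
    for _ in range(50):
        panel = random_panel(rng)
        read = ReadSequence("r", random_seq(rng, rng.randint(1, 12)))
        mats = fill_fanned(read, panel, scheme)
        assert all(int(H.min()) >= 0 for H in mats.left + mats.right)
        assert int(mats.bkpt.min()) >= 0
        res = backtrack(mats, panel, read, scheme)
        assert 0.0 <= res.alpha <= 100.0


def test_strand_involution(scheme):
    """Reverse-complementing the read preserves alpha and flips the strand
    whenever the orientation maxima differ."""
    rng = random.Random(21)
    for _ in range(60):
        panel = random_panel(rng)
        read = random_seq(rng, rng.randint(2, 12))
        a = align_read(ReadSequence("r", read), panel, scheme)
        b = align_read(ReadSequence("r", reverse_complement(read)), panel, scheme)
        assert a.alpha == b.alpha
        fwd = concat_best(read, [r.sequence for r in panel.left_refs],
                          [r.sequence for r in panel.right_refs])
        rev = concat_best(reverse_complement(read),
                          [r.sequence for r in panel.left_refs],
                          [r.sequence for r in panel.right_refs])
        if fwd != rev:
            assert {a.strand, b.strand} == {"+", "-"}


def test_semiglobal_traces_every_read_base(scheme):
    rng = random.Random(31)
    for _ in range(60):
        panel = random_panel(rng)
        read = random_seq(rng, rng.randint(1, 12))
        res = align_read(ReadSequence("r", read), panel, scheme,
                         mode="semiglobal")
        consumed = sum(1 for c in res.aligned_read if c != "-")
        assert consumed == len(read)


def test_semiglobal_equals_local_on_perfect_full_length_reads(scheme):
    rng = random.Random(41)
    for _ in range(20):
        left = random_seq(rng, 15)
        right = random_seq(rng, 15)
        panel = panel_of([left], [right])
        cut = rng.randint(1, 9)
        read = ReadSequence("r", left[-cut:] + right[:10 - cut])
        loc = align_read(read, panel, scheme, mode="local")
        sg = align_read(read, panel, scheme, mode="semiglobal")
        assert loc.alpha == sg.alpha == 100.0


def test_spanning_iff_both_reference_indices_set(scheme):
    rng = random.Random(51)
    for _ in range(80):
        panel = random_panel(rng)
        read = ReadSequence("r", random_seq(rng, rng.randint(1, 12)))
        res = align_read(read, panel, scheme)
        both = res.left_ref_index is not None and res.right_ref_index is not None
        assert res.spanning == both
        if res.spanning:
            left_bases = sum(1 for a, s in zip(res.aligned_read, res.column_sides)
                             if a != "-" and s == "L")
            right_bases = sum(1 for a, s in zip(res.aligned_read, res.column_sides)
                              if a != "-" and s == "R")
            assert left_bases >= 1 and right_bases >= 1


def test_alignment_is_deterministic(scheme):
    rng = random.Random(61)
    panel = random_panel(rng)
    read = ReadSequence("r", random_seq(rng, 10))
    assert align_read(read, panel, scheme) == align_read(read, panel, scheme)


def test_no_double_gap_columns_and_equal_lengths(scheme):
    rng = random.Random(71)
    for mode in ("local", "semiglobal"):
        for _ in range(30):
            panel = random_panel(rng)
            read = ReadSequence("r", random_seq(rng, rng.randint(1, 12)))
            res = align_read(read, panel, scheme, mode=mode)
            assert len(res.aligned_read) == len(res.aligned_ref) == len(res.column_sides)
            for a, b in zip(res.aligned_read, res.aligned_ref):
                assert not (a == "-" and b == "-")
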