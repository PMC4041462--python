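"""Coding- and signal-joint decomposition, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdjoin import (
    AnnotationConfig,
    AnnotationError,
    annotate_coding_joint,
    annotate_signal_joint,
    revcomp,
)
from vdjoin.annotate import signal_flanks
from vdjoin.simulate import SimulationParams, simulate_batch

from .conftest import LEFT_FLANK, RIGHT_FLANK, make_locus, read_for


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_decompose(read, L, R, mh_min=2):
    """Exhaustive search over (left_retained, right_retained) decompositions
    minimising deletions + insertions; ties prefer the larger left match,
    then the larger right match.  Returns (a, b, ins_len, mh_len)."""
    best = None
    for a in range(min(len(read), len(L)) + 1):
        if read[:a] != L[:a] or "N" in read[:a]:
            continue
        for b in range(min(len(read), len(R)) + 1):
            if b and (read[-b:] != R[-b:] or "N" in read[-b:]):
                continue
            if a + b <= len(read):
                ins, mh = len(read) - a - b, 0
            else:
                mh = a + b - len(read)
                ins = 0
                if mh < mh_min:
                    continue
            cost = (len(L) - a) + (len(R) - b) + ins
            key = (cost, -a, -b)
            if best is None or key < best[0]:
                best = (key, (a, b, ins, mh))
    return best[1] if best else None


def brute_force_p(middle, flank_terminal_rc, max_p):
    """Longest contiguous palindromic extension, by direct enumeration."""
    best = 0
    for k in range(1, min(max_p, len(middle)) + 1):
        if middle[:k] == flank_terminal_rc[:k]:
            best = k
    return best


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "junction, expected",
    [
        # perfect blunt join
        (LEFT_FLANK + RIGHT_FLANK,
         dict(del_left=0, del_right=0, n_insertion="", microhomology_len=0)),
        # two bases nibbled from the left coding end
        (LEFT_FLANK[:-2] + RIGHT_FLANK,
         dict(del_left=2, del_right=0, n_insertion="", p_left="", p_right="")),
        # P nucleotides: ...TACTTC + GA, the reverse-complement palindome of TC
        (LEFT_FLANK + "GA" + RIGHT_FLANK,
         dict(del_left=0, del_right=0, p_left="GA", n_insertion="", p_right="")),
    ],
)
def test_coding_joint_examples(coding_locus, junction, expected):
    ann = annotate_coding_joint(read_for(coding_locus, junction))
    for field, value in expected.items():
        assert getattr(ann, field) == value, field


def test_coding_joint_microhomology():
    """Overlap shared by both flanks (left ends ...TACTTC, right starts
    TCGGAACA) is reported once as microhomology."""
    locus = make_locus(right="TC" + RIGHT_FLANK)
    junction = LEFT_FLANK + RIGHT_FLANK  # ...TACTTC|GGAACA...: TC assignable to both
    ann = annotate_coding_joint(read_for(locus, junction))
    assert ann.microhomology_len == 2
    assert ann.microhomology_seq == "TC"
    assert ann.del_left == 0 and ann.del_right == 0
    # below-threshold overlaps are folded into the left retained stretch
    ann2 = annotate_coding_joint(read_for(locus, junction),
                                 config=AnnotationConfig(microhomology_min=3))
    assert ann2.microhomology_len == 0
    assert ann2.left_retained == len(LEFT_FLANK)


def test_unalignable_read_raises(coding_locus):
    with pytest.raises(AnnotationError, match="neither"):
        annotate_coding_joint(read_for(coding_locus, "CCCCCCCC", read_id="bad"))


def test_wrong_joint_kind_raises(signal_locus):
    with pytest.raises(AnnotationError, match="not a coding locus"):
        annotate_coding_joint(read_for(signal_locus, "ACGT"))


def test_in_frame_classification(coding_locus):
    blunt = annotate_coding_joint(read_for(coding_locus, LEFT_FLANK + RIGHT_FLANK))
    assert blunt.in_frame == "in"  # net change 0
    plus2 = annotate_coding_joint(read_for(coding_locus, LEFT_FLANK + "GT" + RIGHT_FLANK))
    assert plus2.in_frame == "out"  # +2 not divisible by 3
    anchorless = make_locus(anchors=(None, 0))
    ann = annotate_coding_joint(read_for(anchorless, LEFT_FLANK + RIGHT_FLANK))
    assert ann.in_frame == "unknown"


def test_p_only_on_unresected_ends(coding_locus):
    """A deleted end cannot carry P nucleotides even if the inserted bases
    happen to form the palindrome."""
    junction = LEFT_FLANK[:-1] + "GA" + RIGHT_FLANK
    ann = annotate_coding_joint(read_for(coding_locus, junction))
    assert ann.del_left == 1
    assert ann.p_left == ""


def test_p_extension_matches_bruteforce(coding_locus, rng):
    cfg = AnnotationConfig()
    for _ in range(200):
        mid = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 6)))
        ann = annotate_coding_joint(
            read_for(coding_locus, LEFT_FLANK + mid + RIGHT_FLANK))
        if ann.del_left == 0 and ann.microhomology_len == 0:
            middle = ann.p_left + ann.n_insertion + ann.p_right
            expected = brute_force_p(middle, revcomp(LEFT_FLANK[-cfg.max_p_length:]),
                                     cfg.max_p_length)
            assert len(ann.p_left) == expected


# ---------------------------------------------------------------------------
# oracle equivalence and reconstruction properties
# ---------------------------------------------------------------------------

@given(middle=st.text(alphabet="ACGT", max_size=8),
       dl=st.integers(0, 8), dr=st.integers(0, 8))
@settings(deadline=None, max_examples=200)
def test_greedy_equals_bruteforce_on_constructed_joints(middle, dl, dr):
    """Greedy decomposition agrees with exhaustive minimal-edit search on
    junction windows <= 30 nt, including the documented left tie-break."""
    locus = make_locus()
    L, R = LEFT_FLANK, RIGHT_FLANK
    junction = L[: len(L) - dl] + middle + R[dr:]
    assert len(junction) - len(middle) + 8 <= 42  # windows stay small
    try:
        ann = annotate_coding_joint(read_for(locus, junction))
    except AnnotationError:
        return
    oracle = brute_force_decompose(junction, L, R)
    assert (ann.left_retained, ann.right_retained) == oracle[:2]
    assert len(ann.insertion) == oracle[2]
    assert ann.microhomology_len == oracle[3]


@given(junction=st.text(alphabet="ACGT", min_size=2, max_size=30))
@settings(deadline=None, max_examples=200)
def test_greedy_equals_bruteforce_on_random_windows(junction):
    """Same equivalence on fully random short windows against short flanks."""
    L, R = "TACTTC", "GGAACA"
    locus = make_locus(left=L, right=R)
    try:
        ann = annotate_coding_joint(read_for(locus, junction))
    except AnnotationError:
        return
    oracle = brute_force_decompose(junction, L, R)
    assert (ann.left_retained, ann.right_retained, len(ann.insertion),
            ann.microhomology_len) == oracle


def test_reconstruction_invariant_on_simulated_cohort(coding_locus):
    """retained + P + N + retained - microhomology reproduces every read."""
    params = SimulationParams(seed=99, n_junctions=400, joint_kind="coding",
                              p_microhomology_join=0.1, p_adr_mechanism=0.1)
    reads, _ = simulate_batch(coding_locus, params)
    for read in reads:
        ann = annotate_coding_joint(read)
        total = (ann.left_retained + len(ann.insertion) + ann.right_retained
                 - ann.microhomology_len)
        assert total == len(read.sequence)


def test_truth_recovery_on_unambiguous_flanks(clean_locus):
    """With junction-proximal flank runs sharing no 2-mer and insertions that
    can extend neither flank, annotation recovers the simulated truth."""
    # composition avoids A (left run) and C (right run): G/T insertions only
    params = SimulationParams(seed=7, n_junctions=500, joint_kind="coding",
                              deletion_mean=2.0, p_p_nucleotides=0.0,
                              n_base_composition=(0.0, 0.0, 0.5, 0.5))
    reads, truths = simulate_batch(clean_locus, params)
    for read, truth in zip(reads, truths):
        ann = annotate_coding_joint(read)
        assert ann.del_left == truth.del_left
        assert ann.del_right == truth.del_right
        assert ann.insertion == truth.p_left + truth.n_insertion + truth.p_right


# ---------------------------------------------------------------------------
# signal joints
# ---------------------------------------------------------------------------

def test_precise_signal_joint(signal_locus):
    SL, SR = signal_flanks(signal_locus)
    assert SL.endswith(revcomp("CACAGTG")) and SR.startswith("CACAGTG")
    ann = annotate_signal_joint(read_for(signal_locus, SL + SR))
    assert ann.precise
    assert ann.apal1_site_present  # blunt heptamer fusion contains GTGCAC
    assert ann.del_left_rss == ann.del_right_rss == 0
    assert ann.insertion == ""


def test_deleted_signal_joint(signal_locus):
    SL, SR = signal_flanks(signal_locus)
    ann = annotate_signal_joint(read_for(signal_locus, SL[:-3] + SR))
    assert not ann.precise
    assert ann.del_left_rss == 3 and ann.del_right_rss == 0
    assert not ann.apal1_site_present


def test_inserted_signal_joint(signal_locus):
    SL, SR = signal_flanks(signal_locus)
    ann = annotate_signal_joint(read_for(signal_locus, SL + "CC" + SR))
    assert not ann.precise
    assert ann.insertion == "CC"
    assert not ann.apal1_site_present
    assert not ann.miscleavage  # CC matches neither coding flank


def test_miscleavage_detection(signal_locus):
    """Inserted bases copying the coding flank abutting an RSS flag
    miscleavage; the left-end copy reads as the flank tail's reverse
    complement because the left RSS is inverted in the joint."""
    SL, SR = signal_flanks(signal_locus)
    left_copy = revcomp(signal_locus.left_segment.coding_flank[-2:])
    ann = annotate_signal_joint(read_for(signal_locus, SL + left_copy + SR))
    assert ann.miscleavage and ann.miscleavage_seq == left_copy
    right_copy = signal_locus.right_segment.coding_flank[-3:]
    ann = annotate_signal_joint(read_for(signal_locus, SL + right_copy + SR))
    assert ann.miscleavage and ann.miscleavage_seq == right_copy
    # single-base match stays below miscleavage_min_match
    one = revcomp(signal_locus.left_segment.coding_flank[-1])
    ann = annotate_signal_joint(read_for(signal_locus, SL + one + SR))
    assert not ann.miscleavage


def test_precise_implies_apal1_on_simulated_reads(signal_locus):
    params = SimulationParams(seed=11, n_junctions=300, joint_kind="signal",
                              sj_imprecision_prob=0.5, p_miscleavage=0.2)
    reads, _ = simulate_batch(signal_locus, params)
    for read in reads:
        ann = annotate_signal_joint(read)
        if ann.precise:
            assert ann.apal1_site_present
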