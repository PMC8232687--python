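"""Read classes, junction accuracy, dual-guide deletion scoring."""

import numpy as np
import pytest

from nhejacc.classification import (
    ClassifiedRead,
    ContractError,
    JunctionCall,
    Orientation,
    ReadClass,
    assess_dual_deletion,
    assess_junction,
    classify_read,
    detect_dsodn,
    summarize_accuracy,
)
from nhejacc.read_processing import CountedRead
from nhejacc.synthetic_data import make_dual_design
from nhejacc.target_model import (
    EndLabel,
    Side,
    compute_cut_site,
    revcomp,
)


def perfect_integration(target, tag, orientation=Orientation.FORWARD):
    cut = compute_cut_site(target).cut
    t = tag.sequence if orientation is Orientation.FORWARD else revcomp(tag.sequence)
    return target.reference[:cut] + t + target.reference[cut:]


class TestDetectDsodn:
    def test_full_tag_detected_forward(self, toy_target, tag):
        read = perfect_integration(toy_target, tag)
        assert detect_dsodn(CountedRead(read, 1), tag) is Orientation.FORWARD

    def test_reference_has_no_tag(self, toy_target, tag):
        assert detect_dsodn(CountedRead(toy_target.reference, 1), tag) is None

    def test_internal_10mer_fragment_detected(self, toy_target, tag):
        fragment = tag.sequence[12:22]
        read = toy_target.reference[:50] + fragment + toy_target.reference[50:]
        assert detect_dsodn(CountedRead(read, 1), tag) is Orientation.FORWARD
        # exhaustive k-mer scan oracle: the fragment is one of the tag's 10-mers
        kmers = {tag.sequence[i : i + 10] for i in range(len(tag.sequence) - 9)}
        assert fragment in kmers

    def test_reverse_orientation_detected(self, toy_target, tag):
        read = perfect_integration(toy_target, tag, Orientation.REVERSE)
        assert detect_dsodn(CountedRead(read, 1), tag) is Orientation.REVERSE


class TestClassifyRead:
    def test_unedited_reference_is_wild_type(self, toy_target, tag):
        cr = classify_read(CountedRead(toy_target.reference, 1), toy_target, tag)
        assert cr.cls is ReadClass.WILD_TYPE

    def test_perfect_integration_is_dsodn(self, toy_target, tag):
        read = perfect_integration(toy_target, tag)
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        assert cr.cls is ReadClass.DSODN_INSERTED

    def test_deletion_without_tag_is_mutation(self, toy_target, tag):
        cut = compute_cut_site(toy_target).cut
        read = toy_target.reference[: cut - 1] + toy_target.reference[cut:]
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        assert cr.cls is ReadClass.MUTATION

    def test_wt_precedence_over_tag(self, toy_target, tag):
        # tag present but far from the intact cut site: WT wins (step order)
        read = toy_target.reference + tag.sequence
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        assert cr.cls is ReadClass.WILD_TYPE


class TestAssessJunction:
    def test_perfect_integration_accurate_at_both_ends(self, toy_target, tag):
        read = perfect_integration(toy_target, tag)
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        for end in EndLabel:
            call = assess_junction(cr, toy_target, tag, end)
            assert call.accurate and call.dsodn_orientation is Orientation.FORWARD

    def test_reverse_integration_accurate_at_both_ends(self, toy_target, tag):
        read = perfect_integration(toy_target, tag, Orientation.REVERSE)
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        assert all(
            assess_junction(cr, toy_target, tag, end).accurate for end in EndLabel
        )

    def test_proximal_deletion_breaks_only_proximal_junction(self, toy_target, tag):
        geom = compute_cut_site(toy_target)
        cut = geom.cut
        ref = toy_target.reference
        # PAM-proximal side of this '+' target is the right side; delete the
        # genomic base adjacent to the cut there
        assert geom.proximal_side is Side.RIGHT
        read = ref[:cut] + tag.sequence + ref[cut + 1 :]
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        assert assess_junction(cr, toy_target, tag, EndLabel.PAM_DISTAL).accurate
        assert not assess_junction(cr, toy_target, tag, EndLabel.PAM_PROXIMAL).accurate

    def test_inserted_base_at_junction_is_inaccurate(self, toy_target, tag):
        cut = compute_cut_site(toy_target).cut
        ref = toy_target.reference
        read = ref[:cut] + "A" + tag.sequence + ref[cut:]
        # make sure the spacer actually breaks contiguity (not tag[0])
        if tag.sequence[0] == "A":
            read = ref[:cut] + "C" + tag.sequence + ref[cut:]
        cr = classify_read(CountedRead(read, 1), toy_target, tag)
        left_end = compute_cut_site(toy_target).end_of(Side.LEFT)
        assert not assess_junction(cr, toy_target, tag, left_end).accurate

    def test_contract_error_for_non_dsodn_read(self, toy_target, tag):
        cr = classify_read(CountedRead(toy_target.reference, 1), toy_target, tag)
        with pytest.raises(ContractError):
            assess_junction(cr, toy_target, tag, EndLabel.PAM_DISTAL)


class TestSummaries:
    def test_hand_tally(self):
        rows = [(ReadClass.WILD_TYPE, 10, None, None)]
        rows += [(ReadClass.DSODN_INSERTED, 1, d, p)
                 for d, p in [(True, True), (True, True), (True, False),
                              (True, False), (False, False), (False, False)]]
        rows += [(ReadClass.MUTATION, 4, None, None)]
        reads = []
        for i, (cls, count, d, p) in enumerate(rows):
            junctions = ()
            if cls is ReadClass.DSODN_INSERTED:
                junctions = (
                    JunctionCall(EndLabel.PAM_DISTAL, d, Orientation.FORWARD),
                    JunctionCall(EndLabel.PAM_PROXIMAL, p, Orientation.FORWARD),
                )
            seq = "ACGT" * 5 + "ACGT"[i % 4] * (i + 1)  # distinct dummy sequences
            reads.append(ClassifiedRead(CountedRead(seq, count), cls, junctions))
        s = summarize_accuracy(reads, "hand")
        assert (s.n_total, s.n_wt, s.n_dsodn, s.n_mutation) == (20, 10, 6, 4)
        assert s.accuracy[EndLabel.PAM_DISTAL] == pytest.approx(4 / 6)
        assert s.accuracy[EndLabel.PAM_PROXIMAL] == pytest.approx(2 / 6)

    def test_all_wild_type_gives_undefined_accuracy(self):
        reads = [ClassifiedRead(CountedRead("ACGT" * 10, 7), ReadClass.WILD_TYPE)]
        s = summarize_accuracy(reads, "wt_only")
        assert s.n_dsodn == 0
        assert s.accuracy[EndLabel.PAM_DISTAL] is None

    def test_accuracy_monotonicity(self):
        base = [
            ClassifiedRead(
                CountedRead("G" * 21, 5), ReadClass.DSODN_INSERTED,
                (JunctionCall(EndLabel.PAM_DISTAL, True, Orientation.FORWARD),),
            ),
            ClassifiedRead(
                CountedRead("C" * 21, 5), ReadClass.DSODN_INSERTED,
                (JunctionCall(EndLabel.PAM_DISTAL, False, Orientation.FORWARD),),
            ),
        ]
        acc0 = summarize_accuracy(base, "m").accuracy[EndLabel.PAM_DISTAL]
        plus_acc = base + [
            ClassifiedRead(
                CountedRead("T" * 21, 3), ReadClass.DSODN_INSERTED,
                (JunctionCall(EndLabel.PAM_DISTAL, True, Orientation.FORWARD),),
            )
        ]
        plus_inacc = base + [
            ClassifiedRead(
                CountedRead("A" * 21, 3), ReadClass.DSODN_INSERTED,
                (JunctionCall(EndLabel.PAM_DISTAL, False, Orientation.FORWARD),),
            )
        ]
        assert summarize_accuracy(plus_acc, "m").accuracy[EndLabel.PAM_DISTAL] >= acc0
        assert summarize_accuracy(plus_inacc, "m").accuracy[EndLabel.PAM_DISTAL] <= acc0


@pytest.fixture(scope="module")
def design():
    return make_dual_design(np.random.default_rng(11), "PAM_in")


class TestDualDeletion:
    def test_precise_excision_is_accurate(self, design):
        ref = design.site_a.reference
        read = ref[: design.geometry_a.cut] + ref[design.geometry_b.cut :]
        nj, nacc, acc = assess_dual_deletion([CountedRead(read, 2)], design)
        assert (nj, nacc, acc) == (2, 2, 1.0)

    def test_two_nt_loss_at_joint_is_inaccurate(self, design):
        ref = design.site_a.reference
        read = ref[: design.geometry_a.cut - 2] + ref[design.geometry_b.cut :]
        nj, nacc, acc = assess_dual_deletion([CountedRead(read, 1)], design)
        assert (nj, nacc, acc) == (1, 0, 0.0)

    def test_hand_tally_seven_of_ten(self, design):
        ref = design.site_a.reference
        ca, cb = design.geometry_a.cut, design.geometry_b.cut
        precise = CountedRead(ref[:ca] + ref[cb:], 7)
        sloppy = CountedRead(ref[: ca - 3] + ref[cb:], 3)
        nj, nacc, acc = assess_dual_deletion([precise, sloppy], design)
        assert (nj, nacc) == (10, 7)
        assert acc == pytest.approx(0.7)

    def test_wild_type_reads_are_not_junction_reads(self, design):
        nj, nacc, acc = assess_dual_deletion(
            [CountedRead(design.site_a.reference, 5)], design
        )
        assert (nj, nacc, acc) == (0, 0, None)

    def test_configuration_labels(self):
        for conf in ("PAM_in", "PAM_out", "PAM_in_out"):
            d = make_dual_design(np.random.default_rng(3), conf)
            assert d.configuration.value == conf
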