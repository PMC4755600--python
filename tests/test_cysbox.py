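"""Gap-signature box scanning and DP segmentation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modmt.cysbox import (
    SEVEN_CYS_BOX,
    BoxProfile,
    _select_optimal,
    architecture_report,
    decompose,
    render_report_text,
    scan_boxes,
)
from modmt.errors import InvalidProfileError
from modmt.records import AMINO_ACIDS, ProteinRecord
from modmt.synthetic_data import ArchitectureSpec, make_protein

#: A perfect consensus instance with every X as Gly.
PERFECT_BOX = "CGCGGGCSCPPGGCGCAGCP"


def test_perfect_box_in_gly_background():
    rec = ProteinRecord("p", "G" * 10 + PERFECT_BOX + "G" * 10)
    boxes = scan_boxes(rec)
    assert len(boxes) == 1
    box = boxes[0]
    assert (box.start, box.end) == (11, 29)  # first..last Cys
    assert box.kind == "seven_cys"
    # base 7 + all six conserved-residue bonuses, no charged flanks
    assert box.score == pytest.approx(13.0)


def test_cys_free_sequence_yields_nothing():
    rec = ProteinRecord("g", "GAGAGAGAGAGAGAGAGAGA")
    assert scan_boxes(rec) == []
    arch = decompose(rec)
    assert arch.boxes == () and arch.unassigned_cys == ()


def test_ncrassa_matches_box_at_tolerance_two(ncrassa):
    """The 26-mer paradigm MT aligns to the 7-Cys box: its gap vector
    [1,5,1,3,1,2] is within +-2 of the consensus [1,3,1,4,1,2]."""
    boxes = scan_boxes(ncrassa)
    assert len(boxes) == 1
    assert boxes[0].cys_positions == (4, 6, 12, 14, 18, 20, 23)
    assert (boxes[0].start, boxes[0].end) == (4, 23)


def test_two_disjoint_perfect_boxes_both_reported():
    rec = ProteinRecord("two", PERFECT_BOX + "GAGAGAGAGA" + PERFECT_BOX)
    boxes = scan_boxes(rec)
    assert len(boxes) == 2
    arch = decompose(rec)
    assert arch.totals["seven_cys"] == 2
    assert len(arch.linkers) == 1


def test_empty_gap_signature_rejected():
    with pytest.raises(InvalidProfileError):
        BoxProfile(name="bad", gap_signature=())


def test_scan_requires_a_profile(ncrassa):
    with pytest.raises(InvalidProfileError):
        scan_boxes(ncrassa, profiles=[])


def test_decompose_recovers_paper_architecture():
    """Six 7-Cys + two 6-Cys boxes + three prefix Cys round-trip."""
    record, truth = make_protein(ArchitectureSpec(
        n_seven_cys_boxes=6, n_six_cys_boxes=2, n_prefix_cys=3, seed=11))
    assert record.sequence.count("C") == 6 * 7 + 2 * 6 + 3  # 57
    arch = decompose(record)
    assert arch.totals == {"seven_cys": 6, "six_cys": 2, "other": 0}
    assert len(arch.unassigned_cys) == 3
    assert [(b.start, b.end) for b in arch.boxes] == \
        [(b.start, b.end) for b in truth.boxes]


def test_degenerate_boxes_need_flag():
    record, _ = make_protein(ArchitectureSpec(
        n_seven_cys_boxes=0, n_six_cys_boxes=2, n_prefix_cys=0, seed=3))
    strict = decompose(record, allow_degenerate=False)
    assert strict.totals["six_cys"] == 0
    relaxed = decompose(record, allow_degenerate=True)
    assert relaxed.totals["six_cys"] == 2


@given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120))
@settings(max_examples=150, deadline=None)
def test_cys_conservation_on_any_input(seq):
    arch = decompose(ProteinRecord("r", seq))
    assert arch.total_cys == seq.count("C")


@given(st.integers(0, 3), st.integers(0, 2), st.integers(0, 3),
       st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_roundtrip_random_architectures(n7, n6, npre, seed):
    record, truth = make_protein(ArchitectureSpec(
        n_seven_cys_boxes=n7, n_six_cys_boxes=n6, n_prefix_cys=npre,
        seed=seed))
    arch = decompose(record)
    assert arch.totals == truth.totals
    assert len(arch.unassigned_cys) == npre
    assert [(b.start, b.end) for b in arch.boxes] == \
        [(b.start, b.end) for b in truth.boxes]


def _bruteforce_best(candidates):
    """Exhaustive max-score non-overlapping subset (oracle)."""
    best = 0.0
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            boxes = sorted(combo, key=lambda b: b.start)
            if any(b2.start <= b1.end
                   for b1, b2 in zip(boxes, boxes[1:])):
                continue
            best = max(best, sum(b.score for b in boxes))
    return best


@pytest.mark.parametrize("seed", range(8))
def test_dp_equals_bruteforce_on_short_proteins(seed):
    record, _ = make_protein(ArchitectureSpec(
        n_seven_cys_boxes=2, n_six_cys_boxes=1, n_prefix_cys=1,
        linker_length_range=(4, 6), seed=seed))
    assert len(record.sequence) <= 100
    candidates = scan_boxes(record, include_degenerate=True)
    assert len(candidates) <= 16  # keeps the exhaustive oracle cheap
    total, _boxes = _select_optimal(candidates)
    assert total == pytest.approx(_bruteforce_best(candidates))


def test_dp_equals_bruteforce_on_overlap_rich_sequence():
    # tandem Cys runs create overlapping candidates the DP must arbitrate
    seq = "CGC" * 12 + "GGG" + PERFECT_BOX
    candidates = scan_boxes(ProteinRecord("o", seq), include_degenerate=True)
    total, _ = _select_optimal(candidates)
    assert total == pytest.approx(_bruteforce_best(candidates))


def test_decompose_additive_over_clean_concatenation():
    a, _ = make_protein(ArchitectureSpec(2, 1, 0, seed=5))
    b, _ = make_protein(ArchitectureSpec(1, 0, 0, seed=6))
    joined = ProteinRecord("ab", a.sequence + "G" * 12 + b.sequence)
    arch_a, arch_b = decompose(a), decompose(b)
    arch_ab = decompose(joined)
    for kind in ("seven_cys", "six_cys"):
        assert arch_ab.totals[kind] == \
            arch_a.totals[kind] + arch_b.totals[kind]


def test_architecture_report_contents():
    record, truth = make_protein(ArchitectureSpec(6, 2, 3, seed=21))
    report = architecture_report(decompose(record))
    assert report["summary"] == "7-Cys: 6, 6-Cys: 2, unassigned Cys: 3"
    assert [b["kind"] for b in report["boxes"]].count("seven_cys") == 6
    text = render_report_text(report)
    assert "7-Cys: 6" in text


def test_architecture_report_empty():
    report = architecture_report(decompose(ProteinRecord("g", "GGGG")))
    assert report["boxes"] == [] and report["totals"]["seven_cys"] == 0
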