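"""Composition summaries, CXC accounting, MT screening, average masses."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modmt.errors import InvalidSequenceError
from modmt.records import AMINO_ACIDS, ProteinRecord
from modmt.seqstats import (
    MtThresholds,
    average_mass,
    average_mass_from_formula,
    count_cys_in_cxc,
    is_mt_like,
    summarize_composition,
)

aa_text = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


# --- composition ----------------------------------------------------------

# (name, length, cys, cys_in_cxc, aromatics), hand-counted over the
# published sequences by an independent letter/window scan
PUBLISHED_COMPOSITIONS = [
    ("Ncrassa_MT", 26, 7, 6, 0),
    ("Cglabrata_MT1", 63, 18, 14, 0),
    ("Cglabrata_MT2", 52, 16, 14, 1),
    ("Ylipolytica_MT3", 55, 9, 8, 1),
    ("Scerevisiae_Cup1", 61, 12, 7, 2),
    ("Scerevisiae_Crs5", 69, 19, 12, 0),
]


@pytest.mark.parametrize("name,length,cys,cxc,arom", PUBLISHED_COMPOSITIONS)
def test_published_mt_compositions(fungal_mts, name, length, cys, cxc, arom):
    s = summarize_composition(fungal_mts[name])
    assert (s.length, s.cys_count, s.cys_in_cxc, s.aromatic_count) == \
        (length, cys, cxc, arom)
    assert s.cys_fraction == pytest.approx(cys / length)


def test_composition_degenerate_all_cys():
    s = summarize_composition(ProteinRecord("x", "CCC"))
    assert s.length == 3 and s.cys_count == 3 and s.cys_fraction == 1.0


def test_composition_counts_sum_to_length(ncrassa):
    s = summarize_composition(ncrassa)
    assert sum(s.residue_counts.values()) == s.length
    assert s.cys_in_cxc <= s.cys_count <= s.length


def test_invalid_alphabet_names_offender():
    with pytest.raises(InvalidSequenceError) as err:
        ProteinRecord("bad", "MGDXZ")
    assert err.value.char == "X" and err.value.position == 4


def test_empty_sequence_rejected():
    with pytest.raises(InvalidSequenceError):
        ProteinRecord("empty", "")


# --- CXC motif accounting -------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("CAC", 2),          # one motif, both ends count
    ("CC", 0),           # adjacency is not CXC
    ("CCC", 2),          # X may itself be Cys: window (1,3)
    ("CACAC", 3),        # shared middle Cys counted once
    ("AAAA", 0),
])
def test_cxc_window_cases(seq, expected):
    assert count_cys_in_cxc(seq) == expected


@given(aa_text)
@settings(max_examples=200, deadline=None)
def test_cxc_matches_bruteforce_window_scan(seq):
    brute = {
        i
        for i in range(len(seq))
        if seq[i] == "C" and (
            (i + 2 < len(seq) and seq[i + 2] == "C")
            or (i - 2 >= 0 and seq[i - 2] == "C")
        )
    }
    assert count_cys_in_cxc(seq) == len(brute)


@given(aa_text, aa_text)
@settings(max_examples=100, deadline=None)
def test_cys_count_additive_under_concatenation(a, b):
    sa = summarize_composition(ProteinRecord("a", a))
    sb = summarize_composition(ProteinRecord("b", b))
    sab = summarize_composition(ProteinRecord("ab", a + b))
    assert sab.cys_count == sa.cys_count + sb.cys_count


def test_summary_invariant_under_id_change(ncrassa):
    renamed = ProteinRecord("other_id", ncrassa.sequence)
    a, b = summarize_composition(ncrassa), summarize_composition(renamed)
    assert (a.length, a.cys_count, a.cys_in_cxc, a.average_mass_da) == \
        (b.length, b.cys_count, b.cys_in_cxc, b.average_mass_da)


# --- MT-likeness ----------------------------------------------------------

def test_mt_screen_on_cys_rich_aromatic_free(ncrassa):
    verdict = is_mt_like(summarize_composition(ncrassa))
    assert verdict.is_mt_like
    assert len(verdict.reasons) == 2  # every rule reported


def test_mt_screen_fails_all_alanine():
    verdict = is_mt_like(summarize_composition(ProteinRecord("a", "A" * 30)))
    assert not verdict.is_mt_like
    assert any("cys_fraction" in r and "fail" in r for r in verdict.reasons)


def test_mt_screen_aromatics_disqualify():
    # 25% Cys but one Trp
    rec = ProteinRecord("w", "CAAW" * 8)
    verdict = is_mt_like(summarize_composition(rec))
    assert not verdict.is_mt_like


def test_mt_screen_quarter_cys_104mer_passes():
    # the screening shape of the database candidate that started the
    # study: 104 residues, 26 Cys, aromatics-free
    rec = ProteinRecord("cand", ("CAAG" * 26))
    s = summarize_composition(rec)
    assert s.length == 104 and s.cys_count == 26
    assert is_mt_like(s).is_mt_like


def test_mt_screen_custom_threshold(ncrassa):
    strict = MtThresholds(min_cys_fraction=0.5)
    assert not is_mt_like(summarize_composition(ncrassa), strict).is_mt_like


# --- average mass ---------------------------------------------------------

def test_single_glycine_mass():
    assert average_mass("G") == pytest.approx(75.07, abs=0.01)


def test_zero_residue_limit_is_water():
    assert average_mass("") == pytest.approx(18.02, abs=0.01)


def test_nterm_extension_prepended():
    assert average_mass("A", "GS") == pytest.approx(
        average_mass("GSA"), abs=1e-9)


@given(aa_text)
@settings(max_examples=300, deadline=None)
def test_mass_dual_route_agreement(seq):
    """Residue-table sum vs elemental-formula accumulation within 0.01 Da."""
    assert average_mass(seq) == pytest.approx(
        average_mass_from_formula(seq), abs=0.01)


def test_mass_against_independent_library(ncrassa):
    """Cross-check the average mass against pyteomics on a published MT."""
    from pyteomics import mass as pmass

    ours = average_mass(ncrassa)
    theirs = pmass.calculate_mass(sequence=ncrassa.sequence, average=True)
    assert ours == pytest.approx(theirs, abs=0.05)
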