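"""Spliced alignment, coding checks, promoter scanning, GFF3 round trip."""

import pytest

from modmt.errors import (
    InvalidMotifError,
    InvalidSequenceError,
    NoAlignmentError,
    NonCanonicalSpliceError,
)
from modmt.genemodel import (
    SplicedAlignParams,
    check_coding,
    export_gff3,
    find_coding_span,
    import_gff3,
    revcomp,
    scan_promoter,
    spliced_align,
)
from modmt.synthetic_data import ArchitectureSpec, GeneSpec, make_gene, make_protein


@pytest.fixture(scope="module")
def protein():
    record, _ = make_protein(ArchitectureSpec(seed=7))
    return record


@pytest.fixture(scope="module")
def planted_gene(protein):
    return make_gene(protein, GeneSpec(n_introns=3, exon_length_range=(150, 320), seed=8))


# --- spliced alignment ----------------------------------------------------

def test_three_planted_introns_recovered(protein):
    spec = GeneSpec(n_introns=3, intron_length_range=(48, 204),
                    exon_length_range=(150, 260), seed=42)
    cdna, genome, truth = make_gene(protein, spec)
    model = spliced_align(cdna, genome)
    assert model.exons == truth.exons
    assert model.n_introns == 3
    assert all(48 <= i.length <= 204 for i in model.introns)


def test_identity_alignment_single_exon(planted_gene):
    cdna, _, _ = planted_gene
    genome = "ACGTAC" * 20 + cdna + "TGCA" * 25
    model = spliced_align(cdna, genome)
    assert model.n_exons == 1 and model.n_introns == 0
    assert model.mismatches == 0
    assert model.exons == ((120, 120 + len(cdna)),)


def test_ten_exon_gene_recovered(protein):
    cdna, genome, truth = make_gene(protein, GeneSpec(n_introns=9, seed=1))
    model = spliced_align(cdna, genome)
    assert model.n_exons == 10 and model.n_introns == 9
    assert model.exons == truth.exons


def test_exon_lengths_sum_to_cdna_length(planted_gene):
    cdna, genome, _ = planted_gene
    model = spliced_align(cdna, genome)
    assert sum(e - s for s, e in model.exons) == len(cdna)


def test_all_introns_canonical(planted_gene):
    cdna, genome, _ = planted_gene
    model = spliced_align(cdna, genome)
    for intron in model.introns:
        assert intron.donor == "GT" and intron.acceptor == "AG"


def test_reverse_complement_symmetry(planted_gene):
    cdna, genome, _ = planted_gene
    fwd = spliced_align(cdna, genome)
    mirrored = spliced_align(cdna, revcomp(genome))
    L = len(genome)
    assert mirrored.strand == "-"
    assert mirrored.exons == tuple(sorted((L - e, L - s)
                                          for s, e in fwd.exons))


def test_minus_strand_ground_truth(protein):
    cdna, genome, truth = make_gene(protein, GeneSpec(n_introns=4, seed=9, strand="-",
                                                      exon_length_range=(100, 250)))
    model = spliced_align(cdna, genome)
    assert model.strand == "-"
    assert model.exons == truth.exons
    assert all(i.donor == "GT" and i.acceptor == "AG" for i in model.introns)


def test_mismatch_tolerant_recovery(protein):
    spec = GeneSpec(n_introns=5, mismatch_rate=0.0125, seed=13,
                    exon_length_range=(80, 220))
    cdna, genome, truth = make_gene(protein, spec)
    model = spliced_align(cdna, genome)
    assert model.exons == truth.exons
    assert 0 < model.mismatches <= 0.02 * len(cdna)


def test_no_alignment_on_unrelated_sequences():
    with pytest.raises(NoAlignmentError):
        spliced_align("ACGT" * 30, "TTAA" * 200)


def test_non_canonical_splice_detected(protein):
    cdna, genome, truth = make_gene(protein, GeneSpec(n_introns=2, seed=30,
                                                      exon_length_range=(150, 320)))
    # corrupt one donor site: GT -> CC
    bad = list(genome)
    donor = truth.introns[0].start
    bad[donor:donor + 2] = "CC"
    with pytest.raises((NonCanonicalSpliceError, NoAlignmentError)):
        spliced_align(cdna, "".join(bad))


def test_cdna_shorter_than_two_seeds_rejected():
    with pytest.raises(InvalidSequenceError):
        spliced_align("ACGTACGT", "ACGT" * 100)


def test_params_validation():
    with pytest.raises(ValueError):
        SplicedAlignParams(seed_kmer=0)
    with pytest.raises(ValueError):
        SplicedAlignParams(min_intron=100, max_intron=50)


# --- coding checks --------------------------------------------------------

def test_coding_span_and_774bp_identity(protein):
    """A 257-aa ORF spans 774 bp = 3*(aa+1), the identity the coding
    check enforces."""
    padded = protein.sequence + "G" * (257 - len(protein.sequence))
    assert len(padded) == 257
    from modmt.records import ProteinRecord

    rec257 = ProteinRecord("padded", padded)
    cdna, genome, truth = make_gene(rec257, GeneSpec(n_introns=9, seed=77))
    model = spliced_align(cdna, genome)
    report = check_coding(model, cdna)
    assert report.ok
    assert report.coding_length == 774 == 3 * (257 + 1)
    assert report.protein_length == 257
    assert report.utr5_length == 69


def test_minimal_orf_atg_stop_only():
    cdna = "ATGTGA"
    span = find_coding_span(cdna)
    assert span == (0, 6)


def test_26aa_orf_is_81bp(ncrassa):
    from modmt.synthetic_data import reverse_translate
    import numpy as np

    cds = reverse_translate(ncrassa.sequence, np.random.default_rng(0)) + "TAA"
    assert len(cds) == 3 * (26 + 1) == 81
    assert find_coding_span(cds) == (0, 81)


def test_missing_atg_diagnosed():
    from modmt.genemodel import GeneModel

    cdna = "CCCCCCTAACCC"  # no ATG anywhere
    model = GeneModel("s", "+", ((0, len(cdna)),), (), "c", len(cdna))
    report = check_coding(model, cdna)
    assert not report.ok
    assert "no ATG" in report.diagnostics[0]


def test_frame_violation_diagnosed():
    from modmt.genemodel import GeneModel

    cdna = "ATGAAAA"  # 7 bases, no stop
    model = GeneModel("s", "+", ((0, 7),), (), "c", 7,
                      coding_span_on_cdna=(0, 7))
    report = check_coding(model, cdna)
    assert not report.in_frame and not report.ok


# --- promoter scanning ----------------------------------------------------

def test_tata_planted_at_minus_38():
    up = "C" * 1462 + "TATAAAT" + "C" * 31  # first base 38 upstream of ATG
    hits = [h for h in scan_promoter(up, {"TATA": "TATAWAW"})
            if h.strand == "+"]
    assert [h.offset for h in hits] == [-38]
    assert hits[0].matched_seq == "TATAAAT"


def test_mre_planted_at_minus_1457():
    up = "G" * 43 + "TGCACAC" + "G" * 1450
    hits = [h for h in scan_promoter(up, {"MRE": "TGCRCNC"})
            if h.strand == "+"]
    assert [h.offset for h in hits] == [-1457]


def test_all_c_upstream_has_no_tata_hits():
    assert scan_promoter("C" * 500, {"TATA": "TATAWAW"}) == []


def test_reverse_strand_hit_reported():
    up = "G" * 100 + revcomp("TGCACAC") + "G" * 93
    hits = scan_promoter(up, {"MRE": "TGCRCNC"})
    assert any(h.strand == "-" and h.offset == -100 for h in hits)


def test_malformed_motif_rejected():
    with pytest.raises(InvalidMotifError):
        scan_promoter("ACGT" * 10, {"bad": "TAT?A"})


def test_gene_round_trip_finds_planted_motifs(protein):
    plants = (("TATA", "TATAAAT", -38), ("MRE", "TGCACAC", -1457))
    cdna, genome, truth = make_gene(
        protein, GeneSpec(n_introns=9, seed=2, promoter_plants=plants))
    model = spliced_align(cdna, genome)
    from modmt.pipeline import _atg_genomic

    atg = _atg_genomic(model)
    hits = scan_promoter(genome[atg - 1500:atg])
    offsets = {(h.motif_name, h.offset) for h in hits if h.strand == "+"}
    assert ("TATA", -38) in offsets and ("MRE", -1457) in offsets


# --- GFF3 -----------------------------------------------------------------

def test_gff3_round_trip_multi_exon(planted_gene):
    cdna, genome, _ = planted_gene
    model = spliced_align(cdna, genome)
    text = export_gff3(model)
    assert text.startswith("##gff-version 3")
    back = import_gff3(text)
    assert back.exons == model.exons
    assert back.strand == model.strand
    assert back.scaffold_id == model.scaffold_id


def test_gff3_single_exon():
    from modmt.genemodel import GeneModel

    model = GeneModel("sc", "+", ((10, 110),), (), "c", 100)
    back = import_gff3(export_gff3(model))
    assert back.exons == ((10, 110),)


def test_gff3_minus_strand_forward_axis(protein):
    cdna, genome, truth = make_gene(protein, GeneSpec(n_introns=2, seed=55, strand="-",
                                                      exon_length_range=(150, 320)))
    model = spliced_align(cdna, genome)
    back = import_gff3(export_gff3(model))
    assert back.strand == "-"
    assert back.exons == model.exons  # forward-axis coordinates preserved
    assert back.exons == tuple(sorted(back.exons))
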