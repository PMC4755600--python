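"""Exon/intron gene models from spliced cDNA-to-genome alignment.

A eukaryotic MT gene is short but surprisingly fragmented: the gene
modelled here splits a ~800 bp transcript into ten exons of 63-105 bp
separated by nine introns of 48-204 bp, every one bounded by the
canonical GT (donor) / AG (acceptor) dinucleotides. This module
reconstructs such models by seed-and-chain spliced alignment:

1. exact k-mer anchors between cDNA and genome are grouped by diagonal
   (genome offset minus cDNA offset) — one diagonal per exon;
2. diagonals are chained collinearly, each diagonal jump being a
   candidate intron whose length must fall within configured bounds;
3. the exact exon boundary inside each junction's ambiguity window is
   resolved by scanning split points left to right and taking the first
   placement that yields GT..AG with the fewest local mismatches.

Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 output. Minus-strand hits are reported on the forward scaffold
axis with strand "-"; donor/acceptor dinucleotides are always given on
the transcribed strand, so a canonical intron reads GT..AG regardless
of strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import (
    InvalidMotifError,
    InvalidSequenceError,
    NoAlignmentError,
    NonCanonicalSpliceError,
)

_NT = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Default promoter motifs: the canonical TATA box and the core of the
#: metal-response element (MRE). Both are config-overridable; reported
#: hits are consensus-dependent.
DEFAULT_MOTIFS: dict[str, str] = {"TATA": "TATAWAW", "MRE": "TGCRCNC"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N nucleotide sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotide(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise InvalidSequenceError(f"{what} is empty")
    for i, ch in enumerate(seq, start=1):
        if ch not in _NT:
            raise InvalidSequenceError(
                f"non-nucleotide {ch!r} at position {i} of {what}",
                char=ch, position=i,
            )
    return seq


@dataclass(frozen=True)
class SplicedAlignParams:
    """Tuning knobs for spliced alignment.

    ``max_mismatch_rate`` defaults to 2%, comfortably above the ~1.25%
    strain polymorphism level observed between independently sequenced
    isolates of the same fungus; ``min_intron``/``max_intron`` bracket
    plausible fungal intron sizes.
    """

    seed_kmer: int = 15
    max_mismatch_rate: float = 0.02
    min_intron: int = 40
    max_intron: int = 5000
    enforce_gt_ag: bool = True
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.seed_kmer <= 32):
            raise ValueError("seed_kmer must be in (0, 32]")
        if self.min_intron >= self.max_intron:
            raise ValueError("min_intron must be < max_intron")


@dataclass(frozen=True)
class Intron:
    """A genomic intron interval with transcribed-strand boundary dinucleotides."""

    start: int  # 0-based half-open, forward scaffold axis
    end: int
    donor: str
    acceptor: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A reconstructed exon/intron structure for one cDNA on one scaffold."""

    scaffold_id: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, forward axis, sorted
    introns: tuple[Intron, ...]
    cdna_id: str
    cdna_length: int
    mismatches: int = 0
    coding_span_on_cdna: tuple[int, int] | None = None  # incl. stop codon
    utr5_length: int | None = None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)


# ---------------------------------------------------------------------------
# spliced alignment


def _diagonal_blocks(cdna: str, genome: str, k: int) -> list[tuple[int, int, int]]:
    """(diag, cstart, cend) runs of exact k-mer matches per diagonal.

    Anchors on one diagonal are merged into a run only while the gap
    between consecutive anchor starts stays below 3k (the shadow of a
    couple of nearby mismatches); distant anchors — usually spurious
    k-mer collisions between similar tandem repeats — form separate
    small blocks that the chaining step can ignore.
    """
    index: dict[str, list[int]] = {}
    for g in range(len(genome) - k + 1):
        kmer = genome[g:g + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(g)
    by_diag: dict[int, list[int]] = {}
    for c in range(len(cdna) - k + 1):
        kmer = cdna[c:c + k]
        if "N" in kmer:
            continue
        for g in index.get(kmer, ()):
            by_diag.setdefault(g - c, []).append(c)
    blocks = []
    for d, starts in by_diag.items():
        starts.sort()
        run_lo = prev = starts[0]
        for c in starts[1:]:
            if c - prev > 3 * k:
                blocks.append((d, run_lo, prev + k))
                run_lo = c
            prev = c
        blocks.append((d, run_lo, prev + k))
    return sorted(blocks)


def _chain_blocks(blocks: list[tuple[int, int, int]],
                  params: SplicedAlignParams) -> list[tuple[int, int, int]]:
    """Best collinear chain of diagonal blocks (max cDNA coverage).

    Diagonals must strictly increase along the chain with each jump
    (the intron length) inside [min_intron, max_intron]; blocks must be
    ordered along the cDNA. Small overlaps (up to one seed length) are
    tolerated because a k-mer that straddles a junction by a base or
    two can anchor on the neighboring exon's diagonal; the exact split
    is resolved later.
    """
    k = params.seed_kmer
    blocks = sorted(blocks, key=lambda b: (b[1], b[0]))
    n = len(blocks)
    best_cov = [0] * n
    prev = [-1] * n
    for i in range(n):
        di, li, hi = blocks[i]
        best_cov[i] = hi - li
        for j in range(i):
            dj, lj, hj = blocks[j]
            jump = di - dj
            if (hj <= li + k and hj < hi and lj < li
                    and (jump == 0
                         or params.min_intron <= jump <= params.max_intron)):
                cov = best_cov[j] + (hi - max(li, hj))
                if cov > best_cov[i]:
                    best_cov[i] = cov
                    prev[i] = j
    if not blocks:
        return []
    end = max(range(n), key=lambda i: (best_cov[i], -blocks[i][1]))
    chain = []
    while end != -1:
        chain.append(blocks[end])
        end = prev[end]
    return chain[::-1]


def _count_mismatches(cdna: str, genome: str, diag: int, a: int, b: int) -> int:
    """Mismatches of cdna[a:b] against the genome on one diagonal; N neutral."""
    mm = 0
    for x in range(a, b):
        cc, gc = cdna[x], genome[diag + x]
        if cc != gc and cc != "N" and gc != "N":
            mm += 1
    return mm


def _resolve_boundary(cdna: str, genome: str, d1: int, d2: int,
                      lo: int, hi: int, enforce: bool) -> tuple[int, int]:
    """Split point for one exon junction, scanning left to right.

    Returns (split, local_mismatches). Among placements achieving the
    minimum local mismatch count, the leftmost GT..AG-satisfying one
    wins; without enforcement the leftmost minimum-mismatch placement
    wins regardless of the dinucleotides.
    """
    candidates: list[tuple[int, int, bool]] = []
    for b in range(lo, hi + 1):
        if d1 + b + 2 > len(genome) or d2 + b - 2 < 0:
            continue
        canonical = (genome[d1 + b:d1 + b + 2] == "GT"
                     and genome[d2 + b - 2:d2 + b] == "AG")
        mm = (_count_mismatches(cdna, genome, d1, lo, b)
              + _count_mismatches(cdna, genome, d2, b, hi))
        candidates.append((b, mm, canonical))
    if not candidates:
        raise NoAlignmentError("empty boundary window")
    if enforce:
        canon = [(b, mm) for b, mm, ok in candidates if ok]
        if not canon:
            raise NonCanonicalSpliceError(
                f"no GT..AG placement in junction window "
                f"cDNA[{lo}..{hi}] (diagonals {d1}->{d2})"
            )
        min_mm = min(mm for _, mm in canon)
        return next((b, mm) for b, mm in canon if mm == min_mm)
    min_mm = min(mm for _, mm, _ in candidates)
    return next((b, mm) for b, mm, _ in candidates if mm == min_mm)


def _align_one_strand(cdna: str, genome: str,
                      params: SplicedAlignParams) -> tuple[list[tuple[int, int]], int]:
    """Align cDNA to one genome strand; returns (exons, mismatches)."""
    k = params.seed_kmer
    blocks = _diagonal_blocks(cdna, genome, k)
    chain = _chain_blocks(blocks, params)
    if not chain:
        raise NoAlignmentError("no anchor blocks found")
    # zero-jump links are same-exon continuations across interior
    # mismatch clusters: fuse them back into single blocks
    fused = [chain[0]]
    for d, lo, hi in chain[1:]:
        pd, plo, phi = fused[-1]
        if d == pd:
            fused[-1] = (d, plo, hi)
        else:
            fused.append((d, lo, hi))
    chain = fused
    covered = sum(hi - lo for _, lo, hi in chain)
    if covered < params.min_coverage * len(cdna):
        raise NoAlignmentError(
            f"anchor coverage {covered}/{len(cdna)} below minimum"
        )
    d_first, d_last = chain[0][0], chain[-1][0]
    if d_first < 0 or d_last + len(cdna) > len(genome):
        raise NoAlignmentError("alignment extends past the genome ends")

    # exon boundaries along the cDNA
    splits = [0]
    junction_mm = 0
    for (d1, _, ce), (d2, cs, _) in zip(chain, chain[1:]):
        lo = max(ce - k, splits[-1])
        hi = min(cs + k, len(cdna))
        b, mm = _resolve_boundary(cdna, genome, d1, d2, lo, hi,
                                  params.enforce_gt_ag)
        splits.append(b)
        junction_mm += mm
    splits.append(len(cdna))

    exons = []
    mismatches = 0
    for (d, _, _), a, b in zip(chain, splits, splits[1:]):
        exons.append((d + a, d + b))
        mismatches += _count_mismatches(cdna, genome, d, a, b)
    if mismatches > params.max_mismatch_rate * len(cdna):
        raise NoAlignmentError(
            f"{mismatches} mismatches exceed rate "
            f"{params.max_mismatch_rate} over {len(cdna)} bases"
        )
    return exons, mismatches


def spliced_align(cdna: str, genome: str,
                  params: SplicedAlignParams | None = None,
                  cdna_id: str = "cdna", scaffold_id: str = "scaffold") -> GeneModel:
    """Reconstruct a gene model by spliced alignment of a cDNA to a genome.

    Both strands are searched and the better-scoring one returned
    (fewer mismatches; ties prefer "+"). Raises
    :class:`NoAlignmentError` when no collinear chain reaches minimum
    coverage and :class:`NonCanonicalSpliceError` when a junction
    admits no GT..AG placement under enforcement.
    """
    params = params or SplicedAlignParams()
    cdna = validate_nucleotide(cdna, "cDNA")
    genome = validate_nucleotide(genome, "genome")
    if len(cdna) < 2 * params.seed_kmer:
        raise InvalidSequenceError(
            f"cDNA shorter than two seed k-mers ({2 * params.seed_kmer})"
        )

    results = {}
    errors = {}
    for strand, g in (("+", genome), ("-", revcomp(genome))):
        try:
            results[strand] = _align_one_strand(cdna, g, params)
        except (NoAlignmentError, NonCanonicalSpliceError) as exc:
            errors[strand] = exc
    if not results:
        raise errors.get("+") or errors["-"]
    strand = min(results, key=lambda s: (results[s][1], s == "-"))
    exons, mismatches = results[strand]

    if strand == "-":
        L = len(genome)
        exons = sorted((L - e, L - s) for s, e in exons)
    introns = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if strand == "+":
            donor = genome[e1:e1 + 2]
            acceptor = genome[s2 - 2:s2]
        else:
            donor = revcomp(genome[s2 - 2:s2])
            acceptor = revcomp(genome[e1:e1 + 2])
        introns.append(Intron(e1, s2, donor, acceptor))

    model = GeneModel(
        scaffold_id=scaffold_id, strand=strand, exons=tuple(exons),
        introns=tuple(introns), cdna_id=cdna_id, cdna_length=len(cdna),
        mismatches=mismatches,
    )
    span = find_coding_span(cdna)
    if span is not None:
        model = replace(model, coding_span_on_cdna=span, utr5_length=span[0])
    return model


# ---------------------------------------------------------------------------
# coding-structure checks


def find_coding_span(cdna: str) -> tuple[int, int] | None:
    """First ATG with an in-frame stop; 0-based half-open incl. the stop."""
    cdna = cdna.upper()
    start = cdna.find("ATG")
    while start != -1:
        for pos in range(start, len(cdna) - 2, 3):
            if cdna[pos:pos + 3] in STOP_CODONS:
                return (start, pos + 3)
        start = cdna.find("ATG", start + 1)
    return None


@dataclass(frozen=True)
class CodingReport:
    """Validation of a gene model's coding structure."""

    has_start_atg: bool
    has_terminal_stop: bool
    in_frame: bool
    coding_length: int
    protein_length: int
    utr5_length: int | None
    diagnostics: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.has_start_atg and self.has_terminal_stop and self.in_frame


def check_coding(model: GeneModel, cdna: str) -> CodingReport:
    """Verify ATG start, terminal stop and frame of a model's coding span.

    The coding length must equal 3*(aa + 1) — protein length plus the
    stop codon. Missing ATG, missing stop, or a frame violation are the
    exact symptoms by which a 5'-truncated gene annotation is detected,
    so each produces an explicit diagnostic rather than a silent fail.
    """
    cdna = validate_nucleotide(cdna, "cDNA")
    diagnostics = []
    span = model.coding_span_on_cdna or find_coding_span(cdna)
    if span is None:
        return CodingReport(False, False, False, 0, 0, None,
                            ("no ATG starting codon in frame with a stop",))
    start, end = span
    coding = cdna[start:end]
    has_atg = coding[:3] == "ATG"
    if not has_atg:
        diagnostics.append(f"first codon is {coding[:3]!r}, not ATG")
    in_frame = len(coding) % 3 == 0
    if not in_frame:
        diagnostics.append(f"coding length {len(coding)} not divisible by 3")
    has_stop = in_frame and coding[-3:] in STOP_CODONS
    if in_frame and not has_stop:
        diagnostics.append(f"final codon {coding[-3:]!r} is not a stop")
    protein_length = len(coding) // 3 - 1 if (in_frame and has_stop) else 0
    return CodingReport(
        has_start_atg=has_atg, has_terminal_stop=has_stop, in_frame=in_frame,
        coding_length=len(coding), protein_length=protein_length,
        utr5_length=start, diagnostics=tuple(diagnostics),
    )


# ---------------------------------------------------------------------------
# promoter motif scanning


@dataclass(frozen=True)
class PromoterHit:
    """A motif match upstream of the translation start.

    Offsets are relative to the A of the ATG: that A is +1, there is no
    position 0, and upstream positions are negative. A hit whose first
    base lies 38 bases upstream of the ATG has offset -38.
    """

    motif_name: str
    offset: int
    matched_seq: str
    strand: str


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_NT:
            raise InvalidMotifError(f"invalid IUPAC letter {ch!r} in motif {motif!r}")
        bases = IUPAC_NT[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _revcomp_motif(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
            "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
            "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}
    return "".join(comp[ch] for ch in motif.upper())[::-1]


def scan_promoter(upstream: str,
                  motifs: dict[str, str] | None = None) -> list[PromoterHit]:
    """All IUPAC-degenerate motif matches on both strands of an upstream region.

    ``upstream`` is given 5'->3' on the coding strand and must end
    immediately before the ATG. Matches are reported with forward-axis
    offsets (see :class:`PromoterHit`); ``matched_seq`` is always the
    coding-strand text at the hit location.
    """
    upstream = validate_nucleotide(upstream, "upstream region")
    motifs = motifs if motifs is not None else DEFAULT_MOTIFS
    L = len(upstream)
    hits: list[PromoterHit] = []
    for name, motif in motifs.items():
        m = len(motif)
        for strand, pattern in (("+", _iupac_regex(motif)),
                                ("-", _iupac_regex(_revcomp_motif(motif)))):
            for match in pattern.finditer(upstream):
                i = match.start()
                hits.append(PromoterHit(
                    motif_name=name, offset=i - L,
                    matched_seq=upstream[i:i + m], strand=strand,
                ))
    hits.sort(key=lambda h: (h.offset, h.motif_name, h.strand))
    return hits


# ---------------------------------------------------------------------------
# GFF3 export / import


def _cdna_to_genome(model: GeneModel, a: int, b: int) -> list[tuple[int, int]]:
    """Map a cDNA interval [a, b) to genomic pieces (forward axis, sorted)."""
    order = model.exons if model.strand == "+" else model.exons[::-1]
    pieces = []
    offset = 0
    for s, e in order:
        length = e - s
        lo, hi = max(a, offset), min(b, offset + length)
        if lo < hi:
            if model.strand == "+":
                pieces.append((s + (lo - offset), s + (hi - offset)))
            else:
                pieces.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return sorted(pieces)


def export_gff3(model: GeneModel, gene_id: str | None = None) -> str:
    """Serialize a gene model as a GFF3 document (1-based inclusive)."""
    gid = gene_id or f"{model.cdna_id}.gene"
    mid = f"{gid}.mRNA"
    seqid, strand = model.scaffold_id, model.strand
    gstart = min(s for s, _ in model.exons) + 1
    gend = max(e for _, e in model.exons)

    def row(ftype, s, e, fid, parent=None):
        attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
        return "\t".join([seqid, "modmt", ftype, str(s), str(e), ".",
                          strand, ".", attrs])

    lines = ["##gff-version 3",
             row("gene", gstart, gend, gid),
             row("mRNA", gstart, gend, mid, gid)]
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(row("exon", s + 1, e, f"{mid}.exon{i}", mid))
    if model.coding_span_on_cdna is not None:
        a, b = model.coding_span_on_cdna
        for i, (s, e) in enumerate(_cdna_to_genome(model, a, b), start=1):
            lines.append(row("CDS", s + 1, e, f"{mid}.cds{i}", mid))
        for i, (s, e) in enumerate(_cdna_to_genome(model, 0, a), start=1):
            lines.append(row("five_prime_UTR", s + 1, e, f"{mid}.utr5.{i}", mid))
    return "\n".join(lines) + "\n"


def import_gff3(text: str) -> GeneModel:
    """Re-import an exported GFF3 document into a (coordinates-only) model.

    Intron boundary dinucleotides are not recoverable from GFF3 alone,
    so introns are rebuilt as intervals with empty donor/acceptor.
    """
    import gffutils

    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique")
    exons = sorted((f.start - 1, f.end) for f in db.features_of_type("exon"))
    gene = next(db.features_of_type("gene"))
    introns = tuple(
        Intron(e1, s2, "", "")
        for (_, e1), (s2, _) in zip(exons, exons[1:])
    )
    return GeneModel(
        scaffold_id=gene.seqid, strand=gene.strand, exons=tuple(exons),
        introns=introns, cdna_id=gene.id.removesuffix(".gene"),
        cdna_length=sum(e - s for s, e in exons),
    )
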