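"""Seeded generators for modular MT proteins, genes, spectra and growth.

Every generator in this module is the inverse of an analysis stage and
returns machine-readable ground truth alongside its output, so the
package's core test suite is parameter recovery: decompose what
``make_protein`` built, realign what ``make_gene`` spliced, reassign
what ``make_peaklist`` planted, renormalize what ``make_growth`` drew.

Defaults mirror the architecture and gene geometry of the long
Tremella-type MT: six 7-Cys boxes + two 6-Cys boxes + three N-terminal
Cys (57 Cys total); ~10 coding exons of 63-105 bp separated by GT..AG
introns of 48-204 bp; a 69-bp 5' UTR; deconvoluted peak lists with
relative mass error well below the 0.1% assignment tolerance;
triplicate OD600 readings per Cu dose.

All randomness flows through a single ``numpy`` Generator per call,
seeded from the spec: identical spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cysbox import CysBox, ModuleArchitecture
from .errors import InfeasibleSpecError, ModmtError
from .genemodel import GeneModel, Intron, revcomp
from .massdeconv import METALS, holo_mass, species_label
from .records import ProteinRecord

# ---------------------------------------------------------------------------
# proteins

#: The 7-Cys consensus with X slots; X drawn from small/polar residues
#: weighted toward Gly/Ala, matching the inter-Cys composition of real
#: boxes.
_BOX_TEMPLATE = "CXCXXXCSCPPGXCXCAXCP"
_X_RESIDUES = list("GASTKQEP")
_X_WEIGHTS = np.array([0.30, 0.25, 0.13, 0.08, 0.08, 0.06, 0.05, 0.05])
#: Residues used for Cys-free linkers and prefix filler.
_LINKER_RESIDUES = list("GASTKNQE")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Recipe for a synthetic modular MT protein."""

    n_seven_cys_boxes: int = 6
    n_six_cys_boxes: int = 2
    n_prefix_cys: int = 3
    linker_length_range: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_seven_cys_boxes, self.n_six_cys_boxes,
               self.n_prefix_cys) < 0:
            raise ModmtError("architecture counts must be >= 0")
        lo, hi = self.linker_length_range
        if not (0 < lo <= hi):
            raise ModmtError("linker_length_range must be positive and ordered")


def _draw_x(rng: np.random.Generator) -> str:
    return str(rng.choice(_X_RESIDUES, p=_X_WEIGHTS / _X_WEIGHTS.sum()))


def _make_box_sequence(rng: np.random.Generator, drop_cys: int | None) -> str:
    """Instantiate the consensus; optionally replace one mandatory Cys.

    ``drop_cys`` is an index into the box's 7 Cys; the dropped Cys is
    replaced by a small non-Cys residue, yielding a 6-Cys degenerate box.
    """
    out = []
    cys_seen = 0
    for ch in _BOX_TEMPLATE:
        if ch == "C":
            if drop_cys is not None and cys_seen == drop_cys:
                out.append(_draw_x(rng))
            else:
                out.append("C")
            cys_seen += 1
        elif ch == "X":
            out.append(_draw_x(rng))
        else:
            out.append(ch)
    return "".join(out)


def _linker(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(_LINKER_RESIDUES, size=n))


def make_protein(spec: ArchitectureSpec) -> tuple[ProteinRecord, ModuleArchitecture]:
    """Build a modular MT protein plus its ground-truth architecture.

    Layout: initiator Met, an N-terminal segment carrying
    ``n_prefix_cys`` isolated Cys, then the 6-Cys boxes followed by the
    7-Cys boxes, separated by Cys-free linkers. Prefix Cys are spaced
    widely enough that they cannot seed a spurious box match.
    """
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = ["M"]
    pos = 1  # 1-based position of the last residue emitted

    prefix_cys: list[int] = []
    for _ in range(spec.n_prefix_cys):
        gap = _linker(rng, spec.linker_length_range)
        parts.append(gap + "C")
        pos += len(gap) + 1
        prefix_cys.append(pos)

    boxes: list[CysBox] = []
    kinds = ["six_cys"] * spec.n_six_cys_boxes + \
            ["seven_cys"] * spec.n_seven_cys_boxes
    for kind in kinds:
        gap = _linker(rng, spec.linker_length_range)
        drop = int(rng.integers(1, 6)) if kind == "six_cys" else None
        box_seq = _make_box_sequence(rng, drop)
        start = pos + len(gap) + 1
        parts.append(gap + box_seq)
        pos += len(gap) + len(box_seq)
        cys = tuple(start + i for i, ch in enumerate(box_seq) if ch == "C")
        boxes.append(CysBox(
            profile_name="seven_cys_box", start=cys[0], end=cys[-1],
            cys_positions=cys, score=float(len(cys)), kind=kind,
        ))
    parts.append(_linker(rng, spec.linker_length_range))
    sequence = "".join(parts)

    record = ProteinRecord(
        id=f"synthetic_mt_s{spec.seed}", sequence=sequence, source="synthetic",
        description=(f"synthetic modular MT: {spec.n_seven_cys_boxes}x7Cys "
                     f"+ {spec.n_six_cys_boxes}x6Cys + {spec.n_prefix_cys} prefix Cys"),
    )
    totals = {"seven_cys": spec.n_seven_cys_boxes,
              "six_cys": spec.n_six_cys_boxes, "other": 0}
    linkers = tuple(
        (left.end + 1, right.start - 1)
        for left, right in zip(boxes, boxes[1:])
        if right.start - left.end > 1
    )
    truth = ModuleArchitecture(
        record_id=record.id, length=len(sequence), boxes=tuple(boxes),
        linkers=linkers, unassigned_cys=tuple(prefix_cys), totals=totals,
    )
    return record, truth


# ---------------------------------------------------------------------------
# genes

_CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneSpec:
    """Recipe for a synthetic intron-bearing gene around a protein."""

    n_introns: int = 9
    intron_length_range: tuple[int, int] = (48, 204)
    exon_length_range: tuple[int, int] = (63, 105)
    utr5_length: int = 69
    utr3_length: int = 0
    upstream_flank: int = 1600
    downstream_flank: int = 200
    promoter_plants: tuple[tuple[str, str, int], ...] = ()  # (name, seq, offset)
    mismatch_rate: float = 0.0
    strand: str = "+"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_introns < 0:
            raise ModmtError("n_introns must be >= 0")
        if self.strand not in "+-":
            raise ModmtError("strand must be '+' or '-'")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Seeded-uniform reverse translation over synonymous codons."""
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))]
                   for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""


def _partition_exons(length: int, n_exons: int,
                     exon_range: tuple[int, int],
                     rng: np.random.Generator) -> list[int]:
    """Split ``length`` into ``n_exons`` pieces within ``exon_range``."""
    lo, hi = exon_range
    if not (n_exons * lo <= length <= n_exons * hi):
        raise InfeasibleSpecError(
            f"cannot split {length} bp into {n_exons} exons of {lo}-{hi} bp"
        )
    sizes = [lo] * n_exons
    remaining = length - n_exons * lo
    while remaining > 0:
        order = rng.permutation(n_exons)
        for i in order:
            if remaining == 0:
                break
            room = hi - sizes[i]
            if room == 0:
                continue
            add = int(min(room, max(1, remaining // n_exons), remaining))
            sizes[i] += add
            remaining -= add
    return sizes


def _make_intron(rng: np.random.Generator,
                 length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "GT" + _random_nt(rng, n - 4) + "AG"


def _boundary_is_ambiguous(genome: str, cdna: str, d1: int, d2: int,
                           b: int, window: int = 20) -> bool:
    """True if any split other than ``b`` also yields GT..AG with 0 mismatches.

    Mirrors the junction resolution rule of the aligner: a competing
    split b' is viable when the exon text still matches on both
    diagonals and the shifted intron still starts GT and ends AG.
    """
    for bp in range(max(0, b - window), min(len(cdna), b + window) + 1):
        if bp == b:
            continue
        if d1 + bp + 2 > len(genome) or d2 + bp - 2 < 0:
            continue
        if not (genome[d1 + bp:d1 + bp + 2] == "GT"
                and genome[d2 + bp - 2:d2 + bp] == "AG"):
            continue
        if bp > b:
            ok = all(genome[d1 + x] == cdna[x] for x in range(b, bp))
        else:
            ok = all(genome[d2 + x] == cdna[x] for x in range(bp, b))
        if ok:
            return True
    return False


def make_gene(protein: ProteinRecord, spec: GeneSpec
              ) -> tuple[str, str, GeneModel]:
    """Reverse-translate a protein into a spliced, flanked genomic locus.

    Returns (cDNA, scaffold, ground-truth GeneModel). The cDNA is
    5'UTR + CDS(+stop) + 3'UTR; the scaffold carries the exons
    interleaved with GT..AG introns inside random uniform-GC flanks,
    with promoter motifs overwriting flank/UTR bases at the requested
    ATG-relative offsets. Intron boundaries are re-drawn until each
    junction has a unique zero-mismatch GT..AG split, so spliced
    alignment recovers the planted coordinates exactly. With
    ``strand="-"`` the scaffold is reverse-complemented and ground-truth
    coordinates are reported on the forward axis.
    """
    rng = np.random.default_rng(spec.seed)
    cds = reverse_translate(protein.sequence, rng) + _STOPS[rng.integers(0, 3)]
    # the 5'UTR must carry no ATG, or coding-span detection would start
    # upstream of the real initiator
    for _ in range(200):
        utr5 = _random_nt(rng, spec.utr5_length)
        if "ATG" not in utr5 + cds[:2]:
            break
    else:  # pragma: no cover
        raise InfeasibleSpecError("could not draw an ATG-free 5'UTR")
    cdna = utr5 + cds + _random_nt(rng, spec.utr3_length)

    n_exons = spec.n_introns + 1
    exon_sizes = _partition_exons(len(cdna), n_exons,
                                  spec.exon_length_range, rng)
    splits = np.cumsum(exon_sizes)[:-1].tolist()

    introns = [_make_intron(rng, spec.intron_length_range)
               for _ in range(spec.n_introns)]

    def assemble() -> tuple[str, list[tuple[int, int]]]:
        up = spec.upstream_flank
        pieces, exon_coords = [], []
        gpos, prev = up, 0
        for b, intron in zip(splits + [len(cdna)], introns + [""]):
            pieces.append(cdna[prev:b])
            exon_coords.append((gpos, gpos + (b - prev)))
            gpos += (b - prev) + len(intron)
            pieces.append(intron)
            prev = b
        body = "".join(pieces)
        genome = _random_nt(rng, up) + body + _random_nt(rng, spec.downstream_flank)
        return genome, exon_coords

    genome, exon_coords = assemble()

    # re-draw intron termini until every junction's split is unambiguous
    for attempt in range(100):
        ambiguous = []
        for j, b in enumerate(splits):
            d1 = exon_coords[j][1] - b
            d2 = exon_coords[j + 1][0] - b
            if _boundary_is_ambiguous(genome, cdna, d1, d2, b):
                ambiguous.append(j)
        if not ambiguous:
            break
        for j in ambiguous:
            introns[j] = _make_intron(rng, spec.intron_length_range)
        genome, exon_coords = assemble()
    else:  # pragma: no cover - vanishingly unlikely
        raise InfeasibleSpecError("could not draw unambiguous intron boundaries")

    # plant promoter motifs relative to the ATG (A = +1, upstream < 0)
    atg_genomic = _cdna_pos_to_genomic(spec.utr5_length, exon_coords, splits, cdna)
    glist = list(genome)
    for name, motif_seq, offset in spec.promoter_plants:
        if offset >= 0:
            raise ModmtError(f"promoter plant {name!r} must be upstream (offset < 0)")
        start = atg_genomic + offset
        if start < 0:
            raise ModmtError(f"plant {name!r} at {offset} falls before the scaffold")
        for i, ch in enumerate(motif_seq.upper()):
            glist[start + i] = ch
        # keep cDNA consistent when the plant overwrites transcribed UTR bases
        utr5_start = atg_genomic - spec.utr5_length
        for i, ch in enumerate(motif_seq.upper()):
            g = start + i
            if utr5_start <= g < atg_genomic:
                c = g - utr5_start
                if c >= spec.utr5_length:
                    raise ModmtError(f"plant {name!r} overlaps the coding sequence")
                cdna = cdna[:c] + ch + cdna[c + 1:]
    if "ATG" in cdna[:spec.utr5_length + 2]:
        raise ModmtError("promoter plant introduced an upstream ATG in the 5'UTR")
    genome = "".join(glist)

    strand = spec.strand
    if strand == "-":
        L = len(genome)
        genome_fwd = revcomp(genome)
        exon_coords_fwd = sorted((L - e, L - s) for s, e in exon_coords)
    else:
        genome_fwd = genome
        exon_coords_fwd = exon_coords

    intron_list = []
    for (s1, e1), (s2, e2) in zip(exon_coords_fwd, exon_coords_fwd[1:]):
        if strand == "+":
            donor, acceptor = genome_fwd[e1:e1 + 2], genome_fwd[s2 - 2:s2]
        else:
            donor = revcomp(genome_fwd[s2 - 2:s2])
            acceptor = revcomp(genome_fwd[e1:e1 + 2])
        intron_list.append(Intron(e1, s2, donor, acceptor))

    coding_span = (spec.utr5_length, spec.utr5_length + len(cds))
    truth = GeneModel(
        scaffold_id=f"synthetic_scaffold_s{spec.seed}", strand=strand,
        exons=tuple(exon_coords_fwd), introns=tuple(intron_list),
        cdna_id=f"synthetic_cdna_s{spec.seed}", cdna_length=len(cdna),
        mismatches=0, coding_span_on_cdna=coding_span,
        utr5_length=spec.utr5_length,
    )
    if spec.mismatch_rate > 0:
        protected = set(range(coding_span[0], coding_span[0] + 3))
        protected.update(range(coding_span[1] - 3, coding_span[1]))
        for b in splits:  # keep junction windows clean so splits stay unique
            protected.update(range(b - 4, b + 4))
        cdna = _apply_mismatches(cdna, spec.mismatch_rate, rng, protected)
    return cdna, genome_fwd, truth


def _cdna_pos_to_genomic(cpos: int, exon_coords: list[tuple[int, int]],
                         splits: list[int], cdna: str) -> int:
    bounds = [0] + splits + [len(cdna)]
    for (gs, _), a, b in zip(exon_coords, bounds, bounds[1:]):
        if a <= cpos < b:
            return gs + (cpos - a)
    raise ModmtError(f"cDNA position {cpos} outside transcript")


def _apply_mismatches(cdna: str, rate: float, rng: np.random.Generator,
                      protected: set[int]) -> str:
    """Substitute bases at the given rate, sparing protected positions
    (start/stop codons and splice-junction windows)."""
    chars = list(cdna)
    eligible = [i for i in range(len(chars)) if i not in protected]
    n = min(int(round(rate * len(chars))), len(eligible))
    sites = rng.choice(len(eligible), size=n, replace=False)
    for idx in sites:
        i = eligible[idx]
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# peak lists


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for a deconvoluted neutral-mass peak list."""

    apo_mass: float = 25377.62
    species: tuple[tuple[tuple[tuple[str, int], ...], float], ...] = ()
    mass_error_rel: float = 0.0002
    seed: int = 0


def zn_ladder_species(lo: int = 17, hi: int = 21
                      ) -> tuple[tuple[tuple[tuple[str, int], ...], float], ...]:
    """A Zn_lo..Zn_hi mixture with equal abundances."""
    return tuple(((("Zn", n),), 1.0) for n in range(lo, hi + 1))


def make_peaklist(spec: SpectrumSpec) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate a deconvoluted peak list from planted holo-species.

    Each species contributes one peak at its theoretical neutral mass
    perturbed by Gaussian relative error ``mass_error_rel``; abundances
    become intensities. Returns (peaks DataFrame with mass_da and
    intensity columns, ground-truth list of stoichiometry dicts).
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth = [], []
    for stoich_items, abundance in spec.species:
        stoich = dict(stoich_items)
        mass = holo_mass(spec.apo_mass, stoich)
        observed = mass + rng.normal(0.0, spec.mass_error_rel * mass) \
            if spec.mass_error_rel > 0 else mass
        rows.append({"mass_da": observed, "intensity": abundance})
        truth.append({"stoichiometry": stoich, "theoretical_mass": mass,
                      "label": species_label(stoich)})
    return pd.DataFrame(rows), truth


def cu_series_species(n_doublets: int
                      ) -> tuple[tuple[tuple[tuple[str, int], ...], float], ...]:
    """Cu-loading doublet species per the (4,5)/(8,9)/(12,13)/+5 series."""
    from .cucapacity import loading_series

    series = loading_series(n_doublets)
    out = []
    for lower, upper in series.doublets:
        out.append(((("Cu", lower),), 1.0))
        out.append(((("Cu", upper),), 0.5))
    return tuple(out)


# ---------------------------------------------------------------------------
# growth tables


@dataclass(frozen=True)
class GrowthSpec:
    """Recipe for a synthetic endpoint-OD600 growth table."""

    strain: str = "synthetic_strain"
    doses: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0, 10.0, 15.0, 20.0, 30.0)
    unit: str = "uM"
    n_replicates: int = 3
    od_max: float = 1.2
    ic50: float = 10.0
    hill: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0


def dose_factor(dose: float, ic50: float, hill: float) -> float:
    """Monotone-decreasing logistic inhibition factor in (0, 1]."""
    return 1.0 / (1.0 + (dose / ic50) ** hill) if dose > 0 else 1.0


def make_growth(spec: GrowthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate-level growth table plus its ground truth.

    Endpoint OD600 = od_max x logistic dose factor + Gaussian noise
    (clipped at 0). Returns (table, truth) where truth carries the
    noise-free expected percent of control per dose.
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth_rows = [], []
    for dose in spec.doses:
        factor = dose_factor(dose, spec.ic50, spec.hill)
        for rep in range(1, spec.n_replicates + 1):
            od = spec.od_max * factor + rng.normal(0.0, spec.noise_sd)
            rows.append({
                "strain": spec.strain, "cu_conc": dose, "unit": spec.unit,
                "replicate": rep, "od600": max(0.0, od),
            })
        truth_rows.append({
            "cu_conc": dose, "expected_percent": 100.0 * factor,
        })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
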