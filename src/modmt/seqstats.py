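"""Protein composition summaries and metallothionein-likeness screening.

Metallothioneins (MTs) are small, cysteine-rich, aromatics-free
polypeptides. Two numbers dominate their sequence-level description: the
cysteine fraction and the count of Cys organized in CXC motifs (two Cys
separated by exactly one residue, the most common arrangement in MT
sequences). This module computes those summaries, applies the screening
rule used to flag MT-like candidates in genome mining (high Cys fraction,
zero F/W/Y), and calculates average (isotope-averaged) peptide masses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._masses import (
    RESIDUE_AVG_MASS,
    RESIDUE_FORMULAS,
    WATER_AVG_MASS,
    formula_mass,
    parse_formula,
)
from .records import ProteinRecord

AROMATIC_RESIDUES = frozenset("FWY")


@dataclass(frozen=True)
class CompositionSummary:
    """Residue-level composition of one protein.

    His and Met are tracked separately from the aromatic count: His is a
    potential metal ligand, Met contributes to the sulfur budget used in
    ICP-based protein quantitation, and neither disqualifies an MT.
    """

    record_id: str
    length: int
    residue_counts: dict[str, int]
    cys_count: int
    cys_fraction: float
    his_count: int
    met_count: int
    aromatic_count: int
    cys_in_cxc: int
    average_mass_da: float

    def to_dict(self) -> dict:
        d = {
            "record_id": self.record_id,
            "length": self.length,
            "residue_counts": dict(sorted(self.residue_counts.items())),
            "cys_count": self.cys_count,
            "cys_fraction": round(self.cys_fraction, 4),
            "cys_percent": round(100.0 * self.cys_fraction, 1),
            "his_count": self.his_count,
            "met_count": self.met_count,
            "aromatic_count": self.aromatic_count,
            "cys_in_cxc": self.cys_in_cxc,
            "average_mass_da": round(self.average_mass_da, 2),
        }
        return d


@dataclass(frozen=True)
class MtThresholds:
    """Cutoffs for the MT-likeness screen."""

    min_cys_fraction: float = 0.15
    max_aromatics: int = 0


@dataclass(frozen=True)
class MtLikeVerdict:
    """Outcome of the MT-likeness screen with per-rule reasons."""

    is_mt_like: bool
    reasons: list[str] = field(default_factory=list)
    thresholds_used: MtThresholds = field(default_factory=MtThresholds)

    def to_dict(self) -> dict:
        return {
            "is_mt_like": self.is_mt_like,
            "reasons": list(self.reasons),
            "thresholds_used": {
                "min_cys_fraction": self.thresholds_used.min_cys_fraction,
                "max_aromatics": self.thresholds_used.max_aromatics,
            },
        }


def cys_positions(sequence: str) -> list[int]:
    """1-based positions of every Cys in the sequence."""
    return [i + 1 for i, ch in enumerate(sequence) if ch == "C"]


def count_cys_in_cxc(record: ProteinRecord | str) -> int:
    """Number of distinct Cys participating in at least one CXC motif.

    A Cys at position i counts if either (i, i+2) or (i-2, i) has Cys at
    both ends; each Cys is counted once even when it belongs to two
    windows. X is any residue, Cys included: in "CCC" the window (1, 3)
    exists, so both terminal Cys count.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    in_motif = set()
    for i in range(len(seq) - 2):
        if seq[i] == "C" and seq[i + 2] == "C":
            in_motif.add(i)
            in_motif.add(i + 2)
    return len(in_motif)


def summarize_composition(record: ProteinRecord) -> CompositionSummary:
    """Full composition summary of one protein record. Deterministic."""
    seq = record.sequence
    counts = Counter(seq)
    cys = counts.get("C", 0)
    return CompositionSummary(
        record_id=record.id,
        length=len(seq),
        residue_counts=dict(counts),
        cys_count=cys,
        cys_fraction=cys / len(seq),
        his_count=counts.get("H", 0),
        met_count=counts.get("M", 0),
        aromatic_count=sum(counts.get(a, 0) for a in AROMATIC_RESIDUES),
        cys_in_cxc=count_cys_in_cxc(seq),
        average_mass_da=average_mass(record),
    )


def is_mt_like(summary: CompositionSummary,
               thresholds: MtThresholds | None = None) -> MtLikeVerdict:
    """Screen a composition summary for MT-likeness.

    The verdict is true iff the Cys fraction reaches ``min_cys_fraction``
    and the sequence contains no aromatic residues (F/W/Y). Every rule
    evaluated is listed in ``reasons`` with its outcome.
    """
    thr = thresholds or MtThresholds()
    cys_ok = summary.cys_fraction >= thr.min_cys_fraction
    arom_ok = summary.aromatic_count <= thr.max_aromatics
    reasons = [
        (f"cys_fraction {summary.cys_fraction:.3f} "
         f"{'>=' if cys_ok else '<'} {thr.min_cys_fraction} "
         f"[{'pass' if cys_ok else 'fail'}]"),
        (f"aromatic_count {summary.aromatic_count} "
         f"{'<=' if arom_ok else '>'} {thr.max_aromatics} "
         f"[{'pass' if arom_ok else 'fail'}]"),
    ]
    return MtLikeVerdict(is_mt_like=cys_ok and arom_ok, reasons=reasons,
                         thresholds_used=thr)


def average_mass(record: ProteinRecord | str, n_term_extension: str = "") -> float:
    """Average (not monoisotopic) mass of a peptide in Daltons.

    ``n_term_extension`` is prepended before computation — e.g. the
    Gly-Ser pair left on a recombinant peptide by thrombin cleavage of a
    GST fusion. The zero-residue limit returns one water (18.02 Da).

    Computed as the sum of residue average masses plus one water, from
    the pinned residue-mass table in :mod:`modmt._masses`.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    seq = n_term_extension.upper() + seq
    try:
        return sum(RESIDUE_AVG_MASS[aa] for aa in seq) + WATER_AVG_MASS
    except KeyError as exc:  # pragma: no cover - guarded upstream for records
        from .errors import InvalidSequenceError

        raise InvalidSequenceError(f"non-canonical residue {exc.args[0]!r}") from None


def average_mass_from_formula(record: ProteinRecord | str,
                              n_term_extension: str = "") -> float:
    """Average mass via full elemental-formula accumulation.

    Independent route used to cross-check :func:`average_mass`: residue
    formulas are summed element-wise, one water is added, and the total
    composition is weighted by the atomic-weight table.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    seq = n_term_extension.upper() + seq
    total = Counter({"H": 2, "O": 1})  # one water
    for aa in seq:
        total.update(parse_formula(RESIDUE_FORMULAS[aa]))
    return formula_mass(total)
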