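"""Metal stoichiometry from deconvoluted native-MS masses and ICP-AES.

Native ESI-MS of a metallothionein preparation yields neutral masses of
holo-species. Under the standard neutral-mass bookkeeping, each bound
metal ion displaces one proton per unit charge, so the theoretical mass
of a holo-species is

    apo_mass + sum_i n_i * (A_i - z_i * m_H)

with A_i the average atomic mass of metal i, z_i the charge of the
bound ion (2 for Zn2+/Cd2+, 1 for Cu+) and m_H = 1.00794 Da. Acid-labile
sulfide (S2-) ligands, when modelled, add 32.065 Da each with no proton
displacement.

Peak assignment enumerates all stoichiometries inside explicit bounds
(species here carry at most a few tens of metal ions, so brute force is
exact and fast) and keeps candidates within a relative tolerance of the
measured mass — 0.1% by default, the typical instrument error. Zn and
Cu increments differ by only 0.826 Da per ion, so at moderate loadings
the two are indistinguishable; assignments then report a composite
"M_n" species and set ``ambiguous_ZnCu``.

ICP-AES sulfur provides label-free protein quantitation: every S atom
is assumed to come from the peptide's Cys + Met, so
[protein] = [S] / s_atoms_per_protein, and metal-per-protein ratios
follow by division.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from ._masses import ATOMIC_WEIGHTS
from .errors import InvalidSequenceError, ModmtError, UnknownMetalError

_PROTON_AVG = ATOMIC_WEIGHTS["H"]  # displaced as neutral H in this bookkeeping

#: Acid-labile sulfide ligand: adds its mass with no proton displacement.
SULFIDE_KEY = "S2-"
SULFIDE_MASS = 32.065


@dataclass(frozen=True)
class MetalSpec:
    """A metal ion as seen by neutral-mass bookkeeping."""

    element: str
    bound_charge: int
    avg_atomic_mass: float

    @property
    def mass_increment(self) -> float:
        """Mass added per bound ion: atomic mass minus displaced protons."""
        return self.avg_atomic_mass - self.bound_charge * _PROTON_AVG


#: Built-in metal specs (divalent Zn/Cd, monovalent Cu).
METALS: dict[str, MetalSpec] = {
    "Zn": MetalSpec("Zn", 2, ATOMIC_WEIGHTS["Zn"]),
    "Cd": MetalSpec("Cd", 2, ATOMIC_WEIGHTS["Cd"]),
    "Cu": MetalSpec("Cu", 1, ATOMIC_WEIGHTS["Cu"]),
}


@dataclass(frozen=True)
class HoloSpecies:
    """A metal-loaded species: stoichiometry plus theoretical mass."""

    stoichiometry: dict[str, int]
    theoretical_mass: float
    label: str

    @property
    def total_metals(self) -> int:
        return sum(n for el, n in self.stoichiometry.items() if el != SULFIDE_KEY)


def species_label(stoichiometry: dict[str, int], composite_zn_cu: bool = False) -> str:
    """Human label like "Zn20", "Cu4S2-1" or composite "M15"."""
    if not any(stoichiometry.values()):
        return "apo"
    parts = []
    zn_cu = stoichiometry.get("Zn", 0) + stoichiometry.get("Cu", 0)
    if composite_zn_cu and zn_cu:
        parts.append(f"M{zn_cu}")
    for el, n in sorted(stoichiometry.items()):
        if n == 0 or (composite_zn_cu and el in ("Zn", "Cu")):
            continue
        parts.append(f"{el}{n}")
    return "".join(parts)


def holo_mass(apo_mass: float, stoichiometry: dict[str, int],
              metals: dict[str, MetalSpec] | None = None) -> float:
    """Theoretical neutral mass of a holo-species.

    ``stoichiometry`` maps element symbols to counts; the key "S2-"
    denotes acid-labile sulfide ligands.
    """
    if apo_mass <= 0:
        raise ModmtError(f"apo mass must be positive, got {apo_mass}")
    metals = metals or METALS
    mass = apo_mass
    for el, n in stoichiometry.items():
        if n < 0:
            raise ModmtError(f"negative count for {el}")
        if el == SULFIDE_KEY:
            mass += n * SULFIDE_MASS
        elif el in metals:
            mass += n * metals[el].mass_increment
        else:
            raise UnknownMetalError(f"no MetalSpec for element {el!r}")
    return mass


@dataclass(frozen=True)
class StoichAssignment:
    """Ranked stoichiometry candidates for one deconvoluted peak."""

    peak_mass: float
    candidates: tuple[tuple[HoloSpecies, float, float], ...]  # (species, err_da, err_rel)
    ambiguous_ZnCu: bool
    best: HoloSpecies | None
    best_label: str


def default_metal_bound(cys_count: int, slack: int = 10) -> int:
    """Default cap on total metal count from the Cys budget.

    The densest Cu(I)-thiolate packing relevant here is the Cu5S7
    cluster (5 metals per 7 Cys), so the cap is ceil(cys * 5/7) plus a
    slack margin.
    """
    return math.ceil(cys_count * 5 / 7) + slack


def assign_peaks(peaks: list[float], apo_mass: float,
                 metals: list[str] | None = None,
                 max_total: int | None = None,
                 cys_count: int | None = None,
                 tolerance_rel: float = 0.001,
                 allow_sulfide: bool = False,
                 max_sulfide: int = 10) -> list[StoichAssignment]:
    """Assign each deconvoluted peak to metal/sulfide stoichiometries.

    Candidates are enumerated exhaustively within bounds (``max_total``
    total metal ions; derived from ``cys_count`` via
    :func:`default_metal_bound` when not given) and ranked by absolute
    mass error; only candidates within ``tolerance_rel * peak`` are
    kept. When both Zn and Cu are considered and the best candidate's
    Zn+Cu loading n satisfies n * |dZn - dCu| <= tolerance (the mass gap
    from swapping the entire Zn/Cu content), the species is reported as
    the composite "M_n" and ``ambiguous_ZnCu`` is set.
    """
    if apo_mass <= 0:
        raise ModmtError(f"apo mass must be positive, got {apo_mass}")
    metals = metals if metals is not None else ["Zn", "Cd", "Cu"]
    for el in metals:
        if el not in METALS:
            raise UnknownMetalError(f"no MetalSpec for element {el!r}")
    if max_total is None:
        if cys_count is None:
            raise ModmtError("provide max_total or cys_count to bound enumeration")
        max_total = default_metal_bound(cys_count)

    increments = {el: METALS[el].mass_increment for el in metals}
    zn_cu_gap = abs(METALS["Zn"].mass_increment - METALS["Cu"].mass_increment)

    # enumerate all in-bound stoichiometries once; reused for every peak
    space: list[tuple[dict[str, int], float]] = []
    counts_ranges = [range(max_total + 1)] * len(metals)
    for counts in itertools.product(*counts_ranges):
        if sum(counts) > max_total:
            continue
        for n_s in range(max_sulfide + 1 if allow_sulfide else 1):
            stoich = {el: n for el, n in zip(metals, counts)}
            if allow_sulfide:
                stoich[SULFIDE_KEY] = n_s
            delta = sum(n * increments[el] for el, n in zip(metals, counts))
            delta += n_s * SULFIDE_MASS
            space.append((stoich, apo_mass + delta))

    out = []
    for peak in peaks:
        tol = tolerance_rel * peak
        cands = []
        for stoich, mass in space:
            err = mass - peak
            if abs(err) <= tol:
                sp = HoloSpecies({k: v for k, v in stoich.items() if v},
                                 mass, species_label(stoich))
                cands.append((sp, err, err / peak))
        cands.sort(key=lambda c: (abs(c[1]), c[0].total_metals))
        best = cands[0][0] if cands else None
        ambiguous = False
        label = best.label if best else "unassigned"
        if best is not None and "Zn" in metals and "Cu" in metals:
            n_zn_cu = (best.stoichiometry.get("Zn", 0)
                       + best.stoichiometry.get("Cu", 0))
            if n_zn_cu >= 1 and n_zn_cu * zn_cu_gap <= tol:
                ambiguous = True
                label = species_label(best.stoichiometry, composite_zn_cu=True)
        out.append(StoichAssignment(
            peak_mass=peak, candidates=tuple(cands),
            ambiguous_ZnCu=ambiguous, best=best, best_label=label,
        ))
    return out


# ---------------------------------------------------------------------------
# ICP-AES metal-per-protein ratios


@dataclass(frozen=True)
class IcpMeasurement:
    """Sulfur-based protein quantitation and metal-to-protein ratios."""

    element_concentrations: dict[str, float]
    s_atoms_per_protein: int
    protein_concentration: float
    metal_per_protein: dict[str, float] = field(default_factory=dict)


def metal_per_protein(element_concentrations: dict[str, float],
                      s_atoms_per_protein: int) -> IcpMeasurement:
    """Metal-to-protein molar ratios from ICP-AES element concentrations.

    The protein concentration is [S] / s_atoms_per_protein, where the
    S-atom count is the construct's Cys + Met total (for a recombinant
    GS-extended peptide, count the extension too). Every other element
    in the input is divided by the protein concentration.
    """
    if s_atoms_per_protein < 1:
        raise ModmtError("s_atoms_per_protein must be >= 1")
    s_conc = element_concentrations.get("S", 0.0)
    if s_conc <= 0:
        raise ModmtError("sulfur concentration must be positive for "
                         "protein quantitation")
    protein = s_conc / s_atoms_per_protein
    ratios = {el: conc / protein
              for el, conc in element_concentrations.items() if el != "S"}
    return IcpMeasurement(
        element_concentrations=dict(element_concentrations),
        s_atoms_per_protein=s_atoms_per_protein,
        protein_concentration=protein,
        metal_per_protein=ratios,
    )


def s_atoms_of_sequence(sequence: str, n_term_extension: str = "") -> int:
    """Cys + Met count of a (possibly extended) construct sequence."""
    seq = (n_term_extension + sequence).upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    return seq.count("C") + seq.count("M")
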