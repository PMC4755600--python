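"""Pinned atomic weights and amino-acid residue masses.

All average masses in modmt derive from the single atomic-weight table
below (IUPAC 2005 standard atomic weights, the vintage used by the
deconvolution software contemporary with the measurements this package
models). Pinning one table keeps apo- and holo-mass arithmetic mutually
consistent and reproducible to well under 0.01 Da.

Residue masses are the amino acid minus one water; a peptide's average
mass is the sum of its residue masses plus one water. ``RESIDUE_AVG_MASS``
is frozen numerically so that the residue-table route and the
elemental-formula route (see :func:`modmt.seqstats.average_mass`) are two
genuinely independent computations.
"""

from __future__ import annotations

import re
from collections import Counter

#: Average atomic weights (Da), IUPAC 2005 vintage.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
    # metals used in holo-species bookkeeping
    "Zn": 65.38,
    "Cu": 63.546,
    "Cd": 112.414,
}

#: One water molecule (Da); added once per peptide.
WATER_AVG_MASS: float = 18.01528

#: Elemental formulas of amino-acid *residues* (amino acid minus water).
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

#: Average residue masses (Da), frozen from the formulas under
#: ``ATOMIC_WEIGHTS``. Kept as literals so the two mass routes stay
#: independent in code.
RESIDUE_AVG_MASS: dict[str, float] = {
    "A": 71.07790,
    "C": 103.14290,
    "D": 115.08740,
    "E": 129.11398,
    "F": 147.17386,
    "G": 57.05132,
    "H": 137.13928,
    "I": 113.15764,
    "K": 128.17228,
    "L": 113.15764,
    "M": 131.19606,
    "N": 114.10264,
    "P": 97.11518,
    "Q": 128.12922,
    "R": 156.18568,
    "S": 87.07730,
    "T": 101.10388,
    "V": 99.13106,
    "W": 186.20990,
    "Y": 163.17326,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-style elemental formula into an element→count Counter."""
    counts: Counter = Counter()
    for element, n in _FORMULA_TOKEN.findall(formula):
        if element:
            counts[element] += int(n) if n else 1
    return counts


def formula_mass(counts: Counter) -> float:
    """Average mass (Da) of an elemental composition under the pinned table."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
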