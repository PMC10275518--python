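"""Molecular-formula arithmetic and adduct m/z calculation.

Supports the positive-mode singly charged adducts used for drug
identification in DESI imaging: temozolomide is detected as the sodium
adduct ([M+Na]+, nominal 194 -> 217) and doxorubicin as the protonated
molecule ([M+H]+, nominal 543 -> 544).  The monoisotopic route uses the
hydrogen-atom convention (no electron-mass correction), which reproduces
the conventional leucine-enkephalin lock mass m/z 556.2771 from
C28H37N5O7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import FormulaError, SpecificationError, UnsupportedElementError

# Monoisotopic atomic masses (Da), CODATA/IUPAC values for the most
# abundant isotope of each element.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637064864,
    "F": 18.9984031627,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula like ``"C28H37N5O7"`` into element counts.

    Repeated element symbols accumulate (``"CH3CH3"`` -> ``{C:2, H:6}``).
    Raises :class:`FormulaError` on unknown symbols, zero counts or
    unparseable text.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        if not m.group(0):
            break
        pos = m.end()
        element = m.group(1)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n == 0:
            raise FormulaError(f"zero count for element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text) or not counts:
        raise FormulaError(f"cannot parse formula {text!r}")
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass over the element counts."""
    total = 0.0
    for element, n in counts.items():
        if element not in MONOISOTOPIC_MASS:
            raise UnsupportedElementError(f"no monoisotopic mass for {element!r}")
        if n <= 0:
            raise FormulaError(f"non-positive count for {element!r}")
        total += n * MONOISOTOPIC_MASS[element]
    return total


@dataclass(frozen=True)
class MoleculeSpec:
    """An analyte identified by elemental formula and/or nominal mass.

    At least one of ``formula`` / ``nominal_mass`` must be given; the
    formula is validated eagerly.
    """

    name: str
    formula: str | None = None
    nominal_mass: int | None = None

    def __post_init__(self) -> None:
        if self.formula is None and self.nominal_mass is None:
            raise SpecificationError(
                f"molecule {self.name!r} needs a formula or a nominal mass"
            )
        if self.formula is not None:
            parse_formula(self.formula)
        if self.nominal_mass is not None and self.nominal_mass <= 0:
            raise SpecificationError("nominal_mass must be positive")

    @property
    def monoisotopic(self) -> float:
        if self.formula is None:
            raise SpecificationError(
                f"molecule {self.name!r} has no formula; monoisotopic mass unavailable"
            )
        return monoisotopic_mass(parse_formula(self.formula))


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive-mode adduct.

    ``delta_monoisotopic`` is the mass of the added atoms under the
    hydrogen-atom convention; ``delta_nominal`` the integer equivalent.
    """

    name: str
    delta_monoisotopic: float
    delta_nominal: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise SpecificationError("only +1 adducts are supported (positive mode)")


PROTON = AdductSpec("[M+H]+", MONOISOTOPIC_MASS["H"], 1)
# Hydrogen-atom convention: the electron mass is ignored, so the [M+Na]+
# delta is simply the Na atomic mass.
SODIUM = AdductSpec("[M+Na]+", MONOISOTOPIC_MASS["Na"], 23)

ADDUCTS: dict[str, AdductSpec] = {a.name: a for a in (PROTON, SODIUM)}

# Drug presets as used for ion-image extraction: temozolomide C6H6N6O2
# (nominal 194, observed as [M+Na]+ at 217), doxorubicin C27H29NO11
# (nominal 543, observed as [M+H]+ at 544).
TEMOZOLOMIDE = MoleculeSpec("temozolomide", formula="C6H6N6O2", nominal_mass=194)
DOXORUBICIN = MoleculeSpec("doxorubicin", formula="C27H29NO11", nominal_mass=543)
LEUCINE_ENKEPHALIN = MoleculeSpec("leucine enkephalin", formula="C28H37N5O7")

DRUG_PRESETS: dict[str, tuple[MoleculeSpec, AdductSpec]] = {
    "tmz": (TEMOZOLOMIDE, SODIUM),
    "dox": (DOXORUBICIN, PROTON),
}


def adduct_mz(
    molecule: MoleculeSpec, adduct: AdductSpec, mode: str = "nominal"
) -> float:
    """m/z of the singly charged adduct ion.

    ``mode="nominal"`` uses integer masses (``nominal_mass + delta_nominal``);
    ``mode="monoisotopic"`` uses the formula and reports 4 decimals.
    """
    if mode == "nominal":
        if molecule.nominal_mass is not None:
            base = molecule.nominal_mass
        elif molecule.formula is not None:
            base = int(round(molecule.monoisotopic))
        else:  # pragma: no cover - MoleculeSpec forbids this
            raise SpecificationError("no mass information")
        return float(base + adduct.delta_nominal)
    if mode == "monoisotopic":
        if molecule.formula is None:
            raise SpecificationError(
                f"monoisotopic m/z for {molecule.name!r} requires a formula"
            )
        return round(molecule.monoisotopic + adduct.delta_monoisotopic, 4)
    raise ValueError(f"unknown mode {mode!r}")
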