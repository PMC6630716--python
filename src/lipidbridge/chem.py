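"""Molecular-formula arithmetic and monoisotopic ion m/z computation.

Every diagnostic-ion m/z in the lipid library traces back to a
:class:`MolecularFormula` evaluated here.  Masses are monoisotopic; ion m/z
values carry the electron-mass correction (an ion is not its neutral radical).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

# Monoisotopic atomic masses, Da (CODATA/IUPAC 2021, 6 decimals).
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
}

#: Electron rest mass, Da.
ELECTRON_MASS = 0.000549

#: m/z of a proton (H minus one electron); the [M+H]+ / [M-H]- spacing unit.
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unknown elements or impossible formula arithmetic."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map with element-wise arithmetic.

    Counts are strictly positive; elements that would reach zero are dropped,
    and subtraction below zero raises :class:`FormulaError`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a plain Hill-style string such as ``"C30H52NO7"``.

        Implicit count is 1 (``N`` in the example).  Charge signs and markup
        are not part of the string; polarity lives on :class:`IonSpec`.
        """
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            if not m.group(0):
                break
            el = m.group(1)
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction below zero for element {el}: "
                    f"{self} - {other}"
                )
            counts[el] = new
        return MolecularFormula(counts)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in order
        )

    def __bool__(self) -> bool:
        return bool(self.counts)


def F(text: str) -> MolecularFormula:
    """Shorthand formula constructor."""
    return MolecularFormula.parse(text)


WATER = F("H2O")


@dataclass(frozen=True)
class IonSpec:
    """A charged species: formula plus polarity and charge magnitude."""

    formula: MolecularFormula
    polarity: str  # "positive" | "negative"
    charge_magnitude: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.charge_magnitude < 1:
            raise ValueError("charge_magnitude must be >= 1")


def formula_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    if not f:
        raise FormulaError("empty formula has no mass")
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts.items())


def ion_mz(ion: IonSpec) -> float:
    """m/z of an ion: formula mass corrected by the electron count.

    A cation has lost electrons (lighter than the radical sum); an anion has
    gained them.
    """
    sign = 1.0 if ion.polarity == "positive" else -1.0
    m = formula_mass(ion.formula) - sign * ion.charge_magnitude * ELECTRON_MASS
    return m / ion.charge_magnitude


#: Adduct rules: (formula delta, sign of delta, polarity).
_ADDUCTS = {
    "[M+H]+": (F("H"), +1, "positive"),
    "[M-H]-": (F("H"), -1, "negative"),
    "[M+HCOO]-": (F("CHO2"), +1, "negative"),
}

# Accept the typographic minus that shows up in copied adduct labels.
_ADDUCT_ALIASES = {"[M−H]−": "[M-H]-", "[M−H]-": "[M-H]-",
                   "[M+H]⁺": "[M+H]+", "[M+HCOO]−": "[M+HCOO]-"}


def normalize_adduct(adduct: str) -> str:
    adduct = _ADDUCT_ALIASES.get(adduct, adduct)
    if adduct not in _ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}"
        )
    return adduct


def adduct_ion(neutral: MolecularFormula, adduct: str) -> IonSpec:
    """Apply an adduct rule to a neutral formula.

    ``[M+H]+`` adds a hydrogen (positive), ``[M-H]-`` removes one (negative),
    ``[M+HCOO]-`` adds a formate CHO2 (negative).
    """
    delta, sign, polarity = _ADDUCTS[normalize_adduct(adduct)]
    formula = neutral + delta if sign > 0 else neutral - delta
    return IonSpec(formula=formula, polarity=polarity)


def adduct_mz(neutral: MolecularFormula, adduct: str) -> float:
    return ion_mz(adduct_ion(neutral, adduct))
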