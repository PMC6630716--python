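"""Rule-based in-silico MS/MS spectrum generation for lipid classes.

A lipid is modelled as a glycerol backbone carrying esterified acyl chains and
a class-specific head group.  The head-group composition table below is the
net formula a head group adds to the (mono/di/tri)acylglycerol after the
condensation water loss; it was derived so that the class ions and
composition-dependent neutral losses of the supported classes reproduce the
literature diagnostic m/z values exactly.

Two kinds of diagnostic fragments are generated:

* class ions — head-group fragments (fixed m/z) or class-specific neutral
  losses from the precursor; their presence identifies the lipid class;
* chain ions — acyl carboxylate anions (negative mode) or neutral losses of
  the fatty acids (positive mode); they identify the acyl composition and are
  what makes isomer-specific targeted quantification possible.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import (
    F,
    WATER,
    FormulaError,
    IonSpec,
    MolecularFormula,
    adduct_ion,
    ion_mz,
    normalize_adduct,
)

GLYCEROL = F("C3H8O3")

#: Net head-group addition to the acylglycerol (condensation water already
#: removed).  Derived from known neutral formulas of each class.
HEAD_GROUPS: Dict[str, MolecularFormula] = {
    "PC": F("C5H12NO3P"),      # phosphocholine
    "PE": F("C2H6NO3P"),       # phosphoethanolamine
    "PG": F("C3H7O5P"),        # phosphoglycerol
    "PI": F("C6H11O8P"),       # phosphoinositol
    "PS": F("C3H6NO5P"),       # phosphoserine
    "PMeOH": F("CH3O3P"),      # phosphomethanol
    "GlcADG": F("C6H8O6"),     # glucuronosyl
    "MGDG": F("C6H10O5"),      # galactosyl
    "DGDG": F("C12H20O10"),    # digalactosyl
    "SQDG": F("C6H10O7S"),     # sulfoquinovosyl
    "DGTS": F("C7H13NO2"),     # trimethylhomoserine (DGTS/DGTA)
    "DGCC": F("C7H15NO4"),     # carboxyhydroxymethylcholine
}

#: lipid class -> (number of chains, parent head-group key, has glycerol backbone)
LIPID_CLASSES: Dict[str, Tuple[int, Optional[str], bool]] = {
    "FFA": (1, None, False),
    "DAG": (2, None, True),
    "TAG": (3, None, True),
    "PC": (2, "PC", True),
    "PE": (2, "PE", True),
    "PG": (2, "PG", True),
    "PI": (2, "PI", True),
    "PS": (2, "PS", True),
    "LPC": (1, "PC", True),
    "LPE": (1, "PE", True),
    "LPG": (1, "PG", True),
    "LPS": (1, "PS", True),
    "OxPC": (2, "PC", True),
    "OxPE": (2, "PE", True),
    "OxPG": (2, "PG", True),
    "OxPI": (2, "PI", True),
    "PMeOH": (2, "PMeOH", True),
    "GlcADG": (2, "GlcADG", True),
    "MGDG": (2, "MGDG", True),
    "DGDG": (2, "DGDG", True),
    "SQDG": (2, "SQDG", True),
    "DGTS": (2, "DGTS", True),
    "DGCC": (2, "DGCC", True),
    "LDGCC": (1, "DGCC", True),
}

#: Supported (lipid class -> adduct) pairs for spectrum generation.
SUPPORTED_ADDUCTS: Dict[str, str] = {
    "LDGCC": "[M+H]+",
    "DGCC": "[M+H]+",
    "DGTS": "[M+H]+",
    "OxPC": "[M+HCOO]-",
    "PC": "[M+HCOO]-",
    "LPC": "[M+HCOO]-",
    "OxPE": "[M-H]-",
    "OxPG": "[M-H]-",
    "OxPI": "[M-H]-",
    "PMeOH": "[M-H]-",
    "GlcADG": "[M-H]-",
    "LPG": "[M-H]-",
    "LPS": "[M-H]-",
    "PE": "[M-H]-",
    "PG": "[M-H]-",
    "PI": "[M-H]-",
    "PS": "[M-H]-",
    "LPE": "[M-H]-",
    "MGDG": "[M-H]-",
    "DGDG": "[M-H]-",
    "SQDG": "[M-H]-",
    "FFA": "[M-H]-",
}

#: Fixed-m/z class-diagnostic ions: class -> list of (formula, polarity, annotation).
CLASS_IONS: Dict[str, List[Tuple[MolecularFormula, str, str]]] = {
    "LDGCC": [(F("C5H14NO"), "positive", "choline-like head 104.107"),
              (F("C6H14NO2"), "positive", "head fragment 132.102")],
    "DGCC": [(F("C5H14NO"), "positive", "choline-like head 104.107"),
             (F("C6H14NO2"), "positive", "head fragment 132.102")],
    "DGTS": [(F("C7H14NO2"), "positive", "head fragment 144.102"),
             (F("C10H22NO5"), "positive", "glycerol+head fragment 236.149")],
    "OxPE": [(F("C5H11NO5P"), "negative", "phosphoethanolamine 196.038")],
    "PE": [(F("C5H11NO5P"), "negative", "phosphoethanolamine 196.038")],
    "LPE": [(F("C5H11NO5P"), "negative", "phosphoethanolamine 196.038")],
    "OxPG": [(F("C3H6O5P"), "negative", "glycerophosphate 152.995")],
    "PG": [(F("C3H6O5P"), "negative", "glycerophosphate 152.995")],
    "LPG": [(F("C3H6O5P"), "negative", "glycerophosphate 152.995")],
    "OxPI": [(F("C9H14O9P"), "negative", "glycerophosphoinositol 297.038"),
             (F("C6H10O8P"), "negative", "inositolphosphate-H2O 241.012")],
    "PI": [(F("C9H14O9P"), "negative", "glycerophosphoinositol 297.038"),
           (F("C6H10O8P"), "negative", "inositolphosphate-H2O 241.012")],
    "PMeOH": [(F("C4H8O5P"), "negative", "methylglycerophosphate 167.012"),
              (F("CH4O4P"), "negative", "methylphosphate 110.985")],
    # printed as C9H13O7 in some sources; C9H13O8- is the composition that
    # reproduces the 249.062 glucuronosylglycerol anion
    "GlcADG": [(F("C9H13O8"), "negative", "glucuronosylglycerol 249.062")],
    "DGDG": [(F("C15H25O12"), "negative", "digalactosylglycerol-H2O 397.135")],
    "SQDG": [(F("C6H9O7S"), "negative", "sulfoquinovose 225.007")],
}

#: Class-specific neutral losses from the precursor ion:
#: class -> (neutral formula lost, annotation).
CLASS_NEUTRAL_LOSSES: Dict[str, Tuple[MolecularFormula, str]] = {
    # formate adducts collapse to the demethylated anion: loss of CH3 + HCOOH
    "OxPC": (F("C2H4O2"), "NL of HCOO+CH3"),
    "PC": (F("C2H4O2"), "NL of HCOO+CH3"),
    "LPC": (F("C2H4O2"), "NL of HCOO+CH3"),
    # serine head loss (87.032 Da) from [M-H]-
    "LPS": (F("C3H5NO2"), "NL of serine head"),
    "PS": (F("C3H5NO2"), "NL of serine head"),
}

#: Default relative-abundance template (overridable in generate_spectrum).
DEFAULT_ABUNDANCES = {
    "class_primary": 100.0,
    "class_secondary": 50.0,
    "chain": 40.0,
    "chain_minus_water": 20.0,
    "minor": 5.0,
}

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:\+(\d+)O)?$")


@dataclass(frozen=True)
class AcylChain:
    """A fatty-acyl moiety: carbon count, double bonds, extra oxygens.

    ``20:4+2O`` means 20 carbons, 4 double bonds, 2 additional oxygens (an
    oxidized chain).  The neutral fatty acid formula is
    ``C(n) H(2n-2d) O(2+x)``.
    """

    carbons: int
    double_bonds: int
    extra_oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs >= 2 carbons")
        if not (0 <= self.double_bonds <= self.carbons - 1):
            raise ValueError("double_bonds must be in [0, carbons-1]")
        if not (0 <= self.extra_oxygens <= 4):
            raise ValueError("extra_oxygens must be in [0, 4]")

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        m = _CHAIN_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse acyl chain {text!r}")
        return cls(int(m.group(1)), int(m.group(2)),
                   int(m.group(3)) if m.group(3) else 0)

    @property
    def fatty_acid(self) -> MolecularFormula:
        """Neutral free fatty acid formula."""
        return MolecularFormula({
            "C": self.carbons,
            "H": 2 * self.carbons - 2 * self.double_bonds,
            "O": 2 + self.extra_oxygens,
        })

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.extra_oxygens:
            s += f"+{self.extra_oxygens}O"
        return s


def acyl_anion(chain: AcylChain) -> IonSpec:
    """The carboxylate anion [FA-H]- of a chain."""
    return IonSpec(chain.fatty_acid - F("H"), "negative")


def acyl_anion_mz(chain: AcylChain) -> float:
    """m/z of the acyl carboxylate anion, e.g. 283.264 for 18:0."""
    return ion_mz(acyl_anion(chain))


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class plus its ordered acyl chains (position 1 = SN1)."""

    lipid_class: str
    chains: Tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        n_expected = LIPID_CLASSES[self.lipid_class][0]
        if len(self.chains) != n_expected:
            raise ValueError(
                f"{self.lipid_class} requires {n_expected} chain(s), "
                f"got {len(self.chains)}"
            )
        if self.lipid_class.startswith("Ox") and not any(
            c.extra_oxygens > 0 for c in self.chains
        ):
            raise ValueError("Ox classes need extra oxygens on >= 1 chain")

    @classmethod
    def parse(cls, name: str) -> "LipidSpecies":
        """Parse ``"DGCC 18:0-20:4"`` (underscore dialect accepted)."""
        parts = name.strip().split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"cannot parse lipid name {name!r}")
        lipid_class, chain_text = parts
        chains = tuple(
            AcylChain.parse(c) for c in re.split(r"[-_]", chain_text.replace("–", "-"))
        )
        return cls(lipid_class, chains)

    @property
    def name(self) -> str:
        return f"{self.lipid_class} " + "-".join(str(c) for c in self.chains)

    def __str__(self) -> str:
        return self.name


def neutral_formula(lipid: LipidSpecies) -> MolecularFormula:
    """Neutral molecular formula: backbone + head group + esterified chains.

    Each ester bond loses one water; the head-group table already carries its
    own condensation loss.
    """
    n_chains, head_key, has_backbone = LIPID_CLASSES[lipid.lipid_class]
    total = MolecularFormula({})
    for chain in lipid.chains:
        total = total + chain.fatty_acid
    if has_backbone:
        total = total + GLYCEROL - len(lipid.chains) * WATER
    if head_key is not None:
        total = total + HEAD_GROUPS[head_key]
    return total


@dataclass(frozen=True)
class Fragment:
    """One annotated product ion of a reference spectrum."""

    mz: float
    relative_abundance: float
    annotation: str
    diagnostic: str = "none"  # "class" | "chain" | "none"
    minor: bool = False
    formula: Optional[IonSpec] = field(default=None, compare=False)


@dataclass
class ReferenceSpectrum:
    """A library entry: precursor ion plus annotated fragment list."""

    name: str
    adduct: str
    precursor_mz: float
    fragments: List[Fragment]
    retention_time: Optional[float] = None
    species: Optional[LipidSpecies] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments, key=lambda f: f.mz)

    @property
    def class_fragments(self) -> List[Fragment]:
        return [f for f in self.fragments if f.diagnostic == "class"]

    @property
    def chain_fragments(self) -> List[Fragment]:
        return [f for f in self.fragments if f.diagnostic == "chain"]


def _positive_chain_losses(
    lipid: LipidSpecies, precursor: IonSpec, abundances: Dict[str, float]
) -> List[Fragment]:
    """NL-of-fatty-acid fragments for positive-mode betaine lipids."""
    frags: List[Fragment] = []
    labels = ["SN1", "SN2", "SN3"]
    for label, chain in zip(labels, lipid.chains):
        for extra_water, suffix in ((0, ""), (1, "+H2O")):
            try:
                f = precursor.formula - chain.fatty_acid - extra_water * WATER
            except FormulaError:
                continue
            frags.append(Fragment(
                mz=ion_mz(IonSpec(f, precursor.polarity)),
                relative_abundance=abundances["chain_minus_water"]
                if extra_water else abundances["chain"],
                annotation=f"NL of {label}{suffix} ({chain})",
                diagnostic="chain",
                formula=IonSpec(f, precursor.polarity),
            ))
    return frags


def _negative_chain_ions(
    lipid: LipidSpecies, abundances: Dict[str, float]
) -> List[Fragment]:
    """Acyl carboxylate anions; oxidized chains also lose one and two waters
    (the double dehydration is a rarely-detected minor ion)."""
    frags: List[Fragment] = []
    labels = ["SN1", "SN2", "SN3"]
    single = len(lipid.chains) == 1
    for label, chain in zip(labels, lipid.chains):
        tag = "SN1||SN2" if single else label
        ion = acyl_anion(chain)
        frags.append(Fragment(
            mz=ion_mz(ion), relative_abundance=abundances["chain"],
            annotation=f"{tag} ({chain})", diagnostic="chain", formula=ion,
        ))
        if chain.extra_oxygens > 0:
            for n_water, minor in ((1, False), (2, True)):
                f = ion.formula - n_water * WATER
                dehydrated = IonSpec(f, "negative")
                frags.append(Fragment(
                    mz=ion_mz(dehydrated),
                    relative_abundance=abundances["minor"] if minor
                    else abundances["chain_minus_water"],
                    annotation=f"{tag}-{n_water}H2O ({chain})",
                    diagnostic="chain",
                    minor=minor,
                    formula=dehydrated,
                ))
    return frags


def generate_spectrum(
    lipid: LipidSpecies,
    adduct: Optional[str] = None,
    abundances: Optional[Dict[str, float]] = None,
) -> ReferenceSpectrum:
    """Generate the in-silico MS/MS spectrum of a lipid species.

    The adduct defaults to the class's supported ion form.  Raises for
    unsupported (class, adduct) pairs; abundances follow the class template
    (class ions 100/50, chain ions 40, dehydrated 20, minor 5) rescaled so
    the base peak is 100.
    """
    cls = lipid.lipid_class
    if cls not in SUPPORTED_ADDUCTS:
        raise ValueError(
            f"no spectrum generation rule for class {cls!r}; supported "
            f"classes: {sorted(SUPPORTED_ADDUCTS)}"
        )
    expected = SUPPORTED_ADDUCTS[cls]
    adduct = expected if adduct is None else normalize_adduct(adduct)
    if adduct != expected:
        raise ValueError(
            f"unsupported (class, adduct) pair ({cls}, {adduct}); "
            f"supported: ({cls}, {expected})"
        )
    ab = dict(DEFAULT_ABUNDANCES)
    if abundances:
        ab.update(abundances)

    precursor = adduct_ion(neutral_formula(lipid), adduct)
    frags: List[Fragment] = []

    for i, (formula, polarity, note) in enumerate(CLASS_IONS.get(cls, [])):
        ion = IonSpec(formula, polarity)
        frags.append(Fragment(
            mz=ion_mz(ion),
            relative_abundance=ab["class_primary"] if i == 0 else ab["class_secondary"],
            annotation=note, diagnostic="class", formula=ion,
        ))
    if cls in CLASS_NEUTRAL_LOSSES:
        loss, note = CLASS_NEUTRAL_LOSSES[cls]
        f = precursor.formula - loss
        ion = IonSpec(f, precursor.polarity)
        frags.append(Fragment(
            mz=ion_mz(ion),
            relative_abundance=ab["class_primary"] if not frags else ab["class_secondary"],
            annotation=note, diagnostic="class", formula=ion,
        ))

    if cls == "FFA":
        ion = acyl_anion(lipid.chains[0])
        frags.append(Fragment(
            mz=ion_mz(ion), relative_abundance=ab["class_primary"],
            annotation=f"carboxylate ({lipid.chains[0]})",
            diagnostic="chain", formula=ion,
        ))
    elif cls == "LDGCC":
        pass  # class ions only
    elif precursor.polarity == "positive":
        frags.extend(_positive_chain_losses(lipid, precursor, ab))
    else:
        frags.extend(_negative_chain_ions(lipid, ab))

    top = max(f.relative_abundance for f in frags)
    if top != 100.0:
        frags = [
            Fragment(f.mz, 100.0 * f.relative_abundance / top, f.annotation,
                     f.diagnostic, f.minor, f.formula)
            for f in frags
        ]

    display = cls if cls != "DGTS" else "DGTS/DGTA"
    name = f"{display} " + "-".join(str(c) for c in lipid.chains)
    return ReferenceSpectrum(
        name=name,
        adduct=adduct,
        precursor_mz=ion_mz(precursor),
        fragments=frags,
        species=lipid,
    )


@dataclass(frozen=True)
class ChainSpace:
    """Chain enumeration ranges for library building (one per position)."""

    carbons: Tuple[int, ...]
    double_bonds: Tuple[int, ...]
    extra_oxygens: Tuple[int, ...] = (0,)

    def chains(self) -> List[AcylChain]:
        out = []
        for c, d, x in itertools.product(self.carbons, self.double_bonds,
                                         self.extra_oxygens):
            if d <= c - 1:
                out.append(AcylChain(c, d, x))
        return out


def build_library(
    classes: Iterable[str],
    chain_space: ChainSpace | Sequence[ChainSpace],
) -> List[ReferenceSpectrum]:
    """Cartesian enumeration of lipid species over a chain space.

    Deduplicated by (class, chain multiset); deterministic ordering by name.
    A single ChainSpace applies to every SN position; a sequence gives one
    space per position.
    """
    spectra: Dict[Tuple[str, str], ReferenceSpectrum] = {}
    for cls in classes:
        n_chains = LIPID_CLASSES[cls][0]
        spaces = (
            [chain_space] * n_chains if isinstance(chain_space, ChainSpace)
            else list(chain_space)
        )
        if len(spaces) < n_chains:
            raise ValueError(f"need {n_chains} chain spaces for {cls}")
        seen: set = set()
        for combo in itertools.product(*(s.chains() for s in spaces[:n_chains])):
            key = (cls, tuple(sorted((c.carbons, c.double_bonds, c.extra_oxygens)
                                     for c in combo)))
            if key in seen:
                continue
            if cls.startswith("Ox") and not any(c.extra_oxygens for c in combo):
                continue
            seen.add(key)
            try:
                spec = generate_spectrum(LipidSpecies(cls, tuple(combo)))
            except ValueError:
                continue
            spectra[(spec.name, spec.adduct)] = spec
    if not spectra:
        warnings.warn("empty chain enumeration produced an empty library")
    return [spectra[k] for k in sorted(spectra)]


# ---------------------------------------------------------------------------
# MSP text import/export

def write_msp(spectra: Iterable[ReferenceSpectrum], path) -> None:
    """Write spectra in MSP text format (round-trip safe with read_msp)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"NAME: {s.name}\n")
            fh.write(f"PRECURSORMZ: {s.precursor_mz:.6f}\n")
            fh.write(f"PRECURSORTYPE: {s.adduct}\n")
            if s.retention_time is not None:
                fh.write(f"RETENTIONTIME: {s.retention_time:.4f}\n")
            fh.write(f"Num Peaks: {len(s.fragments)}\n")
            for f in s.fragments:
                flags = f.diagnostic + (";minor" if f.minor else "")
                fh.write(f"{f.mz:.6f}\t{f.relative_abundance:.4f}\t"
                         f"\"{f.annotation}|{flags}\"\n")
            fh.write("\n")


def read_msp(path) -> List[ReferenceSpectrum]:
    """Read an MSP library written by :func:`write_msp`."""
    spectra: List[ReferenceSpectrum] = []
    header: Dict[str, str] = {}
    frags: List[Fragment] = []
    n_expected = 0

    def flush():
        nonlocal header, frags, n_expected
        if header:
            if len(frags) != n_expected:
                raise ValueError(
                    f"MSP entry {header.get('NAME')!r}: expected "
                    f"{n_expected} peaks, found {len(frags)}"
                )
            spectra.append(ReferenceSpectrum(
                name=header["NAME"],
                adduct=header["PRECURSORTYPE"],
                precursor_mz=float(header["PRECURSORMZ"]),
                retention_time=float(header["RETENTIONTIME"])
                if "RETENTIONTIME" in header else None,
                fragments=frags,
            ))
        header, frags, n_expected = {}, [], 0

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip()
                if key == "Num Peaks":
                    n_expected = int(value)
                else:
                    header[key.upper()] = value.strip()
            else:
                cols = line.split("\t")
                mz, inten = float(cols[0]), float(cols[1])
                annotation, diagnostic, minor = "", "none", False
                if len(cols) > 2:
                    meta = cols[2].strip().strip('"')
                    annotation, _, flags = meta.rpartition("|")
                    parts = flags.split(";")
                    diagnostic = parts[0] or "none"
                    minor = "minor" in parts[1:]
                frags.append(Fragment(mz, inten, annotation, diagnostic, minor))
    flush()
    return spectra
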