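"""The untargeted-to-targeted bridge: transition reference libraries.

Each annotation candidate becomes one reference entry whose quantifier is a
chain-diagnostic product ion *unique among co-candidates sharing the same
SWATH window* — uniqueness is exactly what lets the targeted stage resolve
co-eluted isomers that share a precursor.  Class-diagnostic ions ride along
as qualifiers (serialized "Q", checked for presence, not ratio); remaining
products carry their library abundance rescaled so the quantifier reads 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .annotate import AnnotationCandidate
from .lipids import Fragment, ReferenceSpectrum
from .msdata import WindowGrid


@dataclass(frozen=True)
class Product:
    product_mz: float
    role: str  # "quantifier" | "qualifier" | "ratio"
    ratio: Optional[float] = None  # 0-100; None for qualifiers

    def serialized_ratio(self) -> str:
        if self.role == "qualifier":
            return "Q"
        if self.role == "quantifier":
            return "100"
        return f"{self.ratio:.1f}"


@dataclass
class TransitionEntry:
    """One reference row: name, RT, precursor, ordered product list."""

    name: str
    rt: float
    precursor_mz: float
    products: List[Product]
    unique_quantifier: bool = True

    def __post_init__(self) -> None:
        n_quant = sum(1 for p in self.products if p.role == "quantifier")
        if n_quant != 1:
            raise ValueError(
                f"entry {self.name!r} needs exactly one quantifier, "
                f"has {n_quant}")

    @property
    def quantifier(self) -> Product:
        return next(p for p in self.products if p.role == "quantifier")

    @property
    def qualifiers(self) -> List[Product]:
        return [p for p in self.products if p.role == "qualifier"]


def _is_unique(frag: Fragment, others: Sequence[ReferenceSpectrum],
               min_sep: float) -> bool:
    for other in others:
        for f in other.fragments:
            if abs(f.mz - frag.mz) < min_sep:
                return False
    return True


def build_transitions(
    candidates: Sequence[AnnotationCandidate],
    ms2_tol: float = 0.025,
    window_grid: Optional[WindowGrid] = None,
) -> List[TransitionEntry]:
    """Build one transition entry per annotation candidate.

    The quantifier is the most intense chain-diagnostic fragment whose m/z
    is at least 2 x ms2_tol away from every fragment of every co-candidate
    in the same SWATH window (ties: lowest m/z, which favors the SN1 ion for
    the common shorter-chain-first compositions).  Candidates without any
    unique chain fragment fall back to their most intense fragment, with a
    warning.
    """
    grid = window_grid or WindowGrid()
    min_sep = 2 * ms2_tol

    def window_key(c: AnnotationCandidate):
        try:
            return grid.window_for(c.spectrum.precursor_mz)
        except ValueError:
            return None

    entries: List[TransitionEntry] = []
    for cand in candidates:
        spec = cand.spectrum
        wkey = window_key(cand)
        others = [c.spectrum for c in candidates
                  if c is not cand and window_key(c) == wkey
                  and c.spectrum.name != spec.name]
        unique_chain = [f for f in spec.chain_fragments
                        if _is_unique(f, others, min_sep)]
        unique = True
        if unique_chain:
            quant = max(unique_chain,
                        key=lambda f: (f.relative_abundance, -f.mz))
        else:
            unique = False
            quant = max(spec.fragments,
                        key=lambda f: (f.relative_abundance, -f.mz))
            warnings.warn(
                f"{spec.name}: no chain fragment unique among co-candidates; "
                f"quantifier falls back to the most intense fragment "
                f"(m/z {quant.mz:.4f})")
        products: List[Product] = [
            Product(product_mz=quant.mz, role="quantifier", ratio=100.0)]
        for f in spec.fragments:
            if f is quant:
                continue
            if f.diagnostic == "class":
                products.append(Product(product_mz=f.mz, role="qualifier"))
            else:
                products.append(Product(
                    product_mz=f.mz, role="ratio",
                    ratio=100.0 * f.relative_abundance
                    / quant.relative_abundance))
        entries.append(TransitionEntry(
            name=spec.name,
            rt=cand.feature.apex_rt,
            precursor_mz=spec.precursor_mz,
            products=products,
            unique_quantifier=unique,
        ))
    return entries


# ---------------------------------------------------------------------------
# Tab-separated reference format: name, rt_min, precursor_mz, product_mz,
# ratio-or-Q.  RT to 2 decimals, m/z to 4 (fixed dialect for reproducibility).

_HEADER = "name\trt_min\tprecursor_mz\tproduct_mz\tratio"


def write_reference(entries: Sequence[TransitionEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for e in entries:
            for p in e.products:
                fh.write(f"{e.name}\t{e.rt:.2f}\t{e.precursor_mz:.4f}\t"
                         f"{p.product_mz:.4f}\t{p.serialized_ratio()}\n")


def read_reference(path) -> List[TransitionEntry]:
    entries: List[TransitionEntry] = []
    current_key: Optional[Tuple[str, str, str]] = None
    products: List[Product] = []

    def flush():
        nonlocal products, current_key
        if current_key is not None:
            name, rt, prec = current_key
            entries.append(TransitionEntry(
                name=name, rt=float(rt), precursor_mz=float(prec),
                products=products))
        products = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if lineno == 1:
                if line != _HEADER:
                    raise ValueError(
                        f"line 1: unexpected header {line!r}")
                continue
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ValueError(
                    f"line {lineno}: expected 5 tab-separated columns, "
                    f"got {len(cols)}")
            name, rt, prec, prod, ratio = cols
            try:
                prec_f, prod_f = float(prec), float(prod)
                rt_f = float(rt)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad number") from exc
            if prec_f <= 0 or prod_f <= 0:
                raise ValueError(f"line {lineno}: non-positive m/z")
            key = (name, rt, prec)
            if key != current_key:
                flush()
                current_key = key
            if ratio == "Q":
                products.append(Product(prod_f, "qualifier"))
            elif ratio == "100":
                products.append(Product(prod_f, "quantifier", 100.0))
            else:
                try:
                    products.append(Product(prod_f, "ratio", float(ratio)))
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: bad ratio {ratio!r}") from exc
    flush()
    return entries
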