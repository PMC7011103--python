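"""Elemental-formula arithmetic and monoisotopic m/z computation.

Everything downstream — candidate enumeration, precursor/fragment matching,
transition lists — reduces to exact integer formula arithmetic plus a fixed
table of monoisotopic atomic masses. m/z values are computed for singly
charged negative ions without an electron-mass correction; that convention
reproduces the printed reference values for carboxylate-anion fragments
(e.g. 16:0 -> 255.232, 18:3-O -> 293.212) which a ~0.55 mDa electron term
would break at 3 decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "AcylChain",
    "AdductSpec",
    "FormulaError",
    "formula_combine",
    "monoisotopic_mass",
    "carboxylate_fragment_mz",
    "ppm_error",
    "round_mz",
    "PROTON",
    "WATER",
    "GLYCEROL",
    "ACETATE",
    "SERINE_HEAD_LOSS",
]


class FormulaError(ValueError):
    """Raised when formula arithmetic would produce a negative element count."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: element symbol -> non-negative count.

    Zero-count elements are dropped so equality is element-wise. Supports
    ``+``/``-`` (element-wise, subtraction errors on a negative count) and
    ``int * formula``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style string such as ``"C18H30O3"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            if not m.group(0):
                break
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return formula_combine(self, other, +1)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return formula_combine(self, other, -1)

    def __rmul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise FormulaError("multiplier must be non-negative")
        return ElementalFormula({el: k * n for el, n in self.counts.items()})

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def hill(self) -> str:
        """Hill notation: C, H, then remaining elements alphabetically."""
        parts = []
        for el in ("C", "H"):
            n = self[el]
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        for el, n in self.counts.items():
            if el in ("C", "H"):
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.hill()


def formula_combine(a: ElementalFormula, b: ElementalFormula, sign: int = +1) -> ElementalFormula:
    """Element-wise sum (sign=+1) or difference (sign=-1) of two formulas.

    Raises :class:`FormulaError` naming the offending element if a
    subtraction would go negative.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    counts = dict(a.counts)
    for el, n in b.counts.items():
        new = counts.get(el, 0) + sign * n
        if new < 0:
            raise FormulaError(
                f"removing {el}{n} from {a.hill() or 'empty'} leaves a negative {el} count"
            )
        counts[el] = new
    return ElementalFormula(counts)


@dataclass(frozen=True)
class IsotopeTable:
    """Monoisotopic atomic masses (Da) plus the 13C-12C spacing."""

    masses: Mapping[str, float]
    isotope_spacing: float = 1.0033548

    def __post_init__(self) -> None:
        required = {"C", "H", "N", "O", "P"}
        missing = required - set(self.masses)
        if missing:
            raise ValueError(f"isotope table missing elements: {sorted(missing)}")
        for el, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for {el}")
        object.__setattr__(self, "masses", dict(self.masses))


#: Standard IUPAC monoisotopic masses; reproduce the curated reference to 3 dp.
DEFAULT_ISOTOPES = IsotopeTable(
    masses={
        "C": 12.000000,
        "H": 1.00782503,
        "N": 14.00307401,
        "O": 15.99491462,
        "P": 30.97376151,
    },
    isotope_spacing=1.0033548,
)


def monoisotopic_mass(f: ElementalFormula, iso: IsotopeTable = DEFAULT_ISOTOPES) -> float:
    """Monoisotopic mass in Da: sum of count x atomic mass, no electron term."""
    total = 0.0
    for el, n in f:
        try:
            total += n * iso.masses[el]
        except KeyError:
            raise KeyError(f"element {el} not in isotope table") from None
    return total


PROTON = ElementalFormula({"H": 1})
WATER = ElementalFormula({"H": 2, "O": 1})
GLYCEROL = ElementalFormula.parse("C3H8O3")
ACETATE = ElementalFormula.parse("C2H3O2")
#: Neutral serine head fragment lost by PS on ionization (C3H5NO2, 87.032 Da).
SERINE_HEAD_LOSS = ElementalFormula.parse("C3H5NO2")


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty acyl chain: carbons, double bonds, and extra oxygens.

    ``extra_oxygens`` counts oxygens beyond the two of the carboxyl group:
    0 for a normal chain, 1 for mono-oxygenated oxylipins (hydroxy/keto),
    2 for di-oxygenated ones (dihydroxy, hydroperoxy, ketol). The free-acid
    composition is C(n) H(2n-2d) O(2+x).
    """

    carbons: int
    double_bonds: int = 0
    extra_oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if self.double_bonds < 0 or 2 * self.double_bonds > self.carbons:
            raise ValueError(f"invalid double bond count {self.double_bonds} for C{self.carbons}")
        if not 0 <= self.extra_oxygens <= 2:
            raise ValueError("extra_oxygens must be 0, 1 or 2")

    @property
    def is_oxidized(self) -> bool:
        return self.extra_oxygens > 0

    def free_acid_formula(self) -> ElementalFormula:
        return ElementalFormula(
            {
                "C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": 2 + self.extra_oxygens,
            }
        )

    def label(self) -> str:
        """Shorthand such as ``18:3-O`` or ``18:2-2O``."""
        base = f"{self.carbons}:{self.double_bonds}"
        if self.extra_oxygens == 1:
            return base + "-O"
        if self.extra_oxygens == 2:
            return base + "-2O"
        return base

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        """Parse shorthand like ``16:0``, ``18:3-O``, ``18:2-2O``."""
        m = re.fullmatch(r"(\d+):(\d+)(?:-(\d?)O)?", text.strip())
        if m is None:
            raise ValueError(f"cannot parse acyl chain {text!r}")
        extra = 0
        if m.group(3) is not None:
            extra = int(m.group(3)) if m.group(3) else 1
        return cls(int(m.group(1)), int(m.group(2)), extra)


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged negative-mode adduct as a signed formula change.

    ``gains``/``losses`` are applied to the neutral molecule; charge is
    always -1 and no electron-mass correction is applied.
    """

    name: str
    gains: ElementalFormula = field(default_factory=ElementalFormula)
    losses: ElementalFormula = field(default_factory=ElementalFormula)
    charge: int = -1

    def __post_init__(self) -> None:
        if self.charge != -1:
            raise ValueError("only singly charged negative adducts are supported")

    def apply(self, neutral: ElementalFormula) -> ElementalFormula:
        return (neutral + self.gains) - self.losses

    def mz(self, neutral: ElementalFormula, iso: IsotopeTable = DEFAULT_ISOTOPES) -> float:
        return monoisotopic_mass(self.apply(neutral), iso)


def carboxylate_fragment_mz(chain: AcylChain, iso: IsotopeTable = DEFAULT_ISOTOPES) -> float:
    """m/z of the chain's carboxylate anion released by CID.

    The anion is the free acid minus one proton. Di-oxygenated chains (two
    extra oxygens) are detected after in-source/CID water loss, so their
    anion additionally loses H2O and collapses onto the anion of the chain
    with one more double bond and one fewer extra oxygen (e.g. 18:2-2O is
    seen as the 18:3-O anion, 18:3-2O as the 18:4-O anion).
    """
    frag = chain.free_acid_formula() - PROTON
    if chain.extra_oxygens == 2:
        frag = frag - WATER
    return monoisotopic_mass(frag, iso)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in ppm: (observed - theoretical)/theoretical x 1e6.

    Positive means the observed m/z is higher than theory.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def round_mz(value: float, ndigits: int = 3) -> float:
    """Round-half-up display rounding; matching always uses unrounded values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
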