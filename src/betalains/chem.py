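"""Elemental-formula arithmetic and monoisotopic mass / m/z computation.

All ions are treated as singly protonated positive ions ([M+H]+); the rest
of the package builds on the three primitives here: formula parsing,
monoisotopic mass summation, and signed ppm mass accuracy.
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ElementComposition",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "compose_add",
    "compose_subtract",
    "round_half_away",
]

#: Monoisotopic atomic masses in Da (most abundant isotope), CODATA/IUPAC
#: values at >=6 decimals.  Carbon-12 is exact by definition.
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
    "Na": 22.98976928,
    "K": 38.96370649,
}

#: Mass of a proton in Da (mass of H minus one electron mass).
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Raised for malformed or unparseable molecular formulas."""


# One element token: symbol, optional underscore-wrapped or plain count.
# Accepts both "C24H26N2O13" and the underscore-subscript dialect
# "C_24_H_26_N_2_O_13_" (counts of 1 may be implicit in either).
_TOKEN = re.compile(r"([A-Z][a-z]?)(?:_(\d+)_|(\d+))?")


@dataclass(frozen=True)
class ElementComposition:
    """Immutable element -> count map for a molecular formula.

    Supports ``+`` and ``-`` element-wise; subtraction raises
    :class:`FormulaError` if any count would go negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    def __hash__(self) -> int:
        return hash(tuple(self.counts.items()))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        return compose_add(self, other)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        return compose_subtract(self, other)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ElementComposition:
    """Parse a molecular formula in compact or underscore-subscript dialect.

    >>> parse_formula("C_24_H_26_N_2_O_13_").counts
    {'C': 24, 'H': 26, 'N': 2, 'O': 13}
    """
    if text is None:
        raise FormulaError("empty formula")
    stripped = re.sub(r"\s+", "", text)
    if not stripped:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if m is None:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol = m.group(1)
        if symbol not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        count = m.group(2) or m.group(3)
        counts[symbol] = counts.get(symbol, 0) + (int(count) if count else 1)
        pos = m.end()
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of a neutral composition (empty -> 0)."""
    counts = comp.counts if isinstance(comp, ElementComposition) else comp
    total = 0.0
    for el, n in counts.items():
        try:
            total += n * ATOMIC_MASSES[el]
        except KeyError:
            raise FormulaError(f"element {el!r} not in atomic mass table") from None
    return total


def protonated_mz(
    comp: ElementComposition | Mapping[str, int], decimals: int | None = 4
) -> float:
    """m/z of the singly protonated ion [M+H]+ of a neutral molecule.

    By convention theoretical m/z values are reported at 4 decimals; pass
    ``decimals=None`` for the unrounded value.
    """
    mz = monoisotopic_mass(comp) + PROTON_MASS
    return mz if decimals is None else round_half_away(mz, decimals)


def neutral_mass_from_mz(mz: float) -> float:
    """Neutral monoisotopic mass implied by an [M+H]+ m/z value."""
    return mz - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass accuracy in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def compose_add(a: ElementComposition, b: ElementComposition) -> ElementComposition:
    counts = dict(a.counts)
    for el, n in b.counts.items():
        counts[el] = counts.get(el, 0) + n
    return ElementComposition(counts)


def compose_subtract(a: ElementComposition, b: ElementComposition) -> ElementComposition:
    counts = dict(a.counts)
    for el, n in b.counts.items():
        remaining = counts.get(el, 0) - n
        if remaining < 0:
            raise FormulaError(f"subtraction underflow on element {el}: {a} - {b}")
        counts[el] = remaining
    return ElementComposition(counts)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used for reported values).

    Python's builtin round() is banker's rounding; reported m/z and ppm
    columns follow the half-away-from-zero convention instead.
    """
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
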