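"""Elemental compositions and monoisotopic masses.

Element masses and natural isotope abundances come from the NIST table
shipped with :mod:`pyteomics` (``pyteomics.mass.nist_mass``); carbon-12 is
exactly 12 Da by definition. The proton mass used for ionization arithmetic
is the hydrogen atom minus one electron.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from pyteomics import mass as _ptmass

#: Elements allowed in formula enumeration.
ENUMERATION_ELEMENTS = ("C", "H", "N", "O", "S", "Cl", "Br")
#: Additional elements accepted by descriptors and mass arithmetic.
EXTRA_ELEMENTS = ("F", "P", "I", "Na", "K")
#: Halogens counted in ring-and-double-bond arithmetic.
HALOGENS = ("F", "Cl", "Br", "I")

ELECTRON_MASS = _ptmass.nist_mass["e*"][0][0]
#: Mass of H+ in Da: the hydrogen atom less one electron.
PROTON_MASS = _ptmass.nist_mass["H"][1][0] - ELECTRON_MASS


def monoisotopic_element_mass(symbol: str) -> float:
    """Principal-isotope mass of one atom of *symbol* in Da."""
    try:
        return _ptmass.nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def isotope_distribution(symbol: str, min_abundance: float = 1e-9) -> list[tuple[float, float]]:
    """Natural isotopes of *symbol* as ``(mass_da, abundance)`` pairs.

    Only isotopes with non-negligible natural abundance are returned,
    sorted by mass ascending; abundances sum to ~1.
    """
    try:
        entries = _ptmass.nist_mass[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
    iso = [
        (m, ab)
        for key, (m, ab) in entries.items()
        if key != 0 and ab > min_abundance
    ]
    if not iso:  # monoisotopic entry only (e.g. synthetic tables)
        iso = [entries[0]]
    iso.sort(key=lambda p: p[0])
    return iso


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts of a neutral molecule.

    Counts are stored sparsely; absent elements count zero. Instances are
    immutable and hashable so they can key dictionaries and sets.
    """

    _counts: tuple[tuple[str, int], ...] = field(default=())

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = dict(counts or {})
        merged.update(kw)
        for sym, n in merged.items():
            monoisotopic_element_mass(sym)  # raises on unknown symbol
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
        object.__setattr__(
            self,
            "_counts",
            tuple(sorted((s, int(n)) for s, n in merged.items() if n > 0)),
        )

    # -- mapping-ish surface ------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return dict(self._counts).get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(s for s, _ in self._counts)

    def items(self) -> tuple[tuple[str, int], ...]:
        return self._counts

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- chemistry ----------------------------------------------------------
    def monoisotopic_mass(self) -> float:
        """Sum of count x principal-isotope mass, in Da."""
        return sum(n * monoisotopic_element_mass(s) for s, n in self._counts)

    def hill_formula(self) -> str:
        """Hill notation: C first, then H, then the rest alphabetically."""
        counts = self.counts
        parts: list[str] = []
        order = [s for s in ("C", "H") if s in counts]
        order += sorted(s for s in counts if s not in ("C", "H"))
        for s in order:
            n = counts[s]
            parts.append(s if n == 1 else f"{s}{n}")
        return "".join(parts)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a plain molecular formula like ``C8H10N4O2``."""
        if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
            raise ValueError(f"malformed molecular formula: {formula!r}")
        counts: dict[str, int] = {}
        for sym, digits in _FORMULA_TOKEN.findall(formula):
            if not sym:
                continue
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        return cls(counts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalComposition({self.hill_formula()!r})"


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic (principal-isotope) mass of *composition* in Da."""
    return composition.monoisotopic_mass()
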