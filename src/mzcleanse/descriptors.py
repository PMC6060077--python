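"""Elemental descriptors of assigned formulas.

For every feature that received a molecular formula, compute the atom
counts, the van-Krevelen-style atomic ratios X/C (X = H, N, O, S), the
double bond equivalents DBE = C + 1 + (N - X - H)/2 with X the halogen
count, and DBE - O. These place each feature in composition space
(saturation, oxygenation, heteroatom content) for downstream dissolved-
organic-matter interpretation. Values are reported as computed — negative
or half-integer DBE is not clamped here, since validity filtering already
happened at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import HALOGENS, ElementalComposition
from .formula_engine import rdbe
from .mode_merger import NeutralFeature


@dataclass(frozen=True)
class ElementalDescriptors:
    n_C: int
    n_H: int
    n_N: int
    n_O: int
    n_S: int
    n_halogen: int
    hc: float
    nc: float
    oc: float
    sc: float
    dbe: float
    dbe_minus_o: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_C": self.n_C, "n_H": self.n_H, "n_N": self.n_N, "n_O": self.n_O,
            "n_S": self.n_S, "n_halogen": self.n_halogen,
            "H/C": self.hc, "N/C": self.nc, "O/C": self.oc, "S/C": self.sc,
            "DBE": self.dbe, "DBE-O": self.dbe_minus_o,
        }


def compute_descriptors(composition: ElementalComposition) -> ElementalDescriptors:
    """Atom counts, X/C ratios, DBE and DBE-O of a neutral formula."""
    n_c = composition["C"]
    if n_c < 1:
        raise ValueError("descriptors require at least one carbon")
    dbe = rdbe(composition)
    return ElementalDescriptors(
        n_C=n_c,
        n_H=composition["H"],
        n_N=composition["N"],
        n_O=composition["O"],
        n_S=composition["S"],
        n_halogen=sum(composition[h] for h in HALOGENS),
        hc=composition["H"] / n_c,
        nc=composition["N"] / n_c,
        oc=composition["O"] / n_c,
        sc=composition["S"] / n_c,
        dbe=dbe,
        dbe_minus_o=dbe - composition["O"],
    )


def annotate_table(features: list[NeutralFeature]) -> list[NeutralFeature]:
    """Attach descriptors to every feature carrying a picked formula.

    Features without a formula pass through untouched; re-annotation is a
    no-op. Mutates and returns the same list for chaining.
    """
    for f in features:
        if f.formula is not None:
            f.descriptors = compute_descriptors(f.formula.composition)
    return features
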