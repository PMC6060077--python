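"""Shared test utilities: independent oracles and small table builders."""

from __future__ import annotations

import numpy as np

from mzcleanse.chem import monoisotopic_element_mass
from mzcleanse.feature_io import Feature, FeatureTable

ELEMENT_ORDER = ("C", "H", "N", "O", "S", "Cl", "Br")

REDUCED_RANGES = {
    "C": (1, 15), "H": (1, 25), "O": (0, 8), "N": (0, 4),
    "S": (0, 2), "Cl": (0, 2), "Br": (0, 1),
}


def brute_force_formulas(target_mass, tol_ppm, ranges):
    """Exhaustive vectorized enumeration over the full composition grid.

    Independent of the package's pruned search: materializes every count
    combination in the ranges, filters by mass window, then applies the
    ratio/RDBE rules element-wise with numpy. Returns a set of count
    tuples in C,H,N,O,S,Cl,Br order.
    """
    axes = [np.arange(ranges[e][0], ranges[e][1] + 1) for e in ELEMENT_ORDER]
    grid = np.stack(
        [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1
    ).astype(float)
    masses = grid @ np.array([monoisotopic_element_mass(e) for e in ELEMENT_ORDER])
    tol_da = target_mass * tol_ppm * 1e-6
    grid = grid[np.abs(masses - target_mass) <= tol_da]
    c, h, n, o, s, cl, br = grid.T
    rdbe = c + 1 + (n - cl - br - h) / 2.0
    keep = (
        (h / c < 3.2)
        & (o / c < 1.2)
        & (n / c < 1.3)
        & (s / c < 0.8)
        & (rdbe == np.round(rdbe))
        & (rdbe >= 0)
        & (rdbe <= 40)
    )
    return {tuple(int(x) for x in row) for row in grid[keep]}


def composition_key(comp):
    """Count tuple of a composition in the oracle's element order."""
    return tuple(comp[e] for e in ELEMENT_ORDER)


def make_feature(fid="F1", mz=300.0, rt=5.0, charge=1, heights=None, areas=None,
                 candidates=None, flags=None, samples=("S1", "S2", "S3"),
                 blanks=("B1", "B2", "B3")):
    names = list(samples) + list(blanks)
    h = (
        dict(zip(names, heights))
        if heights
        else {n: (1e5 if n in samples else 0.0) for n in names}
    )
    a = dict(zip(names, areas)) if areas else {n: 10 * v for n, v in h.items()}
    return Feature(feature_id=fid, mz=mz, rt=rt, charge=charge, heights=h, areas=a,
                   candidates=list(candidates or []), flags=set(flags or []))


def make_table(features, mode="PI", samples=("S1", "S2", "S3"), blanks=("B1", "B2", "B3")):
    return FeatureTable(
        mode=mode,
        features=list(features),
        sample_groups={"sample": list(samples), "blank": list(blanks)},
        blank_group="blank",
    )
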