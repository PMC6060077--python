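"""m/z <-> neutral-mass arithmetic for protonated/deprotonated ions.

Electrospray at the soft energies used for water screening yields almost
exclusively [M+zH]z+ in positive mode and [M-zH]z- in negative mode, so the
neutral monoisotopic mass follows from m/z, charge and mode by moving z
protons.
"""

from __future__ import annotations

from .chem import PROTON_MASS

MODES = ("PI", "NI")


def _check(mode: str, charge: int) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if charge not in (1, 2):
        raise ValueError(f"charge must be 1 or 2, got {charge!r}")


def neutral_mass(mz: float, charge: int, mode: str) -> float:
    """Neutral monoisotopic mass in Da for an [M+zH]z+ / [M-zH]z- ion."""
    _check(mode, charge)
    if mz <= PROTON_MASS:
        raise ValueError(f"m/z {mz} not above the proton mass")
    sign = -1.0 if mode == "PI" else 1.0
    m = charge * mz + sign * charge * PROTON_MASS
    if m <= 0:
        raise ValueError(f"non-positive neutral mass from mz={mz}, charge={charge}, mode={mode}")
    return m


def ionized_mz(neutral: float, charge: int, mode: str) -> float:
    """m/z of the [M+zH]z+ (PI) or [M-zH]z- (NI) ion of a neutral mass."""
    _check(mode, charge)
    sign = 1.0 if mode == "PI" else -1.0
    return (neutral + sign * charge * PROTON_MASS) / charge


def ppm_difference(value: float, reference: float) -> float:
    """Signed deviation of *value* from *reference* in parts per million."""
    return (value - reference) / reference * 1e6
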