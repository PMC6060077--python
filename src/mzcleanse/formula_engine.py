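"""Molecular-formula assignment for LC-HRMS features.

Given the neutral monoisotopic mass implied by a feature's m/z, charge and
ionization mode, this module enumerates every elemental composition over
C/H/N/O/S/Cl/Br that reproduces the mass within a ppm window and survives
chemical plausibility heuristics (element-ratio bounds and a 0-40 integer
ring-and-double-bond-equivalent range), scores each candidate against the
observed isotope pattern, and picks a single best formula.

F and P are deliberately excluded from enumeration: both are monoisotopic,
carry no isotope-pattern information, and admit too many spurious mass
matches in complex water samples.

The candidate serialization ``FormX IsoY MassZ`` (X = neutral formula in
Hill notation, Y = isotope-pattern score in [0, 1], Z = neutral monoisotopic
mass in Da) is the identity string embedded in feature-table exports.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import (
    HALOGENS,
    ElementalComposition,
    isotope_distribution,
    monoisotopic_element_mass,
    monoisotopic_mass,
)
from .ions import ionized_mz, neutral_mass as ion_neutral_mass, ppm_difference

#: Atomic count ranges used for formula prediction (inclusive bounds).
DEFAULT_RANGES: dict[str, tuple[int, int]] = {
    "C": (1, 80),
    "H": (1, 100),
    "O": (0, 20),
    "N": (0, 15),
    "S": (0, 4),
    "Cl": (0, 4),
    "Br": (0, 4),
}

#: Element-ratio upper bounds (strict) covering ~99.7% of registered small molecules.
MAX_HC = 3.2
MAX_OC = 1.2
MAX_NC = 1.3
MAX_SC = 0.8
RDBE_RANGE = (0.0, 40.0)

MASS_TOL_PPM = 5.0
MIN_ISO_SCORE = 0.60
#: No formula for doubly charged ions above this m/z, nor for neutral masses >= 1000 Da.
CHARGE2_MZ_LIMIT = 500.0
MAX_NEUTRAL_MASS = 1000.0


# ---------------------------------------------------------------------------
# candidate container


@dataclass(frozen=True)
class FormulaCandidate:
    """One formula hypothesis for a feature.

    ``neutral_mass`` is always the monoisotopic mass recomputed from the
    composition; ``ppm_error`` is the signed deviation of that mass from the
    feature-derived neutral mass (NaN when no feature context exists, e.g.
    after parsing a serialized candidate).
    """

    composition: ElementalComposition
    iso_score: float = 0.0
    ppm_error: float = math.nan
    neutral_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.iso_score <= 1.0:
            raise ValueError(f"iso_score must lie in [0, 1], got {self.iso_score}")
        object.__setattr__(self, "neutral_mass", monoisotopic_mass(self.composition))


@dataclass(frozen=True)
class IsotopePattern:
    """A centroided isotope pattern: (m/z, intensity) peaks sorted by m/z."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i <= 0 for _, i in pk):
            raise ValueError("isotope pattern intensities must be positive")
        object.__setattr__(self, "peaks", pk)

    def normalized(self) -> "IsotopePattern":
        """Scale intensities so the base (tallest) peak is 1."""
        top = max(i for _, i in self.peaks)
        return IsotopePattern(tuple((m, i / top) for m, i in self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# chemistry rules


def rdbe(composition: ElementalComposition) -> float:
    """Ring-and-double-bond equivalents: C + 1 + (N - halogens - H) / 2.

    May be half-integer; half-integer values flag compositions that cannot
    form a neutral even-electron molecule.
    """
    x = sum(composition[h] for h in HALOGENS)
    return composition["C"] + 1 + (composition["N"] - x - composition["H"]) / 2.0


def passes_constraints(
    composition: ElementalComposition,
    max_hc: float = MAX_HC,
    max_oc: float = MAX_OC,
    max_nc: float = MAX_NC,
    max_sc: float = MAX_SC,
    rdbe_range: tuple[float, float] = RDBE_RANGE,
) -> bool:
    """Element-ratio and RDBE plausibility test for a candidate composition.

    All ratio bounds are strict inequalities; RDBE must be integer-valued
    (even-electron neutral molecule) and inside ``rdbe_range`` inclusive.
    Requires at least one carbon.
    """
    n_c = composition["C"]
    if n_c < 1:
        raise ValueError("constraint test requires at least one carbon")
    if composition["H"] / n_c >= max_hc:
        return False
    if composition["O"] / n_c >= max_oc:
        return False
    if composition["N"] / n_c >= max_nc:
        return False
    if composition["S"] / n_c >= max_sc:
        return False
    r = rdbe(composition)
    if r != int(r):
        return False
    return rdbe_range[0] <= r <= rdbe_range[1]


# ---------------------------------------------------------------------------
# enumeration


def enumerate_formulas(
    target_mass: float,
    tol_ppm: float = MASS_TOL_PPM,
    ranges: Mapping[str, tuple[int, int]] | None = None,
) -> list[ElementalComposition]:
    """All constrained compositions within ``tol_ppm`` of a neutral mass.

    Loops run over the heavy elements (Br, Cl, S, O, N) with mass-based
    pruning, carbon next, and hydrogen solved directly from the residual
    mass — at 5 ppm the residual window admits at most one H count, which
    keeps the search linear in the heavy-element combinations actually
    feasible for the target mass.

    Results are sorted by absolute mass error ascending (ties by Hill
    formula) and every returned composition satisfies
    :func:`passes_constraints`.
    """
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    rng = dict(DEFAULT_RANGES)
    if ranges:
        rng.update({k: (int(lo), int(hi)) for k, (lo, hi) in ranges.items()})
    tol_da = target_mass * tol_ppm * 1e-6
    hi_mass = target_mass + tol_da
    lo_mass = target_mass - tol_da

    m = {s: monoisotopic_element_mass(s) for s in ("C", "H", "N", "O", "S", "Cl", "Br")}
    c_lo, c_hi = rng["C"]
    h_lo, h_hi = rng["H"]
    # minimum mass any completion must still add
    min_tail = c_lo * m["C"] + h_lo * m["H"]

    out: list[tuple[float, str, ElementalComposition]] = []
    for n_br in range(rng["Br"][0], rng["Br"][1] + 1):
        m_br = n_br * m["Br"]
        if m_br + min_tail > hi_mass:
            break
        for n_cl in range(rng["Cl"][0], rng["Cl"][1] + 1):
            m_cl = m_br + n_cl * m["Cl"]
            if m_cl + min_tail > hi_mass:
                break
            for n_s in range(rng["S"][0], rng["S"][1] + 1):
                m_s = m_cl + n_s * m["S"]
                if m_s + min_tail > hi_mass:
                    break
                for n_o in range(rng["O"][0], rng["O"][1] + 1):
                    m_o = m_s + n_o * m["O"]
                    if m_o + min_tail > hi_mass:
                        break
                    for n_n in range(rng["N"][0], rng["N"][1] + 1):
                        m_n = m_o + n_n * m["N"]
                        if m_n + min_tail > hi_mass:
                            break
                        for n_c in range(c_lo, c_hi + 1):
                            m_c = m_n + n_c * m["C"]
                            if m_c + h_lo * m["H"] > hi_mass:
                                break
                            # hydrogen count solved from the residual mass
                            res_lo = lo_mass - m_c
                            res_hi = hi_mass - m_c
                            first_h = max(h_lo, math.ceil(res_lo / m["H"] - 1e-12))
                            last_h = min(h_hi, math.floor(res_hi / m["H"] + 1e-12))
                            for n_h in range(first_h, last_h + 1):
                                total = m_c + n_h * m["H"]
                                if not (lo_mass <= total <= hi_mass):
                                    continue
                                comp = ElementalComposition(
                                    C=n_c, H=n_h, N=n_n, O=n_o, S=n_s, Cl=n_cl, Br=n_br
                                )
                                if passes_constraints(comp):
                                    out.append(
                                        (abs(total - target_mass), comp.hill_formula(), comp)
                                    )
    out.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in out]


# ---------------------------------------------------------------------------
# isotope patterns


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]],
              floor: float) -> dict[int, tuple[float, float]]:
    # distributions map nucleon shift -> (probability, mean mass offset)
    out: dict[int, tuple[float, float]] = {}
    for s1, (p1, m1) in a.items():
        for s2, (p2, m2) in b.items():
            p = p1 * p2
            if p < floor:
                continue
            s = s1 + s2
            if s in out:
                p0, m0 = out[s]
                out[s] = (p0 + p, (p0 * m0 + p * (m1 + m2)) / (p0 + p))
            else:
                out[s] = (p, m1 + m2)
    return out


def theoretical_isotope_pattern(
    composition: ElementalComposition,
    charge: int = 1,
    mode: str = "PI",
    prune_rel: float = 1e-4,
) -> IsotopePattern:
    """Isotopologue-resolution isotope pattern of an ion of *composition*.

    Per-element isotope distributions are convolved (exponentiation by
    squaring over atom counts), aggregating isotopologues that share a
    nucleon count into one abundance-weighted centroid — the resolution at
    which an Orbitrap-type instrument reports patterns. Peaks are converted
    to m/z space for the protonated (PI) or deprotonated (NI) ion at the
    given charge, pruned below ``prune_rel`` of the base peak, and
    normalized to base peak 1.
    """
    floor = prune_rel * 1e-4
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for symbol, count in composition.items():
        iso = isotope_distribution(symbol)
        principal = iso[0][0] if len(iso) == 1 else min(iso, key=lambda p: -p[1])[0]
        # offsets are relative to the principal (most abundant) isotope
        atom = {
            int(round(mass_da - principal)): (ab, mass_da - principal)
            for mass_da, ab in iso
        }
        # exponentiation by squaring over the atom count
        acc: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
        base = atom
        n = count
        while n:
            if n & 1:
                acc = _convolve(acc, base, floor)
            n >>= 1
            if n:
                base = _convolve(base, base, floor)
        dist = _convolve(dist, acc, floor)

    mono = monoisotopic_mass(composition)
    top = max(p for p, _ in dist.values())
    peaks = []
    for shift, (p, moff) in sorted(dist.items()):
        if p < prune_rel * top:
            continue
        peaks.append((ionized_mz(mono + moff, charge, mode), p / top))
    return IsotopePattern(tuple(peaks))


def isotope_score(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    tol_ppm: float = MASS_TOL_PPM,
    min_intensity: float = 0.0,
) -> float:
    """L1 similarity of two isotope patterns on [0, 1].

    Both patterns are normalized to base peak 1, peaks are paired greedily
    by smallest ppm gap within ``tol_ppm`` (each peak used once), and the
    score is ``1 - sum(|dI| over pairs + I over unpaired) / (sum I_obs +
    sum I_theo)``: identical patterns score 1, disjoint patterns 0.
    Observed peaks below ``min_intensity`` (raw units, pre-normalization)
    are ignored as instrument noise.
    """
    obs_peaks = [(m, i) for m, i in observed.peaks if i >= min_intensity]
    if not obs_peaks:
        raise ValueError("observed pattern has no peaks above min_intensity")
    obs = IsotopePattern(tuple(obs_peaks)).normalized().peaks
    theo = theoretical.normalized().peaks

    pairs = []
    for i, (mo, _) in enumerate(obs):
        for j, (mt, _) in enumerate(theo):
            gap = abs(ppm_difference(mo, mt))
            if gap <= tol_ppm:
                pairs.append((gap, min(mo, mt), i, j))
    pairs.sort()
    used_o: set[int] = set()
    used_t: set[int] = set()
    mismatch = 0.0
    for _, _, i, j in pairs:
        if i in used_o or j in used_t:
            continue
        used_o.add(i)
        used_t.add(j)
        mismatch += abs(obs[i][1] - theo[j][1])
    mismatch += sum(inten for k, (_, inten) in enumerate(obs) if k not in used_o)
    mismatch += sum(inten for k, (_, inten) in enumerate(theo) if k not in used_t)
    total = sum(i for _, i in obs) + sum(i for _, i in theo)
    return max(0.0, 1.0 - mismatch / total)


# ---------------------------------------------------------------------------
# prediction and picking


def predict_candidates(
    feature,
    mode: str,
    observed_pattern: IsotopePattern | None = None,
    min_score: float = MIN_ISO_SCORE,
    tol_ppm: float = MASS_TOL_PPM,
    ranges: Mapping[str, tuple[int, int]] | None = None,
) -> list[FormulaCandidate]:
    """Formula candidates for a feature, scored and ranked.

    Returns an empty list for doubly charged ions above 500 m/z and for
    neutral masses of 1000 Da or more, where assignment is unreliable.
    When an observed pattern is available each candidate's theoretical
    pattern is scored against it and candidates below ``min_score`` are
    dropped; without a pattern every candidate keeps score 0 and is
    retained. Ordering: score descending, then |ppm error|, then Hill
    formula.
    """
    if feature.charge == 2 and feature.mz > CHARGE2_MZ_LIMIT:
        return []
    target = ion_neutral_mass(feature.mz, feature.charge, mode)
    if target >= MAX_NEUTRAL_MASS:
        return []
    cands = []
    for comp in enumerate_formulas(target, tol_ppm=tol_ppm, ranges=ranges):
        score = 0.0
        if observed_pattern is not None:
            theo = theoretical_isotope_pattern(comp, feature.charge, mode)
            score = isotope_score(observed_pattern, theo, tol_ppm=tol_ppm)
            if score < min_score:
                continue
        cands.append(
            FormulaCandidate(
                comp,
                iso_score=score,
                ppm_error=ppm_difference(monoisotopic_mass(comp), target),
            )
        )
    cands.sort(
        key=lambda c: (-c.iso_score, abs(c.ppm_error), c.composition.hill_formula())
    )
    return cands


def pick_best_candidate(
    candidates: Sequence[FormulaCandidate],
    max_score_deviation: float = 0.10,
    max_runner_up_ppm: float = 1.0,
    runner_up_relative_ppm: bool = False,
) -> FormulaCandidate | None:
    """Select one formula from score-ranked candidates.

    The top-scoring candidate wins unless the runner-up is nearly as good
    on the isotope pattern (relative score deviation below
    ``max_score_deviation``) AND clearly better on mass accuracy — by
    default its own |ppm error| below ``max_runner_up_ppm``; with
    ``runner_up_relative_ppm`` the |difference| of the two ppm errors is
    compared instead — in which case the runner-up wins.
    """
    if not candidates:
        return None
    first = candidates[0]
    if len(candidates) == 1:
        return first
    second = candidates[1]
    if first.iso_score > 0:
        deviation = (first.iso_score - second.iso_score) / first.iso_score
        ppm = (
            abs(second.ppm_error - first.ppm_error)
            if runner_up_relative_ppm
            else abs(second.ppm_error)
        )
        if deviation < max_score_deviation and ppm < max_runner_up_ppm:
            return second
    return first


# ---------------------------------------------------------------------------
# serialization

_CANDIDATE_RE = re.compile(
    r"^Form(?P<formula>[A-Za-z0-9]+)\s+Iso(?P<iso>\d+(?:\.\d+)?)\s+Mass(?P<mass>\d+(?:\.\d+)?)$"
)


def format_candidate(candidate: FormulaCandidate) -> str:
    """Serialize as ``Form<Hill formula> Iso<score> Mass<Da>``."""
    return (
        f"Form{candidate.composition.hill_formula()}"
        f" Iso{candidate.iso_score:.2f}"
        f" Mass{candidate.neutral_mass:.4f}"
    )


def parse_candidate(s: str) -> FormulaCandidate:
    """Inverse of :func:`format_candidate`.

    The printed mass is checked against the mass recomputed from the
    formula (within print precision); the candidate's ``neutral_mass`` is
    always the recomputed value.
    """
    m = _CANDIDATE_RE.match(s.strip())
    if not m:
        raise ValueError(f"not a 'FormX IsoY MassZ' candidate string: {s!r}")
    comp = ElementalComposition.from_formula(m.group("formula"))
    iso = float(m.group("iso"))
    printed_mass = float(m.group("mass"))
    cand = FormulaCandidate(comp, iso_score=iso)
    if abs(cand.neutral_mass - printed_mass) > 5e-4:
        raise ValueError(
            f"printed mass {printed_mass} disagrees with formula mass "
            f"{cand.neutral_mass:.4f} for {s!r}"
        )
    return cand
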