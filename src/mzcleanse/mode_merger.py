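"""Neutral-mass conversion and positive/negative-mode merging.

Both ionization modes of the same chromatographic method observe the same
neutral molecules, so after cleanup the two feature tables are expressed on
the neutral-mass scale and cross-mode duplicates — pairs agreeing within
5 ppm in neutral mass and 0.5 min in retention time — collapse to a single
record. The positive-mode feature is kept as the representative; per-mode
intensities are preserved in distinct, mode-prefixed columns (never
summed), and the negative-mode partner's identity is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .feature_io import Feature, FeatureTable
from .formula_engine import FormulaCandidate, format_candidate, parse_candidate
from .ions import neutral_mass

MERGE_MZ_TOL_PPM = 5.0
MERGE_RT_TOL_MIN = 0.5


@dataclass
class NeutralFeature:
    """A feature on the neutral-mass scale, possibly merged across modes."""

    feature_id: str
    neutral_mass: float
    rt: float
    charge: int
    source_mode: str
    merged_from: list[str]
    heights: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)
    formula: FormulaCandidate | None = None
    flags: set[str] = field(default_factory=set)
    descriptors: "object | None" = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        if not self.merged_from:
            raise ValueError("merged_from must name at least the source feature")


def _picked_formula(f: Feature) -> FormulaCandidate | None:
    # convention: the first identity string is the picked candidate
    if not f.candidates:
        return None
    try:
        return parse_candidate(f.candidates[0])
    except ValueError:
        return None


def _to_neutral(f: Feature, mode: str) -> NeutralFeature:
    return NeutralFeature(
        feature_id=f.feature_id,
        neutral_mass=neutral_mass(f.mz, f.charge, mode),
        rt=f.rt,
        charge=f.charge,
        source_mode=mode,
        merged_from=[f.feature_id],
        heights={f"{mode}:{s}": v for s, v in f.heights.items()},
        areas={f"{mode}:{s}": v for s, v in f.areas.items()},
        formula=_picked_formula(f),
        flags=set(f.flags),
    )


def merge_modes(
    pi: FeatureTable,
    ni: FeatureTable,
    mz_tol_ppm: float = MERGE_MZ_TOL_PPM,
    rt_tol_min: float = MERGE_RT_TOL_MIN,
) -> list[NeutralFeature]:
    """Unite cleaned PI and NI tables on the neutral-mass scale.

    Each NI feature merges into at most one PI feature: candidates within
    both tolerances (ppm measured against the PI neutral mass) are ranked
    by mass gap, then retention-time gap. Where both partners carry a
    picked formula and the formulas differ, the higher isotope score wins
    and the record is flagged ``formula_conflict``. Unmatched features of
    either mode pass through unchanged.
    """
    if pi.mode != "PI" or ni.mode != "NI":
        raise ValueError("merge_modes expects (PI table, NI table)")
    out = [_to_neutral(f, "PI") for f in pi.features]
    ni_neutral = [_to_neutral(f, "NI") for f in ni.features]

    for nf in ni_neutral:
        best = None
        best_key = None
        for pf in out:
            if pf.source_mode != "PI":
                continue
            dppm = abs(nf.neutral_mass - pf.neutral_mass) / pf.neutral_mass * 1e6
            drt = abs(nf.rt - pf.rt)
            if dppm < mz_tol_ppm and drt < rt_tol_min:
                key = (dppm, drt)
                if best_key is None or key < best_key:
                    best, best_key = pf, key
        if best is None:
            out.append(nf)
            continue
        best.merged_from.append(nf.feature_id)
        best.heights.update(nf.heights)
        best.areas.update(nf.areas)
        best.flags |= {"merged_pi_ni"}
        if nf.formula is not None:
            if best.formula is None:
                best.formula = nf.formula
            elif nf.formula.composition != best.formula.composition:
                best.flags.add("formula_conflict")
                if nf.formula.iso_score > best.formula.iso_score:
                    best.formula = nf.formula
    return out


def write_neutral_table(features: list[NeutralFeature], path: str | Path) -> None:
    """Write the combined table with neutral mass, modes and descriptors."""
    sample_cols = sorted({s for f in features for s in f.heights})
    rows = []
    for f in features:
        row: dict[str, object] = {
            "feature_id": f.feature_id,
            "neutral_mass": repr(f.neutral_mass),
            "rt": f.rt,
            "charge": f.charge,
            "source_mode": f.source_mode,
            "merged_from": ";".join(f.merged_from),
            "formula": format_candidate(f.formula) if f.formula else "",
            "flags": ";".join(sorted(f.flags)),
        }
        for s in sample_cols:
            row[f"{s} Peak height"] = f.heights.get(s, 0.0)
            row[f"{s} Peak area"] = f.areas.get(s, 0.0)
        if f.descriptors is not None:
            row.update(f.descriptors.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
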