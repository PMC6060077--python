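"""The feature-table cleanup cascade.

Order of the default cascade: internal-standard removal, square-peak
(extraction artifact) removal, replicate-CV filtering, blank-ratio
correction, adduct removal. Filters only change table membership,
intensities and provenance flags — never m/z or retention time — and each
is idempotent. Every removal can be recorded in an audit list with the
stage and the triggering value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .chem import ElementalComposition
from .feature_io import Feature, FeatureTable
from .mass_correction import IS_FLAG

SQUARE_RATIO_MAX = 30.0
CV_MAX = 0.30
BLANK_RATIO_MIN = 3.0
BLANK_CV_MAX = 0.30
ADDUCT_RT_TOL_MIN = 0.03
ADDUCT_MZ_TOL_PPM = 5.0
ADDUCT_HEIGHT_FRAC = 0.5

AuditList = list[dict[str, object]]


def _audit(audit: AuditList | None, feature: Feature, stage: str, value: object) -> None:
    if audit is not None:
        audit.append({"feature_id": feature.feature_id, "stage": stage, "value": value})


def write_audit_log(audit: AuditList, path: str | Path) -> None:
    pd.DataFrame(audit, columns=["feature_id", "stage", "value"]).to_csv(path, index=False)


def replicate_cv(values: Iterable[float]) -> float:
    """Coefficient of variation with the sample (n-1) standard deviation.

    0 when all replicates are zero; +inf when the mean is zero but the
    spread is not.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if mean == 0:
        return 0.0 if sd == 0 else math.inf
    return sd / mean


# ---------------------------------------------------------------------------
# stage 1: internal standards


def remove_internal_standards(table: FeatureTable, audit: AuditList | None = None) -> FeatureTable:
    """Drop features flagged as matched internal standards."""
    out = table.copy()
    kept = []
    for f in out.features:
        if IS_FLAG in f.flags:
            _audit(audit, f, "internal_standard", IS_FLAG)
        else:
            kept.append(f)
    out.features = kept
    return out


# ---------------------------------------------------------------------------
# stage 2: square peaks


def filter_square_peaks(
    table: FeatureTable, max_ratio: float = SQUARE_RATIO_MAX, audit: AuditList | None = None
) -> FeatureTable:
    """Remove peak-extraction artifacts with area/height ratio above 30.

    The ratio is the per-sample maximum over samples with nonzero height
    (conservative reading); features with zero height everywhere carry no
    evidence and are kept.
    """
    out = table.copy()
    kept = []
    for f in out.features:
        ratios = [f.areas[s] / f.heights[s] for s in f.heights if f.heights[s] > 0]
        worst = max(ratios) if ratios else None
        if worst is not None and worst > max_ratio:
            _audit(audit, f, "square_peak", worst)
        else:
            kept.append(f)
    out.features = kept
    return out


# ---------------------------------------------------------------------------
# stage 3: replicate CV


def filter_by_cv(
    table: FeatureTable,
    max_cv: float = CV_MAX,
    use: str = "heights",
    audit: AuditList | None = None,
) -> FeatureTable:
    """Null replicate groups whose CV exceeds 30%; drop features left empty.

    CV is computed per non-blank replicate group on heights by default
    (areas configurable). A failing group has all its intensities zeroed;
    a feature survives while at least one non-blank group retains signal.
    """
    if use not in ("heights", "areas"):
        raise ValueError("use must be 'heights' or 'areas'")
    out = table.copy()
    kept = []
    for f in out.features:
        surviving = 0
        for group in out.non_blank_groups:
            names = out.sample_groups[group]
            if len(names) < 2:
                raise ValueError(f"group {group!r} has <2 replicates; CV undefined")
            values = [getattr(f, use)[s] for s in names]
            cv = replicate_cv(values)
            if cv > max_cv:
                for s in names:
                    f.heights[s] = 0.0
                    f.areas[s] = 0.0
                _audit(audit, f, "high_cv", cv)
            elif any(v > 0 for v in values):
                surviving += 1
        if surviving:
            kept.append(f)
        else:
            _audit(audit, f, "cv_removed", None)
    out.features = kept
    return out


# ---------------------------------------------------------------------------
# stage 4: blank correction


def blank_correct(
    table: FeatureTable,
    min_ratio: float = BLANK_RATIO_MIN,
    blank_cv_max: float = BLANK_CV_MAX,
    audit: AuditList | None = None,
) -> FeatureTable:
    """Remove blank-dominated signal and subtract blank background.

    Per feature and non-blank group, with r = mean(group area) / mean(blank
    area): groups with r below 3 are considered background and nulled;
    groups with r of 3 or more are reduced by the blank mean (heights and
    areas in parallel, floored at 0) when the blank replicates are
    consistent (blank CV under 30%), else kept uncorrected. A zero blank
    mean leaves a detected group untouched. Features with no group left
    carrying signal are removed. Re-application is a no-op: corrected
    groups are tagged ``blank_corrected:<group>`` and skipped.
    """
    out = table.copy()
    blanks = out.sample_groups[out.blank_group]
    kept = []
    for f in out.features:
        blank_area_mean = float(np.mean([f.areas[s] for s in blanks]))
        blank_height_mean = float(np.mean([f.heights[s] for s in blanks]))
        blank_cv = replicate_cv([f.areas[s] for s in blanks]) if len(blanks) >= 2 else 0.0
        surviving = 0
        for group in out.non_blank_groups:
            names = out.sample_groups[group]
            group_mean = float(np.mean([f.areas[s] for s in names]))
            if group_mean == 0:
                continue
            if f"blank_corrected:{group}" in f.flags:
                surviving += 1
                continue
            ratio = math.inf if blank_area_mean == 0 else group_mean / blank_area_mean
            if ratio < min_ratio:
                for s in names:
                    f.heights[s] = 0.0
                    f.areas[s] = 0.0
                _audit(audit, f, "blank_dominated", ratio)
                continue
            if blank_area_mean > 0 and blank_cv < blank_cv_max:
                for s in names:
                    f.areas[s] = max(0.0, f.areas[s] - blank_area_mean)
                    f.heights[s] = max(0.0, f.heights[s] - blank_height_mean)
                f.flags.add("blank_corrected")
                f.flags.add(f"blank_corrected:{group}")
            if any(f.areas[s] > 0 for s in names):
                surviving += 1
        if surviving:
            kept.append(f)
        else:
            _audit(audit, f, "blank_removed", None)
    out.features = kept
    return out


# ---------------------------------------------------------------------------
# stage 5: adducts


@dataclass(frozen=True)
class AdductRule:
    """m/z offset of an adduct ion relative to the primary ion at equal charge."""

    label: str
    delta_mz: float
    charge: int = 1


def _mass(formula: str) -> float:
    return ElementalComposition.from_formula(formula).monoisotopic_mass()


def default_adduct_rules(mode: str) -> list[AdductRule]:
    """The electrospray adducts searched in each ionization mode.

    Deltas are composed from the element mass table relative to the
    prevalent ion ([M+H]+ in PI, [M-H]- in NI); electron masses cancel at
    equal charge. The two doubly charged sodium/potassium adducts pair
    against the charge-2 primary ion [M+2H]2+, where the per-charge offset
    equals the singly charged one.
    """
    na_h = _mass("Na") - _mass("H")
    k_h = _mass("K") - _mass("H")
    if mode == "PI":
        return [
            AdductRule("[M+NH4]+", _mass("NH3"), 1),
            AdductRule("[M+Na]+", na_h, 1),
            AdductRule("[M+2Na]2+", na_h, 2),
            AdductRule("[M+K]+", k_h, 1),
            AdductRule("[M+2K]2+", k_h, 2),
            AdductRule("[M+CH3OH]+", _mass("CH4O"), 1),
        ]
    if mode == "NI":
        return [
            AdductRule("[M-H2O-H]-", -_mass("H2O"), 1),
            AdductRule("[M-2(H2O)-H]-", -2 * _mass("H2O"), 1),
            AdductRule("[M-2H+K]-", k_h, 1),
            AdductRule("[M-2H+Na]-", na_h, 1),
            AdductRule("[M+Cl]-", _mass("HCl"), 1),
            AdductRule("[M-H+HAc]-", _mass("C2H4O2"), 1),
            AdductRule("[M+Br]-", _mass("HBr"), 1),
            AdductRule("[M-H+FA]-", _mass("CH2O2"), 1),
        ]
    raise ValueError(f"mode must be 'PI' or 'NI', got {mode!r}")


def remove_adducts(
    table: FeatureTable,
    rules: list[AdductRule] | None = None,
    rt_tol_min: float = ADDUCT_RT_TOL_MIN,
    mz_tol_ppm: float = ADDUCT_MZ_TOL_PPM,
    max_height_frac: float = ADDUCT_HEIGHT_FRAC,
    audit: AuditList | None = None,
) -> FeatureTable:
    """Remove co-eluting adduct ions of stronger primary features.

    Feature B is removed when some feature A at the same charge as the rule
    co-elutes within ``rt_tol_min``, B's m/z sits within ``mz_tol_ppm`` of
    A's m/z plus the rule delta, and B's tallest peak is at most
    ``max_height_frac`` of A's.
    """
    if rules is None:
        rules = default_adduct_rules(table.mode)
    out = table.copy()
    kept = []
    for b in out.features:
        b_height = max(b.heights.values(), default=0.0)
        parent = None
        label = None
        for rule in rules:
            if b.charge != rule.charge:
                continue
            for a in out.features:
                if a is b or a.charge != rule.charge:
                    continue
                if abs(a.rt - b.rt) > rt_tol_min:
                    continue
                expected = a.mz + rule.delta_mz
                if abs(b.mz - expected) / b.mz * 1e6 > mz_tol_ppm:
                    continue
                a_height = max(a.heights.values(), default=0.0)
                if a_height <= 0 or b_height > max_height_frac * a_height:
                    continue
                parent, label = a, rule.label
                break
            if parent is not None:
                break
        if parent is not None:
            b.flags.add(f"adduct_of:{parent.feature_id}")
            _audit(audit, b, "adduct", f"{label} of {parent.feature_id}")
        else:
            kept.append(b)
    out.features = kept
    return out


# ---------------------------------------------------------------------------
# cascade


def run_cleanup(
    table: FeatureTable,
    square_ratio_max: float = SQUARE_RATIO_MAX,
    cv_max: float = CV_MAX,
    blank_ratio_min: float = BLANK_RATIO_MIN,
    blank_cv_max: float = BLANK_CV_MAX,
    adduct_rules: list[AdductRule] | None = None,
    adduct_rt_tol_min: float = ADDUCT_RT_TOL_MIN,
    adduct_mz_tol_ppm: float = ADDUCT_MZ_TOL_PPM,
    adduct_height_frac: float = ADDUCT_HEIGHT_FRAC,
    audit: AuditList | None = None,
) -> tuple[FeatureTable, list[dict[str, object]]]:
    """Apply the full default cascade; returns the table and per-stage counts."""
    stages = [
        ("internal_standards", lambda t: remove_internal_standards(t, audit=audit)),
        ("square_peaks", lambda t: filter_square_peaks(t, square_ratio_max, audit=audit)),
        ("cv", lambda t: filter_by_cv(t, cv_max, audit=audit)),
        ("blank", lambda t: blank_correct(t, blank_ratio_min, blank_cv_max, audit=audit)),
        (
            "adducts",
            lambda t: remove_adducts(
                t, adduct_rules, adduct_rt_tol_min, adduct_mz_tol_ppm,
                adduct_height_frac, audit=audit,
            ),
        ),
    ]
    report = []
    for name, fn in stages:
        n_in = len(table)
        table = fn(table)
        report.append({"stage": name, "features_in": n_in, "removed": n_in - len(table),
                       "features_out": len(table)})
    return table, report
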