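"""Internal-standard-based linear m/z recalibration.

Orbitrap mass accuracy drifts slowly and approximately linearly in m/z
within a run. Spiked internal standards (IS) of known mass anchor the drift:
after matching IS to features, the Da-scale mass error is regressed on
observed m/z separately below and above 400 Da, gross outliers beyond a
4x-interquartile-range fence are discarded first, and a range's model is
only applied when at least 3 IS remain to define it. The fitted error is
then subtracted from every feature m/z in the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_io import FeatureTable, InternalStandard
from .ions import ppm_difference

MZ_TOL_PPM = 5.0
RT_TOL_MIN = 0.3
SPLIT_DA = 400.0
OUTLIER_IQR_MULT = 4.0
MIN_IS = 3

IS_FLAG = "is_internal_standard"
CORRECTED_FLAG = "mz_corrected"


@dataclass(frozen=True)
class ISMatch:
    """An internal standard located in a feature table."""

    standard: InternalStandard
    feature_id: str
    mz_observed: float
    error_da: float
    error_ppm: float


@dataclass(frozen=True)
class CorrectionModel:
    """Linear mass-error model over one m/z range.

    The fitted error is ``intercept + slope * mz`` in Da; ``applied`` is
    False (and the range left uncorrected) when fewer than 3 IS defined
    the fit.
    """

    range_low: float
    range_high: float
    slope: float = 0.0
    intercept: float = 0.0
    n_is_used: int = 0
    applied: bool = False

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")
        if self.applied and self.n_is_used < MIN_IS:
            raise ValueError(f"model applied with only {self.n_is_used} IS")

    def error_at(self, mz: float) -> float:
        return self.intercept + self.slope * mz

    def contains(self, mz: float) -> bool:
        return self.range_low <= mz < self.range_high


def match_internal_standards(
    table: FeatureTable,
    standards: list[InternalStandard],
    mz_tol_ppm: float = MZ_TOL_PPM,
    rt_tol_min: float = RT_TOL_MIN,
) -> list[ISMatch]:
    """Locate each IS in the table within m/z and retention-time tolerances.

    At most one feature matches each standard — the nearest in m/z among
    those inside both windows. Matched features are flagged
    ``is_internal_standard`` in place so the cleanup stage can drop them.
    """
    matches: list[ISMatch] = []
    for std in standards:
        best = None
        best_gap = None
        for f in table.features:
            if abs(f.rt - std.rt_expected) > rt_tol_min:
                continue
            ppm = ppm_difference(f.mz, std.mz_theoretical)
            if abs(ppm) > mz_tol_ppm:
                continue
            gap = abs(f.mz - std.mz_theoretical)
            if best_gap is None or gap < best_gap:
                best, best_gap = f, gap
        if best is not None:
            best.flags.add(IS_FLAG)
            matches.append(
                ISMatch(
                    standard=std,
                    feature_id=best.feature_id,
                    mz_observed=best.mz,
                    error_da=best.mz - std.mz_theoretical,
                    error_ppm=ppm_difference(best.mz, std.mz_theoretical),
                )
            )
    return matches


def _fence(errors: np.ndarray, mult: float) -> np.ndarray:
    """Boolean mask of values inside the Tukey-style IQR fence."""
    q1, q3 = np.percentile(errors, [25, 75])  # linear-interpolation quartiles
    iqr = q3 - q1
    return (errors >= q1 - mult * iqr) & (errors <= q3 + mult * iqr)


def fit_correction_models(
    matches: list[ISMatch],
    split_da: float = SPLIT_DA,
    outlier_iqr_mult: float = OUTLIER_IQR_MULT,
    min_is: int = MIN_IS,
) -> list[CorrectionModel]:
    """Fit the below-400 and above-400 Da linear error models.

    Within each range, IS whose Da error falls outside
    [Q1 - mult*IQR, Q3 + mult*IQR] are discarded in a single pass, then
    ordinary least squares of error on observed m/z defines the model if at
    least ``min_is`` IS remain; otherwise the range is marked not applied.
    """
    out: list[CorrectionModel] = []
    for lo, hi in ((0.0, split_da), (split_da, float("inf"))):
        in_range = [m for m in matches if lo <= m.mz_observed < hi]
        if in_range:
            err = np.array([m.error_da for m in in_range])
            keep = _fence(err, outlier_iqr_mult)
            in_range = [m for m, k in zip(in_range, keep) if k]
        if len(in_range) >= min_is:
            x = np.array([m.mz_observed for m in in_range])
            y = np.array([m.error_da for m in in_range])
            # center the regressor for numerical conditioning
            x0 = x.mean()
            slope, b0 = np.polyfit(x - x0, y, 1)
            intercept = b0 - slope * x0
            out.append(
                CorrectionModel(lo, hi, float(slope), float(intercept), len(in_range), True)
            )
        else:
            out.append(CorrectionModel(lo, hi, 0.0, 0.0, len(in_range), False))
    return out


def apply_correction(table: FeatureTable, models: list[CorrectionModel]) -> FeatureTable:
    """Subtract the fitted mass error from every feature m/z.

    Features in a range whose model was not applied (too few IS) keep their
    m/z. Corrected features are flagged ``mz_corrected``. Returns a new
    table; the input is untouched.
    """
    corrected = table.copy()
    for f in corrected.features:
        for model in models:
            if model.contains(f.mz):
                if model.applied:
                    f.mz = f.mz - model.error_at(f.mz)
                    f.flags.add(CORRECTED_FLAG)
                break
    return corrected
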