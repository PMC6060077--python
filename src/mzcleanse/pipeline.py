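"""End-to-end orchestration of the cleansing workflow.

Stage order: internal-standard matching, range-wise linear m/z correction,
formula prediction and best-candidate picking, the cleanup cascade
(IS removal, square peaks, replicate CV, blank correction, adducts),
positive/negative-mode merging on the neutral-mass scale, and elemental
descriptor annotation. Every threshold defaults to the workflow's
published value and is overridable; the run is fully deterministic for
fixed inputs and configuration.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cleanup_filters, mass_correction
from .feature_io import FeatureTable, InternalStandard, read_feature_table, read_is_list
from .formula_engine import (
    IsotopePattern,
    format_candidate,
    pick_best_candidate,
    predict_candidates,
)
from .mode_merger import NeutralFeature, merge_modes, write_neutral_table
from .descriptors import annotate_table
from .synthetic import read_patterns


@dataclass
class PipelineParams:
    """All tunable thresholds of the workflow (defaults = published values)."""

    is_mz_tol_ppm: float = 5.0        # IS database search: mass tolerance
    is_rt_tol_min: float = 0.3        # IS database search: rt tolerance
    correction_split_da: float = 400.0  # linear models over and under 400 Da
    correction_iqr_mult: float = 4.0  # IS outliers beyond 4x IQR discarded
    correction_min_is: int = 3        # omit correction below 3 IS
    prediction_tol_ppm: float = 5.0   # formula mass tolerance
    min_iso_score: float = 0.60       # minimum isotope match score
    square_ratio_max: float = 30.0    # area/height above 30 = extraction artifact
    cv_max: float = 0.30              # replicate CV ceiling
    blank_ratio_min: float = 3.0      # sample:blank ratio floor
    blank_cv_max: float = 0.30        # blank CV ceiling for subtraction
    adduct_rt_tol_min: float = 0.03   # adduct co-elution window
    adduct_mz_tol_ppm: float = 5.0
    adduct_height_frac: float = 0.5   # adduct at most 50% of primary height
    merge_mz_tol_ppm: float = 5.0     # cross-mode duplicate mass window
    merge_rt_tol_min: float = 0.5     # cross-mode duplicate rt window


@dataclass
class PipelineConfig:
    """File-level inputs and parameters of one run."""

    pi_table: str | None = None
    ni_table: str | None = None
    is_pi: str | None = None
    is_ni: str | None = None
    patterns: str | None = None
    sample_groups: dict[str, list[str]] = field(
        default_factory=lambda: {"sample": ["S1", "S2", "S3"], "blank": ["B1", "B2", "B3"]}
    )
    blank_group: str = "blank"
    output_dir: str = "mzcleanse_out"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> list[str]:
        problems = []
        if self.pi_table is None and self.ni_table is None:
            problems.append("config names neither a PI nor an NI feature table")
        for label in ("pi_table", "ni_table", "is_pi", "is_ni", "patterns"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                problems.append(f"{label}: file not found: {value}")
        if self.blank_group not in self.sample_groups:
            problems.append(f"blank_group {self.blank_group!r} not among sample_groups")
        return problems


def _log(report: list[dict], stage: str, n_in: int, n_out: int, t0: float) -> None:
    entry = {"stage": stage, "features_in": n_in, "removed": n_in - n_out,
             "features_out": n_out, "seconds": round(time.perf_counter() - t0, 3)}
    report.append(entry)
    print(
        f"[{entry['stage']}] in={n_in} removed={entry['removed']} out={n_out} "
        f"({entry['seconds']}s)",
        file=sys.stderr,
    )


def process_mode(
    table: FeatureTable,
    standards: list[InternalStandard],
    patterns: dict[str, IsotopePattern] | None = None,
    params: PipelineParams | None = None,
    audit: list | None = None,
    report: list | None = None,
) -> FeatureTable:
    """Correct, predict, pick and clean one ionization mode's table."""
    p = params or PipelineParams()
    report = report if report is not None else []
    mode = table.mode

    t0 = time.perf_counter()
    matches = mass_correction.match_internal_standards(
        table, standards, p.is_mz_tol_ppm, p.is_rt_tol_min)
    _log(report, f"{mode}:is_match", len(table), len(table), t0)

    t0 = time.perf_counter()
    models = mass_correction.fit_correction_models(
        matches, p.correction_split_da, p.correction_iqr_mult, p.correction_min_is)
    table = mass_correction.apply_correction(table, models)
    _log(report, f"{mode}:mz_correction", len(table), len(table), t0)

    t0 = time.perf_counter()
    for f in table.features:
        if mass_correction.IS_FLAG in f.flags:
            continue
        pattern = (patterns or {}).get(f.feature_id)
        cands = predict_candidates(
            f, mode, observed_pattern=pattern,
            min_score=p.min_iso_score, tol_ppm=p.prediction_tol_ppm)
        picked = pick_best_candidate(cands)
        if picked is not None:
            rest = [c for c in cands if c is not picked]
            f.candidates = [format_candidate(picked)] + [format_candidate(c) for c in rest]
        else:
            f.candidates = []
    _log(report, f"{mode}:formula_prediction", len(table), len(table), t0)

    t0 = time.perf_counter()
    table, stage_report = cleanup_filters.run_cleanup(
        table,
        square_ratio_max=p.square_ratio_max,
        cv_max=p.cv_max,
        blank_ratio_min=p.blank_ratio_min,
        blank_cv_max=p.blank_cv_max,
        adduct_rt_tol_min=p.adduct_rt_tol_min,
        adduct_mz_tol_ppm=p.adduct_mz_tol_ppm,
        adduct_height_frac=p.adduct_height_frac,
        audit=audit,
    )
    for entry in stage_report:
        report.append({**entry, "stage": f"{mode}:{entry['stage']}"})
    _log(report, f"{mode}:cleanup_total",
         stage_report[0]["features_in"], stage_report[-1]["features_out"], t0)
    return table


def run_tables(
    pi_table: FeatureTable | None,
    ni_table: FeatureTable | None,
    is_pi: list[InternalStandard] | None = None,
    is_ni: list[InternalStandard] | None = None,
    patterns: dict[tuple[str, str], IsotopePattern] | None = None,
    params: PipelineParams | None = None,
    audit: list | None = None,
) -> tuple[list[NeutralFeature], list[dict]]:
    """Run the full workflow on in-memory tables; returns (features, report)."""
    p = params or PipelineParams()
    report: list[dict] = []
    patterns = patterns or {}

    cleaned: dict[str, FeatureTable] = {}
    for table, standards in ((pi_table, is_pi), (ni_table, is_ni)):
        if table is None:
            continue
        mode_patterns = {fid: pat for (m, fid), pat in patterns.items() if m == table.mode}
        cleaned[table.mode] = process_mode(
            table.copy(), standards or [], mode_patterns, p, audit, report)

    t0 = time.perf_counter()
    if "PI" in cleaned and "NI" in cleaned:
        features = merge_modes(cleaned["PI"], cleaned["NI"],
                               p.merge_mz_tol_ppm, p.merge_rt_tol_min)
    else:
        only = next(iter(cleaned.values()))
        from .mode_merger import _to_neutral
        features = [_to_neutral(f, only.mode) for f in only.features]
    n_in = sum(len(t) for t in cleaned.values())
    _log(report, "merge", n_in, len(features), t0)

    t0 = time.perf_counter()
    annotate_table(features)
    _log(report, "descriptors", len(features), len(features), t0)
    return features, report


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: read inputs, run, write outputs and a report."""
    problems = config.validate()
    if problems:
        raise FileNotFoundError("; ".join(problems))
    p = config.params

    def load(path, mode):
        return (
            read_feature_table(path, mode, config.sample_groups, config.blank_group)
            if path else None
        )

    pi = load(config.pi_table, "PI")
    ni = load(config.ni_table, "NI")
    std_pi = read_is_list(config.is_pi) if config.is_pi else []
    std_ni = read_is_list(config.is_ni) if config.is_ni else []
    patterns = read_patterns(config.patterns) if config.patterns else {}

    audit: list = []
    features, report = run_tables(pi, ni, std_pi, std_ni, patterns, p, audit)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_neutral_table(features, out / "combined_features.csv")
    cleanup_filters.write_audit_log(audit, out / "audit_log.csv")
    run_report = {
        "stages": report,
        "n_output_features": len(features),
        "params": asdict(p),
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(run_report, fh, indent=2)
    return run_report
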