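"""Feature-table and internal-standard-list I/O.

The on-disk dialect mirrors an MZmine 2 CSV export: one row per aligned
feature with ``row ID``, ``row m/z``, ``row retention time``, ``row
charge``, a ``row identity (all IDs)`` column holding ";"-joined
``FormX IsoY MassZ`` candidate strings, and per-sample ``<sample> Peak
height`` / ``<sample> Peak area`` columns. A ``row flags`` column carries
provenance tags across write/read cycles; files without it read fine.
Empty intensity cells read as 0.0, matching how gap-filled absent peaks are
exported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

MZ_COL = "row m/z"
RT_COL = "row retention time"
ID_COL = "row ID"
CHARGE_COL = "row charge"
IDENTITY_COL = "row identity (all IDs)"
FLAGS_COL = "row flags"
HEIGHT_SUFFIX = " Peak height"
AREA_SUFFIX = " Peak area"
CANDIDATE_SEP = ";"


class FeatureTableFormatError(ValueError):
    """Raised when a CSV does not conform to the feature-table dialect."""


@dataclass
class Feature:
    """One aligned molecular feature."""

    feature_id: str
    mz: float
    rt: float
    charge: int = 1
    heights: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0, got {self.rt}")
        if self.charge not in (1, 2):
            raise ValueError(f"feature {self.feature_id}: charge must be 1 or 2, got {self.charge}")
        if set(self.heights) != set(self.areas):
            raise ValueError(
                f"feature {self.feature_id}: heights and areas must cover the same samples"
            )

    def copy(self) -> "Feature":
        return replace(
            self,
            heights=dict(self.heights),
            areas=dict(self.areas),
            candidates=list(self.candidates),
            flags=set(self.flags),
        )


@dataclass(frozen=True)
class InternalStandard:
    """A spiked compound of known m/z and retention time."""

    name: str
    mz_theoretical: float
    rt_expected: float

    def __post_init__(self) -> None:
        if not self.mz_theoretical > 0:
            raise ValueError(f"IS {self.name}: theoretical m/z must be positive")


@dataclass
class FeatureTable:
    """An ordered feature collection plus replicate-group metadata.

    ``sample_groups`` maps group names (e.g. "sample", "blank") to the
    replicate column names belonging to each; ``blank_group`` names the
    solvent-blank group within it.
    """

    mode: str
    features: list[Feature]
    sample_groups: dict[str, list[str]]
    blank_group: str

    def __post_init__(self) -> None:
        if self.mode not in ("PI", "NI"):
            raise ValueError(f"mode must be 'PI' or 'NI', got {self.mode!r}")
        if self.blank_group not in self.sample_groups:
            raise ValueError(f"blank group {self.blank_group!r} not among sample groups")
        seen: dict[str, str] = {}
        for group, names in self.sample_groups.items():
            for name in names:
                if name in seen:
                    raise ValueError(f"sample {name!r} assigned to both {seen[name]!r} and {group!r}")
                seen[name] = group
        for f in self.features:
            for name in f.heights:
                if name not in seen:
                    raise ValueError(
                        f"feature {f.feature_id} references sample {name!r} absent from groups"
                    )

    @property
    def sample_names(self) -> list[str]:
        return [n for names in self.sample_groups.values() for n in names]

    @property
    def non_blank_groups(self) -> list[str]:
        return [g for g in self.sample_groups if g != self.blank_group]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            mode=self.mode,
            features=[f.copy() for f in self.features],
            sample_groups={g: list(n) for g, n in self.sample_groups.items()},
            blank_group=self.blank_group,
        )

    def __len__(self) -> int:
        return len(self.features)


def tables_equal(a: FeatureTable, b: FeatureTable, mz_tol: float = 1e-6) -> bool:
    """Field-by-field equality with an m/z tolerance (for round-trip checks)."""
    if (a.mode, a.sample_groups, a.blank_group) != (b.mode, b.sample_groups, b.blank_group):
        return False
    if len(a) != len(b):
        return False
    for fa, fb in zip(a.features, b.features):
        if fa.feature_id != fb.feature_id or fa.charge != fb.charge:
            return False
        if abs(fa.mz - fb.mz) > mz_tol or not math.isclose(fa.rt, fb.rt, abs_tol=1e-9):
            return False
        if fa.candidates != fb.candidates or fa.flags != fb.flags:
            return False
        for key in set(fa.heights) | set(fb.heights):
            if not math.isclose(fa.heights.get(key, 0.0), fb.heights.get(key, 0.0),
                                rel_tol=1e-9, abs_tol=1e-9):
                return False
            if not math.isclose(fa.areas.get(key, 0.0), fb.areas.get(key, 0.0),
                                rel_tol=1e-9, abs_tol=1e-9):
                return False
    return True


# ---------------------------------------------------------------------------
# feature tables


def _cell_float(value, default: float = 0.0) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return default
    return float(value)


def read_feature_table(
    path: str | Path,
    mode: str,
    sample_groups: Mapping[str, Iterable[str]],
    blank_group: str,
) -> FeatureTable:
    """Read a feature-table CSV in the MZmine-export dialect.

    ``sample_groups``/``blank_group`` declare which intensity columns are
    sample replicates and which are the solvent blank; every intensity
    column present in the file must be covered.
    """
    df = pd.read_csv(path, dtype={IDENTITY_COL: str, FLAGS_COL: str, ID_COL: str})
    for col in (MZ_COL, RT_COL):
        if col not in df.columns:
            raise FeatureTableFormatError(f"{path}: missing required column {col!r}")
    samples = [c[: -len(HEIGHT_SUFFIX)] for c in df.columns if c.endswith(HEIGHT_SUFFIX)]

    features: list[Feature] = []
    for idx, row in df.iterrows():
        try:
            mz = float(row[MZ_COL])
            rt = float(row[RT_COL])
        except (TypeError, ValueError) as exc:
            raise FeatureTableFormatError(f"{path}: row {idx}: non-numeric m/z or rt") from exc
        charge = int(_cell_float(row.get(CHARGE_COL), 1.0))
        identity = row.get(IDENTITY_COL)
        candidates = (
            [c for c in str(identity).split(CANDIDATE_SEP) if c]
            if isinstance(identity, str) and identity
            else []
        )
        raw_flags = row.get(FLAGS_COL)
        flags = (
            {f for f in str(raw_flags).split(CANDIDATE_SEP) if f}
            if isinstance(raw_flags, str) and raw_flags
            else set()
        )
        heights = {s: _cell_float(row.get(f"{s}{HEIGHT_SUFFIX}")) for s in samples}
        areas = {s: _cell_float(row.get(f"{s}{AREA_SUFFIX}")) for s in samples}
        features.append(
            Feature(
                feature_id=str(row[ID_COL]) if ID_COL in df.columns else str(idx),
                mz=mz,
                rt=rt,
                charge=charge,
                heights=heights,
                areas=areas,
                candidates=candidates,
                flags=flags,
            )
        )
    return FeatureTable(
        mode=mode,
        features=features,
        sample_groups={g: list(n) for g, n in sample_groups.items()},
        blank_group=blank_group,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table in the same dialect ``read_feature_table`` accepts.

    m/z is serialized at full float precision (well beyond 6 significant
    digits) so write/read round-trips are lossless for practical purposes.
    """
    samples = table.sample_names
    rows = []
    for f in table.features:
        row: dict[str, object] = {
            ID_COL: f.feature_id,
            MZ_COL: repr(f.mz),
            RT_COL: repr(f.rt),
            CHARGE_COL: f.charge,
            IDENTITY_COL: CANDIDATE_SEP.join(f.candidates),
            FLAGS_COL: CANDIDATE_SEP.join(sorted(f.flags)),
        }
        for s in samples:
            row[f"{s}{HEIGHT_SUFFIX}"] = repr(f.heights.get(s, 0.0))
            row[f"{s}{AREA_SUFFIX}"] = repr(f.areas.get(s, 0.0))
        rows.append(row)
    columns = [ID_COL, MZ_COL, RT_COL, CHARGE_COL, IDENTITY_COL, FLAGS_COL]
    for s in samples:
        columns += [f"{s}{HEIGHT_SUFFIX}", f"{s}{AREA_SUFFIX}"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# internal-standard lists


def read_is_list(
    path: str | Path,
    header_map: Mapping[str, str] | None = None,
) -> list[InternalStandard]:
    """Read an internal-standard list CSV (columns ``name,mz,rt`` by default).

    ``header_map`` renames nonstandard headers, e.g. ``{"Compound": "name",
    "m/z": "mz", "RT (min)": "rt"}``, so supplementary lists with other
    conventions load without editing the file.
    """
    df = pd.read_csv(path)
    if header_map:
        df = df.rename(columns=dict(header_map))
    for col in ("name", "mz", "rt"):
        if col not in df.columns:
            raise FeatureTableFormatError(f"{path}: missing IS-list column {col!r}")
    out: list[InternalStandard] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        name = str(row["name"])
        if name in seen:
            raise FeatureTableFormatError(f"{path}: duplicate internal standard name {name!r}")
        seen.add(name)
        try:
            mz = float(row["mz"])
            rt = float(row["rt"])
        except (TypeError, ValueError) as exc:
            raise FeatureTableFormatError(f"{path}: row {idx}: non-numeric mz or rt") from exc
        if mz <= 0:
            raise FeatureTableFormatError(f"{path}: row {idx}: non-positive m/z {mz}")
        out.append(InternalStandard(name=name, mz_theoretical=mz, rt_expected=rt))
    return out


def write_is_list(standards: Iterable[InternalStandard], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": s.name, "mz": repr(s.mz_theoretical), "rt": repr(s.rt_expected)} for s in standards],
        columns=["name", "mz", "rt"],
    ).to_csv(path, index=False)
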