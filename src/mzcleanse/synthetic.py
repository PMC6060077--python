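"""Synthetic LC-HRMS feature tables with planted ground truth.

The generator emulates the study design every stage downstream expects:
triplicate filtered-water samples plus triplicate solvent blanks per
ionization mode, spiked internal standards spanning both calibration
ranges, a linear mass drift error(mz) = a + b*mz planted per range, and
configurable counts of features that violate exactly one cleanup rule
(square peaks, irreproducible replicates, blank-dominated signal,
co-eluting adducts) or duplicate across modes. Planted compositions come
from a fixed list of real small molecules (pharmaceuticals, pesticides,
natural products, halogenated contaminants) chosen to exercise the
element-ratio constraint space.

What it does not emulate: raw spectra, chromatographic peak shapes,
retention-time drift between runs, matrix/ion-suppression effects, and
isotope-pattern distortion at low abundance — observed patterns are the
exact theoretical patterns of the planted compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ElementalComposition
from .feature_io import (
    Feature,
    FeatureTable,
    InternalStandard,
    write_feature_table,
    write_is_list,
)
from .formula_engine import IsotopePattern, theoretical_isotope_pattern
from .ions import ionized_mz

# name -> neutral formula; all pass the prediction constraints and ranges
COMPOUND_LIBRARY: dict[str, str] = {
    "caffeine": "C8H10N4O2", "paracetamol": "C8H9NO2", "ibuprofen": "C13H18O2",
    "naproxen": "C14H14O3", "diclofenac": "C14H11Cl2NO2", "carbamazepine": "C15H12N2O",
    "sulfamethoxazole": "C10H11N3O3S", "trimethoprim": "C14H18N4O3",
    "atenolol": "C14H22N2O3", "metoprolol": "C15H25NO3", "propranolol": "C16H21NO2",
    "atrazine": "C8H14ClN5", "simazine": "C7H12ClN5", "diuron": "C9H10Cl2N2O",
    "glucose": "C6H12O6", "sucrose": "C12H22O11", "citric acid": "C6H8O7",
    "salicylic acid": "C7H6O3", "benzoic acid": "C7H6O2", "phenol": "C6H6O",
    "4-bromophenol": "C6H5BrO", "2,4,6-tribromophenol": "C6H3Br3O",
    "triclosan": "C12H7Cl3O2", "bisphenol A": "C15H16O2", "nicotine": "C10H14N2",
    "cotinine": "C10H12N2O", "theophylline": "C7H8N4O2", "gabapentin": "C9H17NO2",
    "venlafaxine": "C17H27NO2", "erythromycin": "C37H67NO13",
    "azithromycin": "C38H72N2O12", "amoxicillin": "C16H19N3O5S",
    "penicillin G": "C16H18N2O4S", "cephalexin": "C16H17N3O4S",
    "tetracycline": "C22H24N2O8", "oxytetracycline": "C22H24N2O9",
    "ketoprofen": "C16H14O3", "gemfibrozil": "C15H22O3",
    "clofibric acid": "C10H11ClO3", "bezafibrate": "C19H20ClNO4",
    "metformin": "C4H11N5", "ranitidine": "C13H22N4O3S", "cimetidine": "C10H16N6S",
    "omeprazole": "C17H19N3O3S", "diazepam": "C16H13ClN2O",
    "oxazepam": "C15H11ClN2O2", "lorazepam": "C15H10Cl2N2O2",
    "alprazolam": "C17H13ClN4", "codeine": "C18H21NO3", "morphine": "C17H19NO3",
    "tramadol": "C16H25NO2", "methamphetamine": "C10H15N", "MDMA": "C11H15NO2",
    "cocaine": "C17H21NO4", "benzoylecgonine": "C16H19NO4",
    "progesterone": "C21H30O2", "estrone": "C18H22O2", "estradiol": "C18H24O2",
    "ethinylestradiol": "C20H24O2", "testosterone": "C19H28O2",
    "cholesterol": "C27H46O", "DEET": "C12H17NO", "benzotriazole": "C6H5N3",
    "tolyltriazole": "C7H7N3", "dodecyl sulfate": "C12H26O4S",
    "nonylphenol": "C15H24O", "vanillin": "C8H8O3", "ferulic acid": "C10H10O4",
    "gallic acid": "C7H6O5", "fumaric acid": "C4H4O4", "succinic acid": "C4H6O4",
    "glutaric acid": "C5H8O4", "adipic acid": "C6H10O4", "lactic acid": "C3H6O3",
    "glycerol": "C3H8O3", "creatinine": "C4H7N3O", "uric acid": "C5H4N4O3",
    "adenine": "C5H5N5", "guanine": "C5H5N5O", "cytosine": "C4H5N3O",
    "thymine": "C5H6N2O2", "uracil": "C4H4N2O2", "adenosine": "C10H13N5O4",
    "riboflavin": "C17H20N4O6", "niacin": "C6H5NO2", "pyridoxine": "C8H11NO3",
    "ascorbic acid": "C6H8O6", "linoleic acid": "C18H32O2", "oleic acid": "C18H34O2",
    "palmitic acid": "C16H32O2", "lauric acid": "C12H24O2",
    "methionine": "C5H11NO2S", "cysteine": "C3H7NO2S", "tryptophan": "C11H12N2O2",
    "phenylalanine": "C9H11NO2", "tyrosine": "C9H11NO3", "leucine": "C6H13NO2",
    "histidine": "C6H9N3O2", "arginine": "C6H14N4O2", "lysine": "C6H14N2O2",
    "glutamine": "C5H10N2O3", "2,4-D": "C8H6Cl2O3", "MCPA": "C9H9ClO3",
    "2,4-dichlorophenol": "C6H4Cl2O", "4-chlorophenol": "C6H5ClO",
    "bromoform": "CHBr3", "musk ketone": "C14H18N2O5", "galaxolide": "C18H26O",
    "carbaryl": "C12H11NO2", "carbofuran": "C12H15NO3",
    "imidacloprid": "C9H10ClN5O2", "thiacloprid": "C10H9ClN4S",
    "metolachlor": "C15H22ClNO2", "alachlor": "C14H20ClNO2",
    "terbuthylazine": "C9H16ClN5", "irgarol": "C11H19N5S",
    "naphthalene": "C10H8", "phenanthrene": "C14H10", "pyrene": "C16H10",
    "benzo[a]pyrene": "C20H12", "hydroquinone": "C6H6O2",
}

# spiked standards, distinct from the library, >=3 per calibration range
IS_LIBRARY: dict[str, str] = {
    "acetanilide": "C8H9NO", "phenacetin": "C10H13NO2", "antipyrine": "C11H12N2O",
    "quinine": "C20H24N2O2", "strychnine": "C21H22N2O2", "yohimbine": "C21H26N2O3",
    "leucine-enkephalin": "C28H37N5O7", "reserpine": "C33H40N2O9",
    "digoxin": "C41H64O14", "rifampicin": "C43H58N4O12",
    "roxithromycin": "C41H76N2O15", "ivermectin": "C48H74O14",
}

SAMPLE_NAMES = ["S1", "S2", "S3"]
BLANK_NAMES = ["B1", "B2", "B3"]
GROUPS = {"sample": SAMPLE_NAMES, "blank": BLANK_NAMES}
BLANK_GROUP = "blank"


@dataclass(frozen=True)
class FixtureConfig:
    """Counts and conditions of one synthetic two-mode experiment.

    The drift pairs are (intercept a in Da, slope b in Da/Da) for the
    below- and above-400 Da calibration ranges; defaults sit at the
    sub-ppm to ~1 ppm scale typical of within-run Orbitrap drift.
    ``noise_cv`` is the lognormal replicate intensity CV and
    ``mz_noise_ppm`` the 1-sigma random mass error on top of the drift;
    both default to 0 so planted violations are exact.
    """

    n_clean_pi: int = 30
    n_clean_ni: int = 20
    n_charge2: int = 2
    n_square_peak: int = 3
    n_high_cv: int = 3
    n_blank_dominated: int = 3
    n_adducts: int = 3
    n_duplicate_pairs: int = 3
    n_nonduplicate_pairs: int = 2
    drift_low: tuple[float, float] = (1.2e-4, 3.0e-7)
    drift_high: tuple[float, float] = (-8.0e-5, 6.0e-7)
    noise_cv: float = 0.0
    mz_noise_ppm: float = 0.0
    intensity_range: tuple[float, float] = (1e5, 1e7)
    rt_range: tuple[float, float] = (0.5, 30.0)
    with_correction: bool = True


@dataclass
class PlantedFeature:
    feature_id: str
    mode: str
    formula: str | None
    neutral_mass: float | None
    charge: int
    rt: float
    labels: list[str] = field(default_factory=list)


@dataclass
class FixtureTruth:
    """Ground truth of one generated fixture."""

    planted: dict[str, PlantedFeature] = field(default_factory=dict)
    drift: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    patterns: dict[tuple[str, str], IsotopePattern] = field(default_factory=dict)

    def with_label(self, label: str, mode: str | None = None) -> list[str]:
        return [
            p.feature_id
            for p in self.planted.values()
            if (mode is None or p.mode == mode) and any(l.startswith(label) for l in p.labels)
        ]


@dataclass
class Fixture:
    pi_table: FeatureTable
    ni_table: FeatureTable
    is_pi: list[InternalStandard]
    is_ni: list[InternalStandard]
    truth: FixtureTruth


def _drift(mz: float, cfg: FixtureConfig, mode: str, truth: FixtureTruth) -> float:
    # planted error is linear in the *measured* m/z — error(obs) = a + b*obs —
    # so obs solves obs = mz + a + b*obs
    a, b = truth.drift[(mode, "low" if mz < 400 else "high")]
    return (mz + a) / (1.0 - b)


def _intensities(rng: np.random.Generator, base: float, cv: float, n: int = 3) -> list[float]:
    if cv <= 0:
        return [base] * n
    sigma = np.sqrt(np.log1p(cv * cv))  # lognormal with the requested CV
    return list(base * rng.lognormal(-sigma * sigma / 2, sigma, n))


class _Builder:
    def __init__(self, mode: str, cfg: FixtureConfig, rng: np.random.Generator,
                 truth: FixtureTruth):
        self.mode = mode
        self.cfg = cfg
        self.rng = rng
        self.truth = truth
        self.features: list[Feature] = []
        self._n = 0

    def _next_id(self) -> str:
        self._n += 1
        return f"{self.mode}-{self._n:04d}"

    def add(
        self,
        formula: str | None,
        charge: int = 1,
        rt: float | None = None,
        labels: list[str] | None = None,
        mz: float | None = None,
        base_intensity: float | None = None,
        heights: list[float] | None = None,
        areas: list[float] | None = None,
        blank_areas: list[float] | None = None,
        area_per_height: float = 10.0,
        with_pattern: bool = True,
        fid: str | None = None,
    ) -> Feature:
        cfg, rng = self.cfg, self.rng
        fid = fid or self._next_id()
        neutral = None
        if mz is None:
            comp = ElementalComposition.from_formula(formula)
            neutral = comp.monoisotopic_mass()
            mz = ionized_mz(neutral, charge, self.mode)
        exact_mz = mz
        obs_mz = _drift(mz, cfg, self.mode, self.truth)
        if cfg.mz_noise_ppm > 0:
            obs_mz += rng.normal(0, cfg.mz_noise_ppm * 1e-6 * mz)
        rt = float(rng.uniform(*cfg.rt_range)) if rt is None else rt
        if base_intensity is None:
            lo, hi = cfg.intensity_range
            base_intensity = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if heights is None:
            heights = _intensities(rng, base_intensity, cfg.noise_cv)
        if areas is None:
            areas = [h * area_per_height for h in heights]
        blank_areas = blank_areas if blank_areas is not None else [0.0, 0.0, 0.0]
        hmap = dict(zip(SAMPLE_NAMES, heights))
        amap = dict(zip(SAMPLE_NAMES, areas))
        for name, ba in zip(BLANK_NAMES, blank_areas):
            amap[name] = ba
            hmap[name] = ba / area_per_height
        f = Feature(feature_id=fid, mz=obs_mz, rt=rt, charge=charge,
                    heights=hmap, areas=amap)
        self.features.append(f)
        self.truth.planted[fid] = PlantedFeature(
            fid, self.mode, formula, neutral, charge, rt, list(labels or []))
        if formula is not None and with_pattern:
            comp = ElementalComposition.from_formula(formula)
            self.truth.patterns[(self.mode, fid)] = theoretical_isotope_pattern(
                comp, charge, self.mode)
        return f


def generate_fixture(config: FixtureConfig | None = None, seed: int = 0) -> Fixture:
    """Build one deterministic two-mode fixture with planted violations.

    Raises on infeasible configurations (e.g. drift correction requested
    with fewer than 3 IS available per range).
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    truth = FixtureTruth()
    for mode in ("PI", "NI"):
        truth.drift[(mode, "low")] = cfg.drift_low
        truth.drift[(mode, "high")] = cfg.drift_high

    names = list(COMPOUND_LIBRARY)
    rng.shuffle(names)
    # recycle if a config asks for more features than the library holds
    pool = iter([COMPOUND_LIBRARY[n] for n in names] * 10)

    is_pi: list[InternalStandard] = []
    is_ni: list[InternalStandard] = []
    builders = {m: _Builder(m, cfg, rng, truth) for m in ("PI", "NI")}

    # internal standards: exact theoretical m/z in the list, drifted in the table
    per_range = {"low": 0, "high": 0}
    for name, formula in IS_LIBRARY.items():
        comp = ElementalComposition.from_formula(formula)
        neutral = comp.monoisotopic_mass()
        rt = float(rng.uniform(*cfg.rt_range))
        for mode, is_list in (("PI", is_pi), ("NI", is_ni)):
            mz_theo = ionized_mz(neutral, 1, mode)
            is_list.append(InternalStandard(name=name, mz_theoretical=mz_theo, rt_expected=rt))
            builders[mode].add(formula, rt=rt, labels=["internal_standard"],
                               with_pattern=False)
        per_range["low" if ionized_mz(neutral, 1, "PI") < 400 else "high"] += 1
    if cfg.with_correction and min(per_range.values()) < 3:
        raise ValueError("drift-correction fixtures need >=3 IS per m/z range")

    # clean formula-bearing features
    for mode, n_clean in (("PI", cfg.n_clean_pi), ("NI", cfg.n_clean_ni)):
        b = builders[mode]
        for i in range(n_clean):
            charge = 2 if i < cfg.n_charge2 else 1
            b.add(next(pool), charge=charge, labels=["clean"])

    # planted cleanup violations (PI side; filters are mode-agnostic)
    b = builders["PI"]
    for _ in range(cfg.n_square_peak):
        base = 1e6
        b.add(next(pool), labels=["square_peak"], base_intensity=base,
              area_per_height=35.0)
    for _ in range(cfg.n_high_cv):
        b.add(next(pool), labels=["high_cv"], heights=[1e5, 1e6, 1.9e6])
    for _ in range(cfg.n_blank_dominated):
        b.add(next(pool), labels=["blank_dominated"], base_intensity=1e6,
              blank_areas=[4e6, 4e6, 4e6])  # sample area 1e7, ratio 2.5
    na_minus_h = (ElementalComposition(Na=1).monoisotopic_mass()
                  - ElementalComposition(H=1).monoisotopic_mass())
    for _ in range(cfg.n_adducts):
        parent = b.add(next(pool), labels=["adduct_parent"], base_intensity=5e6)
        # plant in exact-mass space so the drift model moves parent and adduct alike
        parent_exact = ionized_mz(
            ElementalComposition.from_formula(
                truth.planted[parent.feature_id].formula).monoisotopic_mass(), 1, "PI")
        b.add(None, mz=parent_exact + na_minus_h, rt=parent.rt,
              labels=[f"adduct_of:{parent.feature_id}"],
              heights=[v * 0.2 for v in [parent.heights[s] for s in SAMPLE_NAMES]])

    # cross-mode duplicates: same molecule seen in PI and NI at one rt
    for _ in range(cfg.n_duplicate_pairs):
        formula = next(pool)
        rt = float(rng.uniform(*cfg.rt_range))
        fp = builders["PI"].add(formula, rt=rt, labels=["pi_ni_duplicate"])
        builders["NI"].add(formula, rt=rt,
                           labels=[f"pi_ni_duplicate", f"duplicate_of:{fp.feature_id}"])
    for _ in range(cfg.n_nonduplicate_pairs):
        formula = next(pool)
        rt = float(rng.uniform(cfg.rt_range[0], cfg.rt_range[1] - 1.0))
        fp = builders["PI"].add(formula, rt=rt, labels=["non_duplicate"])
        builders["NI"].add(formula, rt=rt + 0.6, labels=["non_duplicate"])  # outside 0.5 min

    tables = {
        mode: FeatureTable(mode=mode, features=builders[mode].features,
                           sample_groups={g: list(n) for g, n in GROUPS.items()},
                           blank_group=BLANK_GROUP)
        for mode in ("PI", "NI")
    }
    return Fixture(tables["PI"], tables["NI"], is_pi, is_ni, truth)


# ---------------------------------------------------------------------------
# on-disk form


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture in the package's CSV dialects plus truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pi_table": out / "features_PI.csv",
        "ni_table": out / "features_NI.csv",
        "is_pi": out / "internal_standards_PI.csv",
        "is_ni": out / "internal_standards_NI.csv",
        "truth": out / "truth.csv",
        "patterns": out / "patterns.csv",
    }
    write_feature_table(fixture.pi_table, paths["pi_table"])
    write_feature_table(fixture.ni_table, paths["ni_table"])
    write_is_list(fixture.is_pi, paths["is_pi"])
    write_is_list(fixture.is_ni, paths["is_ni"])
    pd.DataFrame(
        [
            {
                "feature_id": p.feature_id, "mode": p.mode, "formula": p.formula or "",
                "neutral_mass": "" if p.neutral_mass is None else repr(p.neutral_mass),
                "charge": p.charge, "rt": p.rt, "labels": ";".join(p.labels),
            }
            for p in fixture.truth.planted.values()
        ]
    ).to_csv(paths["truth"], index=False)
    pd.DataFrame(
        [
            {"mode": mode, "feature_id": fid, "mz": repr(mz), "intensity": repr(inten)}
            for (mode, fid), pattern in fixture.truth.patterns.items()
            for mz, inten in pattern.peaks
        ]
    ).to_csv(paths["patterns"], index=False)
    return paths


def read_patterns(path: str | Path) -> dict[tuple[str, str], IsotopePattern]:
    """Read a patterns sidecar back into per-feature isotope patterns."""
    df = pd.read_csv(path)
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault((row.mode, str(row.feature_id)), []).append(
            (float(row.mz), float(row.intensity)))
    return {k: IsotopePattern(tuple(v)) for k, v in out.items()}
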