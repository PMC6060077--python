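# Methods

## Scope and data model

`mzcleanse` operates on aligned feature tables, not raw spectra. A
*feature* is one chromatographic peak aligned across injections: m/z,
retention time (minutes), charge (1 or 2), and per-sample heights and
areas (arbitrary units). A *feature table* adds replicate-group metadata —
which intensity columns are sample replicates and which are the solvent
blank — and an ionization mode (PI/NI, electrospray positive/negative).
Everything upstream (centroiding, chromatogram building, isotopologue
grouping, alignment, gap filling) is assumed done by peak-picking software;
everything downstream (ordination, trend analysis of DOM composition) is
out of scope.

Element masses and isotope abundances come from the NIST table bundled
with pyteomics; ¹²C is exactly 12 Da and the proton mass is the hydrogen
atom minus one electron (1.00727646 Da). Retention times are minutes
throughout.

## Mass recalibration

Model: the instrument's mass error in Da is approximately linear in m/z
within a run, with a possible regime change between low and high masses —
hence two independent models split at 400 Da (a value at 400 Da belongs to
the upper range). For the internal standards matched within 5 ppm and
0.3 min (nearest-in-m/z wins when several features qualify), the error
eᵢ = m/zᵢ(observed) − m/zᵢ(theoretical) is regressed on observed m/z by
OLS. Choices that the published description leaves open, fixed here:

- **Response unit.** The regression is on Da error, not ppm error; the
  correction is then a plain subtraction, m/z − (â + b̂·m/z), and Da-scale
  drift is how calibration error accumulates on Orbitrap-type analyzers.
- **Outlier fence.** "Outliers > 4× interquartile range" is read as a
  Tukey-style fence: errors outside [Q1 − 4·IQR, Q3 + 4·IQR] are dropped,
  quartiles by linear interpolation, in a single pass (no re-iteration).
  Note the fence is computed on raw errors, not fit residuals: when IS
  masses cluster, a legitimate IS far from the cluster can be trimmed even
  if it lies on the drift line. This is a property of the method, not a
  defect of the fit; the remaining IS still determine the line.
- **Omission rule.** A range with fewer than 3 surviving IS keeps its
  features uncorrected (model `applied=False`).
- The regressor is centered before the least-squares solve purely for
  numerical conditioning; the reported slope/intercept are in the original
  coordinates.

Properties guaranteed by construction and verified by tests: correction
never increases the IS RMS error (least squares), preserves m/z ordering
for |slope| < 1, and is idempotent on noise-free data.

## Formula assignment

The neutral mass of a feature is M = z·(m/z) − z·m_p in PI and
M = z·(m/z) + z·m_p in NI (m_p = proton mass), reflecting the prevalence of
[M+zH]z+ / [M−zH]z− under soft electrospray. No formula is attempted for
M ≥ 1000 Da or for z = 2 ions above 500 m/z, where false assignment rates
are high.

**Enumeration.** All compositions over C₁–₈₀ H₁–₁₀₀ O₀–₂₀ N₀–₁₅ S₀–₄
Cl₀–₄ Br₀–₄ with monoisotopic mass within ±5 ppm of M. The search loops
over the heavy elements with mass pruning and solves the hydrogen count
from the residual mass — at 5 ppm the residual window admits at most one H
value, so runtime scales with the feasible heavy-element combinations
(milliseconds below 400 Da, ~0.5 s near 950 Da). A vectorized exhaustive
grid enumeration serves as the independent oracle in the tests. F and P are
excluded: both are monoisotopic and contribute nothing to pattern-based
discrimination, inviting spurious matches.

**Plausibility rules.** Strict ratio bounds H/C < 3.2, O/C < 1.2,
N/C < 1.3, S/C < 0.8 (covering ~99.7% of registered small molecules),
plus RDBE = C + 1 + (N − X − H)/2 (X = halogen count) required to be
integer-valued — an even-electron neutral molecule — and within [0, 40].
No valence-graph (Senior) test is applied; the rule set is deliberately
the documented constraint set and nothing more. The same S/C bound is used
in both modes.

**Isotope patterns.** Theoretical patterns are computed by convolving
per-element isotope distributions (exponentiation by squaring over atom
counts), aggregating isotopologues per nucleon count into an
abundance-weighted centroid — the resolution at which Orbitrap-class
instruments report patterns — then converting to m/z at the ion's charge
and mode and pruning below 10⁻⁴ of the base peak. The score between an
observed and a theoretical pattern is an L1 similarity: both normalized to
base peak 1, peaks paired greedily by smallest ppm gap within 5 ppm, and

    score = 1 − (Σ|ΔI| over pairs + Σ I over unpaired) / (Σ I_obs + Σ I_theo).

It is symmetric, bounded in [0, 1], 1 exactly for peak-for-peak agreement
and 0 for disjoint patterns. This formula is this package's definition of
the published score's semantics (the original tool's formula is
unpublished); it is used self-consistently everywhere, and the
pattern-generation and scoring routes are cross-checked against an
independent combinatorial isotopologue expansion in the tests. Observed
peaks below a configurable absolute intensity are ignored as noise.
Candidates scoring below 0.60 are dropped when an observed pattern exists;
features without a pattern keep all candidates at score 0 (the pipeline
consumes patterns from a sidecar table, since pattern extraction from raw
spectra is upstream of this package).

**Picking.** Candidates are ranked by score, then |ppm error|, then Hill
formula (a deterministic tie-break). The top candidate is selected unless
the runner-up has (score₁ − score₂)/score₁ < 0.10 *and* |ppm error| < 1,
in which case the runner-up is preferred — mass accuracy overrides a
near-tie in pattern score. The published sentence admits a second reading
(|ppm₂ − ppm₁| < 1); it is available as `runner_up_relative_ppm=True`.
On exact-mass synthetic data this rule occasionally (≈1–2% of features)
prefers a wrong runner-up whose mass error happens to fall under 1 ppm;
that is faithful behavior of the algorithm, not an implementation error.

## Cleanup cascade

Default order: IS removal → square peaks → replicate CV → blank →
adducts. Filters change membership, intensities and provenance flags only
— never m/z or retention time — and each is idempotent.

- **Square peaks** (extraction artifacts): removed when the per-sample
  maximum area/height ratio over samples with nonzero height exceeds 30.
  The maximum is the conservative reading of an unaggregated "per-feature
  ratio"; features with zero height everywhere carry no evidence and are
  kept.
- **Replicate CV**: per non-blank triplicate group, CV = sd/mean with the
  sample (n−1) standard deviation (the R default the original workflow
  relied on), on heights by default (configurable to areas; the source
  description says only "intensity"). A group above 30% is zeroed; a
  feature with no group left carrying signal is removed. CV is 0 when all
  replicates are zero and +∞ when the mean is zero with nonzero spread.
- **Blank correction**: r = mean(group area)/mean(blank area); r < 3
  removes the group (background), r ≥ 3 subtracts the blank mean (heights
  and areas in parallel, floored at 0) when blank CV < 30%, else leaves
  intensities untouched. r = 3 exactly is kept; a zero blank mean means no
  background to subtract. Corrected groups are tagged so re-application is
  a no-op.
- **Adducts**: feature B is removed when a parent A at the rule's charge
  co-elutes within 0.03 min, B's m/z matches A's plus the rule delta within
  5 ppm, and B's tallest peak is at most 50% of A's. Deltas are composed
  from the element mass table, never hard-coded: PI [M+NH₄]⁺, [M+Na]⁺,
  [M+2Na]²⁺, [M+K]⁺, [M+2K]²⁺, [M+CH₃OH]⁺ relative to [M+H]⁺ (doubly
  charged rules pair charge-2 features against [M+2H]²⁺, where the
  per-charge offset equals the singly charged one); NI [M−H₂O−H]⁻,
  [M−2H₂O−H]⁻, [M−2H+K]⁻, [M−2H+Na]⁻, [M+Cl]⁻, [M−H+HAc]⁻ (acetate,
  +60.02113 Da), [M+Br]⁻, [M−H+FA]⁻ (formate, +46.00548 Da) relative to
  [M−H]⁻. Adduct intensity is *not* added to the parent.

No intensity normalization across spectra and no mathematical baseline
correction are performed; both were evaluated by the originating study and
rejected (normalization worsened replicate CV; baseline modeling risks
uncontrolled information loss).

## Mode merging and descriptors

Both chromatographic modes share the same method, so retention times are
comparable. After cleanup, each feature moves to the neutral-mass scale
and PI/NI pairs within 5 ppm (measured against the PI mass) and 0.5 min
merge greedily, nearest mass first, then nearest rt; each NI feature joins
at most one PI feature. The PI record is retained as representative,
per-mode intensities are kept in distinct mode-prefixed columns (never
summed), and when both partners carry formulas that disagree the higher
isotope score wins under a `formula_conflict` flag. Features with an
assigned formula receive atom counts, X/C ratios, DBE and DBE − O;
negative or half-integer values are reported as computed, since validity
filtering already happened at prediction.

## Synthetic data

The generator emulates the study conditions: triplicate filtered-water
samples plus triplicate blanks per mode; 12 spiked IS (real small
molecules distinct from the analyte library) giving ≥3 per calibration
range in both modes; a planted linear drift, by default (a, b) =
(1.2e-4 Da, 3e-7) below 400 Da and (−8e-5 Da, 6e-7) above — sub-ppm to
~1 ppm, typical within-run Orbitrap scale; analyte compositions drawn from
a fixed library of ~115 real small molecules (pharmaceuticals, drugs of
abuse, pesticides, natural products, surfactants, Cl/Br contaminants)
chosen to cover the constraint space up to the ratio bounds; retention
times uniform on [0.5, 30] min; intensities log-uniform on [1e5, 1e7] a.u.
with optional lognormal replicate noise (multiplicative, matching the use
of CV as the replicate statistic) and optional Gaussian m/z noise in ppm.
Violation features are planted to be *exactly* removable: area/height 35,
replicate heights (0.1, 1, 1.9)×10⁶ (CV 90%), sample:blank area ratio 2.5,
sodium adducts at 20% of the parent height; PI/NI duplicate pairs share a
molecule and rt, control pairs sit 0.6 min apart. The planted drift is a
linear function of the *measured* m/z, the same model family the
correction fits, which makes coefficient recovery well-posed.

Observed isotope patterns in fixtures are the exact theoretical patterns
of the planted compositions. Consequently, passing tests demonstrate the
correctness of the algorithms under the stated model — they do not
demonstrate robustness to pattern distortion at low abundance, matrix
effects, retention-time drift, or chimeric features, none of which the
generator simulates.

## Numerical choices and degenerate inputs

- Quartiles by linear interpolation (numpy default); OLS on a centered
  regressor.
- m/z serialized at full float precision; round-trips are lossless to
  < 1e-6 Da.
- Missing intensity cells read as 0 (absent gap-filled peaks).
- Empty candidate lists, empty IS lists, single-mode runs and empty tables
  are all valid inputs, not errors; a replicate group with fewer than two
  members makes CV undefined and raises.
- Candidate ties broken by Hill formula; all stages are deterministic, so
  identical inputs and configuration reproduce outputs byte-for-byte.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations for desk
hardware: 200 random target masses below 350 Da against the exhaustive
enumeration oracle under reduced ranges (C≤15, H≤25, O≤8, N≤4, S≤2, Cl≤2,
Br≤1); 20 replicate fixtures for the noisy-calibration median; and a
~500-feature two-mode fixture for end-to-end formula recovery. These run
in well under a minute each.

## Known limitations

- The isotope score is this package's own definition; absolute score
  values are not comparable to other software's "isotope similarity".
- The adduct search treats any qualifying feature as a potential parent;
  chained adduct relations (an adduct of an adduct) are removed relative
  to whichever parent matches first.
- Formula assignment beyond 500 Da is increasingly ambiguous at 5 ppm even
  with perfect patterns; the 1000 Da cutoff is a hard stop, not a
  confidence model.
- Real MZmine exports vary in column naming across versions; the reader
  covers the documented dialect plus a header map for IS lists, not every
  dialect in the wild.
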