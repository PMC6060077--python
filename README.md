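# mzcleanse

Cleansing of non-targeted LC-HRMS feature tables from environmental water
screening.

Non-targeted screening of dissolved organic matter (DOM) in wastewater by
liquid chromatography–high-resolution mass spectrometry produces feature
tables — thousands of aligned chromatographic peaks with m/z, retention
time, charge and per-sample intensities — that are contaminated by mass
drift, extraction artifacts, irreproducible signals, solvent background and
redundant adduct ions. `mzcleanse` turns such a table (one per electrospray
ionization mode) into a single annotated list of neutral molecular features
ready for compositional analysis. It is aimed at environmental and
analytical chemists working downstream of peak-picking software such as
MZmine 2, whose CSV export dialect it reads directly.

## What it does

1. **Mass recalibration.** Spiked internal standards (IS) are located
   within 5 ppm / 0.3 min. The Da-scale mass error is regressed on observed
   m/z by ordinary least squares separately below and above 400 Da, after
   discarding IS outside a Tukey fence of 4×IQR; a range is corrected only
   when ≥3 IS define its model: m/z ← m/z − (â + b̂·m/z).
2. **Molecular formula assignment.** For each feature's neutral mass
   M = z·(m/z) ∓ z·1.007276 (−: positive, +: negative mode, M < 1000 Da;
   no assignment for z = 2 ions above 500 m/z), all compositions over
   C₁–₈₀H₁–₁₀₀O₀–₂₀N₀–₁₅S₀–₄Cl₀–₄Br₀–₄ within ±5 ppm are enumerated,
   filtered by H/C < 3.2, O/C < 1.2, N/C < 1.3, S/C < 0.8 and an integer
   ring-and-double-bond equivalent in [0, 40], and scored in [0, 1] against
   the observed isotope pattern (L1 mismatch of base-peak-normalized
   patterns, peaks paired within 5 ppm; candidates below 0.60 are dropped).
   The top-scoring candidate is picked unless the runner-up lies within 10%
   of its score and under 1 ppm mass error, in which case the runner-up
   wins. Candidates serialize as `FormX IsoY MassZ`.
3. **Cleanup cascade.** IS removal → square-peak removal (area/height > 30)
   → replicate-CV filter (CV > 30% nulls a triplicate group) → blank
   correction (sample:blank area ratio < 3 removes; ≥ 3 with blank CV < 30%
   subtracts the blank mean) → adduct removal (co-elution within 0.03 min,
   5 ppm against the mode's adduct deltas, adduct height ≤ 50% of the
   primary ion).
4. **Mode merging and descriptors.** Both tables move to the neutral-mass
   scale; cross-mode duplicates within 5 ppm and 0.5 min collapse to one
   record. Assigned formulas gain atom counts, X/C ratios,
   DBE = C + 1 + (N − X − H)/2 (X = halogens) and DBE − O.

A deterministic synthetic-data generator (`mzcleanse.synthetic`) emulates
the study design — triplicate samples and blanks, IS with planted linear
drift, co-eluting adducts, cross-mode duplicates, features with known
compositions and exact isotope patterns — so the whole workflow is testable
without instrument data.

## Worked example

Generate a two-mode fixture and run the full workflow on it:

```sh
mzcleanse simulate --seed 3 --out-dir demo
cat > demo/config.yaml <<EOF
pi_table: demo/features_PI.csv
ni_table: demo/features_NI.csv
is_pi: demo/internal_standards_PI.csv
is_ni: demo/internal_standards_NI.csv
patterns: demo/patterns.csv
output_dir: demo/out
EOF
mzcleanse run demo/config.yaml
```

which logs one line per stage and finishes with the combined table:

```
[PI:is_match] in=62 removed=0 out=62 (0.0s)
[PI:mz_correction] in=62 removed=0 out=62 (0.001s)
[PI:formula_prediction] in=62 removed=0 out=62 (0.642s)
[PI:cleanup_total] in=62 removed=24 out=38 (0.003s)
[NI:is_match] in=37 removed=0 out=37 (0.0s)
[NI:mz_correction] in=37 removed=0 out=37 (0.001s)
[NI:formula_prediction] in=37 removed=0 out=37 (0.115s)
[NI:cleanup_total] in=37 removed=12 out=25 (0.002s)
[merge] in=63 removed=3 out=60 (0.001s)
[descriptors] in=60 removed=0 out=60 (0.0s)
wrote 60 features to demo/out
```

The 24 PI removals are the 12 spiked IS plus the planted square peaks,
high-CV features, blank-dominated features and sodium adducts; the merge
stage collapses the three planted PI/NI duplicate pairs (63 → 60). One
output row reads

```
PI-0013,228.11502975223993,22.445...,2,PI,PI-0013,FormC15H16O2 Iso1.00 Mass228.1150,mz_corrected,...,15,16,0,2,0,0,1.0666...,0.0,0.1333...,0.0,8.0,6.0
```

a doubly charged feature whose corrected neutral mass (228.11503 Da)
received the formula C15H16O2 with a perfect isotope-pattern score; the
trailing columns are its descriptors — 15 C, 16 H, 0 N, 2 O, 0 S,
0 halogens, H/C = 1.067, O/C = 0.133, DBE = 8, DBE − O = 6.

The same run is available as a library call
(`mzcleanse.run_tables(pi_table, ni_table, ...)`); see `docs/methods.md`
for the model details and parameter meanings.

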