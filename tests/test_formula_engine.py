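"""Formula enumeration, isotope patterns, scoring and candidate picking."""

import collections
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import REDUCED_RANGES, brute_force_formulas, composition_key, make_feature

from mzcleanse.chem import ElementalComposition, monoisotopic_mass
from mzcleanse.formula_engine import (
    FormulaCandidate,
    IsotopePattern,
    enumerate_formulas,
    format_candidate,
    isotope_score,
    parse_candidate,
    passes_constraints,
    pick_best_candidate,
    predict_candidates,
    rdbe,
    theoretical_isotope_pattern,
)
from mzcleanse.ions import ionized_mz


def comp(formula):
    return ElementalComposition.from_formula(formula)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula, expected, tol",
        [
            ("C", 12.0, 1e-12),          # carbon-12 defines the scale
            ("H2O", 18.010565, 1e-5),    # sum of NIST isotope masses
            ("C8H10N4O2", 194.080376, 1e-5),
        ],
    )
    def test_reference_masses(self, formula, expected, tol):
        assert monoisotopic_mass(comp(formula)) == pytest.approx(expected, abs=tol)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            ElementalComposition({"Xx": 1})


class TestRdbeAndConstraints:
    @pytest.mark.parametrize(
        "formula, expected",
        [("C6H6", 4), ("C2H3Cl", 1), ("CH4", 0), ("CHCl3", 0), ("C8H10N4O2", 6)],
    )
    def test_rdbe_closed_forms(self, formula, expected):
        assert rdbe(comp(formula)) == expected

    @pytest.mark.parametrize(
        "formula, ok",
        [
            ("C2H8", False),    # H/C = 4 >= 3.2
            ("C6H6O", True),
            ("CH2Cl", False),   # rdbe = 0.5, non-integer
            ("C2H6O3", False),  # O/C = 1.5 >= 1.2
            ("CH4N2", False),   # N/C = 2 >= 1.3
            ("C2H6S2", False),  # S/C = 1 >= 0.8
            ("C6H12O6", True),
        ],
    )
    def test_ratio_and_rdbe_rules(self, formula, ok):
        assert passes_constraints(comp(formula)) is ok


class TestEnumeration:
    def test_caffeine_mass_contains_caffeine(self):
        out = enumerate_formulas(194.080376)
        assert comp("C8H10N4O2") in out
        assert out[0] == comp("C8H10N4O2")  # smallest |mass error| first

    def test_infeasible_low_mass_is_empty(self):
        assert enumerate_formulas(5.0) == []

    def test_emitted_candidates_satisfy_contract(self):
        target = 327.078
        for c in enumerate_formulas(target):
            err_ppm = abs(monoisotopic_mass(c) - target) / target * 1e6
            assert err_ppm <= 5.0
            assert passes_constraints(c)

    def test_matches_brute_force_oracle_on_random_masses(self):
        rng = np.random.default_rng(42)
        for target in rng.uniform(60.0, 350.0, 25):
            got = {composition_key(c) for c in enumerate_formulas(target, 5.0, REDUCED_RANGES)}
            assert got == brute_force_formulas(target, 5.0, REDUCED_RANGES), target


class TestIsotopePattern:
    def test_single_carbon_ratio(self):
        pat = theoretical_isotope_pattern(comp("C"), 1, "PI")
        assert len(pat) == 2
        assert pat.peaks[1][1] / pat.peaks[0][1] == pytest.approx(0.0107, rel=0.02)

    def test_chlorine_a_plus_2(self):
        pat = theoretical_isotope_pattern(comp("CCl"), 1, "PI", prune_rel=1e-3)
        by_shift = {round(m - pat.peaks[0][0]): i for m, i in pat.peaks}
        assert by_shift[2] / by_shift[0] == pytest.approx(0.320, rel=0.01)

    def test_c10_first_order_binomial(self):
        pat = theoretical_isotope_pattern(comp("C10"), 1, "PI")
        assert pat.peaks[1][1] / pat.peaks[0][1] == pytest.approx(0.107, rel=0.02)

    def test_charge_and_mode_place_base_peak(self):
        c = comp("C8H10N4O2")
        m = monoisotopic_mass(c)
        for charge in (1, 2):
            for mode in ("PI", "NI"):
                pat = theoretical_isotope_pattern(c, charge, mode)
                base = max(pat.peaks, key=lambda p: p[1])[0]
                assert base == pytest.approx(ionized_mz(m, charge, mode), abs=1e-9)

    def test_agrees_with_pyteomics_isotopologue_expansion(self):
        # independent combinatorial expansion, aggregated per nucleon count
        from pyteomics import mass as ptmass

        for formula in ("C8H10N4O2", "C6H5BrO", "C10H11ClO3"):
            agg = collections.defaultdict(float)
            for iso, ab in ptmass.isotopologues(
                formula, report_abundance=True,
                overall_threshold=1e-9, isotope_threshold=1e-9,
            ):
                agg[round(ptmass.calculate_mass(composition=iso))] += ab
            base = max(agg.values())
            expected = sorted(v / base for v in agg.values() if v / base >= 1e-3)
            pat = theoretical_isotope_pattern(comp(formula), 1, "PI", prune_rel=1e-3)
            got = sorted(i for _, i in pat.peaks)
            assert got == pytest.approx(expected, rel=1e-3)


class TestIsotopeScore:
    def test_identical_patterns_score_one(self):
        pat = theoretical_isotope_pattern(comp("C10H11ClO3"), 1, "PI")
        assert isotope_score(pat, pat) == pytest.approx(1.0)

    def test_missing_a_plus_one_hand_value(self):
        observed = IsotopePattern(((200.0, 1.0),))
        theoretical = IsotopePattern(((200.0, 1.0), (201.0033, 0.1)))
        # mismatch = 0.1 unmatched; totals = 1 + 1.1
        assert isotope_score(observed, theoretical) == pytest.approx(1 - 0.1 / 2.1)

    def test_disjoint_patterns_score_zero(self):
        a = IsotopePattern(((200.0, 1.0),))
        b = IsotopePattern(((300.0, 1.0), (301.0, 0.3)))
        assert isotope_score(a, b) == 0.0

    def test_min_intensity_ignores_noise_peaks(self):
        observed = IsotopePattern(((200.0, 1e6), (201.0033, 1e5), (205.0, 50.0)))
        theoretical = IsotopePattern(((200.0, 1.0), (201.0033, 0.1)))
        assert isotope_score(observed, theoretical, min_intensity=600.0) == pytest.approx(1.0)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, data):
        def pattern(offset):
            n = data.draw(st.integers(1, 4))
            peaks = tuple(
                (offset + k * 1.0033, data.draw(st.floats(0.01, 1.0)))
                for k in range(n)
            )
            return IsotopePattern(peaks)

        a = pattern(data.draw(st.floats(100.0, 110.0)))
        b = pattern(data.draw(st.floats(100.0, 110.0)))
        s_ab = isotope_score(a, b)
        s_ba = isotope_score(b, a)
        assert 0.0 <= s_ab <= 1.0
        assert s_ab == pytest.approx(s_ba, abs=1e-12)


class TestPredictCandidates:
    def test_charge2_above_500_gets_no_formula(self):
        f = make_feature(mz=600.0, charge=2)
        assert predict_candidates(f, "PI") == []

    def test_neutral_mass_above_1000_gets_no_formula(self):
        f = make_feature(mz=1100.0, charge=1)
        assert predict_candidates(f, "PI") == []

    def test_caffeine_with_exact_pattern_ranks_first(self):
        c = comp("C8H10N4O2")
        mz = ionized_mz(monoisotopic_mass(c), 1, "PI")
        f = make_feature(mz=mz, charge=1)
        pattern = theoretical_isotope_pattern(c, 1, "PI")
        cands = predict_candidates(f, "PI", observed_pattern=pattern)
        assert cands and cands[0].composition == c
        assert cands[0].iso_score >= 0.99
        assert all(x.iso_score >= 0.60 for x in cands)

    def test_without_pattern_all_scores_zero_and_retained(self):
        c = comp("C8H10N4O2")
        f = make_feature(mz=ionized_mz(monoisotopic_mass(c), 1, "PI"), charge=1)
        cands = predict_candidates(f, "PI")
        assert cands and all(x.iso_score == 0.0 for x in cands)
        # ordered by |ppm| when no pattern exists
        errs = [abs(x.ppm_error) for x in cands]
        assert errs == sorted(errs)


class TestPickBestCandidate:
    def _cand(self, score, ppm):
        c = FormulaCandidate(comp("C8H10N4O2"), iso_score=score)
        object.__setattr__(c, "ppm_error", ppm)
        return c

    def test_runner_up_override(self):
        cands = [self._cand(0.90, 3.0), self._cand(0.85, 0.4)]
        assert pick_best_candidate(cands) is cands[1]

    def test_no_override_when_runner_up_error_too_large(self):
        cands = [self._cand(0.90, 3.0), self._cand(0.85, 1.5)]
        assert pick_best_candidate(cands) is cands[0]

    def test_no_override_when_score_gap_too_large(self):
        cands = [self._cand(0.90, 3.0), self._cand(0.80, 0.4)]
        assert pick_best_candidate(cands) is cands[0]

    def test_singleton_and_empty(self):
        only = self._cand(0.5, 2.0)
        assert pick_best_candidate([only]) is only
        assert pick_best_candidate([]) is None

    def test_invariant_to_trailing_candidates(self):
        cands = [self._cand(0.90, 3.0), self._cand(0.85, 0.4)]
        tail = [self._cand(0.1, 0.01) for _ in range(5)]
        assert pick_best_candidate(cands + tail) is pick_best_candidate(cands)

    def test_relative_ppm_reading_config_switch(self):
        cands = [self._cand(0.90, -3.0), self._cand(0.85, -2.5)]
        # own-|ppm| reading: 2.5 >= 1 -> first; relative reading: |Δ| = 0.5 < 1 -> second
        assert pick_best_candidate(cands) is cands[0]
        assert pick_best_candidate(cands, runner_up_relative_ppm=True) is cands[1]


class TestSerialization:
    def test_caffeine_template(self):
        cand = FormulaCandidate(comp("C8H10N4O2"), iso_score=0.95)
        assert format_candidate(cand) == "FormC8H10N4O2 Iso0.95 Mass194.0804"

    @given(
        formula=st.sampled_from(
            ["C8H10N4O2", "C6H5BrO", "C10H11ClO3", "C12H26O4S", "C37H67NO13"]
        ),
        score=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_round_trip(self, formula, score):
        cand = FormulaCandidate(comp(formula), iso_score=round(score, 2))
        back = parse_candidate(format_candidate(cand))
        assert back.composition == cand.composition
        assert back.iso_score == pytest.approx(cand.iso_score, abs=5e-3)
        assert back.neutral_mass == cand.neutral_mass

    @pytest.mark.parametrize("bad", ["garbage", "FormC8 Iso2 Mass", "Iso0.5 Mass100.0"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_candidate(bad)

    def test_inconsistent_printed_mass_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            parse_candidate("FormC8H10N4O2 Iso0.95 Mass200.0000")
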