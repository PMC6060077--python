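"""The cleanup cascade: planted violations removed, clean features untouched."""

import pytest

from helpers import make_feature, make_table

from mzcleanse.chem import ElementalComposition
from mzcleanse.cleanup_filters import (
    blank_correct,
    default_adduct_rules,
    filter_by_cv,
    filter_square_peaks,
    remove_adducts,
    remove_internal_standards,
    run_cleanup,
)
from mzcleanse.mass_correction import IS_FLAG

S = ("S1", "S2", "S3")
B = ("B1", "B2", "B3")


def feature_with(heights_s, areas_s=None, heights_b=(0, 0, 0), areas_b=None, **kw):
    areas_s = areas_s if areas_s is not None else [10 * h for h in heights_s]
    areas_b = areas_b if areas_b is not None else [10 * h for h in heights_b]
    return make_feature(
        heights=list(heights_s) + list(heights_b),
        areas=list(areas_s) + list(areas_b),
        **kw,
    )


class TestRemoveInternalStandards:
    def test_flagged_features_removed(self):
        feats = [make_feature(fid=f"F{i}", mz=100.0 + i) for i in range(10)]
        feats[2].flags.add(IS_FLAG)
        feats[7].flags.add(IS_FLAG)
        out = remove_internal_standards(make_table(feats))
        assert len(out) == 8
        assert all(IS_FLAG not in f.flags for f in out.features)

    def test_no_flags_is_identity_and_idempotent(self):
        table = make_table([make_feature(fid=f"F{i}", mz=100.0 + i) for i in range(4)])
        once = remove_internal_standards(table)
        assert len(once) == 4
        assert len(remove_internal_standards(once)) == 4


class TestSquarePeaks:
    @pytest.mark.parametrize("area, kept", [(3100.0, False), (2900.0, True)])
    def test_ratio_threshold(self, area, kept):
        f = feature_with([100.0, 100.0, 100.0], [area, 1000.0, 1000.0])
        out = filter_square_peaks(make_table([f]))
        assert (len(out) == 1) is kept

    def test_all_zero_heights_kept(self):
        f = feature_with([0.0, 0.0, 0.0], [100.0, 100.0, 100.0])
        assert len(filter_square_peaks(make_table([f]))) == 1

    def test_idempotent(self):
        feats = [feature_with([100.0] * 3, [3100.0, 1000.0, 1000.0], fid="bad"),
                 feature_with([100.0] * 3, fid="good")]
        once = filter_square_peaks(make_table(feats))
        twice = filter_square_peaks(once)
        assert [f.feature_id for f in twice.features] == ["good"]


class TestCVFilter:
    def test_zero_cv_kept(self):
        out = filter_by_cv(make_table([feature_with([100.0, 100.0, 100.0])]))
        assert len(out) == 1

    def test_hand_computed_cv_090_nulled_and_removed(self):
        # heights (10, 100, 190): mean 100, sample sd 90, CV 0.90
        out = filter_by_cv(make_table([feature_with([10.0, 100.0, 190.0])]))
        assert len(out) == 0

    def test_failing_group_zeroed_but_other_group_survives(self):
        from mzcleanse.feature_io import FeatureTable

        f = make_feature(
            heights=[10.0, 100.0, 190.0, 80.0, 100.0, 120.0],
            samples=("A1", "A2", "A3"),
            blanks=("C1", "C2", "C3"),
        )
        table = FeatureTable(
            mode="PI", features=[f], blank_group="blank",
            sample_groups={"g1": ["A1", "A2", "A3"], "g2": ["C1", "C2", "C3"], "blank": []},
        )
        out = filter_by_cv(table)
        assert len(out) == 1
        kept = out.features[0]
        assert all(kept.heights[s] == 0.0 for s in ("A1", "A2", "A3"))
        assert kept.heights["C2"] == 100.0

    def test_single_replicate_group_is_an_error(self):
        from mzcleanse.feature_io import FeatureTable

        f = make_feature(heights=[100.0], samples=("S1",), blanks=())
        table = FeatureTable(
            mode="PI", features=[f], blank_group="blank",
            sample_groups={"sample": ["S1"], "blank": []},
        )
        with pytest.raises(ValueError, match="CV"):
            filter_by_cv(table)


class TestBlankCorrection:
    def test_ratio_below_3_removed(self):
        f = feature_with([25.0] * 3, [250.0] * 3, heights_b=[10.0] * 3, areas_b=[100.0] * 3)
        assert len(blank_correct(make_table([f]))) == 0

    def test_hand_arithmetic_subtraction(self):
        f = feature_with([40.0, 41.0, 39.0], [400.0, 410.0, 390.0],
                         heights_b=[10.0] * 3, areas_b=[100.0] * 3)
        out = blank_correct(make_table([f]))
        assert len(out) == 1
        kept = out.features[0]
        assert [kept.areas[s] for s in S] == [300.0, 310.0, 290.0]
        assert [kept.heights[s] for s in S] == [30.0, 31.0, 29.0]
        assert "blank_corrected" in kept.flags

    def test_noisy_blank_kept_uncorrected(self):
        f = feature_with([40.0] * 3, [400.0] * 3,
                         heights_b=[1.0, 10.0, 19.0], areas_b=[10.0, 100.0, 190.0])
        out = blank_correct(make_table([f]))  # blank CV 0.9 >= 0.3
        assert out.features[0].areas["S1"] == 400.0
        assert "blank_corrected" not in out.features[0].flags

    def test_zero_blank_kept_untouched(self):
        f = feature_with([50.0] * 3, [500.0] * 3)
        out = blank_correct(make_table([f]))
        assert out.features[0].areas["S1"] == 500.0

    def test_ratio_exactly_3_kept(self):
        f = feature_with([30.0] * 3, [300.0] * 3, heights_b=[10.0] * 3, areas_b=[100.0] * 3)
        out = blank_correct(make_table([f]))
        assert len(out) == 1
        assert out.features[0].areas["S1"] == 200.0

    def test_idempotent(self):
        f = feature_with([40.0, 41.0, 39.0], [400.0, 410.0, 390.0],
                         heights_b=[10.0] * 3, areas_b=[100.0] * 3)
        once = blank_correct(make_table([f]))
        twice = blank_correct(once)
        assert [twice.features[0].areas[s] for s in S] == [300.0, 310.0, 290.0]


class TestAdducts:
    NA_MINUS_H = (ElementalComposition(Na=1).monoisotopic_mass()
                  - ElementalComposition(H=1).monoisotopic_mass())

    def _pair(self, b_height=2e5, b_rt=5.01, b_mz=None):
        a = feature_with([1e6] * 3, fid="A", mz=200.0, rt=5.00)
        b = feature_with([b_height] * 3, fid="B",
                         mz=b_mz if b_mz is not None else 200.0 + self.NA_MINUS_H,
                         rt=b_rt)
        return make_table([a, b])

    def test_sodium_adduct_delta_from_mass_table(self):
        assert self.NA_MINUS_H == pytest.approx(21.98194, abs=1e-5)

    def test_sodium_adduct_removed(self):
        out = remove_adducts(self._pair())
        assert [f.feature_id for f in out.features] == ["A"]

    def test_height_above_50_percent_kept(self):
        out = remove_adducts(self._pair(b_height=6e5))
        assert len(out) == 2

    def test_rt_gap_keeps_feature(self):
        out = remove_adducts(self._pair(b_rt=5.10))
        assert len(out) == 2

    def test_mz_outside_tolerance_kept(self):
        out = remove_adducts(self._pair(b_mz=200.0 + self.NA_MINUS_H + 0.01))
        assert len(out) == 2

    def test_ni_water_loss_removed(self):
        h2o = ElementalComposition.from_formula("H2O").monoisotopic_mass()
        a = feature_with([1e6] * 3, fid="A", mz=300.0, rt=8.0)
        b = feature_with([1e5] * 3, fid="B", mz=300.0 - h2o, rt=8.0)
        out = remove_adducts(make_table([a, b], mode="NI"))
        assert [f.feature_id for f in out.features] == ["A"]

    def test_rules_never_modify_mz_or_rt(self):
        table = self._pair()
        before = [(f.mz, f.rt) for f in table.features]
        out = remove_adducts(table)
        assert [(f.mz, f.rt) for f in table.features] == before
        assert all((f.mz, f.rt) in before for f in out.features)

    def test_rule_labels_unique_per_mode(self):
        for mode in ("PI", "NI"):
            labels = [r.label for r in default_adduct_rules(mode)]
            assert len(labels) == len(set(labels))


class TestCascade:
    def test_counts_add_up_and_stages_ordered(self):
        feats = [feature_with([100.0] * 3, fid=f"ok{i}", mz=150.0 + 7 * i) for i in range(5)]
        flagged = feature_with([100.0] * 3, fid="is", mz=130.0)
        flagged.flags.add(IS_FLAG)
        square = feature_with([100.0] * 3, [3100.0, 500.0, 500.0], fid="sq", mz=140.0)
        noisy = feature_with([10.0, 100.0, 190.0], fid="cv", mz=145.0)
        blanky = feature_with([25.0] * 3, [250.0] * 3, heights_b=[10.0] * 3,
                              areas_b=[100.0] * 3, fid="bl", mz=148.0)
        audit = []
        table = make_table(feats + [flagged, square, noisy, blanky])
        out, report = run_cleanup(table, audit=audit)
        assert [r["stage"] for r in report] == [
            "internal_standards", "square_peaks", "cv", "blank", "adducts"]
        assert sum(r["removed"] for r in report) == len(table) - len(out)
        assert {a["feature_id"] for a in audit} >= {"is", "sq", "cv", "bl"}
        assert {f.feature_id for f in out.features} == {f"ok{i}" for i in range(5)}
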