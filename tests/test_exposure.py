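"""Exposure banding and scoring: cut-points, point grid, subscore partition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crirs.exposure import (
    DustForm,
    ExposureClass,
    ExposureIndicator,
    ExposureProfile,
    ExposureScoringTable,
    PhysicalForm,
    classify_count,
    classify_measured_exposure,
    classify_volatility_dustiness,
    classify_volume,
    distribution_subscore,
    handling_subscore,
    measured_subscore,
    raw_exposure_score,
)

EC = ExposureClass
EI = ExposureIndicator

LIQUID = PhysicalForm("liquid_gas", boiling_point_C=80.0)
SOLID = PhysicalForm("solid", dust_form=DustForm.POWDER_CRYSTALLINE)

# Independent restatement of the published point grid.
EXPECTED_GRID = {
    EI.E1: {EC.C1: 30, EC.C2: 24, EC.C3: 18, EC.C4: 12, EC.C5: 6, EC.NOT_CLASSIFIED: 0},
    EI.E2: {EC.C1: 10, EC.C2: 8, EC.C3: 6, EC.C4: 4, EC.C5: 2, EC.NOT_CLASSIFIED: 0},
    EI.E3: {EC.C1: 10, EC.C2: 8, EC.C3: 6, EC.C4: 4, EC.C5: 2, EC.NOT_CLASSIFIED: 0},
    EI.E4: {EC.C1: 10, EC.C2: 8, EC.C3: 6, EC.NOT_CLASSIFIED: 0},
    EI.E5: {EC.C1: 40, EC.C2: 32, EC.C3: 24, EC.C4: 16, EC.C5: 8, EC.NOT_CLASSIFIED: 0},
}


class TestGrid:
    def test_every_cell_matches_published_grid(self):
        table = ExposureScoringTable()
        for ind in EI:
            assert dict(table.points[ind]) == EXPECTED_GRID[ind]

    def test_maxima_partition_30_10_10_10_40(self):
        table = ExposureScoringTable()
        assert [table.max_points(i) for i in EI] == [30, 10, 10, 10, 40]
        assert sum(table.max_points(i) for i in EI) == 100

    def test_e4_has_no_class_4_or_5(self):
        with pytest.raises(ValueError, match="three classes"):
            ExposureScoringTable(
                {**ExposureScoringTable().points, EI.E4: {EC.C4: 1, EC.NOT_CLASSIFIED: 0}}
            )


class TestBands:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (2000, EC.C1), (1000.0001, EC.C1), (1000, EC.C2), (10, EC.C2),
            (9.999, EC.C3), (1, EC.C3), (0.999, EC.C4), (0.1, EC.C4),
            (0.0999, EC.C5), (0.05, EC.C5), (0, EC.C5),
        ],
    )
    def test_volume_bands_including_edges(self, value, expected):
        assert classify_volume(value) is expected

    @pytest.mark.parametrize(
        "n,expected",
        [
            (301, EC.C1), (300, EC.C2), (100, EC.C2), (99, EC.C3), (50, EC.C3),
            (49, EC.C4), (5, EC.C4), (4, EC.C5), (0, EC.C5),
        ],
    )
    def test_count_bands_including_edges(self, n, expected):
        assert classify_count(n, "workers") is expected
        assert classify_count(n, "workplaces") is expected

    @pytest.mark.parametrize(
        "bp,expected",
        [(40, EC.C1), (49.999, EC.C1), (50, EC.C2), (150, EC.C2), (150.001, EC.C3)],
    )
    def test_volatility_bands_boiling_point(self, bp, expected):
        form = PhysicalForm("liquid_gas", boiling_point_C=bp)
        assert classify_volatility_dustiness(form) is expected

    @pytest.mark.parametrize(
        "dust,expected",
        [
            (DustForm.TLV_NOTATION, EC.C1),
            (DustForm.POWDER_CRYSTALLINE, EC.C2),
            (DustForm.PELLET_NONFRIABLE, EC.C3),
        ],
    )
    def test_dustiness_bands(self, dust, expected):
        form = PhysicalForm("solid", dust_form=dust)
        assert classify_volatility_dustiness(form) is expected

    @pytest.mark.parametrize(
        "value,expected",
        [
            (600, EC.C1), (500, EC.C2), (50, EC.C2), (49.9, EC.C3), (5, EC.C3),
            (4.9, EC.C4), (0.5, EC.C4), (0.3, EC.C5), (0, EC.C5),
        ],
    )
    def test_measured_bands_liquid_gas_ppm(self, value, expected):
        assert classify_measured_exposure(value, LIQUID) is expected

    @pytest.mark.parametrize(
        "value,expected",
        [
            (11, EC.C1), (10, EC.C2), (1, EC.C2), (0.99, EC.C3), (0.1, EC.C3),
            (0.099, EC.C4), (0.01, EC.C4), (0.005, EC.C5), (0, EC.C5),
        ],
    )
    def test_measured_bands_solid_mgm3(self, value, expected):
        assert classify_measured_exposure(value, SOLID) is expected

    @pytest.mark.parametrize(
        "classifier",
        [
            classify_volume,
            lambda v: classify_count(int(v), "workers"),
            lambda v: classify_measured_exposure(v, LIQUID),
            lambda v: classify_measured_exposure(v, SOLID),
        ],
    )
    def test_negative_values_rejected(self, classifier):
        with pytest.raises(ValueError, match="non-negative"):
            classifier(-1.0)

    def test_missing_values_not_classified(self):
        assert classify_volume(None) is EC.NOT_CLASSIFIED
        assert classify_count(None) is EC.NOT_CLASSIFIED
        assert classify_volatility_dustiness(None) is EC.NOT_CLASSIFIED
        assert classify_measured_exposure(None, LIQUID) is EC.NOT_CLASSIFIED
        assert classify_measured_exposure(1.0, None) is EC.NOT_CLASSIFIED

    @settings(max_examples=300, derandomize=True)
    @given(
        v=st.one_of(
            st.floats(0, 2000, allow_nan=False),
            st.sampled_from([0.1, 1.0, 10.0, 1000.0]),  # force band edges
        ),
        w=st.floats(0, 2000, allow_nan=False),
    )
    def test_volume_banding_total_and_monotone(self, v, w):
        """Every value lands in exactly one band; severity is monotone."""
        cv, cw = classify_volume(v), classify_volume(w)
        assert cv in EC and cw in EC
        if v <= w:
            assert cv.severity <= cw.severity
        else:
            assert cv.severity >= cw.severity

    @settings(max_examples=300, derandomize=True)
    @given(a=st.floats(0, 1000, allow_nan=False), b=st.floats(0, 1000, allow_nan=False))
    def test_measured_banding_monotone_both_states(self, a, b):
        lo, hi = sorted((a, b))
        for form in (LIQUID, SOLID):
            assert (
                classify_measured_exposure(lo, form).severity
                <= classify_measured_exposure(hi, form).severity
            )

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(-50, 400, allow_nan=False), b=st.floats(-50, 400, allow_nan=False))
    def test_higher_boiling_point_never_more_volatile(self, a, b):
        lo, hi = sorted((a, b))
        c_lo = classify_volatility_dustiness(PhysicalForm("liquid_gas", boiling_point_C=lo))
        c_hi = classify_volatility_dustiness(PhysicalForm("liquid_gas", boiling_point_C=hi))
        assert c_lo.severity >= c_hi.severity


class TestScores:
    def test_all_class1_profile_scores_100(self, top_exposure_profile):
        assert raw_exposure_score(top_exposure_profile) == 100
        assert handling_subscore(top_exposure_profile) == 30
        assert distribution_subscore(top_exposure_profile) == 30
        assert measured_subscore(top_exposure_profile) == 40

    def test_empty_profile_scores_0(self):
        empty = ExposureProfile()
        assert raw_exposure_score(empty) == 0
        assert (
            handling_subscore(empty)
            == distribution_subscore(empty)
            == measured_subscore(empty)
            == 0
        )

    def test_mixed_profile_hand_sum(self, mixed_exposure_profile):
        assert raw_exposure_score(mixed_exposure_profile) == 60
        assert handling_subscore(mixed_exposure_profile) == 24
        assert distribution_subscore(mixed_exposure_profile) == 20
        assert measured_subscore(mixed_exposure_profile) == 16

    def test_circulation_substitutes_for_missing_volume(self):
        a = ExposureProfile(handling_volume_tpy=None, circulation_tpy=2000.0)
        b = ExposureProfile(handling_volume_tpy=2000.0)
        assert handling_subscore(a) == handling_subscore(b) == 30
        # handling volume takes precedence when both are present
        c = ExposureProfile(handling_volume_tpy=0.05, circulation_tpy=2000.0)
        assert handling_subscore(c) == 6

    def test_physical_form_consistency_enforced(self):
        with pytest.raises(ValueError):
            PhysicalForm("liquid_gas", dust_form=DustForm.TLV_NOTATION)
        with pytest.raises(ValueError):
            PhysicalForm("solid", boiling_point_C=100.0)
        with pytest.raises(ValueError, match="physical form"):
            ExposureProfile(measured_exposure=5.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        volume=st.one_of(st.none(), st.floats(0, 5000, allow_nan=False)),
        workers=st.one_of(st.none(), st.integers(0, 2000)),
        workplaces=st.one_of(st.none(), st.integers(0, 2000)),
        bp=st.one_of(st.none(), st.floats(-20, 400, allow_nan=False)),
        measured=st.one_of(st.none(), st.floats(0, 2000, allow_nan=False)),
    )
    def test_subscores_partition_total(self, volume, workers, workplaces, bp, measured):
        form = None if bp is None else PhysicalForm("liquid_gas", boiling_point_C=bp)
        profile = ExposureProfile(
            handling_volume_tpy=volume,
            worker_count=workers,
            workplace_count=workplaces,
            form=form,
            measured_exposure=None if form is None else measured,
        )
        total = raw_exposure_score(profile)
        assert (
            handling_subscore(profile)
            + distribution_subscore(profile)
            + measured_subscore(profile)
            == total
        )
        assert 0 <= total <= 100
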