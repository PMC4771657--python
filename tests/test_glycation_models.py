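"""Unit and property tests for the closed-form glucose <-> HbA1c relations."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycalc import (
    ConfigurationError,
    DomainError,
    GlucoseValue,
    KineticParams,
    MonthlyProfile,
    UnitError,
    WeightScheme,
    convert_glucose,
    eag_from_hba1c,
    get_scheme,
    hba1c_from_eag_adag,
    hba1c_kinetic,
    hba1c_linear,
    preset_schemes,
    weighted_ag,
    weighted_hba1c,
)
from glycalc.glycation_models import SMALL_X_THRESHOLD, _glycated_fraction_constant


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value, unit, target, expected",
        [
            (0.0, "mg/dl", "mmol/l", 0.0),
            (180.156, "mg/dl", "mmol/l", 10.0),  # molar mass 180.156 g/mol
            (10.0, "mmol/l", "mg/dl", 180.156),
            (170.0, "mg/dl", "mg/dl", 170.0),
        ],
    )
    def test_known_conversions(self, value, unit, target, expected):
        out = convert_glucose(GlucoseValue(value, unit), target)
        assert out.unit == target
        assert out.value == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=2000.0))
    def test_round_trip(self, x):
        back = GlucoseValue(x, "mg/dl").to("mmol/l").to("mg/dl")
        assert back.value == pytest.approx(x, rel=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            GlucoseValue(100.0, "g/l")

    def test_negative_glucose_rejected(self):
        with pytest.raises(DomainError):
            GlucoseValue(-5.0, "mg/dl")


class TestAdagRelation:
    @pytest.mark.parametrize(
        "hba1c, eag",
        [(46.7 / 28.7, 0.0), (7.0, 154.2), (10.0, 240.3)],
    )
    def test_eag_from_hba1c(self, hba1c, eag):
        assert eag_from_hba1c(hba1c).value == pytest.approx(eag, abs=1e-9)

    def test_below_zero_crossing_is_domain_error(self):
        with pytest.raises(DomainError):
            eag_from_hba1c(1.0)

    @given(st.floats(min_value=0.0, max_value=500.0))
    def test_inverse_identity(self, eag):
        assert eag_from_hba1c(hba1c_from_eag_adag(eag)).value == pytest.approx(
            eag, abs=1e-10
        )


class TestLinearModel:
    @pytest.mark.parametrize("eag, expected", [(170, 7.45), (148, 6.80), (0, 2.419)])
    def test_known_values(self, eag, expected):
        assert hba1c_linear(eag).percent == pytest.approx(expected, abs=5e-3)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            hba1c_linear(-1.0)


class TestKineticModel:
    @pytest.mark.parametrize("eag, expected", [(170, 7.71), (205, 8.80)])
    def test_table_values(self, eag, expected):
        # printed at 2 dp, half away from zero
        percent = hba1c_kinetic(eag).percent
        assert round(percent * 100) / 100 == pytest.approx(expected, abs=1e-9)

    def test_zero_glucose_limit_is_offset(self):
        assert hba1c_kinetic(1e-12).percent == pytest.approx(2.15, abs=1e-9)

    def test_series_branch_agrees_with_direct_formula_at_threshold(self):
        for x in (SMALL_X_THRESHOLD * 0.99, SMALL_X_THRESHOLD, SMALL_X_THRESHOLD * 1.01):
            series = x / 2.0 - x * x / 6.0
            direct = 1.0 - (1.0 - math.exp(-x)) / x
            assert series == pytest.approx(direct, abs=1e-10)
            assert _glycated_fraction_constant(x) == pytest.approx(series, abs=1e-10)

    def test_bounded_between_offset_and_scale_plus_offset(self):
        p = KineticParams()
        for eag in (1e-6, 1.0, 170.0, 1e4, 1e6):
            percent = hba1c_kinetic(eag, p).percent
            assert p.offset_percent < percent < p.scale_percent + p.offset_percent

    @pytest.mark.parametrize("model", [hba1c_linear, hba1c_kinetic])
    def test_strictly_increasing_in_glucose(self, model):
        grid = [0.5 + 2.0 * i for i in range(500)]  # (0, 1000] mg/dl
        values = [model(g).percent for g in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestWeightedAverage:
    @pytest.mark.parametrize(
        "months, expected",
        [((180, 170, 160), 167.0), ((100, 100, 310), 205.0), ((250, 160, 100), 148.0)],
    )
    def test_table_wag(self, months, expected, default_scheme):
        wag = weighted_ag(MonthlyProfile(months), default_scheme)
        assert wag.value == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=50, max_value=400))
    def test_constant_profile_is_fixed_point(self, level):
        wag = weighted_ag(MonthlyProfile((level,) * 3), get_scheme("default3"))
        assert wag.value == pytest.approx(level, rel=1e-12)

    @given(
        st.tuples(*[st.floats(min_value=40, max_value=500)] * 3),
        st.permutations(range(3)),
    )
    def test_bounded_and_permutation_invariant(self, months, perm):
        scheme = get_scheme("default3")
        wag = weighted_ag(MonthlyProfile(months), scheme).value
        assert min(months) - 1e-9 <= wag <= max(months) + 1e-9
        # permuting months *and* weights together leaves the sum unchanged
        w = scheme.weights
        permuted = sum(w[i] * months[i] for i in perm)
        assert permuted == pytest.approx(sum(w[i] * months[i] for i in range(3)))

    def test_length_mismatch_rejected(self, default_scheme):
        with pytest.raises(ConfigurationError):
            weighted_ag(MonthlyProfile((170, 170, 170, 170)), default_scheme)

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            WeightScheme("bad", (0.2, 0.3, 0.4))

    def test_linearity_in_each_month(self, default_scheme):
        base = weighted_ag(MonthlyProfile((180, 170, 160)), default_scheme).value
        bumped = weighted_ag(MonthlyProfile((180, 170 + 10, 160)), default_scheme).value
        assert bumped - base == pytest.approx(0.30 * 10, abs=1e-9)


class TestWeightedHba1c:
    @pytest.mark.parametrize(
        "months, model, expected",
        [
            ((250, 160, 100), "linear", 6.80),
            ((180, 170, 160), "kinetic", 7.62),
        ],
    )
    def test_published_values(self, months, model, expected, default_scheme):
        out = weighted_hba1c(MonthlyProfile(months), default_scheme, model)
        assert round(out.percent, 2) == pytest.approx(expected, abs=1e-9)

    def test_constant_profile_matches_plain_model(self, default_scheme):
        out = weighted_hba1c(MonthlyProfile((170, 170, 170)), default_scheme, "linear")
        assert out.percent == pytest.approx(hba1c_linear(170).percent, rel=1e-12)

    def test_weighting_shift_has_sign_of_wag_shift(self, default_scheme):
        for months in ((180, 170, 160), (250, 160, 100), (100, 100, 310)):
            profile = MonthlyProfile(months)
            mean = profile.mean_mgdl()
            dh = (
                weighted_hba1c(profile, default_scheme, "linear").percent
                - hba1c_linear(mean).percent
            )
            dw = weighted_ag(profile, default_scheme).value - mean
            assert math.copysign(1, dh) == math.copysign(1, dw)

    def test_unknown_model_rejected(self, issc, default_scheme):
        with pytest.raises(ConfigurationError):
            weighted_hba1c(issc, default_scheme, "quadratic")


class TestPresets:
    def test_presets_validate_and_cover_expected_names(self):
        schemes = {s.name: s for s in preset_schemes()}
        assert schemes["default3"].weights == (0.20, 0.30, 0.50)
        assert schemes["fourmonth"].weights == (0.10, 0.15, 0.25, 0.50)
        assert schemes["tahara3"].weights == (0.25, 0.25, 0.50)
        for s in schemes.values():
            assert sum(s.weights) == pytest.approx(1.0, abs=1e-12)
            assert s.weights[-1] == 0.50  # most recent month carries half

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            get_scheme("nonesuch")
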