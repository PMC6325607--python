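"""Inactivation kinetics, second-order fits and Michaelis-Menten recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coalscan.kinetics import (
    ActivityTimeCourse,
    InactivationModel,
    MichaelisMentenModel,
    SecondOrderModel,
    TETRAMER_MASS_DA,
    activity_from_absorbance,
    fit_inactivation_series,
    recovery_percent,
)
from coalscan.simulate import KineticsSynthConfig, gen_timecourses

LN2 = np.log(2.0)


def _course(k_obs, times=tuple(range(0, 1201, 60)), a0=100.0, label="x", conc=1e-3):
    a = tuple(float(a0 * np.exp(-k_obs * t)) for t in times)
    return ActivityTimeCourse(label, conc, tuple(float(t) for t in times), a)


class TestActivityFromAbsorbance:
    def test_slope_equal_to_epsilon_gives_tenth_unit_in_one_ml(self):
        units, _ = activity_from_absorbance(0.6220, assay_volume_l=1e-3)
        assert units == pytest.approx(0.1)

    def test_zero_slope_zero_units(self):
        assert activity_from_absorbance(0.0, 1e-3)[0] == 0.0

    def test_specific_activity_from_units_and_mass(self):
        # 14.56 U on 0.1 mg -> 145.6 U/mg
        slope = 14.56 * 6220.0 / 1e-3 / 1e6
        units, specific = activity_from_absorbance(slope, 1e-3, enzyme_mg=0.1)
        assert units == pytest.approx(14.56)
        assert specific == pytest.approx(145.6)

    def test_zero_enzyme_mass_errors_for_specific_activity_only(self):
        assert activity_from_absorbance(0.1, 1e-3)[1] is None
        with pytest.raises(ValueError, match="enzyme mass"):
            activity_from_absorbance(0.1, 1e-3, enzyme_mg=0.0)


class TestInactivationFit:
    def test_noiseless_decay_recovered_exactly(self):
        res = InactivationModel(_course(3.0e-3)).fit()
        assert res.k_obs == pytest.approx(3.0e-3, rel=1e-6)
        assert res.a0 == pytest.approx(100.0, rel=1e-6)

    def test_half_time_identity(self):
        res = InactivationModel(_course(2.4e-3)).fit()
        assert res.t_half * res.k_obs == pytest.approx(LN2, rel=1e-9)

    def test_noisy_recovery_within_ten_percent(self):
        (tc,) = gen_timecourses(
            KineticsSynthConfig(
                k2=3.0, concentrations=(1e-3,), rel_noise_sd=0.03, seed=42
            )
        )
        res = InactivationModel(tc).fit()
        assert res.k_obs == pytest.approx(3.0e-3, rel=0.10)

    def test_non_decreasing_activity_warns_and_reports_zero(self):
        tc = ActivityTimeCourse("flat", 1e-3, (0.0, 60.0, 120.0), (100.0, 101.0, 100.5))
        with pytest.warns(UserWarning, match="does not decrease"):
            res = InactivationModel(tc).fit()
        assert res.k_obs == 0.0
        assert res.t_half == np.inf

    def test_interpolated_half_time_reads_the_fifty_percent_crossing(self):
        res = InactivationModel(_course(LN2 / 300.0)).fit()
        assert res.t_half_interpolated() == pytest.approx(300.0, rel=0.01)

    def test_log_linear_option_agrees_at_zero_noise(self):
        res = InactivationModel(_course(1.5e-3)).fit(log_linear=True)
        assert res.k_obs == pytest.approx(1.5e-3, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            InactivationModel(
                ActivityTimeCourse("x", 1e-3, (0.0, 60.0), (100.0, 50.0))
            )


class TestSecondOrderFit:
    def test_exact_linear_inputs_return_slope(self):
        res = SecondOrderModel([(1e-3, 3.0e-3), (2e-3, 6.0e-3)]).fit()
        assert res.k2 == pytest.approx(3.0, rel=1e-12)

    def test_all_zero_concentrations_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            SecondOrderModel([(0.0, 1e-3), (0.0, 2e-3)])

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_fit_forward_identity_at_zero_noise(self, k2):
        tcs = gen_timecourses(
            KineticsSynthConfig(
                k2=k2,
                concentrations=(2.5e-4, 5e-4, 7.5e-4, 1e-3),
                times=tuple(np.linspace(0.0, 600.0 / k2, 12)),
            )
        )
        _, res = fit_inactivation_series(tcs)
        assert res.k2 == pytest.approx(k2, rel=1e-6)

    def test_coassscoa_series_recovers_three(self):
        tcs = gen_timecourses(KineticsSynthConfig(k2=3.0))
        _, res = fit_inactivation_series(tcs)
        assert res.k2 == pytest.approx(3.0, rel=1e-9)

    def test_gssg_series_recovers_point_three_four(self):
        tcs = gen_timecourses(
            KineticsSynthConfig(
                k2=0.34, concentrations=(2.5e-3, 5e-3, 7.5e-3, 10e-3), label="GSSG-like"
            )
        )
        _, res = fit_inactivation_series(tcs)
        assert res.k2 == pytest.approx(0.34, rel=1e-9)

    def test_intercept_option_reports_origin_offset(self):
        res = SecondOrderModel(
            [(1e-3, 3.1e-3), (2e-3, 6.1e-3), (3e-3, 9.1e-3)]
        ).fit(intercept=True)
        assert res.intercept == pytest.approx(1e-4, rel=1e-6)
        assert res.k2 == pytest.approx(3.0, rel=1e-6)


class TestRecovery:
    def test_equal_activities_give_hundred_percent(self):
        assert recovery_percent(42.0, 42.0) == 100.0

    @pytest.mark.parametrize(
        "after, initial, expected",
        [
            # peroxide-only treatments recover poorly ...
            (32.0, 100.0, 32.0),
            (12.0, 100.0, 12.0),
            # ... while peroxide + CoA recovers almost fully after DTT
            (93.0, 100.0, 93.0),
            (81.0, 100.0, 81.0),
        ],
    )
    def test_reported_recovery_fractions(self, after, initial, expected):
        assert recovery_percent(after, initial) == pytest.approx(expected)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError, match="initial"):
            recovery_percent(10.0, 0.0)


class TestMichaelisMenten:
    GRID = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0)

    def _fit(self, vmax, km, grid=None):
        s = np.asarray(grid or self.GRID)
        v = vmax * s / (km + s)
        return MichaelisMentenModel(s, v).fit()

    def test_noiseless_recovery_of_g3p_parameters(self):
        res = self._fit(152.0, 1.23)
        assert res.vmax == pytest.approx(152.0, rel=1e-6)
        assert res.km_mm == pytest.approx(1.23, rel=1e-6)

    def test_rate_at_km_is_half_vmax(self):
        res = self._fit(152.0, 1.23)
        assert res.predict(res.km_mm) == pytest.approx(res.vmax / 2.0, rel=1e-9)

    def test_kcat_with_tetramer_mass_reproduces_turnover_number(self):
        res = self._fit(152.0, 1.23)
        assert res.native_molar_mass == pytest.approx(4 * 35363.0)
        # printed 360 +/- 18; unit conversion gives ~358
        assert res.kcat == pytest.approx(358.3, abs=0.5)
        assert abs(res.kcat - 360.0) <= 18.0

    @pytest.mark.parametrize(
        "vmax, km, ratio",
        [(152.0, 1.23, 2.9e5), (152.0, 0.12, 3.0e6), (149.0, 3.65, 9.6e4)],
    )
    def test_catalytic_efficiencies_to_two_significant_figures(self, vmax, km, ratio):
        grid = tuple(km * x for x in (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0))
        res = self._fit(vmax, km, grid)
        assert res.kcat_over_km == pytest.approx(ratio, rel=0.05)

    @given(
        st.floats(min_value=10.0, max_value=1000.0),
        st.floats(min_value=0.05, max_value=5.0),
    )
    def test_exact_recovery_over_two_decades(self, vmax, km):
        grid = tuple(km * x for x in (0.2, 0.5, 1.0, 2.0, 5.0, 10.0))
        res = self._fit(vmax, km, grid)
        assert res.vmax == pytest.approx(vmax, rel=1e-5)
        assert res.km_mm == pytest.approx(km, rel=1e-5)

    def test_per_subunit_convention_quarters_kcat(self):
        s = np.asarray(self.GRID)
        v = 152.0 * s / (1.23 + s)
        tetramer = MichaelisMentenModel(s, v).fit()
        subunit = MichaelisMentenModel(s, v).fit(per_subunit=True)
        assert subunit.kcat == pytest.approx(tetramer.kcat / 4.0, rel=1e-9)

    def test_all_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError, match="positive rates"):
            MichaelisMentenModel(self.GRID, [0.0] * 8)

    def test_summary_reports_fitted_quantities(self):
        text = self._fit(152.0, 1.23).summary()
        assert "Vmax" in text and "kcat" in text and "152" in text
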