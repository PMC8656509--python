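"""GM(1,1): fitting, restoration, accuracy grading, closure forecasting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

import esvgrey as eg
from esvgrey.grey_forecast import GM11Model, predict_at_steps


def oracle_fit(x0):
    """Independent estimate of (a, u): nonlinear least squares (scipy) on
    the stacked background-value equations."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    sol = least_squares(
        lambda p: x0[1:] - (-p[0] * z1 + p[1]), x0=[0.0, x0.mean()], xtol=1e-15
    )
    return sol.x


@pytest.mark.parametrize(
    ("series", "expected"),
    [
        ([1, 2, 3], [1, 3, 6]),
        ([5], [5]),
        ([100, 110, 121], [100, 210, 331]),
    ],
)
def test_ago_is_the_running_cumulative_sum(series, expected):
    assert eg.ago(series).tolist() == expected


def test_ago_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        eg.ago([])
    with pytest.raises(ValueError):
        eg.ago([1.0, np.nan])


class TestFit:
    def test_geometric_series_matches_independent_oracle(self):
        x0 = [100.0, 110.0, 121.0, 133.1]
        model = eg.fit_gm11(x0)
        a_ref, u_ref = oracle_fit(x0)
        assert model.a == pytest.approx(a_ref, rel=1e-8)
        assert model.u == pytest.approx(u_ref, rel=1e-8)
        assert model.a == pytest.approx(-np.log(1.1), abs=1e-3)
        # exact on a constant-ratio series: next values continue the ratio
        assert eg.forecast(model, 2) == pytest.approx([146.41, 161.051], rel=1e-9)

    def test_recovers_generating_parameters_exactly(self):
        x0 = eg.gm11_exact_series(a=0.05, u=200.0, x1=120.0, n=8)
        model = eg.fit_gm11(x0)
        assert model.a == pytest.approx(0.05, rel=1e-8)
        assert model.u == pytest.approx(200.0, rel=1e-8)
        report = eg.posterior_error_test(model)
        assert report.c == pytest.approx(0.0, abs=1e-9)
        assert report.p == 1.0
        assert report.grade == 1

    def test_constant_series_limits_to_linear_response(self):
        model = eg.fit_gm11([7.0, 7.0, 7.0, 7.0])
        assert model.a == pytest.approx(0.0, abs=1e-9)
        assert model.u == pytest.approx(7.0)
        assert eg.forecast(model, 5) == pytest.approx([7.0] * 5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            eg.fit_gm11([1.0, 2.0, 3.0])

    def test_nonpositive_entry_rejected_naming_index(self):
        with pytest.raises(ValueError, match="2"):
            eg.fit_gm11([1.0, 2.0, 0.0, 4.0])


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    a=st.floats(-0.3, 0.3).filter(lambda v: abs(v) > 1e-3),
    u=st.floats(10.0, 1000.0),
    x1=st.floats(1.0, 500.0),
    n=st.integers(4, 12),
)
def test_fit_inverts_the_generator(a, u, x1, n):
    """Fitting a generator-produced response sequence recovers (a, u)
    to machine precision, with a perfect restored series."""
    try:
        x0 = eg.gm11_exact_series(a=a, u=u, x1=x1, n=n)
    except ValueError:
        return  # parameters produce a non-positive series
    model = eg.fit_gm11(x0)
    assert model.a == pytest.approx(a, rel=1e-8, abs=1e-10)
    assert model.u == pytest.approx(u, rel=1e-8)
    assert np.allclose(model.fitted, x0, rtol=1e-7)


def test_recovery_robust_to_one_percent_noise():
    """Multiplicative noise (cv = 1%) moves the recovered development
    coefficient by well under 10% on decade-length series."""
    cv = 0.01
    sigma = np.sqrt(np.log(1.0 + cv**2))
    for seed in range(50):
        a_true = 0.05 if seed % 2 else -0.05
        x0 = eg.gm11_exact_series(a=a_true, u=200.0, x1=120.0, n=10)
        rng = np.random.default_rng([seed, 11])
        noisy = x0 * rng.lognormal(-0.5 * sigma**2, sigma, x0.size)
        model = eg.fit_gm11(noisy)
        assert abs(model.a - a_true) / abs(a_true) < 0.10


class TestForecast:
    def test_negative_a_means_growth(self):
        x0 = eg.gm11_exact_series(a=-0.08, u=50.0, x1=100.0, n=6)
        model = eg.fit_gm11(x0)
        assert model.a < 0
        future = eg.forecast(model, 5)
        assert np.all(np.diff(future) > 0)
        assert future[0] > x0[-1]

    def test_horizon_must_be_positive(self):
        model = eg.fit_gm11([7.0, 7.0, 7.0, 7.0])
        with pytest.raises(ValueError):
            eg.forecast(model, 0)

    def test_step_one_restores_the_first_observation(self):
        model = eg.fit_gm11([100.0, 110.0, 121.0, 133.1])
        assert predict_at_steps(model, [1])[0] == 100.0

    def test_continuous_response_agrees_to_second_order(self):
        x0 = eg.gm11_exact_series(a=0.05, u=200.0, x1=120.0, n=8)
        disc = eg.fit_gm11(x0, response="discrete")
        cont = eg.fit_gm11(x0, response="continuous")
        assert eg.forecast(cont, 3) == pytest.approx(eg.forecast(disc, 3), rel=5e-4)


class TestPosteriorErrorTest:
    def _model_with_residuals(self, x0, residuals):
        x0 = np.asarray(x0, dtype=float)
        residuals = np.asarray(residuals, dtype=float)
        return GM11Model(
            x0=x0,
            x1=np.cumsum(x0),
            z1=np.zeros(x0.size - 1),
            a=0.0,
            u=0.0,
            fitted=x0 - residuals,
            residuals=residuals,
        )

    def test_zero_residuals_grade_one(self):
        model = self._model_with_residuals([1.0, 2.0, 3.0, 4.0], np.zeros(4))
        report = eg.posterior_error_test(model)
        assert (report.c, report.p, report.grade) == (0.0, 1.0, 1)

    def test_residuals_equal_to_data_give_c_of_one(self):
        x0 = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        report = eg.posterior_error_test(self._model_with_residuals(x0, x0))
        assert report.c == pytest.approx(1.0)
        assert report.grade == 4

    def test_constant_data_is_a_perfect_fit_by_convention(self):
        report = eg.posterior_error_test(
            self._model_with_residuals([5.0, 5.0, 5.0, 5.0], np.zeros(4))
        )
        assert (report.c, report.p, report.grade) == (0.0, 1.0, 1)

    @pytest.mark.parametrize("scale", [0.0, 0.1, 0.5, 1.0, 2.0])
    def test_grade_never_improves_as_residuals_grow(self, scale):
        x0 = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        base = np.array([0.0, 0.3, -0.4, 0.5, -0.2])
        grades = [
            eg.posterior_error_test(self._model_with_residuals(x0, s * base)).grade
            for s in (scale, scale + 0.5)
        ]
        assert grades[0] <= grades[1]


class TestLandUseForecast:
    def test_closure_holds_exactly_for_every_forecast_year(self, quiet_areas):
        future = eg.forecast_land_use(quiet_areas, [2025, 2030])
        sums = future.areas.sum(axis=0)
        assert np.allclose(sums, quiet_areas.territory_total, rtol=0, atol=1e-6)

    def test_each_category_continues_its_generating_trend(self, quiet_areas):
        result = eg.forecast_structure(quiet_areas, [2025])
        for cat, model in result.models.items():
            first, last = quiet_areas.areas.loc[cat, [2009, 2018]]
            forecast_2025 = result.areas.areas.loc[cat, 2025]
            if last > first:  # growing category keeps growing
                assert forecast_2025 > last
            elif last < first:
                assert forecast_2025 < last

    def test_zero_noise_decade_models_grade_one(self, quiet_areas):
        result = eg.forecast_structure(quiet_areas, [2025])
        for cat, report in result.accuracy.items():
            assert report.c < 0.35
            assert report.p == 1.0
            assert report.grade == 1

    def test_three_observations_insufficient(self, vc, quiet_areas):
        short = eg.LandUseSeries(
            areas=quiet_areas.areas[[2009, 2010, 2011]],
            territory_total=quiet_areas.territory_total,
        )
        with pytest.raises(ValueError, match="at least 4"):
            eg.forecast_land_use(short, [2025])

    def test_negative_closure_residual_is_clamped_and_rescaled(self):
        # the expanding category will overrun the fixed total; the closure
        # category absorbs the deficit down to zero and the rest rescale
        areas = eg.LandUseSeries(
            areas=pd.DataFrame(
                {
                    2000: {"grass land": 70.0, "unused land": 30.0},
                    2001: {"grass land": 80.0, "unused land": 20.0},
                    2002: {"grass land": 88.0, "unused land": 12.0},
                    2003: {"grass land": 95.0, "unused land": 5.0},
                }
            ),
            territory_total=100.0,
        )
        with pytest.warns(RuntimeWarning, match="closure residual"):
            result = eg.forecast_structure(areas, [2007], closure_category="unused land")
        assert result.clamped_years == [2007]
        assert result.areas.areas.loc["unused land", 2007] == 0.0
        assert result.areas.areas[2007].sum() == pytest.approx(100.0)

    def test_forecast_years_off_the_grid_rejected(self, quiet_areas):
        with pytest.raises(ValueError, match="uniformly|grid"):
            eg.forecast_land_use(
                eg.LandUseSeries(
                    areas=quiet_areas.areas[[2009, 2010, 2012, 2018]],
                    territory_total=quiet_areas.territory_total,
                ),
                [2025],
            )


class TestForecastESV:
    def test_zero_area_future_gives_zero_esv(self, vc):
        future = eg.LandUseSeries(
            areas=pd.DataFrame(0.0, index=list(eg.CATEGORIES), columns=[2025]),
            territory_total=1.0,
        )
        assert eg.forecast_esv(future, vc).totals[2025] == 0.0

    def test_identity_future_reproduces_the_2018_account(self, areas, vc, account):
        future = eg.LandUseSeries(
            areas=areas.areas[[2018]], territory_total=areas.territory_total
        )
        assert eg.forecast_esv(future, vc).totals[2018] == account.totals[2018]

    def test_declining_forest_drags_total_esv_down(self, vc):
        spec = eg.ScenarioSpec(
            first_year=2000,
            n_years=8,
            territory_total=1000.0,
            start_areas={"forest land": 800.0, "construction land": 200.0},
            end_areas={"forest land": 700.0, "construction land": 300.0},
            noise_cv=0.0,
        )
        areas = eg.generate_land_use_series(spec)
        future = eg.forecast_land_use(areas, [2008, 2010, 2012], "construction land")
        totals = eg.forecast_esv(future, vc).totals
        assert totals.is_monotonic_decreasing
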