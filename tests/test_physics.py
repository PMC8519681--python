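import numpy as np
import pytest

from epdd import (
    DepthDoseCurve,
    DomainError,
    EnergyRegressions,
    InconsistencyWarning,
    InputError,
    PrimaryTailParams,
    SingularFitError,
    StoppingPowerModel,
    convert_reading_dose,
    load_table,
    params_from_energy,
    refit_energy_regressions,
    refit_slope_mu_relation,
    slope_mu_relation,
    stopping_power,
)


def closed_form_ols(x, y):
    """Two-parameter least squares via the covariance formula (independent
    of the polyfit route used by the implementation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


class TestEnergyRegressions:
    def test_defaults_are_the_published_coefficients(self):
        reg = EnergyRegressions()
        assert (reg.n_slope, reg.n_intercept) == (31.667, -88.0)
        assert (reg.N_slope, reg.N_intercept) == (0.9975, -2.8535)
        assert (reg.lnmu_slope, reg.lnmu_intercept) == (-0.1355, -6.0986)

    def test_params_from_energy_at_12_mev(self):
        p = params_from_energy(12.0)
        assert p.n == pytest.approx(292.004)
        assert p.N == pytest.approx(9.1165)
        assert p.mu == pytest.approx(np.exp(-7.7246), rel=1e-6)
        assert p.t == 0.0

    def test_params_from_energy_rejects_degenerate_energy(self):
        import warnings

        with pytest.raises(DomainError), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # E=0 also warns (outside the span)
            params_from_energy(0.0)

    def test_warns_outside_regression_span(self):
        with pytest.warns(UserWarning, match="outside"):
            params_from_energy(4.5)

    def test_monotone_with_energy(self):
        energies = np.linspace(6, 18, 13)
        params = [params_from_energy(e) for e in energies]
        assert all(b.n > a.n and b.N > a.N and b.mu < a.mu
                   for a, b in zip(params, params[1:]))


class TestRefit:
    def test_recovers_published_n_regression_from_parameter_table(self):
        reg = refit_energy_regressions(load_table("table2"))
        assert reg.n_slope == pytest.approx(31.667, abs=1e-3)
        assert reg.n_intercept == pytest.approx(-88.0, abs=1e-3)
        assert reg.lnmu_slope == pytest.approx(-0.1355, abs=2e-4)

    def test_matches_closed_form_ols_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            rows = np.column_stack(
                [
                    np.sort(rng.uniform(4, 22, 6)),
                    rng.uniform(1, 20, 6),
                    rng.uniform(50, 600, 6),
                    rng.uniform(1e-4, 2e-3, 6),
                ]
            )
            reg = refit_energy_regressions(rows)
            s, i = closed_form_ols(rows[:, 0], rows[:, 2])
            assert reg.n_slope == pytest.approx(s, abs=1e-9)
            assert reg.n_intercept == pytest.approx(i, abs=1e-9)
            s, i = closed_form_ols(rows[:, 0], np.log(rows[:, 3]))
            assert reg.lnmu_slope == pytest.approx(s, abs=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            refit_energy_regressions([(6, 3.1, 90, 1e-3), (9, 6.2, 210, 7e-4)])

    def test_identical_energies_are_singular(self):
        rows = [(12, 3.0, 90, 1e-3), (12, 6.0, 200, 7e-4), (12, 9.0, 300, 5e-4)]
        with pytest.raises(SingularFitError):
            refit_energy_regressions(rows)


class TestStoppingPower:
    @pytest.mark.parametrize(
        "N,n,depth,expected",
        [
            (8.9, 290.0, 0.0, 0.9802),
            (1.0, 762.0, 0.0, 1.072),  # ln 1 = 0, exponent coefficient vanishes
            (8.9, 290.0, 5.0, 1.103),
        ],
    )
    def test_values(self, N, n, depth, expected):
        assert stopping_power(N, n, depth) == pytest.approx(expected, abs=5e-4)

    def test_depth_independent_exactly_at_n_762(self):
        # -n*5e-5 + 0.0381 = 0 at n = 762
        for d in (0.0, 3.0, 10.0):
            assert stopping_power(1.0, 762.0, d) == pytest.approx(1.072)

    def test_monotone_in_depth_iff_n_below_762(self):
        d = np.linspace(0, 10, 30)
        assert np.all(np.diff(stopping_power(8.9, 290.0, d)) > 0)
        assert np.all(np.diff(stopping_power(8.9, 900.0, d)) < 0)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(DomainError):
            stopping_power(0.0, 290.0, 1.0)
        with pytest.raises(DomainError):
            stopping_power(8.9, -1.0, 1.0)


class TestConvertReadingDose:
    def test_direction_is_required_and_explicit(self, table1b_12mev, reference_params):
        with pytest.raises(InputError):
            convert_reading_dose(table1b_12mev, reference_params, "multiply")

    def test_unit_ratio_is_identity_up_to_renormalization(self, table1b_12mev):
        # n = 762 with N = 1 makes the ratio exactly 1.072 at every depth
        params = PrimaryTailParams(N=1.0, n=762.0, mu=0.0)
        out = convert_reading_dose(table1b_12mev, params, "reading_to_dose")
        expected = table1b_12mev.values / table1b_12mev.values.max() * 100.0
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_constant_reading_becomes_the_exponential(self, reference_params):
        depths = np.arange(0.0, 51.0, 10.0)
        flat = DepthDoseCurve(depths=depths, values=np.full(depths.size, 100.0))
        out = convert_reading_dose(flat, reference_params, "reading_to_dose")
        expo = np.exp((-290.0 * 5e-5 + 0.0381) * depths / 10.0)
        np.testing.assert_allclose(out.values, expo / expo.max() * 100.0, rtol=1e-12)
        assert out.values[-1] == pytest.approx(100.0)  # deepest point is the max

    def test_round_trip_identity(self, reference_params):
        rng = np.random.default_rng(11)
        depths = np.sort(rng.uniform(0, 100, 20))
        depths += np.arange(20) * 1e-3
        curve = DepthDoseCurve(depths=depths, values=rng.uniform(1, 100, 20))
        there = convert_reading_dose(curve, reference_params, "reading_to_dose")
        back = convert_reading_dose(there, reference_params, "dose_to_reading")
        normalized_input = curve.values / curve.values.max() * 100.0
        np.testing.assert_allclose(back.values, normalized_input, rtol=1e-9)


class TestSlopeMuRelation:
    def test_published_formula_is_flagged_inconsistent(self):
        with pytest.warns(InconsistencyWarning):
            value = slope_mu_relation(0.0005)
        assert value == pytest.approx(34.10, abs=0.01)
        # the measured angle for the same beam is -1.35473 rad: the printed
        # relation misses it by more than an order of magnitude
        assert abs(value - (-1.35473)) > 30.0

    @pytest.mark.parametrize(
        "mu,expected",
        [(0.001, 29.47), (float(np.exp(-16.623 / 6.6729)), 0.0)],
    )
    def test_printed_line_values(self, mu, expected):
        with pytest.warns(InconsistencyWarning):
            assert slope_mu_relation(mu) == pytest.approx(expected, abs=0.01)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(DomainError):
            slope_mu_relation(0.0)

    def test_refit_utility_reproduces_measured_angles(self):
        t4 = load_table("table4")
        a, b = refit_slope_mu_relation(t4["mu_per_mm"], t4["atan_slope_rad"])
        predicted = a * np.log(t4["mu_per_mm"]) + b
        np.testing.assert_allclose(predicted, t4["atan_slope_rad"], atol=0.02)
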