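"""Effect-size model, noncentral-t power, sample-size and sign-test solvers."""

import numpy as np
import pytest
from scipy import stats

from spncat import (
    EffectSizeModel,
    PowerQuery,
    amplitude_regression,
    binomial_critical_count,
    cohens_dz,
    fit_effect_model,
    power_one_sample_t,
    power_table,
    predict_dz,
    required_n,
)


class TestCohensDz:
    def test_hand_computed(self):
        assert cohens_dz([-2.0, -1.0, 0.0, -3.0]) == pytest.approx(-1.16190, abs=1e-5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1.0, 20)
        assert cohens_dz(-d) == pytest.approx(-cohens_dz(d), abs=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            cohens_dz([1.0, 1.0, 1.0])


class TestEffectModel:
    def test_exact_quadratic_recovered(self):
        xs = np.linspace(-3.5, 0.5, 9)
        pts = [(x, 0.13 * x**2 + 0.95 * x - 0.03) for x in xs]
        m = fit_effect_model(pts)
        assert (m.a, m.b, m.c) == pytest.approx((0.13, 0.95, -0.03), abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_effect_model([(-1.0, -1.0), (0.0, 0.0)])

    def test_duplicate_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_effect_model([(-1.0, -1.0), (-1.0, -0.9), (-1.0, -1.1)])

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(7)
        truth = (0.13, 0.95, -0.03)
        x = rng.uniform(-3.5, 0.0, 120)
        y = truth[0] * x**2 + truth[1] * x + truth[2] + rng.normal(0, 0.2, x.size)
        m = fit_effect_model(list(zip(x, y)))
        for got, true, se in zip((m.a, m.b, m.c), truth, m.coef_se):
            assert abs(got - true) < 3 * se

    def test_predictions_from_printed_coefficients(self):
        m = EffectSizeModel(a=0.13, b=0.95, c=-0.03, r_squared=0.86, n_points=249)
        assert predict_dz(m, -0.5) == pytest.approx(-0.4725, abs=1e-12)
        assert predict_dz(m, 0.0) == pytest.approx(-0.03, abs=1e-12)

    def test_odd_part_identity(self):
        m = EffectSizeModel(a=0.4, b=-1.2, c=0.3, r_squared=1.0, n_points=10)
        for x in (-2.0, -0.7, 1.3):
            assert predict_dz(m, x) - predict_dz(m, -x) == pytest.approx(2 * m.b * x, abs=1e-12)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            q = PowerQuery(d=0.0, n=24, alpha=alpha)
            assert power_one_sample_t(q) == pytest.approx(alpha, abs=1e-10)

    def test_monte_carlo_oracle_d05_n24(self):
        # 200k simulated paired t-tests at d = 0.5, n = 24
        rng = np.random.default_rng(123)
        reps, n, d = 200_000, 24, 0.5
        x = rng.normal(d, 1.0, size=(reps, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        crit = stats.t.ppf(0.975, n - 1)
        mc = np.mean(np.abs(t) >= crit)
        exact = power_one_sample_t(PowerQuery(d=d, n=n))
        assert exact == pytest.approx(mc, abs=0.005)

    def test_one_tailed_exceeds_two_tailed(self):
        two = power_one_sample_t(PowerQuery(d=0.4, n=30, tails=2))
        one = power_one_sample_t(PowerQuery(d=0.4, n=30, tails=1))
        assert one > two

    def test_large_n_normal_approximation(self):
        # power -> Phi(|d| sqrt(n) - z_{1-alpha/2}) for large n
        d, n = 0.15, 500
        exact = power_one_sample_t(PowerQuery(d=d, n=n))
        approx = stats.norm.cdf(d * np.sqrt(n) - stats.norm.ppf(0.975))
        assert exact == pytest.approx(approx, abs=0.002)


class TestRequiredN:
    @pytest.mark.parametrize("d", [0.2, 0.469, 0.8, 1.5])
    def test_boundary_property(self, d):
        q = PowerQuery(d=d)
        n = required_n(q)
        assert power_one_sample_t(PowerQuery(d=d, n=n)) >= 0.8
        if n > 2:
            assert power_one_sample_t(PowerQuery(d=d, n=n - 1)) < 0.8

    def test_monotone_in_effect_size(self):
        ds = [0.2, 0.3, 0.469, 0.6, 0.9]
        ns = [required_n(PowerQuery(d=d)) for d in ds]
        assert ns == sorted(ns, reverse=True)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            required_n(PowerQuery(d=0.0))


class TestBinomialCritical:
    def test_small_n_has_no_critical_count(self):
        # n = 5: even 5/5 gives two-tailed p = 0.0625 > .05
        assert binomial_critical_count(5) is None

    def test_exact_method_no_larger_than_doubling(self):
        for n in (10, 24, 48):
            k_double = binomial_critical_count(n, method="double")
            k_exact = binomial_critical_count(n, method="exact")
            assert k_exact <= k_double


class TestPowerTable:
    @pytest.fixture()
    def model(self):
        return EffectSizeModel(
            a=0.13, b=0.95, c=-0.03, r_squared=0.86, n_points=249, x_range=(-3.5, 0.0)
        )

    def test_row_count_and_printed_anchor(self, model):
        amps = [-2.0, -1.0, -0.5]
        table = power_table(amps, model)
        assert len(table) == 3
        # at -0.5 uV the predicted effect is ~0.47; required n close to the
        # 38 obtained from d = 0.469 exactly
        row = table[table["amplitude_uV"] == -0.5].iloc[0]
        assert row["predicted_dz"] == pytest.approx(-0.4725, abs=1e-9)
        assert abs(int(row["required_n"]) - required_n(PowerQuery(d=0.469))) <= 1

    def test_required_n_non_increasing_with_effect(self, model):
        amps = list(np.arange(-3.0, -0.24, 0.25))
        table = power_table(amps, model)
        dz = table["predicted_dz"].abs()
        order = np.argsort(dz.to_numpy())
        ns = table["required_n"].to_numpy()[order]
        assert all(ns[i] >= ns[i + 1] for i in range(len(ns) - 1))

    def test_zero_effect_row_flagged(self):
        m = EffectSizeModel(a=0.0, b=0.0, c=0.0, r_squared=0.0, n_points=3)
        table = power_table([-1.0], m)
        assert table["required_n"].isna().all()

    def test_extrapolation_warns(self, model):
        with pytest.warns(UserWarning, match="outside the fitted range"):
            power_table([-5.0], model)


class TestAmplitudeRegression:
    def test_exact_recovery_on_noise_free_points(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 1, 30)
        task = rng.integers(0, 2, 30).astype(float)
        amp = 0.071 - 1.669 * w - 0.416 * task
        fit = amplitude_regression(list(zip(amp, w, task)))
        assert fit.intercept == pytest.approx(0.071, abs=1e-9)
        assert fit.coef_w == pytest.approx(-1.669, abs=1e-9)
        assert fit.coef_task == pytest.approx(-0.416, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_collinear_predictors_rejected(self):
        pts = [(-1.0, 0.5, 1.0), (-1.2, 0.5, 0.0), (-0.8, 0.5, 1.0), (-0.9, 0.5, 0.0)]
        with pytest.raises(ValueError, match="collinear|rank"):
            amplitude_regression(pts)

    def test_intercept_shift_equivariance(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0, 1, 20)
        task = rng.integers(0, 2, 20).astype(float)
        amp = 0.1 - 1.5 * w - 0.4 * task + rng.normal(0, 0.3, 20)
        base = amplitude_regression(list(zip(amp, w, task)))
        shifted = amplitude_regression(list(zip(amp + 2.0, w, task)))
        assert shifted.intercept == pytest.approx(base.intercept + 2.0, abs=1e-9)
        assert shifted.coef_w == pytest.approx(base.coef_w, abs=1e-9)
        assert shifted.coef_task == pytest.approx(base.coef_task, abs=1e-9)
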