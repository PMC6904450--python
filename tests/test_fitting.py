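"""Maximum-likelihood fitting, fixed-point iteration and AIC machinery."""

import numpy as np
import pytest
from scipy import optimize

from sadscale.errors import ComparisonError, DomainError
from sadscale.fitting import (
    akaike,
    estimate_x_max,
    fit_candidate_models,
    fit_double_power_law,
    fit_lognormal,
    fit_power_law,
    fit_shifted_power_law,
    fit_truncated_power_law,
    fit_weibull,
)
from sadscale.models import (
    DoublePowerLawModel,
    LogNormalModel,
    PowerLawModel,
    ShiftedPowerLawModel,
    TruncatedPowerLawModel,
    WeibullModel,
)


class TestPowerLaw:
    def test_closed_form_exact(self):
        x = np.full(12, np.e)
        f = fit_power_law(x)
        assert f.model.alpha == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_equals_numeric_mle(self):
        x = PowerLawModel(1.3).sample(2000, seed=0, discretize=False)
        f = fit_power_law(x)
        slog = np.sum(np.log(x))
        res = optimize.minimize_scalar(
            lambda a: -(len(x) * np.log(a) - (1 + a) * slog),
            bounds=(1e-3, 10),
            method="bounded",
        )
        assert f.model.alpha == pytest.approx(res.x, abs=1e-6)

    def test_recovery_within_stderr(self):
        errs = []
        for s in range(6):
            x = PowerLawModel(0.89).sample(10**4, seed=s, discretize=False)
            f = fit_power_law(x)
            errs.append((f.model.alpha - 0.89) / f.stderr["alpha"])
        assert abs(np.mean(errs)) < 3

    def test_degenerate_all_xmin(self):
        f = fit_power_law(np.ones(20))
        assert not f.converged

    def test_aic_consistent(self):
        x = PowerLawModel(1.5).sample(500, seed=1)
        f = fit_power_law(x)
        assert f.aic == pytest.approx(-2 * f.logL + 2 * f.V)


class TestTwoParameterFamilies:
    @pytest.mark.parametrize(
        "model,fitter,names",
        [
            (TruncatedPowerLawModel(0.5, 1e-3), fit_truncated_power_law, ("beta", "lam")),
            (LogNormalModel(0.5, 2.0), fit_lognormal, ("mu", "sigma")),
            (WeibullModel(0.6, 5.0), fit_weibull, ("k", "scale")),
        ],
        ids=("tpl", "lognormal", "weibull"),
    )
    def test_self_recovery(self, model, fitter, names):
        # continuous draws: tests estimator consistency without the floor
        # discretisation's distortion of densities concentrated near 1
        vals = {n: [] for n in names}
        for s in range(3):
            x = model.sample(10**4, seed=s, discretize=False)
            f = fitter(x)
            for n in names:
                vals[n].append(f.model.params()[n])
        truth = model.params()
        for n in names:
            est = np.mean(vals[n])
            assert est == pytest.approx(truth[n], rel=0.1, abs=0.02 * max(1, abs(truth[n])))


class TestDoublePowerLaw:
    def test_recovery(self):
        m = DoublePowerLawModel(0.36, 1.54, 2313.0)
        dl, al = [], []
        for s in range(10):
            f = fit_double_power_law(m.sample(18022, seed=s))
            p = f.model.params()
            dl.append(p["delta"])
            al.append(p["alpha"])
        assert np.mean(dl) == pytest.approx(0.36, abs=0.05)
        assert np.mean(al) == pytest.approx(1.54, abs=0.05)

    def test_single_regime_data_gives_equal_exponents(self):
        diffs = []
        for s in range(5):
            x = PowerLawModel(1.2).sample(8000, seed=s)
            f = fit_double_power_law(x)
            p = f.model.params()
            pooled = np.hypot(f.stderr["alpha"], f.stderr.get("delta", 0.1))
            diffs.append(abs(p["delta"] - p["alpha"]) / max(pooled, 1e-6))
        assert np.mean(diffs) < 3

    def test_forced_unit_cutoff_matches_pure_fit(self):
        x = PowerLawModel(1.5).sample(2000, seed=2)
        f = fit_double_power_law(x, x_c=1.0)
        pl = fit_power_law(x)
        assert f.model.alpha == pytest.approx(pl.model.alpha, rel=1e-9)
        assert f.model.delta == pytest.approx(pl.model.alpha, rel=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(DomainError):
            fit_double_power_law(np.arange(1, 30))


class TestShiftedPowerLaw:
    def test_recovery_within_3se(self):
        m = ShiftedPowerLawModel(0.89, 20.34)
        al, x0, se_a, se_x = [], [], [], []
        for s in range(10):
            f = fit_shifted_power_law(m.sample(3695, seed=s))
            assert f.converged
            al.append(f.model.alpha)
            x0.append(f.model.x0)
            se_a.append(f.stderr["alpha"])
            se_x.append(f.stderr["x0"])
        assert abs(np.mean(al) - 0.89) < 3 * np.mean(se_a)
        assert abs(np.mean(x0) - 20.34) < 3 * np.mean(se_x)

    def test_pure_power_law_drives_x0_to_zero(self):
        x = PowerLawModel(1.2).sample(5000, seed=1)
        f = fit_shifted_power_law(x)
        assert f.model.x0 == pytest.approx(0.0, abs=1e-3)

    def test_exit_state_satisfies_stationarity(self):
        x = ShiftedPowerLawModel(0.89, 20.34).sample(2000, seed=4).astype(float)
        tol = 1e-6
        f = fit_shifted_power_law(x, tolerance=tol)
        a, z = f.model.alpha, f.model.x0
        S = len(x)
        a_rhs = S / np.sum(np.log((x + z) / (1 + z)))
        z_rhs = a_rhs * S / ((1 + a_rhs) * np.sum(1.0 / (x + z))) - 1.0
        assert abs(a - a_rhs) < 10 * tol
        assert abs(z - z_rhs) < 10 * tol

    def test_nonconvergence_reported(self):
        x = PowerLawModel(1.2).sample(500, seed=0)
        f = fit_shifted_power_law(x, max_iter=2)
        assert not f.converged


class TestEstimateXmax:
    def test_round_trip(self):
        for xm_true in (1e4, 5e6):
            m = ShiftedPowerLawModel(0.88, 30.0, x_max=xm_true)
            assert estimate_x_max(0.88, 30.0, m.mean()) == pytest.approx(xm_true, rel=1e-6)

    def test_mean_monotone_in_xmax(self):
        means = [ShiftedPowerLawModel(0.88, 30.0, x_max=x).mean() for x in (1e3, 1e5, 1e7)]
        assert np.all(np.diff(means) > 0)

    def test_small_mean_rejected(self):
        with pytest.raises(DomainError):
            estimate_x_max(0.88, 30.0, 0.5)

    def test_unbounded_flag(self):
        # alpha > 1: the mean saturates; an unreachable target reports inf
        cap = ShiftedPowerLawModel(3.0, 0.0).mean()
        assert np.isinf(estimate_x_max(3.0, 0.0, cap * 10))


class TestAkaike:
    def _fit(self, seed=0):
        return fit_power_law(PowerLawModel(1.5).sample(300, seed=seed))

    def test_single_model(self):
        c = akaike([self._fit()])
        assert c.delta_aic.tolist() == [0.0]
        assert c.weights.tolist() == [1.0]

    def test_weight_formula(self):
        f1, f2 = self._fit(), self._fit()
        f2.logL = f1.logL - 1.0  # delta AIC = 2
        c = akaike([f1, f2])
        np.testing.assert_allclose(c.weights, [0.731, 0.269], atol=1e-3)

    def test_shift_invariance_and_symmetry(self):
        f1, f2 = self._fit(), self._fit()
        c0 = akaike([f1, f2])
        np.testing.assert_allclose(c0.weights, [0.5, 0.5])
        f1.logL += 11.5
        f2.logL += 11.5
        np.testing.assert_allclose(akaike([f1, f2]).weights, c0.weights)

    def test_order_invariance(self):
        x = TruncatedPowerLawModel(0.5, 1e-3).sample(3000, seed=5)
        fits = [fit_power_law(x), fit_truncated_power_law(x), fit_lognormal(x)]
        best_fwd = akaike(fits).best.family
        best_rev = akaike(fits[::-1]).best.family
        assert best_fwd == best_rev

    def test_differing_data_rejected(self):
        f1 = self._fit(0)
        f2 = fit_power_law(PowerLawModel(1.5).sample(301, seed=1))
        with pytest.raises(ComparisonError):
            akaike([f1, f2])


def test_fit_candidate_models_best_has_zero_delta():
    x = TruncatedPowerLawModel(0.5, 1e-4).sample(5000, seed=9)
    c = fit_candidate_models(x)
    assert c.delta_aic.min() == 0.0
    assert c.weights.sum() == pytest.approx(1.0)
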