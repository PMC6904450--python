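"""Distribution normalisation, closed forms, samplers and reductions."""

import numpy as np
import pytest
from scipy.integrate import quad

from sadscale.errors import DivergingMeanError, DomainError, NotNormalizableError
from sadscale.models import (
    DoublePowerLawModel,
    LogNormalModel,
    PowerLawModel,
    ShiftedPowerLawModel,
    TruncatedPowerLawModel,
    WeibullModel,
    double_pl_constants,
    mean_abundance,
    model_from_dict,
    sample_to_reads,
    shifted_pl_constant,
)

ALL_MODELS = [
    PowerLawModel(1.5),
    TruncatedPowerLawModel(0.5, 1e-3),
    LogNormalModel(0.5, 2.0),
    WeibullModel(0.6, 5.0),
    DoublePowerLawModel(0.36, 1.54, 2313.0),
    ShiftedPowerLawModel(0.89, 20.34),
    ShiftedPowerLawModel(0.89, 20.34, x_max=1e6),
]


def _quad_mass(m):
    hi = m.x_max if np.isfinite(m.x_max) else np.inf
    if m.family == "double_power_law":
        return quad(m.pdf, 1, m.x_c)[0] + quad(m.pdf, m.x_c, np.inf)[0]
    return quad(m.pdf, 1, hi, limit=300)[0]


class TestNormalisation:
    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family + str(m.params()))
    def test_unit_mass(self, m):
        assert _quad_mass(m) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family + str(m.params()))
    def test_ppf_inverts_cdf(self, m):
        u = np.linspace(1e-6, 1 - 1e-6, 501)
        np.testing.assert_allclose(m.cdf(m.ppf(u)), u, atol=1e-6)


class TestDoublePowerLawConstants:
    def test_equal_exponents_reduce_to_pure_law(self):
        A, B = double_pl_constants(1.3, 1.3, 57.0)
        assert A == pytest.approx(1.3) and B == pytest.approx(1.3)

    @pytest.mark.parametrize("delta,alpha,x_c", [(0.36, 1.54, 2313.0), (0.9, 2.5, 10.0), (-0.2, 1.1, 40.0)])
    def test_continuity_and_mass(self, delta, alpha, x_c):
        A, B = double_pl_constants(delta, alpha, x_c)
        assert A * x_c ** (-1 - delta) == pytest.approx(B * x_c ** (-1 - alpha), rel=1e-12)
        m = DoublePowerLawModel(delta, alpha, x_c)
        assert _quad_mass(m) == pytest.approx(1.0, abs=1e-6)

    def test_nonnormalizable_tail(self):
        with pytest.raises(NotNormalizableError):
            double_pl_constants(0.5, -0.2, 10.0)

    def test_x_c_one_is_pure_tail(self):
        m = DoublePowerLawModel(0.5, 1.7, 1.0)
        pl = PowerLawModel(1.7)
        x = np.geomspace(1, 1e6, 50)
        np.testing.assert_allclose(m.logpdf(x), pl.logpdf(x), atol=1e-10)


class TestShiftedConstant:
    def test_reduces_to_pure_power_law(self):
        assert shifted_pl_constant(1.3, 0.0, np.inf) == pytest.approx(1.3)

    def test_printed_parameterisation_normalises(self):
        m = ShiftedPowerLawModel(0.89, 20.34, x_max=1e6)
        assert _quad_mass(m) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_alpha(self):
        vals = [shifted_pl_constant(a, 20.34, 1e6) for a in (0.5, 0.89, 1.3, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            shifted_pl_constant(0.9, 1.0, x_max=0.5)


class TestMean:
    def test_pure_power_law_closed_form(self):
        assert mean_abundance(PowerLawModel(2.0)) == pytest.approx(2.0)
        assert mean_abundance(PowerLawModel(1.5)) == pytest.approx(3.0)

    def test_diverging_mean(self):
        with pytest.raises(DivergingMeanError):
            mean_abundance(PowerLawModel(0.89))
        with pytest.raises(DivergingMeanError):
            mean_abundance(ShiftedPowerLawModel(0.89, 20.34))

    @pytest.mark.parametrize(
        "m",
        [
            TruncatedPowerLawModel(0.5, 1e-3),
            LogNormalModel(0.5, 2.0),
            WeibullModel(0.6, 5.0),
            DoublePowerLawModel(0.36, 1.54, 2313.0),
            ShiftedPowerLawModel(0.89, 20.34, x_max=1e6),
            ShiftedPowerLawModel(1.7, 4.0),
        ],
        ids=lambda m: m.family,
    )
    def test_closed_form_matches_quadrature(self, m):
        hi = m.x_max if np.isfinite(m.x_max) else np.inf
        if m.family == "double_power_law":
            ref = quad(lambda x: x * m.pdf(x), 1, m.x_c)[0] + quad(
                lambda x: x * m.pdf(x), m.x_c, np.inf
            )[0]
        else:
            ref = quad(lambda x: x * m.pdf(x), 1, hi, limit=400)[0]
        assert m.mean() == pytest.approx(ref, rel=1e-7)


class TestSampling:
    def test_deterministic_per_seed(self):
        m = DoublePowerLawModel(0.36, 1.54, 2313.0)
        np.testing.assert_array_equal(m.sample(1000, seed=7), m.sample(1000, seed=7))
        assert not np.array_equal(m.sample(1000, seed=7), m.sample(1000, seed=8))

    def test_empirical_mean_matches_theory(self):
        m = PowerLawModel(2.0)
        x = m.sample(10**5, seed=3)
        se = x.std() / np.sqrt(len(x))
        # floored draws sit below the continuous mean by at most 1
        assert abs(x.mean() - (m.mean() - 0.5)) < 3 * se + 0.5

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family + str(m.params()))
    def test_sampler_matches_survival_function(self, m):
        """Floored inverse-CDF draws satisfy P(K >= k) = sf(k) at integers."""
        d = m.sample(10**5, seed=11)
        uniq = np.unique(d)
        if len(uniq) > 2000:
            uniq = uniq[:: len(uniq) // 2000]
        emp_sf = 1.0 - np.searchsorted(np.sort(d), uniq, side="left") / len(d)
        ks = np.max(np.abs(emp_sf - m.sf(uniq.astype(float))))
        assert ks < 0.02

    def test_tpl_lam_zero_equals_power_law(self):
        tpl = TruncatedPowerLawModel(0.7, 0.0)
        pl = PowerLawModel(0.7)
        x = np.geomspace(1, 1e6, 200)
        np.testing.assert_allclose(tpl.logpdf(x), pl.logpdf(x), atol=1e-12)

    def test_sample_to_reads_stopping_rule(self):
        m = PowerLawModel(1.2)
        v = sample_to_reads(m, 10000, seed=5)
        assert v.N >= 10000
        assert v.N - v.x[-1] < 10000  # without the last draw we were short

    def test_sample_to_reads_single_read(self):
        v = sample_to_reads(PowerLawModel(2.0), 1, seed=0)
        assert v.S >= 1 and v.N >= 1


def test_serialisation_round_trip():
    for m in ALL_MODELS:
        m2 = model_from_dict(m.to_dict())
        assert m2.params() == m.params()
        assert m2.family == m.family
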