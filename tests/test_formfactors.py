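import math

import numpy as np
import pytest
from scipy import integrate, optimize

import sasmodelfit as sm
from sasmodelfit.formfactors import (HAMMOUDA_BRANCHED, SPHERE, FormFactorModel,
                                     Parameter, ParameterRangeError, Registry,
                                     hammouda_branched_intensity, make_template,
                                     sphere_amplitude, sphere_intensity)


class TestSphere:
    def test_forward_scattering_limit(self):
        assert sphere_amplitude(0.0, R=1.0, eta=1.0) == pytest.approx(
            4 * math.pi / 3, rel=1e-12)
        # F(0) = eta * V generally
        assert sphere_amplitude(1e-9, R=3.0, eta=2.0) == pytest.approx(
            2.0 * 4 * math.pi / 3 * 27, rel=1e-9)

    def test_first_zero_from_root_finding_oracle(self):
        # amplitude zero where tan(x) = x; root in (pi, 3pi/2)
        x_star = optimize.brentq(lambda x: math.tan(x) - x, math.pi + 0.1,
                                 1.5 * math.pi - 1e-9, xtol=1e-12)
        assert x_star == pytest.approx(4.493409457909064, abs=1e-9)
        R = 2.0
        q = x_star / R
        assert abs(sphere_amplitude(q, R=R)) < 1e-9
        assert sphere_amplitude(q * 0.99, R=R) * sphere_amplitude(q * 1.01, R=R) < 0

    def test_porod_envelope_slope(self):
        # envelope of the intensity maxima decays ~ q^-4 for qR >> 1
        R = 1.0
        q = np.linspace(50, 500, 200001)
        I = sphere_intensity(q, R=R)
        i_max = (np.flatnonzero((I[1:-1] > I[:-2]) & (I[1:-1] > I[2:])) + 1)
        slope = np.polyfit(np.log(q[i_max]), np.log(I[i_max]), 1)[0]
        assert -4.2 <= slope <= -3.8

    def test_guinier_regression(self):
        R = 5.0
        q = np.linspace(1e-4, 0.2 / R, 100)
        slope = np.polyfit(q**2, np.log(sphere_intensity(q, R=R)), 1)[0]
        Rg2 = 3.0 / 5.0 * R**2
        assert slope == pytest.approx(-Rg2 / 3.0, rel=0.01)

    def test_monotone_decreasing_before_first_zero(self):
        q = np.linspace(0, 4.49, 500)
        I = sphere_intensity(q, R=1.0)
        assert np.all(np.diff(I) < 0)

    def test_even_in_q(self):
        q = np.array([0.3, 1.7])
        np.testing.assert_array_equal(sphere_intensity(q, R=2.0),
                                      sphere_intensity(-q, R=2.0))

    def test_series_matches_direct_at_crossover(self):
        # continuity of the small-argument branch (the kernel itself varies
        # by ~4e-10 relative between the two abscissae)
        a = sphere_amplitude(0.999e-3, R=1.0)
        b = sphere_amplitude(1.001e-3, R=1.0)
        assert a == pytest.approx(b, rel=1e-8)

    def test_invalid_radius(self):
        with pytest.raises(ParameterRangeError, match="'R'"):
            sphere_amplitude(0.1, R=-1.0)


def hammouda_quadrature_oracle(q, Rg, v, c):
    """Direct numeric quadrature of the defining integral."""
    u = q * q * Rg * Rg * (2 * v + 1) * (2 * v + 2) / 6.0
    val, _ = integrate.quad(
        lambda n: c * n ** (c - 1) * (1 - n) * math.exp(-u * n ** (2 * v)),
        0.0, 1.0, epsabs=1e-14, epsrel=1e-12)
    return (c + 1) * val


class TestHammoudaBranched:
    PARAM_SETS = [(3.0, 0.5, 1.0), (5.0, 0.588, 2.0), (2.0, 0.3, 0.5)]

    @pytest.mark.parametrize("Rg,v,c", PARAM_SETS)
    def test_normalization(self, Rg, v, c):
        assert hammouda_branched_intensity(0.0, Rg, v, c) == pytest.approx(1.0)

    @pytest.mark.parametrize("Rg,v,c", PARAM_SETS)
    def test_closed_form_matches_quadrature(self, Rg, v, c):
        q = np.geomspace(1e-3, 10.0 / Rg, 20)
        closed = hammouda_branched_intensity(q, Rg, v, c)
        oracle = np.array([hammouda_quadrature_oracle(qi, Rg, v, c) for qi in q])
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_negative_q_raises_named_error(self):
        with pytest.raises(ParameterRangeError, match="'q'"):
            hammouda_branched_intensity(-0.1, 3.0, 0.5, 1.0)

    @pytest.mark.parametrize("kwargs,par", [
        (dict(Rg=-1.0, v=0.5, c=1.0), "Rg"),
        (dict(Rg=1.0, v=0.0, c=1.0), "v"),
        (dict(Rg=1.0, v=0.5, c=-2.0), "c"),
    ])
    def test_parameter_domain(self, kwargs, par):
        with pytest.raises(ParameterRangeError, match=f"'{par}'"):
            hammouda_branched_intensity(0.1, **kwargs)

    def test_no_amplitude_available(self):
        assert not HAMMOUDA_BRANCHED.has_amplitude
        with pytest.raises(NotImplementedError, match="amplitude"):
            HAMMOUDA_BRANCHED.amplitude(0.1)


class TestRegistry:
    def _params(self):
        return (Parameter("a", "first", 1.0, lo=0.0),
                Parameter("b", "second", 2.0),
                Parameter("c", "third", 3.0))

    def test_template_evaluates_to_zero(self):
        reg = Registry()
        tpl = reg.register(make_template("empty", self._params()))
        q = np.linspace(0, 2, 7)
        np.testing.assert_array_equal(tpl.intensity(q), np.zeros(7))
        assert not tpl.has_amplitude

    def test_duplicate_name_rejected(self):
        reg = Registry()
        reg.register(make_template("dup", self._params()))
        with pytest.raises(ValueError, match="already registered"):
            reg.register(make_template("dup", self._params()))

    def test_registration_without_range_checks_refused(self):
        reg = Registry()
        with pytest.raises(ValueError, match="no parameters"):
            reg.register(FormFactorModel("bare", parameters=()))
        with pytest.raises(ValueError, match="range check"):
            reg.register(FormFactorModel("loose", parameters=("a",)))

    def test_composition_of_registered_models(self):
        reg = Registry()
        reg.register(SPHERE, namespace="built-in")
        double = FormFactorModel(
            "double_sphere",
            parameters=(Parameter("R", "radius", 1.0, lo=0.0, open_lo=True),),
            evaluate_intensity=lambda q, R, models: 2.0 * models["sphere"].intensity(
                q, R=R, eta=1.0),
            uses=("sphere",),
        )
        reg.register(double)
        q = np.linspace(0.01, 1.0, 5)
        np.testing.assert_allclose(reg.get("double_sphere").intensity(q, R=2.0),
                                   2.0 * sphere_intensity(q, R=2.0), rtol=1e-14)

    def test_unknown_import_rejected(self):
        reg = Registry()
        with pytest.raises(ValueError, match="unknown model"):
            reg.register(FormFactorModel(
                "orphan", parameters=self._params(), uses=("nothere",)))

    def test_namespaces_listing(self):
        from sasmodelfit.formfactors import REGISTRY
        listing = REGISTRY.list()
        assert "sphere" in listing["built-in"]
        assert "hammouda_branched" in listing["built-in"]

    def test_shipped_models_pass_their_own_range_checks_at_defaults(self):
        for model in (SPHERE, HAMMOUDA_BRANCHED):
            out = model.intensity(np.array([0.0, 0.5]), **model.defaults())
            assert np.all(np.isfinite(out))

    def test_out_of_range_named_error_via_model(self):
        with pytest.raises(ParameterRangeError, match="'R'"):
            SPHERE.intensity(0.1, R=0.0)
        with pytest.raises(ParameterRangeError, match="'q'"):
            SPHERE.intensity(-0.1, R=1.0)
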