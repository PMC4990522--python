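import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from scatterbmd.simulate import (
    ScatterGeometry,
    scatter_integral,
    scatter_intensity,
    scatter_intensity_differential,
)


class TestScatterIntensity:
    def test_zero_density_scatters_nothing(self):
        assert scatter_intensity(mu=0.2, r=1.0, rho_e=0.0, s=1.0) == 0.0

    def test_no_attenuation_limit_is_product(self):
        assert scatter_intensity(mu=0.0, r=5.0, rho_e=1.1, s=2.0) == pytest.approx(2.2)

    def test_hand_evaluation(self):
        # 6 * e^-0.2, evaluated independently
        expected = 6.0 * math.exp(-0.2)
        got = scatter_intensity(mu=0.2, r=1.0, rho_e=2.0, s=3.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.912384, rel=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": -0.1, "r": 1.0, "rho_e": 1.0, "s": 1.0},
            {"mu": 0.1, "r": 0.0, "rho_e": 1.0, "s": 1.0},
            {"mu": 0.1, "r": 1.0, "rho_e": -1.0, "s": 1.0},
            {"mu": 0.1, "r": 1.0, "rho_e": 1.0, "s": -1.0},
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            scatter_intensity(**kwargs)

    @settings(derandomize=True)
    @given(
        st.floats(0, 2), st.floats(0.1, 5), st.floats(0, 3), st.floats(0, 3),
        st.floats(0.25, 4),
    )
    def test_homogeneous_degree_one_in_rho_and_s(self, mu, r, rho_e, s, k):
        base = scatter_intensity(mu, r, rho_e, s)
        assert scatter_intensity(mu, r, k * rho_e, s) == pytest.approx(k * base)
        assert scatter_intensity(mu, r, rho_e, k * s) == pytest.approx(k * base)

    @settings(derandomize=True)
    @given(st.floats(0.01, 2), st.floats(0.01, 2), st.floats(0.1, 5))
    def test_strictly_decreasing_in_attenuation(self, mu, dmu, r):
        assert scatter_intensity(mu + dmu, r, 1.0, 1.0) < scatter_intensity(
            mu, r, 1.0, 1.0
        )


class TestScatterDifferential:
    def test_zero_density(self):
        geom = ScatterGeometry()
        for r in (0.1, 1.0, 3.0):
            assert scatter_intensity_differential(geom, 0.5, 0.0, r) == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            scatter_intensity_differential(ScatterGeometry(), 0.5, 1.0, 0.0)
        with pytest.raises(ValueError):
            scatter_integral(ScatterGeometry(), 0.5, 1.0, -1.0)

    def test_mu_zero_limit_integral_is_linear_in_radius(self):
        geom = ScatterGeometry(i0=2.0, area=0.5, theta=0.3)
        num, _ = quad(lambda r: scatter_intensity_differential(geom, 0.0, 1.5, r), 0, 2)
        assert num == pytest.approx(scatter_integral(geom, 0.0, 1.5, 2.0), rel=1e-10)
        assert scatter_integral(geom, 0.0, 1.5, 2.0) == pytest.approx(
            (2.0 / 0.5) * 0.3 * 1.5 * 2.0
        )

    def test_closed_form_example(self):
        geom = ScatterGeometry(i0=1.0, area=1.0, theta=1.0)
        num, _ = quad(lambda r: scatter_intensity_differential(geom, 0.5, 1.0, r), 0, 2)
        expected = (1.0 - math.exp(-1.0)) / 0.5
        assert num == pytest.approx(expected, rel=1e-8)
        assert scatter_integral(geom, 0.5, 1.0, 2.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mu_r", np.geomspace(0.01, 5.0, 9).tolist())
    def test_quadrature_matches_closed_form(self, mu_r):
        geom = ScatterGeometry(i0=1.3, area=0.7, theta=2.1)
        radius = 1.7
        mu = mu_r / radius
        num, _ = quad(
            lambda r: scatter_intensity_differential(geom, mu, 0.9, r), 0, radius
        )
        closed = scatter_integral(geom, mu, 0.9, radius)
        assert abs(num - closed) / closed <= 1e-6

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            ScatterGeometry(area=0.0)
        with pytest.raises(ValueError):
            ScatterGeometry(theta=0.0)
        with pytest.raises(ValueError):
            ScatterGeometry(theta=4 * math.pi + 0.1)
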