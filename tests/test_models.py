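"""Forward-model tests: sphere form factor and mixture intensity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import sasbayes as sb
from sasbayes.models import MODEL_REGISTRY, QGrid, SphereMixtureParams, form_factor_sq, intensity


class TestFormFactor:
    def test_limit_at_zero_is_one(self):
        assert form_factor_sq(0.0) == pytest.approx(1.0)

    def test_value_at_pi(self):
        # sin(pi)=0, cos(pi)=-1 -> Phi(pi) = 3/pi^2 exactly
        assert form_factor_sq(np.pi) == pytest.approx((3.0 / np.pi**2) ** 2, rel=1e-12)

    def test_first_zero_location(self):
        # first zero of Phi where tan x = x; locate it independently
        x0 = brentq(lambda x: np.tan(x) - x, np.pi / 2 + 1e-6, 3 * np.pi / 2 - 1e-6)
        assert x0 == pytest.approx(4.4934094579, abs=1e-6)
        assert form_factor_sq(x0) < 1e-12

    def test_series_matches_closed_form_at_crossover(self):
        # just below the switch the series branch is used; the closed form
        # is still accurate there, so both must agree at the same x
        x = 0.99e-2
        closed = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        assert form_factor_sq(x) == pytest.approx(closed, rel=1e-10)

    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_bounded_unit_interval(self, x):
        v = form_factor_sq(x)
        assert 0.0 <= v <= 1.0 + 1e-15

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            form_factor_sq(-0.5)


class TestSphereMixtureParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SphereMixtureParams(R=[1.0, 2.0], S=[1.0, 1.0], B=0.1)  # wrong order
        with pytest.raises(ValueError):
            SphereMixtureParams(R=[2.0, -1.0], S=[1.0, 1.0], B=0.1)
        with pytest.raises(ValueError):
            SphereMixtureParams(R=[2.0], S=[1.0], B=0.0)

    def test_sorted_constructor_orders_pairs(self):
        p = SphereMixtureParams.sorted(R=[2.0, 10.0], S=[250.0, 100.0], B=0.01)
        assert list(p.R) == [10.0, 2.0]
        assert list(p.S) == [100.0, 250.0]  # scales follow their radii

    def test_vector_roundtrip(self):
        p = SphereMixtureParams(R=[10.0, 2.0], S=[250.0, 100.0], B=0.01)
        q = SphereMixtureParams.from_vector(p.to_vector(), K=2)
        np.testing.assert_allclose(q.R, p.R)
        np.testing.assert_allclose(q.S, p.S)
        assert q.B == p.B
        assert p.n_params == 5

    def test_empty_mixture_is_background_model(self):
        p = SphereMixtureParams(R=np.empty(0), S=np.empty(0), B=0.5)
        assert p.K == 0
        grid = QGrid(np.linspace(0.1, 3, 7))
        np.testing.assert_allclose(MODEL_REGISTRY["constant"](p, grid), 0.5)


class TestIntensity:
    def test_forward_scattering_value(self):
        # equal-scale two-sphere model at q -> 0: both form factors -> 1,
        # each component weighted by its volume factor R^3
        p = SphereMixtureParams(R=[10.0, 2.0], S=[250.0, 250.0], B=0.01)
        grid = QGrid(np.array([1e-9, 0.1]))
        expected = 250.0 * 1000.0 + 250.0 * 8.0 + 0.01
        assert intensity(p, grid)[0] == pytest.approx(expected, rel=1e-10)

    def test_single_sphere_value_at_known_x(self):
        # at x = qR = pi: Phi^2 = (3/pi^2)^2 exactly
        p = SphereMixtureParams(R=[10.0], S=[100.0], B=0.01)
        grid = QGrid(np.array([np.pi / 10.0]))
        expected = 100.0 * 1000.0 * (3.0 / np.pi**2) ** 2 + 0.01
        assert intensity(p, grid)[0] == pytest.approx(expected, rel=1e-12)

    def test_background_floor(self):
        p = SphereMixtureParams(R=[5.0, 1.0], S=[10.0, 3.0], B=0.2)
        grid = QGrid(np.linspace(0.05, 3, 101))
        assert np.all(intensity(p, grid) >= 0.2)

    @given(
        st.integers(min_value=1, max_value=4),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_additivity_over_components(self, K, seed):
        rng = np.random.default_rng(seed)
        R = np.sort(rng.uniform(0.5, 20, K))[::-1]
        S = rng.uniform(0.1, 300, K)
        B = rng.uniform(0.001, 1.0)
        grid = QGrid(np.linspace(0.1, 3, 37))
        total = intensity(SphereMixtureParams(R=R, S=S, B=B), grid)
        parts = sum(
            intensity(SphereMixtureParams(R=[r], S=[s], B=B), grid) - B
            for r, s in zip(R, S)
        )
        np.testing.assert_allclose(total, parts + B, rtol=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, c):
        grid = QGrid(np.linspace(0.1, 3, 23))
        p1 = SphereMixtureParams(R=[8.0, 2.0], S=[50.0, 10.0], B=0.05)
        p2 = SphereMixtureParams(R=[8.0, 2.0], S=[50.0 * c, 10.0 * c], B=0.05 * c)
        np.testing.assert_allclose(intensity(p2, grid), c * intensity(p1, grid), rtol=1e-12)

    def test_high_q_decay_envelope(self):
        # scattering above background bounded by S * 9 (1+x)^2 / x^6
        p = SphereMixtureParams(R=[10.0], S=[100.0], B=0.01)
        q = np.linspace(1.0, 3.0, 200)
        x = q * 10.0
        excess = intensity(p, QGrid(q)) - 0.01
        env = 100.0 * 10.0**3 * 9.0 * (1.0 + x) ** 2 / x**6
        assert np.all(excess <= env * (1 + 1e-9))

    def test_registry_dispatch(self):
        assert set(MODEL_REGISTRY) >= {"sphere_mixture", "constant"}
        p = SphereMixtureParams(R=[5.0], S=[10.0], B=0.1)
        grid = QGrid(np.linspace(0.1, 1, 11))
        np.testing.assert_allclose(
            MODEL_REGISTRY["sphere_mixture"](p, grid), intensity(p, grid)
        )


class TestQGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            QGrid(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            QGrid(np.array([1.0, 1.0]))
        assert QGrid(np.array([0.1, 0.2])).N == 2
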