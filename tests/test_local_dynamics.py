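import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphsh.local_dynamics import (
    ModelParams,
    dispersion,
    flat_bifurcation_points,
    flat_states,
    local_force,
    local_force_prime,
    max_growth_rate,
    regime_report,
    topological_eigenvalues,
)
from graphsh.dynamics import jacobian
from graphsh.operators import laplacian_spectrum


class TestLocalForce:
    def test_trivial_state_is_root_for_all_mu(self):
        for mu in (-2.0, -0.5, 0.0, 1.3):
            assert local_force(0.0, ModelParams(mu=mu)) == 0.0

    def test_upper_flat_state_at_mu_minus_one(self):
        assert local_force(1.5, ModelParams(mu=-1.0)) == pytest.approx(0.0, abs=1e-12)

    @given(
        u=st.floats(-3, 3),
        mu=st.floats(-2, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_derivative_consistent_with_finite_differences(self, u, mu):
        p = ModelParams(mu=mu)
        h = 1e-6
        fd = (local_force(u + h, p) - local_force(u - h, p)) / (2 * h)
        assert local_force_prime(u, p) == pytest.approx(fd, abs=1e-4)

    def test_derivative_at_origin(self):
        assert local_force_prime(0.0, ModelParams(mu=0.3)) == -1.3


class TestFlatStates:
    def test_no_nonzero_states_for_positive_mu(self):
        fs = flat_states(ModelParams(mu=0.0))
        assert fs.u0 == 0.0 and not fs.nonzero_exist

    def test_roots_at_mu_minus_one(self):
        fs = flat_states(ModelParams(mu=-1.0))
        assert fs.u_plus == pytest.approx(1.5)
        assert fs.u_minus == pytest.approx(0.0)

    def test_double_root_at_saddle_node(self):
        fs = flat_states(ModelParams(mu=-0.4375))
        assert fs.u_plus == pytest.approx(0.75)
        assert fs.u_minus == pytest.approx(0.75)

    @given(mu=st.floats(-3, -0.44))
    @settings(max_examples=30, deadline=None)
    def test_returned_roots_satisfy_force_equation(self, mu):
        p = ModelParams(mu=mu)
        fs = flat_states(p)
        for root in (fs.u_plus, fs.u_minus):
            assert abs(local_force(root, p)) < 1e-10


class TestDispersion:
    @pytest.mark.parametrize(
        "mu,lam,expected",
        [(0.5, -1.0, -0.5), (-0.25, -1.0, 0.25), (0.7, 0.0, -1.7)],
    )
    def test_trivial_state_growth_rates(self, mu, lam, expected):
        assert dispersion(0.0, ModelParams(mu=mu), lam) == pytest.approx(expected)

    def test_trivial_state_stable_for_positive_mu(self, er60):
        lmax, _ = max_growth_rate(er60, 0.0, ModelParams(mu=0.1))
        assert lmax < 0

    def test_c4_discrete_spectrum_maximum(self, c4):
        # modes {0,-2,-2,-4} all miss the continuum optimum at -1
        lmax, lcrit = max_growth_rate(c4, 0.0, ModelParams(mu=-0.25))
        assert lmax == pytest.approx(-0.75)
        # Lambda = 0 and Lambda = -2 tie exactly; either may be reported
        assert min(abs(lcrit), abs(lcrit + 2)) < 1e-9

    def test_large_ba_spectrum_is_dense_near_critical_mode(self):
        from graphsh.graphs import generate_ba

        net = generate_ba(2000, 1, seed=5)
        lmax, _ = max_growth_rate(net, 0.0, ModelParams(mu=-0.25))
        assert abs(lmax - 0.25) < 0.05

    def test_matches_jacobian_rayleigh_quotient_on_flat_state(self, c4):
        # cross-module consistency: J phi = dispersion(Lambda) phi at flat u
        p = ModelParams(mu=-1.0)
        u = np.full(4, 1.5)
        j = jacobian(c4, u, p).toarray()
        sd = laplacian_spectrum(c4)
        for lam, phi in zip(sd.eigenvalues, sd.eigenvectors.T):
            expected = dispersion(1.5, p, lam)
            assert np.allclose(j @ phi, expected * phi, atol=1e-10)


class TestBifurcationPoints:
    def test_printed_values_reproduced_to_two_decimals(self):
        bp = flat_bifurcation_points(1.5)
        assert round(bp.mu0, 2) == 0.0
        assert round(bp.mu1, 2) == -0.44
        assert round(bp.mu_plus, 2) == -0.62
        assert round(bp.mu_minus, 2) == -1.82

    def test_thresholds_satisfy_defining_equations(self):
        bp = flat_bifurcation_points(1.5)
        for mu in (bp.mu_plus, bp.mu_minus):
            p = ModelParams(mu=mu)
            fs = flat_states(p)
            roots = [fs.u_plus, fs.u_minus]
            # one branch root must sit exactly at the marginal slope f' = -1
            assert min(abs(local_force_prime(r, p) + 1.0) for r in roots) < 1e-9

    def test_ordering(self):
        bp = flat_bifurcation_points(1.5)
        assert bp.mu_minus < bp.mu_plus < bp.mu1 < bp.mu0


class TestTopologicalEigenvalues:
    def test_origin_collision_at_mu_minus_one(self):
        q = np.sort_complex(topological_eigenvalues(-1.0).quartet)
        assert np.allclose(q, [-np.sqrt(2) * 1j, 0, 0, np.sqrt(2) * 1j], atol=1e-10)

    def test_pairwise_imaginary_collision_at_zero(self):
        q = topological_eigenvalues(0.0).quartet
        assert np.allclose(np.sort(q.imag), [-1, -1, 1, 1], atol=1e-12)
        assert np.allclose(q.real, 0.0)

    def test_imaginary_quartet_in_subcritical_window(self):
        q = topological_eigenvalues(-0.25).quartet
        assert np.allclose(q.real, 0.0)
        assert np.allclose(
            np.sort(np.abs(q.imag)),
            np.sort([np.sqrt(0.5), np.sqrt(0.5), np.sqrt(1.5), np.sqrt(1.5)]),
        )

    def test_complex_quartet_for_positive_mu(self):
        q = topological_eigenvalues(0.5).quartet
        assert np.all(np.abs(q.real) > 0) and np.all(np.abs(q.imag) > 0)

    def test_real_pair_below_minus_one(self):
        q = topological_eigenvalues(-2.0).quartet
        assert (np.abs(q.imag) < 1e-12).sum() == 2

    @given(mu=st.floats(-3, 2))
    @settings(max_examples=50, deadline=None)
    def test_quartet_symmetry_and_defining_quartic(self, mu):
        q = topological_eigenvalues(mu).quartet
        # closed under negation and conjugation
        for s in q:
            assert np.min(np.abs(q + s)) < 1e-9
            assert np.min(np.abs(q - np.conj(s))) < 1e-9
        # each root satisfies (1 + s^2)^2 = -mu
        assert np.max(np.abs((1 + q**2) ** 2 + mu)) < 1e-10


def test_regime_report_is_valid_json():
    doc = json.loads(regime_report([-0.5, 0.0, 0.2]))
    assert doc["-0.5"]["regime"] == "global-pattern"
    assert doc["0.2"]["regime"] == "localized-capable"
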