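import numpy as np
import pytest

from graphsh.dynamics import (
    BlowUpError,
    ConvergenceError,
    Pattern,
    Stimulus,
    activation_energy,
    best_connected_node,
    integrate,
    jacobian,
    make_stimulus,
    newton_steady,
    pattern_stability,
    read_pattern,
    relax_to_stable,
    rhs,
    unstable_mode_count,
    write_pattern,
)
from graphsh.graphs import single_node_network
from graphsh.local_dynamics import ModelParams, flat_states, local_force
from graphsh.operators import interaction_current


class TestRhs:
    def test_zero_at_resting_state(self, er60):
        p = ModelParams(mu=0.3)
        assert np.max(np.abs(rhs(er60, np.zeros(er60.node_count), p))) == 0.0

    def test_zero_at_nonzero_flat_state(self, er60):
        p = ModelParams(mu=-1.0)
        u = np.full(er60.node_count, flat_states(p).u_plus)
        assert np.max(np.abs(rhs(er60, u, p))) < 1e-12

    def test_matches_explicit_nodewise_composition(self, ba50):
        # independent path: per-node local force plus explicit neighbor sums
        rng = np.random.default_rng(1)
        u = rng.normal(size=ba50.node_count)
        p = ModelParams(mu=-0.3)
        a = ba50.adjacency.toarray()
        k = a.sum(axis=1)
        oracle = np.empty_like(u)
        for i in range(ba50.node_count):
            l2u = a[i] @ u - k[i] * u[i]
            l2 = a @ u - k * u
            l4u = a[i] @ l2 - k[i] * l2[i]
            oracle[i] = local_force(u[i], p) - (2 * l2u + l4u)
        assert np.allclose(rhs(ba50, u, p), oracle, atol=1e-12)


class TestIntegrate:
    def test_resting_state_is_fixed(self, ba50):
        p = ModelParams(mu=0.2)
        pat, summ = integrate(ba50, np.zeros(50), p, t_max=5.0)
        assert pat.energy == 0.0 and summ.settled

    def test_small_perturbation_decays_for_positive_mu(self, ba200):
        rng = np.random.default_rng(3)
        u0 = 0.01 * rng.uniform(-1, 1, size=200)
        pat, _ = integrate(ba200, u0, ModelParams(mu=0.1))
        assert pat.energy < 1e-10

    def test_turing_pattern_grows_for_negative_mu(self, ba200):
        rng = np.random.default_rng(3)
        u0 = 0.01 * rng.uniform(-1, 1, size=200)
        pat, _ = integrate(ba200, u0, ModelParams(mu=-0.25), settle_tol=1e-6)
        assert pat.energy > 1.0
        assert pat.residual_norm < 1e-8  # polished

    def test_endpoint_energy_reproducible_across_dt(self, ba50):
        rng = np.random.default_rng(4)
        u0 = rng.uniform(-0.5, 0.5, size=50)
        p = ModelParams(mu=-0.25)
        energies = []
        for dt in (0.01, 0.005):
            pat, _ = integrate(ba50, u0, p, dt=dt, polish=False)
            energies.append(pat.energy)
        assert energies[0] == pytest.approx(energies[1], rel=1e-4)

    def test_blow_up_guard_attaches_last_state(self, path3):
        p = ModelParams(mu=0.0)
        with pytest.raises(BlowUpError) as exc:
            integrate(path3, np.full(3, 500.0), p, dt=0.5)
        assert np.all(np.isfinite(exc.value.last_state))

    def test_invalid_dt(self, path3):
        with pytest.raises(ValueError):
            integrate(path3, np.zeros(3), ModelParams(mu=0.0), dt=0.0)


class TestNewtonSteady:
    def test_converges_to_flat_state_from_noisy_start(self, er60):
        p = ModelParams(mu=-1.0)
        rng = np.random.default_rng(5)
        u0 = 1.5 + 1e-3 * rng.uniform(-1, 1, size=er60.node_count)
        pat = newton_steady(er60, u0, p)
        assert np.allclose(pat.u, 1.5, atol=1e-8)
        assert pat.residual_norm < 1e-10

    def test_zero_start_returns_zero(self, ba50):
        pat = newton_steady(ba50, np.zeros(50), ModelParams(mu=0.7))
        assert pat.energy == 0.0

    def test_single_node_recovers_scalar_roots(self):
        net = single_node_network()
        p = ModelParams(mu=-1.0)
        pat = newton_steady(net, np.array([1.4]), p)
        assert pat.u[0] == pytest.approx(1.5, abs=1e-9)
        # u = 0 is a double root at mu = -1 (fold of the flat branch with
        # the trivial state): Newton converges linearly, residual contract
        # still holds
        pat = newton_steady(net, np.array([0.1]), p)
        assert abs(pat.u[0]) < 1e-4
        assert pat.residual_norm < 1e-10

    def test_nonconvergence_is_reported(self, ba50):
        with pytest.raises(ConvergenceError):
            newton_steady(ba50, np.full(50, 0.9), ModelParams(mu=0.5), max_iter=1)

    def test_polish_does_not_move_settled_state(self, ba200):
        rng = np.random.default_rng(3)
        u0 = 0.01 * rng.uniform(-1, 1, size=200)
        p = ModelParams(mu=-0.25)
        raw, _ = integrate(ba200, u0, p, settle_tol=1e-8, polish=False)
        polished = newton_steady(ba200, raw.u, p)
        assert polished.residual_norm < 1e-10
        assert np.max(np.abs(polished.u - raw.u)) < 1e-6


class TestStimulus:
    def test_best_connected_resolves_star_center(self, star4):
        assert best_connected_node(star4) == 0

    def test_path_stimulus_covers_two_jumps(self, path3):
        u = make_stimulus(path3, 0, Stimulus(amplitude=2.0))
        assert np.array_equal(u, [2.0, 2.0, 2.0])

    def test_center_exclusion(self, path3):
        u = make_stimulus(path3, 0, Stimulus(amplitude=2.0, include_center=False))
        assert np.array_equal(u, [0.0, 2.0, 2.0])

    def test_seeded_noise_is_deterministic(self, ba50):
        s = Stimulus(amplitude=1.0, noise_amplitude=0.3, seed=9)
        u1 = make_stimulus(ba50, "best-connected", s)
        u2 = make_stimulus(ba50, "best-connected", s)
        assert np.array_equal(u1, u2)
        u3 = make_stimulus(ba50, "best-connected", Stimulus(1.0, 0.3, seed=10))
        assert not np.array_equal(u1, u3)

    def test_noise_restricted_to_support(self, ba50):
        s = Stimulus(amplitude=1.0, noise_amplitude=0.3, seed=9)
        u = make_stimulus(ba50, "best-connected", s)
        off = make_stimulus(ba50, "best-connected", Stimulus(amplitude=1.0))
        assert np.all(u[off == 0] == 0)


class TestStability:
    def test_resting_state_stable_for_positive_mu(self, ba200):
        p = ModelParams(mu=0.1)
        pat = Pattern.from_state(ba200, np.zeros(200), p)
        assert pattern_stability(ba200, pat, p) < 0

    def test_resting_state_unstable_for_negative_mu(self, ba200):
        p = ModelParams(mu=-0.25)
        pat = Pattern.from_state(ba200, np.zeros(200), p)
        assert pattern_stability(ba200, pat, p) > 0

    def test_upper_flat_branch_stable_only_below_mu_plus(self, er60):
        # u_+ restabilizes below mu_+ ~ -0.6185 and is unstable between
        # mu_+ and the saddle-node at mu_1
        for mu, expect_stable in ((-1.0, True), (-0.5, False)):
            p = ModelParams(mu=mu)
            u = np.full(er60.node_count, flat_states(p).u_plus)
            pat = Pattern.from_state(er60, u, p)
            assert (pattern_stability(er60, pat, p) < 0) is expect_stable

    def test_unstable_mode_count_matches_dispersion_sign(self, c4):
        from graphsh.local_dynamics import dispersion
        from graphsh.operators import laplacian_spectrum

        p = ModelParams(mu=-0.25)
        pat = Pattern.from_state(c4, np.zeros(4), p)
        lams = laplacian_spectrum(c4).eigenvalues
        expected = int((dispersion(0.0, p, lams) > 0).sum())
        assert unstable_mode_count(c4, pat, p) == expected

    def test_relax_to_stable_escapes_symmetric_saddle(self, ba200):
        p = ModelParams(mu=0.1)
        u0 = make_stimulus(ba200, "best-connected", Stimulus(amplitude=2.0))
        pat, lead = relax_to_stable(ba200, u0, p, settle_tol=1e-6)
        assert lead < 1e-8
        assert pat.energy > 1.0  # a genuine localized state, not rest


def test_activation_energy_zero_iff_resting():
    assert activation_energy(np.zeros(5)) == 0.0
    assert activation_energy(np.array([0.0, 0.1])) > 0.0


def test_pattern_file_round_trip(tmp_path, path3):
    p = ModelParams(mu=-1.0)
    pat = Pattern.from_state(path3, np.array([0.1, -0.2, 0.3]), p)
    write_pattern(pat, tmp_path / "pat.csv", meta={"seed": 3})
    u, meta = read_pattern(tmp_path / "pat.csv")
    assert np.allclose(u, pat.u)
    assert meta["mu"] == -1.0 and meta["seed"] == 3


def test_jacobian_is_symmetric(self=None):
    from graphsh.graphs import generate_er

    net = generate_er(40, 4.0, 8)
    rng = np.random.default_rng(2)
    j = jacobian(net, rng.normal(size=net.node_count), ModelParams(mu=0.2))
    assert abs(j - j.T).max() == 0.0
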