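"""Time integration, steady-state solving, stimuli, and pattern stability.

The full nodal system is du/dt = F(u) with

    F_i(u) = f(u_i, mu) - [(2 L2 + L4) u]_i.

The bi-Laplacian makes the system stiff (explicit stepping would require
dt ~ 1/Lambda_max^2), so the integrator treats the linear coupling
implicitly and the local force explicitly, factorizing (I - dt C) once per
(network, dt).  Steady states are polished with a Newton iteration on F,
whose Jacobian J = diag(f'(u)) + C is symmetric, so pattern stability is
decided by its most-positive eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import Network
from .local_dynamics import ModelParams, local_force, local_force_prime
from .operators import coupling, interaction_current

__all__ = [
    "Pattern",
    "Stimulus",
    "TrajectorySummary",
    "rhs",
    "jacobian",
    "integrate",
    "newton_steady",
    "make_stimulus",
    "best_connected_node",
    "pattern_stability",
    "relax_to_stable",
    "activation_energy",
    "BlowUpError",
    "ConvergenceError",
    "FoldProximityError",
]

OVERFLOW_GUARD = 1e6
#: dense eigensolves below this size; iterative extremal solve above
_DENSE_EIG_LIMIT = 1500


class BlowUpError(RuntimeError):
    """Trajectory exceeded the overflow guard; carries the last finite state."""

    def __init__(self, msg: str, last_state: np.ndarray):
        super().__init__(msg)
        self.last_state = last_state


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the requested tolerance."""


class FoldProximityError(RuntimeError):
    """Jacobian is (numerically) singular — likely near a saddle-node;
    use the continuation module's bordered system instead."""


def activation_energy(u: np.ndarray) -> float:
    """Activation energy E = sum_i u_i^2 (squared Euclidean norm), the
    measure plotted on snaking diagrams.  Zero iff the state is resting."""
    u = np.asarray(u, dtype=float)
    return float(u @ u)


@dataclass(frozen=True)
class Pattern:
    """A nodal state together with the parameter at which it is (meant to
    be) stationary, its steady-state residual, and its activation energy."""

    u: np.ndarray
    mu: float
    residual_norm: float
    energy: float

    @classmethod
    def from_state(cls, net: Network, u: np.ndarray, params: ModelParams) -> "Pattern":
        u = np.asarray(u, dtype=float)
        res = float(np.max(np.abs(rhs(net, u, params))))
        return cls(u=u, mu=params.mu, residual_norm=res, energy=activation_energy(u))

    def is_stationary(self, tol: float = 1e-8) -> bool:
        return self.residual_norm < tol


@dataclass(frozen=True)
class Stimulus:
    """Step-like input: ``amplitude`` on a topological neighbourhood,
    optional uniform noise of half-width ``noise_amplitude`` on the same
    support, drawn with ``seed``."""

    amplitude: float
    noise_amplitude: float = 0.0
    seed: int = 0
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


@dataclass
class TrajectorySummary:
    n_steps: int
    t_final: float
    settled: bool
    final_rate: float
    energy_history: list = field(default_factory=list)


def rhs(net: Network, u: np.ndarray, params: ModelParams) -> np.ndarray:
    """F(u) = f(u, mu) + I(u): local force plus interaction current."""
    return local_force(u, params) + interaction_current(net, u)


def jacobian(net: Network, u: np.ndarray, params: ModelParams) -> sp.csr_array:
    """J = diag(f'(u)) - (2 L2 + L4); symmetric."""
    fp = local_force_prime(np.asarray(u, dtype=float), params)
    fp = np.atleast_1d(fp)
    return sp.csr_array(
        coupling(net).matrix + sp.diags_array(fp, format="csr")
    )


def _implicit_factor(net: Network, dt: float):
    """LU factorization of (I - dt C), cached per (network, dt)."""
    key = ("imex_lu", dt)
    if key not in net._cache:
        n = net.node_count
        m = sp.eye_array(n, format="csc") - dt * coupling(net).matrix.tocsc()
        net._cache[key] = spla.splu(sp.csc_matrix(m))
    return net._cache[key]


def integrate(
    net: Network,
    u0: np.ndarray,
    params: ModelParams,
    dt: float = 0.05,
    t_max: float = 2000.0,
    settle_tol: float = 1e-8,
    polish: bool = True,
    record_every: int = 0,
) -> tuple[Pattern, TrajectorySummary]:
    """Relax u0 toward equilibrium with semi-implicit (IMEX) stepping.

    Each step solves (I - dt C) u_{n+1} = u_n + dt f(u_n, mu).  The run
    terminates when the instantaneous rate ||F(u)||_inf drops below
    ``settle_tol`` or at ``t_max``; the endpoint is then polished by
    :func:`newton_steady` (disable with ``polish=False`` to inspect the
    raw integrator endpoint).

    Raises :class:`BlowUpError` (with the last finite state attached) if
    the trajectory exceeds the overflow guard.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u0, dtype=float).copy()
    lu = _implicit_factor(net, dt)
    n_steps = int(np.ceil(t_max / dt))
    summary = TrajectorySummary(n_steps=0, t_final=0.0, settled=False, final_rate=np.inf)
    rate = float(np.max(np.abs(rhs(net, u, params))))
    for step in range(1, n_steps + 1):
        u_new = lu.solve(u + dt * local_force(u, params))
        if not np.all(np.isfinite(u_new)) or np.max(np.abs(u_new)) > OVERFLOW_GUARD:
            raise BlowUpError(
                f"trajectory exceeded overflow guard at t={step * dt:.3f}", u
            )
        u = u_new
        rate = float(np.max(np.abs(rhs(net, u, params))))
        summary.n_steps = step
        summary.t_final = step * dt
        if record_every and step % record_every == 0:
            summary.energy_history.append((step * dt, activation_energy(u)))
        if rate < settle_tol:
            summary.settled = True
            break
    summary.final_rate = rate
    if polish and summary.settled:
        try:
            pattern = newton_steady(net, u, params)
        except (ConvergenceError, FoldProximityError):
            pattern = Pattern.from_state(net, u, params)
    else:
        pattern = Pattern.from_state(net, u, params)
    return pattern, summary


def newton_steady(
    net: Network,
    u0: np.ndarray,
    params: ModelParams,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> Pattern:
    """Newton iteration for F(u) = 0 starting from u0.

    Raises :class:`ConvergenceError` if the residual does not fall below
    ``tol`` in ``max_iter`` iterations and :class:`FoldProximityError` on
    a numerically singular Jacobian (the caller should switch to the
    bordered continuation system near saddle-nodes).
    """
    u = np.asarray(u0, dtype=float).copy()
    if not np.all(np.isfinite(u)):
        raise ValueError("initial state must be finite")
    for _ in range(max_iter):
        r = rhs(net, u, params)
        if np.max(np.abs(r)) < tol:
            return Pattern.from_state(net, u, params)
        j = jacobian(net, u, params).tocsc()
        with np.errstate(divide="raise", invalid="raise"):
            try:
                du = spla.spsolve(sp.csc_matrix(j), -r)
            except (RuntimeError, FloatingPointError) as exc:
                raise FoldProximityError(f"singular Jacobian: {exc}") from exc
        if not np.all(np.isfinite(du)):
            raise FoldProximityError("singular Jacobian (non-finite Newton step)")
        u = u + du
    r = rhs(net, u, params)
    if np.max(np.abs(r)) < tol:
        return Pattern.from_state(net, u, params)
    raise ConvergenceError(
        f"Newton did not converge: residual {np.max(np.abs(r)):.3e} after "
        f"{max_iter} iterations"
    )


def best_connected_node(net: Network) -> int:
    """Node of maximal degree; ties broken by lowest id."""
    return int(np.argmax(net.degrees))


def stimulus_support(net: Network, center: int, include_center: bool = True) -> np.ndarray:
    """Nodes within two jumps of ``center`` (the stimulated neighbourhood)."""
    a = net.adjacency
    ind = np.zeros(net.node_count)
    ind[center] = 1.0
    one = np.minimum(a @ ind, 1.0)
    two = np.minimum(a @ one, 1.0)
    support = np.minimum(one + two, 1.0)
    support[center] = 1.0 if include_center else 0.0
    return np.flatnonzero(support > 0)


def make_stimulus(net: Network, center: int | str, stim: Stimulus) -> np.ndarray:
    """Build a step-like stimulus vector: ``amplitude`` on the one- and
    two-jump neighbourhood of ``center`` (plus the centre itself by
    default), zero elsewhere, with seeded uniform noise on the support.

    ``center='best-connected'`` resolves to the highest-degree node.
    """
    if center == "best-connected":
        center = best_connected_node(net)
    center = int(center)
    if not 0 <= center < net.node_count:
        raise ValueError(f"center {center} out of range")
    support = stimulus_support(net, center, include_center=stim.include_center)
    u = np.zeros(net.node_count)
    u[support] = stim.amplitude
    if stim.noise_amplitude > 0:
        rng = np.random.default_rng(stim.seed)
        u[support] += rng.uniform(
            -stim.noise_amplitude, stim.noise_amplitude, size=support.size
        )
    return u


def pattern_stability(
    net: Network,
    pattern: Pattern,
    params: ModelParams,
    return_vector: bool = False,
):
    """Most-positive eigenvalue of the Jacobian at a stationary pattern.

    The pattern is linearly stable iff the returned value is negative
    (within tolerance).  Dense solve for small networks; iterative
    largest-algebraic solve for large ones.  With ``return_vector`` the
    corresponding eigenvector is returned as well (sign fixed so its
    largest-magnitude component is positive).
    """
    j = jacobian(net, pattern.u, params)
    n = net.node_count
    if n <= _DENSE_EIG_LIMIT:
        if return_vector:
            vals, vecs = np.linalg.eigh(j.toarray())
            v = vecs[:, -1]
        else:
            return float(np.linalg.eigvalsh(j.toarray())[-1])
        lead = float(vals[-1])
    else:
        vals, vecs = spla.eigsh(sp.csc_matrix(j), k=1, which="LA")
        lead, v = float(vals[0]), vecs[:, 0]
        if not return_vector:
            return lead
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return lead, v


def unstable_mode_count(
    net: Network, pattern: Pattern, params: ModelParams, tol: float = 1e-8
) -> int:
    """Number of positive Jacobian eigenvalues at a stationary pattern.

    Across a saddle-node fold this count changes by exactly one; on a
    snaking branch it distinguishes singly- from multiply-unstable
    segments (only the count-zero segments are attractors).
    """
    j = jacobian(net, pattern.u, params)
    if net.node_count <= _DENSE_EIG_LIMIT:
        return int((np.linalg.eigvalsh(j.toarray()) > tol).sum())
    vals = spla.eigsh(
        sp.csc_matrix(j), k=min(64, net.node_count - 2), which="LA",
        return_eigenvectors=False,
    )
    return int((vals > tol).sum())


def relax_to_stable(
    net: Network,
    u0: np.ndarray,
    params: ModelParams,
    dt: float = 0.05,
    t_max: float = 2000.0,
    settle_tol: float = 1e-8,
    stability_tol: float = 1e-8,
    kick: float = 1e-3,
    max_kicks: int = 5,
) -> tuple[Pattern, float]:
    """Relax to a *linearly stable* equilibrium.

    Symmetric stimuli can relax onto saddle equilibria that are invariant
    under a graph automorphism of the stimulated neighbourhood: the
    noiseless dynamics stay on the symmetric manifold, where the saddle
    attracts, although it is unstable to symmetry-breaking perturbations.
    This helper integrates, checks the leading Jacobian eigenvalue, and —
    if it is positive — nudges the state by ``kick`` along the unstable
    eigenvector (deterministic sign) and re-relaxes, so the returned
    pattern is always a genuinely stable equilibrium (or the last iterate,
    with its leading eigenvalue, if ``max_kicks`` is exhausted).

    Returns (pattern, leading eigenvalue).
    """
    pattern, _ = integrate(
        net, u0, params, dt=dt, t_max=t_max, settle_tol=settle_tol
    )
    for _ in range(max_kicks):
        lead, vec = pattern_stability(net, pattern, params, return_vector=True)
        if lead < stability_tol:
            return pattern, lead
        pattern, _ = integrate(
            net, pattern.u + kick * vec, params, dt=dt, t_max=t_max,
            settle_tol=settle_tol,
        )
    lead = pattern_stability(net, pattern, params)
    return pattern, lead


def write_pattern(pattern: Pattern, path, meta: dict | None = None) -> None:
    """Persist a pattern as a node,u table preceded by a JSON header block."""
    import json

    header = {
        "mu": pattern.mu,
        "energy": pattern.energy,
        "residual_norm": pattern.residual_norm,
    }
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("node,u\n")
        for i, v in enumerate(pattern.u):
            fh.write(f"{i},{v:.17g}\n")


def read_pattern(path) -> tuple[np.ndarray, dict]:
    """Read a pattern file written by :func:`write_pattern`."""
    import json

    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        import pandas as pd

        df = pd.read_csv(fh)
    u = df.sort_values("node")["u"].to_numpy()
    return u, meta
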