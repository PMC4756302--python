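"""Pseudo-arclength continuation of stationary states in mu.

Localized stationary states of the network Swift-Hohenberg model organize
into "snaking" branches: as the branch winds back and forth in mu between
successive saddle-node folds, the activated cluster grows node by node and
the activation energy climbs.  Stationary points (u, mu) with F(u, mu) = 0
are traced by a predictor-corrector scheme:

* predictor: secant extrapolation along the branch (first step: the
  tangent from the bordered Jacobian null space);
* corrector: Newton on the bordered system
      [ F(u, mu) = 0 ; tangent . (x - x_pred_base) - ds = 0 ],
  which stays regular through folds where the plain Jacobian is singular.

The arclength step ds adapts: halved on corrector failure, doubled after
fast convergence, clamped to [ds0/16, 4 ds0].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dynamics import Pattern, activation_energy, jacobian, pattern_stability, rhs
from .graphs import Network
from .local_dynamics import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "BranchPoint",
    "Branch",
    "continue_branch",
    "detect_folds",
    "snaking_diagram",
]

_STAB_TOL = 1e-8


@dataclass(frozen=True)
class BranchPoint:
    pattern: Pattern
    mu: float
    energy: float
    stable: bool | None
    tangent: np.ndarray  # unit vector in (u, mu) space
    leading_eigenvalue: float | None = None


@dataclass
class Branch:
    points: list[BranchPoint] = field(default_factory=list)
    truncated: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def mus(self) -> np.ndarray:
        return np.array([p.mu for p in self.points])

    @property
    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.points])

    @property
    def folds(self) -> list[int]:
        return detect_folds(self)

    def __len__(self) -> int:
        return len(self.points)


def _bordered_solve(j: sp.csr_array, f_mu: np.ndarray, t_u: np.ndarray,
                    t_mu: float, r1: np.ndarray, r2: float) -> tuple[np.ndarray, float]:
    """Solve the (N+1) bordered linear system
        [ J    F_mu ] [du ]   [ -r1 ]
        [ t_u  t_mu ] [dmu] = [ -r2 ].
    """
    n = j.shape[0]
    top = sp.hstack([j, sp.csr_array(f_mu.reshape(n, 1))])
    bottom = sp.hstack(
        [sp.csr_array(t_u.reshape(1, n)), sp.csr_array([[t_mu]])]
    )
    m = sp.vstack([top, bottom]).tocsc()
    sol = spla.spsolve(sp.csc_matrix(m), np.concatenate([-r1, [-r2]]))
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("bordered solve produced non-finite step")
    return sol[:n], float(sol[n])


def _initial_tangent(
    net: Network, u: np.ndarray, params: ModelParams, direction: int
) -> np.ndarray:
    """Unit tangent of the solution curve at a regular point.

    Differentiating F(u, mu) = 0 gives J du/dmu = -F_mu with F_mu = -u,
    so the tangent is (J^{-1} u, 1) normalized; ``direction`` selects the
    sign of the mu component.
    """
    n = len(u)
    j = jacobian(net, u, params).tocsc()
    du = spla.spsolve(sp.csc_matrix(j), u)  # = -J^{-1} F_mu
    t = np.concatenate([du, [1.0]])
    t /= np.linalg.norm(t)
    return direction * t


def continue_branch(
    net: Network,
    start: Pattern,
    params: ModelParams,
    ds: float,
    n_steps: int,
    direction: int = -1,
    newton_tol: float = 1e-10,
    max_newton: int = 25,
    ds_min_factor: float = 256.0,
    accept_tol: float = 1e-8,
    stability_every: int = 1,
    mu_range: tuple[float, float] | None = None,
    adapt: bool = True,
) -> Branch:
    """Trace a branch of stationary states from ``start``.

    Parameters
    ----------
    start
        A stationary pattern (residual below ``accept_tol``) at its mu.
    ds
        Nominal arclength step; u and mu are weighted equally in the
        arclength metric.
    n_steps
        Maximum number of accepted points after the start.
    direction
        Sign of the initial mu movement (+1 increases mu first).
    stability_every
        Tag stability every k-th accepted point (1 = every point); other
        points inherit the last computed tag.
    mu_range
        Optional (lo, hi); the trace stops once mu leaves this window.
    adapt
        Enable step adaptation (halve on corrector failure, double after
        fast convergence, clamp to [ds/ds_min_factor, 4 ds]).  With
        ``adapt=False`` the step is fixed, which makes the trace exactly
        reversible.
    """
    if start.residual_norm > accept_tol:
        raise ValueError(
            f"starting pattern is not stationary (residual {start.residual_norm:.2e})"
        )
    n = net.node_count
    b = params.b
    ds0 = ds
    if adapt:
        ds_min, ds_max = ds0 / ds_min_factor, 4.0 * ds0
    else:
        ds_min = ds_max = ds0

    def stab(pat: Pattern, mu: float) -> float:
        return pattern_stability(net, pat, ModelParams(mu=mu, b=b))

    u0, mu0 = start.u.copy(), start.mu
    t = _initial_tangent(net, u0, ModelParams(mu=mu0, b=b), direction)
    lead = stab(start, mu0)
    branch = Branch(
        provenance={
            "start_mu": mu0,
            "start_energy": start.energy,
            "ds": ds0,
            "n_steps": n_steps,
            "direction": direction,
        }
    )
    branch.points.append(
        BranchPoint(
            pattern=start,
            mu=mu0,
            energy=start.energy,
            stable=lead < _STAB_TOL,
            tangent=t,
            leading_eigenvalue=lead,
        )
    )

    x_prev = np.concatenate([u0, [mu0]])
    last_lead = lead
    accepted = 0
    while accepted < n_steps:
        t = branch.points[-1].tangent
        converged = False
        while True:
            x_pred = x_prev + ds * t
            u, mu = x_pred[:n].copy(), float(x_pred[n])
            iters = 0
            ok = False
            for iters in range(1, max_newton + 1):
                p = ModelParams(mu=mu, b=b)
                r1 = rhs(net, u, p)
                r2 = float(t[:n] @ (u - x_prev[:n]) + t[n] * (mu - x_prev[n]) - ds)
                if max(np.max(np.abs(r1)), abs(r2)) < newton_tol:
                    ok = True
                    break
                try:
                    du, dmu = _bordered_solve(
                        jacobian(net, u, p), -u, t[:n], t[n], r1, r2
                    )
                except RuntimeError:
                    break
                u = u + du
                mu = mu + dmu
                if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > 1e6:
                    break
            if ok:
                # branch locality: a corrector that lands far from the
                # predictor has jumped to a different branch — reject it
                step_len = np.linalg.norm(
                    np.concatenate([u, [mu]]) - x_prev
                )
                if step_len <= 2.0 * ds:
                    converged = True
                    break
                ok = False
            if ds <= ds_min * (1 + 1e-12):
                break
            ds = max(ds / 2.0, ds_min)
        if not converged:
            branch.truncated = True
            logger.warning(
                "continuation truncated after %d points (corrector failed at "
                "minimum step)", len(branch.points)
            )
            break

        x_new = np.concatenate([u, [mu]])
        secant = x_new - x_prev
        t_new = secant / np.linalg.norm(secant)
        pat = Pattern.from_state(net, u, ModelParams(mu=mu, b=b))
        accepted += 1
        if stability_every and accepted % stability_every == 0:
            last_lead = stab(pat, mu)
        branch.points.append(
            BranchPoint(
                pattern=pat,
                mu=mu,
                energy=pat.energy,
                stable=last_lead < _STAB_TOL,
                tangent=t_new,
                leading_eigenvalue=last_lead,
            )
        )
        x_prev = x_new
        if adapt and iters <= 3:
            ds = min(ds * 2.0, ds_max)
        if mu_range is not None and not (mu_range[0] <= mu <= mu_range[1]):
            break
    return branch


def detect_folds(branch: Branch | np.ndarray) -> list[int]:
    """Indices where the sign of consecutive mu increments flips
    (saddle-node folds along the branch).  Zero increments inherit the
    previous direction."""
    mus = branch.mus if isinstance(branch, Branch) else np.asarray(branch, dtype=float)
    if len(mus) < 3:
        return []
    dmu = np.diff(mus)
    folds = []
    prev_sign = 0.0
    for i, d in enumerate(dmu):
        s = np.sign(d)
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            folds.append(i)  # fold at the turning point between segments
        prev_sign = s
    return folds


def snaking_diagram(branch: Branch) -> pd.DataFrame:
    """Serialize a branch as a (mu, energy, stable, fold_flag) table.

    Along a snaking branch, stability should alternate at each saddle-node
    fold (standard exchange of stability); a violation is logged as a
    warning but the diagram is still produced.
    """
    if len(branch) == 0:
        raise ValueError("empty branch")
    folds = detect_folds(branch)
    fold_flag = np.zeros(len(branch), dtype=bool)
    fold_flag[folds] = True
    df = pd.DataFrame(
        {
            "mu": branch.mus,
            "energy": branch.energies,
            "stable": [p.stable for p in branch.points],
            "fold_flag": fold_flag,
        }
    )
    for f in folds:
        if 0 < f < len(branch) - 1:
            before = df["stable"].iloc[max(0, f - 2):f].mode()
            after = df["stable"].iloc[f + 1:f + 3].mode()
            if len(before) and len(after) and before.iloc[0] == after.iloc[0]:
                logger.warning(
                    "stability does not alternate across fold at index %d", f
                )
    return df


def stable_plateau_energies(
    branch: Branch, mu_at: float, mu_tol: float
) -> np.ndarray:
    """Energies of the stable branch segments crossing mu = mu_at.

    Each maximal run of consecutive stable points containing a mu within
    ``mu_tol`` of ``mu_at`` contributes the energy of its closest point —
    the discrete "quantized" levels accessible at that parameter value.
    """
    energies = []
    run: list[BranchPoint] = []
    for p in list(branch.points) + [None]:
        if p is not None and p.stable:
            run.append(p)
            continue
        if run:
            ds = [abs(q.mu - mu_at) for q in run]
            i = int(np.argmin(ds))
            if ds[i] <= mu_tol:
                energies.append(run[i].energy)
        run = []
    return np.array(sorted(energies))
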