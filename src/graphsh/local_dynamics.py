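"""On-node nonlinearity, flat states, dispersion relation and bifurcations.

The local force is the cubic double-well derivative

    f(u, mu) = -(1 + mu) u + b u^2 - u^3,        b = 3/2 by default,

so that together with the coupling -(2 L2 + L4) the full model reads

    du/dt = -mu u - (I + L2)^2 u + b u^2 - u^3,

the network analogue of the quadratic-cubic Swift-Hohenberg equation with
the Laplacian standing in for nabla^2.  mu is the bifurcation parameter:
for mu > 0 the resting state u = 0 is linearly stable but supports
localized (homoclinic) activation patterns, while for mu < 0 it is
unstable and global Turing patterns form.

With b = 3/2 the flat-state bifurcation set is, in the dense-spectrum
idealization (Laplacian eigenvalues filling the half-line Lambda <= 0):
mu_0 = 0 (trivial-state threshold), mu_1 = b^2/4 - 1 = -0.4375 (flat
saddle-node), and mu_+ ~= -0.6185, mu_- ~= -1.8190 where the nonzero flat
branches change stability against non-uniform perturbations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .graphs import Network
from .operators import laplacian_spectrum

__all__ = [
    "ModelParams",
    "FlatStates",
    "BifurcationPoints",
    "TopologicalEigenvalues",
    "local_force",
    "local_force_prime",
    "flat_states",
    "dispersion",
    "max_growth_rate",
    "flat_bifurcation_points",
    "topological_eigenvalues",
    "regime_report",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: bifurcation parameter mu and quadratic coefficient b."""

    mu: float
    b: float = 1.5

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("quadratic coefficient b must be positive")


@dataclass(frozen=True)
class FlatStates:
    """Uniform stationary states: u0 = 0 always; u_plus/u_minus when the
    quadratic u^2 - b u + (1 + mu) has real roots."""

    u0: float
    u_plus: float | None
    u_minus: float | None

    @property
    def nonzero_exist(self) -> bool:
        return self.u_plus is not None


@dataclass(frozen=True)
class BifurcationPoints:
    """Flat-state bifurcation values in the dense-spectrum idealization."""

    mu0: float
    mu1: float
    mu_plus: float
    mu_minus: float


@dataclass(frozen=True)
class TopologicalEigenvalues:
    """The four spatial-eigenvalue analogues s solving (1 + s^2)^2 = -mu,
    with the regime they indicate for localized states."""

    quartet: np.ndarray
    regime: str


def local_force(u, params: ModelParams):
    """f(u, mu) = -(1 + mu) u + b u^2 - u^3 (double-well potential force)."""
    u = np.asarray(u, dtype=float)
    out = -(1.0 + params.mu) * u + params.b * u * u - u * u * u
    return out.item() if out.ndim == 0 else out


def local_force_prime(u, params: ModelParams):
    """df/du = -(1 + mu) + 2 b u - 3 u^2."""
    u = np.asarray(u, dtype=float)
    out = -(1.0 + params.mu) + 2.0 * params.b * u - 3.0 * u * u
    return out.item() if out.ndim == 0 else out


def flat_states(params: ModelParams) -> FlatStates:
    """Roots of f(., mu): u0 = 0 and u_pm = [b +- sqrt(b^2 - 4(1+mu))]/2."""
    disc = params.b**2 - 4.0 * (1.0 + params.mu)
    if disc < 0:
        return FlatStates(u0=0.0, u_plus=None, u_minus=None)
    r = math.sqrt(disc)
    return FlatStates(
        u0=0.0, u_plus=(params.b + r) / 2.0, u_minus=(params.b - r) / 2.0
    )


def dispersion(u_bar: float, params: ModelParams, lam) -> float | np.ndarray:
    """Growth rate of the normal mode with Laplacian eigenvalue Lambda,
    linearized about the flat state u_bar:

        lambda(Lambda) = f'(u_bar, mu) - 2 Lambda - Lambda^2.

    The mode is unstable when the rate is positive.  Over continuous
    Lambda <= 0 the maximum sits at Lambda = -1, where
    lambda = f'(u_bar) + 1.
    """
    lam = np.asarray(lam, dtype=float)
    out = local_force_prime(u_bar, params) - 2.0 * lam - lam * lam
    return out.item() if out.ndim == 0 else out


def max_growth_rate(
    net: Network, u_bar: float, params: ModelParams
) -> tuple[float, float]:
    """Maximum of the dispersion relation over the network's actual
    Laplacian spectrum; returns (lambda_max, critical Lambda).

    On finite graphs the spectrum is discrete, so the realized maximum can
    fall short of the dense-spectrum value f'(u_bar) + 1 if no eigenvalue
    lies near Lambda = -1.
    """
    lams = laplacian_spectrum(net).eigenvalues
    rates = dispersion(u_bar, params, lams)
    idx = int(np.argmax(rates))
    return float(rates[idx]), float(lams[idx])


def flat_bifurcation_points(b: float = 1.5) -> BifurcationPoints:
    """Bifurcation values of the flat states for quadratic coefficient b.

    * mu0: the trivial state has f'(0) = -(1+mu); its dense-spectrum
      maximal growth rate f'(0) + 1 = -mu crosses zero at mu0 = 0.
    * mu1: the nonzero flat states collide (saddle-node) when the
      discriminant b^2 - 4(1+mu) vanishes: mu1 = b^2/4 - 1.
    * mu_plus / mu_minus: a nonzero flat branch changes stability against
      non-uniform perturbations when f'(u) + 1 = 0 along f(u) = 0.  On the
      flat branch 1 + mu = b u - u^2, so the condition reduces to
      2 u^2 - b u - 1 = 0; the root u > b/4 belongs to the upper branch.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    mu1 = b * b / 4.0 - 1.0
    r = math.sqrt(b * b + 8.0)
    u_hi = (b + r) / 4.0
    u_lo = (b - r) / 4.0
    mu_plus = b * u_hi - u_hi * u_hi - 1.0
    mu_minus = b * u_lo - u_lo * u_lo - 1.0
    return BifurcationPoints(mu0=0.0, mu1=mu1, mu_plus=mu_plus, mu_minus=mu_minus)


def topological_eigenvalues(mu: float) -> TopologicalEigenvalues:
    """The four roots s of (1 + s^2)^2 = -mu.

    These play the role, on the network, of the spatial eigenvalues of the
    linearization about the resting state in a continuum homoclinic
    analysis.  Their collision structure organizes the localized-pattern
    regimes (a reversible 1:1 resonance at mu = 0):

    * mu > 0:   complex quartet (hyperbolic; localized states possible)
    * mu = 0:   pairwise collision on the imaginary axis at +-i
    * -1<mu<0:  four distinct purely imaginary roots
    * mu = -1:  two roots collide at the origin
    * mu < -1:  a real pair plus an imaginary pair
    """
    s_sq = -1.0 + np.sqrt(complex(-mu))
    s_sq_conj = -1.0 - np.sqrt(complex(-mu))
    roots = []
    for v in (s_sq, s_sq_conj):
        r = np.sqrt(complex(v))
        roots.extend([r, -r])
    quartet = np.array(roots, dtype=complex)
    # canonicalize tiny numerical dust so regime classification is exact
    quartet.real[np.abs(quartet.real) < 1e-12] = 0.0
    quartet.imag[np.abs(quartet.imag) < 1e-12] = 0.0
    if mu > 0:
        regime = "localized-capable"
    elif mu == 0:
        regime = "resonance"
    elif mu > -1:
        regime = "imaginary-quartet"
    elif mu == -1:
        regime = "origin-collision"
    else:
        regime = "real-pair"
    return TopologicalEigenvalues(quartet=quartet, regime=regime)


def regime_report(mus, b: float = 1.5) -> str:
    """JSON report classifying each mu as stable / localized-capable /
    global-pattern for the trivial state."""
    report = {}
    for mu in mus:
        params = ModelParams(mu=float(mu), b=b)
        rate = local_force_prime(0.0, params) + 1.0  # dense-spectrum max
        if mu > 0:
            label = "localized-capable"
        elif rate > 0:
            label = "global-pattern"
        else:
            label = "stable"
        report[f"{mu:g}"] = {
            "regime": label,
            "max_growth_rate_dense": rate,
            "topological_regime": topological_eigenvalues(float(mu)).regime,
        }
    return json.dumps(report, indent=2)
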