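"""Robustness protocols for localized quantized states.

Two stimulus-response experiments probe the quantized character of the
localized patterns:

* an amplitude sweep — stimulate the neighbourhood of a reference node
  with a step signal of increasing amplitude and record the equilibrium
  activation energy.  Small amplitudes relax back to rest; above a
  threshold the response locks onto discrete energy plateaus, and the
  terminal plateau is insensitive to further amplitude increases
  ("robust" quantized state);
* a noise Monte Carlo — perturb the robust stimulus with seeded uniform
  noise of growing noise-to-signal ratio and measure how often the system
  still reaches the base quantized state over many realizations.

Both also back the stability-scan helper producing growth-rate curves of
the flat states over a mu grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    BlowUpError,
    Pattern,
    Stimulus,
    make_stimulus,
    relax_to_stable,
)
from .graphs import Network
from .local_dynamics import ModelParams, flat_states, max_growth_rate

__all__ = [
    "SweepResult",
    "amplitude_sweep",
    "threshold_estimate",
    "noise_monte_carlo",
    "stability_scan",
    "NoThresholdError",
]

ENERGY_ZERO = 1e-6  # below this, the state has relaxed back to rest


class NoThresholdError(RuntimeError):
    """The sweep never produced a robust quantized state."""


@dataclass
class SweepResult:
    """Rows of an amplitude or noise sweep plus plateau segmentation.

    ``table`` columns depend on the sweep kind; ``plateaus`` maps plateau
    id -> list of row indices; ``spec`` records everything needed to rerun
    a single point (used by threshold bisection).
    """

    table: pd.DataFrame
    plateaus: dict[int, list[int]] = field(default_factory=dict)
    spec: dict = field(default_factory=dict)


def _settle_energy(
    net: Network,
    params: ModelParams,
    stim: Stimulus,
    center,
    dt: float,
    t_max: float,
    settle_tol: float,
) -> tuple[float, Pattern | None, str | None]:
    """Stimulate and relax to a stable equilibrium.

    Returns (energy, pattern, error).  Relaxation goes through
    :func:`graphsh.dynamics.relax_to_stable`, so symmetric stimuli that
    first settle on automorphism-invariant saddles are nudged onto the
    neighbouring stable quantized state — the protocol measures the
    energies of attractors, not of saddles.
    """
    u0 = make_stimulus(net, center, stim)
    try:
        pattern, _ = relax_to_stable(
            net, u0, params, dt=dt, t_max=t_max, settle_tol=settle_tol
        )
    except BlowUpError:
        return np.nan, None, "blow-up"
    return pattern.energy, pattern, None


def _segment_plateaus(
    energies: np.ndarray, rows: np.ndarray, rel_tol: float
) -> dict[int, list[int]]:
    """1-D segmentation of consecutive rows into constant-energy runs."""
    plateaus: dict[int, list[int]] = {}
    pid = -1
    prev = None
    scale = max(np.nanmax(np.abs(energies), initial=0.0), 1.0)
    for row, e in zip(rows, energies):
        if prev is None or abs(e - prev) > rel_tol * max(abs(prev), scale * 1e-3):
            pid += 1
            plateaus[pid] = []
        plateaus[pid].append(int(row))
        prev = e
    return plateaus


def amplitude_sweep(
    net: Network,
    params: ModelParams,
    amplitudes: np.ndarray,
    center="best-connected",
    include_center: bool = True,
    dt: float = 0.05,
    t_max: float = 2000.0,
    settle_tol: float = 1e-8,
    plateau_tol: float = 1e-3,
    robust_min: int = 2,
) -> SweepResult:
    """Sweep the step-stimulus amplitude and classify the equilibria.

    Outcomes per row: ``relaxed`` (energy < 1e-6: the stimulus decayed
    back to rest), ``robust`` (the row lies on the terminal energy
    plateau, which extends to the largest amplitude and has at least
    ``robust_min`` members — further amplitude increases do not change the
    final pattern), ``fragile`` (a quantized state formed but not yet the
    amplitude-insensitive one), or ``blow-up``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(np.diff(amplitudes) <= 0):
        raise ValueError("amplitude grid must be strictly increasing")
    rows = []
    for a in amplitudes:
        stim = Stimulus(amplitude=float(a), include_center=include_center)
        energy, _, err = _settle_energy(
            net, params, stim, center, dt, t_max, settle_tol
        )
        rows.append({"amplitude": float(a), "energy": energy, "error": err})
    df = pd.DataFrame(rows)
    nonzero = df.index[(df["error"].isna()) & (df["energy"] >= ENERGY_ZERO)].to_numpy()
    plateaus = (
        _segment_plateaus(df.loc[nonzero, "energy"].to_numpy(), nonzero, plateau_tol)
        if nonzero.size
        else {}
    )
    outcome = np.where(df["error"].notna(), "blow-up", "relaxed").astype(object)
    for pid, members in plateaus.items():
        terminal = members[-1] == len(df) - 1 and len(members) >= robust_min
        for r in members:
            outcome[r] = "robust" if terminal else "fragile"
    df["outcome"] = outcome
    df["plateau"] = -1
    for pid, members in plateaus.items():
        df.loc[members, "plateau"] = pid
    spec = {
        "kind": "amplitude",
        "center": center,
        "include_center": include_center,
        "dt": dt,
        "t_max": t_max,
        "settle_tol": settle_tol,
        "plateau_tol": plateau_tol,
        "mu": params.mu,
        "b": params.b,
    }
    return SweepResult(table=df, plateaus=plateaus, spec=spec)


def threshold_estimate(
    net: Network,
    params: ModelParams,
    sweep: SweepResult,
    refine_to: float | None = None,
    max_bisect: int = 30,
) -> tuple[float, float]:
    """Bracket and refine the stimulus-amplitude threshold for robust
    quantized states.

    The initial bracket is (largest relaxed amplitude below the first
    robust row, first robust amplitude); bisection then reruns the
    stimulate-relax protocol at each midpoint.  Midpoints that relax count
    as below threshold; midpoints forming any quantized state (fragile or
    robust) count as above.  Returns the final (lo, hi) bracket with
    width <= ``refine_to`` (default: grid step / 8).
    """
    df = sweep.table
    robust_rows = df.index[df["outcome"] == "robust"]
    relaxed_rows = df.index[df["outcome"] == "relaxed"]
    if robust_rows.empty or relaxed_rows.empty:
        raise NoThresholdError("sweep lacks a relaxed->robust transition")
    first_robust = robust_rows[0]
    below = relaxed_rows[relaxed_rows < first_robust]
    if below.empty:
        raise NoThresholdError("no relaxed row precedes the robust plateau")
    lo = float(df.loc[below[-1], "amplitude"])
    hi = float(df.loc[first_robust, "amplitude"])
    if refine_to is None:
        refine_to = float(df["amplitude"].diff().min()) / 8.0
    s = sweep.spec
    p = ModelParams(mu=s["mu"], b=s["b"])
    for _ in range(max_bisect):
        if hi - lo <= refine_to:
            break
        mid = 0.5 * (lo + hi)
        stim = Stimulus(amplitude=mid, include_center=s["include_center"])
        energy, _, err = _settle_energy(
            net, p, stim, s["center"], s["dt"], s["t_max"], s["settle_tol"]
        )
        if err is None and energy < ENERGY_ZERO:
            lo = mid
        else:
            hi = mid
    return lo, hi


def _spawn_seed(master: int, ratio_index: int, realization: int) -> int:
    """Deterministic per-realization seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(ratio_index, realization))
    return int(ss.generate_state(1)[0] % (2**31))


def noise_monte_carlo(
    net: Network,
    params: ModelParams,
    base_amplitude: float,
    noise_ratios: np.ndarray,
    n_real: int = 100,
    seed: int = 0,
    center="best-connected",
    include_center: bool = True,
    dt: float = 0.05,
    t_max: float = 2000.0,
    settle_tol: float = 1e-8,
    match_tol: float = 1e-3,
) -> SweepResult:
    """Monte Carlo over noisy stimuli at fixed base amplitude.

    For each noise-to-signal ratio r, ``n_real`` realizations add seeded
    uniform noise of half-width r * base_amplitude on the stimulated
    support; the result records the mean and standard deviation of the
    final energy and the fraction of realizations whose energy matches the
    noise-free quantized state within ``match_tol`` (relative).

    The table carries both the noise-to-signal ratio and its reciprocal
    (signal-to-noise), since either convention appears in practice.
    """
    base_energy, base_pattern, err = _settle_energy(
        net,
        params,
        Stimulus(amplitude=base_amplitude, include_center=include_center),
        center,
        dt,
        t_max,
        settle_tol,
    )
    if err is not None or base_energy < ENERGY_ZERO:
        raise ValueError(
            "base amplitude does not produce a quantized state "
            f"(energy={base_energy!r}, error={err})"
        )
    rows = []
    for ri, ratio in enumerate(np.asarray(noise_ratios, dtype=float)):
        energies = np.empty(n_real)
        first_seed = None
        for r in range(n_real):
            s = _spawn_seed(seed, ri, r)
            if first_seed is None:
                first_seed = s
            stim = Stimulus(
                amplitude=base_amplitude,
                noise_amplitude=float(ratio) * base_amplitude,
                seed=s,
                include_center=include_center,
            )
            e, _, e_err = _settle_energy(
                net, params, stim, center, dt, t_max, settle_tol
            )
            energies[r] = e if e_err is None else np.nan
        valid = energies[np.isfinite(energies)]
        match = (
            np.abs(valid - base_energy) <= match_tol * max(base_energy, 1e-30)
        ).mean() if valid.size else 0.0
        rows.append(
            {
                "noise_ratio": float(ratio),
                "signal_to_noise": np.inf if ratio == 0 else 1.0 / float(ratio),
                "mean_energy": float(np.mean(valid)) if valid.size else np.nan,
                "std_energy": float(np.std(valid)) if valid.size else np.nan,
                "match_fraction": float(match),
                "n_valid": int(valid.size),
                "first_seed": first_seed,
            }
        )
    df = pd.DataFrame(rows)
    spec = {
        "kind": "noise",
        "base_amplitude": base_amplitude,
        "base_energy": base_energy,
        "n_real": n_real,
        "master_seed": seed,
        "center": center,
        "mu": params.mu,
        "b": params.b,
    }
    return SweepResult(table=df, spec=spec)


def stability_scan(
    net: Network, mus: np.ndarray, b: float = 1.5
) -> pd.DataFrame:
    """Maximal growth rate of each flat state over a mu grid (the data
    behind flat-state stability diagrams)."""
    rows = []
    for mu in np.asarray(mus, dtype=float):
        params = ModelParams(mu=float(mu), b=b)
        fs = flat_states(params)
        entry = {"mu": float(mu)}
        lmax, lcrit = max_growth_rate(net, 0.0, params)
        entry["lambda_max_u0"], entry["critical_Lambda_u0"] = lmax, lcrit
        for name, val in (("u_plus", fs.u_plus), ("u_minus", fs.u_minus)):
            if val is None:
                entry[f"lambda_max_{name}"] = np.nan
                entry[f"{name}"] = np.nan
            else:
                lm, _ = max_growth_rate(net, val, params)
                entry[f"lambda_max_{name}"] = lm
                entry[f"{name}"] = val
        rows.append(entry)
    return pd.DataFrame(rows)
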