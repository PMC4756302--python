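"""Run configuration: flat key-value files with dotted namespaces.

A config file holds one ``key = value`` pair per line ('#' comments),
e.g.::

    model.mu = 0.1
    network.kind = ba
    network.n = 200
    continuation.ds = 0.05

Every key has a documented default; unknown keys are rejected so typos
cannot silently fall back to defaults.  CLI flags override config values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid configuration key or value."""


def _bool(v: str) -> bool:
    if str(v).lower() in ("1", "true", "yes", "on"):
        return True
    if str(v).lower() in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


# key -> (type constructor, default)
DEFAULTS: dict[str, tuple] = {
    "network.kind": (str, "ba"),          # ba | er | file
    "network.n": (int, 200),
    "network.m": (int, 1),                # BA edges per new node
    "network.mean_degree": (float, 6.0),  # ER mean degree
    "network.seed": (int, 7),
    "network.path": (str, ""),            # edge list or GraphML when kind=file
    "model.mu": (float, 0.1),
    "model.b": (float, 1.5),
    "integrator.dt": (float, 0.05),
    "integrator.t_max": (float, 2000.0),
    "integrator.settle_tol": (float, 1e-8),
    "stimulus.amplitude": (float, 2.0),
    "stimulus.noise": (float, 0.0),
    "stimulus.seed": (int, 0),
    "stimulus.center": (str, "best-connected"),
    "stimulus.include_center": (_bool, True),
    "continuation.ds": (float, 0.05),
    "continuation.n_steps": (int, 200),
    "continuation.direction": (int, -1),
    "continuation.stability_every": (int, 1),
    "sweep.amplitude_min": (float, 0.0),
    "sweep.amplitude_max": (float, 3.0),
    "sweep.amplitude_step": (float, 0.2),
    "sweep.noise_ratios": (str, "0,0.05,0.1,0.2,0.4,0.8"),
    "sweep.n_real": (int, 100),
    "scan.mu_min": (float, -2.0),
    "scan.mu_max": (float, 0.5),
    "scan.mu_step": (float, 0.05),
    "mfa.tol_fraction": (float, 0.15),
    "output.dir": (str, "graphsh-out"),
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: d for k, (_, d) in DEFAULTS.items()}
        for k, v in self.values.items():
            if k not in DEFAULTS:
                raise ConfigError(f"unknown configuration key: {k!r}")
            ctor = DEFAULTS[k][0]
            try:
                merged[k] = ctor(v)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid value for {k!r}: {v!r} ({exc})") from exc
        self.values = merged

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                k, v = (part.strip() for part in line.split("=", 1))
                raw[k] = v
        return cls(values=raw)

    def override(self, **updates) -> "RunConfig":
        """New config with the given dotted keys replaced (None ignored)."""
        vals = dict(self.values)
        for k, v in updates.items():
            if v is not None:
                vals[k] = v
        return RunConfig(values=vals)

    def __getitem__(self, key: str):
        return self.values[key]

    def noise_ratio_grid(self) -> list[float]:
        return [float(x) for x in str(self["sweep.noise_ratios"]).split(",") if x.strip()]

    def to_manifest(self, extra: dict | None = None) -> str:
        """Deterministically serialized config (byte-identical on reload)."""
        doc = {"config": {k: self.values[k] for k in sorted(self.values)}}
        if extra:
            doc.update(extra)
        return json.dumps(doc, indent=2, sort_keys=True, default=str)
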