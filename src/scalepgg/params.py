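"""Model parameters and flat-file configuration.

The game is parameterised by the population size ``M``, the group (sample)
size ``N``, the contribution cost ``c``, the return multiplier ``r``, the
returns-to-scale exponent ``alpha``, the punishment strength ``delta`` and
cost ``gamma``, the selection strength ``omega`` of the exponential fitness
map ``F = exp(omega * P)``, and the per-reproduction mutation rate ``mu``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["GameParameters", "PARAMETER_KEYS"]

#: Flat configuration keys, in canonical order.
PARAMETER_KEYS = ("M", "N", "c", "r", "alpha", "delta", "gamma", "omega", "mu")


@dataclass(frozen=True)
class GameParameters:
    """All constants of the public goods game and its evolutionary dynamics.

    Parameters
    ----------
    M : int
        Population size (>= 2).
    N : int
        Number of individuals sampled into each game group, ``2 <= N <= M``.
    c : float
        Contribution cost paid by each cooperator and punisher, ``c > 0``.
    r : float
        Return multiplier of the joint project, ``r > 1``.
    alpha : float
        Returns-to-scale exponent: total production is
        ``c * r * contributors**alpha``. ``alpha > 1`` gives increasing
        returns to scale; ``alpha = 1`` is the standard linear game.
    delta : float
        Fine imposed on each defector by each punisher, ``delta >= 0``.
    gamma : float
        Cost paid by each punisher per defector punished, ``gamma >= 0``.
    omega : float
        Selection strength of the exponential fitness map, ``omega > 0``.
    mu : float
        Mutation probability per reproduction event, ``0 <= mu < 1``.
    """

    M: int
    N: int
    c: float = 1.0
    r: float = 3.0
    alpha: float = 1.0
    delta: float = 1.0
    gamma: float = 0.3
    omega: float = 0.1
    mu: float = 0.0

    def __post_init__(self) -> None:
        if int(self.M) != self.M or int(self.N) != self.N:
            raise ValueError("M and N must be integers")
        object.__setattr__(self, "M", int(self.M))
        object.__setattr__(self, "N", int(self.N))
        if not 2 <= self.N <= self.M:
            raise ValueError(f"require 2 <= N <= M, got N={self.N}, M={self.M}")
        if not self.c > 0:
            raise ValueError(f"contribution cost c must be > 0, got {self.c}")
        if not self.r > 1:
            raise ValueError(f"return multiplier r must be > 1, got {self.r}")
        if not self.alpha > 0:
            raise ValueError(f"scale exponent alpha must be > 0, got {self.alpha}")
        if self.delta < 0 or self.gamma < 0:
            raise ValueError("punishment strength/cost must be >= 0")
        if not self.omega > 0:
            raise ValueError(f"selection strength omega must be > 0, got {self.omega}")
        if not 0 <= self.mu < 1:
            raise ValueError(f"mutation rate mu must be in [0, 1), got {self.mu}")

    def replace(self, **changes: Any) -> "GameParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        """Flat key-value form with the canonical configuration keys."""
        return {k: getattr(self, k) for k in PARAMETER_KEYS}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "GameParameters":
        unknown = set(mapping) - set(PARAMETER_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "GameParameters":
        """Load from a flat YAML or JSON file, ignoring non-parameter keys.

        Run-control keys (seed, periods, ...) and provenance fields written
        into run manifests are tolerated so a manifest can be re-fed as a
        configuration file.
        """
        data = load_config(path)
        picked = {k: data[k] for k in PARAMETER_KEYS if k in data}
        return cls(**picked)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML or JSON mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return data
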