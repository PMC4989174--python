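"""One-shot payoff structure of the public goods game with punishment.

A group of ``N`` players holds ``x`` cooperators, ``y`` defectors and ``z``
punishers. Contributors (cooperators and punishers) each pay ``c`` into the
joint project, whose total production follows a Cobb-Douglas form with
defector productivity fixed at zero:

    production = c * r * (x + z)**alpha

The production is divided equally among all ``N`` group members, defectors
included. Each punisher additionally fines every defector by ``delta`` at a
personal cost ``gamma`` per defector, so a defector facing ``z`` punishers
loses ``delta * z`` and a punisher facing ``y`` defectors pays ``gamma * y``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import GameParameters

__all__ = ["GroupComposition", "GroupPayoffs", "total_production", "group_payoffs"]


@dataclass(frozen=True)
class GroupComposition:
    """Strategy counts inside one sampled game group.

    ``x`` cooperators, ``y`` defectors, ``z`` punishers; they must be
    non-negative and sum to the group size ``N`` of the owning parameters
    (validated by :func:`group_payoffs`).
    """

    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("group composition counts must be non-negative")

    @property
    def size(self) -> int:
        return self.x + self.y + self.z


@dataclass(frozen=True)
class GroupPayoffs:
    """Per-strategy payoffs in one group.

    All three entries are always defined: an entry for a strategy absent
    from the group is the payoff a hypothetical member of that strategy
    would receive in this composition (the focal-player constructions in
    the analytic module rely on this counterfactual reading).
    """

    P_x: float
    P_y: float
    P_z: float


def total_production(params: GameParameters, contributors: int) -> float:
    """Total production ``c * r * contributors**alpha`` of one group.

    Zero contributors produce nothing for any ``alpha > 0``.
    """
    if contributors < 0:
        raise ValueError(f"contributors must be >= 0, got {contributors}")
    if contributors > params.N:
        raise ValueError(f"contributors cannot exceed group size N={params.N}")
    if contributors == 0:
        return 0.0
    return params.c * params.r * float(contributors) ** params.alpha


def group_payoffs(params: GameParameters, comp: GroupComposition) -> GroupPayoffs:
    """Payoffs of a cooperator, defector and punisher in composition ``comp``.

    With ``share = production(x + z) / N``:

    * cooperator: ``share - c``
    * defector:   ``share - delta * z``
    * punisher:   ``share - c - gamma * y``

    Hence a cooperator out-earns a punisher by exactly ``gamma * y`` (the
    second-order free-riding advantage) and out-earns a defector by
    ``delta * z - c``: punishment deters defection iff ``delta * z > c``.
    """
    if comp.size != params.N:
        raise ValueError(
            f"composition sums to {comp.size}, expected group size N={params.N}"
        )
    share = total_production(params, comp.x + comp.z) / params.N
    return GroupPayoffs(
        P_x=share - params.c,
        P_y=share - params.delta * comp.z,
        P_z=share - params.c - params.gamma * comp.y,
    )
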