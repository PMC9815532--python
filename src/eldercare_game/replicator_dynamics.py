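"""Replicator vector field of the four-population game.

Each population's share of its first strategy evolves by the Malthusian
replicator rule: growth proportional to the payoff advantage over the
population average.  With two strategies per population this reduces to

    dx/dt = x(1-x) G(y,z,w)      (providers)
    dy/dt = y(1-y) H(x,z,w)      (platforms)
    dz/dt = z(1-z) P(x,y)        (government)
    dw/dt = w(1-w) (Cm - Cw)     (elderly)

where G, H, P are the incentive differences of :mod:`~eldercare_game.payoff_engine`
(single source of truth for the algebra).  Every corner of [0,1]^4 is a fixed
point, and the field never points out of the cube.  States slightly outside
[0,1] (integrator round-off) are evaluated as-is; clamping is the
integrator's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import GameParameters, StrategyProfile
from .payoff_engine import Player, incentive_difference

__all__ = ["StateDerivative", "replicator_rhs", "replicator_rhs_derivative"]

_PLAYERS = (Player.PROVIDER, Player.PLATFORM, Player.GOVERNMENT, Player.ELDERLY)


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives (probability per unit time) of the four shares."""

    dx_dt: float
    dy_dt: float
    dz_dt: float
    dw_dt: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx_dt, self.dy_dt, self.dz_dt, self.dw_dt], dtype=float)


def replicator_rhs(p: GameParameters, s: StrategyProfile) -> StateDerivative:
    """Evaluate the replicator field at state ``s``."""
    probs = s.as_array()
    rates = [
        prob * (1.0 - prob) * incentive_difference(p, s, player)
        for prob, player in zip(probs, _PLAYERS)
    ]
    return StateDerivative(*rates)


def replicator_rhs_derivative(p: GameParameters, s: StrategyProfile) -> tuple[float, float, float, float]:
    """Own-strategy partial derivatives of the replicator field.

    Returns (dF_x/dx, dF_y/dy, dF_z/dz, dF_w/dw) = ((1-2x)G, (1-2y)H,
    (1-2z)P, (1-2w)(Cm-Cw)); the incentive differences do not depend on the
    player's own probability, so these are exact, not approximations.
    """
    probs = s.as_array()
    return tuple(
        (1.0 - 2.0 * prob) * incentive_difference(p, s, player)
        for prob, player in zip(probs, _PLAYERS)
    )
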