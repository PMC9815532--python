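"""Payoff matrix and expected-utility layer of the four-party game.

Each population has two pure strategies:

* provider — high quality ``HQ`` (prob. x) vs low quality ``LQ``;
* platform — positive return visits ``PV`` (prob. y) vs negative ``NV``;
* government — positive regulation ``PR`` (prob. z) vs negative ``NR``;
* elderly — online evaluation ``ON`` (prob. w) vs offline ``OF``.

``payoff_cell`` encodes the 16-cell payoff matrix directly; the
expected-utility layer implements the closed-form expectations and the three
incentive differences G(y,z,w), H(x,z,w), P(x,y) plus the elderly's constant
difference Cm − Cw.  The two layers are implemented independently and their
mutual consistency is a test, not an assumption, which guards against
transcription slips in either one.

Modelling features worth noting: when the government does not regulate and
the platform does not visit, fines/compensation are triggered only through
an elderly complaint and are therefore discounted by the complaint rate β;
offline evaluations reach only a fraction γ of the audience, so every
reputational gain/loss (Is, Ds, Ie, De) is scaled by γ in OF cells.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import pandas as pd

from .parameters import GameParameters, StrategyProfile

__all__ = [
    "Player",
    "ProviderStrategy",
    "PlatformStrategy",
    "GovernmentStrategy",
    "ElderlyStrategy",
    "PureStrategyCombination",
    "PayoffVector",
    "all_combinations",
    "payoff_cell",
    "payoff_table",
    "expected_utilities",
    "incentive_difference",
]


class Player(enum.Enum):
    PROVIDER = "provider"
    PLATFORM = "platform"
    GOVERNMENT = "government"
    ELDERLY = "elderly"


class ProviderStrategy(enum.Enum):
    HQ = "HQ"
    LQ = "LQ"


class PlatformStrategy(enum.Enum):
    PV = "PV"
    NV = "NV"


class GovernmentStrategy(enum.Enum):
    PR = "PR"
    NR = "NR"


class ElderlyStrategy(enum.Enum):
    ON = "ON"
    OF = "OF"


#: Index-1 strategies: the ones whose probabilities are (x, y, z, w).
STRATEGY_ONE = {
    Player.PROVIDER: ProviderStrategy.HQ,
    Player.PLATFORM: PlatformStrategy.PV,
    Player.GOVERNMENT: GovernmentStrategy.PR,
    Player.ELDERLY: ElderlyStrategy.ON,
}
STRATEGY_TWO = {
    Player.PROVIDER: ProviderStrategy.LQ,
    Player.PLATFORM: PlatformStrategy.NV,
    Player.GOVERNMENT: GovernmentStrategy.NR,
    Player.ELDERLY: ElderlyStrategy.OF,
}


@dataclass(frozen=True)
class PureStrategyCombination:
    provider: ProviderStrategy
    platform: PlatformStrategy
    government: GovernmentStrategy
    elderly: ElderlyStrategy

    @classmethod
    def from_labels(cls, provider: str, platform: str, government: str, elderly: str):
        return cls(
            ProviderStrategy(provider),
            PlatformStrategy(platform),
            GovernmentStrategy(government),
            ElderlyStrategy(elderly),
        )

    def labels(self) -> tuple[str, str, str, str]:
        return (
            self.provider.value,
            self.platform.value,
            self.government.value,
            self.elderly.value,
        )


@dataclass(frozen=True)
class PayoffVector:
    """Payoffs of the four players for one pure-strategy combination."""

    provider: float
    platform: float
    government: float
    elderly: float

    def for_player(self, player: Player) -> float:
        return getattr(self, player.value)


def all_combinations() -> list[PureStrategyCombination]:
    """The 16 pure-strategy combinations, provider-major order."""
    return [
        PureStrategyCombination(pr, pl, gv, el)
        for pr, pl, gv, el in itertools.product(
            ProviderStrategy, PlatformStrategy, GovernmentStrategy, ElderlyStrategy
        )
    ]


def payoff_cell(p: GameParameters, combo: PureStrategyCombination) -> PayoffVector:
    """Evaluate one cell of the payoff matrix at parameter set ``p``."""
    hq = combo.provider is ProviderStrategy.HQ
    pv = combo.platform is PlatformStrategy.PV
    pr = combo.government is GovernmentStrategy.PR
    on = combo.elderly is ElderlyStrategy.ON

    # Reputation reach: online evaluation full, offline scaled by gamma.
    reach = 1.0 if on else p.gamma
    eval_cost = p.Cw if on else p.Cm

    if hq:
        provider = (1 - p.alpha) * p.Rs - p.Csh + p.Is * reach
        elderly = p.Ro - eval_cost
        if pv:
            platform = p.alpha * p.Rs - p.Cei - p.Ceo + p.S + p.Ie * reach
            government = (p.Rg - p.Cg - p.S) if pr else (p.Rg - p.S)
        else:
            platform = p.alpha * p.Rs - p.Ceo - p.De * reach
            government = (p.Rg - p.Cg) if pr else p.Rg
    else:
        if pv:
            platform = p.alpha * p.Rs - p.Cei - p.Ceo + p.S + p.Ie * reach
            if pr:
                provider = (1 - p.alpha) * p.Rs - p.Csl - p.Io - p.Fs - p.Ds * reach
                government = p.Fs - p.S - p.Cg - p.Dg
            else:
                provider = (1 - p.alpha) * p.Rs - p.Csl - p.Ds * reach - p.Io
                government = -p.S - p.Dg
            elderly = p.Io - eval_cost - p.Do
        else:
            if pr:
                provider = (1 - p.alpha) * p.Rs - p.Csl - p.Io - p.Fs - p.Ds * reach
                platform = p.alpha * p.Rs - p.Ceo - p.Fe - p.De * reach
                government = p.Fs + p.Fe - p.Cg - p.Dg
                elderly = p.Io - eval_cost - p.Do
            else:
                # Unregulated, unvisited low quality: sanctions and
                # compensation flow only through a complaint (rate beta).
                provider = (
                    (1 - p.alpha) * p.Rs
                    - p.Csl
                    - p.beta * p.Fs
                    - p.Ds * reach
                    - p.beta * p.Io
                )
                platform = p.alpha * p.Rs - p.Ceo - p.beta * p.Fe - p.De * reach
                government = p.beta * (p.Fs + p.Fe - p.Fg) - p.Dg
                elderly = p.beta * (p.Io - p.Co) - eval_cost - p.Do
    return PayoffVector(provider, platform, government, elderly)


def payoff_table(p: GameParameters) -> pd.DataFrame:
    """All 16 cells as a DataFrame (strategy labels + four payoffs).

    Suitable for CSV export and regression snapshots.
    """
    rows = []
    for combo in all_combinations():
        cell = payoff_cell(p, combo)
        provider_label, platform_label, government_label, elderly_label = combo.labels()
        rows.append(
            {
                "provider": provider_label,
                "platform": platform_label,
                "government": government_label,
                "elderly": elderly_label,
                "provider_payoff": cell.provider,
                "platform_payoff": cell.platform,
                "government_payoff": cell.government,
                "elderly_payoff": cell.elderly,
            }
        )
    return pd.DataFrame(rows)


def incentive_difference(
    p: GameParameters, s: StrategyProfile, player: Player
) -> float:
    """Expected-payoff advantage of a player's first strategy over its second.

    Returns G(y, z, w) for the provider, H(x, z, w) for the platform,
    P(x, y) for the government, and the constant Cm − Cw for the elderly.
    The sign of this quantity drives the player's replicator flow.
    """
    if player is Player.PROVIDER:
        y, z, w = s.y, s.z, s.w
        return (
            w * (1 - p.gamma) * (p.Is + p.Ds)
            + z * p.Fs
            + p.Csl
            - p.Csh
            + p.Is * p.gamma
            + p.Ds * p.gamma
            + y * p.Io
            + (1 - y) * z * p.Io
            + (1 - y) * (1 - z) * (p.beta * p.Fs + p.beta * p.Io)
        )
    if player is Player.PLATFORM:
        x, z, w = s.x, s.z, s.w
        return (
            w * (1 - p.gamma) * (p.Ie + p.De)
            + p.Ie * p.gamma
            + p.De * p.gamma
            + p.S
            - p.Cei
            + (1 - x) * (z * p.Fe + (1 - z) * p.beta * p.Fe)
        )
    if player is Player.GOVERNMENT:
        x, y = s.x, s.y
        return (1 - x) * (
            p.Fs + (1 - y) * p.Fe - (1 - y) * p.beta * (p.Fs + p.Fe - p.Fg)
        ) - p.Cg
    if player is Player.ELDERLY:
        return p.Cm - p.Cw
    raise TypeError(f"unknown player: {player!r}")


def expected_utilities(
    p: GameParameters, s: StrategyProfile, player: Player
) -> tuple[float, float, float]:
    """Closed-form expected payoffs (U_strategy1, U_strategy2, U_average).

    U_average mixes the two pure expectations with the player's own
    probability.  The closed forms marginalise the payoff matrix over the
    opponents' mixing probabilities.
    """
    if player is Player.PROVIDER:
        y, z, w = s.y, s.z, s.w
        rep = w * p.Is + (1 - w) * p.Is * p.gamma
        u1 = (1 - p.alpha) * p.Rs - p.Csh + rep
        u2 = (
            (1 - p.alpha) * p.Rs
            - p.Csl
            - w * p.Ds
            - (1 - w) * p.Ds * p.gamma
            - z * p.Fs
            - y * p.Io
            - (1 - y) * z * p.Io
            - (1 - y) * (1 - z) * (p.beta * p.Fs + p.beta * p.Io)
        )
        own = s.x
    elif player is Player.PLATFORM:
        x, z, w = s.x, s.z, s.w
        u1 = (
            p.alpha * p.Rs
            - p.Ceo
            - p.Cei
            + w * p.Ie
            + (1 - w) * p.Ie * p.gamma
            + p.S
        )
        u2 = (
            p.alpha * p.Rs
            - p.Ceo
            - w * p.De
            - (1 - w) * p.De * p.gamma
            - (1 - x) * (z * p.Fe + (1 - z) * p.beta * p.Fe)
        )
        own = s.y
    elif player is Player.GOVERNMENT:
        x, y = s.x, s.y
        u1 = x * p.Rg - y * p.S - p.Cg + (1 - x) * (p.Fs - p.Dg + (1 - y) * p.Fe)
        u2 = x * p.Rg - y * p.S + (1 - x) * (
            (1 - y) * p.beta * (p.Fs + p.Fe - p.Fg) - p.Dg
        )
        own = s.z
    elif player is Player.ELDERLY:
        x, y, z = s.x, s.y, s.z
        common = (1 - x) * (
            (1 - y) * z * p.Io
            + p.beta * (1 - y) * (1 - z) * (p.Io - p.Co)
            + y * p.Io
            - p.Do
        )
        u1 = x * p.Ro - p.Cw + common
        u2 = x * p.Ro - p.Cm + common
        own = s.w
    else:
        raise TypeError(f"unknown player: {player!r}")
    return u1, u2, own * u1 + (1 - own) * u2
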