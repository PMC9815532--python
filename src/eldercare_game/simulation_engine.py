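"""Fixed-step system-dynamics simulation of the replicator field.

Mirrors a stock-flow (Vensim-style) integration of the four replicator
equations: forward Euler on the grid INITIAL TIME = 0, FINAL TIME = 3,
TIME STEP = 0.0125 by default, with a classical RK4 integrator available
for verification.  Post-step clamping to [0,1] is on by default so Euler
overshoot can never produce invalid probabilities.  Runs are deterministic:
no randomness anywhere.

The sensitivity-scenario suites perturb policy levers one at a time
(provider fine Fs and compensation Io; platform fine Fe and subsidy S;
the initial online-evaluation share w; the four reputation parameters
jointly; the complaint rate beta) and compare convergence speed across
variants via time-to-threshold tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    GameParameters,
    StrategyProfile,
    scale_parameter,
    validate_parameters,
)
from .payoff_engine import Player
from .replicator_dynamics import replicator_rhs

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ScenarioVariant",
    "ScenarioSpec",
    "ScenarioResult",
    "IntegrationError",
    "integrate",
    "detect_converged_strategy",
    "time_to_threshold",
    "time_to_stability",
    "builtin_scenarios",
    "run_scenario_suite",
    "plot_trajectory",
]

_PLAYER_INDEX = {
    Player.PROVIDER: 0,
    Player.PLATFORM: 1,
    Player.GOVERNMENT: 2,
    Player.ELDERLY: 3,
}
_STATE_NAMES = ("x", "y", "z", "w")
#: Per-player labels for (strategy 1, strategy 2).
_STRATEGY_LABELS = {
    Player.PROVIDER: ("HQ", "LQ"),
    Player.PLATFORM: ("PV", "NV"),
    Player.GOVERNMENT: ("PR", "NR"),
    Player.ELDERLY: ("ON", "OF"),
}


class IntegrationError(RuntimeError):
    """A non-finite state was produced during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid, scheme and initial state for one run.

    The defaults reproduce the reference simulation grid (t in [0, 3],
    step 0.0125) with forward Euler, matching the fixed-step system-dynamics
    engine used for the original analysis.  The initial state defaults to
    the maximally undecided profile (0.5, 0.5, 0.5, 0.5).
    """

    t_initial: float = 0.0
    t_final: float = 3.0
    step: float = 0.0125
    integrator: str = "euler"
    clamp: bool = True
    initial_state: StrategyProfile = field(
        default_factory=lambda: StrategyProfile(0.5, 0.5, 0.5, 0.5)
    )

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if not self.t_final > self.t_initial:
            raise ValueError("t_final must exceed t_initial")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    @property
    def n_steps(self) -> int:
        return int(math.floor((self.t_final - self.t_initial) / self.step + 1e-9))


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed strategy profiles plus provenance metadata."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 4), columns x, y, z, w
    parameters: GameParameters
    config: SimulationConfig
    label: str = "baseline"

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> StrategyProfile:
        return StrategyProfile.from_array(self.states[-1])

    def values(self, player: Player) -> np.ndarray:
        return self.states[:, _PLAYER_INDEX[player]]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(_STATE_NAMES))
        frame.insert(0, "t", self.times)
        return frame


def _field_function(p: GameParameters, hold: frozenset[int]):
    def rhs(state: np.ndarray) -> np.ndarray:
        deriv = replicator_rhs(p, StrategyProfile.from_array(state)).as_array()
        if hold:
            deriv[list(hold)] = 0.0
        return deriv

    return rhs


def integrate(
    p: GameParameters,
    cfg: SimulationConfig | None = None,
    label: str = "baseline",
    hold: tuple[str, ...] = (),
) -> Trajectory:
    """Forward-step the replicator field on the fixed grid.

    ``hold`` freezes the named state components (subset of "x", "y", "z",
    "w") at their initial values — the alternative reading of the
    online-evaluation scenario in which w is an exogenous share rather than
    an evolving one.  Deterministic for fixed inputs; raises
    :class:`IntegrationError` naming the step if the state turns non-finite.
    """
    cfg = cfg or SimulationConfig()
    unknown = set(hold) - set(_STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown state component(s) to hold: {sorted(unknown)}")
    held = frozenset(_STATE_NAMES.index(name) for name in hold)
    rhs = _field_function(p, held)

    n = cfg.n_steps
    times = cfg.t_initial + cfg.step * np.arange(n + 1)
    states = np.empty((n + 1, 4), dtype=float)
    state = cfg.initial_state.as_array()
    states[0] = state
    h = cfg.step
    for k in range(n):
        if cfg.integrator == "euler":
            state = state + h * rhs(state)
        else:  # rk4
            k1 = rhs(state)
            k2 = rhs(state + 0.5 * h * k1)
            k3 = rhs(state + 0.5 * h * k2)
            k4 = rhs(state + h * k3)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if cfg.clamp:
            state = np.clip(state, 0.0, 1.0)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state at step {k + 1} (t = {times[k + 1]:.6g})"
            )
        states[k + 1] = state
    return Trajectory(times=times, states=states, parameters=p, config=cfg, label=label)


def detect_converged_strategy(
    traj: Trajectory, tol: float = 0.01, window: int = 40
) -> dict[Player, str]:
    """Label each population's settled strategy over the trailing window.

    A population has converged to its first strategy if its probability
    stays at or above 1 - tol throughout the last ``window`` grid points,
    to its second if it stays at or below tol; otherwise "unresolved".
    """
    if window > len(traj):
        raise ValueError(f"window {window} exceeds trajectory length {len(traj)}")
    labels: dict[Player, str] = {}
    for player, (first, second) in _STRATEGY_LABELS.items():
        tail = traj.values(player)[-window:]
        if np.all(tail >= 1.0 - tol):
            labels[player] = first
        elif np.all(tail <= tol):
            labels[player] = second
        else:
            labels[player] = "unresolved"
    return labels


def time_to_threshold(
    traj: Trajectory, player: Player, level: float
) -> float | None:
    """First grid time at which a population crosses ``level`` toward its limit.

    The crossing direction is that of the trajectory's net drift (final
    minus initial value; ties count as upward).  Returns ``None`` when the
    level is never crossed in that direction.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    values = traj.values(player)
    upward = values[-1] >= values[0]
    hit = np.nonzero(values >= level if upward else values <= level)[0]
    if hit.size == 0:
        return None
    return float(traj.times[hit[0]])


def time_to_stability(
    traj: Trajectory, player: Player, margin: float = 0.01
) -> float | None:
    """Time until a population first comes within ``margin`` of its final corner.

    ``None`` when the trajectory does not end near a corner (no settled
    strategy to measure speed toward).
    """
    final = traj.values(player)[-1]
    if final >= 1.0 - margin:
        return time_to_threshold(traj, player, 1.0 - margin)
    if final <= margin:
        return time_to_threshold(traj, player, margin)
    return None


@dataclass(frozen=True)
class ScenarioVariant:
    """One perturbed run: parameter scalings/overrides and initial-state edits."""

    label: str
    scalings: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    hold: tuple[str, ...] = ()

    def apply(
        self, p: GameParameters, cfg: SimulationConfig
    ) -> tuple[GameParameters, SimulationConfig]:
        for name, factor in self.scalings.items():
            p = scale_parameter(p, name, factor)
        if self.overrides:
            p = p.replace(**self.overrides)
            report = validate_parameters(p)
            if not report.ok:
                raise ValueError(
                    f"variant {self.label!r}: " + "; ".join(report.violations)
                )
        if self.initial:
            unknown = set(self.initial) - set(_STATE_NAMES)
            if unknown:
                raise KeyError(
                    f"variant {self.label!r}: unknown initial-state key(s) "
                    f"{sorted(unknown)}"
                )
            cfg = replace(
                cfg, initial_state=replace(cfg.initial_state, **self.initial)
            )
        return p, cfg


@dataclass(frozen=True)
class ScenarioSpec:
    """A named suite of variants sharing one baseline and time grid."""

    scenario_id: str
    description: str
    variants: tuple[ScenarioVariant, ...]


@dataclass(frozen=True)
class ScenarioResult:
    """Per-variant trajectories, convergence labels and speed table."""

    spec: ScenarioSpec
    trajectories: dict
    convergence: dict
    times_to_stability: pd.DataFrame
    errors: dict


def builtin_scenarios() -> list[ScenarioSpec]:
    """The five built-in sensitivity suites.

    1. ``penalty_provider`` — provider fine Fs and compensation Io each
       fluctuated 50 % up and down around baseline (Fs in {10, 20, 30},
       Io in {5, 10, 15}).
    2. ``penalty_subsidy_platform`` — platform fine Fe in {2.5, 5, 7.5} and
       subsidy S in {5, 10, 15}.
    3. ``online_evaluation`` — initial online-evaluation share w in
       {0.25, 0.75} (w still evolves; use ``hold=("w",)`` on a variant for
       the exogenous-share reading).
    4. ``reputation`` — Is, Ds, Ie, De jointly scaled by 0.5 and 1.5.
    5. ``complaint_rate`` — complaint rate beta in {0.01, 0.41}.
    """
    rep = {"Is": 1.0, "Ds": 1.0, "Ie": 1.0, "De": 1.0}
    return [
        ScenarioSpec(
            "penalty_provider",
            "Provider fine Fs and compensation Io fluctuated 50% up/down",
            tuple(
                [ScenarioVariant(f"Fs x{f}", scalings={"Fs": f}) for f in (0.5, 1.0, 1.5)]
                + [ScenarioVariant(f"Io x{f}", scalings={"Io": f}) for f in (0.5, 1.0, 1.5)]
            ),
        ),
        ScenarioSpec(
            "penalty_subsidy_platform",
            "Platform fine Fe and subsidy S fluctuated 50% up/down",
            tuple(
                [ScenarioVariant(f"Fe x{f}", scalings={"Fe": f}) for f in (0.5, 1.0, 1.5)]
                + [ScenarioVariant(f"S x{f}", scalings={"S": f}) for f in (0.5, 1.0, 1.5)]
            ),
        ),
        ScenarioSpec(
            "online_evaluation",
            "Initial online-evaluation share w of the elderly",
            (
                ScenarioVariant("w0=0.25", initial={"w": 0.25}),
                ScenarioVariant("w0=0.75", initial={"w": 0.75}),
            ),
        ),
        ScenarioSpec(
            "reputation",
            "Reputational gains/losses Is, Ds, Ie, De jointly scaled",
            (
                ScenarioVariant(
                    "reputation x0.5", scalings={k: 0.5 for k in rep}
                ),
                ScenarioVariant(
                    "reputation x1.5", scalings={k: 1.5 for k in rep}
                ),
            ),
        ),
        ScenarioSpec(
            "complaint_rate",
            "Elderly complaint rate beta",
            (
                ScenarioVariant("beta=0.01", overrides={"beta": 0.01}),
                ScenarioVariant("beta=0.41", overrides={"beta": 0.41}),
            ),
        ),
    ]


def run_scenario_suite(
    p: GameParameters,
    spec: ScenarioSpec,
    cfg: SimulationConfig | None = None,
    margin: float = 0.01,
) -> ScenarioResult:
    """Integrate every variant of a suite from the same configuration.

    Integration failures are recorded per-variant (``result.errors``)
    without aborting the rest of the suite.
    """
    cfg = cfg or SimulationConfig()
    trajectories: dict = {}
    convergence: dict = {}
    errors: dict = {}
    rows = []
    for variant in spec.variants:
        try:
            vp, vcfg = variant.apply(p, cfg)
            traj = integrate(vp, vcfg, label=variant.label, hold=variant.hold)
        except (IntegrationError, ValueError, KeyError) as exc:
            errors[variant.label] = str(exc)
            continue
        trajectories[variant.label] = traj
        window = min(40, len(traj))
        convergence[variant.label] = detect_converged_strategy(
            traj, tol=margin, window=window
        )
        row = {"variant": variant.label}
        for player in _PLAYER_INDEX:
            t = time_to_stability(traj, player, margin=margin)
            row[f"{player.value}_time"] = math.nan if t is None else t
        rows.append(row)
    table = pd.DataFrame(rows)
    return ScenarioResult(
        spec=spec,
        trajectories=trajectories,
        convergence=convergence,
        times_to_stability=table,
        errors=errors,
    )


def plot_trajectory(traj: Trajectory, path) -> None:
    """Write a PNG line plot of the four probabilities against time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, column in zip(_STATE_NAMES, traj.states.T):
        ax.plot(traj.times, column, label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("strategy probability")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(traj.label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
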