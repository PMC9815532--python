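"""Corner equilibria, Lyapunov stability, analytic thresholds and strategy volumes.

In a multi-population replicator system an evolutionarily stable strategy
(ESS) must be a strict Nash equilibrium, i.e. a pure-strategy corner of
[0,1]^4.  This module enumerates the 16 corners (named E1..E16: E1-E8 on the
offline face w=0, E9-E16 on the online face w=1), computes the corner
Jacobian (diagonal, by the structure of the field), classifies each corner
by Lyapunov's first method, and evaluates the analytic by-products of the
incentive differences:

* thresholds — the online-evaluation shares w0 / w1 that flip the provider
  and platform, the high-quality share x0 that flips the government, and the
  policy levels (provider fine Fs', platform subsidy S', superior-government
  penalty Fg') at which the corresponding incentive vanishes;
* strategy volumes — integrals of the threshold surfaces over the opposing
  probability cube, read as the probability mass from which each population
  settles on a given strategy.

All thresholds are defined as roots of G/H/P, never re-transcribed from
derived formulas, so the defining property "substituting the threshold back
into the incentive function yields zero" holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    GameParameters,
    StrategyProfile,
    sample_admissible_parameters,
)
from .payoff_engine import Player, incentive_difference
from .replicator_dynamics import replicator_rhs_derivative

__all__ = [
    "EquilibriumReport",
    "ThresholdResult",
    "VolumeResult",
    "DegenerateThresholdError",
    "CORNER_ORDER",
    "enumerate_corner_equilibria",
    "corner_name",
    "corner_jacobian",
    "table_eigenvalues",
    "classify_equilibrium",
    "stability_report",
    "reports_to_frame",
    "threshold_w0",
    "threshold_w1",
    "threshold_x0",
    "penalty_threshold_Fs",
    "subsidy_threshold_S",
    "superior_penalty_threshold_Fg",
    "strategy_volumes",
]


class DegenerateThresholdError(ValueError):
    """The coefficient defining a threshold vanishes; no finite root exists."""


#: E1..E16 corner coordinates (x, y, z, w), frozen to the conventional tabulation order:
#: the offline-evaluation face (w=0) first, then the online face (w=1).
CORNER_ORDER: tuple[tuple[str, tuple[int, int, int, int]], ...] = (
    ("E1", (0, 0, 0, 0)),
    ("E2", (1, 0, 0, 0)),
    ("E3", (0, 1, 0, 0)),
    ("E4", (0, 0, 1, 0)),
    ("E5", (1, 1, 0, 0)),
    ("E6", (0, 1, 1, 0)),
    ("E7", (1, 0, 1, 0)),
    ("E8", (1, 1, 1, 0)),
    ("E9", (0, 0, 0, 1)),
    ("E10", (1, 0, 0, 1)),
    ("E11", (0, 1, 0, 1)),
    ("E12", (0, 0, 1, 1)),
    ("E13", (1, 1, 0, 1)),
    ("E14", (0, 1, 1, 1)),
    ("E15", (1, 0, 1, 1)),
    ("E16", (1, 1, 1, 1)),
)

_NAME_BY_CORNER = {corner: name for name, corner in CORNER_ORDER}


def enumerate_corner_equilibria() -> list[StrategyProfile]:
    """The 16 pure-strategy fixed points in E1..E16 order."""
    return [StrategyProfile(*map(float, corner)) for _, corner in CORNER_ORDER]


def corner_name(corner: StrategyProfile) -> str:
    """E-label of a corner profile (E1..E16)."""
    key = tuple(int(round(v)) for v in corner)
    if not corner.is_corner():
        raise ValueError(f"{corner} is not a corner profile")
    return _NAME_BY_CORNER[key]


def corner_jacobian(p: GameParameters, corner: StrategyProfile) -> np.ndarray:
    """Jacobian of the replicator field at a pure-strategy corner.

    At a corner every off-diagonal entry vanishes (each cross-derivative
    carries a factor v(1-v) = 0), so the matrix is diagonal with entries
    (1-2x)G, (1-2y)H, (1-2z)P, (1-2w)(Cm-Cw) — the eigenvalues used by
    Lyapunov's first method.
    """
    if not corner.is_corner():
        raise ValueError(
            f"{corner} is not a corner; use finite differences of the "
            "replicator field for interior states"
        )
    return np.diag(replicator_rhs_derivative(p, corner))


def table_eigenvalues(p: GameParameters, name: str) -> tuple[float, float, float, float]:
    """The tabulated symbolic corner eigenvalues, evaluated at ``p``.

    These are the literal printed expressions of the stability tables,
    retained as an independent transcription of the corner Jacobian diagonal
    for cross-validation.  One correction is applied: the conventionally tabulated E16
    first eigenvalue carries a spurious ``-S`` term; direct evaluation of
    -G(1,1,1) gives Csh-Csl-Is-Ds-Fs-Io, which is what this function
    returns.
    """
    g = p.gamma
    table = {
        "E1": (
            p.Is * g + p.Csl - p.Csh + p.Ds * g + p.beta * p.Fs + p.beta * p.Io,
            p.Ie * g - p.Cei + p.S + p.De * g + p.beta * p.Fe,
            p.Fs + p.Fe - p.beta * p.Fs - p.beta * p.Fe + p.beta * p.Fg - p.Cg,
            p.Cm - p.Cw,
        ),
        "E2": (
            p.Csh - p.Csl - p.Is * g - p.Ds * g - p.beta * p.Fs - p.beta * p.Io,
            p.Ie * g + p.De * g + p.S - p.Cei,
            -p.Cg,
            p.Cm - p.Cw,
        ),
        "E3": (
            p.Is * g + p.Csl - p.Csh + p.Ds * g + p.Io,
            p.Cei - p.Ie * g - p.De * g - p.S - p.beta * p.Fe,
            p.Fs - p.Cg,
            p.Cm - p.Cw,
        ),
        "E4": (
            p.Is * g + p.Fs + p.Csl - p.Csh + p.Ds * g + p.Io,
            p.Ie * g - p.Cei + p.De * g + p.S + p.Fe,
            p.beta * p.Fe + p.beta * p.Fs + p.Cg - p.Fs - p.Fe - p.beta * p.Fg,
            p.Cm - p.Cw,
        ),
        "E5": (
            p.Csh - p.Csl - p.Is * g - p.Ds * g - p.Io,
            p.Cei - p.Ie * g - p.De * g - p.S,
            -p.Cg,
            p.Cm - p.Cw,
        ),
        "E6": (
            p.Is * g + p.Fs + p.Csl - p.Csh + p.Ds * g + p.Io,
            p.Cei - p.Ie * g - p.De * g - p.S - p.Fe,
            p.Cg - p.Fs,
            p.Cm - p.Cw,
        ),
        "E7": (
            p.Csh - p.Csl - p.Is * g - p.Ds * g - p.Fs - p.Io,
            p.Ie * g - p.Cei + p.De * g + p.S,
            p.Cg,
            p.Cm - p.Cw,
        ),
        "E8": (
            p.Csh - p.Csl - p.Is * g - p.Ds * g - p.Fs - p.Io,
            p.Cei - p.Ie * g - p.De * g - p.S,
            p.Cg,
            p.Cm - p.Cw,
        ),
        "E9": (
            p.Is + p.Csl - p.Csh + p.Ds + p.beta * p.Fs + p.beta * p.Io,
            p.Ie - p.Cei + p.De + p.S + p.beta * p.Fe,
            p.Fs + p.Fe - p.beta * p.Fs - p.beta * p.Fe + p.beta * p.Fg - p.Cg,
            p.Cw - p.Cm,
        ),
        "E10": (
            p.Csh - p.Csl - p.Is - p.Ds - p.beta * p.Fs - p.beta * p.Io,
            p.Ie + p.De + p.S - p.Cei,
            -p.Cg,
            p.Cw - p.Cm,
        ),
        "E11": (
            p.Is + p.Csl - p.Csh + p.Ds + p.Io,
            p.Cei - p.Ie - p.De - p.S - p.beta * p.Fe,
            p.Fs - p.Cg,
            p.Cw - p.Cm,
        ),
        "E12": (
            p.Is + p.Fs + p.Csl - p.Csh + p.Ds + p.Io,
            p.Ie - p.Cei + p.De + p.S + p.Fe,
            p.beta * p.Fe + p.beta * p.Fs + p.Cg - p.Fs - p.Fe - p.beta * p.Fg,
            p.Cw - p.Cm,
        ),
        "E13": (
            p.Csh - p.Csl - p.Is - p.Ds - p.Io,
            p.Cei - p.Ie - p.De - p.S,
            -p.Cg,
            p.Cw - p.Cm,
        ),
        "E14": (
            p.Is + p.Fs + p.Csl - p.Csh + p.Ds + p.Io,
            p.Cei - p.Ie - p.De - p.S - p.Fe,
            p.Cg - p.Fs,
            p.Cw - p.Cm,
        ),
        "E15": (
            p.Csh - p.Csl - p.Is - p.Ds - p.Fs - p.Io,
            p.Ie + p.De + p.S - p.Cei,
            p.Cg,
            p.Cw - p.Cm,
        ),
        "E16": (
            # corrected first entry; see docstring
            p.Csh - p.Csl - p.Is - p.Ds - p.Fs - p.Io,
            p.Cei - p.S - p.Ie - p.De,
            p.Cg,
            p.Cw - p.Cm,
        ),
    }
    return table[name]


def classify_equilibrium(
    eigs, tol: float = 1e-9
) -> str:
    """Lyapunov first-method label from the four corner eigenvalues.

    ``"ESS"`` if all eigenvalues are below ``-tol`` (locally asymptotically
    stable), ``"unstable"`` if any exceeds ``+tol``, else
    ``"indeterminate"`` (non-hyperbolic; never silently classified).
    """
    eigs = np.asarray(eigs, dtype=float)
    if not np.all(np.isfinite(eigs)):
        raise ValueError(f"non-finite eigenvalues: {eigs}")
    if np.all(eigs < -tol):
        return "ESS"
    if np.any(eigs > tol):
        return "unstable"
    return "indeterminate"


def _ess_condition(corner: tuple[int, int, int, int]) -> str:
    """Condition text for a corner, mirroring the stability tables."""
    x, _, z, w = corner
    lam4 = "Cm - Cw < 0" if w == 0 else "Cw - Cm < 0"
    if x == 1 and z == 1:
        return "never ESS: third eigenvalue is +Cg > 0"
    if x == 1 and z == 0:
        return f"ESS when lambda1 < 0 and lambda2 < 0 (lambda3 = -Cg < 0; {lam4})"
    return f"ESS when lambda1 < 0, lambda2 < 0 and lambda3 < 0 ({lam4})"


@dataclass(frozen=True)
class EquilibriumReport:
    """Stability record for one corner equilibrium."""

    name: str
    corner: StrategyProfile
    eigenvalues: tuple[float, float, float, float]
    label: str
    always_unstable: bool
    ess_condition: str


def stability_report(
    p: GameParameters,
    tol: float = 1e-9,
    n_draws: int = 1000,
    seed: int = 0,
) -> list[EquilibriumReport]:
    """Classify all 16 corners at ``p`` and flag unconditional instability.

    ``always_unstable`` is decided by sign-sampling: a corner is flagged
    when one of its four eigenvalue expressions evaluates positive in
    *every* of ``n_draws`` random admissible parameter sets (all magnitudes
    positive, rates in (0,1), Csh > Csl) — i.e. the expression is
    sign-definite, like the +Cg entry.  This reproduces the "+" sign
    judgements of the stability tables without a symbolic-algebra
    dependency: the corners with x = 1 and z = 1 carry +Cg and can never be
    stable.
    """
    rng = np.random.default_rng(seed)
    draws = [sample_admissible_parameters(rng) for _ in range(n_draws)]
    eig_samples = {
        name: np.array(
            [
                np.diag(corner_jacobian(q, StrategyProfile(*map(float, coords))))
                for q in draws
            ]
        )
        for name, coords in CORNER_ORDER
    }
    reports = []
    for name, coords in CORNER_ORDER:
        corner = StrategyProfile(*map(float, coords))
        eigs = tuple(float(v) for v in np.diag(corner_jacobian(p, corner)))
        label = classify_equilibrium(eigs, tol=tol)
        always = bool(np.any(np.all(eig_samples[name] > tol, axis=0)))
        reports.append(
            EquilibriumReport(
                name=name,
                corner=corner,
                eigenvalues=eigs,
                label=label,
                always_unstable=always,
                ess_condition=_ess_condition(coords),
            )
        )
    return reports


def reports_to_frame(reports: list[EquilibriumReport]) -> pd.DataFrame:
    """Stability report as a 16-row DataFrame for CSV/JSON export."""
    rows = []
    for r in reports:
        rows.append(
            {
                "name": r.name,
                "x": r.corner.x,
                "y": r.corner.y,
                "z": r.corner.z,
                "w": r.corner.w,
                "lambda1": r.eigenvalues[0],
                "lambda2": r.eigenvalues[1],
                "lambda3": r.eigenvalues[2],
                "lambda4": r.eigenvalues[3],
                "label": r.label,
                "always_unstable": r.always_unstable,
                "ess_condition": r.ess_condition,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """A critical parameter/probability level at which an incentive flips."""

    value: float
    context: dict
    interpretation: str


def _root_of_linear(f, lo_arg: float = 0.0, hi_arg: float = 1.0):
    """Root of an affine scalar function from two evaluations."""
    f0 = f(lo_arg)
    f1 = f(hi_arg)
    slope = (f1 - f0) / (hi_arg - lo_arg)
    return f0, slope


def threshold_w0(p: GameParameters, y: float, z: float) -> ThresholdResult:
    """Online-evaluation share above which providers evolve to high quality.

    Root in w of G(y, z, w) = 0; the w-coefficient of G is
    (1-gamma)(Is+Ds).  May fall outside [0,1], meaning the provider's
    incentive has a fixed sign on the whole unit interval.
    """
    def g(w: float) -> float:
        return incentive_difference(p, StrategyProfile(0.0, y, z, w), Player.PROVIDER)

    f0, slope = _root_of_linear(g)
    if abs(slope) < 1e-12:
        raise DegenerateThresholdError(
            "G does not depend on w: (1-gamma)(Is+Ds) = 0"
        )
    return ThresholdResult(
        value=-f0 / slope,
        context={"y": y, "z": z},
        interpretation=(
            "w above this value drives providers to high-quality service "
            "(x -> 1); below it, to low-quality (x -> 0)"
        ),
    )


def threshold_w1(p: GameParameters, x: float, z: float) -> ThresholdResult:
    """Online-evaluation share above which platforms evolve to positive visits.

    Root in w of H(x, z, w) = 0; the w-coefficient is (1-gamma)(Ie+De).
    """
    def h(w: float) -> float:
        return incentive_difference(p, StrategyProfile(x, 0.0, z, w), Player.PLATFORM)

    f0, slope = _root_of_linear(h)
    if abs(slope) < 1e-12:
        raise DegenerateThresholdError(
            "H does not depend on w: (1-gamma)(Ie+De) = 0"
        )
    return ThresholdResult(
        value=-f0 / slope,
        context={"x": x, "z": z},
        interpretation=(
            "w above this value drives platforms to positive return visits "
            "(y -> 1); below it, to negative visits (y -> 0)"
        ),
    )


def threshold_x0(p: GameParameters, y: float) -> ThresholdResult:
    """High-quality share above which the government relaxes regulation.

    Root in x of P(x, y) = 0, equal to 1 - Cg/[Fs + (1-y)m] with
    m = Fe - beta*Fs - beta*Fe + beta*Fg.  P is decreasing in x, so above
    the threshold regulation drifts negative (z -> 0), below it positive.
    """
    def f(x: float) -> float:
        return incentive_difference(p, StrategyProfile(x, y, 0.0, 0.0), Player.GOVERNMENT)

    f0, slope = _root_of_linear(f)
    if abs(slope) < 1e-12:
        raise DegenerateThresholdError(
            "P does not depend on x: Fs + (1-y)m = 0"
        )
    return ThresholdResult(
        value=-f0 / slope,
        context={"y": y},
        interpretation=(
            "x above this value drives the government to negative regulation "
            "(z -> 0); below it, to positive regulation (z -> 1)"
        ),
    )


def penalty_threshold_Fs(
    p: GameParameters, w: float, y: float, z: float
) -> ThresholdResult:
    """Provider fine above which high-quality service becomes dominant.

    Value of Fs making G(y, z, w) vanish.  The Fs-coefficient of G is
    z + (1-y)(1-z)beta; when it vanishes (no regulation and no complaint
    channel) no finite fine can flip the provider.
    """
    def g_at(fs: float) -> float:
        q = p.replace(Fs=fs)
        return incentive_difference(q, StrategyProfile(0.0, y, z, w), Player.PROVIDER)

    f0, slope = _root_of_linear(g_at)
    if abs(slope) < 1e-12:
        raise DegenerateThresholdError(
            "Fs has no effect: z + (1-y)(1-z)beta = 0; no finite penalty threshold"
        )
    return ThresholdResult(
        value=-f0 / slope,
        context={"w": w, "y": y, "z": z},
        interpretation=(
            "fines above this level make the provider's incentive favour "
            "high-quality service at the given (w, y, z)"
        ),
    )


def subsidy_threshold_S(
    p: GameParameters, w: float, x: float, z: float
) -> ThresholdResult:
    """Platform subsidy above which positive return visits become dominant.

    Value of S making H(x, z, w) vanish; the S-coefficient of H is exactly
    1, so the threshold always exists.  A negative value means any
    non-negative subsidy suffices.
    """
    def h_at(s_val: float) -> float:
        q = p.replace(S=s_val)
        return incentive_difference(q, StrategyProfile(x, 0.0, z, w), Player.PLATFORM)

    f0, slope = _root_of_linear(h_at)
    return ThresholdResult(
        value=-f0 / slope,
        context={"w": w, "x": x, "z": z},
        interpretation=(
            "subsidies above this level make the platform's incentive favour "
            "positive return visits at the given (w, x, z)"
        ),
    )


def superior_penalty_threshold_Fg(
    p: GameParameters, x: float, y: float
) -> ThresholdResult:
    """Superior-government penalty above which positive regulation is favoured.

    Value of Fg making P(x, y) vanish.  The Fg-coefficient of P is
    (1-x)(1-y)beta; with a fully compliant provider, a fully visiting
    platform, or no complaints, Fg cannot influence the government.
    """
    def f_at(fg: float) -> float:
        q = p.replace(Fg=fg)
        return incentive_difference(q, StrategyProfile(x, y, 0.0, 0.0), Player.GOVERNMENT)

    f0, slope = _root_of_linear(f_at)
    if abs(slope) < 1e-12:
        raise DegenerateThresholdError(
            "Fg has no effect: (1-x)(1-y)beta = 0; no finite penalty threshold"
        )
    return ThresholdResult(
        value=-f0 / slope,
        context={"x": x, "y": y},
        interpretation=(
            "superior-government penalties above this level make positive "
            "regulation the government's favoured strategy at the given (x, y)"
        ),
    )


@dataclass(frozen=True)
class VolumeResult:
    """Raw and clamped strategy volumes (V0, V1) for one population.

    The raw pair satisfies V0 + V1 = 1 but either member may leave [0,1]
    (the integrand is an unclamped threshold surface); the clamped variants
    are the probability-interpretable values.
    """

    which: str
    v0: float
    v1: float
    v0_clamped: float
    v1_clamped: float
    context: dict


def _clamp01(v: float) -> float:
    return min(max(v, 0.0), 1.0)


def strategy_volumes(
    p: GameParameters,
    which: str,
    y: float | None = None,
    z: float | None = None,
) -> VolumeResult:
    """Closed-form strategy volumes for one population.

    ``which = "provider"`` (requires ``y``): Vx0 = (2a+b)/[2(1-g)(Is+Ds)]
    with a = Csh-Csl-Is*g-Ds*g-y*Io-beta(1-y)(Fs+Io) and
    b = (1-y)(beta*Fs+beta*Io-Io)-Fs — the probability mass of settling on
    low quality, from integrating the w0 surface over (z, x).

    ``which = "platform"`` (requires ``z``): Vy0 = (2c-d)/[2(1-g)(Ie+De)]
    with c = Cei-S-Ie*g-De*g, d = z*Fe+(1-z)*beta*Fe.

    ``which = "government"``: Vz1 = 1 - Cg*ln|1+m/Fs|/m with
    m = Fe-beta*Fs-beta*Fe+beta*Fg, from integrating 1 - Cg/[Fs+(1-y)m]
    over y; the m -> 0 limit is Cg/Fs.  Fs = 0 is a domain error.
    """
    g = p.gamma
    if which == "provider":
        if y is None:
            raise ValueError("provider volumes require the platform probability y")
        a = p.Csh - p.Csl - p.Is * g - p.Ds * g - y * p.Io - p.beta * (1 - y) * (
            p.Fs + p.Io
        )
        b = (1 - y) * (p.beta * p.Fs + p.beta * p.Io - p.Io) - p.Fs
        denom = 2 * (1 - g) * (p.Is + p.Ds)
        if denom == 0:
            raise DegenerateThresholdError("(1-gamma)(Is+Ds) = 0")
        v0 = (2 * a + b) / denom
        context = {"y": y, "a": a, "b": b}
    elif which == "platform":
        if z is None:
            raise ValueError("platform volumes require the government probability z")
        c = p.Cei - p.S - p.Ie * g - p.De * g
        d = z * p.Fe + (1 - z) * p.beta * p.Fe
        denom = 2 * (1 - g) * (p.Ie + p.De)
        if denom == 0:
            raise DegenerateThresholdError("(1-gamma)(Ie+De) = 0")
        v0 = (2 * c - d) / denom
        context = {"z": z, "c": c, "d": d}
    elif which == "government":
        if p.Fs == 0:
            raise DegenerateThresholdError(
                "government volume undefined for Fs = 0"
            )
        m = p.Fe - p.beta * p.Fs - p.beta * p.Fe + p.beta * p.Fg
        if abs(m) < 1e-12:
            v1 = 1 - p.Cg / p.Fs
        else:
            v1 = 1 - p.Cg * math.log(abs(1 + m / p.Fs)) / m
        v0 = 1 - v1
        context = {"m": m}
    else:
        raise ValueError(f"unknown population {which!r}")
    v1 = 1 - v0
    return VolumeResult(
        which=which,
        v0=v0,
        v1=v1,
        v0_clamped=_clamp01(v0),
        v1_clamped=_clamp01(v1),
        context=context,
    )
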