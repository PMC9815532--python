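"""Parameter set and strategy state for the four-party elderly-care regulation game.

The model couples four boundedly rational populations — elderly-care service
providers, elderly-care service information platforms, a junior government,
and the elderly themselves — through revenues, costs, fines, subsidies,
compensation and reputation effects.  This module defines the immutable
parameter container, its validation rules, the canonical baseline parameter
set used throughout the analysis, and flat YAML/JSON config round-tripping.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "GameParameters",
    "StrategyProfile",
    "ValidationReport",
    "PARAMETER_FIELDS",
    "RATE_FIELDS",
    "make_baseline_parameters",
    "validate_parameters",
    "scale_parameter",
    "load_parameters",
    "save_parameters",
    "sample_admissible_parameters",
]


@dataclass(frozen=True)
class GameParameters:
    """The 25 model constants of the regulation game.

    Monetary quantities are in abstract currency units; ``alpha``, ``beta``
    and ``gamma`` are dimensionless rates in [0, 1].

    Attributes
    ----------
    Rs : float
        Total revenue shared by provider and platform for one service.
    alpha : float
        Platform commission share of ``Rs``.
    Csh, Csl : float
        Provider cost of high- / low-quality service (``Csh > Csl``).
    Io : float
        Compensation paid to the elderly when service quality is low.
    Fs : float
        Government fine on providers for low-quality service.  Never named
        explicitly in the model hypotheses, this is the "administrative
        penalty from the government" levied on providers, distinct from the
        compensation ``Io``.
    Is, Ds : float
        Provider reputational gain (high quality) / loss (low quality).
    Cei : float
        Platform cost of making positive return visits.
    Ceo : float
        Platform operating cost.
    S : float
        Government operating subsidy to a positively-visiting platform.
    Fe : float
        Government fine on a negatively-visiting platform when providers are
        confirmed low-quality.
    Ie, De : float
        Platform reputational gain / loss.
    Cg : float
        Government cost of positive regulation.
    Fg : float
        Penalty from the superior government on a negatively-regulating
        junior government after an elderly complaint.
    Rg : float
        Social welfare generated by high-quality service.
    Dg : float
        Social loss caused by low-quality service.
    Cw, Cm : float
        Elderly cost of online / offline evaluation.
    Ro : float
        Elderly gain utility from high-quality service.
    Do : float
        Elderly damage from low-quality service.
    Co : float
        Elderly cost of filing a complaint.
    beta : float
        Elderly complaint rate.
    gamma : float
        Offline social-network size: the share of potential customers an
        offline evaluation reaches relative to an online one.
    """

    Rs: float
    alpha: float
    Csh: float
    Csl: float
    Io: float
    Fs: float
    Is: float
    Ds: float
    Cei: float
    Ceo: float
    S: float
    Fe: float
    Ie: float
    De: float
    Cg: float
    Fg: float
    Rg: float
    Dg: float
    Cw: float
    Cm: float
    Ro: float
    Do: float
    Co: float
    beta: float
    gamma: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given fields replaced."""
        unknown = set(changes) - set(PARAMETER_FIELDS)
        if unknown:
            raise KeyError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)


PARAMETER_FIELDS: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(GameParameters)
)

#: Fields constrained to [0, 1]; all others are non-negative magnitudes.
RATE_FIELDS: frozenset[str] = frozenset({"alpha", "beta", "gamma"})


@dataclass(frozen=True)
class StrategyProfile:
    """Mixed-strategy state (x, y, z, w) of the four populations.

    ``x``: probability the provider offers high-quality service (HQ);
    ``y``: probability the platform makes positive return visits (PV);
    ``z``: probability the government regulates positively (PR);
    ``w``: probability the elderly evaluate online (ON).
    """

    x: float
    y: float
    z: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.w], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StrategyProfile":
        x, y, z, w = (float(v) for v in arr)
        return cls(x, y, z, w)

    def is_valid(self, tol: float = 0.0) -> bool:
        return all(-tol <= v <= 1.0 + tol for v in self.as_array())

    def is_corner(self, tol: float = 1e-12) -> bool:
        return all(abs(v) <= tol or abs(v - 1.0) <= tol for v in self.as_array())

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z, self.w))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a parameter check: ``ok`` iff ``violations`` is empty."""

    ok: bool
    violations: tuple[str, ...]

    @classmethod
    def from_violations(cls, violations: list[str]) -> "ValidationReport":
        return cls(ok=not violations, violations=tuple(violations))


def make_baseline_parameters() -> GameParameters:
    """Return the canonical baseline parameter set.

    Percentages (α = 10 %, β = 1 %, γ = 5 %) are stored as fractions because
    every payoff expression uses them multiplicatively.
    """
    return GameParameters(
        Rs=100.0,
        alpha=0.10,
        Csh=50.0,
        Csl=25.0,
        Io=10.0,
        Fs=20.0,
        Is=20.0,
        Ds=22.0,
        Cei=5.0,
        Ceo=15.0,
        S=10.0,
        Fe=5.0,
        Ie=10.0,
        De=12.0,
        Cg=10.0,
        Fg=200.0,
        Rg=40.0,
        Dg=40.0,
        Cw=8.0,
        Cm=10.0,
        Ro=20.0,
        Do=30.0,
        Co=5.0,
        beta=0.01,
        gamma=0.05,
    )


def validate_parameters(p: GameParameters) -> ValidationReport:
    """Check bounds on a parameter set without raising.

    Rates must lie in [0, 1], magnitudes must be non-negative and finite,
    and the high-quality cost must exceed the low-quality cost
    (``Csh > Csl``) — cutting corners has to save money for the game to be
    non-trivial.
    """
    violations: list[str] = []
    for name in PARAMETER_FIELDS:
        value = getattr(p, name)
        if not math.isfinite(value):
            violations.append(f"{name} = {value} is not finite")
        elif name in RATE_FIELDS:
            if not 0.0 <= value <= 1.0:
                violations.append(f"{name} = {value} outside [0, 1]")
        elif value < 0.0:
            violations.append(f"{name} = {value} is negative")
    if math.isfinite(p.Csh) and math.isfinite(p.Csl) and p.Csh <= p.Csl:
        violations.append(
            f"Csh = {p.Csh} must exceed Csl = {p.Csl} (high-quality service costs more)"
        )
    return ValidationReport.from_violations(violations)


def scale_parameter(p: GameParameters, name: str, factor: float) -> GameParameters:
    """Return a copy of ``p`` with one field multiplied by ``factor``.

    This is the sensitivity-scenario primitive (e.g. fluctuating the provider
    fine Fs up and down by 50 %).  Raises ``KeyError`` for an unknown field,
    ``ValueError`` for a non-positive factor or when the scaled set violates
    the parameter bounds.
    """
    if name not in PARAMETER_FIELDS:
        raise KeyError(f"unknown parameter field: {name!r}")
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    scaled = p.replace(**{name: getattr(p, name) * factor})
    report = validate_parameters(scaled)
    if not report.ok:
        raise ValueError(
            f"scaling {name} by {factor} breaks parameter bounds: "
            + "; ".join(report.violations)
        )
    return scaled


def load_parameters(path: str | Path) -> GameParameters:
    """Load a parameter set from a flat YAML or JSON mapping.

    The file must contain exactly the ``GameParameters`` field names; unknown
    keys raise ``KeyError`` (typo guard for scenario configs), missing keys
    raise ``KeyError`` too.  Values violating the bounds raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return parameters_from_dict(data, source=str(path))


def parameters_from_dict(data: dict, source: str = "<dict>") -> GameParameters:
    unknown = set(data) - set(PARAMETER_FIELDS)
    if unknown:
        raise KeyError(f"{source}: unknown parameter key(s): {sorted(unknown)}")
    missing = set(PARAMETER_FIELDS) - set(data)
    if missing:
        raise KeyError(f"{source}: missing parameter key(s): {sorted(missing)}")
    p = GameParameters(**{k: float(v) for k, v in data.items()})
    report = validate_parameters(p)
    if not report.ok:
        raise ValueError(f"{source}: invalid parameters: " + "; ".join(report.violations))
    return p


def save_parameters(p: GameParameters, path: str | Path) -> None:
    """Write a parameter set as a flat YAML (default) or JSON mapping."""
    path = Path(path)
    data = p.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def sample_admissible_parameters(
    rng: np.random.Generator,
    magnitude_low: float = 0.5,
    magnitude_high: float = 60.0,
) -> GameParameters:
    """Draw one random admissible parameter set.

    Magnitudes are uniform on ``[magnitude_low, magnitude_high]``, rates
    uniform on (0, 1), and ``Csh`` is forced above ``Csl`` by a positive
    margin so the Hypothesis-level constraint always holds.  Used for
    sign-sampling the corner eigenvalue expressions and for property tests.
    """
    def mag() -> float:
        return float(rng.uniform(magnitude_low, magnitude_high))

    csl = mag()
    csh = csl + float(rng.uniform(0.1, magnitude_high))
    values = {name: mag() for name in PARAMETER_FIELDS}
    values.update(
        Csl=csl,
        Csh=csh,
        alpha=float(rng.uniform(0.0, 1.0)),
        beta=float(rng.uniform(1e-3, 1.0)),
        gamma=float(rng.uniform(1e-3, 0.999)),
    )
    return GameParameters(**values)
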