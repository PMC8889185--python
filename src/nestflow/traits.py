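"""Per-agent behavioural traits: activity level and turning index.

Each worker agent carries two fixed traits. The activity level ``A_i`` gates
how often the agent moves (and, by default, initiates interactions): on a
given time step the agent is active iff an Exp(mean 1) draw falls below
``A_i``. The turning index ``T_i`` is the standard deviation, in degrees, of
the per-step heading change of its correlated random walk; large values give
sinuous, spatially faithful paths, small values give straight, far-ranging
paths.

Five population-level conditions control how the traits are distributed:
all-uniform, one trait variable, both variable and independent, or both
variable with a perfect negative rank pairing (a "behavioural syndrome":
the most active agents walk the straightest paths).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Condition",
    "AgentTraits",
    "TraitSet",
    "assign_activity",
    "assign_turning",
    "build_traits",
]


class Condition(str, enum.Enum):
    """Population-level behavioural condition."""

    UNIFORM = "uniform"
    ACTIVITY_VARIABLE = "activity_variable"
    TI_VARIABLE = "ti_variable"
    UNCORRELATED = "uncorrelated"
    CORRELATED = "correlated"

    @property
    def activity_varies(self) -> bool:
        return self in (
            Condition.ACTIVITY_VARIABLE,
            Condition.UNCORRELATED,
            Condition.CORRELATED,
        )

    @property
    def turning_varies(self) -> bool:
        return self in (
            Condition.TI_VARIABLE,
            Condition.UNCORRELATED,
            Condition.CORRELATED,
        )


class AgentTraits(NamedTuple):
    """Traits of a single agent."""

    agent_id: int
    activity: float
    turning: float


@dataclass(frozen=True)
class TraitSet:
    """Trait vectors for a whole population.

    ``activity`` and ``turning`` are aligned float arrays indexed by agent id.
    """

    activity: np.ndarray
    turning: np.ndarray
    condition: Condition

    def __post_init__(self) -> None:
        if self.activity.shape != self.turning.shape or self.activity.ndim != 1:
            raise ConfigurationError("activity and turning must be aligned 1-d arrays")
        if np.any(self.activity <= 0):
            raise ConfigurationError("every activity level must be > 0")
        if np.any(self.turning < 0):
            raise ConfigurationError("every turning index must be >= 0")

    def __len__(self) -> int:
        return self.activity.shape[0]

    def __getitem__(self, agent_id: int) -> AgentTraits:
        return AgentTraits(
            agent_id, float(self.activity[agent_id]), float(self.turning[agent_id])
        )

    def __iter__(self) -> Iterator[AgentTraits]:
        for i in range(len(self)):
            yield self[i]

    def to_csv(self, path: str | Path) -> None:
        """Write ``agent_id,activity,turning`` rows for audit/replay."""
        import pandas as pd

        pd.DataFrame(
            {
                "agent_id": np.arange(len(self)),
                "activity": self.activity,
                "turning": self.turning,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, condition: Condition) -> "TraitSet":
        import pandas as pd

        df = pd.read_csv(path).sort_values("agent_id")
        return cls(
            activity=df["activity"].to_numpy(float),
            turning=df["turning"].to_numpy(float),
            condition=condition,
        )


def assign_activity(
    n: int, a_m: float, variable: bool, rng: np.random.Generator
) -> np.ndarray:
    """Draw activity levels for ``n`` agents.

    Uniform populations share the mean ``a_m``; variable populations draw
    i.i.d. from an exponential distribution with mean ``a_m`` (so most agents
    are relatively inactive while a few are highly active).
    """
    if n < 1:
        raise ConfigurationError(f"need at least one agent, got n={n}")
    if a_m <= 0:
        raise ConfigurationError(f"mean activity must be > 0, got {a_m}")
    if not variable:
        return np.full(n, float(a_m))
    return rng.exponential(scale=a_m, size=n)


def assign_turning(
    n: int, t_m: float, variable: bool, rng: np.random.Generator
) -> np.ndarray:
    """Draw turning indices (degrees) for ``n`` agents.

    Uniform populations share ``t_m``. Variable populations draw
    ``x ~ Exponential(mean t_m)`` and reflect it about the mean,
    ``T_i = 2 t_m - x``, redrawing whenever the reflection would be negative.
    The reflection turns the right-skewed exponential into a left-skewed
    distribution on ``(0, 2 t_m]``: most agents have high turning indices
    (tortuous paths) while a few have low ones (straight paths).
    """
    if n < 1:
        raise ConfigurationError(f"need at least one agent, got n={n}")
    if t_m <= 0:
        raise ConfigurationError(f"mean turning index must be > 0, got {t_m}")
    if not variable:
        return np.full(n, float(t_m))
    out = 2.0 * t_m - rng.exponential(scale=t_m, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = 2.0 * t_m - rng.exponential(scale=t_m, size=int(bad.sum()))
        bad = out < 0
    return out


def build_traits(
    n: int,
    a_m: float,
    t_m: float,
    condition: Condition,
    rng: np.random.Generator,
) -> TraitSet:
    """Assign (activity, turning) pairs to ``n`` agents under a condition.

    Under ``uncorrelated`` the two trait vectors are drawn independently.
    Under ``correlated`` the drawn values are paired by opposite rank — the
    agent with the largest activity gets the smallest turning index and so on
    (Spearman correlation exactly −1) — and the resulting pairs are then
    shuffled across agent ids, which are arbitrary labels.
    """
    condition = Condition(condition)
    activity = assign_activity(n, a_m, condition.activity_varies, rng)
    turning = assign_turning(n, t_m, condition.turning_varies, rng)
    if condition is Condition.CORRELATED:
        a_sorted = np.sort(activity)                # ascending
        t_sorted = np.sort(turning)[::-1]           # descending: opposite ranks
        perm = rng.permutation(n)
        activity = np.empty(n)
        turning = np.empty(n)
        activity[perm] = a_sorted
        turning[perm] = t_sorted
    return TraitSet(activity=activity, turning=turning, condition=condition)
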