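"""Agent-based model of worker movement and directed pairwise interactions.

Agents live on a bounded square nest (50 x 50 patches by default) and perform
activity-gated correlated random walks: on each time step an agent is active
iff an Exp(mean 1) draw falls below its activity level ``A_i``; an active
agent turns by a Normal(0, ``T_i`` degrees) angle and advances one body
length (0.5 patches), with coordinates clamped to the nest boundary.

After all agents have moved, each agent — visited in a fresh random order —
may initiate at most one directed interaction with a uniformly chosen
neighbour within the interaction radius (0.5 patches). Which agents initiate
and which partner becomes the signaller are governed by the initiation and
direction rule variants. The simulator's sole output is the time-ordered
interaction log ``(t, signaller, receiver)``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .traits import Condition, TraitSet, build_traits

__all__ = [
    "InitiationRule",
    "DirectionRule",
    "SimConfig",
    "AgentState",
    "InteractionEvent",
    "InteractionLog",
    "is_active",
    "move_agent",
    "find_neighbours",
    "interaction_phase",
    "run_simulation",
]


class InitiationRule(str, enum.Enum):
    """Who may initiate an interaction on a step."""

    BY_ACTIVITY = "by_activity"   # only currently active agents initiate
    RANDOM_HALF = "random_half"   # any agent initiates with probability 0.5


class DirectionRule(str, enum.Enum):
    """How the signaller of an initiated interaction is chosen."""

    ACTIVE_OUTGOING = "active_outgoing"      # initiator signals (default)
    RANDOM = "random"                        # fair coin
    RELATIVE_ACTIVITY = "relative_activity"  # i signals w.p. A_i/(A_i+A_j)
    TO_ACTIVE = "to_active"                  # initiator receives

    @property
    def activity_determined(self) -> bool:
        """Whether agent activity levels influence edge direction."""
        return self in (
            DirectionRule.ACTIVE_OUTGOING,
            DirectionRule.RELATIVE_ACTIVITY,
            DirectionRule.TO_ACTIVE,
        )


@dataclass(frozen=True)
class SimConfig:
    """Complete, serialisable description of one simulation run."""

    n_agents: int = 100
    n_steps: int = 5000
    grid_size: float = 50.0
    step_length: float = 0.5
    interaction_radius: float = 0.5
    a_m: float = 1.0
    t_m: float = 60.0
    condition: Condition = Condition.UNIFORM
    initiation_rule: InitiationRule = InitiationRule.BY_ACTIVITY
    direction_rule: DirectionRule = DirectionRule.ACTIVE_OUTGOING
    boundary: str = "reflect"  # "reflect" (billiard bounce) or "clamp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigurationError("n_agents must be >= 2")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.grid_size <= 0:
            raise ConfigurationError("grid_size must be > 0")
        if self.interaction_radius <= 0:
            raise ConfigurationError("interaction_radius must be > 0")
        if self.step_length <= 0:
            raise ConfigurationError("step_length must be > 0")
        if self.a_m <= 0 or self.t_m <= 0:
            raise ConfigurationError("a_m and t_m must be > 0")
        if self.boundary not in ("reflect", "clamp"):
            raise ConfigurationError("boundary must be 'reflect' or 'clamp'")
        # normalise string inputs to enums on the frozen dataclass
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "initiation_rule", InitiationRule(self.initiation_rule))
        object.__setattr__(self, "direction_rule", DirectionRule(self.direction_rule))

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k in ("condition", "initiation_rule", "direction_rule"):
            d[k] = d[k].value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class AgentState:
    """Position, heading (degrees, math convention: 0 = +x, 90 = +y) and
    current-step activity flag of one agent."""

    x: float
    y: float
    heading: float
    active: bool = False


class InteractionEvent(NamedTuple):
    t: int
    signaller: int
    receiver: int


@dataclass(frozen=True)
class InteractionLog:
    """Time-ordered directed interaction events plus their provenance.

    ``t``, ``signaller`` and ``receiver`` are aligned integer arrays, sorted
    by time step; within a step, rows keep the randomised initiation order.
    """

    t: np.ndarray
    signaller: np.ndarray
    receiver: np.ndarray
    config: SimConfig
    traits: TraitSet | None = None

    def __post_init__(self) -> None:
        if not (self.t.shape == self.signaller.shape == self.receiver.shape):
            raise ConfigurationError("log columns must be aligned")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ConfigurationError("events must be sorted by time step")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n_agents(self) -> int:
        return self.config.n_agents

    @property
    def n_steps(self) -> int:
        return self.config.n_steps

    @property
    def events(self) -> Iterator[InteractionEvent]:
        for k in range(len(self)):
            yield InteractionEvent(
                int(self.t[k]), int(self.signaller[k]), int(self.receiver[k])
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "signaller": self.signaller, "receiver": self.receiver}
        )

    def to_csv(self, path: str | Path, metadata: bool = True) -> None:
        """Write the log as CSV (header ``t,signaller,receiver``) plus a JSON
        sidecar ``<path>.meta.json`` carrying the full configuration."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if metadata:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(self.config.to_dict(), fh, indent=1)

    @classmethod
    def from_csv(cls, path: str | Path, config: SimConfig | None = None) -> "InteractionLog":
        path = Path(path)
        if config is None:
            meta = Path(str(path) + ".meta.json")
            if not meta.exists():
                raise ConfigurationError(
                    f"no config given and no metadata sidecar at {meta}"
                )
            config = SimConfig.from_dict(json.loads(meta.read_text()))
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(np.int64),
            signaller=df["signaller"].to_numpy(np.int64),
            receiver=df["receiver"].to_numpy(np.int64),
            config=config,
        )

    def replace_events(
        self, t: np.ndarray, signaller: np.ndarray, receiver: np.ndarray
    ) -> "InteractionLog":
        return InteractionLog(
            t=t, signaller=signaller, receiver=receiver,
            config=self.config, traits=self.traits,
        )


def is_active(activity: float, rng: np.random.Generator) -> bool:
    """One activation trial: active iff an Exp(mean 1) draw is below ``A_i``.

    The resulting activation probability is ``1 - exp(-A_i)`` per step.
    """
    if activity <= 0:
        raise ConfigurationError("activity must be > 0")
    return bool(rng.exponential(1.0) < activity)


def _draw_active(activity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised activation trials for the whole population."""
    return rng.exponential(1.0, size=activity.shape[0]) < activity


def _advance(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    active: np.ndarray,
    turning: np.ndarray,
    step_length: float,
    grid_size: float,
    rng: np.random.Generator,
    boundary: str = "reflect",
) -> None:
    """In-place movement update for all active agents.

    Heading gains Normal(0, T_i) degrees (wrapped mod 360) and the agent
    advances ``step_length`` along the new heading. A move that would cross
    the nest wall has the offending coordinate set to the boundary; under the
    default ``reflect`` rule the heading is additionally mirrored in that
    wall (x-wall: h -> 180 - h; y-wall: h -> -h; both at a corner), so agents
    bounce off the walls instead of crawling along them. The ``clamp``
    variant leaves the heading untouched, which makes near-straight walkers
    linger at walls and corners. Movement is independent across agents, so a
    vectorised update is exactly equivalent to any sequential per-agent
    order.
    """
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return
    dtheta = rng.normal(0.0, turning[idx])
    h = np.mod(heading[idx] + dtheta, 360.0)
    rad = np.deg2rad(h)
    nx = x[idx] + step_length * np.cos(rad)
    ny = y[idx] + step_length * np.sin(rad)
    if boundary == "reflect":
        out_x = (nx < 0.0) | (nx > grid_size)
        out_y = (ny < 0.0) | (ny > grid_size)
        h[out_x] = np.mod(180.0 - h[out_x], 360.0)
        h[out_y] = np.mod(-h[out_y], 360.0)
    heading[idx] = h
    x[idx] = np.clip(nx, 0.0, grid_size)
    y[idx] = np.clip(ny, 0.0, grid_size)


def move_agent(
    state: AgentState,
    traits,
    rng: np.random.Generator,
    config: SimConfig,
) -> AgentState:
    """Single-agent movement update (inactive agents do not move).

    ``traits`` is anything with a ``turning`` attribute (an ``AgentTraits``
    tuple). Delegates to the same kernel as the full simulation.
    """
    if not state.active:
        return state
    x = np.array([state.x])
    y = np.array([state.y])
    heading = np.array([state.heading])
    _advance(
        x, y, heading,
        np.array([True]),
        np.array([float(traits.turning)]),
        config.step_length, config.grid_size, rng, config.boundary,
    )
    return AgentState(float(x[0]), float(y[0]), float(heading[0]), True)


def find_neighbours(
    agent_id: int, positions: np.ndarray, radius: float
) -> np.ndarray:
    """Ids of all other agents within Euclidean distance ``radius``
    (inclusive) of the focal agent. ``positions`` is an (n, 2) array."""
    if radius <= 0:
        raise ConfigurationError("radius must be > 0")
    d2 = np.sum((positions - positions[agent_id]) ** 2, axis=1)
    close = np.flatnonzero(d2 <= radius * radius)
    return close[close != agent_id]


def interaction_phase(
    x: np.ndarray,
    y: np.ndarray,
    active: np.ndarray,
    activity: np.ndarray,
    t: int,
    initiation_rule: InitiationRule,
    direction_rule: DirectionRule,
    order_rng: np.random.Generator,
    choice_rng: np.random.Generator,
    radius: float,
) -> list[InteractionEvent]:
    """One interaction phase: visit agents in a fresh random order; each may
    initiate at most one directed interaction with a uniform neighbour.

    Under ``by_activity`` only currently active agents with at least one
    neighbour initiate; under ``random_half`` any agent with a neighbour
    initiates with probability 0.5 regardless of activity. The direction rule
    then assigns signaller and receiver (see :class:`DirectionRule`). An agent
    may be the receiver of several initiators within one step.
    """
    n = x.shape[0]
    r2 = radius * radius
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    mask = (dx * dx + dy * dy) <= r2
    np.fill_diagonal(mask, False)
    has_nb = mask.any(axis=1)

    if initiation_rule is InitiationRule.BY_ACTIVITY:
        initiates = active & has_nb
    else:
        initiates = has_nb.copy()
        cand = np.flatnonzero(has_nb)
        if cand.size:
            initiates[cand] = choice_rng.random(cand.size) < 0.5

    order = order_rng.permutation(n)
    events: list[InteractionEvent] = []
    for i in order[initiates[order]]:
        nbrs = np.flatnonzero(mask[i])
        j = int(nbrs[choice_rng.integers(nbrs.size)])
        i = int(i)
        if direction_rule is DirectionRule.ACTIVE_OUTGOING:
            s, r = i, j
        elif direction_rule is DirectionRule.TO_ACTIVE:
            s, r = j, i
        elif direction_rule is DirectionRule.RANDOM:
            s, r = (i, j) if choice_rng.random() < 0.5 else (j, i)
        else:  # RELATIVE_ACTIVITY
            p = activity[i] / (activity[i] + activity[j])
            s, r = (i, j) if choice_rng.random() < p else (j, i)
        events.append(InteractionEvent(t, s, r))
    return events


def run_simulation(config: SimConfig, traits: TraitSet | None = None) -> InteractionLog:
    """Run the full simulation and return the time-ordered interaction log.

    The master seed is split into independent child streams (traits,
    placement, activation, movement noise, order shuffles, interaction
    choices) so each source of randomness is reproducible in isolation.
    Identical configurations produce identical logs.
    """
    ss = np.random.SeedSequence(config.seed)
    (r_traits, r_place, r_act, r_move, r_order, r_inter) = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    if traits is None:
        traits = build_traits(
            config.n_agents, config.a_m, config.t_m, config.condition, r_traits
        )
    elif len(traits) != config.n_agents:
        raise ConfigurationError("traits size does not match n_agents")

    n = config.n_agents
    x = r_place.uniform(0.0, config.grid_size, n)
    y = r_place.uniform(0.0, config.grid_size, n)
    heading = r_place.uniform(0.0, 360.0, n)
    activity = traits.activity
    turning = traits.turning

    ts: list[int] = []
    ss_: list[int] = []
    rs: list[int] = []
    for t in range(1, config.n_steps + 1):
        active = _draw_active(activity, r_act)
        _advance(x, y, heading, active, turning,
                 config.step_length, config.grid_size, r_move, config.boundary)
        for ev in interaction_phase(
            x, y, active, activity, t,
            config.initiation_rule, config.direction_rule,
            r_order, r_inter, config.interaction_radius,
        ):
            ts.append(ev.t)
            ss_.append(ev.signaller)
            rs.append(ev.receiver)

    return InteractionLog(
        t=np.asarray(ts, dtype=np.int64),
        signaller=np.asarray(ss_, dtype=np.int64),
        receiver=np.asarray(rs, dtype=np.int64),
        config=config,
        traits=traits,
    )
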