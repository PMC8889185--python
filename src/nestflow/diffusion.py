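"""Time-ordered information diffusion over an interaction log.

A single piece of information is seeded on the signaller of the first logged
event. Events are then replayed in time order (within a step, in logged
order): whenever an informed agent signals to a naive receiver, the receiver
becomes informed and can itself transmit in any later event, including later
events of the same time step. Two summaries are recorded: ``T50``, the
earliest step at which at least half the population is informed, and
*efficiency*, the cumulative number of outgoing interactions from informed
agents (to naive or informed partners) up to and including step ``T50`` —
fewer outgoing interactions per agent informed means more efficient spread.

``thin_interactions`` implements the interaction-rate control: conditions
with uniform activity levels generate substantially more interactions, so a
fixed fraction of their events is removed at random before diffusion to
equalise interaction rates across conditions without altering the patterning
of the remaining interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import InteractionLog, SimConfig, run_simulation
from .errors import ConfigurationError
from .traits import Condition

__all__ = [
    "DiffusionResult",
    "thin_interactions",
    "simulate_diffusion",
    "run_diffusion_experiment",
    "simulate_static_diffusion",
]


@dataclass(frozen=True)
class DiffusionResult:
    """Outcome of one diffusion replay.

    ``informed_trajectory[t]`` is the informed count at the end of step ``t``
    (index 0 holds the initial count of 1). ``t50`` and ``efficiency`` are
    ``None`` when the 50% threshold is never reached within the log.
    """

    seed_agent: int
    informed_trajectory: np.ndarray
    t50: int | None
    efficiency: int | None

    @property
    def reached_half(self) -> bool:
        return self.t50 is not None


def thin_interactions(
    log: InteractionLog, fraction: float, rng: np.random.Generator
) -> InteractionLog:
    """Remove ``round(fraction * n_events)`` events uniformly at random.

    Remaining events keep their timestamps and relative order.
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError("removal fraction must be in [0, 1)")
    n = len(log)
    n_remove = round(fraction * n)
    if n_remove == 0:
        return log
    drop = rng.choice(n, size=n_remove, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return log.replace_events(
        t=log.t[keep], signaller=log.signaller[keep], receiver=log.receiver[keep]
    )


def simulate_diffusion(log: InteractionLog) -> DiffusionResult:
    """Replay the log as a diffusion process; see module docstring.

    The threshold is ``ceil(0.5 * n_agents)`` informed agents. Efficiency
    counts every event whose signaller is informed at the moment the event is
    processed and whose timestamp is at most ``t50``.
    """
    if len(log) == 0:
        raise ConfigurationError("cannot seed a diffusion on an empty log")
    n = log.n_agents
    threshold = math.ceil(0.5 * n)
    informed = np.zeros(n, dtype=bool)
    seed_agent = int(log.signaller[0])
    informed[seed_agent] = True
    count = 1

    traj = np.ones(log.n_steps + 1, dtype=np.int64)
    t50: int | None = None
    outgoing = 0
    ts, ss, rs = log.t, log.signaller, log.receiver
    for k in range(len(log)):
        t = int(ts[k])
        s, r = int(ss[k]), int(rs[k])
        if informed[s]:
            if t50 is None or t <= t50:
                outgoing += 1
            if not informed[r]:
                informed[r] = True
                count += 1
                traj[t:] = count
                if t50 is None and count >= threshold:
                    t50 = t
    if t50 is None:
        return DiffusionResult(seed_agent, traj, None, None)
    return DiffusionResult(seed_agent, traj, t50, outgoing)


def run_diffusion_experiment(
    condition: Condition | str,
    n_runs: int,
    config_overrides: dict | None = None,
    master_seed: int = 0,
    thin_fraction: float = 0.2,
) -> pd.DataFrame:
    """Simulate ``n_runs`` colonies under one condition and diffuse over each.

    Runs whose population has uniform activity levels (the ``uniform`` and
    ``ti_variable`` conditions) have ``thin_fraction`` of their interactions
    removed before diffusion, equalising interaction rates across conditions.
    Returns one row per run with ``t50``, ``efficiency`` and their natural
    logs (NaN when the run never reached 50% informed).
    """
    condition = Condition(condition)
    overrides = dict(config_overrides or {})
    thinned = not condition.activity_varies and thin_fraction > 0
    rows = []
    for run in range(n_runs):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(3, run))
        sim_seed, thin_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
        config = SimConfig(condition=condition, seed=sim_seed, **overrides)
        log = run_simulation(config)
        n_events = len(log)
        if thinned:
            log = thin_interactions(
                log, thin_fraction, np.random.default_rng(thin_seed)
            )
        res = simulate_diffusion(log)
        rows.append(
            {
                "condition": condition.value,
                "run": run,
                "seed": sim_seed,
                "seed_agent": res.seed_agent,
                "n_events": n_events,
                "thinned": thinned,
                "t50": res.t50,
                "efficiency": res.efficiency,
                "log_t50": math.log(res.t50) if res.t50 else float("nan"),
                "log_efficiency": (
                    math.log(res.efficiency) if res.efficiency else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_static_diffusion(
    adjacency: np.ndarray, seed_agent: int, max_rounds: int = 10_000
) -> np.ndarray:
    """Exploratory variant: synchronous spread over a static binary network.

    ``adjacency[i, j]`` truthy means an edge ``i -> j`` (mutual dyads should
    appear in both orientations). Each round, every naive node with at least
    one informed in-neighbour becomes informed. Returns the informed count
    per round until the process stalls or ``max_rounds`` is hit. This is a
    coarse, order-free counterpart of the time-ordered replay and is meant
    for qualitative comparison only.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    informed = np.zeros(n, dtype=bool)
    informed[seed_agent] = True
    counts = [1]
    for _ in range(max_rounds):
        new = (~informed) & (adj[informed].any(axis=0))
        if not new.any():
            break
        informed |= new
        counts.append(int(informed.sum()))
    return np.asarray(counts, dtype=np.int64)
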