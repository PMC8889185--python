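"""Time-aggregated networks and majority-rule binary digraphs.

An interaction log is aggregated over a growing time window anchored at
``t = 0`` into a weighted directed network (edge weight = event count). The
weighted network is then binarised dyad by dyad: a dyad with all events in
one direction, or a strict majority in one direction, becomes a single
asymmetric edge in that direction; a dyad with equal non-zero counts in both
directions becomes a mutual (bidirectional) edge; a dyad with no events is
absent. ``grow_to_density`` finds the smallest window whose binary network
reaches a target edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal, Set, Tuple

import numpy as np

from .abm import InteractionLog
from .errors import ConfigurationError, DensityNotReachedError

__all__ = [
    "WeightedDigraph",
    "BinaryDigraph",
    "DENSITY_TARGETS",
    "aggregate",
    "binarize",
    "grow_to_density",
]

#: Network-density schedule used by the condition-contrast experiment.
DENSITY_TARGETS: tuple[int, ...] = tuple(range(150, 1501, 150))

EdgeCounting = Literal["dyads", "arcs"]


@dataclass(frozen=True)
class WeightedDigraph:
    """Directed multigraph collapsed to integer edge weights."""

    n_nodes: int
    weights: Dict[Tuple[int, int], int]

    def weight(self, i: int, j: int) -> int:
        return self.weights.get((i, j), 0)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from((i, j, w) for (i, j), w in self.weights.items())
        return g

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = sorted(self.weights.items())
        pd.DataFrame(
            [(i, j, w) for (i, j), w in rows],
            columns=["source", "target", "weight"],
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BinaryDigraph:
    """Binary directed network with asymmetric and mutual dyads.

    ``asymmetric`` holds ordered pairs ``(i, j)`` meaning ``i -> j``;
    ``mutual`` holds unordered pairs stored as ``(min, max)``. A dyad appears
    in at most one of the two sets. ``t_end`` records the time window that
    produced the network, when known.
    """

    n_nodes: int
    asymmetric: Set[Tuple[int, int]]
    mutual: Set[Tuple[int, int]]
    t_end: int | None = None

    def __post_init__(self) -> None:
        asym_dyads = {(min(i, j), max(i, j)) for i, j in self.asymmetric}
        if asym_dyads & self.mutual:
            raise ConfigurationError("a dyad cannot be both asymmetric and mutual")
        if len(asym_dyads) != len(self.asymmetric):
            raise ConfigurationError("both orientations of a dyad listed as asymmetric")

    def n_edges(self, counting: EdgeCounting = "dyads") -> int:
        """Edge count: ``dyads`` counts each connected dyad once; ``arcs``
        counts a mutual edge twice."""
        if counting == "dyads":
            return len(self.asymmetric) + len(self.mutual)
        if counting == "arcs":
            return len(self.asymmetric) + 2 * len(self.mutual)
        raise ConfigurationError(f"unknown edge counting {counting!r}")

    def dyad_states(self) -> Dict[Tuple[int, int], str]:
        """Map each connected dyad ``(i, j), i < j`` to ``'ij'``, ``'ji'`` or
        ``'mutual'``."""
        out: Dict[Tuple[int, int], str] = {}
        for i, j in self.asymmetric:
            out[(min(i, j), max(i, j))] = "ij" if i < j else "ji"
        for d in self.mutual:
            out[d] = "mutual"
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.asymmetric)
        for i, j in self.mutual:
            g.add_edge(i, j)
            g.add_edge(j, i)
        return g

    def to_csv(self, path: str | Path) -> None:
        """Edge list ``source,target,mutual``; mutual dyads emitted once."""
        import pandas as pd

        rows = [(i, j, 0) for i, j in sorted(self.asymmetric)]
        rows += [(i, j, 1) for i, j in sorted(self.mutual)]
        pd.DataFrame(rows, columns=["source", "target", "mutual"]).to_csv(
            path, index=False
        )


def aggregate(log: InteractionLog, t_end: int) -> WeightedDigraph:
    """Weighted time-aggregated network over the window ``[0, t_end]``."""
    if not 0 <= t_end <= log.n_steps:
        raise ConfigurationError(
            f"t_end={t_end} outside [0, {log.n_steps}]"
        )
    n = log.n_agents
    upto = int(np.searchsorted(log.t, t_end, side="right"))
    keys = log.signaller[:upto] * n + log.receiver[:upto]
    uniq, counts = np.unique(keys, return_counts=True)
    weights = {
        (int(k) // n, int(k) % n): int(c) for k, c in zip(uniq, counts)
    }
    return WeightedDigraph(n_nodes=n, weights=weights)


def binarize(w: WeightedDigraph) -> BinaryDigraph:
    """Collapse each dyad by majority rule.

    Strict majority (or a single direction of flow) gives an asymmetric edge;
    equal non-zero counts give a mutual edge; zero flow leaves the dyad
    absent.
    """
    asym: Set[Tuple[int, int]] = set()
    mutual: Set[Tuple[int, int]] = set()
    seen: Set[Tuple[int, int]] = set()
    for (i, j) in w.weights:
        d = (min(i, j), max(i, j))
        if d in seen:
            continue
        seen.add(d)
        wij = w.weight(d[0], d[1])
        wji = w.weight(d[1], d[0])
        if wij > wji:
            asym.add((d[0], d[1]))
        elif wji > wij:
            asym.add((d[1], d[0]))
        elif wij > 0:
            mutual.add(d)
    return BinaryDigraph(n_nodes=w.n_nodes, asymmetric=asym, mutual=mutual)


def grow_to_density(
    log: InteractionLog,
    n_edges: int,
    edge_counting: EdgeCounting = "dyads",
) -> BinaryDigraph:
    """Smallest-window binary network with at least ``n_edges`` edges.

    Equivalent to ``binarize(aggregate(log, t_end))`` for the smallest
    ``t_end`` (stepped one time step at a time) whose binary network reaches
    the target, but computed incrementally in one pass over the events.
    Raises :class:`DensityNotReachedError` when the full log cannot support
    the target.
    """
    n = log.n_agents
    max_edges = n * (n - 1) // 2 if edge_counting == "dyads" else n * (n - 1)
    if not 1 <= n_edges <= max_edges:
        raise ConfigurationError(
            f"target n_edges={n_edges} outside [1, {max_edges}] for {edge_counting}"
        )

    # per-dyad directed tallies: key (i, j) with i < j -> [count i->j, count j->i]
    tally: Dict[Tuple[int, int], list] = {}
    n_dyads = 0
    n_arcs = 0
    t_arr, s_arr, r_arr = log.t, log.signaller, log.receiver
    n_events = len(log)
    k = 0
    t_end_found: int | None = None
    while k < n_events:
        step = int(t_arr[k])
        while k < n_events and t_arr[k] == step:
            s, r = int(s_arr[k]), int(r_arr[k])
            d = (s, r) if s < r else (r, s)
            slot = 0 if s < r else 1
            cnt = tally.get(d)
            if cnt is None:
                cnt = [0, 0]
                tally[d] = cnt
                n_dyads += 1
                n_arcs += 1  # new dyad enters as asymmetric
            else:
                was_mutual = cnt[0] == cnt[1]
                cnt_other = cnt[1 - slot]
                # arc count: mutual (equal counts) contributes 2, else 1
                if was_mutual:
                    n_arcs -= 1  # mutual -> strict majority
                elif cnt[slot] + 1 == cnt_other:
                    n_arcs += 1  # strict minority catches up -> mutual
                cnt[slot] += 1
                k += 1
                continue
            cnt[slot] += 1
            k += 1
        count = n_dyads if edge_counting == "dyads" else n_arcs
        if count >= n_edges:
            t_end_found = step
            break

    if t_end_found is None:
        achieved = n_dyads if edge_counting == "dyads" else n_arcs
        raise DensityNotReachedError(n_edges, achieved, edge_counting)

    asym: Set[Tuple[int, int]] = set()
    mutual: Set[Tuple[int, int]] = set()
    for (i, j), (wij, wji) in tally.items():
        if wij > wji:
            asym.add((i, j))
        elif wji > wij:
            asym.add((j, i))
        else:
            mutual.add((i, j))
    return BinaryDigraph(
        n_nodes=n, asymmetric=asym, mutual=mutual, t_end=t_end_found
    )
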