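"""Triangle motifs: census, triangle transitivity and significance profiles.

A *triangle* is a node triple whose three dyads are all connected in the
binary network. Depending on how many of those dyads are mutual and how the
asymmetric ones are oriented, a triangle falls into exactly one of seven
classes (standard directed-triad taxonomy restricted to complete triangles):

===========  ==================================================================
class        structure
===========  ==================================================================
``030T``     transitive / feed-forward loop: A->B, A->C, B->C
``030C``     cycle: A->B->C->A
``120D``     one mutual dyad; the outside node sends to both of its ends
``120U``     one mutual dyad; the outside node receives from both of its ends
``120C``     one mutual dyad; the outside node sends to one end, receives from
             the other
``210``      two mutual dyads, one asymmetric
``300``      all three dyads mutual
===========  ==================================================================

Triangle transitivity ``t_tri = 4 (P_t - 0.75)`` rescales the proportion
``P_t`` of transitive triangles so that 0 matches the random-orientation
expectation (3 of the 4 orientations of a purely unidirectional triangle are
transitive) and 1 means every triangle is a feed-forward loop. Following the
convention of the dominance-hierarchy literature, triangles containing
mutual dyads are resolved into all orientations of those dyads with equal
weight, each resolution classified as transitive or cyclic: 120D and 120U
are transitive under either orientation (weight 1), 120C splits 1/2 : 1/2,
and 210 and 300 resolve 3/4 transitive. A ``strict`` variant restricted to
the purely unidirectional triangles (030T vs 030C) is available as a flag.

Triad significance profiles (TSP) standardise the seven class counts of an
observed network against a null ensemble (class-wise Z-scores) and normalise
the resulting vector to unit length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .netbuild import BinaryDigraph

__all__ = [
    "TRIANGLE_CLASSES",
    "TriadCensus",
    "TtriResult",
    "TSPVector",
    "triangle_census",
    "triangle_transitivity",
    "tsp",
]

TRIANGLE_CLASSES: tuple[str, ...] = (
    "030T", "030C", "120D", "120U", "120C", "210", "300",
)


@dataclass(frozen=True)
class TriadCensus:
    """Counts of the seven complete-triangle classes."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {c: int(self.counts.get(c, 0)) for c in TRIANGLE_CLASSES}
        )

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in TRIANGLE_CLASSES], dtype=float)


@dataclass(frozen=True)
class TtriResult:
    """Transitive/cyclic triangle weight and scaled transitivity.

    ``n_transitive`` and ``n_cyclic`` are plain counts under the ``strict``
    scheme and fractional resolution weights under ``weighted``; either way
    ``p_t = n_transitive / (n_transitive + n_cyclic)``. ``p_t`` and ``t_tri``
    are NaN (and ``defined`` is False) when no eligible triangle exists.
    """

    n_transitive: float
    n_cyclic: float
    p_t: float
    t_tri: float
    scheme: str = "weighted"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.t_tri)


#: Fraction of equal-weight resolutions of each triangle class that are
#: transitive (resolving every mutual dyad into its two orientations).
_TRANSITIVE_WEIGHT = {
    "030T": 1.0,
    "030C": 0.0,
    "120D": 1.0,
    "120U": 1.0,
    "120C": 0.5,
    "210": 0.75,
    "300": 0.75,
}


@dataclass(frozen=True)
class TSPVector:
    """Raw and unit-normalised Z-scores of one network against a null
    ensemble, in ``TRIANGLE_CLASSES`` order."""

    z: np.ndarray
    z_normalized: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray


def _classify(states: Tuple[str, str, str]) -> str:
    """Classify a triangle from the states of its three dyads.

    ``states`` are the dyad states for (a,b), (a,c), (b,c) with a < b < c:
    each is ``'ij'`` (low id -> high id), ``'ji'`` or ``'mutual'``.
    """
    n_mut = sum(s == "mutual" for s in states)
    if n_mut == 3:
        return "300"
    if n_mut == 2:
        return "210"
    # out-degree of each node over the asymmetric dyads of the triangle
    out = [0, 0, 0]
    pairs = ((0, 1), (0, 2), (1, 2))
    for (u, v), s in zip(pairs, states):
        if s == "ij":
            out[u] += 1
        elif s == "ji":
            out[v] += 1
    if n_mut == 0:
        # cycle iff every node has exactly one outgoing edge
        return "030C" if out == [1, 1, 1] else "030T"
    # one mutual dyad: classify by the out-degree of the node outside it
    k = states.index("mutual")
    outside = ({0, 1, 2} - set(pairs[k])).pop()
    if out[outside] == 2:
        return "120D"
    if out[outside] == 0:
        return "120U"
    return "120C"


def triangle_census(g: BinaryDigraph) -> TriadCensus:
    """Enumerate all complete triangles of ``g`` and classify each."""
    states = g.dyad_states()
    adj: list[set[int]] = [set() for _ in range(g.n_nodes)]
    for (i, j) in states:
        adj[i].add(j)
        adj[j].add(i)
    counts = {c: 0 for c in TRIANGLE_CLASSES}
    for a in range(g.n_nodes):
        nbrs_a = adj[a]
        for b in nbrs_a:
            if b <= a:
                continue
            for c in nbrs_a & adj[b]:
                if c <= b:
                    continue
                tri = (states[(a, b)], states[(a, c)], states[(b, c)])
                counts[_classify(tri)] += 1
    return TriadCensus(counts)


def triangle_transitivity(
    g: BinaryDigraph | TriadCensus, scheme: str = "weighted"
) -> TtriResult:
    """Scaled triangle transitivity ``t_tri = 4 (P_t - 0.75)``.

    Accepts a binary network or a precomputed census. Under the default
    ``weighted`` scheme every complete triangle contributes, with triangles
    containing mutual dyads split across their equal-weight orientations
    (see module docstring); under ``strict`` only the purely unidirectional
    030T/030C triangles count. With no eligible triangle the statistic is
    undefined and returned as NaN.
    """
    census = g if isinstance(g, TriadCensus) else triangle_census(g)
    if scheme == "strict":
        n_t = float(census["030T"])
        total = n_t + census["030C"]
    elif scheme == "weighted":
        n_t = sum(_TRANSITIVE_WEIGHT[c] * census[c] for c in TRIANGLE_CLASSES)
        total = float(census.total)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if total == 0:
        return TtriResult(0.0, 0.0, float("nan"), float("nan"), scheme)
    p_t = n_t / total
    return TtriResult(n_t, total - n_t, p_t, 4.0 * (p_t - 0.75), scheme)


def tsp(
    observed: Sequence[TriadCensus] | TriadCensus,
    null_ensemble: Sequence[TriadCensus],
) -> list[TSPVector] | TSPVector:
    """Triad significance profile(s) of observed network(s) vs a null.

    For each class, ``Z = (N_obs - mean_null) / sd_null`` (sample sd over the
    ensemble); the Z vector is then scaled to unit Euclidean norm. A class
    whose null sd is zero yields Z = 0 when the observation matches the null
    mean and raises otherwise, since no standardisation exists.
    """
    single = isinstance(observed, TriadCensus)
    obs_list = [observed] if single else list(observed)
    if len(null_ensemble) < 2:
        raise UndefinedMetricError("null ensemble needs at least 2 networks")
    null = np.stack([c.as_array() for c in null_ensemble])
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)

    out = []
    for census in obs_list:
        n_obs = census.as_array()
        z = np.zeros_like(mean)
        ok = sd > 0
        z[ok] = (n_obs[ok] - mean[ok]) / sd[ok]
        bad = (~ok) & (n_obs != mean)
        if bad.any():
            cls = [TRIANGLE_CLASSES[i] for i in np.flatnonzero(bad)]
            raise UndefinedMetricError(
                f"null sd is 0 but observation differs from null mean for {cls}"
            )
        norm = float(np.linalg.norm(z))
        z_norm = z / norm if norm > 0 else np.zeros_like(z)
        out.append(TSPVector(z=z, z_normalized=z_norm, null_mean=mean, null_sd=sd))
    return out[0] if single else out
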