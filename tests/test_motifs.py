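import itertools

import networkx as nx
import numpy as np
import pytest

from nestflow import (
    TRIANGLE_CLASSES,
    BinaryDigraph,
    TriadCensus,
    UndefinedMetricError,
    triangle_census,
    triangle_transitivity,
    tsp,
)


def graph(asym=(), mutual=(), n=None):
    nodes = {x for e in (*asym, *mutual) for x in e}
    n = n or (max(nodes) + 1 if nodes else 1)
    return BinaryDigraph(n, asymmetric=set(asym), mutual=set(mutual))


def random_binary_digraph(rng, n_nodes, p_dyad=0.5, p_mutual=0.2):
    asym, mutual = set(), set()
    for i, j in itertools.combinations(range(n_nodes), 2):
        u = rng.random()
        if u < p_dyad * p_mutual:
            mutual.add((i, j))
        elif u < p_dyad:
            asym.add((i, j) if rng.random() < 0.5 else (j, i))
    return BinaryDigraph(n_nodes, asymmetric=asym, mutual=mutual)


class TestTriangleCensus:
    def test_feed_forward_loop(self):
        c = triangle_census(graph(asym=[(0, 1), (0, 2), (1, 2)]))
        assert c.counts == {"030T": 1, **{k: 0 for k in TRIANGLE_CLASSES if k != "030T"}}

    def test_cycle(self):
        c = triangle_census(graph(asym=[(0, 1), (1, 2), (2, 0)]))
        assert c["030C"] == 1 and c.total == 1

    def test_bidirectional_edge_triangle(self):
        # A sends to both ends of the mutual dyad {B, C}
        c = triangle_census(graph(asym=[(0, 1), (0, 2)], mutual=[(1, 2)]))
        assert c["120D"] == 1 and c.total == 1

    def test_matches_exhaustive_triple_enumeration_oracle(self):
        """Census equals per-triple classification by networkx's triad
        taxonomy over every node triple, for 100 random digraphs."""
        rng = np.random.default_rng(4242)
        for _ in range(100):
            g = random_binary_digraph(rng, int(rng.integers(5, 13)))
            nxg = g.to_networkx()
            expected = {k: 0 for k in TRIANGLE_CLASSES}
            for triple in itertools.combinations(range(g.n_nodes), 3):
                sub = nxg.subgraph(triple)
                kind = nx.triads.triad_type(sub)
                if kind in expected:
                    expected[kind] += 1
            assert triangle_census(g).counts == expected

    def test_total_matches_undirected_triangle_count(self, rng):
        g = random_binary_digraph(rng, 20)
        und = nx.Graph()
        und.add_nodes_from(range(20))
        und.add_edges_from(g.dyad_states())
        assert triangle_census(g).total == sum(nx.triangles(und).values()) // 3

    def test_invariant_under_relabelling(self, rng):
        g = random_binary_digraph(rng, 10)
        perm = rng.permutation(10)
        relabel = lambda e: (int(perm[e[0]]), int(perm[e[1]]))
        g2 = BinaryDigraph(
            10,
            asymmetric={relabel(e) for e in g.asymmetric},
            mutual={tuple(sorted(relabel(e))) for e in g.mutual},
        )
        assert triangle_census(g).counts == triangle_census(g2).counts


class TestTriangleTransitivity:
    def test_single_transitive_triangle_scores_one(self):
        tt = triangle_transitivity(graph(asym=[(0, 1), (0, 2), (1, 2)]))
        assert tt.p_t == 1.0 and tt.t_tri == pytest.approx(1.0)

    def test_three_to_one_ratio_matches_random_expectation(self):
        tt = triangle_transitivity(TriadCensus({"030T": 3, "030C": 1}))
        assert tt.t_tri == pytest.approx(0.0)

    def test_single_cycle_scores_minus_three(self):
        tt = triangle_transitivity(graph(asym=[(0, 1), (1, 2), (2, 0)]))
        assert tt.t_tri == pytest.approx(-3.0)

    def test_undefined_without_triangles(self):
        tt = triangle_transitivity(graph(asym=[(0, 1)], n=4))
        assert not tt.defined and np.isnan(tt.t_tri)

    def test_strict_scheme_ignores_mutual_triangles(self):
        census = TriadCensus({"030T": 2, "030C": 2, "120C": 50})
        assert triangle_transitivity(census, scheme="strict").p_t == 0.5
        # weighted: (2 + 25) / 54
        assert triangle_transitivity(census).p_t == pytest.approx(27 / 54)

    def test_bounded_in_minus_three_one(self, rng):
        for _ in range(50):
            tt = triangle_transitivity(random_binary_digraph(rng, 12))
            if tt.defined:
                assert -3.0 <= tt.t_tri <= 1.0

    def test_random_orientation_mean_near_zero(self):
        """Randomly oriented dyads produce no transitivity signal: mean t_tri
        over 100 random 100-node, 1000-edge digraphs is ~0."""
        rng = np.random.default_rng(77)
        dyads = list(itertools.combinations(range(100), 2))
        vals = []
        for _ in range(100):
            idx = rng.choice(len(dyads), 1000, replace=False)
            asym = {
                dyads[i] if rng.random() < 0.5 else dyads[i][::-1] for i in idx
            }
            vals.append(triangle_transitivity(graph(asym=asym, n=100)).t_tri)
        assert abs(np.mean(vals)) < 0.05


class TestTSP:
    def c(self, *counts):
        return TriadCensus(dict(zip(TRIANGLE_CLASSES, counts)))

    def test_observation_equal_to_null_mean_gives_zero_vector(self):
        null = [self.c(4, 2, 0, 0, 0, 0, 0), self.c(6, 4, 0, 0, 0, 0, 0)]
        v = tsp(self.c(5, 3, 0, 0, 0, 0, 0), null)
        assert np.allclose(v.z, 0) and np.allclose(v.z_normalized, 0)

    def test_unit_norm_arithmetic(self):
        # null means (3, 6), sample sds (2, 4); observation (9, 22) -> Z = (3, 4)
        null = [
            self.c(1, 2, 0, 0, 0, 0, 0),
            self.c(3, 6, 0, 0, 0, 0, 0),
            self.c(5, 10, 0, 0, 0, 0, 0),
        ]
        v = tsp(self.c(9, 22, 0, 0, 0, 0, 0), null)
        assert np.allclose(v.z[:2], [3, 4])
        assert np.allclose(v.z_normalized[:2], [0.6, 0.8])
        assert np.isclose(np.linalg.norm(v.z_normalized), 1.0)

    def test_degenerate_null_with_discrepant_observation_raises(self):
        null = [self.c(5, 0, 0, 0, 0, 0, 0)] * 3
        with pytest.raises(UndefinedMetricError):
            tsp(self.c(9, 0, 0, 0, 0, 0, 0), null)

    def test_small_null_ensemble_rejected(self):
        with pytest.raises(UndefinedMetricError):
            tsp(self.c(1, 0, 0, 0, 0, 0, 0), [self.c(1, 0, 0, 0, 0, 0, 0)])
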