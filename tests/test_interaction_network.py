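import itertools
import random

import numpy as np
import pytest

import oracles

from trialflow.interaction_network import (
    betweenness_centrality,
    bonacich_power,
    build_network,
    centrality_report,
    closeness_centrality,
    degree_centrality,
)


def net_from_edges(n, edges):
    records = [(k, str(i), str(j)) for k, (i, j) in enumerate(sorted(edges))]
    records += [(len(records) + k, str(v), str(v)) for k, v in enumerate(range(n))]
    # self-records above are dropped; add isolated nodes via a trick below
    net = build_network([r for r in records if r[1] != r[2]])
    for v in range(n):
        net.graph.add_node(str(v))
    return net


class TestBuild:
    def test_aggregation(self):
        net = build_network([(0, "PI", "OCR"), (1, "PI", "OCR"), (2, "PI", "OCR")])
        assert net.weight("PI", "OCR") == 3
        assert net.weight("OCR", "PI") == 0
        assert net.out_initiations("PI") == 3

    def test_empty_log(self):
        net = build_network([])
        assert net.nodes == []
        assert centrality_report(net).empty

    def test_malformed_record(self):
        with pytest.raises(ValueError):
            build_network([(0, "", "OCR")])
        with pytest.raises(ValueError):
            build_network([(0,)])

    def test_self_loops_dropped_by_default(self):
        net = build_network([(0, "OCR", "OCR"), (1, "OCR", "PI")])
        assert net.weight("OCR", "OCR") == 0
        net = build_network([(0, "OCR", "OCR")], allow_self_loops=True)
        assert net.weight("OCR", "OCR") == 1


class TestSmallCases:
    def test_directed_cycle_degrees(self):
        net = build_network([(0, "a", "b"), (1, "b", "c"), (2, "c", "a")])
        assert degree_centrality(net) == {"a": (1.0, 1.0), "b": (1.0, 1.0),
                                          "c": (1.0, 1.0)}

    def test_star_degrees(self):
        net = build_network([(i, "hub", leaf) for i, leaf in
                             enumerate(["a", "b", "c", "d"])])
        deg = degree_centrality(net)
        assert deg["hub"] == (0.0, 4.0)
        assert all(deg[x] == (1.0, 0.0) for x in "abcd")

    def test_weighted_degree(self):
        net = build_network([(0, "a", "b"), (1, "a", "b"), (2, "a", "c")])
        assert degree_centrality(net, weighted=True)["a"] == (0.0, 3.0)

    def test_path_closeness(self):
        net = build_network([(0, "a", "b"), (1, "b", "c")])
        clo = closeness_centrality(net)
        assert clo["a"][1] == pytest.approx(1.0 + 0.5)  # out: d(a,b)=1, d(a,c)=2
        assert clo["a"][0] == 0.0                        # nothing reaches a
        assert clo["c"][0] == pytest.approx(1.5)

    def test_path_betweenness(self):
        net = build_network([(0, "a", "b"), (1, "b", "c")])
        bt = betweenness_centrality(net)
        assert bt == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_digraph_symmetry(self):
        edges = [(i, u, v) for i, (u, v) in
                 enumerate(itertools.permutations("abcd", 2))]
        net = build_network(edges)
        assert set(betweenness_centrality(net).values()) == {0.0}
        clo = closeness_centrality(net)
        assert len({round(v[0], 12) for v in clo.values()}) == 1


class TestBonacich:
    def test_beta_zero_reduces_to_degree(self):
        net = build_network([(0, "a", "b"), (1, "b", "c"), (2, "c", "d"),
                             (3, "d", "a"), (4, "a", "c")])
        power = bonacich_power(net, beta=0.0)
        deg = {n: sum(1 for m in net.nodes
                      if net.weight(n, m) + net.weight(m, n) > 0)
               for n in net.nodes}
        # proportional to symmetrized degree
        ratios = {n: power[n] / deg[n] for n in net.nodes}
        assert max(ratios.values()) == pytest.approx(min(ratios.values()))

    def test_star_center_dominates_under_negative_beta(self):
        net = build_network([(i, "hub", leaf) for i, leaf in
                             enumerate(["a", "b", "c", "d"])])
        power = bonacich_power(net)  # default negative beta
        assert power["hub"] > max(power[x] for x in "abcd")

    def test_matches_truncated_series(self):
        edges = {(0, 1), (1, 2), (2, 3), (0, 2)}
        net = net_from_edges(4, edges)
        beta = -0.2
        got = bonacich_power(net, beta=beta)
        want = oracles.brute_bonacich(4, edges, beta)
        for v in range(4):
            assert got[str(v)] == pytest.approx(want[v], abs=1e-9)

    def test_divergent_beta_rejected(self):
        net = build_network([(0, "a", "b")])
        with pytest.raises(ValueError):
            bonacich_power(net, beta=1.5)

    def test_normalization(self):
        net = build_network([(0, "a", "b"), (1, "b", "c")])
        power = bonacich_power(net, beta=-0.3)
        assert sum(v * v for v in power.values()) == pytest.approx(len(power))


def _assert_matches_oracles(n, edges):
    net = net_from_edges(n, edges)
    deg = degree_centrality(net)
    want_deg = oracles.brute_degree(n, edges)
    clo = closeness_centrality(net)
    want_clo = oracles.brute_harmonic_closeness(n, edges)
    bt = betweenness_centrality(net)
    want_bt = oracles.brute_betweenness(n, edges)
    for v in range(n):
        key = str(v)
        assert deg[key] == (float(want_deg[v][0]), float(want_deg[v][1]))
        assert clo[key][0] == pytest.approx(want_clo[v][0])
        assert clo[key][1] == pytest.approx(want_clo[v][1])
        assert bt[key] == pytest.approx(want_bt[v])
    lam = oracles.spectral_radius(n, edges)
    if lam > 0:
        beta = -0.5 / lam
        got = bonacich_power(net, beta=beta)
        want = oracles.brute_bonacich(n, edges, beta, terms=400)
        for v in range(n):
            assert got[str(v)] == pytest.approx(want[v], abs=1e-8)


@pytest.mark.parametrize("n", [2, 3])
def test_exhaustive_equivalence_on_tiny_digraphs(n):
    """All four measures match brute-force enumeration on every digraph."""
    for edges in oracles.all_digraphs(n):
        _assert_matches_oracles(n, edges)


@pytest.mark.parametrize("n", [4, 5, 6])
def test_random_digraph_equivalence(n):
    """Seeded random digraphs up to 6 nodes match the brute-force oracles."""
    rnd = random.Random(n * 1000 + 7)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for _ in range(25):
        edges = {p for p in pairs if rnd.random() < 0.35}
        _assert_matches_oracles(n, edges)


def test_relabeling_equivariance():
    edges = {(0, 1), (1, 2), (2, 0), (0, 3), (3, 4)}
    net = net_from_edges(5, edges)
    mapping = {0: 3, 1: 0, 2: 4, 3: 1, 4: 2}
    permuted = {(mapping[i], mapping[j]) for i, j in edges}
    net2 = net_from_edges(5, permuted)
    rep1 = centrality_report(net, beta=-0.2)
    rep2 = centrality_report(net2, beta=-0.2)
    for old, new in mapping.items():
        np.testing.assert_allclose(rep1.loc[str(old)].to_numpy(),
                                   rep2.loc[str(new)].to_numpy(), atol=1e-9)
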