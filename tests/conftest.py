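"""Shared fixtures and independent brute-force oracles.

The oracles here re-implement the blocking rules by naive path enumeration,
independently of the package's moralized-graph d-separation, so the two
routes can be checked against each other.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from confsel import CausalDAG, make_figure_dag


@pytest.fixture(params=["fig1", "fig2", "fig3", "fig4", "fig5"])
def figure_dag(request):
    return make_figure_dag(request.param)


@pytest.fixture
def fig1():
    return make_figure_dag("fig1")


@pytest.fixture
def fig2():
    return make_figure_dag("fig2")


@pytest.fixture
def fig3():
    return make_figure_dag("fig3")


@pytest.fixture
def fig4():
    return make_figure_dag("fig4")


@pytest.fixture
def fig5():
    return make_figure_dag("fig5")


# ---------------------------------------------------------------------------
# Brute-force path-enumeration oracle for d-separation


def trail_blocked(g: nx.DiGraph, path, z: frozenset) -> bool:
    """Blocking rules applied to one explicit trail, written from scratch."""
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        collider = g.has_edge(prev, node) and g.has_edge(nxt, node)
        if collider:
            if not (({node} | nx.descendants(g, node)) & z):
                return True
        else:
            if node in z:
                return True
    return False


def oracle_d_separated(dag: CausalDAG, x: str, y: str, given) -> bool:
    """d-separation by enumerating every trail and testing its blockage."""
    z = frozenset(given)
    g = dag.to_networkx()
    skel = nx.Graph(g.edges())
    skel.add_nodes_from(g.nodes)
    for path in nx.all_simple_paths(skel, x, y):
        if not trail_blocked(g, list(path), z):
            return False
    return True


def oracle_valid_adjustment(dag: CausalDAG, members) -> bool:
    """Backdoor criterion by brute force: descendant check + per-path blockage."""
    z = frozenset(members)
    g = dag.to_networkx()
    if any(m in nx.descendants(g, dag.exposure) for m in z):
        return False
    skel = nx.Graph(g.edges())
    skel.add_nodes_from(g.nodes)
    for path in nx.all_simple_paths(skel, dag.exposure, dag.outcome):
        p = list(path)
        if g.has_edge(p[1], p[0]) and not trail_blocked(g, p, z):
            return False
    return True


def all_labelled_dags(nodes: tuple[str, ...]):
    """Every labelled DAG on the given nodes (feasible up to 4 nodes)."""
    pairs = [
        (a, b) for a, b in itertools.permutations(nodes, 2)
    ]
    for bits in itertools.product([False, True], repeat=len(pairs)):
        edges = [p for p, keep in zip(pairs, bits) if keep]
        if any((b, a) in edges for a, b in edges):
            continue  # 2-cycles: cheap pre-filter
        g = nx.DiGraph(edges)
        g.add_nodes_from(nodes)
        if nx.is_directed_acyclic_graph(g):
            yield frozenset(edges)
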