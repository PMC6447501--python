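"""Causal DAG data model, d-separation, and backdoor-criterion machinery.

The central question this module answers is: given a causal diagram with an
exposure A, an outcome Y, measured covariates, and possibly unmeasured
(latent) variables, which sets of measured covariates suffice to control for
confounding?  Validity of a candidate adjustment set is decided by Pearl's
backdoor criterion: no member may be a descendant of the exposure, and every
backdoor path (a path from A to Y whose first edge points into A) must be
blocked given the set.

d-separation is implemented via moralized-ancestral-graph reachability: two
nodes are d-separated given Z iff they are disconnected in the moralized
subgraph induced on the ancestors of {x, y} ∪ Z after removing Z.  A
brute-force path-enumeration blocker lives in the test suite as the oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Sequence

import networkx as nx

__all__ = [
    "CausalDAG",
    "AdjustmentSet",
    "DagError",
    "UnknownNodeError",
    "PreconditionError",
    "SizeError",
    "is_acyclic",
    "ancestors",
    "descendants",
    "d_separated",
    "backdoor_paths",
    "path_is_blocked",
    "is_valid_adjustment_set",
    "all_valid_subsets",
    "minimal_valid_subsets",
]


class DagError(ValueError):
    """Base class for causal-DAG validation errors."""


class UnknownNodeError(DagError, KeyError):
    """A node identifier does not belong to the graph."""


class PreconditionError(DagError):
    """An operation was called with arguments violating its contract."""


class SizeError(DagError):
    """An exhaustive enumeration would exceed its configured cap."""


@dataclass(frozen=True)
class CausalDAG:
    """A directed acyclic graph with exposure/outcome/latent node roles.

    Parameters
    ----------
    nodes
        All node identifiers (opaque, case-sensitive strings).
    edges
        Directed edges as (tail, head) pairs.
    exposure, outcome
        The treatment variable A and the outcome variable Y.
    latent
        Nodes flagged as unmeasured; these may never be conditioned on or
        placed in an adjustment set.

    All remaining non-latent nodes are the measured covariates.
    """

    nodes: FrozenSet[str]
    edges: FrozenSet[tuple[str, str]]
    exposure: str
    outcome: str
    latent: FrozenSet[str] = frozenset()

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        exposure: str,
        outcome: str,
        latent: Iterable[str] = (),
    ):
        object.__setattr__(self, "nodes", frozenset(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        object.__setattr__(self, "exposure", exposure)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "latent", frozenset(latent))
        self._validate()

    def _validate(self) -> None:
        if self.exposure == self.outcome:
            raise DagError("exposure and outcome must be distinct nodes")
        for special, name in ((self.exposure, "exposure"), (self.outcome, "outcome")):
            if special not in self.nodes:
                raise UnknownNodeError(f"{name} node {special!r} is not declared")
            if special in self.latent:
                raise DagError(f"{name} node {special!r} may not be latent")
        stray = self.latent - self.nodes
        if stray:
            raise UnknownNodeError(f"latent nodes not declared: {sorted(stray)}")
        for tail, head in self.edges:
            if tail == head:
                raise DagError(f"self-loop on node {tail!r}")
            if tail not in self.nodes or head not in self.nodes:
                raise UnknownNodeError(f"edge {tail!r}->{head!r} uses undeclared node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise DagError("graph contains a directed cycle")

    # -- derived views -----------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """The underlying directed graph as a :class:`networkx.DiGraph`."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def measured_covariates(self) -> FrozenSet[str]:
        """All non-latent nodes other than exposure and outcome."""
        return self.nodes - self.latent - {self.exposure, self.outcome}

    def parents(self, x: str) -> FrozenSet[str]:
        self._require(x)
        return frozenset(t for t, h in self.edges if h == x)

    def children(self, x: str) -> FrozenSet[str]:
        self._require(x)
        return frozenset(h for t, h in self.edges if t == x)

    def _require(self, *xs: str) -> None:
        for x in xs:
            if x not in self.nodes:
                raise UnknownNodeError(f"unknown node {x!r}")


@dataclass(frozen=True)
class AdjustmentSet:
    """A candidate covariate set with its backdoor-criterion verdict.

    ``justification`` lists the open backdoor paths (as node sequences) when
    the verdict is "invalid", or names the offending exposure-descendant.
    """

    members: FrozenSet[str]
    valid: str  # "valid" | "invalid" | "undetermined"
    justification: tuple = ()

    def __post_init__(self):
        if self.valid not in ("valid", "invalid", "undetermined"):
            raise ValueError(f"bad verdict {self.valid!r}")
        if self.valid == "invalid" and not self.justification:
            raise ValueError("invalid verdict requires a justification")

    def __bool__(self) -> bool:
        return self.valid == "valid"


# ---------------------------------------------------------------------------
# Basic graph operations


def is_acyclic(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> bool:
    """True iff the directed graph has no directed cycle.

    Accepts raw nodes/edges so it can vet input *before* CausalDAG
    construction (which rejects cyclic graphs outright).
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(g)


def ancestors(dag: CausalDAG, x: str) -> FrozenSet[str]:
    """All nodes with a directed path into ``x`` (``x`` excluded)."""
    dag._require(x)
    return frozenset(nx.ancestors(dag.to_networkx(), x))


def descendants(dag: CausalDAG, x: str) -> FrozenSet[str]:
    """All nodes reachable from ``x`` along directed edges (``x`` excluded)."""
    dag._require(x)
    return frozenset(nx.descendants(dag.to_networkx(), x))


# ---------------------------------------------------------------------------
# d-separation (moralized ancestral graph reachability)


def d_separated(dag: CausalDAG, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """Decide whether ``x`` and ``y`` are d-separated given a conditioning set.

    Standard blocking rules: a path is blocked if it passes through a
    non-collider in the conditioning set, or through a collider none of whose
    descendants (including itself) is in the conditioning set.

    Latent nodes may never appear in ``given``: unmeasured means
    unconditionable, and violating that is an error rather than a warning.
    """
    z = frozenset(given)
    dag._require(x, y, *z)
    if x == y:
        raise PreconditionError("x and y must be distinct")
    if x in z or y in z:
        raise PreconditionError("query nodes may not appear in the conditioning set")
    bad = z & dag.latent
    if bad:
        raise PreconditionError(f"cannot condition on latent node(s) {sorted(bad)}")
    return _d_separated_unchecked(dag.to_networkx(), x, y, z)


def _d_separated_unchecked(g: nx.DiGraph, x: str, y: str, z: frozenset) -> bool:
    # ancestral subgraph of {x, y} ∪ z
    relevant = set(z) | {x, y}
    anc = set(relevant)
    for v in relevant:
        anc |= nx.ancestors(g, v)
    sub = g.subgraph(anc)
    # moralize: undirected skeleton + marriages between co-parents
    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes)
    moral.add_edges_from(sub.edges())
    for v in sub.nodes:
        for p, q in itertools.combinations(sorted(sub.predecessors(v)), 2):
            moral.add_edge(p, q)
    moral.remove_nodes_from(z)
    return not nx.has_path(moral, x, y)


# ---------------------------------------------------------------------------
# Backdoor paths and the backdoor criterion


def _all_trails(g: nx.DiGraph, x: str, y: str) -> list[list[str]]:
    """All simple paths between x and y in the undirected skeleton."""
    skel = nx.Graph(g.edges())
    skel.add_nodes_from(g.nodes)
    if x not in skel or y not in skel:
        return []
    return [list(p) for p in nx.all_simple_paths(skel, x, y)]


def backdoor_paths(dag: CausalDAG) -> list[list[str]]:
    """Every path from exposure to outcome starting with an edge into the exposure.

    Paths are returned as ordered node sequences beginning at the exposure,
    sorted lexicographically for determinism.
    """
    g = dag.to_networkx()
    out = [
        p
        for p in _all_trails(g, dag.exposure, dag.outcome)
        if g.has_edge(p[1], p[0])  # first edge points *into* the exposure
    ]
    out.sort()
    return out


def path_is_blocked(
    dag: CausalDAG, path: Sequence[str], given: Iterable[str] = ()
) -> bool:
    """Apply the d-separation blocking rules to one explicit trail.

    A node on the trail is a collider iff both adjacent trail edges point into
    it.  Non-colliders block when conditioned on; colliders block unless they
    or one of their descendants is conditioned on.
    """
    z = frozenset(given)
    g = dag.to_networkx()
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        is_collider = g.has_edge(prev, node) and g.has_edge(nxt, node)
        if is_collider:
            if not (({node} | nx.descendants(g, node)) & z):
                return True
        elif node in z:
            return True
    return False


def is_valid_adjustment_set(dag: CausalDAG, s: Iterable[str]) -> AdjustmentSet:
    """Backdoor-criterion verdict for a candidate adjustment set.

    Valid iff (i) no member is a descendant of the exposure and (ii) every
    backdoor path from exposure to outcome is blocked given the set.  Invalid
    verdicts carry the open paths (or the offending descendant) as
    justification.

    Raises
    ------
    PreconditionError
        If the set contains a latent node, the exposure, or the outcome.
    """
    members = frozenset(s)
    dag._require(*members)
    forbidden = members & (dag.latent | {dag.exposure, dag.outcome})
    if forbidden:
        raise PreconditionError(
            f"adjustment set may contain only measured covariates; got {sorted(forbidden)}"
        )
    desc_a = descendants(dag, dag.exposure)
    offenders = members & desc_a
    if offenders:
        return AdjustmentSet(
            members,
            "invalid",
            tuple(f"descendant-of-exposure:{v}" for v in sorted(offenders)),
        )
    open_paths = [
        tuple(p) for p in backdoor_paths(dag) if not path_is_blocked(dag, p, members)
    ]
    if open_paths:
        return AdjustmentSet(members, "invalid", tuple(open_paths))
    return AdjustmentSet(members, "valid")


def all_valid_subsets(dag: CausalDAG, cap: int = 12) -> list[FrozenSet[str]]:
    """Exhaustively enumerate every valid measured adjustment set.

    Ordered by set size, then lexicographically.  Refuses graphs with more
    than ``cap`` measured covariates (2^cap subsets).
    """
    cov = sorted(dag.measured_covariates)
    if len(cov) > cap:
        raise SizeError(
            f"{len(cov)} measured covariates exceeds the enumeration cap of {cap}"
        )
    bps = backdoor_paths(dag)
    desc_a = descendants(dag, dag.exposure)
    out = []
    for r in range(len(cov) + 1):
        for combo in itertools.combinations(cov, r):
            s = frozenset(combo)
            if s & desc_a:
                continue
            if all(path_is_blocked(dag, p, s) for p in bps):
                out.append(s)
    return out


def minimal_valid_subsets(dag: CausalDAG, cap: int = 12) -> list[FrozenSet[str]]:
    """Valid sets with no valid proper subset."""
    valid = all_valid_subsets(dag, cap=cap)
    return [s for s in valid if not any(t < s for t in valid)]
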