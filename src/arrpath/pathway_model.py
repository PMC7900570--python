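"""Core data model for signed, directed molecular-pathway graphs.

A pathway is a directed graph whose nodes hold zero or more gene products
(HGNC symbols) and whose edges carry an interaction sign: activation,
inhibition, or undefined.  Terminal "molecular function" nodes represent
physiological outcomes rather than gene products.

The structural primitives here — reachability counts, weak connectivity,
and central-node selection — are what the role-annotation recursion in
:mod:`arrpath.arr_annotator` is built on.  The central node of a pathway
is the node maximising N+M, where N is the number of other nodes reachable
from it along directed edges and M the number of other nodes from which it
can be reached.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "EdgeType",
    "PathwayNode",
    "Edge",
    "Pathway",
    "ReachCounts",
    "AnnotationConfig",
    "PathwayError",
    "validate_pathway",
    "reachable_counts",
    "is_weakly_connected",
    "find_central_node",
]


class PathwayError(ValueError):
    """Raised on structurally invalid pathways or violated preconditions."""


class EdgeType(str, enum.Enum):
    """Sign of a molecular interaction edge."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    UNDEFINED = "undefined"

    @property
    def sign(self) -> int:
        """+1 for activation, -1 for inhibition, +1 for undefined.

        The undefined sign is the pass-through convention; callers that
        want to skip undefined edges handle that before consulting it.
        """
        return -1 if self is EdgeType.INHIBITION else 1


@dataclass(frozen=True)
class PathwayNode:
    """One pathway vertex, holding any number of gene products.

    ``is_function_node`` flags terminal physiological-outcome nodes
    ("molecular function" nodes), which carry no genes and anchor
    micropathway extraction.
    """

    node_id: str
    label: str = ""
    genes: frozenset[str] = frozenset()
    is_function_node: bool = False

    def __post_init__(self) -> None:
        if not self.node_id:
            raise PathwayError("node_id must be a nonempty string")
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.label:
            object.__setattr__(self, "label", self.node_id)


@dataclass(frozen=True)
class Edge:
    """A directed, signed interaction between two nodes."""

    source: str
    target: str
    etype: EdgeType = EdgeType.ACTIVATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "etype", EdgeType(self.etype))


@dataclass
class Pathway:
    """A named pathway graph: nodes with gene content plus signed edges."""

    name: str
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    database: str = ""
    kind: str = "core"  # "core" (full-size) or "micro"

    def __post_init__(self) -> None:
        if self.kind not in ("core", "micro"):
            raise PathwayError(f"kind must be 'core' or 'micro', got {self.kind!r}")

    # -- convenience accessors ------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise PathwayError(f"unknown node {node_id!r} in pathway {self.name!r}")

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for n in self.nodes:
            out |= n.genes
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        """Directed multigraph view; edge key = index into ``self.edges``."""
        g = nx.MultiDiGraph(name=self.name)
        for n in self.nodes:
            g.add_node(n.node_id, data=n)
        for i, e in enumerate(self.edges):
            g.add_edge(e.source, e.target, key=i, etype=e.etype)
        return g


@dataclass(frozen=True)
class ReachCounts:
    """Directed reachability counts for one node.

    ``n_forward``: nodes (other than the node itself) reachable from it;
    ``m_backward``: nodes from which it can be reached.  Transitive
    reachability, not mere adjacency; self-loops never contribute.
    """

    n_forward: int
    m_backward: int

    @property
    def total(self) -> int:
        return self.n_forward + self.m_backward


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable choices of the annotation procedure.

    tie_break
        How to pick among several nodes sharing the maximal N+M:
        ``"lexicographic"`` (smallest node_id; deterministic default) or
        ``"random"`` (seeded uniform draw).
    seed
        Seed for the random tie-break.
    propagation
        ``"multiplicative"``: a proposed role is the source node's role
        times the edge sign, so inhibition of an inhibitor activates.
        ``"edge_only"``: the proposal is the edge sign alone.
    undefined_edge_policy
        ``"pass_through"``: undefined edges propagate the source sign
        unchanged; ``"skip"``: they are consumed without propagating.
    per_component
        Annotate each weakly connected component separately instead of
        rejecting disconnected pathways.
    """

    tie_break: str = "lexicographic"
    seed: int = 0
    propagation: str = "multiplicative"
    undefined_edge_policy: str = "pass_through"
    per_component: bool = False

    def __post_init__(self) -> None:
        if self.tie_break not in ("lexicographic", "random"):
            raise PathwayError(f"unknown tie_break {self.tie_break!r}")
        if self.propagation not in ("multiplicative", "edge_only"):
            raise PathwayError(f"unknown propagation {self.propagation!r}")
        if self.undefined_edge_policy not in ("pass_through", "skip"):
            raise PathwayError(
                f"unknown undefined_edge_policy {self.undefined_edge_policy!r}"
            )


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def validate_pathway(pathway: Pathway) -> list[str]:
    """Return a list of violation descriptions; empty iff well formed.

    Checks node-id uniqueness, edge endpoint resolvability, legal edge
    types and nonempty gene symbols.  Reports, never raises.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for n in pathway.nodes:
        if n.node_id in seen:
            violations.append(f"duplicated node_id {n.node_id!r}")
        seen.add(n.node_id)
        for g in n.genes:
            if not isinstance(g, str) or not g:
                violations.append(f"node {n.node_id!r} holds an empty gene symbol")
    for i, e in enumerate(pathway.edges):
        if e.source not in seen:
            violations.append(f"edge {i} references missing node {e.source!r}")
        if e.target not in seen:
            violations.append(f"edge {i} references missing node {e.target!r}")
        if not isinstance(e.etype, EdgeType):
            violations.append(f"edge {i} has illegal type {e.etype!r}")
    return violations


def _require_node(pathway: Pathway, node_id: str) -> None:
    if node_id not in set(pathway.node_ids):
        raise PathwayError(f"unknown node {node_id!r} in pathway {pathway.name!r}")


def reachable_counts(pathway: Pathway, node_id: str) -> ReachCounts:
    """N and M for one node: transitive descendants and ancestors."""
    _require_node(pathway, node_id)
    g = pathway.to_networkx()
    return ReachCounts(
        n_forward=len(nx.descendants(g, node_id)),
        m_backward=len(nx.ancestors(g, node_id)),
    )


def all_reach_counts(pathway: Pathway) -> dict[str, ReachCounts]:
    """Reachability counts for every node in one pass."""
    g = pathway.to_networkx()
    return {
        v: ReachCounts(len(nx.descendants(g, v)), len(nx.ancestors(g, v)))
        for v in g.nodes
    }


def is_weakly_connected(pathway: Pathway) -> bool:
    """True iff the underlying undirected graph is one component."""
    if not pathway.nodes:
        raise PathwayError("empty pathway has no connectivity")
    return nx.is_weakly_connected(pathway.to_networkx())


def weak_components(pathway: Pathway) -> list[set[str]]:
    """Weakly connected components as node-id sets, largest first."""
    if not pathway.nodes:
        raise PathwayError("empty pathway has no components")
    comps = nx.weakly_connected_components(pathway.to_networkx())
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def find_central_node(
    pathway: Pathway,
    config: AnnotationConfig | None = None,
    *,
    within: Iterable[str] | None = None,
) -> str:
    """Pick the central node: the one maximising N+M.

    Ties are broken per ``config.tie_break``: lexicographically smallest
    node_id (default) or a seeded uniform draw among the maximal nodes.
    ``within`` restricts the candidate set (used for per-component
    annotation); reach counts are still computed on the full graph, which
    is equivalent within a weak component.
    """
    config = config or AnnotationConfig()
    if not pathway.nodes:
        raise PathwayError("cannot pick a central node of an empty pathway")
    if within is None and not is_weakly_connected(pathway):
        if not config.per_component:
            comps = weak_components(pathway)
            raise PathwayError(
                f"pathway {pathway.name!r} is not weakly connected "
                f"({len(comps)} components: "
                + "; ".join(sorted(min(c) for c in comps))
                + "); use per_component mode"
            )
    counts = all_reach_counts(pathway)
    candidates = sorted(within) if within is not None else sorted(counts)
    best = max(counts[v].total for v in candidates)
    maximal = [v for v in candidates if counts[v].total == best]
    if len(maximal) == 1 or config.tie_break == "lexicographic":
        return maximal[0]
    return random.Random(config.seed).choice(maximal)
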