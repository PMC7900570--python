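"""Recursive activator/repressor role (ARR) annotation of pathway graphs.

Every gene product in a pathway gets an ARR coefficient in
{-1, -0.5, 0, 0.5, 1}: pathway activator (1), rather activator (0.5),
repressor (-1), rather repressor (-0.5), or inconsistent role (0).

The procedure:

1.  *Initialization.*  The central node — the node maximising N+M
    (forward plus backward reachable node counts) — is assigned ARR = 1
    and seeds the traversal.
2.  *Recursion.*  Starting from the nodes adjacent to the central node,
    roles propagate breadth-first along edges in both orientations.  An
    activation edge proposes the source's sign, an inhibition edge the
    opposite sign (multiplicative mode; in the literal edge-only mode the
    proposal is the edge sign regardless of the source role).  Each edge
    is consumed at most once, which guarantees termination on cyclic
    graphs.  Every gene product in a newly proposed node receives the
    node's proposal, resolved against any role the gene already holds.
3.  *Conflict resolution.*  Opposite-sign proposals resolve to 0;
    proposals within 0.5 of the held value resolve to +0.5 or -0.5
    depending on which sign is present.
4.  *Stop rule.*  Nodes whose resolved role is 0, 0.5 or -0.5 are never
    expanded further — otherwise a single inconsistency would bleach the
    whole graph.  Genes only reachable through such nodes stay
    unannotated and are reported as excluded.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .pathway_model import (
    AnnotationConfig,
    Edge,
    EdgeType,
    Pathway,
    PathwayError,
    find_central_node,
    validate_pathway,
    weak_components,
)

__all__ = [
    "ARR_VALUES",
    "AnnotationState",
    "AnnotatedPathway",
    "TraceEvent",
    "resolve_conflict",
    "propose_arr",
    "propagate_arr",
    "annotate_pathway",
]

#: The five legal ARR coefficients.
ARR_VALUES: frozenset[float] = frozenset((-1.0, -0.5, 0.0, 0.5, 1.0))

#: Roles at which the traversal stops expanding.
_STOP_VALUES: frozenset[float] = frozenset((-0.5, 0.0, 0.5))


def _check_arr(value: float, name: str) -> float:
    value = float(value)
    if value not in ARR_VALUES:
        raise PathwayError(f"{name} must be one of {sorted(ARR_VALUES)}, got {value}")
    return value


def resolve_conflict(previous: float, proposed: float) -> float:
    """Resolve a newly proposed ARR against the currently held one.

    Rules, in order:

    1. identical values keep the held value;
    2. opposite signs resolve to 0 (inconsistent role);
    3. values within 0.5 of each other with a positive member resolve
       to 0.5 ("rather activator");
    4. values within 0.5 of each other with a negative member resolve
       to -0.5 ("rather repressor");
    5. otherwise the held value is kept — in particular a held 0 is
       sticky against a ±1 proposal (the gap exceeds 0.5 and an
       inconsistent role stays inconsistent).
    """
    previous = _check_arr(previous, "previous")
    proposed = _check_arr(proposed, "proposed")
    if previous == proposed:
        return previous
    if previous * proposed < 0:
        return 0.0
    if abs(previous - proposed) <= 0.5:
        if previous > 0 or proposed > 0:
            return 0.5
        if previous < 0 or proposed < 0:
            return -0.5
    return previous


def propose_arr(
    source_arr: float, etype: EdgeType, config: AnnotationConfig | None = None
) -> float:
    """ARR proposal carried by one edge out of a node with role ``source_arr``.

    Only full-role nodes (±1) are ever expanded, per the stop rule.
    Multiplicative mode multiplies the source role by the edge sign, so an
    inhibitor of an inhibitor proposes activation; edge-only mode emits
    the edge sign alone.  Undefined edges carry +1 under the pass-through
    policy (policy "skip" is handled by the traversal, which consumes the
    edge without calling here).
    """
    config = config or AnnotationConfig()
    source_arr = _check_arr(source_arr, "source_arr")
    if source_arr not in (1.0, -1.0):
        raise PathwayError(
            f"internal error: expanding a stopped node (ARR={source_arr})"
        )
    sign = float(EdgeType(etype).sign)
    if config.propagation == "multiplicative":
        return source_arr * sign
    return sign


@dataclass(frozen=True)
class TraceEvent:
    """One edge-processing event in the traversal log."""

    edge_index: int
    source: str
    target: str
    etype: EdgeType
    proposed: float
    node_resolved: float
    gene_resolutions: tuple[tuple[str, float], ...]

    def as_line(self) -> str:
        genes = ",".join(f"{g}={v:+g}" for g, v in self.gene_resolutions)
        return (
            f"edge[{self.edge_index}] {self.source}->{self.target}"
            f" ({self.etype.value}) proposed={self.proposed:+g}"
            f" node={self.node_resolved:+g} genes[{genes}]"
        )


@dataclass
class AnnotationState:
    """Mutable traversal state: resolved roles, edge ledger, frontier."""

    node_arr: dict[str, float] = field(default_factory=dict)
    gene_arr: dict[str, float] = field(default_factory=dict)
    gene_history: dict[str, list[float]] = field(default_factory=dict)
    visited_edges: set[int] = field(default_factory=set)
    frontier: deque[str] = field(default_factory=deque)
    trace: list[TraceEvent] = field(default_factory=list)


@dataclass
class AnnotatedPathway:
    """A pathway together with its resolved roles and traversal trace."""

    pathway: Pathway
    central_node: str
    node_arr: dict[str, float]
    gene_arr: dict[str, float]
    excluded_genes: set[str]
    trace: list[TraceEvent]

    @property
    def name(self) -> str:
        return self.pathway.name


def _assign_node_genes(
    state: AnnotationState, genes: frozenset[str], proposed: float
) -> list[tuple[str, float]]:
    resolutions = []
    for g in sorted(genes):
        if g in state.gene_arr:
            resolved = resolve_conflict(state.gene_arr[g], proposed)
        else:
            resolved = proposed
        state.gene_arr[g] = resolved
        state.gene_history.setdefault(g, []).append(proposed)
        resolutions.append((g, resolved))
    return resolutions


def _incident_edges(pathway: Pathway, node_id: str) -> list[tuple[int, Edge, str]]:
    """Unvisited-order incident edges: outgoing first, then incoming,
    each block sorted by (neighbour id, edge type, edge index)."""
    out, inc = [], []
    for i, e in enumerate(pathway.edges):
        if e.source == node_id and e.target != node_id:
            out.append((e.target, e.etype.value, i, e))
        elif e.target == node_id and e.source != node_id:
            inc.append((e.source, e.etype.value, i, e))
    ordered = sorted(out) + sorted(inc)
    return [(i, e, nbr) for nbr, _t, i, e in ordered]


def propagate_arr(
    pathway: Pathway,
    central: str,
    config: AnnotationConfig | None = None,
    state: AnnotationState | None = None,
) -> AnnotationState:
    """Run the role-propagation traversal from ``central``.

    Breadth-first from the central node (which gets ARR = 1, as do its
    genes).  At each expanded node, incident edges not yet consumed are
    processed in a fixed deterministic order; the neighbour's role and its
    genes' roles are updated through :func:`resolve_conflict`.  Neighbours
    resolving to a full role (±1) join the frontier; 0 and ±0.5 stop.
    Passing ``state`` lets per-component annotation accumulate into one
    ledger.
    """
    config = config or AnnotationConfig()
    state = state or AnnotationState()

    state.node_arr[central] = 1.0
    central_node = pathway.node(central)
    state.trace.append(
        TraceEvent(
            edge_index=-1,
            source=central,
            target=central,
            etype=EdgeType.UNDEFINED,
            proposed=1.0,
            node_resolved=1.0,
            gene_resolutions=tuple(_assign_node_genes(state, central_node.genes, 1.0)),
        )
    )
    state.frontier.append(central)

    nodes_by_id = {n.node_id: n for n in pathway.nodes}
    while state.frontier:
        current = state.frontier.popleft()
        source_arr = state.node_arr.get(current)
        if source_arr not in (1.0, -1.0):
            continue  # stop rule: the node's role degraded since enqueueing
        for edge_index, edge, neighbour in _incident_edges(pathway, current):
            if edge_index in state.visited_edges:
                continue
            state.visited_edges.add(edge_index)
            if (
                edge.etype is EdgeType.UNDEFINED
                and config.undefined_edge_policy == "skip"
            ):
                continue
            proposed = propose_arr(source_arr, edge.etype, config)
            if neighbour in state.node_arr:
                resolved = resolve_conflict(state.node_arr[neighbour], proposed)
            else:
                resolved = proposed
            state.node_arr[neighbour] = resolved
            gene_res = _assign_node_genes(
                state, nodes_by_id[neighbour].genes, proposed
            )
            state.trace.append(
                TraceEvent(
                    edge_index=edge_index,
                    source=current,
                    target=neighbour,
                    etype=edge.etype,
                    proposed=proposed,
                    node_resolved=resolved,
                    gene_resolutions=tuple(gene_res),
                )
            )
            if resolved not in _STOP_VALUES:
                state.frontier.append(neighbour)
    return state


def annotate_pathway(
    pathway: Pathway, config: AnnotationConfig | None = None
) -> AnnotatedPathway:
    """Annotate a whole pathway: central-node selection plus propagation.

    Disconnected pathways are rejected unless ``config.per_component`` is
    set, in which case every weak component is annotated from its own
    central node and the results merged (the reported ``central_node`` is
    the largest component's).  Genes in nodes the traversal never reaches
    are listed in ``excluded_genes`` and absent from ``gene_arr``.
    """
    config = config or AnnotationConfig()
    violations = validate_pathway(pathway)
    if violations:
        raise PathwayError(
            f"invalid pathway {pathway.name!r}: " + "; ".join(violations)
        )
    comps = weak_components(pathway)
    if len(comps) > 1 and not config.per_component:
        raise PathwayError(
            f"pathway {pathway.name!r} is not weakly connected; "
            f"{len(comps)} components (smallest members: "
            + ", ".join(sorted(min(c) for c in comps))
            + "). Enable per_component to annotate anyway."
        )

    state = AnnotationState()
    centrals = []
    for comp in comps:
        central = find_central_node(pathway, config, within=comp)
        centrals.append(central)
        propagate_arr(pathway, central, config, state)

    reached_genes = set(state.gene_arr)
    excluded = pathway.all_genes - reached_genes
    return AnnotatedPathway(
        pathway=pathway,
        central_node=centrals[0],
        node_arr=dict(state.node_arr),
        gene_arr=dict(state.gene_arr),
        excluded_genes=excluded,
        trace=list(state.trace),
    )
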