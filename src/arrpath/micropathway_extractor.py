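"""Micropathway extraction.

A micropathway is the sub-graph around one terminal "molecular function"
node: the function node itself plus every node lying on some directed
path of at most ``max_len`` edges that ends at the function node
(default bound: 3 edges).  Full-size pathways often have several terminal
branches with distinct physiological outcomes; extracting each branch
separately lets them be scored independently.
"""

from __future__ import annotations

from collections import deque

from .pathway_model import Pathway, PathwayError

__all__ = [
    "find_function_nodes",
    "extract_micropathway",
    "extract_all_micropathways",
]

DEFAULT_MAX_PATH_LEN = 3


def find_function_nodes(pathway: Pathway) -> list[str]:
    """Node ids of terminal molecular-function (outcome) nodes.

    A node qualifies if explicitly flagged, or — reader heuristic for
    unflagged inputs — if it carries no genes and has no outgoing edges.
    """
    flagged = [n.node_id for n in pathway.nodes if n.is_function_node]
    if flagged:
        return flagged
    sources = {e.source for e in pathway.edges if e.source != e.target}
    return [
        n.node_id
        for n in pathway.nodes
        if not n.genes and n.node_id not in sources
    ]


def extract_micropathway(
    pathway: Pathway, function_node: str, max_len: int = DEFAULT_MAX_PATH_LEN
) -> Pathway:
    """Sub-pathway of all nodes within ``max_len`` directed edges of the
    function node (paths running *into* it), plus all induced edges.

    The bound counts edges and is an upper limit, so nodes closer to the
    terminal are always retained.  Edges between any two retained nodes
    are kept even when not on a qualifying path, so the micropathway is a
    self-consistent graph that can be re-annotated.
    """
    if max_len < 0:
        raise PathwayError("max_len must be nonnegative")
    target = pathway.node(function_node)  # raises on unknown node

    # reverse BFS, depth-limited: dist(u -> function_node) <= max_len
    predecessors: dict[str, list[str]] = {}
    for e in pathway.edges:
        predecessors.setdefault(e.target, []).append(e.source)
    keep = {function_node}
    frontier = deque([(function_node, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth == max_len:
            continue
        for pred in predecessors.get(node, ()):
            if pred not in keep:
                keep.add(pred)
                frontier.append((pred, depth + 1))

    nodes = [n for n in pathway.nodes if n.node_id in keep]
    edges = [e for e in pathway.edges if e.source in keep and e.target in keep]
    return Pathway(
        name=f"{pathway.name}__{target.label}",
        nodes=nodes,
        edges=edges,
        database=pathway.database,
        kind="micro",
    )


def extract_all_micropathways(
    pathway: Pathway, max_len: int = DEFAULT_MAX_PATH_LEN
) -> list[Pathway]:
    """One micropathway per function node; empty list when there is none.

    Node sets of different micropathways may overlap when terminal
    branches share an upstream stem.
    """
    return [
        extract_micropathway(pathway, f, max_len)
        for f in find_function_nodes(pathway)
    ]
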