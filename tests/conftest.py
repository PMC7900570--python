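"""Shared toy-pathway builders and oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from arrpath.pathway_model import Edge, EdgeType, Pathway, PathwayNode


def make_node(node_id: str, gene: str | None = None, function: bool = False) -> PathwayNode:
    genes = frozenset({gene}) if gene else frozenset()
    return PathwayNode(node_id=node_id, genes=genes, is_function_node=function)


def make_pathway(name, node_specs, edge_specs) -> Pathway:
    """node_specs: (id, gene|None[, function]); edge_specs: (src, dst[, type])."""
    nodes = [make_node(*spec) for spec in node_specs]
    edges = [Edge(*spec) for spec in edge_specs]
    return Pathway(name=name, nodes=nodes, edges=edges)


@pytest.fixture
def star_pathway() -> Pathway:
    """Hub with four activation leaves; hub is the unique N+M maximum."""
    return make_pathway(
        "star",
        [("H", "G_H")] + [(f"L{i}", f"G_L{i}") for i in range(4)],
        [("H", f"L{i}", "activation") for i in range(4)],
    )


@pytest.fixture
def diamond_pathway() -> Pathway:
    """Two branches from C reconverging on T with opposite signs."""
    return make_pathway(
        "diamond",
        [(x, f"G_{x}") for x in "CABDT"],
        [
            ("C", "A", "activation"),
            ("C", "B", "activation"),
            ("C", "D", "activation"),
            ("A", "T", "activation"),
            ("B", "T", "inhibition"),
        ],
    )


@pytest.fixture
def chain_to_function() -> Pathway:
    """n1 -> ... -> n5 -> F with F a terminal molecular-function node."""
    return make_pathway(
        "chain",
        [(f"n{i}", f"G{i}") for i in range(1, 6)] + [("F", None, True)],
        [(f"n{i}", f"n{i+1}", "activation") for i in range(1, 5)]
        + [("n5", "F", "activation")],
    )


# ---------------------------------------------------------------------------
# independent oracles (no arrpath graph code)
# ---------------------------------------------------------------------------


def bfs_reachable(adjacency: dict[str, set[str]], start: str) -> set[str]:
    """Plain breadth-first reachability, excluding the start node."""
    seen, queue = {start}, [start]
    while queue:
        v = queue.pop()
        for w in adjacency.get(v, ()):
            if w not in seen:
                seen.add(w)
                queue.append(w)
    return seen - {start}


def reach_counts_oracle(pathway: Pathway) -> dict[str, tuple[int, int]]:
    """All-pairs transitive closure by repeated BFS on raw edge lists."""
    fwd: dict[str, set[str]] = {n.node_id: set() for n in pathway.nodes}
    back: dict[str, set[str]] = {n.node_id: set() for n in pathway.nodes}
    for e in pathway.edges:
        if e.source != e.target:
            fwd[e.source].add(e.target)
            back[e.target].add(e.source)
    return {
        v: (len(bfs_reachable(fwd, v)), len(bfs_reachable(back, v)))
        for v in fwd
    }


def path_sign_oracle(pathway: Pathway, root: str) -> dict[str, float]:
    """On an out-tree: role of each node = product of edge signs from root,
    by depth-first multiplication over the raw edge list."""
    children: dict[str, list[tuple[str, int]]] = {}
    for e in pathway.edges:
        sign = -1 if e.etype is EdgeType.INHIBITION else 1
        children.setdefault(e.source, []).append((e.target, sign))
    roles = {root: 1.0}
    stack = [root]
    while stack:
        v = stack.pop()
        for child, sign in children.get(v, ()):
            roles[child] = roles[v] * sign
            stack.append(child)
    return roles


def random_dag(n_nodes: int, p_edge: float, seed: int) -> Pathway:
    """Random DAG (edges only forward in a fixed order), one gene per node."""
    rng = np.random.default_rng(seed)
    names = [f"d{i:03d}" for i in range(n_nodes)]
    nodes = [make_node(nm, f"G_{nm.upper()}") for nm in names]
    etypes = ["activation", "inhibition", "undefined"]
    edges = [
        Edge(names[i], names[j], etypes[int(rng.integers(0, 3))])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return Pathway(name=f"dag_{n_nodes}_{seed}", nodes=nodes, edges=edges)
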