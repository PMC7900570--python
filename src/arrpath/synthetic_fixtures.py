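"""Synthetic pathways and expression matrices with known ground truth.

Every generator is a pure function of its parameters and seed.  The
fixtures cover the structures the annotation algorithm must handle —
signed out-trees (where the true role of each node is the product of
edge signs along its root path), directed cycles (where every node ties
on N+M), and expression matrices constructed so that a target PAL is
recovered exactly in the noise-free limit.

Expression baselines sit at 100 arbitrary units and noise, when
requested, is multiplicative lognormal on the log10 scale — expression
is nonnegative by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arr_annotator import AnnotatedPathway
from .pal_engine import (
    DEFAULT_CASE_PREFIX,
    DEFAULT_CONTROL_PREFIX,
    ExpressionMatrix,
)
from .pathway_model import Edge, EdgeType, Pathway, PathwayError, PathwayNode

__all__ = [
    "generate_signed_tree",
    "generate_cyclic_pathway",
    "generate_expression_for_pal",
]

BASELINE_EXPRESSION = 100.0


def _node_name(i: int) -> str:
    # children sort after "r" so the root wins lexicographic N+M ties
    # (on an out-tree the root always attains the maximal N+M)
    return "r" if i == 0 else f"s{i:03d}"


def generate_signed_tree(
    n_nodes: int, p_inhibition: float, seed: int
) -> tuple[Pathway, dict[str, float]]:
    """Random out-tree rooted at node ``r`` with signed edges.

    Each non-root node attaches to a uniformly chosen earlier node; each
    edge is inhibitory with probability ``p_inhibition``.  Every node
    carries one gene (``G_<node>``).  Returns the pathway and the
    ground-truth role per node id: the product of edge signs along the
    unique path from the root (the root itself is +1).
    """
    if n_nodes < 1:
        raise PathwayError("n_nodes must be >= 1")
    if not 0 <= p_inhibition <= 1:
        raise PathwayError("p_inhibition must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [
        PathwayNode(node_id=_node_name(i), genes=frozenset({f"G_{_node_name(i).upper()}"}))
        for i in range(n_nodes)
    ]
    edges: list[Edge] = []
    truth = {_node_name(0): 1.0}
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        inhib = bool(rng.random() < p_inhibition)
        etype = EdgeType.INHIBITION if inhib else EdgeType.ACTIVATION
        edges.append(Edge(_node_name(parent), _node_name(i), etype))
        truth[_node_name(i)] = truth[_node_name(parent)] * etype.sign
    return (
        Pathway(name=f"synthetic_tree_{n_nodes}_{seed}", nodes=nodes, edges=edges),
        truth,
    )


def generate_cyclic_pathway(n_nodes: int, seed: int) -> Pathway:
    """Directed cycle with random edge signs; one gene per node.

    By symmetry every node reaches, and is reached by, all others, so all
    nodes tie on N+M — the central node is then a pure tie-break choice.
    """
    if n_nodes < 3:
        raise PathwayError("a cycle needs at least 3 nodes")
    rng = np.random.default_rng(seed)
    names = [f"c{i:03d}" for i in range(n_nodes)]
    nodes = [
        PathwayNode(node_id=nm, genes=frozenset({f"G_{nm.upper()}"})) for nm in names
    ]
    edges = [
        Edge(
            names[i],
            names[(i + 1) % n_nodes],
            EdgeType.INHIBITION if rng.random() < 0.5 else EdgeType.ACTIVATION,
        )
        for i in range(n_nodes)
    ]
    return Pathway(name=f"synthetic_cycle_{n_nodes}_{seed}", nodes=nodes, edges=edges)


def generate_expression_for_pal(
    annotated: AnnotatedPathway,
    target_pal: float,
    n_cases: int,
    n_controls: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = BASELINE_EXPRESSION,
) -> ExpressionMatrix:
    """Expression matrix engineered to yield a known PAL.

    Controls sit at the baseline; in cases each gene g is shifted to
    ``baseline * 10^(ARR_g * target_pal)``, so with zero noise the
    ARR-weighted mean log10 CNR — the PAL — equals ``target_pal``
    exactly.  ``noise_sd`` adds gene-and-sample-wise Gaussian noise on
    the log10 scale (multiplicative lognormal on the raw scale).  Sample
    names carry the standard ``Tumour_`` / ``Norm_`` markers.
    """
    if n_cases < 1 or n_controls < 1:
        raise PathwayError("need at least one case and one control sample")
    if noise_sd < 0:
        raise PathwayError("noise_sd must be nonnegative")
    genes = sorted(g for g, arr in annotated.gene_arr.items() if arr != 0)
    if not genes:
        raise PathwayError("annotated pathway has no nonzero-ARR genes")
    arr = np.array([annotated.gene_arr[g] for g in genes])
    rng = np.random.default_rng(seed)

    case_names = [f"{DEFAULT_CASE_PREFIX}{i + 1:03d}" for i in range(n_cases)]
    control_names = [f"{DEFAULT_CONTROL_PREFIX}{i + 1:03d}" for i in range(n_controls)]

    log10_controls = np.full((len(genes), n_controls), np.log10(baseline))
    log10_cases = np.log10(baseline) + arr[:, None] * target_pal
    log10_cases = np.broadcast_to(log10_cases, (len(genes), n_cases)).copy()
    if noise_sd > 0:
        log10_cases += rng.normal(0.0, noise_sd, size=log10_cases.shape)

    df = pd.DataFrame(
        np.hstack([10.0**log10_cases, 10.0**log10_controls]),
        index=genes,
        columns=case_names + control_names,
    )
    return ExpressionMatrix(df)
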