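"""Pathway activation level (PAL) scoring.

Given an ARR-annotated pathway knowledgebase and a normalized gene
expression matrix with case and control samples, this module computes

* the case-to-norm ratio (CNR) per gene and case sample:
  ``CNR_gs = expr_gs / mean(expr_g over controls)`` (epsilon-floored);
* node activation: the sum of ``log10 CNR`` over all genes in a node;
* the PAL of a pathway in one case sample:

  .. math:: PAL = \\frac{\\sum_g ARR_g \\log_{10} CNR_g}{\\sum_g |ARR_g|}

  — an ARR-weighted mean log expression shift over the pathway's
  annotated genes.  Positive PAL means the pathway is activated in the
  case relative to the controls, negative that it is suppressed.  Genes
  with ARR = 0 (inconsistent role) drop out of both sums; the
  unnormalized numerator is available via ``normalized=False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arr_annotator import AnnotatedPathway
from .pathway_model import PathwayError, PathwayNode

__all__ = [
    "ExpressionMatrix",
    "SampleGroups",
    "PalConfig",
    "split_samples",
    "compute_cnr",
    "node_activation",
    "compute_pal",
    "compute_pal_table",
]

logger = logging.getLogger(__name__)

DEFAULT_CASE_PREFIX = "Tumour_"
DEFAULT_CONTROL_PREFIX = "Norm_"
DEFAULT_EPSILON = 1e-8


@dataclass
class ExpressionMatrix:
    """Normalized, nonnegative expression values, genes x samples.

    ``values`` is a DataFrame indexed by unique HGNC symbols with one
    column per sample.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise PathwayError(f"duplicated gene symbols: {dupes}")
        if (df.to_numpy() < 0).any():
            bad = sorted(df.index[(df < 0).any(axis=1)])
            raise PathwayError(f"negative expression values in rows: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleGroups:
    """Disjoint, nonempty case and control sample name lists."""

    cases: tuple[str, ...]
    controls: tuple[str, ...]
    unmatched: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cases:
            raise PathwayError("no case samples matched")
        if not self.controls:
            raise PathwayError("no control samples matched")
        if set(self.cases) & set(self.controls):
            raise PathwayError("a sample matched both case and control markers")


@dataclass(frozen=True)
class PalConfig:
    """Scoring options: log base, epsilon floor, normalization.

    ``log_base`` is 10 by default; ``epsilon`` floors both the case value
    and the control mean before the ratio so zeros never divide;
    ``normalized=False`` reports the raw ARR-weighted sum instead of the
    mean; ``min_coverage`` is the pathway gene-coverage fraction below
    which a warning is logged.
    """

    log_base: float = 10.0
    epsilon: float = DEFAULT_EPSILON
    normalized: bool = True
    min_coverage: float = 0.5


def split_samples(
    sample_names: list[str],
    case_prefix: str = DEFAULT_CASE_PREFIX,
    control_prefix: str = DEFAULT_CONTROL_PREFIX,
) -> SampleGroups:
    """Partition sample names into cases and controls by substring match.

    Names containing the case marker (default ``Tumour_``) become cases,
    those containing the control marker (``Norm_``) controls; names
    matching neither are reported and excluded.  Both groups must end up
    nonempty.
    """
    if not sample_names:
        raise PathwayError("no sample names given")
    cases, controls, unmatched = [], [], []
    for name in sample_names:
        is_case = case_prefix in name
        is_control = control_prefix in name
        if is_case and is_control:
            raise PathwayError(f"sample {name!r} matches both markers")
        elif is_case:
            cases.append(name)
        elif is_control:
            controls.append(name)
        else:
            unmatched.append(name)
    if unmatched:
        logger.warning("samples matched neither marker, excluded: %s", unmatched)
    return SampleGroups(tuple(cases), tuple(controls), tuple(unmatched))


def compute_cnr(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Case-to-norm ratio matrix, genes x case samples.

    For gene g and case sample s:
    ``CNR = max(expr[g, s], eps) / max(mean_c expr[g, c], eps)`` with the
    arithmetic mean over controls.  Entries are strictly positive.
    """
    missing = [s for s in groups.cases + groups.controls if s not in expr.values]
    if missing:
        raise PathwayError(f"samples absent from expression matrix: {missing}")
    control_mean = expr.values[list(groups.controls)].mean(axis=1)
    denominator = control_mean.clip(lower=epsilon)
    numerator = expr.values[list(groups.cases)].clip(lower=epsilon)
    return numerator.div(denominator, axis=0)


def node_activation(
    node: PathwayNode, cnr_column: pd.Series, log_base: float = 10.0
) -> float:
    """Sum of log case-to-norm ratios over the node's genes.

    Genes absent from the CNR column are skipped with a debug log; a node
    with no scorable gene scores 0.
    """
    present = [g for g in sorted(node.genes) if g in cnr_column.index]
    skipped = node.genes - set(present)
    if skipped:
        logger.debug(
            "node %s: genes without expression skipped: %s",
            node.node_id,
            sorted(skipped),
        )
    if not present:
        return 0.0
    return float(np.sum(np.log(cnr_column[present]) / math.log(log_base)))


def compute_pal(
    annotated: AnnotatedPathway,
    cnr_column: pd.Series,
    config: PalConfig | None = None,
) -> float:
    """PAL of one annotated pathway in one case sample.

    The ARR-weighted mean of log CNR over annotated genes present in the
    expression data.  Returns NaN when no annotated gene with a nonzero
    role has expression (zero denominator).
    """
    config = config or PalConfig()
    log_base = math.log(config.log_base)
    numerator = 0.0
    denominator = 0.0
    for gene, arr in annotated.gene_arr.items():
        if arr == 0 or gene not in cnr_column.index:
            continue
        numerator += arr * math.log(cnr_column[gene]) / log_base
        denominator += abs(arr)
    if denominator == 0:
        return math.nan
    return numerator / denominator if config.normalized else numerator


def compute_pal_table(
    knowledgebase: list[AnnotatedPathway],
    expr: ExpressionMatrix,
    groups: SampleGroups,
    config: PalConfig | None = None,
) -> pd.DataFrame:
    """PAL for every (pathway, case sample) pair.

    Rows are pathway names, columns case sample names; NaN where the PAL
    is undefined.  Pathways whose annotated-gene coverage in the
    expression matrix falls below ``config.min_coverage`` are warned
    about.
    """
    if not knowledgebase:
        raise PathwayError("empty knowledgebase")
    config = config or PalConfig()
    cnr = compute_cnr(expr, groups, config.epsilon)
    rows = {}
    for ann in knowledgebase:
        genes = set(ann.gene_arr)
        if genes:
            coverage = len(genes & set(cnr.index)) / len(genes)
            if coverage < config.min_coverage:
                logger.warning(
                    "pathway %s: only %.0f%% of annotated genes have expression",
                    ann.name,
                    100 * coverage,
                )
        rows[ann.name] = {
            sample: compute_pal(ann, cnr[sample], config) for sample in groups.cases
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=list(groups.cases))
    table.index.name = "pathway"
    return table
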