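"""Readers and writers for the pathway CSV knowledgebase format.

Each pathway is stored as three worksheets — *genes* (symbol and ARR),
*edges* (source node, target node, interaction type) and *nodes* (node
id, its ';'-separated gene list, function-node flag).  Two physical
layouts are accepted:

* three sibling files ``<stem>.genes.csv`` / ``<stem>.edges.csv`` /
  ``<stem>.nodes.csv`` (canonical, what the writer emits);
* a single CSV with a leading ``worksheet`` column valued
  ``genes`` / ``edges`` / ``nodes``.

Also here: the expression-matrix CSV reader (HGNC symbols in the first
column, one numeric column per sample), a gene-alias renaming operation,
and a whole-directory knowledgebase loader.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .arr_annotator import ARR_VALUES, AnnotatedPathway
from .pal_engine import ExpressionMatrix
from .pathway_model import Edge, EdgeType, Pathway, PathwayError, PathwayNode

__all__ = [
    "read_pathway",
    "write_pathway",
    "read_expression",
    "write_pal_table",
    "apply_alias_map",
    "read_knowledgebase_dir",
    "KnowledgebaseSummary",
]

logger = logging.getLogger(__name__)

_WORKSHEETS = ("genes", "edges", "nodes")
_GENE_HEADER = ["gene", "arr"]
_EDGE_HEADER = ["source_node", "target_node", "type"]
_NODE_HEADER = ["node", "genes", "is_function"]


class ParseError(PathwayError):
    """Malformed knowledgebase file; message carries file and line."""


def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


def _parse_arr(value: str, where: str) -> float | None:
    if value == "":
        return None
    try:
        arr = float(value)
    except ValueError:
        raise ParseError(f"{where}: illegal ARR value {value!r}") from None
    if arr not in ARR_VALUES:
        raise ParseError(
            f"{where}: ARR {arr} not in {sorted(ARR_VALUES)}"
        )
    return arr


def _parse_edge_type(value: str, where: str) -> EdgeType:
    try:
        return EdgeType(value)
    except ValueError:
        raise ParseError(
            f"{where}: illegal edge type {value!r} "
            f"(expected activation/inhibition/undefined)"
        ) from None


def _split_worksheets(path: Path) -> dict[str, list[tuple[int, list[str]]]]:
    """Single-file dialect: route rows by the leading ``worksheet`` column."""
    sections: dict[str, list[tuple[int, list[str]]]] = {w: [] for w in _WORKSHEETS}
    for lineno, row in enumerate(_read_rows(path), start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        tag, rest = row[0].strip(), row[1:]
        if tag == "worksheet":  # header line of the dialect
            continue
        if tag not in sections:
            raise ParseError(f"{path}:{lineno}: unknown worksheet tag {tag!r}")
        sections[tag].append((lineno, rest))
    return sections


def _sibling_paths(path: Path) -> dict[str, Path] | None:
    name = path.name
    for ws in _WORKSHEETS:
        suffix = f".{ws}.csv"
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            return {w: path.with_name(f"{stem}.{w}.csv") for w in _WORKSHEETS}
    stem_path = path if path.suffix != ".csv" else path.with_suffix("")
    candidate = {w: stem_path.with_name(stem_path.name + f".{w}.csv") for w in _WORKSHEETS}
    if all(p.exists() for p in candidate.values()):
        return candidate
    return None


def _strip_header(
    rows: list[tuple[int, list[str]]], expected: list[str]
) -> list[tuple[int, list[str]]]:
    if rows and [c.strip().lower() for c in rows[0][1][: len(expected)]] == expected:
        return rows[1:]
    return rows


def read_pathway(path: str | Path) -> Pathway:
    """Load one pathway from either on-disk layout.

    ``path`` may be a worksheet file, the common stem of the three-file
    layout, or a single sectioned CSV.  Gene symbols are upper-cased;
    node ids are case-sensitive.  ARR values present in the genes
    worksheet are validated and attached as ``pathway.gene_arr_hint``.
    """
    path = Path(path)
    siblings = _sibling_paths(path)
    if siblings is not None:
        sections = {}
        for ws, p in siblings.items():
            if not p.exists():
                raise ParseError(f"missing worksheet file {p}")
            sections[ws] = [(i, row) for i, row in enumerate(_read_rows(p), start=1)]
        name = siblings["genes"].name[: -len(".genes.csv")]
    elif path.exists():
        sections = _split_worksheets(path)
        name = path.stem
    else:
        raise ParseError(f"no pathway found at {path}")

    gene_rows = _strip_header(sections["genes"], _GENE_HEADER)
    edge_rows = _strip_header(sections["edges"], _EDGE_HEADER)
    node_rows = _strip_header(sections["nodes"], _NODE_HEADER)

    gene_arr_hint: dict[str, float] = {}
    for lineno, row in gene_rows:
        if not row or not row[0].strip():
            continue
        gene = row[0].strip().upper()
        arr = _parse_arr(row[1].strip() if len(row) > 1 else "", f"genes:{lineno}")
        if arr is not None:
            gene_arr_hint[gene] = arr

    nodes = []
    for lineno, row in node_rows:
        if not row or not row[0].strip():
            continue
        node_id = row[0].strip()
        genes = frozenset(
            g.strip().upper()
            for g in (row[1].split(";") if len(row) > 1 and row[1].strip() else [])
            if g.strip()
        )
        is_function = len(row) > 2 and row[2].strip() in ("1", "true", "True")
        nodes.append(
            PathwayNode(node_id=node_id, genes=genes, is_function_node=is_function)
        )

    edges = []
    for lineno, row in edge_rows:
        if not row or not row[0].strip():
            continue
        if len(row) < 2:
            raise ParseError(f"edges:{lineno}: need source and target columns")
        etype = _parse_edge_type(
            row[2].strip() if len(row) > 2 and row[2].strip() else "undefined",
            f"edges:{lineno}",
        )
        edges.append(Edge(source=row[0].strip(), target=row[1].strip(), etype=etype))

    kind = "micro" if "__" in name else "core"
    pathway = Pathway(name=name, nodes=nodes, edges=edges, kind=kind)
    pathway.gene_arr_hint = gene_arr_hint  # type: ignore[attr-defined]
    return pathway


def write_pathway(
    annotated: AnnotatedPathway | Pathway, path: str | Path
) -> list[Path]:
    """Write the three worksheet files for a pathway.

    ``path`` is the common stem; ``<stem>.genes.csv`` etc. are produced.
    For an annotated pathway the genes worksheet carries the resolved
    ARRs and omits excluded genes; row order is sorted, so output is
    byte-stable.  Returns the paths written.
    """
    if isinstance(annotated, AnnotatedPathway):
        pathway = annotated.pathway
        gene_arr: dict[str, float] = annotated.gene_arr
    else:
        pathway = annotated
        gene_arr = {g: None for g in sorted(pathway.all_genes)}  # type: ignore[misc]

    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {w: stem.with_name(stem.name + f".{w}.csv") for w in _WORKSHEETS}

    with open(paths["genes"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_GENE_HEADER)
        for gene in sorted(gene_arr):
            arr = gene_arr[gene]
            w.writerow([gene, "" if arr is None else f"{arr:g}"])

    with open(paths["edges"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EDGE_HEADER)
        for e in sorted(pathway.edges, key=lambda e: (e.source, e.target, e.etype.value)):
            w.writerow([e.source, e.target, e.etype.value])

    with open(paths["nodes"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_NODE_HEADER)
        for n in sorted(pathway.nodes, key=lambda n: n.node_id):
            w.writerow(
                [n.node_id, ";".join(sorted(n.genes)), "1" if n.is_function_node else "0"]
            )

    return [paths[w] for w in _WORKSHEETS]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Expression CSV: first column gene symbols, the rest numeric samples.

    Duplicate symbols and negative values are rejected with the
    offending rows named.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise PathwayError(f"non-numeric expression values in {path}: {exc}") from None
    return ExpressionMatrix(df)  # validates duplicates/negatives


def write_pal_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write ``pal.csv``: header ``pathway,<case samples...>``, one row
    per pathway, missing PALs as empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out.index.name = "pathway"
    out.to_csv(path, na_rep="", float_format="%.6g", encoding="utf-8")
    return path


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV old-symbol -> HGNC symbol (header optional)."""
    mapping: dict[str, str] = {}
    for lineno, row in enumerate(_read_rows(Path(path)), start=1):
        if not row or not row[0].strip():
            continue
        if lineno == 1 and row[0].strip().lower() in ("old", "alias", "old_symbol"):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: alias map needs two columns")
        mapping[row[0].strip().upper()] = row[1].strip().upper()
    return mapping


def apply_alias_map(obj, mapping: dict[str, str]):
    """Rename gene symbols per an old -> HGNC mapping table.

    For a :class:`Pathway`, symbols mapping to the same target are merged
    (sets absorb duplicates).  For an :class:`ExpressionMatrix` a
    collision — two present rows renamed to one symbol — is an error,
    since their values cannot be merged unambiguously.
    """
    mapping = {k.upper(): v.upper() for k, v in mapping.items()}
    if isinstance(obj, Pathway):
        nodes = [
            PathwayNode(
                node_id=n.node_id,
                label=n.label,
                genes=frozenset(mapping.get(g, g) for g in n.genes),
                is_function_node=n.is_function_node,
            )
            for n in obj.nodes
        ]
        return Pathway(
            name=obj.name,
            nodes=nodes,
            edges=list(obj.edges),
            database=obj.database,
            kind=obj.kind,
        )
    if isinstance(obj, ExpressionMatrix):
        renamed = [mapping.get(g, g) for g in obj.values.index]
        if len(set(renamed)) < len(renamed):
            dupes = sorted({g for g in renamed if renamed.count(g) > 1})
            raise PathwayError(
                f"alias map collides expression rows onto: {dupes}"
            )
        df = obj.values.copy()
        df.index = pd.Index(renamed)
        return ExpressionMatrix(df)
    raise TypeError(f"cannot apply alias map to {type(obj).__name__}")


@dataclass
class KnowledgebaseSummary:
    """Counts and gene union from a knowledgebase directory load."""

    n_pathways: int = 0
    n_core: int = 0
    n_micro: int = 0
    gene_union: set[str] = field(default_factory=set)
    failures: list[tuple[str, str]] = field(default_factory=list)


def read_knowledgebase_dir(
    directory: str | Path,
) -> tuple[list[Pathway], KnowledgebaseSummary]:
    """Load every pathway under a directory.

    Both layouts are accepted; three-file triplets are loaded once per
    stem.  Individual file failures are collected in the summary instead
    of aborting the load.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise PathwayError(f"not a directory: {directory}")
    stems: dict[str, Path] = {}
    singles: list[Path] = []
    for p in sorted(directory.glob("*.csv")):
        for ws in _WORKSHEETS:
            if p.name.endswith(f".{ws}.csv"):
                stems.setdefault(p.name[: -len(f".{ws}.csv")], p)
                break
        else:
            singles.append(p)

    pathways: list[Pathway] = []
    summary = KnowledgebaseSummary()
    for source in list(stems.values()) + singles:
        try:
            pathways.append(read_pathway(source))
        except (ParseError, PathwayError, OSError) as exc:
            summary.failures.append((str(source), str(exc)))
            logger.warning("failed to load %s: %s", source, exc)
    summary.n_pathways = len(pathways)
    summary.n_core = sum(1 for p in pathways if p.kind == "core")
    summary.n_micro = sum(1 for p in pathways if p.kind == "micro")
    for p in pathways:
        summary.gene_union |= p.all_genes
    return pathways, summary
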