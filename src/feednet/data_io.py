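"""Readers, writers and validated containers for every external format the pipeline touches.

Matrices travel as TSV (UTF-8, tab-delimited, header row of sample ids,
first column feature ids). Networks travel as SIF with an optional sidecar
node-type TSV, gene sets as GMT, and microbe-gene co-mention counts as a
long-format TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = frozenset({"species", "de_gene", "transient_gene"})
EDGE_TYPES = frozenset({"co_abundance", "co_expression", "literature_relation"})


class ParseError(ValueError):
    """Malformed cell or line in an input file."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class AbundanceTable:
    """Species x sample percent abundances with a per-sample group label.

    ``values[i, j]`` is the percent abundance (0-100 scale) of
    ``species_ids[i]`` in ``sample_ids[j]``; ``group[j]`` labels the
    feeding condition of sample j (canonically ``BF`` or ``FF``).
    """

    species_ids: list[str]
    sample_ids: list[str]
    group: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.sample_ids)} samples"
            )
        if len(self.group) != len(self.sample_ids):
            raise ConfigurationError("one group label per sample required")
        _check_ids(self.species_ids, "species ids")
        _check_ids(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite abundance values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative abundance at species {self.species_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-seen order."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g)
        return list(seen)

    def sample_indices(self, group: str) -> np.ndarray:
        idx = np.asarray([j for j, g in enumerate(self.group) if g == group])
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def subset_group(self, group: str) -> "AbundanceTable":
        idx = self.sample_indices(group)
        return AbundanceTable(
            species_ids=list(self.species_ids),
            sample_ids=[self.sample_ids[j] for j in idx],
            group=[group] * idx.size,
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with per-sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    group: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group) != len(self.sample_ids):
            raise ConfigurationError("one group label per sample required")
        _check_ids(self.gene_ids, "gene ids")
        _check_ids(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite expression values")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g)
        return list(seen)

    def sample_indices(self, group: str) -> np.ndarray:
        idx = np.asarray([j for j, g in enumerate(self.group) if g == group])
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        out = {
            t: (name, frozenset(m & universe))
            for t, (name, m) in self.sets.items()
            if m & universe
        }
        return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# matrix TSV


def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate feature ids")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {raw!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def _groups_for(sample_ids: list[str], group_map: Mapping[str, str]) -> list[str]:
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise ConfigurationError(f"no group label for samples: {missing}")
    return [group_map[s] for s in sample_ids]


def read_abundance(path: str | Path, group_map: Mapping[str, str]) -> AbundanceTable:
    """Read a species x sample abundance TSV.

    Percent (columns summing to ~100) and proportion (~1) scales are
    auto-detected; proportions are rescaled to percent internally.
    """
    df = _read_matrix_tsv(path)
    if (df.to_numpy() < 0).any():
        bad = np.argwhere(df.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative abundance at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    col_sums = df.to_numpy().sum(axis=0)
    positive = col_sums[col_sums > 0]
    if positive.size and np.median(positive) < 2.0:  # proportion scale
        logger.info("abundance table detected on proportion scale; rescaling to percent")
        df = df * 100.0
    sample_ids = list(df.columns)
    return AbundanceTable(
        species_ids=list(df.index),
        sample_ids=sample_ids,
        group=_groups_for(sample_ids, group_map),
        values=df.to_numpy(),
    )


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="species")


def read_expression(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene x sample log2-expression TSV."""
    df = _read_matrix_tsv(path)
    sample_ids = list(df.columns)
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=sample_ids,
        group=_groups_for(sample_ids, group_map),
        values=df.to_numpy(),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# typed graphs / SIF


def new_typed_graph() -> nx.Graph:
    return nx.Graph()


def add_typed_node(graph: nx.Graph, node: str, node_type: str) -> None:
    if node_type not in NODE_TYPES:
        raise ValueError(f"unknown node type {node_type!r}; accepted: {sorted(NODE_TYPES)}")
    graph.add_node(node, node_type=node_type)


def add_typed_edge(
    graph: nx.Graph, u: str, v: str, edge_type: str, weight: float | None = None
) -> None:
    if edge_type not in EDGE_TYPES:
        raise ValueError(f"unknown edge type {edge_type!r}; accepted: {sorted(EDGE_TYPES)}")
    if u == v:
        raise ValueError(f"self-loop on {u!r} not allowed")
    attrs: dict = {"edge_type": edge_type}
    if weight is not None:
        attrs["weight"] = float(weight)
    graph.add_edge(u, v, **attrs)


def validate_typed_graph(graph: nx.Graph) -> None:
    """Enforce the typed-graph invariants.

    Undirected, no self-loops, every node typed, co_abundance edges join
    species only and literature_relation edges join species to genes.
    """
    if graph.is_directed():
        raise ValueError("typed graphs are undirected")
    for n, data in graph.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {n!r} has invalid type {data.get('node_type')!r}")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        et = data.get("edge_type")
        if et not in EDGE_TYPES:
            raise ValueError(f"edge ({u!r},{v!r}) has invalid type {et!r}")
        tu = graph.nodes[u]["node_type"]
        tv = graph.nodes[v]["node_type"]
        if et == "co_abundance" and {tu, tv} != {"species"}:
            raise ValueError(f"co_abundance edge ({u!r},{v!r}) must join species nodes")
        if et == "literature_relation" and not (
            ("species" in (tu, tv)) and ({tu, tv} - {"species"})
        ):
            raise ValueError(
                f"literature_relation edge ({u!r},{v!r}) must join a species to a gene"
            )


def read_sif(
    path: str | Path,
    node_types_path: str | Path | None = None,
    edge_type_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a SIF network (one edge per line: source, edge type, target).

    Lines may be tab- or whitespace-delimited; a single-token line declares
    an isolated node. Node types come from a sidecar TSV (id <TAB> type);
    without one every node defaults to ``species`` with a warning.
    ``edge_type_map`` translates foreign edge-type tokens into the accepted
    vocabulary.
    """
    path = Path(path)
    graph = nx.Graph()
    edge_type_map = dict(edge_type_map or {})
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            tokens = [t for t in tokens if t]
            if len(tokens) == 1:
                graph.add_node(tokens[0])
            elif len(tokens) >= 3:
                src, et, *targets = tokens
                et = edge_type_map.get(et, et)
                if et not in EDGE_TYPES:
                    raise ParseError(
                        f"{path}:{lineno}: unknown edge type {tokens[1]!r}; "
                        f"accepted: {sorted(EDGE_TYPES)} (or map it via edge_type_map)"
                    )
                for tgt in targets:
                    if src == tgt:
                        raise ParseError(f"{path}:{lineno}: self-loop on {src!r}")
                    graph.add_edge(src, tgt, edge_type=et)
            else:
                raise ParseError(f"{path}:{lineno}: expected 1 or >=3 fields, got {len(tokens)}")

    if node_types_path is not None:
        types = read_node_types(node_types_path)
        unknown = set(graph.nodes) - set(types)
        if unknown:
            raise ConfigurationError(
                f"nodes missing from sidecar {node_types_path}: {sorted(unknown)[:5]}"
            )
        nx.set_node_attributes(graph, {n: types[n] for n in graph.nodes}, "node_type")
    else:
        logger.warning("%s: no node-type sidecar; defaulting all nodes to 'species'", path)
        nx.set_node_attributes(graph, "species", "node_type")
    return graph


def write_sif(graph: nx.Graph, path: str | Path, node_types_path: str | Path | None = None) -> None:
    """Write a graph as SIF (tab-delimited) plus an optional node-type sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            et = data.get("edge_type", "co_abundance")
            fh.write(f"{u}\t{et}\t{v}\n")
        for n in sorted(nx.isolates(graph), key=str):
            fh.write(f"{n}\n")
    if node_types_path is not None:
        write_node_types(graph, node_types_path)


def read_node_types(path: str | Path) -> dict[str, str]:
    types: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'id<TAB>type'")
            node, ntype = parts
            if ntype not in NODE_TYPES:
                raise ParseError(
                    f"{path}:{lineno}: unknown node type {ntype!r}; accepted: {sorted(NODE_TYPES)}"
                )
            types[node] = ntype
    return types


def write_node_types(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in sorted(graph.nodes, key=str):
            fh.write(f"{n}\t{graph.nodes[n].get('node_type', 'species')}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, members...).

    Duplicate members within a set are collapsed; an empty file yields an
    empty collection with a logged warning.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(parts)}")
            term, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {term!r} has no members")
            sets[term] = (desc, frozenset(members))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# co-mention counts


COUNT_COLUMNS = ["species", "gene", "n_both", "n_species_only", "n_gene_only", "n_neither"]


def read_cooccurrence_counts(path: str | Path) -> pd.DataFrame:
    """Read the long-format microbe-gene co-mention count table.

    Each row is a (species, gene) pair with its 2x2 abstract counts:
    both mentioned, species only, gene only, neither. All four cells must
    be nonnegative and every pair must sum to the same corpus size.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species": str, "gene": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    counts = df[COUNT_COLUMNS[2:]].to_numpy()
    if (counts < 0).any():
        raise ParseError(f"{path}: negative counts present")
    totals = counts.sum(axis=1)
    if totals.min() <= 0:
        raise ParseError(f"{path}: a pair has empty corpus (N=0)")
    if len(set(totals.tolist())) > 1:
        logger.warning("%s: corpus size differs across pairs", path)
    return df[COUNT_COLUMNS].copy()


def write_cooccurrence_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
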