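"""Per-condition gene co-expression networks from Pearson correlation.

Edges join gene pairs whose correlation across one feeding group's
samples clears a fixed cutoff (default r >= 0.8, unweighted), yielding
directly comparable network densities between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import ExpressionMatrix


def pearson(x, y) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need >=3 observations")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal, NaN where undefined


def correlation_matrix(matrix: ExpressionMatrix, group: str | None = None) -> CorrelationMatrix:
    """All-pairs Pearson r among genes, optionally within one group.

    Rows with zero variance get NaN against every other gene (their
    correlation is undefined, not zero); the diagonal is fixed at 1.
    """
    values = matrix.values
    if group is not None:
        values = values[:, matrix.sample_indices(group)]
    if values.shape[1] < 3:
        raise ValueError("need >=3 samples to correlate")
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.asarray(r, dtype=float)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(gene_ids=list(matrix.gene_ids), r=r)


def threshold_network(
    corr: CorrelationMatrix,
    cutoff: float = 0.8,
    mode: str = "positive",
    node_type: str = "de_gene",
) -> nx.Graph:
    """Unweighted co_expression network at a correlation cutoff.

    ``mode='positive'`` keeps pairs with r >= cutoff; ``'absolute'`` keeps
    |r| >= cutoff.  Every gene appears as a node (isolated allowed);
    undefined correlations never create edges.  The realized r is kept as
    edge metadata.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if mode not in {"positive", "absolute"}:
        raise ValueError("mode must be 'positive' or 'absolute'")
    g = nx.Graph()
    for gene in corr.gene_ids:
        g.add_node(gene, node_type=node_type)
    m = len(corr.gene_ids)
    score = np.abs(corr.r) if mode == "absolute" else corr.r
    for i in range(m):
        for j in range(i + 1, m):
            if not np.isnan(score[i, j]) and score[i, j] >= cutoff:
                g.add_edge(
                    corr.gene_ids[i],
                    corr.gene_ids[j],
                    edge_type="co_expression",
                    weight=float(corr.r[i, j]),
                )
    return g


def coexpression_network(
    matrix: ExpressionMatrix,
    group: str,
    cutoff: float = 0.8,
    mode: str = "positive",
    genes: list[str] | None = None,
) -> nx.Graph:
    """Co-expression network for one group, optionally on a gene subset.

    Both conditions should be run over the same gene universe so their
    densities are comparable.
    """
    if genes is not None:
        index = {g: i for i, g in enumerate(matrix.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        sel = [index[g] for g in genes]
        matrix = ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(matrix.sample_ids),
            group=list(matrix.group),
            values=matrix.values[sel, :],
        )
    return threshold_network(correlation_matrix(matrix, group=group), cutoff=cutoff, mode=mode)


def density(graph: nx.Graph) -> float:
    """Edge density 2|E| / (|V| (|V|-1))."""
    if graph.number_of_nodes() < 2:
        raise ValueError("density needs >=2 nodes")
    return float(nx.density(graph))


def density_ratio(g1: nx.Graph, g2: nx.Graph) -> float:
    """density(g1) / density(g2); inf when g2 has no edges but g1 does."""
    d1, d2 = density(g1), density(g2)
    if d2 == 0:
        return float("inf") if d1 > 0 else float("nan")
    return d1 / d2
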