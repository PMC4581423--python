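"""Species co-abundance network inference and network-level significance.

Per feeding group, pairwise Bray-Curtis similarity between species
abundance profiles is computed across that group's samples; a bootstrap
over samples attaches a per-pair mean and SD, and pairs whose mean
similarity is less than k standard deviations above zero are filtered
out as sampling noise.  Surviving pairs become unweighted co_abundance
edges (similarity retained as edge metadata).  Whole-network significance
comes from a degree-preserving double-edge-swap permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial import distance

from .data_io import AbundanceTable

logger = logging.getLogger(__name__)


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity s = 1 - sum|x-y| / sum(x+y).

    Both vectors must be nonnegative and not both all-zero (a pair of
    absent species has no defined co-occurrence; returns NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        return float("nan")
    return float(1.0 - distance.braycurtis(x, y))


@dataclass
class SimilarityMatrix:
    """Species x species Bray-Curtis similarities with bootstrap stability."""

    feature_ids: list[str]
    similarity: np.ndarray  # observed, NaN where undefined
    boot_mean: np.ndarray
    boot_sd: np.ndarray
    n_boot: int


def _pairwise_bc(values: np.ndarray) -> np.ndarray:
    """All-pairs Bray-Curtis similarity between rows; NaN for all-zero pairs."""
    m = values.shape[0]
    sims = np.full((m, m), np.nan)
    totals = values.sum(axis=1)
    # vectorized: |x-y| and (x+y) row-pair sums
    for i in range(m):
        diff = np.abs(values[i][None, :] - values).sum(axis=1)
        denom = totals[i] + totals
        with np.errstate(invalid="ignore", divide="ignore"):
            sims[i] = np.where(denom > 0, 1.0 - diff / denom, np.nan)
    return sims


def pairwise_species_similarity(
    table: AbundanceTable,
    group: str,
    n_boot: int = 200,
    seed: int = 0,
) -> SimilarityMatrix:
    """Species x species similarity over one group's samples, with bootstrap.

    The bootstrap resamples that group's sample columns with replacement
    ``n_boot`` times and records the per-pair mean and SD of the
    similarity, quantifying how stable each pairwise similarity is under
    sampling noise.  Species absent in the group produce NaN rows (they
    stay isolated in the network).
    """
    sub = table.subset_group(group)
    n = len(sub.sample_ids)
    if n < 2:
        raise ValueError(f"group {group!r} needs >=2 samples")
    if n_boot < 1:
        raise ValueError("n_boot must be >=1")
    obs = _pairwise_bc(sub.values)
    rng = np.random.default_rng(seed)
    m = len(sub.species_ids)
    acc = np.zeros((m, m))
    acc2 = np.zeros((m, m))
    count = np.zeros((m, m))
    for _ in range(n_boot):
        cols = rng.integers(0, n, size=n)
        s = _pairwise_bc(sub.values[:, cols])
        ok = ~np.isnan(s)
        acc[ok] += s[ok]
        acc2[ok] += s[ok] ** 2
        count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, acc / count, np.nan)
        var = np.where(count > 1, (acc2 - count * mean**2) / (count - 1), np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    if n_boot == 1:
        sd = np.where(np.isnan(mean), np.nan, np.inf)  # one draw: stability unknown
        logger.warning("n_boot=1: bootstrap SD undefined, all pairs flagged unstable")
    return SimilarityMatrix(
        feature_ids=list(sub.species_ids),
        similarity=obs,
        boot_mean=mean,
        boot_sd=sd,
        n_boot=n_boot,
    )


def filter_edges(sim: SimilarityMatrix, k: float = 2.0) -> list[tuple[str, str, float]]:
    """Keep pairs whose bootstrap mean similarity is >= k bootstrap SDs above 0.

    Returns (species_i, species_j, mean similarity) triples, i < j.  Pairs
    with zero or undefined mean are always dropped.
    """
    edges = []
    m = len(sim.feature_ids)
    for i in range(m):
        for j in range(i + 1, m):
            mean, sd = sim.boot_mean[i, j], sim.boot_sd[i, j]
            if np.isnan(mean) or mean <= 0 or np.isnan(sd):
                continue
            if mean >= k * sd:
                edges.append((sim.feature_ids[i], sim.feature_ids[j], float(mean)))
    return edges


def community_network(
    table: AbundanceTable,
    group: str,
    k: float = 2.0,
    n_boot: int = 200,
    seed: int = 0,
) -> nx.Graph:
    """Unweighted species co-abundance network for one feeding group.

    All species appear as nodes (isolated nodes mark the absence of
    co-occurrence); filtered similarities become co_abundance edges with
    the bootstrap-mean similarity kept as metadata.
    """
    sim = pairwise_species_similarity(table, group, n_boot=n_boot, seed=seed)
    g = nx.Graph()
    for s in sim.feature_ids:
        g.add_node(s, node_type="species")
    for u, v, w in filter_edges(sim, k=k):
        g.add_edge(u, v, edge_type="co_abundance", weight=w)
    return g


# ---------------------------------------------------------------------------
# degree-preserving permutation null


def degree_preserving_rewire(
    graph: nx.Graph, n_swaps: int | None = None, seed: int | np.random.Generator = 0
) -> nx.Graph:
    """Randomize a simple graph by double-edge swaps, preserving all degrees.

    Each attempted swap picks two distinct edges (a,b), (c,d) and replaces
    them with (a,d), (c,b) unless that would create a self-loop or a
    multi-edge.  ``n_swaps`` counts attempts (default 10|E|).  Graphs with
    fewer than 2 edges are returned unchanged (no swap possible).
    """
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("expected a simple undirected graph")
    out = graph.copy()
    if out.number_of_edges() < 2:
        logger.warning("graph has <2 edges; rewiring is a no-op")
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = 10 * out.number_of_edges()
    edges = list(out.edges())
    m = len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return out


STATISTICS = {
    "edge_count": lambda g: float(g.number_of_edges()),
    "clustering": lambda g: float(nx.average_clustering(g)),
    "mean_weight": lambda g: float(
        np.mean([d.get("weight", 1.0) for _, _, d in g.edges(data=True)])
    )
    if g.number_of_edges()
    else float("nan"),
}


@dataclass
class PermutationTestResult:
    """Observed network statistic against its degree-preserving null."""

    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p_empirical: float
    p_zscore: float  # NaN when the null is constant

    def to_jsonable(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_permutations": self.n_permutations,
            "p_empirical": self.p_empirical,
            "p_zscore": None if np.isnan(self.p_zscore) else self.p_zscore,
        }


def network_permutation_test(
    graph: nx.Graph,
    statistic: str = "clustering",
    n_permutations: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Test a network statistic against degree-preserving rewired nulls.

    ``p_empirical`` uses the add-one estimator (1 + #{null >= observed}) /
    (B + 1); ``p_zscore`` fits a normal to the null draws, matching the
    parametric-from-null convention that can report p-values finer than
    1/(B+1).  ``alternative`` is 'greater' or 'less'.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(STATISTICS)}")
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    stat_fn = STATISTICS[statistic]
    observed = stat_fn(graph)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = stat_fn(degree_preserving_rewire(graph, seed=rng))
    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
        z_tail = lambda z: stats.norm.sf(z)  # noqa: E731
    else:
        extreme = int(np.sum(null <= observed))
        z_tail = lambda z: stats.norm.cdf(z)  # noqa: E731
    p_emp = (1.0 + extreme) / (n_permutations + 1.0)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    p_z = float(z_tail((observed - mu) / sd)) if sd > 0 else float("nan")
    return PermutationTestResult(
        statistic=statistic,
        observed=observed,
        null_mean=mu,
        null_sd=sd,
        n_permutations=n_permutations,
        p_empirical=float(p_emp),
        p_zscore=p_z,
    )
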