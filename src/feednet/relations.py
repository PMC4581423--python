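"""Microbe-gene relation screening and correlation validation.

The input contract is a literature co-mention count table: for each
(species, gene) pair, the 2x2 abstract counts (both, species only, gene
only, neither).  Fisher's exact test screens pairs for co-mention
enrichment; accepted relations are then validated against the omics data
by correlating species abundance with gene expression across samples and
comparing against a random-pair baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AbundanceTable, ExpressionMatrix
from .coexpression import pearson
from .differential import bh_adjust


def fisher_exact_p(n_both: int, n_species_only: int, n_gene_only: int, n_neither: int) -> float:
    """Two-sided Fisher exact p for one 2x2 co-mention table.

    Two-sided by summation of all hypergeometric tables (with the observed
    margins) whose probability does not exceed the observed table's.
    """
    table = np.array([[n_both, n_species_only], [n_gene_only, n_neither]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def accept_relations(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    de_genes: set[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Screen co-mention pairs by Fisher exact test at raw p < alpha.

    Adds ``p`` (and ``p_adj`` when ``adjust``), a boolean ``accepted``,
    and ``gene_type`` (de_gene if the gene is in the DE set, else
    transient_gene).  By default raw p-values are thresholded; BH
    adjustment is available behind ``adjust=True``.
    """
    de_genes = de_genes or set()
    df = counts.copy()
    df["p"] = [
        fisher_exact_p(r.n_both, r.n_species_only, r.n_gene_only, r.n_neither)
        for r in df.itertuples()
    ]
    crit = df["p"].to_numpy()
    if adjust:
        df["p_adj"] = bh_adjust(crit)
        crit = df["p_adj"].to_numpy()
    df["accepted"] = crit < alpha
    df["gene_type"] = ["de_gene" if g in de_genes else "transient_gene" for g in df["gene"]]
    return df


def relation_edges(accepted: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(species, gene, gene_type) triples for the accepted relations."""
    sel = accepted[accepted["accepted"]]
    return [(r.species, r.gene, r.gene_type) for r in sel.itertuples()]


def validate_relations(
    relations: list[tuple[str, str]] | list[tuple[str, str, str]],
    abundance: AbundanceTable,
    expression: ExpressionMatrix,
    group: str | None = None,
) -> pd.DataFrame:
    """Correlate species abundance with gene expression per relation.

    For each accepted (species, gene) pair, Pearson r across the shared
    samples of one feeding group (or pooled when ``group`` is None) with a
    two-sided t-based p.  Pairs where either vector is constant (e.g. the
    species is absent from the group) get missing r, mirroring how a taxon
    undetected under one feeding mode yields NA.
    """
    shared = [s for s in abundance.sample_ids if s in set(expression.sample_ids)]
    if not shared:
        raise ValueError("abundance and expression share no samples")
    ab_col = {s: j for j, s in enumerate(abundance.sample_ids)}
    ex_col = {s: j for j, s in enumerate(expression.sample_ids)}
    if group is not None:
        ab_groups = dict(zip(abundance.sample_ids, abundance.group))
        shared = [s for s in shared if ab_groups[s] == group]
        if len(shared) < 3:
            raise ValueError(f"group {group!r} has <3 shared samples")
    ai = [ab_col[s] for s in shared]
    ei = [ex_col[s] for s in shared]
    sp_row = {s: i for i, s in enumerate(abundance.species_ids)}
    g_row = {g: i for i, g in enumerate(expression.gene_ids)}

    rows = []
    n = len(shared)
    for rel in relations:
        species, gene = rel[0], rel[1]
        if species not in sp_row or gene not in g_row:
            continue
        x = abundance.values[sp_row[species]][ai]
        y = expression.values[g_row[gene]][ei]
        if x.std() == 0 or y.std() == 0:
            r, p = float("nan"), float("nan")
        else:
            r = pearson(x, y)
            t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append((species, gene, group if group is not None else "pooled", r, p))
    return pd.DataFrame(rows, columns=["species", "gene", "group", "r", "p_r"])


def random_pair_baseline(
    abundance: AbundanceTable,
    expression: ExpressionMatrix,
    n_pairs: int = 1000,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
    group: str | None = None,
) -> dict:
    """Mean |r| over random (species, gene) pairs — the null reference.

    Pairs are drawn uniformly from species x genes excluding the accepted
    relations (so the null is not contaminated by real signal); pairs with
    undefined correlation (constant vectors) are reported but excluded
    from the mean.
    """
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    pool = [
        (s, g)
        for s in abundance.species_ids
        for g in expression.gene_ids
        if (s, g) not in exclude
    ]
    if not pool:
        raise ValueError("no random pairs available outside the excluded set")
    idx = rng.integers(0, len(pool), size=n_pairs)
    chosen = [pool[i] for i in idx]
    val = validate_relations(chosen, abundance, expression, group=group)
    defined = val["r"].dropna()
    if defined.empty:
        raise ValueError("all random pairs had undefined correlation")
    return {
        "mean_abs_r": float(defined.abs().mean()),
        "n_pairs": int(n_pairs),
        "n_undefined": int(val["r"].isna().sum()),
        "group": group if group is not None else "pooled",
        "seed": int(seed),
    }
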