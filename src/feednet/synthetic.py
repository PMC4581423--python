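"""Synthetic inputs with known planted structure.

Generates the three input layers the pipeline consumes — a sparse
zero-inflated species abundance table, a log2 expression matrix with
condition-specific co-expression blocks, and a microbe-gene literature
co-mention count table — together with the planted ground truth, so every
downstream stage can be tested for parameter recovery without any
external download.

Default sizes mirror the study design the pipeline targets: two feeding
groups (BF, FF) of six infants each, ~35 microbial species with many zero
entries, a few hundred genes.  All generators are pure functions of
(parameters, seed); one root seed fans out deterministically to named
child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import AbundanceTable, ExpressionMatrix, COUNT_COLUMNS

GROUPS = ("BF", "FF")


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset."""

    differential_species: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    true_relations: set[tuple[str, str]] = field(default_factory=set)
    coexpression_blocks: dict[str, list[list[str]]] = field(default_factory=dict)
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["differential_species"] = sorted(self.differential_species)
        d["de_genes"] = sorted(self.de_genes)
        d["true_relations"] = sorted([list(p) for p in self.true_relations])
        d["coupling"] = {f"{s}::{g}": b for (s, g), b in sorted(self.coupling.items())}
        return d


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic named child stream from one root seed."""
    root = np.random.SeedSequence(seed)
    salt = int.from_bytes(stream.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=(salt,)))


def _sample_labels(n_per_group: int) -> tuple[list[str], list[str]]:
    samples = [f"{g}{i + 1}" for g in GROUPS for i in range(n_per_group)]
    groups = [g for g in GROUPS for _ in range(n_per_group)]
    return samples, groups


def simulate_abundance(
    n_species: int = 35,
    n_per_group: int = 6,
    n_differential: int = 4,
    log2_effect: float = 3.0,
    zero_prob: float = 0.3,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Zero-inflated log-normal percent abundances for two groups.

    Each species has a fixed log-scale baseline; per-cell abundance is
    log-normal around it with SD ``dispersion``.  The ``n_differential``
    planted species are shifted by ``log2_effect`` (on log2 scale) in the
    FF group.  Cells are zeroed independently with probability
    ``zero_prob`` (planted species are protected from zero-inflation so
    the planted effect is a mean shift, not a presence/absence artifact),
    then every column is renormalized to sum to 100.
    """
    if n_differential > n_species:
        raise ValueError("n_differential cannot exceed n_species")
    if not 0 <= zero_prob < 1:
        raise ValueError("zero_prob must be in [0, 1)")
    if n_per_group < 2:
        raise ValueError("need >=2 samples per group for group statistics")

    rng = _child_rng(seed, "abundance")
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    samples, groups = _sample_labels(n_per_group)
    n_samples = 2 * n_per_group

    # species baselines span several orders of magnitude, like real taxa
    base_log = rng.normal(0.0, 2.0, size=n_species)
    log_vals = base_log[:, None] + dispersion * rng.normal(0.0, 1.0, size=(n_species, n_samples))

    # plant effects on sub-dominant taxa: boosting a dominant taxon would
    # deflate every other species' share under closure and distort the
    # planted fold change itself
    lower_half = np.argsort(base_log)[: max(n_differential, n_species // 2)]
    diff_idx = rng.choice(lower_half, size=n_differential, replace=False)
    ff_cols = np.asarray([j for j, g in enumerate(groups) if g == "FF"])
    for i in diff_idx:
        log_vals[i, ff_cols] += log2_effect * np.log(2.0)

    values = np.exp(log_vals)

    if zero_prob > 0:
        keep = rng.random((n_species, n_samples)) >= zero_prob
        keep[diff_idx, :] = True
        # a column must retain at least one taxon to be a valid sample
        for j in range(n_samples):
            if not keep[:, j].any():
                keep[int(np.argmax(values[:, j])), j] = True
        values = values * keep

    values = 100.0 * values / values.sum(axis=0, keepdims=True)

    truth = SyntheticTruth(differential_species={species[i] for i in diff_idx})
    table = AbundanceTable(species_ids=species, sample_ids=samples, group=groups, values=values)
    return table, truth


def simulate_expression(
    n_genes: int = 300,
    n_per_group: int = 6,
    n_de: int = 20,
    log2_effect: float = 3.0,
    block_sizes_by_group: dict[str, list[int]] | None = None,
    within_block_r: float = 0.99,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log2 expression with planted DE genes and group-specific blocks.

    Genes inside a block share a per-sample latent factor *in that group
    only*, giving pairwise correlation ~ ``within_block_r`` there and ~0 in
    the other group.  DE genes are shifted by ``log2_effect`` in FF.

    The default block layout plants more/larger blocks in BF than FF,
    mimicking a denser co-expression network under breast feeding.
    """
    if not 0 < within_block_r < 1:
        raise ValueError("within_block_r must be in (0, 1)")
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_per_group < 2:
        raise ValueError("need >=2 samples per group")
    if block_sizes_by_group is None:
        # denser planted co-expression under BF; scales with the gene count
        big, small = max(4, n_genes // 12), max(3, n_genes // 20)
        block_sizes_by_group = {"BF": [big, small], "FF": [small]}
    for g, sizes in block_sizes_by_group.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if any(s < 2 for s in sizes):
            raise ValueError("block sizes must be >=2")
    total_block = sum(s for sizes in block_sizes_by_group.values() for s in sizes)
    if total_block > n_genes:
        raise ValueError("block sizes exceed n_genes")

    rng = _child_rng(seed, "expression")
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    samples, groups = _sample_labels(n_per_group)
    n_samples = 2 * n_per_group
    cols = {g: np.asarray([j for j, lab in enumerate(groups) if lab == g]) for g in GROUPS}

    base = rng.normal(8.0, 2.0, size=n_genes)
    values = base[:, None] + noise_sd * rng.normal(0.0, 1.0, size=(n_genes, n_samples))

    # assign block genes from the front, disjointly across groups
    blocks: dict[str, list[list[str]]] = {g: [] for g in GROUPS}
    cursor = 0
    r = within_block_r
    for g in GROUPS:
        for size in block_sizes_by_group.get(g, []):
            idx = np.arange(cursor, cursor + size)
            cursor += size
            factor = rng.normal(0.0, 1.0, size=len(cols[g]))
            eps = rng.normal(0.0, 1.0, size=(size, len(cols[g])))
            correlated = np.sqrt(r) * factor[None, :] + np.sqrt(1.0 - r) * eps
            values[np.ix_(idx, cols[g])] = base[idx][:, None] + noise_sd * correlated
            blocks[g].append([genes[i] for i in idx])

    de_idx = rng.choice(np.arange(cursor, n_genes), size=n_de, replace=False) if n_de else np.asarray([], dtype=int)
    values[np.ix_(de_idx, cols["FF"])] += log2_effect

    truth = SyntheticTruth(de_genes={genes[i] for i in de_idx}, coexpression_blocks=blocks)
    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=samples, group=groups, values=values)
    return matrix, truth


def simulate_corpus_counts(
    n_species: int = 35,
    n_genes: int = 300,
    n_true: int = 15,
    corpus_size: int = 100_000,
    base_rate: float = 0.02,
    enrichment_factor: float = 20.0,
    seed: int = 0,
    n_pairs: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Binomial-corpus microbe-gene co-mention counts with planted pairs.

    Each (species, gene) pair gets a 2x2 abstract count table drawn from a
    multinomial over ``corpus_size`` abstracts.  Marginal mention rates are
    ``base_rate``; the joint rate is independent (base_rate^2) except for
    the ``n_true`` planted pairs, where it is inflated by
    ``enrichment_factor``.  ``n_pairs`` limits how many non-planted pairs
    are sampled (default: all species x gene pairs, capped at 2000).
    """
    if corpus_size <= 0:
        raise ValueError("corpus_size must be positive")
    if n_true > 0 and enrichment_factor <= 1:
        raise ValueError("enrichment_factor must exceed 1 for planted pairs")
    if not 0 < base_rate < 0.5:
        raise ValueError("base_rate must be in (0, 0.5)")

    rng = _child_rng(seed, "corpus")
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]

    all_pairs = [(s, g) for s in species for g in genes]
    true_idx = rng.choice(len(all_pairs), size=n_true, replace=False) if n_true else np.asarray([], dtype=int)
    true_set = {all_pairs[i] for i in true_idx}

    if n_pairs is None:
        n_pairs = min(len(all_pairs), 2000)
    n_pairs = max(n_pairs, n_true)
    other_idx = [i for i in rng.permutation(len(all_pairs)) if all_pairs[i] not in true_set]
    chosen = list(true_idx) + other_idx[: n_pairs - n_true]

    rows = []
    truth = SyntheticTruth(true_relations=true_set)
    for i in chosen:
        s, g = all_pairs[i]
        p_s, p_g = base_rate, base_rate
        f = enrichment_factor if (s, g) in true_set else 1.0
        p11 = min(f * p_s * p_g, 0.9 * min(p_s, p_g))
        p10 = p_s - p11
        p01 = p_g - p11
        p00 = 1.0 - p11 - p10 - p01
        n11, n10, n01, n00 = rng.multinomial(corpus_size, [p11, p10, p01, p00])
        rows.append((s, g, int(n11), int(n10), int(n01), int(n00)))

    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df = df.sort_values(["species", "gene"], ignore_index=True)
    return df, truth


def apply_coupling(
    expression: ExpressionMatrix,
    abundance: AbundanceTable,
    relations: set[tuple[str, str]],
    beta: float = 1.0,
) -> tuple[ExpressionMatrix, dict[tuple[str, str], float]]:
    """Couple gene expression to species abundance for planted relations.

    For each (species, gene) relation the gene's expression gains
    ``beta * standardized(species percent abundance)`` across the shared
    samples, so abundance-expression correlation validation has
    recoverable positive signal.  Pairs whose species has zero variance
    are left uncoupled (and omitted from the returned coefficient map).
    """
    if expression.sample_ids != abundance.sample_ids:
        raise ValueError("expression and abundance must share aligned sample ids")
    values = expression.values.copy()
    sp_index = {s: i for i, s in enumerate(abundance.species_ids)}
    g_index = {g: i for i, g in enumerate(expression.gene_ids)}
    coupling: dict[tuple[str, str], float] = {}
    for s, g in sorted(relations):
        if s not in sp_index or g not in g_index:
            continue
        x = abundance.values[sp_index[s]]
        sd = x.std()
        if sd == 0:
            continue
        values[g_index[g]] += beta * (x - x.mean()) / sd
        coupling[(s, g)] = beta
    coupled = ExpressionMatrix(
        gene_ids=list(expression.gene_ids),
        sample_ids=list(expression.sample_ids),
        group=list(expression.group),
        values=values,
    )
    return coupled, coupling


@dataclass
class SyntheticStudy:
    """A coherent synthetic study: all three input layers plus truth."""

    abundance: AbundanceTable
    expression: ExpressionMatrix
    counts: pd.DataFrame
    truth: SyntheticTruth


def simulate_study(
    seed: int = 0,
    n_species: int = 35,
    n_genes: int = 300,
    n_per_group: int = 6,
    n_differential: int = 4,
    n_de: int = 20,
    n_true_relations: int = 15,
    beta: float = 1.0,
    **overrides,
) -> SyntheticStudy:
    """Generate abundance, expression and corpus layers over shared samples.

    Planted literature relations preferentially pair differentially
    abundant species with DE genes (so the validation stage sees the
    study's structure), with the remainder drawn uniformly.  With
    ``beta`` > 0 expression is coupled to abundance for every planted
    relation.
    """
    ab_kw = {k[len("abundance_"):]: v for k, v in overrides.items() if k.startswith("abundance_")}
    ex_kw = {k[len("expression_"):]: v for k, v in overrides.items() if k.startswith("expression_")}
    co_kw = {k[len("corpus_"):]: v for k, v in overrides.items() if k.startswith("corpus_")}

    abundance, ab_truth = simulate_abundance(
        n_species=n_species, n_per_group=n_per_group, n_differential=n_differential,
        seed=seed, **ab_kw,
    )
    expression, ex_truth = simulate_expression(
        n_genes=n_genes, n_per_group=n_per_group, n_de=n_de, seed=seed, **ex_kw,
    )

    rng = _child_rng(seed, "relations")
    diff_sp = sorted(ab_truth.differential_species)
    de_genes = sorted(ex_truth.de_genes)
    relations: set[tuple[str, str]] = set()
    if diff_sp and de_genes:
        for _ in range(min(n_true_relations, len(diff_sp) * len(de_genes))):
            for _attempt in range(100):
                pair = (diff_sp[rng.integers(len(diff_sp))], de_genes[rng.integers(len(de_genes))])
                if pair not in relations:
                    relations.add(pair)
                    break
    while len(relations) < n_true_relations:
        pair = (
            abundance.species_ids[rng.integers(n_species)],
            expression.gene_ids[rng.integers(n_genes)],
        )
        relations.add(pair)

    counts, _ = simulate_corpus_counts(
        n_species=n_species, n_genes=n_genes, n_true=0, seed=seed, **co_kw,
    )
    # overwrite/append planted pairs with enriched counts
    factor = co_kw.get("enrichment_factor", 20.0)
    corpus_size = co_kw.get("corpus_size", 100_000)
    base_rate = co_kw.get("base_rate", 0.02)
    planted_df, _ = _planted_counts(relations, corpus_size, base_rate, factor, rng)
    key = counts.set_index(["species", "gene"]).index
    counts = counts[~key.isin(planted_df.set_index(["species", "gene"]).index)]
    counts = pd.concat([counts, planted_df], ignore_index=True)
    counts = counts.sort_values(["species", "gene"], ignore_index=True)

    coupling: dict[tuple[str, str], float] = {}
    if beta:
        expression, coupling = apply_coupling(expression, abundance, relations, beta=beta)

    truth = SyntheticTruth(
        differential_species=ab_truth.differential_species,
        de_genes=ex_truth.de_genes,
        true_relations=relations,
        coexpression_blocks=ex_truth.coexpression_blocks,
        coupling=coupling,
    )
    return SyntheticStudy(abundance=abundance, expression=expression, counts=counts, truth=truth)


def _planted_counts(relations, corpus_size, base_rate, factor, rng):
    rows = []
    for s, g in sorted(relations):
        p11 = min(factor * base_rate * base_rate, 0.9 * base_rate)
        p10 = base_rate - p11
        p01 = base_rate - p11
        p00 = 1.0 - p11 - p10 - p01
        n11, n10, n01, n00 = rng.multinomial(corpus_size, [p11, p10, p01, p00])
        rows.append((s, g, int(n11), int(n10), int(n01), int(n00)))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS), None
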