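"""Per-sample alpha diversity and composition summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import AbundanceTable


def shannon_index(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats.

    Zero entries contribute nothing (0*ln 0 := 0); the result is invariant
    to rescaling of the input vector.  An all-zero vector has no defined
    composition and returns NaN.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Renormalize each sample column to percent (sum 100)."""
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[table.sample_ids[j] for j in zero]}")
    return AbundanceTable(
        species_ids=list(table.species_ids),
        sample_ids=list(table.sample_ids),
        group=list(table.group),
        values=100.0 * table.values / sums,
    )


def diversity_report(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon H (nats) with group labels.

    Returns a DataFrame (sample, group, shannon); use
    :func:`group_diversity_summary` for per-group mean and SD.
    """
    h = [shannon_index(table.values[:, j]) for j in range(len(table.sample_ids))]
    return pd.DataFrame({"sample": table.sample_ids, "group": table.group, "shannon": h})


def group_diversity_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of Shannon H per group (ddof=1)."""
    return (
        report.groupby("group", sort=True)["shannon"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
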