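"""Moderated-t differential screening for expression and abundance.

Two-group comparison with an empirical-Bayes moderated t-statistic: the
per-feature pooled variance s2_g is shrunk toward a prior (d0, s0^2)
estimated across features by moment matching on log variances (Smyth
2004), the moderated t is referred to a t distribution on d0 + df_g
degrees of freedom, and selection combines a BH-adjusted p cutoff with a
|log2 fold change| threshold.

The same machinery screens genes (log2 expression) and microbial species
(percent abundance after a log2(x + pseudocount) transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceTable, ExpressionMatrix


@dataclass
class GroupStats:
    """Per-feature two-group summary statistics."""

    feature_ids: list[str]
    mean_a: np.ndarray  # reference group (BF)
    mean_b: np.ndarray  # comparison group (FF)
    logfc: np.ndarray  # mean_b - mean_a, log2 scale
    s2: np.ndarray  # pooled sample variance
    df: int  # n_a + n_b - 2
    n_a: int
    n_b: int
    group_a: str
    group_b: str


def fit_group_stats(
    values: np.ndarray,
    groups: list[str],
    feature_ids: list[str],
    group_pair: tuple[str, str] = ("BF", "FF"),
) -> GroupStats:
    """Per-feature group means, log2 fold change and pooled variance.

    logFC is mean(second group) - mean(first group); on log2 data this is
    the log2 fold change of the second group over the first.
    """
    ga, gb = group_pair
    ia = np.asarray([j for j, g in enumerate(groups) if g == ga])
    ib = np.asarray([j for j, g in enumerate(groups) if g == gb])
    if ia.size < 2 or ib.size < 2:
        raise ValueError(f"each of groups {ga!r}, {gb!r} needs >=2 samples")
    a, b = values[:, ia], values[:, ib]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    df = ia.size + ib.size - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    return GroupStats(
        feature_ids=list(feature_ids),
        mean_a=mean_a,
        mean_b=mean_b,
        logfc=mean_b - mean_a,
        s2=ss / df,
        df=df,
        n_a=ia.size,
        n_b=ib.size,
        group_a=ga,
        group_b=gb,
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < tol:
            break
    return float(x)


def ebayes_moderate(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate the variance prior (d0, s0^2) and shrink s2 toward it.

    The observed log variances z_g = log s2_g follow (under a scaled-chisq
    model) a shifted log-F; matching the mean to digamma and the excess
    variance to trigamma functions yields method-of-moments estimates.
    Returns (d0, s0^2, moderated variances); if the excess variance is
    nonpositive the features are consistent with a single common variance,
    d0 = inf and every moderated variance equals s0^2.

    Zero variances are admitted (they carry no log-scale information and
    are handled by offsetting with a tiny floor, as in limma's practice of
    requiring positive variances; callers should flag such features).
    """
    s2 = np.asarray(s2, dtype=float)
    finite = np.isfinite(s2) & (s2 > 0)
    if finite.sum() < 2:
        raise ValueError("need >=2 finite positive variances to fit the prior")
    z = np.log(s2[finite])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        s2_tilde = np.full_like(s2, s0_sq)
    return float(d0), s0_sq, s2_tilde


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def moderated_t_test(
    values: np.ndarray,
    groups: list[str],
    feature_ids: list[str],
    group_pair: tuple[str, str] = ("BF", "FF"),
    moderation: bool = True,
) -> pd.DataFrame:
    """Full moderated-t screen: stats, shrinkage, t, p, BH-adjusted p.

    With ``moderation=False`` (the d0 = 0 limit) the statistic reduces to
    the ordinary pooled two-sample t.  Features with zero variance in both
    groups get missing t and p.
    """
    gs = fit_group_stats(values, groups, feature_ids, group_pair)
    se_factor = 1.0 / gs.n_a + 1.0 / gs.n_b
    if moderation:
        d0, s0_sq, s2_tilde = ebayes_moderate(gs.s2, gs.df)
        df_total = gs.df + d0
    else:
        d0, s0_sq = 0.0, np.nan
        s2_tilde = gs.s2.copy()
        df_total = gs.df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = gs.logfc / np.sqrt(s2_tilde * se_factor)
    undefined = s2_tilde <= 0
    t = np.where(undefined, np.nan, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), np.nan, p)

    res = pd.DataFrame(
        {
            "feature": gs.feature_ids,
            "logFC": gs.logfc,
            "s2": gs.s2,
            "s2_moderated": s2_tilde,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    res.attrs.update({"d0": d0, "s0_sq": s0_sq, "df_residual": gs.df, "df_total": df_total,
                      "contrast": f"{gs.group_b} - {gs.group_a} (log2)"})
    return res


def select_features(results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 2.0) -> pd.DataFrame:
    """Apply the selection rule p_adj <= alpha AND |logFC| >= fc_min.

    Missing p_adj never selects.  Adds a boolean ``selected`` column and
    returns the (copied) table; the selected set is
    ``set(res.loc[res.selected, 'feature'])``.
    """
    res = results.copy()
    res["selected"] = (res["p_adj"] <= alpha) & (res["logFC"].abs() >= fc_min)
    res["selected"] = res["selected"].fillna(False).astype(bool)
    return res


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    group_pair: tuple[str, str] = ("BF", "FF"),
    moderation: bool = True,
) -> pd.DataFrame:
    """Moderated-t DE screen on a log2 expression matrix."""
    res = moderated_t_test(matrix.values, matrix.group, matrix.gene_ids, group_pair, moderation)
    return select_features(res, alpha=alpha, fc_min=fc_min)


def differential_abundance(
    table: AbundanceTable,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = 0.01,
    group_pair: tuple[str, str] = ("BF", "FF"),
    moderation: bool = True,
) -> pd.DataFrame:
    """Moderated-t screen on log2(percent abundance + pseudocount).

    The log transform makes the sparse compositional abundances roughly
    Gaussian so the same linear-model screen used for expression applies.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log2(table.values + pseudocount)
    res = moderated_t_test(logged, table.group, table.species_ids, group_pair, moderation)
    return select_features(res, alpha=alpha, fc_min=fc_min)
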