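"""Phenotype computations: GSI, comparative-Ct expression, group tests.

The gonadosomatic index, GSI = gonad weight (g) x 100 / body weight (g),
is the standard maturation proxy in fish. Relative qPCR expression uses
the comparative Ct method, 2^-ddCt, normalizing the target gene to a
reference gene (*ef1a* in this pipeline's source data) and calibrating to
a designated sample's dCt.

Group comparisons follow a normality-gated scheme common in endocrine
phenotyping: two groups are compared with an unpaired t test only when
both pass the D'Agostino-Pearson omnibus normality test and both have at
least 8 observations; otherwise the two-sided Mann-Whitney test is used
(exact by enumeration when both sides have at most 7 observations, the
tie-corrected normal approximation otherwise). More than two groups are
compared with Kruskal-Wallis followed by Dunn's pairwise z tests with
Holm adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def gsi(gonad_weight: float, body_weight: float) -> float:
    """Gonadosomatic index in percent: gonad (g) x 100 / body (g)."""
    if gonad_weight <= 0 or body_weight <= 0:
        raise ValueError("weights must be positive")
    if gonad_weight >= body_weight:
        raise ValueError("gonad weight must be below total body weight")
    return gonad_weight * 100.0 / body_weight


def relative_expression(ct_target: float, ct_ref: float, calibrator_dct: float) -> float:
    """Comparative-Ct fold change: 2^-((ct_target - ct_ref) - calibrator_dct)."""
    for v in (ct_target, ct_ref, calibrator_dct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    return 2.0 ** -((ct_target - ct_ref) - calibrator_dct)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled observed values
    to the first group (the exact conditional null, valid with ties) and
    returns (U, p) where p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(sum(ranks[list(idx)])) - n1 * (n1 + 1) / 2.0
        if abs(u - mid) >= dev - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two- or multi-group comparison."""

    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    group_sizes: Dict[str, int]
    normality_p: Dict[str, float] = field(default_factory=dict)
    posthoc: tuple[PairwiseComparison, ...] = ()


def _normality_gate(samples: Dict[str, np.ndarray], alpha: float) -> tuple[bool, Dict[str, float]]:
    """True when every group has n >= 8 and passes D'Agostino-Pearson."""
    pvals: Dict[str, float] = {}
    ok = True
    for name, values in samples.items():
        if len(values) < 8:
            return False, pvals
        stat_p = float(stats.normaltest(values).pvalue)
        pvals[name] = stat_p
        if stat_p <= alpha:
            ok = False
    return ok, pvals


def dunn_posthoc(
    samples: Dict[str, np.ndarray], alpha: float = 0.05, adjust: str = "holm"
) -> List[PairwiseComparison]:
    """Dunn's pairwise rank comparisons with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p from the normal
    distribution, adjusted for multiplicity (Holm by default).
    """
    names = list(samples)
    pooled = np.concatenate([samples[k] for k in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: Dict[str, float] = {}
    start = 0
    for name in names:
        n = len(samples[name])
        mean_ranks[name] = float(np.mean(ranks[start : start + n]))
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    zs, ps, pairs = [], [], []
    for g1, g2 in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / len(samples[g1]) + 1.0 / len(samples[g2])))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
        pairs.append((g1, g2))
    adjusted = multipletests(ps, alpha=alpha, method=adjust)[1] if ps else []
    return [
        PairwiseComparison(g1, g2, z, p, padj, padj < alpha)
        for (g1, g2), z, p, padj in zip(pairs, zs, ps, adjusted)
    ]


def compare_groups(
    groups: Dict[str, Sequence[float]],
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    adjust: str = "holm",
) -> GroupComparison:
    """Normality-gated comparison of two or more labelled samples."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, values in samples.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    sizes = {k: len(v) for k, v in samples.items()}

    if len(samples) > 2:
        stat, p = stats.kruskal(*samples.values())
        posthoc = tuple(dunn_posthoc(samples, alpha=alpha, adjust=adjust))
        return GroupComparison(
            "kruskal-wallis+dunn", float(stat), float(p), p < alpha, alpha, sizes, {}, posthoc
        )

    (n1_name, x), (n2_name, y) = samples.items()
    normal, norm_p = _normality_gate(samples, normality_alpha)
    if normal:
        stat, p = stats.ttest_ind(x, y, equal_var=True)
        return GroupComparison(
            "t-test", float(stat), float(p), p < alpha, alpha, sizes, norm_p
        )
    if len(x) <= 7 and len(y) <= 7:
        u, p = mann_whitney_exact(x, y)
        return GroupComparison(
            "mann-whitney-exact", float(u), float(p), p < alpha, alpha, sizes, norm_p
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        "mann-whitney", float(res.statistic), float(res.pvalue), res.pvalue < alpha,
        alpha, sizes, norm_p,
    )


def maturity_by_genotype(records: pd.DataFrame) -> pd.DataFrame:
    """Genotype x maturity x month contingency counts with fractions.

    Expects columns ``genotype`` (or ``label``), ``maturity`` and
    ``sampling_month``. Returns one row per cell with the count and the
    within-genotype fraction; empty input yields an empty table.
    """
    if records.empty:
        return pd.DataFrame(columns=["genotype", "sampling_month", "maturity", "n", "fraction"])
    df = records.rename(columns={"label": "genotype"})
    counts = (
        df.groupby(["genotype", "sampling_month", "maturity"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
    totals = counts.groupby("genotype")["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    return counts
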