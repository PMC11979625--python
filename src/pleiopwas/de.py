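"""Differential-expression validation of candidate genes.

Per-gene tests on normalized expression: a Kolmogorov-Smirnov normality
pre-check (parametric-bootstrap reference, since the naive KS test with
estimated parameters is anti-conservative), then a Welch two-group t-test or
a one-way ANOVA across three or more groups, called at a configurable alpha.
Group means are always reported so the direction of a shift (e.g. case-group
downregulation) is checkable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DeResult, ExpressionMatrix


def _ks_statistic(x: np.ndarray) -> float:
    """Two-sided KS distance of a standardized sample from N(0, 1)."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def ks_normality(values: np.ndarray, n_boot: int = 1000, seed: int = 0) -> float:
    """Normality p-value by KS test with a parametric bootstrap reference.

    The KS statistic is computed against a normal with the sample's own mean
    and standard deviation; its null distribution (which is not the textbook
    KS distribution once parameters are estimated) is taken from ``n_boot``
    seeded normal samples of the same size, each re-standardized the same way.
    A constant input returns p = 0 (degenerate).
    """
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("ks_normality requires at least 3 values")
    if x.std(ddof=1) == 0:
        return 0.0
    d_obs = _ks_statistic(x)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_boot, len(x)))
    draws = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
    draws.sort(axis=1)
    grid = np.arange(1, len(x) + 1) / len(x)
    cdf = stats.norm.cdf(draws)
    d_boot = np.maximum((grid - cdf).max(axis=1), (cdf - (grid - 1 / len(x))).max(axis=1))
    return float((1 + np.sum(d_boot >= d_obs)) / (n_boot + 1))


def two_group_test(
    expr: ExpressionMatrix,
    gene: str,
    groups: tuple[str, str],
    alpha: float = 0.05,
    normality_seed: int = 0,
) -> DeResult:
    """Welch unequal-variance t-test of one gene between two groups."""
    if len(groups) != 2:
        raise ValueError("two_group_test requires exactly two group labels")
    a = expr.group_values(gene, groups[0])
    b = expr.group_values(gene, groups[1])
    pooled = np.concatenate([a - a.mean(), b - b.mean()])
    norm_p = ks_normality(pooled, seed=normality_seed)
    if a.mean() == b.mean():
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(p):  # zero within-group variance with a mean shift
            return DeResult(gene, "welch_t", float("inf"), np.nan,
                            {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
                            norm_p, called=False, alpha=alpha, degenerate=True)
    return DeResult(
        gene=gene,
        test="welch_t",
        statistic=float(stat),
        p=float(max(p, np.finfo(float).tiny)),
        group_means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        normality_p=norm_p,
        called=bool(p < alpha),
        alpha=alpha,
    )


def anova_test(
    expr: ExpressionMatrix,
    gene: str,
    groups: tuple[str, ...],
    alpha: float = 0.05,
    normality_seed: int = 0,
) -> DeResult:
    """One-way ANOVA of one gene across three or more groups."""
    if len(groups) < 3:
        raise ValueError(
            "anova_test requires at least three groups; use two_group_test for two"
        )
    samples = [expr.group_values(gene, g) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group must have at least 2 samples")
    pooled = np.concatenate([s - s.mean() for s in samples])
    norm_p = ks_normality(pooled, seed=normality_seed)
    if all(np.allclose(s.mean(), samples[0].mean()) for s in samples) and np.allclose(
        np.var(pooled), 0
    ):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.f_oneway(*samples)
        if not np.isfinite(p):
            p = 1.0
            stat = 0.0
    return DeResult(
        gene=gene,
        test="anova",
        statistic=float(stat),
        p=float(max(p, np.finfo(float).tiny)),
        group_means={g: float(s.mean()) for g, s in zip(groups, samples)},
        normality_p=norm_p,
        called=bool(p < alpha),
        alpha=alpha,
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a nonempty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
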