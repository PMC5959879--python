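"""Per-gene cohort statistics: correlation significance, subtype ANOVA with
homoscedasticity checks, and binomial subtype-enrichment tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_selection import bh_fdr


@dataclass
class CorrelationTest:
    """Pearson correlation with its t-based significance and a Spearman check.

    The statistic is t* = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees
    of freedom, with r computed on non-transformed values.
    """

    r: float
    t_star: float
    df: int
    p: float
    spearman_rho: float
    spearman_p: float
    undefined: bool = False


@dataclass
class SubtypeAnova:
    """One-way ANOVA across groups with its robustness companions."""

    anova_p: float
    brown_forsythe_p: float
    variance_ratio: float
    kruskal_p: float
    homoscedastic: bool


def correlation_test(x, y) -> CorrelationTest:
    """Test a Pearson correlation via t* = r sqrt(n-2) / sqrt(1-r^2).

    Two-sided p from the t distribution with n - 2 df; a Spearman rank
    correlation is reported alongside as confirmation.  Zero variance in
    either input leaves r undefined (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("correlation test needs aligned inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationTest(np.nan, np.nan, n - 2, np.nan, np.nan, np.nan, True)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t_star, p = np.inf if r > 0 else -np.inf, 0.0
    else:
        t_star = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t_star), df)
    rho, sp = stats.spearmanr(x, y)
    return CorrelationTest(r, float(t_star), df, float(p), float(rho), float(sp))


def subtype_anova(
    values: pd.Series, labels: pd.Series, variance_ratio_threshold: float = 3.0
) -> SubtypeAnova:
    """One-way ANOVA of log-transformed expression across subtype groups.

    Zeros are excluded by the log transform (log2; zero -> missing).
    Homoscedasticity is checked two ways: the Brown-Forsythe test
    (median-centered Levene, threshold 0.05) and the max/min group-variance
    ratio against ``variance_ratio_threshold`` (the textbook rule-of-thumb
    criterion; the cutoff is configurable).  A Kruskal-Wallis p is reported
    as a rank-based confirmation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    with np.errstate(divide="ignore"):
        logged = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), np.nan)
    groups = []
    for lab in pd.unique(labels):
        g = logged[(labels == lab) & np.isfinite(logged)]
        if len(g) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 usable samples")
        groups.append(g)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    anova_p = float(stats.f_oneway(*groups).pvalue)
    bf_p = float(stats.levene(*groups, center="median").pvalue)
    variances = [float(np.var(g, ddof=1)) for g in groups]
    vr = max(variances) / min(variances) if min(variances) > 0 else np.inf
    kw_p = float(stats.kruskal(*groups).pvalue)
    return SubtypeAnova(
        anova_p=anova_p,
        brown_forsythe_p=bf_p,
        variance_ratio=float(vr),
        kruskal_p=kw_p,
        homoscedastic=bool(bf_p >= 0.05 and vr <= variance_ratio_threshold),
    )


def binomial_enrichment(
    above: dict[str, int] | pd.Series,
    totals: dict[str, int] | pd.Series,
    expected: float = 0.5,
) -> pd.DataFrame:
    """Two-tailed exact binomial test per group, with BH FDR across groups.

    ``above[g]`` successes out of ``totals[g]`` trials are tested against
    the expected success probability (default 0.5, e.g. samples above the
    cohort median).  Two-tailed by the minimum-likelihood convention (the
    scipy default).  Groups with zero total are skipped with a warning.
    """
    above = pd.Series(dict(above) if not isinstance(above, pd.Series) else above)
    totals = pd.Series(dict(totals) if not isinstance(totals, pd.Series) else totals)
    if not 0 < expected < 1:
        raise ValueError("expected frequency must be in (0, 1)")
    rows = []
    for g in totals.index:
        n = int(totals[g])
        if n == 0:
            warnings.warn(f"group {g!r} has zero total; skipped")
            continue
        k = int(above[g])
        if k > n:
            raise ValueError(f"group {g!r}: above > total")
        p = stats.binomtest(k, n, expected, alternative="two-sided").pvalue
        rows.append({"group": g, "above": k, "total": n, "p": float(p)})
    out = pd.DataFrame(rows).set_index("group")
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out
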