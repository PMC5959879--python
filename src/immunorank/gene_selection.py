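"""Multi-criterion differential gene selection, trimming, and FDR machinery.

The hybrid cascade keeps a gene only when it is simultaneously
differentially expressed between two sample groups, heterogeneously
expressed across samples, and of adequate signal quality:

a. the relative variation of the two group medians,
   (max - min) / (min + eps) with machine double eps, lies strictly in the
   top 50% of all genes;
b. the two-sided Wilcoxon rank-sum p between the groups is calculable
   (not the all-identical degenerate case) and < 0.01, and the gene is
   "present" (value >= 0.5) in more than 60% of all samples;
c. the Storey q-value over the criterion-(b) p-values is < 0.01;
d. the gene's overall median is strictly greater than the first octile
   (12.5th-percentile order statistic) of all gene medians;
e. the gene's standard deviation lies strictly in the top 50% of all genes
   (the gene-ontology variant e' tightens this to the top 1/3).

"Strictly in the top fraction f" means strictly greater than the largest
value excluded from the top floor(f*m) order statistics, so boundary ties
fail.  All rank thresholds are computed on the full input gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

EPS = np.finfo(float).eps
PRESENCE_THRESHOLD = 0.5


@dataclass
class SelectionParams:
    """Thresholds of the selection cascade, at their standard defaults."""

    wilcoxon_alpha: float = 0.01
    storey_alpha: float = 0.01
    presence_fraction: float = 0.60
    median_variation_top: float = 0.5
    sd_top: float = 0.5
    octile: float = 0.125


@dataclass
class GeneFilterReport:
    """Per-gene statistics and pass flags of the selection cascade."""

    table: pd.DataFrame
    # columns: relative_median_variation, wilcoxon_p, presence_count,
    #          storey_q, median_value, sd_value, pass_a..pass_e, selected
    params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


# ---------------------------------------------------------------------------
# rank-threshold helpers
# ---------------------------------------------------------------------------

def strict_top_mask(values: np.ndarray, fraction: float) -> np.ndarray:
    """True where a value is strictly inside the top ``fraction`` of all values.

    The top set has floor(fraction * m) members; a value passes iff it is
    strictly greater than the largest excluded order statistic, so ties at
    the boundary fail.
    """
    m = len(values)
    k = int(np.floor(fraction * m))
    if k <= 0:
        return np.zeros(m, dtype=bool)
    if k >= m:
        return np.ones(m, dtype=bool)
    boundary = np.sort(values)[m - k - 1]
    return values > boundary


def strict_bottom_mask(values: np.ndarray, fraction: float) -> np.ndarray:
    """True where a value is strictly inside the lowest ``fraction``."""
    m = len(values)
    k = int(np.floor(fraction * m))
    if k <= 0:
        return np.zeros(m, dtype=bool)
    if k >= m:
        return np.ones(m, dtype=bool)
    boundary = np.sort(values)[k]
    return values < boundary


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (lower) order statistic: sorted[ceil(q*m)] with 1-based ceil."""
    m = len(values)
    if m < int(round(1 / q)):
        raise ValueError(f"need at least {int(round(1 / q))} values for quantile {q}")
    k = max(int(np.ceil(q * m)), 1)
    return float(np.sort(values)[k - 1])


# ---------------------------------------------------------------------------
# FDR machinery
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(pvals, lambdas=None) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated over a grid
    (default 0.05..0.95 step 0.05), smoothed with a 3-df least-squares fit,
    and read off at the largest lambda; the estimate is clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size
    pi0_l = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambdas])
    if len(lambdas) < 4:
        pi0 = pi0_l[-1]
    else:
        # smoother with 3 degrees of freedom (quadratic least squares),
        # evaluated at the largest lambda
        coeffs = np.polyfit(lambdas, pi0_l, 2)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_q(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0-scaled BH-style step-up, monotone in p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p) if m >= 20 else 1.0
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(pi0 * p[i] * m / rank, prev)
        q[i] = val
        prev = val
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Wilcoxon helper
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, NaN for the degenerate all-identical case.

    Exact distribution for groups of at most 20 without ties, normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return np.nan
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def hybrid_select(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    params: SelectionParams | None = None,
) -> GeneFilterReport:
    """Run the five-criterion cascade (a-e) between two sample groups."""
    params = params or SelectionParams()
    g1, g2 = set(group1), set(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if g1 & g2:
        raise ValueError("groups must be disjoint")
    if matrix.n_genes < 8:
        raise ValueError("cascade needs at least 8 genes (first octile undefined)")

    X = matrix.values
    all_cols = list(X.columns)
    X1 = X.loc[:, [c for c in all_cols if c in g1]].to_numpy(dtype=float)
    X2 = X.loc[:, [c for c in all_cols if c in g2]].to_numpy(dtype=float)
    Xall = X.to_numpy(dtype=float)
    n_total = Xall.shape[1]

    med1 = np.nanmedian(X1, axis=1)
    med2 = np.nanmedian(X2, axis=1)
    mx, mn = np.maximum(med1, med2), np.minimum(med1, med2)
    rel_var = (mx - mn) / (mn + EPS)

    overall_median = np.nanmedian(Xall, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(Xall, axis=1, ddof=1)
    presence = np.nansum(Xall >= PRESENCE_THRESHOLD, axis=1).astype(int)

    pass_a = strict_top_mask(rel_var, params.median_variation_top)

    wilcoxon_p = np.array(
        [wilcoxon_rank_sum_p(X1[i][~np.isnan(X1[i])], X2[i][~np.isnan(X2[i])])
         for i in range(matrix.n_genes)]
    )
    relevant = presence > params.presence_fraction * n_total
    calculable = ~np.isnan(wilcoxon_p)
    pass_b = calculable & relevant & (wilcoxon_p < params.wilcoxon_alpha)

    # Storey q over the calculable & relevant p-values only
    storey = np.full(matrix.n_genes, np.nan)
    pool = calculable & relevant
    if pool.any():
        storey[pool] = storey_q(wilcoxon_p[pool])
    pass_c = pass_b & np.where(np.isnan(storey), False, storey < params.storey_alpha)

    octile_value = nearest_rank_quantile(overall_median, params.octile)
    pass_d = overall_median > octile_value

    pass_e = strict_top_mask(sd, params.sd_top)

    selected = pass_a & pass_b & pass_c & pass_d & pass_e
    table = pd.DataFrame(
        {
            "relative_median_variation": rel_var,
            "wilcoxon_p": wilcoxon_p,
            "presence_count": presence,
            "storey_q": storey,
            "median_value": overall_median,
            "sd_value": sd,
            "pass_a": pass_a,
            "pass_b": pass_b,
            "pass_c": pass_c,
            "pass_d": pass_d,
            "pass_e": pass_e,
            "selected": selected,
        },
        index=pd.Index(matrix.gene_keys(), name="gene"),
    )
    return GeneFilterReport(table=table, params=params)


def go_variant_select(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    params: SelectionParams | None = None,
) -> GeneFilterReport:
    """The gene-ontology variant of the cascade: criterion e' = SD strictly
    in the top 1/3 of the original gene universe."""
    params = params or SelectionParams()
    variant = SelectionParams(**{**params.__dict__, "sd_top": 1.0 / 3.0})
    return hybrid_select(matrix, group1, group2, variant)


def trim_for_gene_set_export(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop sparse/flat genes before gene-set export.

    A gene is removed when its mean, its standard deviation, or its count
    of present values (>= 0.5) is strictly in the lowest 1/8 of the input,
    each rank computed on the full input gene list.
    """
    X = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
        sd = np.nanstd(X, axis=1, ddof=1)
    presence = np.nansum(X >= PRESENCE_THRESHOLD, axis=1).astype(float)
    drop = (
        strict_bottom_mask(mean, 0.125)
        | strict_bottom_mask(sd, 0.125)
        | strict_bottom_mask(presence, 0.125)
    )
    keep = [i for i in range(matrix.n_genes) if not drop[i]]
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------------------
# enrichment-term filtering
# ---------------------------------------------------------------------------

def filter_enrichment_terms(
    terms: pd.DataFrame,
    min_members: int = 2,
    p_threshold: float = 1e-3,
    ontology: str = "BP",
) -> pd.DataFrame:
    """Filter an external enrichment tool's term table.

    Keeps terms of the requested ontology with at least ``min_members``
    member genes and p below ``p_threshold``.  ``terms`` needs columns
    ontology, term, p, members (an iterable or comma-separated string).
    Unknown ontology tags are skipped with a warning.
    """
    known = {"BP", "MF", "CC"}
    unknown = set(terms["ontology"]) - known
    if unknown:
        warnings.warn(f"skipping terms with unknown ontology tags {sorted(unknown)}")

    def _count(members) -> int:
        if isinstance(members, str):
            return len([m for m in members.replace(",", " ").split() if m])
        return len(list(members))

    mask = (
        (terms["ontology"] == ontology)
        & (terms["members"].map(_count) >= min_members)
        & (terms["p"] < p_threshold)
    )
    return terms.loc[mask].copy()
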