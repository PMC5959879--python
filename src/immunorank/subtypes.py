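"""Nearest-centroid subtype assignment and subtype aggregation.

Tumors are labeled with one of the four squamous expression subtypes
(Classical, Basal, Primitive, Secretory) by Pearson correlation against
published predictor centroids, after per-gene log2 transform (zeros become
missing) and median centering.  The correlation-based aggregation then
pairs the four subtypes into two groups — empirically Classical+Basal (CB)
and Primitive+Secretory (PS) — and fixes the heat-map display order.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .core_io import SUBTYPES, ExpressionMatrix, SubtypeCentroids
from .cluster_structure import log_center


@dataclass
class SubtypeAssignment:
    """Per-sample correlations against the four centroids plus the argmax label."""

    correlations: pd.DataFrame  # index: sample; columns: the four subtypes
    labels: pd.Series  # index: sample; values: subtype or NaN (unassignable)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class AggregateDefinition:
    """The CB/PS-style pairing of the four subtypes.

    ``mean_vectors`` holds the per-gene subtype means V_C, V_B, V_P, V_S;
    ``pair_correlations`` the six pairwise Pearson coefficients; the two
    aggregates partition the subtypes; ``display_order`` puts the two
    largest subtypes at the heat-map flanks.
    """

    mean_vectors: pd.DataFrame  # index: gene key; columns: subtypes
    pair_correlations: dict[tuple[str, str], float]
    aggregates: tuple[tuple[str, str], tuple[str, str]]
    display_order: tuple[str, str, str, str]
    # greedy pairing (global max pair + forced remainder) can differ from the
    # max-weight perfect matching over the three pairings; flagged when it does
    matching_agrees: bool = True


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pairwise-complete (both finite) positions."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def assign_subtypes(
    matrix: ExpressionMatrix, centroids: SubtypeCentroids
) -> SubtypeAssignment:
    """Assign each sample the subtype of its most correlated centroid.

    The matrix is reduced to genes shared with the centroid table (matched
    by symbol, falling back to Entrez), log2 transformed (zeros -> missing)
    and median centered per gene; per-sample Pearson correlations against
    each centroid run over the non-missing genes.  Ties break by the fixed
    subtype order; samples with fewer than 2 usable genes are unassignable
    (NaN label).
    """
    by_symbol = {}
    by_entrez = {}
    for i, g in enumerate(matrix.genes):
        if g.symbol is not None:
            by_symbol.setdefault(g.symbol, i)
        if g.entrez is not None:
            by_entrez.setdefault(g.entrez, i)
    rows, crows = [], []
    for j, g in enumerate(centroids.genes):
        i = by_symbol.get(g.symbol) if g.symbol is not None else None
        if i is None and g.entrez is not None:
            i = by_entrez.get(g.entrez)
        if i is not None:
            rows.append(i)
            crows.append(j)
    if len(rows) < 2:
        raise ValueError("fewer than 2 genes shared with the centroids")

    sub = matrix.subset_genes(rows)
    cm = log_center(sub, mode="median")
    X = cm.values.to_numpy()  # genes x samples, NaN = missing
    C = centroids.table.iloc[crows][list(SUBTYPES)].to_numpy()

    corr = np.full((matrix.n_samples, 4), np.nan)
    for s in range(matrix.n_samples):
        x = X[:, s]
        if np.isfinite(x).sum() < 2:
            continue
        for k in range(4):
            corr[s, k] = _pairwise_pearson(x, C[:, k])
    cdf = pd.DataFrame(corr, index=matrix.samples, columns=list(SUBTYPES))
    labels = pd.Series(index=cdf.index, dtype=object)
    for s, row in cdf.iterrows():
        if row.isna().all():
            labels[s] = np.nan
        else:
            labels[s] = row.idxmax()  # first (fixed subtype order) on ties
    return SubtypeAssignment(correlations=cdf, labels=labels)


def aggregate_subtypes(
    matrix: ExpressionMatrix, labels: pd.Series
) -> AggregateDefinition:
    """Pair the four subtypes by their two highest mutually exclusive correlations.

    Per-subtype mean vectors are computed over all genes; the six pairwise
    Pearson coefficients are ranked; the globally best pair is taken and the
    remaining two subtypes form the second aggregate (greedy, which the
    forced second choice makes equivalent to the stated stepwise rule).
    Display order puts the two most populous subtypes at the flanks, with
    each aggregate kept contiguous.
    """
    labels = labels.loc[matrix.samples]
    counts = labels.value_counts()
    for st in SUBTYPES:
        if counts.get(st, 0) == 0:
            raise ValueError(f"subtype {st} has no samples")

    means = {}
    for st in SUBTYPES:
        cols = labels.index[labels == st]
        means[st] = matrix.values.loc[:, cols].mean(axis=1, skipna=True)
    mv = pd.DataFrame(means)
    mv.index = pd.Index(matrix.gene_keys(), name="gene")

    pair_corr = {
        (a, b): _pairwise_pearson(mv[a].to_numpy(), mv[b].to_numpy())
        for a, b in combinations(SUBTYPES, 2)
    }

    def _canon(pair):
        a, b = pair
        return (a, b) if (a, b) in pair_corr else (b, a)

    best = max(pair_corr, key=lambda p: pair_corr[p])
    rest = tuple(s for s in SUBTYPES if s not in best)
    aggregates = (best, rest)

    def _complement(pair):
        return tuple(s for s in SUBTYPES if s not in pair)

    pairings = [(p, _complement(p)) for p in pair_corr if SUBTYPES[0] in p]
    matching = max(
        pairings, key=lambda pr: pair_corr[_canon(pr[0])] + pair_corr[_canon(pr[1])]
    )
    matching_agrees = {frozenset(best), frozenset(rest)} == {
        frozenset(matching[0]),
        frozenset(matching[1]),
    }
    if not matching_agrees:
        warnings.warn(
            "greedy subtype pairing differs from the max-weight matching; "
            "reporting the greedy (stepwise) pairing"
        )

    # order aggregates and their members so the two largest-n subtypes flank
    def _agg_sorted(agg: tuple[str, str]) -> list[str]:
        return sorted(agg, key=lambda s: -counts[s])

    a1, a2 = (_agg_sorted(a) for a in aggregates)
    # bigger flank subtype first overall
    if counts[a2[0]] > counts[a1[0]]:
        a1, a2 = a2, a1
    display = (a1[0], a1[1], a2[1], a2[0])
    return AggregateDefinition(
        mean_vectors=mv,
        pair_correlations=pair_corr,
        aggregates=aggregates,
        display_order=display,
        matching_agrees=matching_agrees,
    )


def aggregate_classes(labels: pd.Series, aggregates) -> pd.Series:
    """Map subtype labels to binary classes: 0 for the first aggregate, 1 for the second."""
    first = set(aggregates[0])
    return labels.map(lambda s: 0 if s in first else 1)
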