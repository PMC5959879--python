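"""Matrix transforms and structure: log/center, hierarchical ordering,
subtype dissimilarity, and the two heat-map splitting rules.

The transform convention follows the legacy clustering tools the field
uses: values are log2 transformed with zeros mapped to missing (NaN), then
centered per gene by mean or median; similarity for clustering is the
uncentered correlation (cosine about zero) with average linkage, computed
over pairwise-complete positions when data are missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .core_io import SUBTYPES, ExpressionMatrix


@dataclass
class ClusteredMatrix:
    """Log2-transformed, per-gene centered matrix with ordering metadata."""

    values: pd.DataFrame  # genes x samples, NaN = missing
    gene_keys: list[str]
    centering: str  # "mean" or "median"
    row_order: list[int] | None = None
    col_order: list[int] | None = None
    all_missing_rows: list[int] | None = None

    def ordered_values(self) -> pd.DataFrame:
        v = self.values
        if self.row_order is not None:
            v = v.iloc[self.row_order]
        if self.col_order is not None:
            v = v.iloc[:, self.col_order]
        return v


@dataclass
class DissimilarityResult:
    """City-block distances between per-gene subtype mean vectors."""

    subtype_means: pd.DataFrame  # genes x subtypes
    distances: pd.DataFrame  # 4 x 4 symmetric, zero diagonal
    maximal_pair: tuple[str, str]


@dataclass
class SplitResult:
    """Outcome of the ordered heat-map split.

    ``split_index`` is the 0-based index (in row order) of the last gene of
    the upper portion; ``delta`` is the scanned Delta(CB, PS) sequence.
    """

    split_index: int | None
    delta: pd.Series
    upper: list[int]
    lower: list[int]
    no_split: bool = False


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def log_center(matrix: ExpressionMatrix, mode: str = "mean") -> ClusteredMatrix:
    """Log2 transform (zeros -> missing) then center each gene row.

    Centering uses the chosen statistic over the non-missing entries of the
    row.  A gene that is zero everywhere yields an all-missing row, which
    is retained and flagged.
    """
    if mode not in ("mean", "median"):
        raise ValueError(f"unknown centering mode {mode!r}")
    vals = matrix.values.to_numpy(dtype=float).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = (
            np.nanmean(vals, axis=1) if mode == "mean" else np.nanmedian(vals, axis=1)
        )
    all_missing = [i for i in range(vals.shape[0]) if np.isnan(vals[i]).all()]
    centered = vals - np.where(np.isnan(center), 0.0, center)[:, None]
    df = pd.DataFrame(centered, columns=matrix.samples)
    return ClusteredMatrix(
        values=df,
        gene_keys=matrix.gene_keys(),
        centering=mode,
        all_missing_rows=all_missing,
    )


# ---------------------------------------------------------------------------
# hierarchical ordering
# ---------------------------------------------------------------------------

def uncentered_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise uncentered correlation (cosine about zero) of the rows of X.

    Missing entries are handled pairwise-complete: each pair of rows uses
    only the positions where both are finite.  Rows with no overlap or zero
    norm get similarity NaN.
    """
    n = X.shape[0]
    finite = np.isfinite(X)
    if finite.all():
        norms = np.sqrt((X * X).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (X @ X.T) / np.outer(norms, norms)
        sim[~np.isfinite(sim)] = np.nan
        return sim
    sim = np.full((n, n), np.nan)
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            ok = finite[i] & finite[j]
            if not ok.any():
                continue
            xi, xj = X[i, ok], X[j, ok]
            denom = np.sqrt((xi * xi).sum() * (xj * xj).sum())
            if denom == 0:
                continue
            sim[i, j] = sim[j, i] = float((xi * xj).sum() / denom)
    return sim


def _leaf_order_from_similarity(sim: np.ndarray) -> list[int]:
    n = sim.shape[0]
    isolated = [i for i in range(n) if np.isnan(np.delete(sim[i], i)).all()]
    if isolated:
        warnings.warn(f"{len(isolated)} item(s) had no overlap with any other; placed last")
    keep = [i for i in range(n) if i not in isolated]
    if len(keep) < 2:
        return keep + isolated
    d = 1.0 - sim[np.ix_(keep, keep)]
    np.fill_diagonal(d, 0.0)
    # a pair with no overlap among otherwise-connected items: maximally distant
    d[np.isnan(d)] = 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    order = [keep[i] for i in leaves_list(Z)]
    return order + isolated


def hierarchical_order(cm: ClusteredMatrix, axes: str = "both") -> ClusteredMatrix:
    """Order rows and/or columns by average-linkage, uncentered-correlation
    clustering; returns a copy carrying the leaf orders."""
    if axes not in ("rows", "cols", "both"):
        raise ValueError(f"unknown axes {axes!r}")
    X = cm.values.to_numpy(dtype=float)
    row_order, col_order = cm.row_order, cm.col_order
    if axes in ("rows", "both"):
        if X.shape[0] < 2:
            raise ValueError("need >= 2 rows to cluster")
        row_order = _leaf_order_from_similarity(uncentered_correlation_matrix(X))
    if axes in ("cols", "both"):
        if X.shape[1] < 2:
            raise ValueError("need >= 2 columns to cluster")
        col_order = _leaf_order_from_similarity(uncentered_correlation_matrix(X.T))
    return ClusteredMatrix(
        values=cm.values,
        gene_keys=cm.gene_keys,
        centering=cm.centering,
        row_order=row_order,
        col_order=col_order,
        all_missing_rows=cm.all_missing_rows,
    )


# ---------------------------------------------------------------------------
# genomic dissimilarity
# ---------------------------------------------------------------------------

def genomic_dissimilarity(
    matrix: ExpressionMatrix, labels: pd.Series
) -> DissimilarityResult:
    """City-block (L1) distances among the four subtypes' per-gene means.

    d(A, B) = sum_i |mean_i(A) - mean_i(B)|.  Returns all six distances and
    the maximal pair.
    """
    labels = labels.loc[matrix.samples]
    means = {}
    for st in SUBTYPES:
        cols = labels.index[labels == st]
        if len(cols) == 0:
            raise ValueError(f"subtype {st} missing")
        means[st] = matrix.values.loc[:, cols].mean(axis=1, skipna=True)
    mv = pd.DataFrame(means)
    dist = pd.DataFrame(0.0, index=list(SUBTYPES), columns=list(SUBTYPES))
    for a, b in combinations(SUBTYPES, 2):
        d = float((mv[a] - mv[b]).abs().sum(skipna=True))
        dist.loc[a, b] = dist.loc[b, a] = d
    maximal = max(combinations(SUBTYPES, 2), key=lambda p: dist.loc[p[0], p[1]])
    return DissimilarityResult(subtype_means=mv, distances=dist, maximal_pair=maximal)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def hyperexpression_fractions(
    cm: ClusteredMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Per gene and subtype: fraction of samples at or above the gene mean.

    "Hyper-expression" is inclusive (value >= the gene's mean over all
    samples, missing excluded).  Rows follow the clustered row order when
    present.
    """
    vals = cm.values
    if cm.row_order is not None:
        vals = vals.iloc[cm.row_order]
    labels = labels.loc[vals.columns]
    X = vals.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gene_mean = np.nanmean(X, axis=1)
    above = X >= gene_mean[:, None]  # NaN compares False
    out = {}
    for st in SUBTYPES:
        mask = (labels == st).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"subtype {st} missing")
        out[st] = above[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=vals.index)


def delta_cb_ps(fractions: pd.DataFrame) -> pd.Series:
    """Delta(CB, PS) = mean(%Classical, %Basal) - mean(%Primitive, %Secretory)."""
    cb = fractions[["Classical", "Basal"]].mean(axis=1)
    ps = fractions[["Primitive", "Secretory"]].mean(axis=1)
    return cb - ps


def heatmap_split(
    cm: ClusteredMatrix,
    labels: pd.Series,
    window: tuple[int, int] = (1899, 2399),
    tolerance: int = 3,
) -> SplitResult:
    """Locate the upper/lower boundary of a clustered matrix by the
    Delta(CB, PS) sign change.

    Scans rows (clustered order) inside ``window`` (0-based, inclusive) for
    the maximal prefix where Delta < 0, tolerating interior runs of at most
    ``tolerance`` consecutive violations (Delta >= 0); a longer violation
    run ends the prefix at its start.  The split index is the row after the
    prefix's last Delta < 0 gene, i.e. the first row of the Delta > 0
    regime; the upper portion is rows 0..split_index inclusive.
    """
    n = cm.values.shape[0]
    lo, hi = window
    if not (0 <= lo <= hi < n):
        raise ValueError(f"window {window} out of bounds for {n} rows")
    fr = hyperexpression_fractions(cm, labels)
    delta_all = delta_cb_ps(fr)
    delta = delta_all.iloc[lo : hi + 1]
    d = delta.to_numpy()

    if (d < 0).all() or (d >= 0).all():
        return SplitResult(None, delta, [], list(range(n)), no_split=True)

    last_neg = None
    run = 0
    for i, v in enumerate(d):
        if v < 0:
            last_neg = i
            run = 0
        else:
            run += 1
            if run > tolerance:
                break
    if last_neg is None:
        return SplitResult(None, delta, [], list(range(n)), no_split=True)
    split = lo + last_neg + 1  # first row of the positive regime
    upper = list(range(split + 1))
    lower = list(range(split + 1, n))
    return SplitResult(split, delta, upper, lower)


def splitting_point(seq) -> int | None:
    """First sustained sign change in a sequence of reals.

    Starting from the sign regime of the first element, the first flip to
    the opposite sign that persists for at least five following couples of
    consecutive values (i.e. the next six elements keep the new sign) is
    the splitting point; the returned index is that of the last element of
    the old regime (the top portion is 0..index).  A flip that reverts
    within five couples is ignored and the original regime resumes.
    Returns None when no sustained flip exists.  Zeros match neither sign.
    """
    s = np.sign(np.asarray(list(seq), dtype=float))
    n = len(s)
    if n < 7:
        raise ValueError("splitting point needs length >= 7")
    regime = s[0]
    if regime == 0:
        return None
    i = 1
    while i < n:
        if s[i] == regime:
            i += 1
            continue
        new = s[i]
        if new != 0 and i + 5 < n and (s[i : i + 6] == new).all():
            return i - 1
        # reversion: skip to where the original regime resumes
        while i < n and s[i] != regime:
            i += 1
    return None


def gradient_fractions(
    cm: ClusteredMatrix, labels: pd.Series, split_index: int
) -> pd.DataFrame:
    """Mean hyper-expression fraction per half and subtype.

    Rows up to ``split_index`` (inclusive, clustered order) form the upper
    half.  For each half and each subtype (Classical, Basal, Primitive,
    Secretory order) the fractions from
    :func:`hyperexpression_fractions` are averaged over genes; the output
    carries monotonicity flags (upper increasing left-to-right, lower
    decreasing).
    """
    fr = hyperexpression_fractions(cm, labels)
    n = fr.shape[0]
    if not 0 <= split_index < n - 1:
        raise ValueError("split leaves an empty half")
    upper = fr.iloc[: split_index + 1].mean(axis=0)
    lower = fr.iloc[split_index + 1 :].mean(axis=0)
    out = pd.DataFrame({"upper": upper, "lower": lower}).T[list(SUBTYPES)]
    out["monotone"] = [
        bool(np.all(np.diff(out.loc["upper", list(SUBTYPES)].to_numpy()) > 0)),
        bool(np.all(np.diff(out.loc["lower", list(SUBTYPES)].to_numpy()) < 0)),
    ]
    return out
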