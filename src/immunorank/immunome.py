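"""Rank-based immune cell-type density scoring.

The scoring system estimates the relative density of an immune cell type
in each tumor sample from bulk expression, without deconvolution:

1. each marker gene's expression values are ranked across the n samples
   from lowest to highest on a 1..n scale;
2. ties receive the average of their ranks (Wilcoxon convention);
3. for every sample, the ranks are averaged across the cell type's marker
   genes (genes annotated to two cell types contribute to both);
4. the resulting average rank is the sample's density score for that cell
   type.

Because only ranks enter, the score is invariant under any strictly
increasing per-gene transform of expression, and for every cell type the
mean score over samples is exactly (n + 1) / 2 (tie-averaged ranks
conserve rank sums).  A sample can be enriched for any number of cell
types simultaneously — the scores are relative across samples, not parts
of a composition.

The CD14 score summarizes, for the nine CD14+ myeloid populations, how
strongly a cell type's density tracks CD14 expression: it is the 1..9 rank
of the ratio of the type's mean density score in CD14-high (>= median)
versus CD14-low samples, 9 for the highest ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .cluster_structure import (
    ClusteredMatrix,
    _leaf_order_from_similarity,
    uncentered_correlation_matrix,
)
from .core_io import ClinicalTable, ExpressionMatrix, GeneId, ImmuneSignature
from .survival import SurvivalEffect, median_split_effect

CD14_CELL_TYPES = (
    "aDC",
    "DC",
    "iDC",
    "IM",
    "M1",
    "M2",
    "Macrophages",
    "MDSC",
    "Neutrophils",
)


@dataclass
class DensityScores:
    """Sample x cell-type grid of average-rank density scores on 1..n."""

    scores: pd.DataFrame  # index: sample; columns: cell types
    n: int

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if arr.size and (np.nanmin(arr) < 1 or np.nanmax(arr) > self.n):
            raise ValueError("density scores must lie in [1, n]")


@dataclass
class CD14ScoreTable:
    """Per CD14+ cell type: high/low-CD14 density ratio, its 1..9 rank, and
    the median-split survival effect of the type's density."""

    table: pd.DataFrame  # index: cell type; columns: ratio, cd14_score,
    #                      hr, ci_low, ci_high, logrank_p, n_high, n_low


# ---------------------------------------------------------------------------
# signature assembly
# ---------------------------------------------------------------------------

def assemble_signature(
    base: ImmuneSignature,
    additions: list[tuple[str, str, list[str]]],
    universe: list[GeneId],
) -> ImmuneSignature:
    """Merge marker additions into a base signature and match to a universe.

    ``additions`` is a list of (cell_type, immunity_tag, gene keys); cell
    types not already declared are appended.  Genes are then matched to the
    expression universe by Entrez id, falling back to symbol for genes
    without one; unmatched genes are discarded.  An addition that would put
    a gene under a third cell type is an error naming the gene.
    """
    cell_types = list(base.cell_types)
    merged: dict[str, tuple[str, list[str]]] = {
        k: (imm, list(t)) for k, (imm, t) in base.entries.items()
    }
    for ct, imm, genes in additions:
        if ct not in cell_types:
            cell_types.append(ct)
        for token in genes:
            key = GeneId.from_key(token).key
            entry = merged.setdefault(key, (imm, []))
            if ct not in entry[1]:
                entry[1].append(ct)
            if len(entry[1]) > 2:
                raise ValueError(
                    f"gene {key!r} would belong to {len(entry[1])} cell types: {entry[1]}"
                )

    uni_entrez = {g.entrez for g in universe if g.entrez is not None}
    uni_symbol = {g.symbol for g in universe if g.symbol is not None}

    def _matched(key: str) -> bool:
        gid = GeneId.from_key(key)
        if gid.entrez is not None:
            return gid.entrez in uni_entrez
        return gid.symbol in uni_symbol

    entries = {
        k: (imm, tuple(t)) for k, (imm, t) in merged.items() if _matched(k)
    }
    used_types = {t for _i, ts in entries.values() for t in ts}
    return ImmuneSignature(
        entries=entries, cell_types=[c for c in cell_types if c in used_types]
    )


# ---------------------------------------------------------------------------
# density scoring
# ---------------------------------------------------------------------------

def _match_rows(matrix: ExpressionMatrix, key: str) -> int | None:
    """Row index of a signature gene in the matrix (Entrez first, then symbol)."""
    gid = GeneId.from_key(key)
    for i, g in enumerate(matrix.genes):
        if gid.entrez is not None and g.entrez == gid.entrez:
            return i
        if gid.entrez is None and gid.symbol is not None and g.symbol == gid.symbol:
            return i
    return None


def density_scores(
    matrix: ExpressionMatrix, signature: ImmuneSignature
) -> DensityScores:
    """Compute per-sample average-rank density scores for every cell type.

    Ranks are ascending 1..n with average ties, per marker gene; a cell
    type whose markers are all absent from the matrix yields no column
    (warned).  The result does not depend on sample order.
    """
    n = matrix.n_samples
    X = matrix.values.to_numpy(dtype=float)
    rank_cache: dict[int, np.ndarray] = {}

    def _ranks(row: int) -> np.ndarray:
        if row not in rank_cache:
            rank_cache[row] = rankdata(X[row], method="average")
        return rank_cache[row]

    cols = {}
    for ct in signature.cell_types:
        rows = []
        for key in signature.genes_of(ct):
            r = _match_rows(matrix, key)
            if r is not None:
                rows.append(r)
        if not rows:
            warnings.warn(f"cell type {ct!r} has no markers in the matrix; skipped")
            continue
        cols[ct] = np.mean([_ranks(r) for r in rows], axis=0)
    scores = pd.DataFrame(cols, index=matrix.samples)
    return DensityScores(scores=scores, n=n)


# ---------------------------------------------------------------------------
# CD14 scores
# ---------------------------------------------------------------------------

def cd14_scores(
    density: DensityScores,
    cd14: pd.Series,
    clinical: ClinicalTable,
    cd14_types: tuple[str, ...] = CD14_CELL_TYPES,
) -> CD14ScoreTable:
    """Score the nine CD14+ cell types against CD14 expression and survival.

    Samples split at the CD14 median (>= inclusive in high).  Per type, the
    ratio mean(score | high) / mean(score | low) is ranked 1..9 (9 =
    highest ratio; ties keep the declared type order), and the type's
    density is screened for survival by the median split (HR, Wald CI,
    log-rank p).
    """
    if len(cd14_types) != 9:
        raise ValueError("exactly 9 CD14+ cell types expected")
    missing = [t for t in cd14_types if t not in density.scores.columns]
    if missing:
        raise ValueError(f"cell types not scored: {missing}")
    cd14 = cd14.loc[density.scores.index].astype(float)
    med = float(cd14.median())
    high = cd14 >= med
    if high.all() or not high.any():
        raise ValueError("CD14 median split left one group empty")

    ratios = {}
    for ct in cd14_types:
        s = density.scores[ct]
        ratios[ct] = float(s[high].mean() / s[~high].mean())
    rvals = np.array([ratios[ct] for ct in cd14_types])
    # ascending rank 1..9; stable sort keeps declared order on ties
    order = np.argsort(rvals, kind="mergesort")
    rank = np.empty(9, dtype=int)
    rank[order] = np.arange(1, 10)

    rows = []
    for i, ct in enumerate(cd14_types):
        eff: SurvivalEffect = median_split_effect(
            density.scores[ct].loc[clinical.samples], clinical
        )
        rows.append(
            {
                "cell_type": ct,
                "ratio": ratios[ct],
                "cd14_score": int(rank[i]),
                "hr": eff.hazard_ratio,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "logrank_p": eff.logrank_p,
                "n_high": eff.n_high,
                "n_low": eff.n_low,
            }
        )
    return CD14ScoreTable(table=pd.DataFrame(rows).set_index("cell_type"))


# ---------------------------------------------------------------------------
# cell-type correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CellTypeCorrelations:
    """Spearman correlation structure among cell-type density scores."""

    matrix: pd.DataFrame  # symmetric, unit diagonal
    order: list[str]  # hierarchical leaf order (applies to both axes)
    color_bounds: tuple[float, float]  # min/max of the coefficient matrix


def celltype_correlations(density: DensityScores) -> CellTypeCorrelations:
    """Spearman correlations among cell types, hierarchically ordered.

    The coefficient matrix is clustered in both dimensions on its raw
    values (no transformation, no centering) with the same
    uncentered-correlation / average-linkage engine used for expression
    heat maps; the matrix is symmetric so one leaf order serves both axes.
    Constant columns yield undefined (NaN) coefficients, which are flagged.
    """
    if density.scores.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = density.scores.corr(method="spearman")
    np.fill_diagonal(rho.to_numpy(), 1.0)
    if rho.isna().any().any():
        warnings.warn("constant cell-type column(s): undefined correlation entries")
    sim = uncentered_correlation_matrix(rho.to_numpy(dtype=float))
    leaf = _leaf_order_from_similarity(sim)
    order = [rho.columns[i] for i in leaf]
    arr = rho.to_numpy()
    finite = arr[np.isfinite(arr)]
    return CellTypeCorrelations(
        matrix=rho,
        order=order,
        color_bounds=(float(finite.min()), float(finite.max())),
    )
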