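"""Three-condition replicate microarray analysis and cross-species matching.

The design is normal bronchial epithelium (4 replicates) -> primary tumor
line (3) -> metastasis-derived subclone (3).  A gene is selected when it is
differentially expressed between the normal condition and at least one
tumor condition, and its condition means follow a sustained monotone
gradient across all replicates (patterns A-1/A-2 rising, B-1/B-2 falling).

Differential expression between two replicate groups requires:

a. complete separation — every replicate of one group strictly above (or
   below) every replicate of the other; under exchangeability this carries
   an implied p of 1 / C(n1 + n2, n2);
b. the relative difference of the group means >= 50% (relative to the
   smaller mean; indeterminate when a mean is nonpositive);
c. the gene's range (max - min over all its samples) strictly within the
   top 75% of ranges genome-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneId, OrthologMap
from .gene_selection import (
    PRESENCE_THRESHOLD,
    bh_fdr,
    strict_top_mask,
    wilcoxon_rank_sum_p,
)


@dataclass
class ReplicateDesign:
    """Ordered conditions (normal, primary, metastatic) with replicate counts."""

    normal: int = 4
    primary: int = 3
    metastatic: int = 3

    def __post_init__(self) -> None:
        for n in (self.normal, self.primary, self.metastatic):
            if n < 2:
                raise ValueError("each condition needs >= 2 replicates")

    @property
    def total(self) -> int:
        return self.normal + self.primary + self.metastatic

    def split(self, row: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = row[: self.normal]
        b = row[self.normal : self.normal + self.primary]
        c = row[self.normal + self.primary :]
        return a, b, c


@dataclass
class DifferentialFlags:
    separated: bool  # (a) complete separation in either direction
    mean_shift: bool  # (b) relative mean difference >= 50%
    range_top: bool | None  # (c) range in the genome-wide top 75% (None if not supplied)
    indeterminate: bool = False  # nonpositive mean made (b) undefined

    @property
    def differential(self) -> bool:
        rng = True if self.range_top is None else self.range_top
        return self.separated and self.mean_shift and rng and not self.indeterminate


@dataclass
class PatternSelection:
    """Per-gene differential and gradient-pattern flags."""

    table: pd.DataFrame
    # columns: diff_primary, diff_metastatic, differential, A1, A2, B1, B2,
    #          pattern_A, pattern_B, selected

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse multi-probe genes to a single row per symbol.

    Probes without a gene symbol are dropped.  For a repeated symbol,
    numerically identical rows deduplicate to one; otherwise the row with
    the highest standard deviation survives.
    """
    keep: dict[str, int] = {}
    X = matrix.values.to_numpy(dtype=float)
    sd = np.nanstd(X, axis=1, ddof=1)
    for i, g in enumerate(matrix.genes):
        if g.symbol is None:
            continue
        j = keep.get(g.symbol)
        if j is None or sd[i] > sd[j]:
            keep[g.symbol] = i
    return matrix.subset_genes(sorted(keep.values()))


# ---------------------------------------------------------------------------
# differential criteria
# ---------------------------------------------------------------------------

def separation_p(n1: int, n2: int) -> float:
    """Implied p of complete separation in a given direction: 1 / C(n1+n2, n2).

    Under exchangeable random ordering of the pooled values, exactly one of
    the C(n1+n2, n2) label arrangements puts every member of one group
    above every member of the other in the designated direction.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("replicate counts must be >= 1")
    return 1.0 / comb(n1 + n2, n2)


def _separated(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(a.max() < b.min() or b.max() < a.min())


def differential_flags(
    a, b, range_in_top: bool | None = None
) -> DifferentialFlags:
    """Evaluate the two-group differential criteria for one gene.

    ``range_in_top`` supplies criterion (c) — whether the gene's range is
    strictly in the genome-wide top 75% — since it depends on all genes;
    pass None to leave it out of the verdict.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sep = _separated(a, b)
    ma, mb = float(a.mean()), float(b.mean())
    lo = min(ma, mb)
    if lo <= 0:
        return DifferentialFlags(sep, False, range_in_top, indeterminate=True)
    shift = abs(ma - mb) / lo >= 0.5
    return DifferentialFlags(sep, shift, range_in_top)


# ---------------------------------------------------------------------------
# gradient patterns
# ---------------------------------------------------------------------------

def classify_pattern(mbec, kln, ln4k1) -> dict[str, bool]:
    """Evaluate the four gradient sub-patterns for one gene.

    Rising family (A): A-1 requires full separation metastatic > primary >
    normal plus the metastatic mean strictly above the primary mean; A-2
    requires every metastatic value strictly above, and every primary and
    normal value strictly below, the grand mean over all replicates.  The
    falling family (B) mirrors both with the inequalities reversed.  A and
    B flags cannot co-occur; the two sub-patterns within a family can.
    """
    m = np.asarray(mbec, dtype=float)
    k = np.asarray(kln, dtype=float)
    l = np.asarray(ln4k1, dtype=float)
    grand = float(np.concatenate([m, k, l]).mean())

    a1 = (
        l.min() > k.max()
        and k.min() > m.max()
        and l.mean() > k.mean()
    )
    a2 = l.min() > grand and k.max() < grand and m.max() < grand
    b1 = (
        l.max() < k.min()
        and k.max() < m.min()
        and l.mean() < k.mean()
    )
    b2 = l.max() < grand and k.min() > grand and m.min() > grand
    return {"A1": a1, "A2": a2, "B1": b1, "B2": b2}


def select_pattern_genes(
    matrix: ExpressionMatrix,
    design: ReplicateDesign | None = None,
    range_top_fraction: float = 0.75,
) -> PatternSelection:
    """Run the full differential + gradient-pattern selection.

    Matrix columns must follow the design order (normal replicates, then
    primary, then metastatic).  A gene is selected when it is differential
    between normal and primary, or normal and metastatic (or both), and
    follows pattern A or B.
    """
    design = design or ReplicateDesign()
    if matrix.n_samples != design.total:
        raise ValueError(
            f"matrix has {matrix.n_samples} columns; design needs {design.total}"
        )
    X = matrix.values.to_numpy(dtype=float)
    rng = np.nanmax(X, axis=1) - np.nanmin(X, axis=1)
    range_top = strict_top_mask(rng, range_top_fraction)

    rows = []
    for i in range(matrix.n_genes):
        m, k, l = design.split(X[i])
        d1 = differential_flags(m, k, range_in_top=bool(range_top[i]))
        d2 = differential_flags(m, l, range_in_top=bool(range_top[i]))
        pat = classify_pattern(m, k, l)
        differential = d1.differential or d2.differential
        pattern_a = pat["A1"] or pat["A2"]
        pattern_b = pat["B1"] or pat["B2"]
        rows.append(
            {
                "diff_primary": d1.differential,
                "diff_metastatic": d2.differential,
                "differential": differential,
                **pat,
                "pattern_A": pattern_a,
                "pattern_B": pattern_b,
                "selected": differential and (pattern_a or pattern_b),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(matrix.gene_keys(), name="gene"))
    return PatternSelection(table=table)


# ---------------------------------------------------------------------------
# cross-species selection
# ---------------------------------------------------------------------------

def cross_species_select(
    mouse_selected: list[str],
    human: ExpressionMatrix,
    labels: pd.Series,
    orthomap: OrthologMap,
    presence_fraction: float = 0.60,
    fdr_threshold: float = 5e-5,
    group_a: str = "Classical",
    group_b: str = "Secretory",
) -> tuple[list[str], list[str]]:
    """Match mouse-selected genes to human orthologs and screen them.

    Orthologs are kept when present (value >= 0.5) in more than
    ``presence_fraction`` of the two subtypes' samples and when the BH FDR
    of the Wilcoxon rank-sum p between the two subtypes (computed across
    the presence survivors) is below ``fdr_threshold``.  Survivors split by
    the ratio median(group_a) / median(group_b): above 1 versus below;
    a zero group_b median makes the ratio infinite (assigned to the > 1
    list, warned).
    """
    human_keys = []
    seen = set()
    for ms in mouse_selected:
        msym = GeneId.from_key(ms).symbol
        for h in orthomap.human_of(msym):
            if h.key not in seen:
                seen.add(h.key)
                human_keys.append(h.key)
    if not human_keys:
        return [], []

    labels = labels.loc[human.samples]
    cols_a = [s for s in human.samples if labels[s] == group_a]
    cols_b = [s for s in human.samples if labels[s] == group_b]
    if not cols_a or not cols_b:
        raise ValueError(f"labels must contain both {group_a} and {group_b} samples")

    index = {}
    for i, k in enumerate(human.gene_keys()):
        index.setdefault(k, i)
    by_symbol = {}
    for i, g in enumerate(human.genes):
        if g.symbol is not None:
            by_symbol.setdefault(g.symbol, i)

    candidates = []
    for key in human_keys:
        i = index.get(key)
        if i is None:
            i = by_symbol.get(GeneId.from_key(key).symbol)
        if i is not None:
            candidates.append((key, i))

    X = human.values
    n_cs = len(cols_a) + len(cols_b)
    surv = []
    for key, i in candidates:
        row = X.iloc[i]
        present = (
            (row.loc[cols_a + cols_b] >= PRESENCE_THRESHOLD).sum() / n_cs
        )
        if present > presence_fraction:
            p = wilcoxon_rank_sum_p(
                row.loc[cols_a].to_numpy(), row.loc[cols_b].to_numpy()
            )
            if not np.isnan(p):
                surv.append((key, i, p))
    if not surv:
        return [], []
    fdr = bh_fdr([p for _k, _i, p in surv])
    up, down = [], []
    for (key, i, _p), q in zip(surv, fdr):
        if q >= fdr_threshold:
            continue
        med_a = float(X.iloc[i].loc[cols_a].median())
        med_b = float(X.iloc[i].loc[cols_b].median())
        if med_b == 0:
            warnings.warn(f"gene {key!r}: zero {group_b} median; ratio infinite")
            up.append(key)
        elif med_a / med_b > 1:
            up.append(key)
        else:
            down.append(key)
    return up, down
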