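"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes in
real cohorts — a four-subtype expression cohort with gene modules and
zero-inflated nonnegative values on a normalized RNA-seq-like scale,
survival times whose hazard depends on a designated marker, immune marker
modules sharing latent per-sample activities (one coupled to a CD14-like
gene), and 4+3+3-replicate three-condition arrays with planted monotone
gradient genes.  Noise is log-normal (Gaussian on the log2 scale) since
the pipeline consumes normalized expression values, not counts.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    SUBTYPES,
    ClinicalTable,
    ExpressionMatrix,
    GeneId,
    ImmuneSignature,
    SubtypeCentroids,
)
from .mouse_patterns import ReplicateDesign


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort, for recovery tests."""

    labels: pd.Series | None = None
    module_genes: dict[str, list[str]] = field(default_factory=dict)
    hazard_ratio: float | None = None
    marker: str | None = None
    celltype_modules: dict[str, list[str]] = field(default_factory=dict)
    coupled_type: str | None = None
    coupling: float = 0.0
    pattern_truth: pd.Series | None = None
    seed: int | None = None


def generate_cohort(
    n_samples: int = 348,
    n_genes: int = 200,
    subtype_props: tuple[float, float, float, float] = (0.35, 0.25, 0.12, 0.28),
    noise_sd: float = 0.5,
    zero_rate: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, SubtypeCentroids, CohortTruth]:
    """Draw a four-subtype expression cohort around planted centroids.

    Four centroid vectors are drawn on the log2 scale (standard normal per
    gene); each sample is exp2(centroid + N(0, noise_sd)) with a fraction
    ``zero_rate`` of entries zeroed, exercising the zero -> missing path
    downstream.  Default proportions give Classical and Secretory the two
    largest groups, mirroring the display convention of real squamous
    cohorts.  Returns the matrix, true labels, the centroid table (on the
    centered log2 scale nearest-centroid assignment expects) and the truth.
    """
    props = np.asarray(subtype_props, dtype=float)
    if len(props) != 4 or not np.isclose(props.sum(), 1.0) or (props <= 0).any():
        raise ValueError("subtype proportions must be 4 positive values summing to 1")
    if n_samples < 40:
        raise ValueError("need n_samples >= 40")
    rng = np.random.default_rng(seed)

    centroids = rng.normal(0.0, 1.0, size=(n_genes, 4))
    counts = np.floor(props * n_samples).astype(int)
    counts[0] += n_samples - counts.sum()
    labels = np.repeat(np.arange(4), counts)

    log_expr = centroids[:, labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    expr = np.exp2(log_expr + 6.0)  # shift keeps typical values well above 0.5
    zeros = rng.random(size=expr.shape) < zero_rate
    expr[zeros] = 0.0

    samples = [f"S{i:04d}" for i in range(n_samples)]
    gene_keys = [f"G{i:05d}|{i + 1}" for i in range(n_genes)]
    genes = [GeneId.from_key(k) for k in gene_keys]
    matrix = ExpressionMatrix(
        genes=genes, values=pd.DataFrame(expr, index=gene_keys, columns=samples)
    )
    label_s = pd.Series([SUBTYPES[j] for j in labels], index=samples)

    # centroid table centered the way the cohort itself centers: subtract the
    # per-gene median of the noise-free log2 profile, so a noiseless sample
    # correlates exactly 1 with its own centroid
    noise_free_median = np.median(centroids[:, labels], axis=1, keepdims=True)
    ctab = pd.DataFrame(
        centroids - noise_free_median,
        index=gene_keys,
        columns=list(SUBTYPES),
    )
    truth = CohortTruth(labels=label_s, seed=seed)
    return matrix, label_s, SubtypeCentroids(table=ctab), truth


def generate_survival(
    marker: pd.Series,
    hr: float = 2.0,
    censor_rate: float = 0.3,
    baseline_rate: float = 0.2,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential survival with the hazard raised for marker-high samples.

    Samples at or above the marker median get event rate baseline * hr;
    censoring is an independent exponential tuned so roughly
    ``censor_rate`` of records are censored.  Times are on the years scale.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    marker = marker.astype(float)
    high = (marker >= marker.median()).to_numpy()
    rate = baseline_rate * np.where(high, hr, 1.0)
    event_t = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = baseline_rate * censor_rate / (1.0 - censor_rate)
        censor_t = rng.exponential(1.0 / c_rate, size=len(marker))
    else:
        censor_t = np.full(len(marker), np.inf)
    t = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    df = pd.DataFrame(
        {"survival_years": t, "event": event, "stage": None}, index=marker.index
    )
    return ClinicalTable(df)


def generate_signature_cohort(
    n_samples: int = 200,
    n_celltypes: int = 9,
    markers_per_type: int = 10,
    coupling: float = 0.9,
    dual_fraction: float = 0.05,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ImmuneSignature, CohortTruth]:
    """Build an expression matrix of immune marker modules plus a CD14-like gene.

    Each cell type's markers share a latent per-sample activity; the first
    cell type's activity is correlated (strength ``coupling``) with the
    CD14-like gene.  A fraction of markers is annotated to two cell types.
    Cell types are named CT1..CTk except the canonical nine CD14+ labels
    when k = 9.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from .immunome import CD14_CELL_TYPES

    names = (
        list(CD14_CELL_TYPES)
        if n_celltypes == 9
        else [f"CT{i + 1}" for i in range(n_celltypes)]
    )
    cd14_latent = rng.normal(size=n_samples)
    activities = {}
    for i, ct in enumerate(names):
        indep = rng.normal(size=n_samples)
        if i == 0:
            activities[ct] = coupling * cd14_latent + np.sqrt(1 - coupling**2) * indep
        else:
            activities[ct] = indep

    rows, gene_keys, entries = [], [], {}
    entrez = 1000
    for ct in names:
        for j in range(markers_per_type):
            key = f"{ct}MK{j}|{entrez}"
            entrez += 1
            gene_keys.append(key)
            entries[key] = ("innate", (ct,))
            rows.append(activities[ct] + rng.normal(0.0, noise_sd, size=n_samples))
    # dual-type annotation for a fraction of markers (second type = next label)
    n_dual = int(round(dual_fraction * len(gene_keys)))
    for key in gene_keys[:n_dual]:
        first = entries[key][1][0]
        second = names[(names.index(first) + 1) % len(names)]
        entries[key] = ("innate", (first, second))

    cd14_key = "CD14|929"
    gene_keys.append(cd14_key)
    rows.append(cd14_latent + rng.normal(0.0, noise_sd * 0.5, size=n_samples))

    expr = np.exp2(np.asarray(rows) + 6.0)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(
        genes=[GeneId.from_key(k) for k in gene_keys],
        values=pd.DataFrame(expr, index=gene_keys, columns=samples),
    )
    sig = ImmuneSignature(entries=entries, cell_types=names)
    truth = CohortTruth(
        celltype_modules={ct: [k for k, (_i, t) in entries.items() if ct in t] for ct in names},
        coupled_type=names[0],
        coupling=coupling,
        marker=cd14_key,
        seed=seed,
    )
    return matrix, sig, truth


def generate_mouse_arrays(
    n_genes: int = 1000,
    n_planted_a: int = 50,
    n_planted_b: int = 50,
    effect: float = 3.0,
    noise_sd: float = 0.3,
    baseline: float = 6.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Three-condition replicate arrays with planted monotone gradient genes.

    Null genes are i.i.d. around a common baseline (RMA-like log scale
    shifted to a positive linear scale is not applied — arrays stay on the
    normalized scale the pattern rules consume).  Planted rising (A) genes
    have condition means baseline, baseline + effect, baseline + 2*effect
    across normal -> primary -> metastatic; falling (B) genes mirror them.
    Truth labels per gene: "A", "B" or "null".
    """
    if n_planted_a + n_planted_b > n_genes:
        raise ValueError("planted counts exceed gene budget")
    rng = np.random.default_rng(seed)
    design = ReplicateDesign()
    cond = np.array(
        [0] * design.normal + [1] * design.primary + [2] * design.metastatic
    )
    means = np.full((n_genes, design.total), baseline)
    truth = np.array(["null"] * n_genes, dtype=object)
    truth[:n_planted_a] = "A"
    truth[n_planted_a : n_planted_a + n_planted_b] = "B"
    for i in range(n_genes):
        if truth[i] == "A":
            means[i] = baseline + effect * cond
        elif truth[i] == "B":
            means[i] = baseline + effect * (2 - cond)
    expr = means + rng.normal(0.0, noise_sd, size=means.shape)
    expr = np.clip(expr, 0.0, None)

    samples = (
        [f"MBEC_{i + 1}" for i in range(design.normal)]
        + [f"KLN205_{i + 1}" for i in range(design.primary)]
        + [f"LN4K1_{i + 1}" for i in range(design.metastatic)]
    )
    gene_keys = [f"Mg{i:05d}" for i in range(n_genes)]
    matrix = ExpressionMatrix(
        genes=[GeneId(symbol=k) for k in gene_keys],
        values=pd.DataFrame(expr, index=gene_keys, columns=samples),
    )
    return matrix, CohortTruth(
        pattern_truth=pd.Series(truth, index=gene_keys), seed=seed
    )


def generate_synthetic_signature(
    n_genes: int = 598,
    n_dual: int = 26,
    n_celltypes: int = 29,
    seed: int = 0,
) -> ImmuneSignature:
    """A synthetic immune signature with a fixed composition.

    Produces ``n_celltypes`` cell-type lists over ``n_genes`` genes of
    which ``n_dual`` carry a second cell type; defaults mirror the
    composition of curated immunome compendia (598 genes, 572 single-type,
    26 dual-type, 29 cell types).  Gene identifiers are synthetic.
    """
    if n_dual > n_genes:
        raise ValueError("n_dual exceeds n_genes")
    rng = np.random.default_rng(seed)
    names = [f"CT{i + 1:02d}" for i in range(n_celltypes)]
    entries = {}
    for i in range(n_genes):
        first = names[i % n_celltypes]
        imm = "innate" if i % 2 == 0 else "adaptive"
        key = f"IG{i:04d}|{i + 100000}"
        if i < n_dual:
            second = names[(i + 1 + rng.integers(0, n_celltypes - 2)) % n_celltypes]
            if second == first:
                second = names[(names.index(first) + 1) % n_celltypes]
            entries[key] = (imm, (first, second))
        else:
            entries[key] = (imm, (first,))
    return ImmuneSignature(entries=entries, cell_types=names)
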