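"""Survival-record preprocessing and survival statistics.

Covers the clinical cleaning rules, Kaplan-Meier / log-rank group
comparisons, median- and quartile-split tests, and the batch per-gene
median-split proportional-hazards screen with Benjamini-Hochberg FDR.

Conventions
-----------
* Survival is measured in years (days / 365).
* The "high" expression group is inclusive at the median (value >= median);
  "low" is strictly below.  The split therefore depends on ranks only, so
  every effect here is invariant under strictly increasing transforms of
  the expression values.
* Hazard ratios come from a univariate Cox proportional-hazards fit on the
  binary high/low indicator with the Efron tie approximation (Breslow is
  available behind a switch); the 95% CI is Wald on the log-HR scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .core_io import ClinicalTable, ExpressionMatrix, RawClinicalRecord

DAYS_PER_YEAR = 365.0


@dataclass
class SurvivalEffect:
    """High-vs-low group effect: hazard ratio, Wald 95% CI, log-rank p."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_high: int
    n_low: int
    untestable: bool = False


@dataclass
class SurvivalScreenTable:
    """Per-gene median-split screen results with BH FDR across the batch."""

    table: pd.DataFrame  # index: gene key; columns: hr, ci_low, ci_high,
    #                      logrank_p, fdr, n_high, n_low, untestable


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_survival(
    raw: list[RawClinicalRecord],
    conflict_overrides: dict[str, str] | None = None,
) -> tuple[ClinicalTable, list[RawClinicalRecord]]:
    """Clean raw clinical records into an analysis-ready survival table.

    Rules, applied in order:

    i.   records with a negative days-to-last-follow-up are discarded
         (returned separately) — a data conflict that cannot be repaired;
    ii.  event = 1 for vital label "dead", 0 for "alive";
    iii. dead patients: survival days = days-to-death;
    iv.  alive patients: survival days = max(days-to-last-follow-up,
         days-to-last-known-alive) over the fields present;
    v.   years = days / 365.

    An alive record carrying a positive days-to-death is an internal
    conflict; it is flagged (resolution defaults to the vital label, i.e.
    alive) and can be overridden per sample via ``conflict_overrides``
    mapping sample -> "alive"/"dead".  Alive records with no follow-up
    field at all are dropped with a warning.
    """
    overrides = conflict_overrides or {}
    rows, discarded = [], []
    for rec in raw:
        if rec.days_to_last_followup is not None and rec.days_to_last_followup < 0:
            discarded.append(rec)
            continue
        label = rec.vital_status_label.strip().lower()
        if label not in ("dead", "alive"):
            raise ValueError(f"sample {rec.sample!r}: unknown vital status {label!r}")
        conflict = label == "alive" and (rec.days_to_death or 0) > 0
        if conflict and rec.sample in overrides:
            label = overrides[rec.sample].strip().lower()
        if label == "dead":
            if rec.days_to_death is None:
                warnings.warn(f"sample {rec.sample!r}: dead without days_to_death; dropped")
                discarded.append(rec)
                continue
            days, event = rec.days_to_death, 1
        else:
            candidates = [
                d
                for d in (rec.days_to_last_followup, rec.days_to_last_known_alive)
                if d is not None
            ]
            if not candidates:
                warnings.warn(f"sample {rec.sample!r}: alive without follow-up; dropped")
                discarded.append(rec)
                continue
            days, event = max(candidates), 0
        if days < 0:
            discarded.append(rec)
            continue
        rows.append(
            {
                "sample": rec.sample,
                "survival_years": days / DAYS_PER_YEAR,
                "event": event,
                "stage": rec.stage,
                "conflict": conflict,
            }
        )
    table = pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame(
        columns=["survival_years", "event", "stage", "conflict"]
    )
    return ClinicalTable(table), discarded


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def logrank_groups(
    clinical: ClinicalTable, groups: pd.Series | dict
) -> tuple[float, int]:
    """K-group log-rank (Mantel-Cox) test: returns (p, df) with df = k - 1."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[clinical.samples]
    counts = groups.value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    res = multivariate_logrank_test(
        clinical.data["survival_years"].to_numpy(),
        groups.to_numpy(),
        clinical.data["event"].to_numpy(),
    )
    return float(res.p_value), int(counts.size - 1)


def median_split_effect(
    values: pd.Series,
    clinical: ClinicalTable,
    tie_method: str = "efron",
) -> SurvivalEffect:
    """Median-split survival effect of a per-sample quantity.

    High = value >= sample median (inclusive), low = value < median; HR from
    a Cox fit on the binary indicator, Wald 95% CI, log-rank p on the same
    split.  Constant input leaves one group empty: the effect is returned
    flagged untestable (with HR NaN) rather than raising, so batch screens
    can skip it.
    """
    values = values.loc[clinical.samples].astype(float)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("median split needs finite values")
    med = float(values.median())
    high = (values >= med).astype(int)
    n_high, n_low = int(high.sum()), int((1 - high).sum())
    if n_high == 0 or n_low == 0:
        return SurvivalEffect(np.nan, np.nan, np.nan, np.nan, n_high, n_low, True)

    df = pd.DataFrame(
        {
            "T": clinical.data["survival_years"].to_numpy(),
            "E": clinical.data["event"].to_numpy(),
            "high": high.to_numpy(),
        }
    )
    lr = multivariate_logrank_test(df["T"], df["high"], df["E"])
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except Exception:
            return SurvivalEffect(
                np.nan, np.nan, np.nan, float(lr.p_value), n_high, n_low, True
            )
    beta = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    return SurvivalEffect(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        logrank_p=float(lr.p_value),
        n_high=n_high,
        n_low=n_low,
    )


def quartile_split_logrank(values: pd.Series, clinical: ClinicalTable) -> float:
    """Four-group log-rank p with groups cut at the three quartile points.

    The lower/middle/upper quartiles are dividing points for the population;
    ties that collapse a group to empty are an error naming the cut.
    """
    values = values.loc[clinical.samples].astype(float)
    if len(values) < 20:
        raise ValueError("quartile split needs n >= 20")
    q1, q2, q3 = values.quantile([0.25, 0.5, 0.75])
    grp = pd.Series(
        np.select(
            [values < q1, values < q2, values < q3],
            [0, 1, 2],
            default=3,
        ),
        index=values.index,
    )
    counts = grp.value_counts()
    for g, cut in zip(range(4), (q1, q2, q3, None)):
        if counts.get(g, 0) == 0:
            raise ValueError(f"quartile group {g} empty (cut at {cut})")
    p, _df = logrank_groups(clinical, grp)
    return p


# ---------------------------------------------------------------------------
# batch screen
# ---------------------------------------------------------------------------

def batch_gene_survival(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    gene_subset: list[str] | None = None,
    tie_method: str = "efron",
) -> SurvivalScreenTable:
    """Median-split screen over genes: HR, CI, log-rank p per gene, BH FDR.

    ``gene_subset`` selects rows by gene key (all genes when None).
    Untestable genes (constant expression) carry no FDR; the BH correction
    runs across the testable genes only.
    """
    keys = matrix.gene_keys()
    if gene_subset is None:
        rows = list(range(matrix.n_genes))
    else:
        if not gene_subset:
            raise ValueError("empty gene subset")
        index = {}
        for i, k in enumerate(keys):
            index.setdefault(k, i)
        missing = [g for g in gene_subset if g not in index]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_subset]

    records = []
    for i in rows:
        vals = matrix.values.iloc[i].loc[clinical.samples]
        eff = median_split_effect(vals.fillna(0.0), clinical, tie_method=tie_method)
        records.append(
            {
                "gene": keys[i],
                "hr": eff.hazard_ratio,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "logrank_p": eff.logrank_p,
                "n_high": eff.n_high,
                "n_low": eff.n_low,
                "untestable": eff.untestable,
            }
        )
    out = pd.DataFrame(records).set_index("gene")
    out["fdr"] = np.nan
    testable = ~out["untestable"] & out["logrank_p"].notna()
    if testable.any():
        out.loc[testable, "fdr"] = multipletests(
            out.loc[testable, "logrank_p"].to_numpy(), method="fdr_bh"
        )[1]
    return SurvivalScreenTable(table=out)


def write_screen_table(screen: SurvivalScreenTable, path) -> None:
    cols = ["hr", "ci_low", "ci_high", "logrank_p", "fdr", "n_high", "n_low"]
    screen.table[cols].to_csv(path, sep="\t", na_rep="NA")
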