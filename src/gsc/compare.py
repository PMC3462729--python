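"""Comparison analyses over consistency records.

Once every gene set has its seven metrics, the question becomes which
*source* of sets (GO namespace, KEGG maps, predicted operons, SEED
subsystems/scenarios/paths, ...) delivers the most consistent sets —
and whether apparent differences are artefacts of set size or organism
composition.  This module provides:

* per-source means with direction-aware ranks (spread metrics: smaller
  is better; correlation metrics: larger is better);
* the 7x7 Pearson correlation table between the metrics themselves,
  computed complete-case;
* per-source mean-by-set-size profiles, suppressing sparse bins;
* four nested ordinary-least-squares models predicting a metric from
  source, then + log10(set size), then + organism, then + all
  interactions — nested, so r^2 is non-decreasing;
* variance decompositions of log10(set size) by organism and by
  source, and the organism-level gene-count vs set-count correlation.

Model fitting is ordinary least squares with treatment-coded
categorical predictors (statsmodels); p-values are per-coefficient t
tests on residual degrees of freedom, unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .io_formats import METRIC_NAMES, ConsistencyRecord, records_to_frame

#: Metrics where smaller means more consistent.
SMALLER_IS_BETTER = ("s_mean_diff", "s_median_diff", "s_mean_exp", "s_median_exp")
#: Metrics where larger means more consistent.
LARGER_IS_BETTER = ("corr_mean", "corr_median", "pc1")
#: The four metrics the headline comparisons focus on.
HEADLINE_METRICS = ("s_mean_diff", "s_mean_exp", "corr_mean", "pc1")

#: Default set-size binning: exact sizes up to 20, then coarse bins.
DEFAULT_BINS: tuple[tuple[int, float], ...] = tuple(
    [(k, float(k)) for k in range(2, 21)]
    + [(21, 30.0), (31, 50.0), (51, 100.0), (101, math.inf)]
)


@dataclass(frozen=True)
class SourceSummary:
    """Per-source metric means and direction-aware ranks (1 = best)."""

    means: pd.DataFrame  # sources x metrics
    ranks: pd.DataFrame  # sources x metrics, integer ranks (nan where undefined)


@dataclass(frozen=True)
class SizeProfile:
    """Per-source mean metric value by set-size bin."""

    metric: str
    table: pd.DataFrame  # columns: source, bin_label, size_lo, size_hi, n_sets, mean


@dataclass(frozen=True)
class ModelFit:
    """One fitted OLS model: r^2 plus per-coefficient effects."""

    model_id: int
    terms: tuple[str, ...]
    r2: float
    effects: pd.DataFrame  # index: coefficient name; columns: estimate, se, t, p
    n_obs: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


def summarize_by_source(
    records: Iterable[ConsistencyRecord],
    metrics: Sequence[str] = METRIC_NAMES,
) -> SourceSummary:
    """Mean of each metric by source, with ranks (1 = most consistent).

    Undefined metric values are excluded from the means.  Ranks run in
    the metric's consistency direction; a source with no defined value
    for a metric gets a missing cell and is excluded from that
    metric's ranking.  Exact mean ties are broken alphabetically by
    source label so ranks are a deterministic permutation.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")
    means = df.groupby("source")[list(metrics)].mean()  # skipna by default
    means = means.sort_index()
    ranks = pd.DataFrame(index=means.index, columns=list(metrics), dtype=float)
    for m in metrics:
        col = means[m].dropna()
        ascending = m in SMALLER_IS_BETTER
        # stable sort on (value, label) for deterministic tie-breaks
        ordered = col.reset_index().sort_values(
            by=[m, "source"], ascending=[ascending, True], kind="mergesort"
        )["source"]
        for i, src in enumerate(ordered, start=1):
            ranks.loc[src, m] = i
    return SourceSummary(means=means, ranks=ranks)


@dataclass(frozen=True)
class MetricCorrelationTable:
    """Symmetric Pearson correlations between the seven metric columns."""

    table: pd.DataFrame
    n_complete: int


def metric_correlations(
    records: Iterable[ConsistencyRecord],
) -> MetricCorrelationTable:
    """Pairwise Pearson correlation between metric columns, complete-case.

    Rows with any undefined metric are dropped first so every entry of
    the 7x7 table is computed over the same sets.
    """
    df = records_to_frame(records)[list(METRIC_NAMES)].dropna()
    if len(df) < 3:
        raise ValueError(
            f"need >=3 records with all metrics defined, got {len(df)}"
        )
    corr = df.corr(method="pearson")
    return MetricCorrelationTable(table=corr, n_complete=len(df))


def size_stratified_profile(
    records: Iterable[ConsistencyRecord],
    metric: str,
    min_sets: int = 20,
    bins: Sequence[tuple[int, float]] = DEFAULT_BINS,
) -> SizeProfile:
    """Mean metric value per (source, set-size bin), sparse bins suppressed.

    ``bins`` is a sequence of (lower, upper) bounds, both inclusive;
    the default uses exact sizes 2..20 then (20,30], (30,50],
    (50,100], (100,inf).  Bins holding fewer than ``min_sets`` sets
    for a source are dropped from the profile.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    df = records_to_frame(records).dropna(subset=[metric])
    rows = []
    for src, grp in df.groupby("source"):
        for lo, hi in bins:
            sel = grp[(grp["n_genes"] >= lo) & (grp["n_genes"] <= hi)]
            if len(sel) < min_sets:
                continue
            label = str(lo) if lo == hi else f"({lo - 1},{'inf' if math.isinf(hi) else int(hi)}]"
            rows.append(
                {
                    "source": src,
                    "bin_label": label,
                    "size_lo": lo,
                    "size_hi": hi,
                    "n_sets": len(sel),
                    "mean": float(sel[metric].mean()),
                }
            )
    table = pd.DataFrame(
        rows, columns=["source", "bin_label", "size_lo", "size_hi", "n_sets", "mean"]
    )
    return SizeProfile(metric=metric, table=table)


def _fit_ols(formula: str, data: pd.DataFrame, model_id: int, terms: tuple[str, ...]) -> ModelFit:
    fit = smf.ols(formula, data=data).fit()
    r2 = float(fit.rsquared)
    if not math.isfinite(r2):
        r2 = 0.0  # constant response: zero total SS, nothing to explain
    effects = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelFit(
        model_id=model_id,
        terms=terms,
        r2=r2,
        effects=effects,
        n_obs=int(fit.nobs),
    )


def fit_nested_models(
    records: Iterable[ConsistencyRecord], metric: str
) -> list[ModelFit]:
    """Four nested OLS models predicting one metric.

    Model 1: source only; model 2: + log10(set size); model 3:
    + organism; model 4: + all interaction terms between the three.
    Records with the metric undefined are dropped.  Sources and
    organisms are treatment-coded; a rank-deficient design (e.g. a
    single organism) leaves statsmodels to drop the aliased columns,
    which does not affect r^2.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    df = records_to_frame(records).dropna(subset=[metric]).copy()
    if df["source"].nunique() < 2:
        raise ValueError("need records from at least 2 sources")
    df["log_size"] = np.log10(df["n_genes"].astype(float))
    df = df.rename(columns={metric: "y"})
    specs = [
        (1, "y ~ C(source)", ("source",)),
        (2, "y ~ C(source) + log_size", ("source", "log10_size")),
        (3, "y ~ C(source) + log_size + C(organism)", ("source", "log10_size", "organism")),
        (
            4,
            "y ~ C(source) * log_size * C(organism)",
            ("source", "log10_size", "organism", "interactions"),
        ),
    ]
    return [_fit_ols(f, df, mid, terms) for mid, f, terms in specs]


def size_variance_decomposition(
    records: Iterable[ConsistencyRecord],
) -> tuple[ModelFit, ModelFit]:
    """How much of the spread in log10(set size) each factor explains.

    Two separate one-way OLS regressions of log10(n_genes): on
    organism alone and on source alone.  Their r^2 values are the
    between-group / total sum-of-squares ratios of the corresponding
    one-way ANOVAs.
    """
    df = records_to_frame(records).copy()
    df["y"] = np.log10(df["n_genes"].astype(float))
    by_organism = _fit_ols("y ~ C(organism)", df, 1, ("organism",))
    by_source = _fit_ols("y ~ C(source)", df, 2, ("source",))
    return by_organism, by_source


def organism_level_correlation(table: pd.DataFrame) -> float:
    """Pearson r between per-organism gene counts and total set counts.

    ``table`` must contain columns ``n_genes`` and ``n_sets`` with one
    row per organism.
    """
    if len(table) < 3:
        raise ValueError(f"need >=3 organisms, got {len(table)}")
    r, _ = scipy.stats.pearsonr(
        table["n_genes"].astype(float), table["n_sets"].astype(float)
    )
    return float(r)
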