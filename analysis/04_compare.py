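#!/usr/bin/env python
"""Compare the simulated set sources on the consistency metrics.

From records.tsv: per-source means with direction-aware ranks, the
7x7 between-metric Pearson correlation table, per-source mean-by-size
profiles (bins with >= 10 sets at this scale), the four nested OLS
models per headline metric, the size variance decomposition, and the
organism-level gene-count vs set-count correlation from the bundled
17-organism table.  Tables land in results/analysis/.
"""

from pathlib import Path

import pandas as pd

import gsc
from gsc import (
    HEADLINE_METRICS,
    fit_nested_models,
    metric_correlations,
    organism_level_correlation,
    read_records,
    size_stratified_profile,
    size_variance_decomposition,
    summarize_by_source,
)

BASE = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    records = read_records(BASE / "records.tsv")

    summary = summarize_by_source(records)
    tab = summary.means.round(4).astype(str)
    for src in summary.ranks.index:
        for m in summary.ranks.columns:
            r = summary.ranks.loc[src, m]
            if r == r:
                tab.loc[src, m] += f" ({int(r)})"
    tab.to_csv(BASE / "source_summary.tsv", sep="\t")
    print("per-source means (rank):")
    print(tab[list(HEADLINE_METRICS)].to_string())

    corr = metric_correlations(records)
    corr.table.round(3).to_csv(BASE / "metric_correlations.tsv", sep="\t")
    print(f"\nmetric intercorrelation over {corr.n_complete} complete records:")
    print(f"  mean vs median diff spread r = "
          f"{corr.table.loc['s_mean_diff', 's_median_diff']:.3f}; "
          f"corr_mean vs pc1 r = {corr.table.loc['corr_mean', 'pc1']:.3f}")

    profiles = pd.concat(
        [size_stratified_profile(records, m, min_sets=10).table.assign(metric=m)
         for m in HEADLINE_METRICS],
        ignore_index=True,
    )
    profiles.to_csv(BASE / "size_profiles.tsv", sep="\t", index=False)

    rows = []
    for m in HEADLINE_METRICS:
        for fit in fit_nested_models(records, m):
            rows.append({"metric": m, "model": fit.model_id,
                         "terms": "+".join(fit.terms), "r2": fit.r2,
                         "n": fit.n_obs})
    fits = pd.DataFrame(rows)
    fits.to_csv(BASE / "model_fits.tsv", sep="\t", index=False)
    print("\nnested-model r2 (corr_mean):",
          [round(r, 3) for r in fits.query("metric == 'corr_mean'")["r2"]])

    by_org, by_src = size_variance_decomposition(records)
    print(f"log10 set size r2: organism {by_org.r2:.4f}, source {by_src.r2:.4f} "
          "(single simulated organism, so only source can explain size)")

    r = organism_level_correlation(gsc.load_organism_table())
    print(f"\nbundled 17-organism table: gene count vs total set count r = {r:.3f}")


if __name__ == "__main__":
    main()
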