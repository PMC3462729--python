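# Methods

## The consistency model

Every metric in this package treats a gene set *N* (n ≥ 2 genes) as a
hypothesis: *these genes respond as a unit*.  The observed
differential expression of member *i* between two arrays decomposes
conceptually as a set-level effect plus a gene-level departure plus
noise; a set is "consistent" to the degree that the gene-level and
noise terms are small relative to the set-level term.  Each metric
probes that decomposition through the lens of one analysis style:

- `s_mean_diff` / `s_median_diff` summarise, over array pairs (k, l),
  the sample SD across genes of dᵢ = eₖ,ᵢ − eₗ,ᵢ.  If the set
  responds as a unit, the dᵢ are nearly equal and the SD collapses —
  whatever the magnitude of the shared response.  Units: log2
  expression (a log-ratio spread).
- `s_mean_exp` / `s_median_exp` apply the same idea to the raw values
  per array: the SD across genes of eₖ,ᵢ, averaged (or medianed) over
  all P arrays.  This penalises sets whose members sit at different
  baseline levels even when co-regulated.
- `corr_mean` / `corr_median` summarise all n(n−1)/2 pairwise Pearson
  correlations across arrays.  Location-invariant: a co-regulated set
  with heterogeneous baselines still scores high.
- `pc1` is λ₁/Σλ of the n×n sample covariance of the set (genes =
  variables, arrays = observations, per-gene centring, no scaling).
  It demands not just high but *mutually consistent* correlation:
  one latent factor must carry the set.

Directionality: the spread metrics fall and the correlation metrics
rise with consistency.  All ranks produced by `summarize_by_source`
are direction-aware (rank 1 = most consistent).

## Estimators and sampling rules

- Sample SD everywhere (n−1 denominator), matching the convention of
  standard statistical environments' `sd`/`prcomp`.
- With P arrays there are P(P−1)/2 pairs; `diff_spread` metrics are
  estimated from `n_pairs = 100` uniformly sampled distinct pairs
  (without replacement) whenever the exhaustive count exceeds that,
  and exhaustively otherwise.  The sample mean is an unbiased
  estimator of the exhaustive mean; the tests verify the 3-SE
  agreement on a 30-array compendium.  One pair sample is drawn per
  matrix and shared by all sets, so between-set comparisons within an
  organism see identical pairs.
- Sets above `max_genes = 50` members are subsampled (uniform,
  without replacement) before the pairwise-correlation summaries; one
  subsample is shared by `corr_mean` and `corr_median`.  `pc1` uses
  the full set by default — the covariance eigenstructure is cheap
  via SVD even for wide sets — with an optional cap for extreme
  cases.
- Per-set randomness is derived as `crc32(set_id)` mixed with the
  master seed, so a set's subsample never depends on which other sets
  are evaluated, and all derived seeds stay below 2³¹.
- Median of an even-length list is the mean of the two central
  values.
- Zero-variance genes: Pearson correlation is undefined, so pairs
  containing such a gene are excluded from the corr summaries (all
  pairs excluded ⇒ `NA`); they are *included* in spread metrics and
  in the PCA, where they legitimately contribute zero variance.  An
  all-constant set has zero covariance trace and `pc1 = NA`.

## Set construction and filtering

Hierarchical vocabularies (DAGs of terms, as in the GO's three
namespaces) are propagated bottom-up: a term's set is its direct
annotations plus those of every descendant, computed in one reverse
topological pass (cycles are reported with a witness).  Terms whose
propagated set is empty are omitted.  Parent/child sets that end up
identical are both kept — deduplication would silently change set
counts per source.

Collections are then filtered to the expression matrix: members
without expression data are dropped and sets retaining fewer than 2
measured genes are removed.  The "reduced analysis" filter
(`restrict_to_universe`) defaults to *membership* semantics — a set
survives if it touches the universe, its contents untouched — because
the restriction is meant to change which sets are analysed, not what
they contain; trimming to the intersection is an explicit option.
Genome coverage percentages use the measured-gene universe of the
matrix as denominator.

## Comparison analyses

- Per-source means exclude `NA` values metric-wise; ranks break exact
  mean ties alphabetically by source label (deterministic, and a
  measure-zero event on real data).
- The 7×7 metric intercorrelation table is complete-case (rows with
  any `NA` dropped) so all entries share a row basis.
- Size profiles default to exact-size bins 2–20 then (20,30],
  (30,50], (50,100], (100,∞), suppressing (source, bin) cells with
  fewer than `min_sets = 20` sets; both the binning and the threshold
  are configurable, since any size-axis treatment is a presentation
  choice.
- The four nested models are OLS with treatment coding:
  (1) `metric ~ source`, (2) `+ log10(n_genes)`, (3) `+ organism`,
  (4) all interactions (`source * log10size * organism`).  Nesting
  guarantees non-decreasing r²; the model-4 gain over model 3 is
  reported, not asserted.  P-values are per-coefficient t tests,
  unadjusted.  A constant response has zero total sum of squares; r²
  is defined as 0 in that case.  Rank-deficient designs (one organism
  in model 3) are left to the fitter's pseudoinverse, which does not
  affect r².

## The synthetic generator

`generate` emulates the features of an RMA-normalised compendium that
the metrics are sensitive to, with a single-factor Gaussian block per
set: gᵢ(a) = μᵢ + λ·f_s(a) + εᵢ(a), λ chosen from the target
within-set correlation ρ via λ²/(λ²+σ²) = ρ.  This gives closed-form
oracles: realized mean pairwise correlation → ρ; as ρ→1 with small σ
and no offsets, diff spread → √2·σ and pc1 → 1; raising
`offset_spread` inflates the absolute-expression spread while leaving
correlations untouched.  Per-gene means combine a per-set level
(SD `baseline_mean_spread` = 1.5 around a grand log2 level of 7,
typical of RMA output) with per-gene offsets; residual SD defaults to
0.5.  A Student-t noise option (df > 2, variance-matched) produces
the heavy tails that separate mean- from median-based metrics.
Optional array-group mean shifts emulate condition structure.

What it does *not* emulate: probe-level artefacts, normalisation
residuals, correlated background structure, non-Gaussian marginals of
real compendia, overlapping biological pathways (overlap is injected
separately by `make_overlapping_collection`), or realistic set-size
distributions per source.  Passing tests on synthetic data therefore
demonstrate correctness of the estimators and the directional
behaviour of the pipeline, not field performance on any real
organism.

Default study conditions used by the acceptance checks: 40-array
compendia, 200 sets per source of size 10 for parameter recovery at
ρ ∈ {0.1, 0.5, 0.9}; a 30-array compendium (435 exhaustive pairs) for
the sampling-estimator check over 50 seeds; 240 five-gene ρ = 0.9
blocks aggregated 1/2/4/8-fold for the size-effect trend.  These
sizes are large enough that Monte-Carlo error sits well inside the
stated tolerances while the whole suite runs in seconds.

## Bundled data

`gsc/data/organism_set_counts.tsv` carries the printed per-organism
characteristics of a published 17-bacteria Affymetrix compendium
(genome size, array count, gene-set counts per source) used for the
organism-level correlation cross-check; it is a typed copy of a
printed table, not a computed artefact.

## Known limitations

- Pair sampling is shared per matrix but the *pair list* differs
  between organisms with different P even at the same seed; cross-
  organism comparability relies on the unbiasedness of the estimator,
  not on identical pairs.
- `corr_median` on a subsampled set estimates the subsample median,
  which is not an unbiased estimator of the full-set median (the same
  is true of any subsampled median).
- The nested models assume homoscedastic Gaussian residuals; real
  metric distributions are bounded and skewed, so the reported
  p-values are approximate (r² comparisons are unaffected).
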