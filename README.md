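# gsc — gene-set consistency metrics for expression compendia

Statistical analyses of bacterial gene expression data — differential
expression ranking, on/off calling, clustering, network inference —
lean on *gene sets*: named groups of genes taken from GO terms, KEGG
maps, SEED subsystems/scenarios/paths or predicted operons.  The
power of all of those analyses depends on how *consistently* the
genes of a set actually behave across expression arrays.  `gsc`
implements a family of seven per-set consistency metrics together
with the machinery to build and filter set collections, compare set
sources fairly (controlling for set size and organism), and simulate
compendia with known ground truth.

## The metrics

For a set *N* of *n* genes with log2 expression values *e*ₖ,ᵢ (array
*k*, gene *i*) over *P* arrays:

- **Differential expression spread** — for an array pair (*k*, *l*)
  compute the log-ratios *d*ᵢ = *e*ₖ,ᵢ − *e*ₗ,ᵢ and their sample
  standard deviation *s*₍N,(k,l)₎ across the *n* genes.
  *s*ₘₑₐₙ,diff and *s*ₘₑdᵢₐₙ,diff are the mean and median of
  *s*₍N,(k,l)₎ over array pairs (estimated from 100 randomly sampled
  pairs when P(P−1)/2 is larger).  Small values mean the set moves
  coherently between conditions.
- **Absolute expression spread** — per array *k*, the sample SD of
  the set's *n* values; *s*ₘₑₐₙ,exp and *s*ₘₑdᵢₐₙ,exp summarise it
  over all *P* arrays.  Small values mean the set sits at a common
  expression level.
- **Pairwise correlation** — corrₘₑₐₙ and corrₘₑdᵢₐₙ over all
  n(n−1)/2 Pearson correlations *r*ᵢ,ⱼ between member genes (sets
  above 50 genes are subsampled to 50).  Large values mean
  co-regulation.
- **PC1 fraction** — λ₁/Σλ of the set's n×n sample covariance matrix
  (genes as variables, arrays as observations): the proportion of
  total variance explained by the first principal component.  Large
  when a single latent factor drives the whole set.

All SDs and covariances use the n−1 denominator.  Metrics undefined
on degenerate sets (e.g. a zero-variance gene in every pair) are
reported as `NA`, never silently zeroed.

## Worked example

```python
import gsc

# simulate a compendium: three sources with decreasing within-set
# correlation (0.7 / 0.5 / 0.3) over 40 arrays
matrix, collections, truth = gsc.generate(gsc.SyntheticConfig(seed=1))
records = gsc.evaluate_collections(collections, matrix, seed=1)
summary = gsc.summarize_by_source(records)
print(summary.means.round(3)[["s_mean_diff", "corr_mean", "pc1"]])
```

prints

```
             s_mean_diff  corr_mean    pc1
source
GO_LIKE            0.693      0.299  0.360
OPERON_LIKE        0.655      0.693  0.769
PATH_LIKE          0.678      0.480  0.557
```

The operon-like source (generated with within-set correlation 0.7)
comes out most consistent on every metric — largest corr_mean and
pc1, smallest differential spread — and the ranking in
`summary.ranks` follows the generating order exactly.

The same pipeline runs from the shell:

```sh
gsc run --config config.yaml --out-dir out/   # simulate → evaluate → compare
gsc evaluate --expr matrix.tsv --gmt GO_BP go.gmt --seed 1 --out records.tsv
```

and the numbered scripts under `analysis/` walk through it step by
step (simulate, build/filter sets, evaluate, compare), writing their
tables under `results/analysis/`.

## File formats

Expression matrices are TSV (genes × arrays, log2 scale, `#`
comments, `NA` missing token); gene sets are GMT; hierarchical
vocabularies enter as two-column TSVs of direct annotations
(term, gene) and child→parent edges, and are propagated so each
term's set includes all descendant terms' genes.

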