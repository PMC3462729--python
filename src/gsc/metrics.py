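"""The seven gene-set consistency metrics and their subsampling estimators.

A consistency metric summarises, for one gene set, how similarly the
set's genes behave across a compendium of expression arrays.  Three
classes of metric mirror three classes of downstream analysis:

* **Differential expression** — for an array pair (k, l) the
  differential value of gene i is the log-ratio
  ``d_i = e_{k,i} - e_{l,i}``.  The sample standard deviation of the
  d_i over the set's n genes, s_{N,(k,l)}, measures how coherently the
  set responds between the two conditions.  ``s_mean_diff`` and
  ``s_median_diff`` are the mean and median of s_{N,(k,l)} over array
  pairs.  With many arrays the P(P-1)/2 pairs are estimated from a
  random sample of pairs (100 by default), which is unbiased for the
  mean.  Smaller is more consistent.

* **Absolute expression** — per array k, the sample standard deviation
  of the set's n expression values, s_{N,k}; ``s_mean_exp`` and
  ``s_median_exp`` are its mean and median over all P arrays (no
  sampling).  Smaller is more consistent.

* **Correlation** — all pairwise Pearson correlations r_{i,j} between
  the set's genes across arrays; ``corr_mean`` and ``corr_median``
  summarise them (sets larger than 50 genes are first subsampled to
  50).  ``pc1`` is the fraction of total variance carried by the first
  principal component of the set's gene-by-gene sample covariance
  matrix — large when one latent factor drives the whole set.  Larger
  is more consistent.

Sample statistics use the n-1 denominator throughout.  Metrics that
are undefined on a degenerate set (e.g. every gene pair involves a
zero-variance gene) come back as ``nan``, never as an exception.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ConsistencyRecord, ExpressionMatrix, GeneSet, GeneSetCollection

#: Modulus keeping derived seeds within a 32-bit signed range.
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class PairSample:
    """Unordered array-index pairs used by the differential-spread metrics."""

    pairs: tuple[tuple[int, int], ...]
    exhaustive: bool
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        seen = set()
        for k, l in self.pairs:
            if k == l:
                raise ValueError(f"self-pair ({k}, {l})")
            key = (min(k, l), max(k, l))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


def derive_seed(master_seed: int, label: str) -> int:
    """A per-set seed from a master seed and a stable identifier hash.

    Uses crc32 of the label so the stream for one set never depends on
    which other sets are present, and stays below 2**31.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % _SEED_MOD


def sample_array_pairs(P: int, n_pairs: int = 100, seed: int = 0) -> PairSample:
    """Draw ``n_pairs`` distinct unordered array pairs uniformly.

    If the total number of pairs P(P-1)/2 does not exceed ``n_pairs``
    all pairs are returned and the sample is flagged exhaustive.
    Pairs are oriented k < l; sampling is without replacement and
    reproducible under ``seed``.
    """
    if P < 2:
        raise ValueError(f"need at least 2 arrays, got P={P}")
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    total = P * (P - 1) // 2
    all_pairs = list(combinations(range(P), 2))
    if total <= n_pairs:
        return PairSample(pairs=tuple(all_pairs), exhaustive=True, seed=seed)
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n_pairs, replace=False)
    return PairSample(
        pairs=tuple(all_pairs[i] for i in idx), exhaustive=False, seed=seed
    )


def _set_values(gene_set: GeneSet, matrix: ExpressionMatrix) -> np.ndarray:
    genes = gene_set.sorted_genes()
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise ValueError(
            f"set {gene_set.set_id!r} has unmeasured genes {missing}; "
            "filter the collection to the matrix first"
        )
    if len(genes) < 2:
        raise ValueError(f"set {gene_set.set_id!r} has fewer than 2 genes")
    return matrix.values_for(genes)


def diff_spread(
    gene_set: GeneSet, matrix: ExpressionMatrix, pairs: PairSample
) -> tuple[float, float]:
    """Mean and median spread of differential expression over array pairs.

    For each pair (k, l): the sample SD across the set's genes of
    ``d_i = e_{k,i} - e_{l,i}``; then the mean and the median of those
    SDs over the pairs in ``pairs``.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair sample")
    X = _set_values(gene_set, matrix)
    ks = np.fromiter((p[0] for p in pairs.pairs), dtype=int)
    ls = np.fromiter((p[1] for p in pairs.pairs), dtype=int)
    diffs = X[:, ks] - X[:, ls]  # genes x pairs
    sds = np.std(diffs, axis=0, ddof=1)
    return float(np.mean(sds)), float(np.median(sds))


def abs_spread(gene_set: GeneSet, matrix: ExpressionMatrix) -> tuple[float, float]:
    """Mean and median per-array spread of absolute expression.

    Per array k: the sample SD of the set's n expression values; then
    the mean and median over all P arrays.  Uses every array — no
    sampling is involved.
    """
    X = _set_values(gene_set, matrix)
    sds = np.std(X, axis=0, ddof=1)
    return float(np.mean(sds)), float(np.median(sds))


def subsample_genes(
    gene_set: GeneSet, max_genes: int, seed: int
) -> list[str]:
    """The seeded uniform subset of members used for large sets.

    Sets with at most ``max_genes`` members are returned whole.  The
    draw is over the lexicographically sorted member list, so it
    depends only on the membership and the seed.
    """
    genes = gene_set.sorted_genes()
    if len(genes) <= max_genes:
        return genes
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=max_genes, replace=False)
    return [genes[i] for i in sorted(idx)]


def corr_summary(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    max_genes: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and median pairwise Pearson correlation within a set.

    Sets above ``max_genes`` members are first reduced to a seeded
    uniform subset (estimating the full-set summaries without the
    quadratic cost).  Pairs involving a zero-variance gene have no
    defined correlation and are excluded from both summaries; if every
    pair is excluded both summaries are ``nan``.
    """
    genes = subsample_genes(gene_set, max_genes, seed)
    X = matrix.values_for(genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    iu = np.triu_indices(len(genes), k=1)
    r = corr[iu]
    r = r[np.isfinite(r)]
    if r.size == 0:
        return math.nan, math.nan
    return float(np.mean(r)), float(np.median(r))


def pc1_fraction(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    max_genes: int | None = None,
    seed: int = 0,
) -> float:
    """Fraction of variance on the first principal component.

    Genes are the variables, arrays the observations; each gene is
    centred but not scaled, so this is the eigendecomposition of the
    n x n sample covariance matrix.  Computed via SVD of the centred
    data (eigenvalues are squared singular values over P-1), which is
    exact and cheap even when n greatly exceeds P.  By default the
    whole set is used; ``max_genes`` enables a seeded cap for sets so
    large that even the SVD is impractical.

    Returns ``nan`` for an all-constant set (zero total variance).
    """
    if max_genes is not None:
        genes = subsample_genes(gene_set, max_genes, seed)
    else:
        genes = gene_set.sorted_genes()
    X = matrix.values_for(genes)
    Xc = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        return math.nan
    return float(s[0] ** 2 / total)


def evaluate_set(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    pairs: PairSample,
    max_genes: int = 50,
    seed: int = 0,
) -> ConsistencyRecord:
    """All seven metrics for one (already filtered) gene set."""
    smd, smdd = diff_spread(gene_set, matrix, pairs)
    sme, smed = abs_spread(gene_set, matrix)
    cm, cmed = corr_summary(gene_set, matrix, max_genes=max_genes, seed=seed)
    p1 = pc1_fraction(gene_set, matrix)
    return ConsistencyRecord(
        organism=matrix.organism,
        source=gene_set.source,
        set_id=gene_set.set_id,
        n_genes=len(gene_set),
        s_mean_diff=smd,
        s_median_diff=smdd,
        s_mean_exp=sme,
        s_median_exp=smed,
        corr_mean=cm,
        corr_median=cmed,
        pc1=p1,
    )


def evaluate_collections(
    collections: Iterable[GeneSetCollection],
    matrix: ExpressionMatrix,
    n_pairs: int = 100,
    max_genes: int = 50,
    seed: int = 0,
) -> list[ConsistencyRecord]:
    """Evaluate every set of every collection against one matrix.

    One array-pair sample is drawn per matrix (per organism) and
    shared by all sets; the gene subsample for each large set uses a
    stream derived from ``seed`` and the set identifier, so adding or
    removing sets never changes another set's result.  Per-set
    undefined metrics propagate as ``nan``; the batch never aborts.
    """
    pairs = sample_array_pairs(matrix.n_arrays, n_pairs=n_pairs, seed=seed)
    records: list[ConsistencyRecord] = []
    for collection in collections:
        for s in collection.sets:
            records.append(
                evaluate_set(
                    s,
                    matrix,
                    pairs,
                    max_genes=max_genes,
                    seed=derive_seed(seed, s.set_id),
                )
            )
    return records
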