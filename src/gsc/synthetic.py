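"""Synthetic expression compendia with known consistency structure.

Real evaluations of gene-set consistency need thousands of arrays and
live annotation databases; the generator here builds small compendia
in which the ground truth is known exactly, so every pipeline stage is
testable end to end.

Each synthetic gene set follows a single-factor Gaussian model: on
array *a*, member gene *i* has

    g_i(a) = mu_i + lambda * f_s(a) + eps_i(a)

with one latent factor f_s per set (standard normal across arrays),
loading ``lambda`` shared by the set's members, and independent noise
eps with standard deviation sigma.  The expected pairwise Pearson
correlation between two members is then exactly

    rho = lambda^2 / (lambda^2 + sigma^2)

so a target within-set correlation rho in [0, 1) fixes the loading as
``lambda = sigma * sqrt(rho / (1 - rho))`` — an analytic oracle for the
correlation metrics.  Per-gene baselines mu_i combine a per-set level
(SD ``baseline_mean_spread`` around a grand log2 level) with a
per-gene offset (SD ``offset_spread``); the offsets raise the
absolute-expression spread without touching correlations, which is
how a co-regulated set with heterogeneous expression levels looks.
Background genes are independent noise around their own baselines.
Optionally, noise can be Student-t distributed (heavy tails) and
array groups can receive a global mean shift (a condition effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

#: Grand mean log2 expression level (typical RMA output is centred ~7).
GRAND_MEAN = 7.0


@dataclass(frozen=True)
class SourceConfig:
    """Generative parameters for one synthetic gene-set source.

    ``within_set_correlation`` is the target expected pairwise Pearson
    correlation rho for members of each set; ``size_range`` bounds the
    (uniform) set sizes; ``offset_spread`` is the SD of per-gene level
    offsets within a set; ``noise_df`` switches noise from Gaussian to
    Student-t with that many degrees of freedom (heavy tails).
    """

    label: str
    n_sets: int
    size_range: tuple[int, int] = (5, 20)
    within_set_correlation: float = 0.5
    baseline_mean_spread: float = 1.5
    baseline_sd: float = 0.5
    offset_spread: float = 1.0
    noise_df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_set_correlation < 1.0:
            raise ValueError(
                f"within_set_correlation must be in [0, 1), got "
                f"{self.within_set_correlation}"
            )
        if self.n_sets < 1:
            raise ValueError("n_sets must be positive")
        lo, hi = self.size_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid size_range {self.size_range}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic compendium."""

    n_arrays: int = 40
    n_background_genes: int = 200
    sources: tuple[SourceConfig, ...] = (
        SourceConfig(label="OPERON_LIKE", n_sets=30, size_range=(2, 8),
                     within_set_correlation=0.7, offset_spread=0.6),
        SourceConfig(label="PATH_LIKE", n_sets=30, size_range=(3, 12),
                     within_set_correlation=0.5, offset_spread=0.8),
        SourceConfig(label="GO_LIKE", n_sets=30, size_range=(5, 40),
                     within_set_correlation=0.3, offset_spread=1.0),
    )
    condition_groups: int = 1
    condition_effect: float = 0.0
    organism: str = "synthetic_organism"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.n_arrays < 3:
            raise ValueError(f"n_arrays must be >= 3, got {self.n_arrays}")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    target_rho: dict[str, float]       # set_id -> rho
    members: dict[str, tuple[str, ...]]  # set_id -> gene ids
    gene_mean: dict[str, float]        # gene id -> mu_i
    gene_loading: dict[str, float]     # gene id -> lambda (0 for background)
    seed: int


def _noise(rng: np.random.Generator, shape, sd: float, df: float | None) -> np.ndarray:
    if df is None:
        return rng.normal(0.0, sd, size=shape)
    # Student-t scaled to variance sd^2 (requires df > 2).
    scale = sd / math.sqrt(df / (df - 2.0))
    return scale * rng.standard_t(df, size=shape)


def generate(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[GeneSetCollection], GroundTruth]:
    """Generate a compendium, one collection per source, and its truth.

    Deterministic under ``config.seed``.  Gene identifiers are
    ``<source>_s<set>_g<k>`` for set members and ``bg_<k>`` for
    background genes; array identifiers are ``arr_<k>``.
    """
    rng = np.random.default_rng(config.seed)
    P = config.n_arrays
    array_ids = [f"arr_{k:04d}" for k in range(P)]

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    collections: list[GeneSetCollection] = []
    target_rho: dict[str, float] = {}
    members: dict[str, tuple[str, ...]] = {}
    gene_mean: dict[str, float] = {}
    gene_loading: dict[str, float] = {}

    # optional condition structure: equal-size array groups with mean shifts
    shift = np.zeros(P)
    if config.condition_groups > 1 and config.condition_effect != 0.0:
        group = np.arange(P) % config.condition_groups
        group_shift = rng.normal(0.0, config.condition_effect, size=config.condition_groups)
        shift = group_shift[group]

    for src in config.sources:
        rho = src.within_set_correlation
        sigma = src.baseline_sd
        lam = sigma * math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
        sets = []
        for s_idx in range(src.n_sets):
            set_id = f"{src.label}_s{s_idx:04d}"
            n = int(rng.integers(src.size_range[0], src.size_range[1] + 1))
            factor = rng.normal(0.0, 1.0, size=P)
            set_level = GRAND_MEAN + rng.normal(0.0, src.baseline_mean_spread)
            ids = []
            for g_idx in range(n):
                gid = f"{src.label}_s{s_idx:04d}_g{g_idx:03d}"
                mu = set_level + rng.normal(0.0, src.offset_spread)
                profile = mu + lam * factor + _noise(rng, P, sigma, src.noise_df) + shift
                gene_ids.append(gid)
                gene_rows.append(profile)
                ids.append(gid)
                gene_mean[gid] = mu
                gene_loading[gid] = lam
            sets.append(GeneSet(set_id=set_id, genes=frozenset(ids), source=src.label))
            target_rho[set_id] = rho
            members[set_id] = tuple(ids)
        collections.append(
            GeneSetCollection(organism=config.organism, source=src.label, sets=tuple(sets))
        )

    for b_idx in range(config.n_background_genes):
        gid = f"bg_{b_idx:05d}"
        mu = GRAND_MEAN + rng.normal(0.0, 1.5)
        profile = mu + rng.normal(0.0, 0.5, size=P) + shift
        gene_ids.append(gid)
        gene_rows.append(profile)
        gene_mean[gid] = mu
        gene_loading[gid] = 0.0

    data = pd.DataFrame(np.vstack(gene_rows), index=gene_ids, columns=array_ids)
    matrix = ExpressionMatrix(organism=config.organism, data=data)
    truth = GroundTruth(
        target_rho=target_rho,
        members=members,
        gene_mean=gene_mean,
        gene_loading=gene_loading,
        seed=config.seed,
    )
    return matrix, collections, truth


def make_overlapping_collection(
    base: GeneSetCollection, overlap_fraction: float, seed: int = 0
) -> GeneSetCollection:
    """Rewire a collection so a target fraction of its genes sit in >= 2 sets.

    Picks the requested fraction of the collection's genes (among those
    currently in exactly one set) and adds each to one other randomly
    chosen set.  With fraction 0 the collection is returned with its
    original memberships; with fraction 1 every gene ends up shared.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    if len(base.sets) < 2:
        raise ValueError("need at least 2 sets to create overlap")
    rng = np.random.default_rng(seed)
    membership = {s.set_id: set(s.genes) for s in base.sets}
    home: dict[str, str] = {}
    for s in base.sets:
        for g in s.genes:
            home.setdefault(g, s.set_id)
    singletons = sorted(g for g in home if sum(g in m for m in membership.values()) == 1)
    n_target = int(round(overlap_fraction * len(home)))
    chosen = rng.choice(len(singletons), size=min(n_target, len(singletons)), replace=False)
    set_ids = sorted(membership)
    for i in chosen:
        g = singletons[i]
        others = [sid for sid in set_ids if sid != home[g]]
        membership[others[rng.integers(len(others))]].add(g)
    sets = tuple(
        GeneSet(set_id=s.set_id, genes=frozenset(membership[s.set_id]), source=s.source)
        for s in base.sets
    )
    return GeneSetCollection(organism=base.organism, source=base.source, sets=sets)


def write_truth(truth: GroundTruth, path) -> None:
    """Write per-set ground truth (target rho, members) as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\ttarget_rho\tn_genes\tmembers\n")
        for set_id in sorted(truth.target_rho):
            fh.write(
                f"{set_id}\t{truth.target_rho[set_id]!r}\t"
                f"{len(truth.members[set_id])}\t"
                + ",".join(truth.members[set_id])
                + "\n"
            )
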