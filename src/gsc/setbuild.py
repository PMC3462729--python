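"""Construct, filter and interrogate gene-set collections.

Gene sets arrive either ready-made (GMT) or as term->gene annotation
tables plus a term hierarchy.  For hierarchical vocabularies arranged
as a directed acyclic graph (the GO's three namespaces being the model
case), a term's gene set is its direct annotations plus the
annotations of every descendant term, so parent sets are supersets of
their children's.

Every collection is then filtered against the expression matrix: only
genes actually measured count, and a set must retain at least two
measured genes to be analysable (a standard deviation over one gene is
meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection


@dataclass(frozen=True)
class TermAnnotation:
    """Genes directly annotated to one term (pre-propagation)."""

    term_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))


@dataclass(frozen=True)
class TermHierarchy:
    """Child -> parent edges over term identifiers; must be acyclic."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        for child, parent in self.edges:
            if child == parent:
                raise ValueError(f"self-edge on term {child!r}")

    def graph(self) -> nx.DiGraph:
        """The hierarchy as a parent -> child digraph (top-down)."""
        g = nx.DiGraph()
        for child, parent in self.edges:
            g.add_edge(parent, child)
        return g


def read_annotations(path) -> list[TermAnnotation]:
    """Read a two-column TSV of (term_id, gene_id) direct annotations."""
    from .io_formats import FormatError, _data_lines

    by_term: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        by_term.setdefault(fields[0], set()).add(fields[1])
    return [TermAnnotation(t, frozenset(g)) for t, g in sorted(by_term.items())]


def read_hierarchy(path) -> TermHierarchy:
    """Read a two-column TSV edge list of (child_term, parent_term)."""
    from .io_formats import FormatError, _data_lines

    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        edges.append((fields[0], fields[1]))
    return TermHierarchy(edges=tuple(edges))


def propagate_hierarchy(
    annotations: Iterable[TermAnnotation],
    hierarchy: TermHierarchy,
    source: str,
    organism: str = "unknown",
) -> GeneSetCollection:
    """Build one gene set per term by descendant closure over the DAG.

    Each term's set is its direct annotations unioned with the direct
    annotations of every descendant term (child, grandchild, ...).
    Terms whose propagated set is empty are omitted, so the resulting
    collection counts only sets that exist.

    Raises
    ------
    ValueError
        If the hierarchy contains a cycle; the message lists one.
    """
    direct: dict[str, frozenset[str]] = {a.term_id: a.gene_ids for a in annotations}
    g = hierarchy.graph()  # parent -> child
    g.add_nodes_from(direct)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"term hierarchy contains a cycle: {path}")

    # One bottom-up pass in reverse topological order: a term's closure
    # is its direct genes plus the closures of its children.
    closure: dict[str, frozenset[str]] = {}
    for term in reversed(list(nx.topological_sort(g))):
        genes = set(direct.get(term, ()))
        for child in g.successors(term):
            genes |= closure[child]
        closure[term] = frozenset(genes)

    sets = tuple(
        GeneSet(set_id=term, genes=closure[term], source=source)
        for term in sorted(closure)
        if closure[term]
    )
    return GeneSetCollection(organism=organism, source=source, sets=sets)


def filter_to_matrix(
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    min_genes: int = 2,
) -> GeneSetCollection:
    """Intersect each set with the measured genes; drop small survivors.

    Sets retaining fewer than ``min_genes`` measured genes are removed
    (default 2 — the minimum on which any of the metrics is defined).
    The input collection is not modified.
    """
    if min_genes < 2:
        raise ValueError(f"min_genes must be >= 2, got {min_genes}")
    measured = set(matrix.gene_ids)
    kept = []
    for s in collection.sets:
        surviving = s.genes & measured
        if len(surviving) >= min_genes:
            kept.append(GeneSet(set_id=s.set_id, genes=frozenset(surviving), source=s.source))
    return GeneSetCollection(
        organism=collection.organism, source=collection.source, sets=tuple(kept)
    )


def restrict_to_universe(
    collection: GeneSetCollection,
    universe: set[str],
    trim: bool = False,
) -> GeneSetCollection:
    """Keep only sets that touch a gene universe.

    The default (membership mode) keeps every set with at least one
    gene in ``universe`` and leaves the surviving sets' contents
    untouched — the restriction changes which sets are analysed, not
    what they contain.  With ``trim=True`` surviving sets are instead
    intersected with the universe (and must retain >= 2 genes).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe = set(universe)
    kept = []
    for s in collection.sets:
        hit = s.genes & universe
        if not hit:
            continue
        if trim:
            if len(hit) >= 2:
                kept.append(GeneSet(set_id=s.set_id, genes=frozenset(hit), source=s.source))
        else:
            kept.append(s)
    return GeneSetCollection(
        organism=collection.organism, source=collection.source, sets=tuple(kept)
    )


@dataclass(frozen=True)
class OverlapReport:
    """Between-set overlap and genome coverage for one source.

    ``pct_multi_set``: of the genes appearing in at least one set, the
    percentage appearing in two or more.  ``pct_genome_covered``: the
    percentage of the organism's measured genes in at least one set.
    """

    source: str
    pct_multi_set: float
    pct_genome_covered: float

    def __post_init__(self) -> None:
        for name in ("pct_multi_set", "pct_genome_covered"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")


def overlap_report(
    collection: GeneSetCollection, organism_genes: set[str]
) -> OverlapReport:
    """Count multi-set membership and genome coverage for a collection.

    ``organism_genes`` is the measured-gene universe (the expression
    matrix's genes), the denominator for coverage.
    """
    counts: dict[str, int] = {}
    for s in collection.sets:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise ValueError("no gene appears in any set")
    in_any = len(counts)
    in_multi = sum(1 for c in counts.values() if c >= 2)
    covered = len(set(counts) & set(organism_genes))
    return OverlapReport(
        source=collection.source,
        pct_multi_set=100.0 * in_multi / in_any,
        pct_genome_covered=100.0 * covered / len(organism_genes),
    )
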