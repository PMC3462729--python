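"""File formats and core containers for expression data and gene sets.

The pipeline works on two kinds of inputs: a genes x arrays matrix of
log2-scale expression values (RMA-style output, one row per gene, one
column per array), and collections of named gene sets tagged with a
source label (GO_BP, KEGG, OPERON, ...).  Both travel as plain text:
the matrix as a TSV with a header row of array identifiers, the sets in
the community-standard GMT dialect.

All readers are strict: duplicate identifiers, non-numeric cells and
malformed lines raise immediately rather than being silently dropped.
The fixed TSV dialect is UTF-8, tab-separated, ``#``-prefixed comment
lines ignored, and ``NA`` as the missing-value token.  Expression
values are assumed to already be on the log2 scale; nothing here ever
re-logs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: Order of the seven consistency-metric columns in records files.
METRIC_NAMES = (
    "s_mean_diff",
    "s_median_diff",
    "s_mean_exp",
    "s_median_exp",
    "corr_mean",
    "corr_median",
    "pc1",
)


class FormatError(ValueError):
    """Malformed input file (duplicates, wrong field counts, bad cells)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression values, genes as rows, arrays as columns.

    Parameters
    ----------
    organism
        Free-text organism label; carried into every downstream record.
    data
        DataFrame indexed by gene identifier with one column per array
        identifier.  Values must be finite floats.
    """

    organism: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate array identifiers: {dups}")
        if self.data.shape[1] < 2:
            raise FormatError(
                f"need at least 2 arrays, got {self.data.shape[1]}"
            )
        if self.data.shape[0] < 2:
            raise FormatError(f"need at least 2 genes, got {self.data.shape[0]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, array {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.data.shape[1]

    def values_for(self, genes: Sequence[str]) -> np.ndarray:
        """Rows for ``genes`` (in the given order) as a float ndarray."""
        return self.data.loc[list(genes)].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered group of gene identifiers from one source."""

    set_id: str
    genes: frozenset[str]
    source: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        """Members in lexicographic order (the canonical iteration order)."""
        return sorted(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """All gene sets for one organism from one source."""

    organism: str
    source: str
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        if not self.source:
            raise ValueError("source label must be non-empty")
        seen: set[str] = set()
        for s in self.sets:
            if s.set_id in seen:
                raise FormatError(f"duplicate set identifier: {s.set_id!r}")
            seen.add(s.set_id)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out


@dataclass(frozen=True)
class ConsistencyRecord:
    """The seven consistency metrics for one gene set.

    Spread metrics (``s_*``) are in log2 expression units and are >= 0;
    ``corr_mean``/``corr_median`` are Pearson correlations in [-1, 1];
    ``pc1`` is the fraction of variance on the first principal
    component, in (0, 1].  An undefined metric (e.g. all gene pairs
    involving a zero-variance gene) is stored as ``nan`` and written as
    ``NA``.
    """

    organism: str
    source: str
    set_id: str
    n_genes: int
    s_mean_diff: float = math.nan
    s_median_diff: float = math.nan
    s_mean_exp: float = math.nan
    s_median_exp: float = math.nan
    corr_mean: float = math.nan
    corr_median: float = math.nan
    pc1: float = math.nan

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)


def _data_lines(path: Path) -> list[tuple[int, str]]:
    """(1-based line number, text) for non-comment, non-blank lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_expression_matrix(path: str | Path, organism: str | None = None) -> ExpressionMatrix:
    """Read a genes x arrays TSV into a validated :class:`ExpressionMatrix`.

    The first header field is ignored (a corner label such as
    ``gene_id``); remaining header fields are array identifiers.  Row
    and column order are preserved from the file.  If ``organism`` is
    not given it is taken from an ``# organism: <label>`` comment line
    (written by :func:`write_expression_matrix`), defaulting to
    ``"unknown"``.
    """
    path = Path(path)
    if organism is None:
        organism = "unknown"
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                if raw.startswith("# organism:"):
                    organism = raw.split(":", 1)[1].strip()
                elif not raw.startswith("#"):
                    break
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression matrix")
    header = lines[0][1].split("\t")
    array_ids = header[1:]
    if len(array_ids) < 2:
        raise FormatError(f"{path}: need at least 2 array columns, got {len(array_ids)}")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for arr_id, cell in zip(array_ids, fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} "
                    f"for gene {fields[0]!r}, array {arr_id!r}"
                ) from None
        rows.append(row)
    df = pd.DataFrame(rows, index=gene_ids, columns=array_ids, dtype=float)
    return ExpressionMatrix(organism=organism, data=df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (round-trip safe)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# organism: {matrix.organism}\n")
        fh.write("gene_id\t" + "\t".join(matrix.array_ids) + "\n")
        values = matrix.data.to_numpy()
        for gene, row in zip(matrix.gene_ids, values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gmt(path: str | Path, source: str, organism: str = "unknown") -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members.

    The description field is ignored.  A gene repeated within a line is
    deduplicated with a logged warning; a repeated set name is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        set_id = fields[0]
        genes = fields[2:]
        unique = set(genes)
        if len(unique) < len(genes):
            logger.warning(
                "%s:%d: set %r lists %d duplicate gene entries; deduplicated",
                path, lineno, set_id, len(genes) - len(unique),
            )
        sets.append(GeneSet(set_id=set_id, genes=frozenset(unique), source=source))
    return GeneSetCollection(organism=organism, source=source, sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format; the description column is ``.``."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, "."] + s.sorted_genes()) + "\n")


_RECORD_COLUMNS = ("organism", "source", "set_id", "n_genes") + METRIC_NAMES


def write_records(records: Iterable[ConsistencyRecord], path: str | Path) -> None:
    """Write consistency records as TSV, one row per gene set.

    Undefined metrics are written as ``NA``; finite values at full
    double precision so that a round-trip is exact.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RECORD_COLUMNS) + "\n")
        for r in records:
            cells = [r.organism, r.source, r.set_id, str(r.n_genes)]
            for name in METRIC_NAMES:
                v = r.metric(name)
                cells.append(NA_TOKEN if math.isnan(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")


def read_records(path: str | Path) -> list[ConsistencyRecord]:
    """Read a records TSV written by :func:`write_records`."""
    path = Path(path)
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty records file")
    header = lines[0][1].split("\t")
    if tuple(header) != _RECORD_COLUMNS:
        raise FormatError(f"{path}: unexpected records header {header}")
    out: list[ConsistencyRecord] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(_RECORD_COLUMNS):
            raise FormatError(
                f"{path}:{lineno}: expected {len(_RECORD_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        metrics = {
            name: (math.nan if cell == NA_TOKEN else float(cell))
            for name, cell in zip(METRIC_NAMES, fields[4:])
        }
        out.append(
            ConsistencyRecord(
                organism=fields[0],
                source=fields[1],
                set_id=fields[2],
                n_genes=int(fields[3]),
                **metrics,
            )
        )
    return out


def records_to_frame(records: Iterable[ConsistencyRecord]) -> pd.DataFrame:
    """Records as a DataFrame with one column per field (nan = undefined)."""
    records = list(records)
    return pd.DataFrame(
        {
            "organism": [r.organism for r in records],
            "source": [r.source for r in records],
            "set_id": [r.set_id for r in records],
            "n_genes": [r.n_genes for r in records],
            **{m: [r.metric(m) for r in records] for m in METRIC_NAMES},
        }
    )
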