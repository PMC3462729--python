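"""Gene-set consistency metrics for bacterial expression compendia.

Tools to score how consistently the genes of a set (an operon, a
pathway, a GO term's annotation closure, ...) behave across a
compendium of expression arrays, and to compare set *sources* on that
basis while controlling for set size and organism.
"""

from importlib import resources

import pandas as pd

from .io_formats import (
    METRIC_NAMES,
    ConsistencyRecord,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    read_records,
    records_to_frame,
    write_expression_matrix,
    write_gmt,
    write_records,
)
from .metrics import (
    PairSample,
    abs_spread,
    corr_summary,
    diff_spread,
    evaluate_collections,
    evaluate_set,
    pc1_fraction,
    sample_array_pairs,
)
from .setbuild import (
    OverlapReport,
    TermAnnotation,
    TermHierarchy,
    filter_to_matrix,
    overlap_report,
    propagate_hierarchy,
    restrict_to_universe,
)
from .compare import (
    HEADLINE_METRICS,
    MetricCorrelationTable,
    ModelFit,
    SizeProfile,
    SourceSummary,
    fit_nested_models,
    metric_correlations,
    organism_level_correlation,
    size_stratified_profile,
    size_variance_decomposition,
    summarize_by_source,
)
from .synthetic import (
    GroundTruth,
    SourceConfig,
    SyntheticConfig,
    generate,
    make_overlapping_collection,
)

__version__ = "0.1.0"


def load_organism_table() -> pd.DataFrame:
    """The bundled per-organism genome-size / array / set-count table."""
    with resources.files("gsc.data").joinpath("organism_set_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
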