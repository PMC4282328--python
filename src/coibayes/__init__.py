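"""coibayes: naive Bayesian k-mer classification of COI DNA barcodes.

Rank-flexible taxonomic assignment of insect COI barcode sequences with
bootstrap confidence, plus the machinery to curate reference databases,
cross-validate them, calibrate bootstrap-support cutoffs, and generate
synthetic benchmark data.
"""

from importlib.resources import files as _files

from .taxonomy import (
    DEFAULT_RANKS,
    Lineage,
    ReferenceRecord,
    TaxonomyError,
    TaxonomyTree,
    build_tree,
    parse_lineage_header,
    read_training_files,
    write_training_files,
)
from .reference import (
    Candidate,
    FilterPolicy,
    FilterReport,
    TrainingSet,
    build_training_set,
    enforce_rank_completeness,
    screen_record,
    singleton_census,
)
from .classifier import (
    Assignment,
    ClassifierParams,
    KmerModel,
    classify,
    extract_words,
    genus_log_score,
    summarize_to_rank,
    train,
)
from .evaluation import (
    ErrorRates,
    EvalOutcome,
    MatchCounts,
    accuracy_by_rank,
    classify_queries,
    complete_reference_test,
    coverage_summary,
    error_rates,
    load_described_table,
    loocv,
    match_table,
    misclassification_by_group,
    select_cutoffs,
    support_histogram,
)
from .simulate import (
    LabeledQuery,
    LabeledQuerySet,
    SimParams,
    Simulator,
    make_queries,
    sample_fragment,
    simulate_reference,
)

__version__ = "0.1.0"


def described_insect_taxa():
    """The bundled per-order described/represented insect taxon counts."""
    path = _files("coibayes").joinpath("data/insect_orders_described.tsv")
    return load_described_table(path)


__all__ = [
    "DEFAULT_RANKS",
    "Lineage",
    "ReferenceRecord",
    "TaxonomyError",
    "TaxonomyTree",
    "build_tree",
    "parse_lineage_header",
    "read_training_files",
    "write_training_files",
    "Candidate",
    "FilterPolicy",
    "FilterReport",
    "TrainingSet",
    "build_training_set",
    "enforce_rank_completeness",
    "screen_record",
    "singleton_census",
    "Assignment",
    "ClassifierParams",
    "KmerModel",
    "classify",
    "extract_words",
    "genus_log_score",
    "summarize_to_rank",
    "train",
    "ErrorRates",
    "EvalOutcome",
    "MatchCounts",
    "accuracy_by_rank",
    "classify_queries",
    "complete_reference_test",
    "coverage_summary",
    "error_rates",
    "load_described_table",
    "loocv",
    "match_table",
    "misclassification_by_group",
    "select_cutoffs",
    "support_histogram",
    "LabeledQuery",
    "LabeledQuerySet",
    "SimParams",
    "Simulator",
    "make_queries",
    "sample_fragment",
    "simulate_reference",
    "described_insect_taxa",
]
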