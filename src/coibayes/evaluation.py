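"""Classifier validation: cross-validation, error rates, cutoff calibration,
and database-coverage summaries.

Leave-one-out cross-validation (LOOCV) classifies every reference sequence
with its own counts removed from the model, simulating an incomplete
database; the complete-reference test classifies against the untouched
model, simulating a database known to contain an exact match.  From the
resulting outcomes this module computes:

* accuracy by rank among queries retained at a bootstrap-support cutoff
  (100 x correct / tested);
* type I error (misclassified yet retained at the cutoff) and type II error
  (correct yet withheld), both as percentages of all queries, so that
  type I + type II + correct-retained + wrong-withheld = 100;
* the smallest support cutoff on a 5-point grid reaching a target retained
  accuracy per (rank, query-length class);
* match / nonmatch / not-classified partitions against independent truth
  labels (the morphology-comparison layout);
* per-group misclassification rates and support histograms;
* coverage of described taxa by a reference set, per order and aggregate.

Singletons — taxa with exactly one reference sequence — can never be
classified correctly under LOOCV at the trained rank; accuracy and cutoff
summaries exclude them by default while error tables include them, and both
choices are parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import Assignment, ClassifierParams, KmerModel, classify, train
from .reference import TrainingSet
from .simulate import LabeledQuerySet, sample_fragment
from .taxonomy import Lineage

log = logging.getLogger(__name__)

#: Support cutoffs scanned when calibrating (5-point grid covers the
#: round cutoffs practitioners use).
CUTOFF_GRID: tuple[int, ...] = tuple(range(0, 101, 5))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EvalOutcome:
    """Truth, assignment, and per-rank correctness for one test query."""

    query_id: str
    truth: Lineage
    assignment: Assignment
    correct: Mapping[str, bool]  # rank -> assigned taxon equals truth taxon
    singleton: bool  # truth taxon at the trained rank had one sequence


def _outcome(
    query_id: str,
    truth: Lineage,
    assignment: Assignment,
    model: KmerModel,
    singleton: bool,
) -> EvalOutcome:
    correct = {}
    for rank in model.rank_order:
        t = truth.name_at(rank)
        if t is not None:
            correct[rank] = assignment.taxon_at(rank) == t
    return EvalOutcome(query_id, truth, assignment, correct, singleton)


def loocv(
    training_set: TrainingSet,
    params: ClassifierParams,
    fragment_length: int | None = None,
    seed: int = 0,
) -> list[EvalOutcome]:
    """Leave-one-out cross-validation, one outcome per training sequence.

    The held-out sequence's counts are removed from the model during its own
    classification and restored afterwards (exactly equivalent to a full
    retrain without it); a taxon emptied by the removal is excluded from the
    candidates for that query.  If `fragment_length` is given, the query is
    a single random contiguous window of that length; sequences shorter than
    the fragment are skipped with a warning.
    """
    model = train(training_set, params)
    seeds = np.random.SeedSequence(seed).spawn(len(training_set.records))
    outcomes: list[EvalOutcome] = []
    n_skipped = 0
    for record, ss in zip(training_set.records, seeds):
        rng = np.random.default_rng(ss)
        truth = record.lineage
        leaf = truth.name_at(model.trained_rank)
        singleton = model.M[leaf] == 1
        if fragment_length is not None and fragment_length > len(record.sequence):
            n_skipped += 1
            continue
        model.decrement(record)
        try:
            query = (
                record.sequence
                if fragment_length is None
                else sample_fragment(record.sequence, fragment_length, rng)
            )
            assignment = classify(model, query, params, rng=rng, query_id=record.id)
        finally:
            model.increment(record)
        outcomes.append(_outcome(record.id, truth, assignment, model, singleton))
    if n_skipped:
        log.warning(
            "loocv: skipped %d sequences shorter than fragment length %d",
            n_skipped,
            fragment_length,
        )
    return outcomes


def complete_reference_test(
    training_set: TrainingSet, params: ClassifierParams, seed: int = 0
) -> list[EvalOutcome]:
    """Classify every training sequence against the full, untouched model."""
    model = train(training_set, params)
    seeds = np.random.SeedSequence(seed).spawn(len(training_set.records))
    outcomes = []
    for record, ss in zip(training_set.records, seeds):
        rng = np.random.default_rng(ss)
        truth = record.lineage
        singleton = model.M[truth.name_at(model.trained_rank)] == 1
        assignment = classify(
            model, record.sequence, params, rng=rng, query_id=record.id
        )
        outcomes.append(_outcome(record.id, truth, assignment, model, singleton))
    return outcomes


def classify_queries(
    model: KmerModel,
    queries: LabeledQuerySet | Iterable,
    params: ClassifierParams,
    seed: int = 0,
) -> list[EvalOutcome]:
    """Classify an external labelled query set (e.g. a simulated field set)."""
    queries = list(queries)
    seeds = np.random.SeedSequence(seed).spawn(len(queries))
    outcomes = []
    for q, ss in zip(queries, seeds):
        rng = np.random.default_rng(ss)
        assignment = classify(model, q.sequence, params, rng=rng, query_id=q.id)
        leaf = q.lineage.name_at(model.trained_rank)
        singleton = model.M.get(leaf, 0) == 1
        outcomes.append(_outcome(q.id, q.lineage, assignment, model, singleton))
    return outcomes


# ---------------------------------------------------------------------------
# Summaries over outcomes


def _filtered(
    outcomes: Sequence[EvalOutcome], include_singletons: bool
) -> list[EvalOutcome]:
    if include_singletons:
        return list(outcomes)
    return [o for o in outcomes if not o.singleton]


def accuracy_by_rank(
    outcomes: Sequence[EvalOutcome],
    cutoff: float = 0,
    include_singletons: bool = False,
) -> dict[str, float | None]:
    """Percent correct among queries retained at `cutoff`, per rank.

    Retention is judged by the support at the summarization rank.  Ranks
    with no retained queries map to None.
    """
    pool = _filtered(outcomes, include_singletons)
    ranks: list[str] = []
    for o in pool:
        for r in o.correct:
            if r not in ranks:
                ranks.append(r)
    result: dict[str, float | None] = {}
    for rank in ranks:
        retained = [
            o
            for o in pool
            if rank in o.correct and o.assignment.support_at(rank) >= cutoff
        ]
        if not retained:
            result[rank] = None
        else:
            result[rank] = 100 * sum(o.correct[rank] for o in retained) / len(retained)
    return result


@dataclass(frozen=True)
class ErrorRates:
    """Percentages over all queries at one rank; the four sum to 100."""

    type_i: float  # wrong and retained at the cutoff (false positives)
    type_ii: float  # correct but below the cutoff (false negatives)
    correct_retained: float
    wrong_withheld: float
    cutoff: float
    include_singletons: bool


def error_rates(
    outcomes: Sequence[EvalOutcome],
    cutoff: float = 90,
    include_singletons: bool = True,
) -> dict[str, ErrorRates]:
    """Type I / type II error per rank at a support cutoff (default 90)."""
    pool = _filtered(outcomes, include_singletons)
    if not pool:
        raise ValueError("no outcomes to summarize")
    out: dict[str, ErrorRates] = {}
    ranks: list[str] = []
    for o in pool:
        for r in o.correct:
            if r not in ranks:
                ranks.append(r)
    for rank in ranks:
        sub = [o for o in pool if rank in o.correct]
        n = len(sub)
        t1 = sum(
            (not o.correct[rank]) and o.assignment.support_at(rank) >= cutoff
            for o in sub
        )
        t2 = sum(
            o.correct[rank] and o.assignment.support_at(rank) < cutoff for o in sub
        )
        cr = sum(
            o.correct[rank] and o.assignment.support_at(rank) >= cutoff for o in sub
        )
        ww = sum(
            (not o.correct[rank]) and o.assignment.support_at(rank) < cutoff
            for o in sub
        )
        out[rank] = ErrorRates(
            100 * t1 / n,
            100 * t2 / n,
            100 * cr / n,
            100 * ww / n,
            cutoff,
            include_singletons,
        )
    return out


def select_cutoffs(
    outcomes_by_length: Mapping[str, Sequence[EvalOutcome]],
    ranks: Sequence[str],
    target: float = 99.0,
    grid: Sequence[int] = CUTOFF_GRID,
    include_singletons: bool = False,
) -> dict[tuple[str, str], int | None]:
    """Smallest cutoff reaching `target` percent retained accuracy.

    Keys are (rank, length-class); None marks entries where no grid value
    qualifies (either accuracy never reaches the target or nothing remains
    retained).
    """
    table: dict[tuple[str, str], int | None] = {}
    for length_class, outcomes in outcomes_by_length.items():
        for rank in ranks:
            chosen: int | None = None
            prev_retained = math.inf
            for cutoff in grid:
                acc = accuracy_by_rank(outcomes, cutoff, include_singletons)
                retained = sum(
                    1
                    for o in _filtered(outcomes, include_singletons)
                    if rank in o.correct and o.assignment.support_at(rank) >= cutoff
                )
                assert retained <= prev_retained, "retained count must shrink"
                prev_retained = retained
                if retained >= 1 and acc.get(rank) is not None and acc[rank] >= target:
                    chosen = cutoff
                    break
            table[(rank, length_class)] = chosen
    return table


@dataclass(frozen=True)
class MatchCounts:
    """Partition of queries against independent truth labels at one rank."""

    match: int
    nonmatch: int
    not_classified: int

    @property
    def total(self) -> int:
        return self.match + self.nonmatch + self.not_classified

    def percent(self) -> tuple[float, float, float]:
        n = self.total
        return (100 * self.match / n, 100 * self.nonmatch / n, 100 * self.not_classified / n)


def match_table(
    outcomes: Sequence[EvalOutcome], rank: str, cutoff: float
) -> MatchCounts:
    """Match / nonmatch / not-classified counts at `rank` and `cutoff`.

    A query below the cutoff is "not classified"; otherwise it matches iff
    the assigned taxon at `rank` equals the truth taxon.
    """
    match = nonmatch = notclass = 0
    for o in outcomes:
        if o.assignment.support_at(rank) < cutoff:
            notclass += 1
        elif o.correct.get(rank, False):
            match += 1
        else:
            nonmatch += 1
    return MatchCounts(match, nonmatch, notclass)


def misclassification_by_group(
    outcomes: Sequence[EvalOutcome],
    grouping_rank: str = "order",
    cutoff: float = 0,
    include_singletons: bool = True,
) -> dict[str, tuple[int, float]]:
    """Per-group (n sequences, percent misclassified retained at `cutoff`).

    Queries are grouped by their *true* taxon at `grouping_rank`;
    misclassification is judged at the trained (leaf) rank.
    """
    pool = _filtered(outcomes, include_singletons)
    if not pool:
        raise ValueError("no outcomes to summarize")
    leaf_rank = pool[0].assignment.lineage.ranks[-1]
    groups: dict[str, list[EvalOutcome]] = {}
    for o in pool:
        g = o.truth.name_at(grouping_rank)
        groups.setdefault(g, []).append(o)
    out = {}
    for g, members in sorted(groups.items()):
        wrong = sum(
            (not o.correct.get(leaf_rank, False))
            and o.assignment.support_at(leaf_rank) >= cutoff
            for o in members
        )
        out[g] = (len(members), 100 * wrong / len(members))
    return out


def support_histogram(
    assignments: Sequence[Assignment], rank: str, bin_width: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of queries per support bin at `rank`.

    Bins cover [0, 100] in `bin_width` steps with the last bin closed (a
    support of 100 lands in the terminal bin); proportions sum to 1.
    Returns (bin_edges, proportions).
    """
    if not assignments:
        raise ValueError("no assignments to bin")
    supports = np.array([a.support_at(rank) for a in assignments], dtype=float)
    edges = np.arange(0, 100 + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(supports, bins=edges)
    return edges, counts / len(supports)


# ---------------------------------------------------------------------------
# Coverage of described taxa

COVERAGE_COLUMNS = (
    "families_described",
    "families_represented",
    "genera_described",
    "genera_represented",
)


def count_represented(training_set: TrainingSet, rank: str) -> dict[str, int]:
    """Unique named taxa at `rank` per order in a training set."""
    out: dict[str, set[str]] = {}
    for rec in training_set.records:
        order = rec.lineage.name_at("order")
        name = rec.lineage.name_at(rank)
        if order is None or name is None:
            continue
        out.setdefault(order, set()).add(name)
    return {k: len(v) for k, v in out.items()}


def coverage_summary(
    described: pd.DataFrame, training_set: TrainingSet | None = None
) -> pd.DataFrame:
    """Percent of described taxa represented in a reference set, per order.

    `described` is indexed by order with columns ``families_described``,
    ``genera_described`` (NaN where the literature offers no estimate) and,
    unless `training_set` is given, ``families_represented`` /
    ``genera_represented``.  Per-order percentages are rounded half-up.
    The "Total" row is the ratio of column sums, with described sums taken
    over orders that have an estimate while represented sums cover all
    orders; the "Average" row is the mean of per-order (unrounded)
    percentages over orders with estimates.
    """
    df = described.copy()
    if training_set is not None:
        fam = count_represented(training_set, "family")
        gen = count_represented(training_set, "genus")
        df["families_represented"] = [fam.get(o, 0) for o in df.index]
        df["genera_represented"] = [gen.get(o, 0) for o in df.index]
    for col in COVERAGE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    rows = {}
    for group in ("families", "genera"):
        desc = df[f"{group}_described"]
        rep = df[f"{group}_represented"]
        if (desc == 0).any():
            bad = df.index[desc == 0].tolist()
            raise ValueError(f"no described estimate (zero) for {bad}; use NaN")
        pct = 100 * rep / desc  # NaN where described is NaN
        known = desc.notna()
        rows[f"{group}_pct"] = pct.map(
            lambda x: _round_half_up(x) if pd.notna(x) else pd.NA
        )
        rows[f"{group}_total"] = (
            int(desc[known].sum()),
            int(rep.sum()),
            _round_half_up(100 * rep.sum() / desc[known].sum()),
        )
        rows[f"{group}_avg"] = (
            _round_half_up(desc[known].mean()),
            _round_half_up(rep.mean()),
            _round_half_up(pct[known].mean()),
        )
    out = pd.DataFrame(index=list(df.index) + ["Total", "Average"])
    for group in ("families", "genera"):
        desc = df[f"{group}_described"]
        rep = df[f"{group}_represented"]
        tot = rows[f"{group}_total"]
        avg = rows[f"{group}_avg"]
        out[f"{group}_described"] = list(desc) + [tot[0], avg[0]]
        out[f"{group}_represented"] = list(rep) + [tot[1], avg[1]]
        out[f"{group}_pct"] = list(rows[f"{group}_pct"]) + [tot[2], avg[2]]
    return out


def load_described_table(path) -> pd.DataFrame:
    """Read a described-taxa TSV (order, counts; blank or '?' = unknown)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["?", ""])
    df = df.set_index("order")
    return df
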