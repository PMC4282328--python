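"""Naive Bayesian k-mer classifier with bootstrap confidence.

A query sequence is decomposed into all overlapping words of length k
(default 8).  Training counts, per reference sequence, which words each
genus-level (or family-level) taxon contains.  With N training sequences,
n(w) of which contain word w, and M(G) sequences in taxon G, m(w, G) of
which contain w, the score of G for a query word set is

    score(G) = sum_w log P(w | G),
    P(w | G) = (m(w, G) + Pi(w)) / (M(G) + 1),
    Pi(w)    = (n(w) + 0.5) / (N + 1),

the word prior Pi(w) acting as a smoothing floor so no score is ever
-infinity.  The taxon with the highest score wins; its full lineage is
reported.  Confidence comes from bootstrap resampling: each of 100 trials
redraws one eighth of the query's words (with replacement, from the word
multiset) and re-runs the argmax; the support of a taxon at any rank is the
percentage of trials whose winner's lineage passes through it, so support
never decreases toward the root.

Both orientations of the query are scored by default and the better one
used, since barcode reads arrive in either strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .reference import TrainingSet
from .taxonomy import Lineage, ReferenceRecord

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_RC)[::-1]


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the classifier.

    k=8 and 100 bootstrap trials over 1/8 of the query's words are the
    standard settings for barcode-scale classification.
    """

    k: int = 8
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.125
    seed: int = 0
    check_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must be in (0, 1]")


class QueryTooShortError(ValueError):
    pass


def extract_words(sequence: str, k: int) -> tuple[list[str], set[str], int]:
    """All overlapping k-words of `sequence`.

    Returns (multiset as a list in sequence order, deduplicated set, number
    of windows dropped for containing a non-ACGT character).  A sequence of
    length L yields L - k + 1 windows before dropping.
    """
    L = len(sequence)
    if L < k:
        raise QueryTooShortError(f"query of length {L} is shorter than k={k}")
    words: list[str] = []
    dropped = 0
    for i in range(L - k + 1):
        w = sequence[i : i + k]
        if set(w) <= _VALID:
            words.append(w)
        else:
            dropped += 1
    return words, set(words), dropped


class KmerModel:
    """Word-containment counts per taxon, supporting decremental updates.

    Counts record *presence* of a word in a sequence, not occurrences, so
    m(w, G) <= M(G) always holds.  ``decrement``/``increment`` remove and
    restore one record's contribution, which makes leave-one-out
    cross-validation exact without retraining.
    """

    def __init__(self, k: int, trained_rank: str, rank_order: Sequence[str]):
        self.k = k
        self.trained_rank = trained_rank
        self.rank_order = tuple(rank_order)  # root -> trained rank
        self.N = 0
        self.n: dict[str, int] = {}
        self.M: dict[str, int] = {}
        self.m: dict[str, dict[str, int]] = {}
        self.lineages: dict[str, Lineage] = {}

    # -- training ----------------------------------------------------------

    def _leaf(self, record: ReferenceRecord) -> str:
        name = record.lineage.name_at(self.trained_rank)
        if name is None:
            raise ValueError(
                f"record {record.id!r} lacks a taxon at rank {self.trained_rank!r}"
            )
        return name

    def add_record(self, record: ReferenceRecord) -> None:
        leaf = self._leaf(record)
        lineage = record.lineage.truncate(self.trained_rank)
        if leaf in self.lineages and self.lineages[leaf] != lineage:
            raise ValueError(
                f"taxon {leaf!r} appears with two different lineages; "
                "leaf names must be unambiguous"
            )
        _, word_set, _ = extract_words(record.sequence, self.k)
        self.N += 1
        self.lineages.setdefault(leaf, lineage)
        self.M[leaf] = self.M.get(leaf, 0) + 1
        mG = self.m.setdefault(leaf, {})
        for w in word_set:
            self.n[w] = self.n.get(w, 0) + 1
            mG[w] = mG.get(w, 0) + 1

    def decrement(self, record: ReferenceRecord) -> None:
        """Remove one record's counts (for leave-one-out testing)."""
        leaf = self._leaf(record)
        _, word_set, _ = extract_words(record.sequence, self.k)
        self.N -= 1
        self.M[leaf] -= 1
        mG = self.m[leaf]
        for w in word_set:
            self.n[w] -= 1
            mG[w] -= 1

    def increment(self, record: ReferenceRecord) -> None:
        """Restore a previously decremented record."""
        leaf = self._leaf(record)
        _, word_set, _ = extract_words(record.sequence, self.k)
        self.N += 1
        self.M[leaf] += 1
        mG = self.m[leaf]
        for w in word_set:
            self.n[w] += 1
            mG[w] += 1

    # -- scoring -----------------------------------------------------------

    def genera(self) -> list[str]:
        """Active candidate taxa (≥1 sequence), lexicographically sorted."""
        return sorted(g for g, cnt in self.M.items() if cnt > 0)

    def word_prior(self, word: str) -> float:
        return (self.n.get(word, 0) + 0.5) / (self.N + 1)

    def log_prob_matrix(
        self, words: Sequence[str], genera: Sequence[str]
    ) -> np.ndarray:
        """log P(w|G) for each (word, genus) pair, shape (len(words), len(genera))."""
        n_arr = np.array([self.n.get(w, 0) for w in words], dtype=np.float64)
        pi = (n_arr + 0.5) / (self.N + 1)
        out = np.empty((len(words), len(genera)), dtype=np.float64)
        for j, g in enumerate(genera):
            mG = self.m[g]
            m_arr = np.array([mG.get(w, 0) for w in words], dtype=np.float64)
            out[:, j] = np.log((m_arr + pi) / (self.M[g] + 1))
        return out


def train(training_set: TrainingSet, params: ClassifierParams) -> KmerModel:
    """Count word containment over the training set; deterministic."""
    if not training_set.records:
        raise ValueError("empty training set")
    rank_idx = None
    rank_order = []
    for rank in training_set.records[0].lineage.ranks:
        rank_order.append(rank)
        if rank == training_set.trained_rank:
            rank_idx = rank
            break
    if rank_idx is None:
        raise ValueError(
            f"trained rank {training_set.trained_rank!r} absent from lineages"
        )
    model = KmerModel(params.k, training_set.trained_rank, rank_order)
    for record in training_set.records:
        if len(record.sequence) < params.k:
            log.warning(
                "record %s shorter than k=%d; excluded from training",
                record.id,
                params.k,
            )
            continue
        model.add_record(record)
    if model.N == 0:
        raise ValueError("no trainable records (all shorter than k)")
    return model


def genus_log_score(model: KmerModel, word_set: Sequence[str] | set[str], genus: str) -> float:
    """Sum of log P(w|G) over the (deduplicated) word set; finite always."""
    if genus not in model.M or model.M[genus] <= 0:
        raise KeyError(f"unknown or empty taxon {genus!r}")
    total = 0.0
    mG = model.m[genus]
    denom = model.M[genus] + 1
    for w in word_set:
        pi = model.word_prior(w)
        total += math.log((mG.get(w, 0) + pi) / denom)
    return total


@dataclass(frozen=True)
class Assignment:
    """Per-rank taxon calls with bootstrap support for one query."""

    query_id: str
    taxon: str  # winning leaf taxon at the trained rank
    lineage: Lineage  # winner's lineage, root -> trained rank
    support: Mapping[str, int]  # rank -> percent of bootstrap trials
    orientation: str  # "+" (as given) or "-" (reverse complement)
    singleton: bool  # winner represented by exactly one training sequence

    def taxon_at(self, rank: str) -> str:
        name = self.lineage.name_at(rank)
        if name is None:
            raise KeyError(f"rank {rank!r} not in assignment lineage")
        return name

    def support_at(self, rank: str) -> int:
        return self.support[rank]


def _best_score(scores: np.ndarray) -> float:
    return float(scores.max())


def classify(
    model: KmerModel,
    sequence: str,
    params: ClassifierParams,
    rng: np.random.Generator | None = None,
    query_id: str = "query",
) -> Assignment:
    """Assign `sequence` to the best-scoring taxon with bootstrap support.

    Orientation: both strands are scored (unless disabled) and the strand
    with the higher best score is used; ties keep the given orientation.
    Argmax ties break lexicographically by taxon name and are logged.
    """
    genera = model.genera()
    if not genera:
        raise ValueError("model has no taxa with training sequences")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    fwd_words, fwd_set, _ = extract_words(sequence, params.k)
    fwd_unique = sorted(fwd_set)
    fwd_mat = model.log_prob_matrix(fwd_unique, genera)
    fwd_scores = fwd_mat.sum(axis=0)
    words, unique, mat, scores, orientation = (
        fwd_words,
        fwd_unique,
        fwd_mat,
        fwd_scores,
        "+",
    )
    if params.check_reverse_complement:
        rev = reverse_complement(sequence)
        rev_words, rev_set, _ = extract_words(rev, params.k)
        rev_unique = sorted(rev_set)
        rev_mat = model.log_prob_matrix(rev_unique, genera)
        rev_scores = rev_mat.sum(axis=0)
        if _best_score(rev_scores) > _best_score(fwd_scores):
            words, unique, mat, scores, orientation = (
                rev_words,
                rev_unique,
                rev_mat,
                rev_scores,
                "-",
            )

    win_idx = int(np.argmax(scores))  # first max = lexicographic tie-break
    if np.sum(scores == scores[win_idx]) > 1:
        log.info(
            "query %s: argmax tie between %d taxa; lexicographic break -> %s",
            query_id,
            int(np.sum(scores == scores[win_idx])),
            genera[win_idx],
        )
    winner = genera[win_idx]
    winner_lineage = model.lineages[winner]

    # bootstrap: resample from the word multiset, re-run the argmax
    n_words = len(words)
    n_draw = math.ceil(n_words * params.bootstrap_fraction)
    trial_winners: np.ndarray
    if n_draw == 0 or n_words == 0:
        trial_winners = np.zeros(params.n_bootstrap, dtype=np.intp)
    else:
        row_of = {w: i for i, w in enumerate(unique)}
        word_rows = np.array([row_of[w] for w in words], dtype=np.intp)
        idx = rng.integers(0, n_words, size=(params.n_bootstrap, n_draw))
        trial_scores = mat[word_rows[idx]].sum(axis=1)  # (n_boot, n_genera)
        trial_winners = np.argmax(trial_scores, axis=1)

    # support at each rank of the winner's lineage: trials whose winner's
    # lineage passes through the same taxon
    support: dict[str, int] = {}
    for rank in model.rank_order:
        target = winner_lineage.name_at(rank)
        names = np.array(
            [model.lineages[genera[j]].name_at(rank) for j in range(len(genera))]
        )
        hits = int(np.sum(names[trial_winners] == target))
        support[rank] = round(100 * hits / params.n_bootstrap)

    return Assignment(
        query_id=query_id,
        taxon=winner,
        lineage=winner_lineage,
        support=support,
        orientation=orientation,
        singleton=model.M[winner] == 1,
    )


def summarize_to_rank(assignment: Assignment, rank: str, cutoff: float) -> str:
    """Taxon at `rank` if its support clears `cutoff`, else "unclassified".

    Raising the cutoff trades the number of assignments for their accuracy;
    summarizing to a more inclusive rank recovers assignments because
    support never decreases toward the root.
    """
    if assignment.support_at(rank) >= cutoff:
        return assignment.taxon_at(rank)
    return "unclassified"
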