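"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's scoring and cross-validation code
paths: posterior scores are enumerated in exact rational arithmetic (no
logs), and leave-one-out runs retrain the model from scratch for every
query instead of decrementing counts.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from coibayes import (
    ClassifierParams,
    TrainingSet,
    classify,
    train,
)
from coibayes.reference import TrainingSet as _TS
from coibayes.taxonomy import Lineage, ReferenceRecord, build_tree


def brute_force_argmax(
    records: list[tuple[str, str]], query: str, k: int
) -> list[str]:
    """Co-winning genera by exact rational posterior products, no logs.

    `records` is a list of (genus, sequence); the query's deduplicated word
    set is scored as prod_w (m(w,G) + Pi(w)) / (M(G) + 1) with
    Pi(w) = (n(w) + 0.5) / (N + 1).  Returns every genus achieving the
    exact maximum (usually one; floating-point scoring cannot distinguish
    members of an exact tie, so the caller checks membership).
    """

    def words_of(seq: str) -> set[str]:
        return {
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if set(seq[i : i + k]) <= set("ACGT")
        }

    N = len(records)
    genera = sorted({g for g, _ in records})
    M = {g: sum(1 for gg, _ in records if gg == g) for g in genera}
    seq_words = [(g, words_of(s)) for g, s in records]
    qwords = sorted(words_of(query))

    scores = {}
    for g in genera:
        score = Fraction(1)
        for w in qwords:
            n_w = sum(1 for _, ws in seq_words if w in ws)
            m_wg = sum(1 for gg, ws in seq_words if gg == g and w in ws)
            pi = Fraction(2 * n_w + 1, 2 * (N + 1))
            score *= (m_wg + pi) / (M[g] + 1)
        scores[g] = score
    best = max(scores.values())
    return [g for g in genera if scores[g] == best]


def toy_training_set(records: list[tuple[str, str]]) -> TrainingSet:
    """Genus-trained set from (genus, sequence) pairs; one family per genus."""
    refs = []
    for i, (genus, seq) in enumerate(records):
        lineage = Lineage(
            (
                ("kingdom", "Animalia"),
                ("phylum", "Arthropoda"),
                ("class", "Insecta"),
                ("order", f"Ord_{genus[0]}"),
                ("family", f"Fam_{genus}"),
                ("genus", genus),
            )
        )
        refs.append(ReferenceRecord(f"r{i}", seq, lineage))
    return _TS(tuple(refs), build_tree(refs), "genus")


def naive_retrain_loocv(
    training_set: TrainingSet, params: ClassifierParams, seed: int = 0
):
    """Full-retrain leave-one-out: rebuild the model without each record.

    Mirrors the decrement-based run exactly (same per-query seed stream), so
    outcomes must be identical when the decremental bookkeeping is correct.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(training_set.records))
    results = []
    for i, (record, ss) in enumerate(zip(training_set.records, seeds)):
        rest = [r for j, r in enumerate(training_set.records) if j != i]
        sub = _TS(tuple(rest), build_tree(rest), training_set.trained_rank)
        model = train(sub, params)
        rng = np.random.default_rng(ss)
        results.append(
            classify(model, record.sequence, params, rng=rng, query_id=record.id)
        )
    return results


def random_toy_model(rng: np.random.Generator, k: int = 4):
    """Random (records, query) pair: ≤4 genera, ≤6 sequences, ≤30 nt."""
    bases = "ACGT"
    n_genera = int(rng.integers(1, 5))
    genera = [f"G{chr(65 + i)}" for i in range(n_genera)]
    n_seqs = int(rng.integers(n_genera, 7))
    records = []
    for i in range(n_seqs):
        genus = genera[i] if i < n_genera else genera[int(rng.integers(0, n_genera))]
        L = int(rng.integers(k, 31))
        seq = "".join(bases[b] for b in rng.integers(0, 4, size=L))
        records.append((genus, seq))
    Lq = int(rng.integers(k, 31))
    query = "".join(bases[b] for b in rng.integers(0, 4, size=Lq))
    return records, query
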