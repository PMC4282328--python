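"""Cross-validation, error accounting, cutoff calibration, and coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coibayes as cb
from coibayes.classifier import Assignment
from coibayes.evaluation import EvalOutcome
from coibayes.taxonomy import Lineage
from oracles import naive_retrain_loocv, toy_training_set

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def _lineage(order="OrdA", family="FamA", genus="GenA"):
    return Lineage(
        (
            ("kingdom", "Animalia"),
            ("phylum", "Arthropoda"),
            ("class", "Insecta"),
            ("order", order),
            ("family", family),
            ("genus", genus),
        )
    )


def fake_outcome(correct=True, support=100, order="OrdA", genus="GenA", singleton=False, qid="q"):
    """Outcome with uniform support and all-rank correctness flags."""
    assigned = _lineage(order=order, genus=genus)
    truth = assigned if correct else _lineage(order="OrdZ", family="FamZ", genus="GenZ")
    a = Assignment(
        query_id=qid,
        taxon=assigned.leaf,
        lineage=assigned,
        support={r: support for r in RANKS},
        orientation="+",
        singleton=False,
    )
    flags = {r: truth.name_at(r) == assigned.name_at(r) for r in RANKS}
    # keep the inclusive ranks correct in the "wrong" case only below order
    return EvalOutcome(qid, truth, a, flags, singleton)


class TestLoocv:
    def test_twin_sequences_give_full_genus_accuracy(self):
        # every genus has two identical sequences: the left-out query still
        # has an exact twin in the reference
        recs = []
        for g, seq in [("GenA", "ACGTTGCA" * 8), ("GenB", "TTGGCCAA" * 8), ("GenC", "ACCTTGGA" * 8)]:
            recs += [(g, seq), (g, seq)]
        ts = toy_training_set(recs)
        outcomes = cb.loocv(ts, cb.ClassifierParams(seed=0), seed=0)
        acc = cb.accuracy_by_rank(outcomes, cutoff=0, include_singletons=True)
        assert acc["genus"] == 100

    def test_all_singletons_score_zero_at_genus(self):
        recs = [("GenA", "ACGTTGCA" * 8), ("GenB", "TTGGCCAA" * 8), ("GenC", "ACCTTGGA" * 8)]
        ts = toy_training_set(recs)
        outcomes = cb.loocv(ts, cb.ClassifierParams(seed=0), seed=0)
        assert all(o.singleton for o in outcomes)
        acc = cb.accuracy_by_rank(outcomes, cutoff=0, include_singletons=True)
        assert acc["genus"] == 0  # the true genus left with its only sequence

    def test_decrement_equals_full_retrain(self, training_set):
        # 12-sequence toy slice: decremental counts vs. scratch retrain
        recs = [(r.lineage.name_at("genus"), r.sequence) for r in training_set.records[:12]]
        ts = toy_training_set(recs)
        params = cb.ClassifierParams(seed=4)
        fast = cb.loocv(ts, params, seed=11)
        slow = naive_retrain_loocv(ts, params, seed=11)
        assert [o.assignment for o in fast] == slow

    def test_fragment_longer_than_sequence_is_skipped(self):
        recs = [("GenA", "ACGTTGCA" * 8), ("GenA", "ACGTTGCA" * 8), ("GenB", "TTGGCCAA" * 8)]
        ts = toy_training_set(recs)
        outcomes = cb.loocv(ts, cb.ClassifierParams(seed=0), fragment_length=100, seed=0)
        assert outcomes == []


class TestCompleteReference:
    def test_distinct_genera_fully_recovered(self):
        recs = [("GenA", "ACGTTGCA" * 8), ("GenB", "TTGGCCAA" * 8)]
        ts = toy_training_set(recs)
        outcomes = cb.complete_reference_test(ts, cb.ClassifierParams(seed=0))
        acc = cb.accuracy_by_rank(outcomes, include_singletons=True)
        assert all(v == 100 for v in acc.values())

    def test_identical_sequences_in_two_genera_resolve_lexicographically(self):
        seq = "ACGTTGCA" * 8
        ts = toy_training_set([("GenB", seq), ("GenA", seq)])
        outcomes = cb.complete_reference_test(ts, cb.ClassifierParams(seed=0))
        assert all(o.assignment.taxon == "GenA" for o in outcomes)
        # per the tie-break, the GenA record is correct, the GenB one is not
        assert [o.correct["genus"] for o in outcomes] == [False, True]

    def test_complete_reference_at_least_as_accurate_as_loocv(self, training_set, params):
        com = cb.complete_reference_test(training_set, params, seed=3)
        loo = cb.loocv(training_set, params, seed=3)
        acc_c = cb.accuracy_by_rank(com, include_singletons=True)
        acc_l = cb.accuracy_by_rank(loo, include_singletons=True)
        for rank in acc_c:
            assert acc_c[rank] >= acc_l[rank]


def test_accuracy_non_decreasing_toward_inclusive_ranks(training_set, params):
    """Correctness at genus implies correctness at family and order, so
    accuracy can only rise toward more inclusive ranks."""
    outcomes = cb.loocv(training_set, params, fragment_length=50, seed=2)
    acc = cb.accuracy_by_rank(outcomes, include_singletons=True)
    assert acc["order"] >= acc["family"] >= acc["genus"]


class TestAccuracyByRank:
    def test_direct_ratio(self):
        outcomes = [fake_outcome(correct=True) for _ in range(8)] + [
            fake_outcome(correct=False) for _ in range(2)
        ]
        acc = cb.accuracy_by_rank(outcomes, cutoff=0, include_singletons=True)
        assert acc["genus"] == 80

    def test_all_retained_correct(self):
        outcomes = [fake_outcome(correct=True, support=95) for _ in range(5)]
        acc = cb.accuracy_by_rank(outcomes, cutoff=90, include_singletons=True)
        assert acc["genus"] == 100

    def test_singleton_exclusion_changes_result(self):
        outcomes = [
            fake_outcome(correct=True),
            fake_outcome(correct=True),
            fake_outcome(correct=False, singleton=True),
        ]
        assert cb.accuracy_by_rank(outcomes, include_singletons=True)["genus"] == pytest.approx(200 / 3)
        assert cb.accuracy_by_rank(outcomes, include_singletons=False)["genus"] == 100


class TestErrorRates:
    def test_all_confident_and_correct(self):
        outcomes = [fake_outcome(correct=True, support=100) for _ in range(4)]
        e = cb.error_rates(outcomes, cutoff=90)["genus"]
        assert (e.type_i, e.type_ii) == (0, 0)

    def test_correct_but_unsupported_is_all_type_ii(self):
        outcomes = [fake_outcome(correct=True, support=50) for _ in range(4)]
        e = cb.error_rates(outcomes, cutoff=90)["genus"]
        assert e.type_ii == 100 and e.type_i == 0

    def test_hand_counted_mixture(self):
        outcomes = (
            [fake_outcome(correct=False, support=95)]
            + [fake_outcome(correct=True, support=50) for _ in range(2)]
            + [fake_outcome(correct=True, support=95) for _ in range(7)]
        )
        e = cb.error_rates(outcomes, cutoff=90)["genus"]
        assert e.type_i == 10 and e.type_ii == 20
        assert e.correct_retained == 70 and e.wrong_withheld == 0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    flags=st.lists(
        st.tuples(st.booleans(), st.integers(0, 100), st.booleans()),
        min_size=1,
        max_size=40,
    ),
    cutoff=st.integers(0, 100),
)
def test_error_partition_identity(flags, cutoff):
    """type I + type II + correct-retained + wrong-withheld is exactly 100%."""
    outcomes = [
        fake_outcome(correct=c, support=s, singleton=sg, qid=f"q{i}")
        for i, (c, s, sg) in enumerate(flags)
    ]
    for rank, e in cb.error_rates(outcomes, cutoff=cutoff).items():
        assert e.type_i + e.type_ii + e.correct_retained + e.wrong_withheld == pytest.approx(100)


class TestSelectCutoffs:
    def test_already_accurate_at_zero(self):
        outcomes = [fake_outcome(correct=True, support=s) for s in (10, 50, 100)]
        table = cb.select_cutoffs({"FULL": outcomes}, ["genus"], include_singletons=True)
        assert table[("genus", "FULL")] == 0

    def test_unreachable_target_is_none(self):
        outcomes = [fake_outcome(correct=False, support=100) for _ in range(3)]
        table = cb.select_cutoffs({"50": outcomes}, ["genus"], include_singletons=True)
        assert table[("genus", "50")] is None

    def test_smallest_qualifying_grid_value(self):
        # 98% accurate at cutoff 0, but perfectly accurate among support=100
        outcomes = [fake_outcome(correct=True, support=100) for _ in range(49)] + [
            fake_outcome(correct=False, support=60)
        ]
        table = cb.select_cutoffs({"FULL": outcomes}, ["genus"], include_singletons=True)
        # the wrong query drops out at the first grid value above 60
        assert table[("genus", "FULL")] == 65


class TestMatchTable:
    def test_all_exact_matches_at_cutoff_zero(self):
        outcomes = [fake_outcome(correct=True) for _ in range(5)]
        mt = cb.match_table(outcomes, "genus", 0)
        assert (mt.match, mt.nonmatch, mt.not_classified) == (5, 0, 0)

    def test_reference_lacking_true_order_yields_all_nonmatch(self):
        outcomes = [fake_outcome(correct=False, support=80) for _ in range(4)]
        mt = cb.match_table(outcomes, "order", 0)
        assert (mt.match, mt.nonmatch, mt.not_classified) == (0, 4, 0)

    def test_high_cutoff_converts_nonmatch_to_not_classified(self):
        outcomes = [fake_outcome(correct=False, support=80) for _ in range(4)]
        mt = cb.match_table(outcomes, "order", 90)
        assert (mt.match, mt.nonmatch, mt.not_classified) == (0, 0, 4)

    def test_partition_sums_to_n(self):
        outcomes = [fake_outcome(correct=bool(i % 2), support=10 * i) for i in range(10)]
        for cutoff in (0, 35, 90):
            assert cb.match_table(outcomes, "genus", cutoff).total == 10


class TestMisclassificationByGroup:
    def test_hand_counted_two_groups(self):
        outcomes = [
            fake_outcome(correct=True, order="OrdA", qid="a1"),
            fake_outcome(correct=False, order="OrdZ", qid="a2", support=95),
            fake_outcome(correct=True, order="OrdA", qid="a3"),
        ]
        # the wrong outcome's *truth* order is OrdZ
        res = cb.misclassification_by_group(outcomes, "order", cutoff=0)
        assert res["OrdA"] == (2, 0)
        assert res["OrdZ"] == (1, 100)

    def test_raising_cutoff_never_increases_misclassification_counts(self):
        outcomes = [
            fake_outcome(correct=bool(i % 3), support=10 * (i % 11), qid=f"q{i}")
            for i in range(30)
        ]
        prev = None
        for cutoff in (0, 30, 60, 90):
            res = cb.misclassification_by_group(outcomes, "order", cutoff=cutoff)
            counts = {g: n * pct / 100 for g, (n, pct) in res.items()}
            if prev is not None:
                assert all(counts[g] <= prev[g] + 1e-9 for g in counts)
            prev = counts


class TestSupportHistogram:
    def test_all_full_support_in_terminal_bin(self):
        assignments = [fake_outcome(support=100).assignment for _ in range(6)]
        _, props = cb.support_histogram(assignments, "genus")
        assert props[-1] == 1 and props.sum() == pytest.approx(1)

    def test_uniform_supports_spread_over_bins(self):
        assignments = [
            fake_outcome(support=s).assignment for s in range(0, 100, 5)
        ]
        _, props = cb.support_histogram(assignments, "genus")
        assert props.sum() == pytest.approx(1)
        assert np.all(props[:-1] == pytest.approx(0.1))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cb.support_histogram([], "genus")


@pytest.fixture(scope="module")
def table():
    return cb.coverage_summary(cb.described_insect_taxa())


class TestCoverageSummary:
    def test_per_order_percentages(self, table):
        assert table.loc["Archaeognatha", "genera_pct"] == 14
        assert table.loc["Blattodea", "families_pct"] == 71
        assert table.loc["Lepidoptera", "genera_pct"] == 22
        assert pd.isna(table.loc["Hemiptera", "genera_pct"])

    def test_total_row_is_ratio_of_sums(self, table):
        assert table.loc["Total", "families_described"] == 1031
        assert table.loc["Total", "families_represented"] == 633
        assert table.loc["Total", "families_pct"] == 61
        assert table.loc["Total", "genera_described"] == 72618
        assert table.loc["Total", "genera_represented"] == 8679
        assert table.loc["Total", "genera_pct"] == 12

    def test_average_row_is_mean_of_percentages(self, table):
        assert table.loc["Average", "families_pct"] == 65
        assert table.loc["Average", "genera_pct"] == 14
        assert table.loc["Average", "genera_described"] == 2905

    def test_zero_described_estimate_is_an_error(self):
        df = cb.described_insect_taxa().copy()
        df.loc["Odonata", "genera_described"] = 0
        with pytest.raises(ValueError, match="described"):
            cb.coverage_summary(df)

    def test_represented_counts_derivable_from_training_set(self, training_set):
        desc = pd.DataFrame(
            {
                "families_described": [4, 4],
                "genera_described": [10, 10],
            },
            index=pd.Index(["Ord01", "Ord02"], name="order"),
        )
        out = cb.coverage_summary(desc, training_set)
        # the simulated world has 2 families and 6 genera per order
        assert out.loc["Ord01", "families_represented"] == 2
        assert out.loc["Ord01", "genera_represented"] == 6
        assert out.loc["Ord01", "families_pct"] == 50
        assert out.loc["Ord01", "genera_pct"] == 60
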