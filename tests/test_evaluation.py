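"""Top-N retrieval metrics, decoy statistics, and printed-table aggregation."""

import itertools

import numpy as np
import pytest

from targetfish.evaluation import (
    aggregate_table,
    decoy_evaluate,
    evaluate,
    prf_at_n,
    success_rate,
)
from targetfish.pipeline import PredictionRecord


def ranked(names):
    """A ranked prediction list from target names (rank = position)."""
    return [
        PredictionRecord(
            target_name=name, pdb_id=f"P{i:03d}", target_class="c",
            t_ligand=0.5, t_binding=0.5, combined=0.5,
            docking_energy=None, predicted_activity=None, rank=i + 1,
        )
        for i, name in enumerate(names)
    ]


def brute_force_prf(names, truth, n):
    """Independent oracle for precision/recall/F1 at n."""
    matched = set()
    for name in names[:n]:
        if name in truth:
            matched.add(name)
    tp = len(matched)
    denom = min(n, len(names))
    precision = tp / denom if denom else 0.0
    recall = tp / len(truth)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return recall, precision, f1


class TestSuccessRate:
    def test_best_case(self):
        results = {"q": ranked(["T1", "T2"])}
        truth = {"q": {"T1"}}
        for n in (1, 5, 10):
            assert success_rate(results, truth, n) == 1.0

    def test_rank_thresholding(self):
        results = {
            "q1": ranked([f"X{i}" for i in range(2)] + ["TRUE1"] + [f"Y{i}" for i in range(9)]),
            "q2": ranked([f"Z{i}" for i in range(11)] + ["TRUE2"]),
        }
        truth = {"q1": {"TRUE1"}, "q2": {"TRUE2"}}
        assert success_rate(results, truth, 1) == 0.0
        assert success_rate(results, truth, 5) == 0.5
        assert success_rate(results, truth, 10) == 0.5

    def test_name_matching_normalized(self):
        results = {"q": ranked(["  HIV  protease "])}
        assert success_rate(results, {"q": {"hiv protease"}}, 1) == 1.0

    def test_query_without_truth_excluded(self):
        results = {"q1": ranked(["T1"]), "q2": ranked(["T2"])}
        assert success_rate(results, {"q1": {"T1"}}, 1) == 1.0

    def test_multi_target_any_match_counts(self):
        results = {"q": ranked(["B"])}
        assert success_rate(results, {"q": {"A", "B"}}, 1) == 1.0

    def test_non_decreasing_in_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            names = [f"T{i}" for i in rng.permutation(12)]
            results = {"q": ranked(names)}
            truth = {"q": {f"T{i}" for i in rng.choice(12, size=2, replace=False)}}
            rates = [success_rate(results, truth, n) for n in (1, 5, 10)]
            assert rates == sorted(rates)


class TestPrfAtN:
    def test_hand_case(self):
        # 2 true targets, 1 matched within top 10 of exactly 10 records
        names = ["TRUE1"] + [f"X{i}" for i in range(9)]
        recall, precision, f1 = prf_at_n({"q": ranked(names)}, {"q": {"TRUE1", "TRUE2"}}, 10)
        assert recall == pytest.approx(0.5)
        assert precision == pytest.approx(0.1)
        assert f1 == pytest.approx(2 * (0.1 * 0.5) / (0.1 + 0.5))

    def test_perfect_retrieval(self):
        truth = {"q": {"A", "B", "C"}}
        recall, precision, f1 = prf_at_n({"q": ranked(["A", "B", "C"])}, truth, 3)
        assert (recall, precision, f1) == (1.0, 1.0, 1.0)

    def test_total_miss(self):
        assert prf_at_n({"q": ranked(["X", "Y"])}, {"q": {"A"}}, 10) == (0.0, 0.0, 0.0)

    def test_zero_records_flagged_as_zero(self):
        assert prf_at_n({"q": []}, {"q": {"A"}}, 10) == (0.0, 0.0, 0.0)

    def test_duplicate_pdb_entries_count_once(self):
        # same target_name twice in top N contributes a single TP
        recall, precision, f1 = prf_at_n(
            {"q": ranked(["A", "A", "X", "Y"])}, {"q": {"A", "B"}}, 4
        )
        assert recall == pytest.approx(0.5)
        assert precision == pytest.approx(0.25)

    def test_f1_bounded_by_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            names = [f"T{i}" for i in rng.permutation(12)]
            truth = {f"T{i}" for i in rng.choice(12, size=rng.integers(1, 4), replace=False)}
            _, _, f1 = prf_at_n({"q": ranked(names)}, {"q": truth}, 10)
            assert 0.0 <= f1 <= 1.0

    def test_matches_brute_force_oracle(self):
        """Enumerate short ranked lists and truth sets against the oracle."""
        universe = ["A", "B", "C", "D", "E"]
        for length in (0, 1, 3, 5):
            for names in itertools.permutations(universe, length):
                for truth_size in (1, 2, 3):
                    for truth in itertools.combinations(universe[:4], truth_size):
                        for n in (1, 2, 5, 10):
                            got = prf_at_n({"q": ranked(list(names))},
                                           {"q": set(t.casefold() for t in truth)}, n)
                            want = brute_force_prf([s.casefold() for s in names],
                                                   {t.casefold() for t in truth}, n)
                            assert got == pytest.approx((want[0], want[1], want[2]))


class TestEvaluateReport:
    def test_report_aggregates(self):
        results = {
            "q1": ranked(["TRUE1", "X1", "X2"]),
            "q2": ranked(["Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "TRUE2"]),
        }
        truth = {"q1": {"TRUE1"}, "q2": {"TRUE2"}}
        report = evaluate(results, truth)
        assert report.success_rate_at == {1: 0.5, 5: 0.5, 10: 1.0}
        ranks = {o.query_id: o.first_true_rank for o in report.per_query}
        assert ranks == {"q1": 1, "q2": 7}
        assert 0.0 <= report.mean_f1_at_10 <= 1.0


class TestDecoyEvaluation:
    def test_counts_and_percentages(self):
        # 50 decoys for one target: intended target in top10 for 3 of them
        results = {}
        intended = {}
        for i in range(50):
            name = f"d{i}"
            intended[name] = "CA II"
            if i < 2:
                results[name] = ranked(["X1", "X2", "X3", "CA II"])  # rank 4: top5/top10
            elif i == 2:
                results[name] = ranked([f"X{j}" for j in range(8)] + ["CA II"])  # rank 9
            else:
                results[name] = ranked([f"X{j}" for j in range(12)])
        report = decoy_evaluate(results, intended)
        row = report.per_target["ca ii"]
        assert (row.top1, row.top5, row.top10) == (0, 2, 3)
        assert row.fail == 47
        assert row.top10_pct == 6 and row.fail_pct == 94

    def test_total_rejection(self):
        results = {f"d{i}": ranked(["X", "Y"]) for i in range(10)}
        report = decoy_evaluate(results, {f"d{i}": "T" for i in range(10)})
        assert report.per_target["t"].fail_pct == 100

    def test_counts_cumulative(self):
        rng = np.random.default_rng(7)
        results, intended = {}, {}
        for i in range(30):
            pos = int(rng.integers(0, 15))
            names = [f"X{j}" for j in range(12)]
            if pos < 12:
                names[pos] = "T"
            results[f"d{i}"] = ranked(names)
            intended[f"d{i}"] = "T"
        row = decoy_evaluate(results, intended).per_target["t"]
        assert row.top1 <= row.top5 <= row.top10
        assert row.fail == 30 - row.top10

    def test_missing_intended_target_rejected(self):
        with pytest.raises(ValueError):
            decoy_evaluate({"d0": ranked(["X"])}, {})


class TestAggregateTable:
    def test_count_conservation_and_percentages(self):
        per_class = {
            "a": {"top1": 3, "top10": 10, "fail": 0},
            "b": {"top1": 1, "top10": 5, "fail": 5},
        }
        out = aggregate_table(per_class)
        assert out["totals"] == {"top1": 4, "top10": 15, "fail": 5}
        assert out["n_ligands"] == 20
        assert out["percent"]["top10"] == 75

    def test_all_zero_counts(self):
        out = aggregate_table({"a": {"top1": 0, "top10": 0, "fail": 7}})
        assert out["percent"]["top10"] == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_table({"a": {"top1": 5, "top10": 3, "fail": 0}})
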