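"""Retrieval performance measures: top-N success, precision/recall/F1, decoys.

A prediction for a query is correct when a returned target_name matches any
known target of that query (name matching is case-insensitive after
whitespace normalisation).  For top-N evaluation the first N returned
records are the predicted positives and the query's known targets the
actual positives:

    recall    = TP / (TP + FN)
    precision = TP / predicted positives, with min(N, records returned)
                as the denominator so short lists never inflate precision
    F1        = 2 * precision * recall / (precision + recall)   (0 when both 0)

Duplicate PDB entries of one target_name within the top N count once toward
TP.  Aggregates are unweighted means over queries.  Decoy evaluation counts
how often a presumed-inactive molecule recovers its intended target within
the top 1/5/10 — the method's false-positive tendency.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pipeline import PredictionRecord

logger = logging.getLogger(__name__)

TOP_NS = (1, 5, 10)


def normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _ranked_names(records: Sequence[PredictionRecord]) -> list[str]:
    ranked = sorted((r for r in records if r.rank is not None), key=lambda r: r.rank)
    return [normalize_name(r.target_name) for r in ranked]


@dataclass
class QueryOutcome:
    query_id: str
    first_true_rank: int | None  # None = fail
    hits_at: dict[int, bool]
    precision_at: dict[int, float]
    recall_at: dict[int, float]
    f1_at: dict[int, float]


@dataclass
class EvaluationReport:
    """Per-query retrieval outcomes and their aggregates."""

    per_query: list[QueryOutcome]
    success_rate_at: dict[int, float]
    mean_precision_at_10: float
    mean_recall_at_10: float
    mean_f1_at_10: float

    def to_dict(self) -> dict:
        return {
            "success_rate": {str(n): v for n, v in self.success_rate_at.items()},
            "mean_precision_at_10": self.mean_precision_at_10,
            "mean_recall_at_10": self.mean_recall_at_10,
            "mean_f1_at_10": self.mean_f1_at_10,
            "n_queries": len(self.per_query),
        }


def _query_prf(names: list[str], truth: set[str], n: int) -> tuple[float, float, float, int]:
    top = names[:n]
    tp = len(truth & set(top))
    fn = len(truth) - tp
    predicted_positives = min(n, len(names))
    if predicted_positives == 0:
        logger.warning("query returned zero records; precision/recall/F1 = 0")
        return 0.0, 0.0, 0.0, tp
    precision = tp / predicted_positives
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1, tp


def _truth_sets(truth: Mapping[str, Sequence[str] | set[str]]) -> dict[str, set[str]]:
    out = {}
    for qid, names in truth.items():
        normalized = {normalize_name(n) for n in names}
        if not normalized:
            raise ValueError(f"empty truth set for query {qid!r}")
        out[qid] = normalized
    return out


def success_rate(
    results: Mapping[str, Sequence[PredictionRecord]],
    truth: Mapping[str, Sequence[str] | set[str]],
    n: int,
) -> float:
    """Fraction of queries with >= 1 true target within the top n records."""
    truth_sets = _truth_sets(truth)
    hits = 0
    evaluated = 0
    for qid, records in results.items():
        if qid not in truth_sets:
            logger.warning("query %s has no ground truth; excluded", qid)
            continue
        evaluated += 1
        names = _ranked_names(records)
        if truth_sets[qid] & set(names[:n]):
            hits += 1
    if evaluated == 0:
        raise ValueError("no evaluable queries")
    return hits / evaluated


def prf_at_n(
    results: Mapping[str, Sequence[PredictionRecord]],
    truth: Mapping[str, Sequence[str] | set[str]],
    n: int,
) -> tuple[float, float, float]:
    """Unweighted mean (recall, precision, F1) at top n over evaluable queries."""
    truth_sets = _truth_sets(truth)
    precisions, recalls, f1s = [], [], []
    for qid, records in results.items():
        if qid not in truth_sets:
            logger.warning("query %s has no ground truth; excluded", qid)
            continue
        p, r, f1, _ = _query_prf(_ranked_names(records), truth_sets[qid], n)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    if not precisions:
        raise ValueError("no evaluable queries")
    return float(np.mean(recalls)), float(np.mean(precisions)), float(np.mean(f1s))


def evaluate(
    results: Mapping[str, Sequence[PredictionRecord]],
    truth: Mapping[str, Sequence[str] | set[str]],
) -> EvaluationReport:
    """Full per-query report with success rates at top 1/5/10 and mean P/R/F1."""
    truth_sets = _truth_sets(truth)
    outcomes: list[QueryOutcome] = []
    for qid, records in results.items():
        if qid not in truth_sets:
            logger.warning("query %s has no ground truth; excluded", qid)
            continue
        names = _ranked_names(records)
        tset = truth_sets[qid]
        first = next((i + 1 for i, name in enumerate(names) if name in tset), None)
        hits, precs, recs, f1s = {}, {}, {}, {}
        for n in TOP_NS:
            p, r, f1, _ = _query_prf(names, tset, n)
            hits[n] = first is not None and first <= n
            precs[n], recs[n], f1s[n] = p, r, f1
        outcomes.append(
            QueryOutcome(
                query_id=qid, first_true_rank=first,
                hits_at=hits, precision_at=precs, recall_at=recs, f1_at=f1s,
            )
        )
    if not outcomes:
        raise ValueError("no evaluable queries")
    return EvaluationReport(
        per_query=outcomes,
        success_rate_at={n: float(np.mean([o.hits_at[n] for o in outcomes])) for n in TOP_NS},
        mean_precision_at_10=float(np.mean([o.precision_at[10] for o in outcomes])),
        mean_recall_at_10=float(np.mean([o.recall_at[10] for o in outcomes])),
        mean_f1_at_10=float(np.mean([o.f1_at[10] for o in outcomes])),
    )


# ---------------------------------------------------------------------------
# Decoy (negative-compound) evaluation
# ---------------------------------------------------------------------------

@dataclass
class DecoyTargetReport:
    """False-positive counts for one intended target over its decoy set."""

    intended_target: str
    n_decoys: int
    top1: int
    top5: int
    top10: int
    fail: int = field(init=False)
    top10_pct: int = field(init=False)
    fail_pct: int = field(init=False)

    def __post_init__(self):
        if not self.top1 <= self.top5 <= self.top10 <= self.n_decoys:
            raise ValueError("decoy counts must be cumulative and <= n_decoys")
        self.fail = self.n_decoys - self.top10
        self.top10_pct = round(100 * self.top10 / self.n_decoys)
        self.fail_pct = round(100 * self.fail / self.n_decoys)


@dataclass
class DecoyReport:
    per_target: dict[str, DecoyTargetReport]


def decoy_evaluate(
    decoy_results: Mapping[str, Sequence[PredictionRecord]],
    intended_target: Mapping[str, str],
) -> DecoyReport:
    """Count decoys whose intended target appears within the top 1/5/10."""
    counts: dict[str, dict[int, int]] = {}
    totals: dict[str, int] = {}
    for decoy_id, records in decoy_results.items():
        if decoy_id not in intended_target:
            raise ValueError(f"decoy {decoy_id!r} has no intended target")
        target = intended_target[decoy_id]
        key = normalize_name(target)
        totals[key] = totals.get(key, 0) + 1
        counts.setdefault(key, {n: 0 for n in TOP_NS})
        names = _ranked_names(records)
        for n in TOP_NS:
            if key in names[:n]:
                counts[key][n] += 1
    per_target = {
        key: DecoyTargetReport(
            intended_target=key, n_decoys=totals[key],
            top1=counts[key][1], top5=counts[key][5], top10=counts[key][10],
        )
        for key in sorted(totals)
    }
    return DecoyReport(per_target=per_target)


def aggregate_table(
    per_class_counts: Mapping[str, Mapping[str, int]]
) -> dict[str, int | dict[str, int]]:
    """Pool per-class top-N hit and fail counts into totals and percentages.

    Input per class: ``{"top1": .., "top10": .., "fail": ..}`` where
    top10 + fail equals the class ligand count.  Output: column-wise sums
    and pooled percentages over the union of ligands, rounded to nearest
    integer.
    """
    totals = {"top1": 0, "top10": 0, "fail": 0}
    n_ligands = 0
    for cls, counts in per_class_counts.items():
        size = counts["top10"] + counts["fail"]
        if counts["top1"] > counts["top10"] or counts["top10"] > size:
            raise ValueError(f"inconsistent counts for class {cls!r}")
        for key in totals:
            totals[key] += counts[key]
        n_ligands += size
    if n_ligands == 0:
        raise ValueError("no ligands in aggregate table")
    percentages = {key: round(100 * totals[key] / n_ligands) for key in totals}
    return {"totals": totals, "n_ligands": n_ligands, "percent": percentages}
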