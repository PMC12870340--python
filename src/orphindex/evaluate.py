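"""Evaluation of predicted concept sets against gold labels.

Metrics are micro-averaged over (document, concept) decision pairs:
precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean. Two
set-exactness metrics summarise per-document behaviour: CorrectRatio (share
of documents with at least one correct concept) and ExactRatio (share whose
predicted set equals the gold set). Ratio-type metrics carry Wilson score
confidence intervals, whose small-sample behaviour is preferable to the
normal approximation.

Gold sets are typically built by filtering an externally annotated corpus
(e.g. MeSH-labelled benchmarks) down to documents with at least one label
that maps into the disease taxonomy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy.stats import norm

from .taxonomy import Taxonomy, UnresolvableConceptError, resolve_concept

__all__ = [
    "GoldSet",
    "EvalReport",
    "filter_gold_by_taxonomy",
    "evaluate",
    "wilson_interval",
    "compare_engines",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldSet:
    """Gold labels: document id -> non-empty set of concept codes."""

    labels: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for doc_id, codes in self.labels.items():
            if not codes:
                raise ValueError(f"gold set for {doc_id!r} is empty")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EvalReport:
    """Counts, metrics and Wilson intervals for one prediction run."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    correct_ratio: float
    exact_ratio: float
    n_docs: int
    wilson_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    confidence: float = 0.95
    averaging: str = "micro"

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "correct_ratio": self.correct_ratio,
            "exact_ratio": self.exact_ratio,
            "n_docs": self.n_docs,
            "wilson_ci": {k: list(v) for k, v in self.wilson_ci.items()},
            "confidence": self.confidence,
            "averaging": self.averaging,
        }


def filter_gold_by_taxonomy(
    external_labels: Mapping[str, set[str]],
    mapping: Mapping[str, str],
    tax: Taxonomy,
    provenance: str = "",
) -> GoldSet:
    """Build a gold set from externally labelled documents.

    A document is retained iff at least one of its external-vocabulary labels
    maps (via ``mapping``) into the taxonomy; retained documents keep only
    the mapped codes, resolved through deprecation links. Labels mapping to
    terminal-deprecated codes are dropped.
    """
    if not mapping:
        raise ValueError("empty external-to-taxonomy mapping")
    kept: dict[str, frozenset[str]] = {}
    for doc_id, labels in external_labels.items():
        codes: set[str] = set()
        for label in labels:
            code = mapping.get(label)
            if code is None or code not in tax:
                continue
            try:
                codes.add(resolve_concept(tax, code))
            except UnresolvableConceptError:
                logger.debug("dropping terminal-deprecated gold code %s", code)
        if codes:
            kept[doc_id] = frozenset(codes)
    if not kept:
        logger.warning("no documents retained: no external label maps into the taxonomy")
    return GoldSet(labels=kept, provenance=provenance)


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    Uses z at the (1+confidence)/2 normal quantile; the interval always
    contains k/n and lies within [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    z = float(norm.ppf((1.0 + confidence) / 2.0))
    p = k / n
    z2n = z * z / n
    denom = 1.0 + z2n
    centre = (p + z2n / 2.0) / denom
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    # at the boundaries the interval endpoint is exactly the proportion
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return (lo, hi)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def evaluate(
    predictions: Mapping[str, set[str]],
    gold: GoldSet,
    confidence: float = 0.95,
    averaging: str = "micro",
) -> EvalReport:
    """Score predictions against a gold set.

    Counts are restricted to gold documents; a gold document missing from
    ``predictions`` is treated as an empty prediction (logged). Wilson
    intervals use pair-level n for precision (tp+fp) and recall (tp+fn) and
    document-level n for CorrectRatio/ExactRatio. ``averaging="example"``
    replaces micro P/R/F1 by per-document means.
    """
    if len(gold) == 0:
        raise ValueError("empty gold set")
    if averaging not in ("micro", "example"):
        raise ValueError(f"unknown averaging {averaging!r}")
    tp = fp = fn = 0
    n_correct = n_exact = 0
    per_doc_p: list[float] = []
    per_doc_r: list[float] = []
    for doc_id, gold_codes in gold.labels.items():
        if doc_id not in predictions:
            logger.debug("no prediction for gold document %s; treated as empty", doc_id)
        pred = set(predictions.get(doc_id, set()))
        inter = pred & gold_codes
        tp += len(inter)
        fp += len(pred - gold_codes)
        fn += len(gold_codes - pred)
        if inter:
            n_correct += 1
        if pred == set(gold_codes):
            n_exact += 1
        per_doc_p.append(_safe_div(len(inter), len(pred)))
        per_doc_r.append(len(inter) / len(gold_codes))
    n = len(gold)
    if averaging == "micro":
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
    else:
        precision = sum(per_doc_p) / n
        recall = sum(per_doc_r) / n
    f1 = _safe_div(2 * precision * recall, precision + recall)
    ci: dict[str, tuple[float, float]] = {}
    if averaging == "micro":
        if tp + fp > 0:
            ci["precision"] = wilson_interval(tp, tp + fp, confidence)
        ci["recall"] = wilson_interval(tp, tp + fn, confidence)
    ci["correct_ratio"] = wilson_interval(n_correct, n, confidence)
    ci["exact_ratio"] = wilson_interval(n_exact, n, confidence)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        correct_ratio=n_correct / n,
        exact_ratio=n_exact / n,
        n_docs=n,
        wilson_ci=ci,
        confidence=confidence,
        averaging=averaging,
    )


_METRICS = ("precision", "recall", "f1", "correct_ratio", "exact_ratio")


def compare_engines(report_a: EvalReport, report_b: EvalReport) -> pd.DataFrame:
    """Side-by-side metric table for two reports on the same gold set.

    Rows are metrics; columns hold each engine's point estimate, its Wilson
    interval where defined, and the delta (a minus b).
    """
    if report_a.n_docs != report_b.n_docs:
        raise ValueError(
            f"reports computed on different gold sets "
            f"(n_docs {report_a.n_docs} vs {report_b.n_docs})"
        )
    rows = []
    for metric in _METRICS:
        va = getattr(report_a, metric)
        vb = getattr(report_b, metric)
        rows.append(
            {
                "metric": metric,
                "a": va,
                "a_ci": report_a.wilson_ci.get(metric),
                "b": vb,
                "b_ci": report_b.wilson_ci.get(metric),
                "delta": va - vb,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
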