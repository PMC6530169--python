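"""Scoring of resolution output against gold annotations.

Classification semantics: an item is TRUE when the resolved accepted id
equals the gold accepted id, FALSE when a match disagrees with gold
(including matches on items whose gold is none), and NOT FOUND when the
decision was no-match.  Recall is TRUE / TOTAL, precision is
TRUE / (TRUE + FALSE), F is their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Optional, Sequence

from .alignment import ResolutionResult
from .taxa_io import TaxonomyTable, resolve_accepted


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvalCounts:
    true_count: int
    false_count: int
    not_found: int
    total: int

    def __post_init__(self) -> None:
        if min(self.true_count, self.false_count, self.not_found) < 0:
            raise EvaluationError("negative count")
        if self.true_count + self.false_count + self.not_found != self.total:
            raise EvaluationError("counts do not partition total")


@dataclass(frozen=True)
class EvalReport:
    counts: EvalCounts
    precision: float
    recall: float
    f_score: float
    precision_display: float
    recall_display: float
    f_score_display: float


def evaluate(
    results: Sequence[ResolutionResult],
    gold: Sequence[Optional[str]],
    table: TaxonomyTable,
) -> EvalCounts:
    """Classify each (result, gold) pair; comparison is on accepted ids
    after synonym resolution on both sides."""
    if len(results) != len(gold):
        raise EvaluationError(
            f"results ({len(results)}) and gold ({len(gold)}) differ in length"
        )
    t = f = nf = 0
    for res, g in zip(results, gold):
        gold_accepted = None
        if g is not None:
            gold_accepted = resolve_accepted(table, g).record_id
        if res.decision == "no_match":
            nf += 1
        elif gold_accepted is not None and res.accepted_id == gold_accepted:
            t += 1
        else:
            f += 1
    return EvalCounts(t, f, nf, len(results))


def _round_display(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def report_metrics(counts: EvalCounts, decimals: int = 2) -> EvalReport:
    """Precision/recall/F from counts, raw and display-rounded.

    Raw values keep full precision.  Display values use banker's rounding
    and the displayed F is the harmonic mean of the already-rounded P and
    R — the combination that reproduces published two-decimal tables of
    this kind (a raw-F display would flip several third-decimal cases).
    """
    denom = counts.true_count + counts.false_count
    precision = counts.true_count / denom if denom else 0.0
    recall = counts.true_count / counts.total if counts.total else 0.0
    f_score = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    p_disp = _round_display(precision, decimals)
    r_disp = _round_display(recall, decimals)
    f_disp = (
        _round_display(2 * p_disp * r_disp / (p_disp + r_disp), decimals)
        if p_disp + r_disp
        else 0.0
    )
    return EvalReport(
        counts=counts,
        precision=precision,
        recall=recall,
        f_score=f_score,
        precision_display=p_disp,
        recall_display=r_disp,
        f_score_display=f_disp,
    )


def format_report(report: EvalReport) -> str:
    """Human-readable confusion table plus metrics."""
    c = report.counts
    rows = [
        ("TRUE", c.true_count),
        ("FALSE", c.false_count),
        ("NOT FOUND", c.not_found),
        ("TOTAL", c.total),
        ("PRECISION", f"{report.precision_display:.2f}"),
        ("RECALL", f"{report.recall_display:.2f}"),
        ("F-SCORE", f"{report.f_score_display:.2f}"),
    ]
    width = max(len(label) for label, _ in rows)
    return "\n".join(f"{label:<{width}}  {value}" for label, value in rows)
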