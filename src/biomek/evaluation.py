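"""Per-value precision/recall/F evaluation, macro/micro averages and the
majority-value baseline.

Percentages are reported half-up to one decimal; all averaging happens on
unrounded intermediates (macro averages include zero-support values, i.e.
they divide by the full number of legal values of the dimension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .scheme import DIMENSIONS, VALUES


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (55.25 -> 55.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def f_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalRow:
    value: str
    gold: int
    predicted: int
    tp: int

    @property
    def precision(self) -> float:  # percent, unrounded
        return 100.0 * self.tp / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / self.gold if self.gold else 0.0

    @property
    def f(self) -> float:
        return f_score(self.precision, self.recall)

    def rounded(self) -> tuple[float, float, float]:
        return (
            round_half_up(self.recall),
            round_half_up(self.precision),
            round_half_up(self.f),
        )


@dataclass
class DimensionResult:
    dimension: str
    rows: dict[str, EvalRow] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(r.gold for r in self.rows.values())

    def macro(self) -> tuple[float, float, float]:
        """Unweighted mean of per-value R, P, F over all legal values."""
        values = VALUES[self.dimension]
        r = sum(self.rows[v].recall for v in values) / len(values)
        p = sum(self.rows[v].precision for v in values) / len(values)
        f = sum(self.rows[v].f for v in values) / len(values)
        return r, p, f

    def micro(self) -> tuple[float, float, float]:
        """Pooled counts; equals accuracy in the single-label setting."""
        tp = sum(r.tp for r in self.rows.values())
        gold = sum(r.gold for r in self.rows.values())
        pred = sum(r.predicted for r in self.rows.values())
        p = 100.0 * tp / pred if pred else 0.0
        r = 100.0 * tp / gold if gold else 0.0
        return r, p, f_score(p, r)

    def macro_rounded(self) -> tuple[float, float, float]:
        return tuple(round_half_up(x) for x in self.macro())

    def micro_rounded(self) -> tuple[float, float, float]:
        return tuple(round_half_up(x) for x in self.micro())


def prf(
    gold: Sequence[str], predicted: Sequence[str], dimension: str
) -> DimensionResult:
    """Per-value counts and scores for aligned gold/predicted labels."""
    if len(gold) != len(predicted):
        raise ValueError(
            f"{dimension}: gold/predicted length mismatch ({len(gold)} vs {len(predicted)})"
        )
    result = DimensionResult(dimension=dimension)
    for value in VALUES[dimension]:
        g = sum(1 for x in gold if x == value)
        p = sum(1 for x in predicted if x == value)
        tp = sum(1 for x, y in zip(gold, predicted) if x == y == value)
        result.rows[value] = EvalRow(value=value, gold=g, predicted=p, tp=tp)
    return result


def macro_micro(result: DimensionResult) -> dict[str, tuple[float, float, float]]:
    return {"macro": result.macro(), "micro": result.micro()}


def evaluate_counts(
    dimension: str, gold_counts: Mapping[str, int], predicted_value: str
) -> DimensionResult:
    """Evaluate an every-event-gets-``predicted_value`` assignment directly
    from per-value gold counts (no label lists needed)."""
    total = sum(gold_counts.values())
    result = DimensionResult(dimension=dimension)
    for value in VALUES[dimension]:
        g = gold_counts.get(value, 0)
        is_majority = value == predicted_value
        result.rows[value] = EvalRow(
            value=value,
            gold=g,
            predicted=total if is_majority else 0,
            tp=g if is_majority else 0,
        )
    return result


def majority_baseline(
    gold: Mapping[str, Sequence[str]] | None = None,
    counts: Mapping[str, Mapping[str, int]] | None = None,
    train: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, DimensionResult]:
    """Assign every event the most frequent value of each dimension.

    Accepts either per-dimension gold label sequences (``gold``) or
    per-dimension count tables (``counts``).  The majority value is taken
    from ``train`` when given, else from the evaluation gold itself.
    """
    if (gold is None) == (counts is None):
        raise ValueError("provide exactly one of gold or counts")
    out: dict[str, DimensionResult] = {}
    if counts is not None:
        for dim, table in counts.items():
            majority = max(VALUES[dim], key=lambda v: (table.get(v, 0),))
            out[dim] = evaluate_counts(dim, table, majority)
        return out
    for dim, labels in gold.items():
        source = train[dim] if train is not None else labels
        majority = max(VALUES[dim], key=lambda v: (list(source).count(v),))
        predicted = [majority] * len(labels)
        out[dim] = prf(labels, predicted, dim)
    return out


def format_report(
    results: Mapping[str, DimensionResult],
    baseline: Mapping[str, DimensionResult] | None = None,
) -> str:
    """Tab-separated table: value, gold count, R/P/F (and baseline R/P/F)."""

    def _fmt(t: tuple[float, float, float]) -> str:
        return " / ".join(f"{x:.1f}" for x in t)

    lines = ["Dimension\tValue\tCount\tR / P / F" + ("\tMajority (R / P / F)" if baseline else "")]
    for dim in DIMENSIONS:
        if dim not in results:
            continue
        res = results[dim]
        for value in VALUES[dim]:
            row = res.rows[value]
            cells = [dim, value, str(row.gold), _fmt(row.rounded())]
            if baseline:
                cells.append(_fmt(baseline[dim].rows[value].rounded()))
            lines.append("\t".join(cells))
        for name, fn in (("Macro Average", "macro_rounded"), ("Micro Average", "micro_rounded")):
            cells = [dim, name, str(res.n), _fmt(getattr(res, fn)())]
            if baseline:
                cells.append(_fmt(getattr(baseline[dim], fn)()))
            lines.append("\t".join(cells))
    return "".join(line + "\n" for line in lines)
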