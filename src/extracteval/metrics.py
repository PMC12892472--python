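"""Confusion tallies, performance metrics, and the sampling margin of error.

Per attribute, token/value-level outcomes are pooled into a confusion table
(TP, FP, TN, FN) from which precision TP/(TP+FP), recall TP/(TP+FN),
accuracy (TP+TN)/(TP+TN+FP+FN) and F1 (harmonic mean of precision and
recall) are computed.  Two summaries are offered: the macro average (the
unweighted arithmetic mean over attributes, including for F1) and the micro
average (metrics of the element-wise pooled confusion table).  Any metric
whose denominator is zero is reported as undefined rather than 0 or NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records_io import round_half_up

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "compute_metrics",
    "macro_average",
    "margin_of_error",
    "metric_table",
    "micro_average",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Non-negative TP/FP/TN/FN tallies at attribute or pooled level."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def support(self) -> int:
        """Number of manually extracted items: TP + FN."""
        return self.tp + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Precision/recall/accuracy/F1 as fractions; None marks undefined."""

    precision: float | None
    recall: float | None
    accuracy: float | None
    f1: float | None

    def as_percent(self, ndigits: int = 1) -> dict[str, float | None]:
        """Display form: percentages rounded half-up to ``ndigits``."""
        return {
            name: None if v is None else round_half_up(100.0 * v, ndigits)
            for name, v in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("accuracy", self.accuracy),
                ("f1", self.f1),
            )
        }


def _ratio(num: int | float, den: int | float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionTable) -> MetricSet:
    """All four metrics of one confusion table, full precision."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    accuracy = _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(precision, recall, accuracy, f1)


def macro_average(per_attribute: Sequence[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean of each metric over attributes.

    Macro-F1 is the mean of the per-attribute F1 values, not the harmonic
    mean of macro-precision and macro-recall.  Attributes where a metric is
    undefined are excluded from that metric's mean with a warning.
    """
    if not per_attribute:
        raise ValueError("macro_average needs at least one attribute")
    out: dict[str, float | None] = {}
    for name in ("precision", "recall", "accuracy", "f1"):
        values = [getattr(m, name) for m in per_attribute]
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            warnings.warn(
                f"macro_average: {len(values) - len(defined)} attribute(s) "
                f"with undefined {name} excluded",
                stacklevel=2,
            )
        out[name] = sum(defined) / len(defined) if defined else None
    if all(v is None for v in out.values()):
        raise ValueError("macro_average: every metric undefined on every attribute")
    return MetricSet(**out)


def micro_average(per_attribute: Iterable[ConfusionTable]) -> MetricSet:
    """Metrics of the element-wise sum of the confusion tables."""
    tables = list(per_attribute)
    if not tables:
        raise ValueError("micro_average needs at least one table")
    pooled = ConfusionTable()
    for t in tables:
        pooled = pooled + t
    return compute_metrics(pooled)


def margin_of_error(
    N: int, n: int, p: float = 0.5, z: float = 1.96
) -> float:
    """Finite-population margin of error for a sampled proportion.

    ``MOE = z * sqrt(p(1-p)) / sqrt((N-1) * n / (N-n))`` for a sample of
    ``n`` drawn from a population of ``N``; ``p=0.5`` is the conservative
    default and ``z=1.96`` the 95% critical value.
    """
    if not 0 < n < N:
        raise ValueError("need 0 < n < N")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return z * math.sqrt(p * (1.0 - p)) / math.sqrt((N - 1) * n / (N - n))


def metric_table(
    per_attribute: Mapping[str, ConfusionTable], ndigits: int = 1
) -> pd.DataFrame:
    """Per-attribute confusion + metric table with Total/Macro/Micro rows.

    Columns follow the reporting layout: attribute, number of manually
    extracted items (TP+FN), the four outcome tallies, then the four metrics
    as percentages rounded half-up to ``ndigits``.
    """
    if not per_attribute:
        raise ValueError("metric_table needs at least one attribute")
    rows = []
    metric_sets = {}
    for name, table in per_attribute.items():
        metric_sets[name] = compute_metrics(table)
        pct = metric_sets[name].as_percent(ndigits)
        rows.append(
            {
                "attribute": name,
                "manual_items": table.support,
                "TP": table.tp,
                "FP": table.fp,
                "FN": table.fn,
                "TN": table.tn,
                **pct,
            }
        )
    pooled = ConfusionTable()
    for t in per_attribute.values():
        pooled = pooled + t
    rows.append(
        {
            "attribute": "Total",
            "manual_items": pooled.support,
            "TP": pooled.tp,
            "FP": pooled.fp,
            "FN": pooled.fn,
            "TN": pooled.tn,
            "precision": None,
            "recall": None,
            "accuracy": None,
            "f1": None,
        }
    )
    macro = macro_average(list(metric_sets.values())).as_percent(ndigits)
    micro = micro_average(per_attribute.values()).as_percent(ndigits)
    for label, pct in (("Macro-average", macro), ("Micro-average", micro)):
        rows.append(
            {
                "attribute": label,
                "manual_items": None,
                "TP": None,
                "FP": None,
                "FN": None,
                "TN": None,
                **pct,
            }
        )
    return pd.DataFrame(rows)
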