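"""End-to-end evaluation of an automated extraction against the manual baseline.

For every article x attribute cell the two datasets are compared with the
matcher appropriate to the attribute kind — fuzzy token matching for term
attributes, ±0.01° matching for coordinates, year-level matching for dates —
and the outcomes are pooled into per-attribute confusion tables, the metric
table (with macro and micro rows), entry tallies, and suggested 2/1/0
agreement scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .agreement import AgreementSummary, suggest_agreement_score, summary_table
from .metrics import ConfusionTable, metric_table
from .normalization import NormalizationPolicy, normalize_cell
from .records_io import AttributeKind, Dataset, entry_table
from .term_matching import MatchOutcome, MatchPolicy, match_multisets
from .value_matching import (
    extract_years,
    match_coordinates,
    match_years,
    parse_coordinates,
)

__all__ = ["EvaluationResult", "evaluate_datasets"]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """Everything the evaluation computes, cell level upward."""

    per_cell: dict[tuple[str, str], MatchOutcome]
    confusion_by_attribute: dict[str, ConfusionTable]
    coordinate_parse_failures: list[tuple[str, str, str]] = field(default_factory=list)

    def pooled(self) -> ConfusionTable:
        total = ConfusionTable()
        for t in self.confusion_by_attribute.values():
            total = total + t
        return total

    def metric_table(self, ndigits: int = 1) -> pd.DataFrame:
        return metric_table(self.confusion_by_attribute, ndigits)

    def match_report(self) -> pd.DataFrame:
        """Long-format per-token report of every TP/FP/FN/TN decision."""
        rows = []
        for (article, attr), outcome in sorted(self.per_cell.items()):
            for m_tok, a_tok, sim in outcome.matched_pairs:
                rows.append((article, attr, m_tok, a_tok, sim, "TP"))
            for tok, n in sorted(outcome.fp_tokens.items()):
                rows.extend([(article, attr, "", tok, None, "FP")] * n)
            for tok, n in sorted(outcome.fn_tokens.items()):
                rows.extend([(article, attr, tok, "", None, "FN")] * n)
            if outcome.tn_flag:
                rows.append((article, attr, "", "", None, "TN"))
        return pd.DataFrame(
            rows,
            columns=[
                "article_id", "attribute", "manual_token", "auto_token",
                "similarity", "outcome",
            ],
        )

    def suggested_scores(self) -> dict[tuple[str, str], int]:
        return {
            key: suggest_agreement_score(outcome)
            for key, outcome in self.per_cell.items()
        }

    def suggested_agreement_table(self, ndigits: int = 1) -> pd.DataFrame:
        counts: dict[str, list[int]] = {}
        for (_, attr), score in self.suggested_scores().items():
            counts.setdefault(attr, [0, 0, 0])[score] += 1
        summaries = {
            attr: AgreementSummary(full=c[2], partial=c[1], disagree=c[0])
            for attr, c in counts.items()
        }
        return summary_table(summaries, ndigits)

    def summary(self) -> str:
        """Readable multi-line overview of the evaluation."""
        pooled = self.pooled()
        table = self.metric_table()
        lines = [
            "Extraction evaluation (automated vs. manual baseline)",
            f"  cells compared : {len(self.per_cell)}",
            f"  pooled counts  : TP={pooled.tp} FP={pooled.fp} "
            f"FN={pooled.fn} TN={pooled.tn}",
            f"  coordinate parse failures: {len(self.coordinate_parse_failures)}",
            "",
            table.to_string(index=False),
        ]
        return "\n".join(lines)


def evaluate_datasets(
    manual: Dataset,
    automated: Dataset,
    norm_policy: NormalizationPolicy | None = None,
    match_policy: MatchPolicy = MatchPolicy(),
    coordinate_tolerance: float = 0.01,
) -> EvaluationResult:
    """Compare two complete datasets cell by cell.

    Both datasets must cover the same article x attribute cells; a mismatch
    raises ``ValueError`` naming the missing cells.
    """
    norm_policy = norm_policy or NormalizationPolicy()
    keys_m = set(manual.records)
    keys_a = set(automated.records)
    if keys_m != keys_a:
        missing = sorted(keys_m ^ keys_a)
        raise ValueError(
            f"article/attribute cells differ between datasets; "
            f"first mismatches: {missing[:10]}"
        )

    per_cell: dict[tuple[str, str], MatchOutcome] = {}
    confusion: dict[str, ConfusionTable] = {
        attr: ConfusionTable() for attr in manual.attributes
    }
    parse_failures: list[tuple[str, str, str]] = []

    for key in sorted(keys_m):
        article, attr = key
        spec = manual.attributes[attr]
        rec_m = manual.records[key]
        rec_a = automated.records[key]
        both_none = rec_m.none_reported and rec_a.none_reported

        if spec.kind is AttributeKind.TERM:
            ms_m = normalize_cell(rec_m.values, norm_policy, stemmed=spec.stemmed)
            ms_a = normalize_cell(rec_a.values, norm_policy, stemmed=spec.stemmed)
            outcome = match_multisets(
                ms_m, ms_a, match_policy, both_none_reported=both_none
            )
        elif spec.kind is AttributeKind.COORDINATE:
            pairs_m, fail_m = parse_coordinates(rec_m.values)
            pairs_a, fail_a = parse_coordinates(rec_a.values)
            for raw in fail_m + fail_a:
                parse_failures.append((article, attr, raw))
            outcome = match_coordinates(
                pairs_m, pairs_a, coordinate_tolerance,
                both_none_reported=both_none,
            )
        else:
            outcome = match_years(
                extract_years(rec_m.values),
                extract_years(rec_a.values),
                both_none_reported=both_none,
            )
        per_cell[key] = outcome
        confusion[attr] = confusion[attr] + ConfusionTable(
            tp=outcome.tp, fp=outcome.fp, tn=outcome.tn, fn=outcome.fn
        )
        logger.debug(
            "%s / %s: TP=%d FP=%d FN=%d TN=%d",
            article, attr, outcome.tp, outcome.fp, outcome.fn, outcome.tn,
        )

    for attr, table in confusion.items():
        logger.info(
            "attribute %r: TP=%d FP=%d FN=%d TN=%d",
            attr, table.tp, table.fp, table.fn, table.tn,
        )
    result = EvaluationResult(per_cell, confusion, parse_failures)
    return result


def entry_tallies(manual: Dataset, automated: Dataset) -> pd.DataFrame:
    """Convenience re-export of the side-by-side entry tally table."""
    return entry_table(manual, automated)
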