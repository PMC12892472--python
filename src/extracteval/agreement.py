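"""Weighted 2/1/0 agreement scoring and replicate-run agreement.

Human reviewers compare the two extractions cell by cell and assign 2 (full
agreement), 1 (partial agreement: at least one piece of information agrees)
or 0 (disagreement).  Scores are pooled per attribute and expressed as a
percentage of the maximum possible score (2 points per article).  The
package can also *suggest* scores from its own match outcomes — a stricter,
purely mechanical first pass that never overwrites a human-assigned score —
and measure agreement between two automated runs of the same extractor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .normalization import NormalizationPolicy, normalize_cell
from .records_io import Dataset, round_half_up
from .term_matching import MatchOutcome, MatchPolicy, eligible

__all__ = [
    "AgreementRecord",
    "AgreementSummary",
    "Provenance",
    "ReplicateMode",
    "attribute_agreement",
    "overall_agreement",
    "read_agreement_scores",
    "replicate_agreement",
    "suggest_agreement_score",
    "summary_table",
]


class Provenance(str, enum.Enum):
    HUMAN_ASSIGNED = "human_assigned"
    SUGGESTED = "suggested"


class ReplicateMode(str, enum.Enum):
    EXACT = "exact"
    FUZZY = "fuzzy"


@dataclass(frozen=True)
class AgreementRecord:
    """One cell's agreement score."""

    article_id: str
    attribute: str
    score: int
    provenance: Provenance = Provenance.HUMAN_ASSIGNED

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2):
            raise ValueError(f"score must be 0, 1 or 2, got {self.score}")


@dataclass(frozen=True)
class AgreementSummary:
    """Score counts for one attribute (or a pool of attributes)."""

    full: int
    partial: int
    disagree: int

    def __post_init__(self) -> None:
        if min(self.full, self.partial, self.disagree) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.full + self.partial + self.disagree

    @property
    def percent(self) -> float:
        """Weighted score as a fraction of the maximum (2 per cell), in %."""
        return attribute_agreement(self.full, self.partial, self.disagree)


def attribute_agreement(full: int, partial: int, disagree: int) -> float:
    """100 * (2*full + partial) / (2 * number of cells)."""
    n = full + partial + disagree
    if n == 0:
        raise ValueError("agreement percentage undefined for zero cells")
    return 100.0 * (2 * full + partial) / (2 * n)


def overall_agreement(summaries: Sequence[AgreementSummary]) -> float:
    """Agreement of the pooled counts across attributes."""
    if not summaries:
        raise ValueError("overall_agreement needs at least one summary")
    return attribute_agreement(
        sum(s.full for s in summaries),
        sum(s.partial for s in summaries),
        sum(s.disagree for s in summaries),
    )


def suggest_agreement_score(outcome: MatchOutcome) -> int:
    """Mechanical 2/1/0 rubric over a cell's match outcome.

    2 when everything matched (or both sides correctly empty), 1 when at
    least one token matched but others did not, 0 when nothing matched.
    Stricter than a human rating, which allows semantic leeway.
    """
    if outcome.tn_flag:
        return 2
    if outcome.tp > 0 and outcome.fp == 0 and outcome.fn == 0:
        return 2
    if outcome.tp > 0:
        return 1
    return 0


def summary_table(
    summaries: dict[str, AgreementSummary], ndigits: int = 1
) -> pd.DataFrame:
    """Attribute-level table with a pooled "All attributes" row."""
    rows = [
        {
            "attribute": name,
            "agreement": s.full,
            "partial": s.partial,
            "disagreement": s.disagree,
            "agreement_pct": round_half_up(s.percent, ndigits),
        }
        for name, s in summaries.items()
    ]
    pooled = AgreementSummary(
        sum(s.full for s in summaries.values()),
        sum(s.partial for s in summaries.values()),
        sum(s.disagree for s in summaries.values()),
    )
    rows.append(
        {
            "attribute": "All attributes",
            "agreement": pooled.full,
            "partial": pooled.partial,
            "disagreement": pooled.disagree,
            "agreement_pct": round_half_up(pooled.percent, ndigits),
        }
    )
    return pd.DataFrame(rows)


def read_agreement_scores(path: str | Path) -> list[AgreementRecord]:
    """Read a scores CSV: article_id, attribute, score[, provenance]."""
    frame = pd.read_csv(path, dtype={"article_id": str, "attribute": str})
    records = []
    for row in frame.itertuples(index=False):
        provenance = Provenance(getattr(row, "provenance", "human_assigned"))
        records.append(
            AgreementRecord(str(row.article_id), str(row.attribute), int(row.score), provenance)
        )
    return records


def summarize_records(records: Iterable[AgreementRecord]) -> dict[str, AgreementSummary]:
    """Per-attribute score counts from individual records."""
    counts: dict[str, list[int]] = {}
    for rec in records:
        c = counts.setdefault(rec.attribute, [0, 0, 0])
        c[rec.score] += 1
    return {
        attr: AgreementSummary(full=c[2], partial=c[1], disagree=c[0])
        for attr, c in counts.items()
    }


def replicate_agreement(
    run_a: Dataset,
    run_b: Dataset,
    mode: ReplicateMode | str = ReplicateMode.EXACT,
    norm_policy: NormalizationPolicy | None = None,
    match_policy: MatchPolicy | None = None,
) -> float:
    """Mean per-cell fraction of values agreeing between two extraction runs.

    Under ``exact`` mode values must be equal strings after normalization;
    under ``fuzzy`` mode tokens may pair whenever they are eligible under
    the fuzzy-matching thresholds.  Cells where both runs report nothing
    count as full agreement.  Returns a percentage.
    """
    mode = ReplicateMode(mode)
    norm_policy = norm_policy or NormalizationPolicy()
    match_policy = match_policy or MatchPolicy()
    keys_a = set(run_a.records)
    keys_b = set(run_b.records)
    if keys_a != keys_b:
        diff = sorted(keys_a ^ keys_b)[:5]
        raise ValueError(f"runs cover different cells, e.g. {diff}")
    fractions = []
    for key in sorted(keys_a):
        rec_a, rec_b = run_a.records[key], run_b.records[key]
        spec = run_a.attributes[key[1]]
        tokens_a = normalize_cell(rec_a.values, norm_policy, stemmed=spec.stemmed).flatten()
        tokens_b = normalize_cell(rec_b.values, norm_policy, stemmed=spec.stemmed).flatten()
        if not tokens_a and not tokens_b:
            fractions.append(1.0)
            continue
        if not tokens_a or not tokens_b:
            fractions.append(0.0)
            continue
        remaining = list(tokens_b)
        matched = 0
        for tok in tokens_a:
            for i, other in enumerate(remaining):
                ok = tok == other if mode is ReplicateMode.EXACT else eligible(
                    tok, other, match_policy
                )
                if ok:
                    matched += 1
                    del remaining[i]
                    break
        fractions.append(matched / max(len(tokens_a), len(tokens_b)))
    return 100.0 * sum(fractions) / len(fractions)
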