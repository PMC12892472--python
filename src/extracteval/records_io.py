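"""Data model and CSV ingestion for paired extraction datasets.

An evaluation compares two extractions of the same article sample: a
``manual`` (human-reviewer) dataset and an ``automated`` one.  Each dataset
is a grid of article x attribute cells; a cell holds either one or more raw
string values or the explicit sentinel "none reported".

The CSV carrier is long format, UTF-8, one value per row, with columns
``article_id, attribute, value`` and an optional ``ontology_source``.
Raw value text is preserved byte-for-byte apart from surrounding whitespace;
every text transform belongs to the normalization stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "NONE_REPORTED",
    "AttributeKind",
    "AttributeSpec",
    "AttributeRegistry",
    "Dataset",
    "ExtractionRecord",
    "Source",
    "default_registry",
    "read_extractions",
    "tally_entries",
    "entry_table",
    "write_extractions",
]

#: Sentinel value (case-insensitive in input) marking an empty cell.
NONE_REPORTED = "none reported"


class AttributeKind(str, enum.Enum):
    TERM = "term"
    COORDINATE = "coordinate"
    DATE = "date"


class Source(str, enum.Enum):
    MANUAL = "manual"
    AUTOMATED = "automated"


@dataclass(frozen=True)
class AttributeSpec:
    """One extraction attribute and how its values are compared.

    ``stemmed`` is meaningful only for term attributes; coordinate and date
    attributes are matched numerically and ignore it.
    """

    name: str
    kind: AttributeKind = AttributeKind.TERM
    stemmed: bool = False
    ontology_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is not AttributeKind.TERM and self.stemmed:
            raise ValueError(
                f"attribute {self.name!r}: stemmed applies only to term attributes"
            )


class AttributeRegistry(Mapping[str, AttributeSpec]):
    """Ordered name -> AttributeSpec lookup."""

    def __init__(self, specs: Iterable[AttributeSpec]):
        self._specs: dict[str, AttributeSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate attribute {spec.name!r}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> AttributeSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)


def default_registry() -> AttributeRegistry:
    """The 11 coastal-wetland restoration study attributes.

    Term attributes describing methods, actions, ecosystems and responses are
    stemmed; study sites and focal species are not, preserving place names
    and Latin nomenclature.
    """
    T, C, D = AttributeKind.TERM, AttributeKind.COORDINATE, AttributeKind.DATE
    return AttributeRegistry(
        [
            AttributeSpec("study site", T, stemmed=False),
            AttributeSpec("latitude/longitude", C),
            AttributeSpec("ecosystem type", T, stemmed=True),
            AttributeSpec("restoration actions", T, stemmed=True),
            AttributeSpec("restoration start date", D),
            AttributeSpec("restoration end date", D),
            AttributeSpec("sampling and monitoring methods", T, stemmed=True),
            AttributeSpec("monitoring start date", D),
            AttributeSpec("monitoring end date", D),
            AttributeSpec("focal species", T, stemmed=False),
            AttributeSpec("response variables", T, stemmed=True),
        ]
    )


@dataclass(frozen=True)
class ExtractionRecord:
    """One article x attribute x source observation."""

    article_id: str
    attribute: str
    source: Source
    values: tuple[str, ...] = ()
    none_reported: bool = False
    ontology_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.none_reported != (len(self.values) == 0):
            raise ValueError(
                f"{self.article_id}/{self.attribute}: none_reported must hold "
                "exactly when there are no values"
            )


@dataclass
class Dataset:
    """All records of one source over an article sample."""

    source: Source
    attributes: AttributeRegistry
    records: dict[tuple[str, str], ExtractionRecord] = field(default_factory=dict)

    @property
    def articles(self) -> tuple[str, ...]:
        return tuple(sorted({a for a, _ in self.records}))

    def cell(self, article_id: str, attribute: str) -> ExtractionRecord:
        return self.records[(article_id, attribute)]

    def add(self, record: ExtractionRecord) -> None:
        key = (record.article_id, record.attribute)
        if key in self.records:
            raise ValueError(f"duplicate record for {key}")
        if record.attribute not in self.attributes:
            raise ValueError(f"unknown attribute {record.attribute!r}")
        self.records[key] = record

    def complete(self, articles: Iterable[str] | None = None) -> "Dataset":
        """Return a dataset where every article x attribute cell exists.

        Missing cells become none_reported records; existing records are
        never altered.
        """
        arts = tuple(articles) if articles is not None else self.articles
        out = Dataset(self.source, self.attributes, dict(self.records))
        for article in arts:
            for attr in self.attributes:
                key = (article, attr)
                if key not in out.records:
                    out.records[key] = ExtractionRecord(
                        article, attr, self.source, (), none_reported=True
                    )
        return out

    @property
    def is_complete(self) -> bool:
        return all(
            (a, attr) in self.records for a in self.articles for attr in self.attributes
        )

    def total_values(self) -> int:
        return sum(len(r.values) for r in self.records.values())


def read_extractions(
    path: str | Path,
    source: Source | str,
    registry: AttributeRegistry | None = None,
    *,
    complete: bool = True,
) -> Dataset:
    """Read a long-format extraction CSV into a completed :class:`Dataset`.

    Rows for the same (article, attribute) cell are merged in row order.  A
    cell mixing a real value with the "none reported" sentinel is rejected,
    as is any row naming an unknown attribute.  Row order never affects the
    resulting dataset (values keep within-cell order of appearance).
    """
    source = Source(source)
    registry = registry if registry is not None else default_registry()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"article_id", "attribute", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    cells: dict[tuple[str, str], dict] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        article = str(row.article_id).strip()
        attribute = str(row.attribute).strip()
        if attribute not in registry:
            raise ValueError(
                f"{path} row {idx}: unknown attribute {attribute!r} "
                f"(expected one of {list(registry)})"
            )
        value = str(row.value).strip()
        onto = str(getattr(row, "ontology_source", "")).strip()
        cell = cells.setdefault(
            (article, attribute), {"values": [], "onto": [], "none": False}
        )
        if value.lower() == NONE_REPORTED or value == "":
            cell["none"] = True
        else:
            cell["values"].append(value)
            cell["onto"].append(onto)
        if cell["none"] and cell["values"]:
            raise ValueError(
                f"{path} row {idx}: cell ({article!r}, {attribute!r}) mixes a "
                f"value with the 'none reported' sentinel"
            )

    dataset = Dataset(source, registry)
    for (article, attribute), cell in sorted(cells.items()):
        dataset.add(
            ExtractionRecord(
                article,
                attribute,
                source,
                tuple(cell["values"]),
                none_reported=not cell["values"],
                ontology_sources=tuple(cell["onto"]) if any(cell["onto"]) else (),
            )
        )
    return dataset.complete() if complete else dataset


def write_extractions(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the long-format CSV (round-trip safe)."""
    rows = []
    for (article, attribute), rec in sorted(dataset.records.items()):
        if rec.none_reported:
            rows.append((article, attribute, NONE_REPORTED, ""))
        else:
            ontos = rec.ontology_sources or ("",) * len(rec.values)
            for value, onto in zip(rec.values, ontos):
                rows.append((article, attribute, value, onto))
    pd.DataFrame(
        rows, columns=["article_id", "attribute", "value", "ontology_source"]
    ).to_csv(path, index=False)


def tally_entries(dataset: Dataset) -> pd.DataFrame:
    """Per-attribute entry counts and per-article rates.

    An entry is one extracted term regardless of word count; none_reported
    cells contribute zero.  Rates are count / number of articles, rounded to
    one decimal for display (the ``rate`` column keeps full precision,
    ``rate_1dp`` is the display value).
    """
    if not dataset.records:
        raise ValueError("cannot tally an empty dataset")
    n_articles = len(dataset.articles)
    rows = []
    for attr in dataset.attributes:
        count = sum(
            len(rec.values)
            for (a, at), rec in dataset.records.items()
            if at == attr
        )
        rate = count / n_articles
        rows.append((attr, count, rate, round_half_up(rate, 1)))
    return pd.DataFrame(rows, columns=["attribute", "entries", "rate", "rate_1dp"])


def entry_table(manual: Dataset, automated: Dataset) -> pd.DataFrame:
    """Side-by-side entry tallies for the two sources with rate differences."""
    m = tally_entries(manual).set_index("attribute")
    a = tally_entries(automated).set_index("attribute")
    out = pd.DataFrame(
        {
            "manual_entries": m["entries"],
            "automated_entries": a["entries"],
            "manual_rate": m["rate_1dp"],
            "automated_rate": a["rate_1dp"],
        }
    )
    out["rate_difference"] = (out["automated_rate"] - out["manual_rate"]).round(1)
    total = pd.DataFrame(
        {
            "manual_entries": [int(out["manual_entries"].sum())],
            "automated_entries": [int(out["automated_entries"].sum())],
            "manual_rate": [round_half_up(out["manual_rate"].sum(), 1)],
            "automated_rate": [round_half_up(out["automated_rate"].sum(), 1)],
            "rate_difference": [
                round_half_up(
                    out["automated_rate"].sum() - out["manual_rate"].sum(), 1
                )
            ],
        },
        index=["All attributes"],
    )
    out = pd.concat([out, total])
    out.index.name = "attribute"
    return out.reset_index()


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for display values (0.05 -> 0.1)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
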