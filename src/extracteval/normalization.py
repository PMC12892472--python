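"""Attribute-aware text normalization.

Raw extraction values are free text; before any comparison they are reduced
to multisets of comparable tokens by a fixed pipeline:

    synonym substitution -> tokenization -> stopword removal
        -> short-token filter -> (optional) stemming

Synonym substitution happens at phrase level (before tokenization) so that
multi-word patterns such as "sea grass" can be rewritten.  Stemming uses the
Snowball English algorithm and is applied only for attributes flagged as
stemmed (e.g. ecosystem type, restoration actions) — study sites and focal
species keep their surface form so place names and Latin binomials stay
distinct.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._porter2 import stem as _snowball_stem

__all__ = [
    "DEFAULT_SYNONYMS",
    "NormalizationPolicy",
    "TokenMultiset",
    "apply_synonyms",
    "default_stopwords",
    "load_stopwords",
    "load_synonyms",
    "normalize_cell",
    "tokenize",
]

#: The three equivalences found to block obvious matches in coastal-wetland
#: vocabulary, canonicalized to the compact form.
DEFAULT_SYNONYMS: tuple[tuple[str, str], ...] = (
    ("saline", "salt"),
    ("sea grass", "seagrass"),
    ("salt marsh", "saltmarsh"),
)

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


def default_stopwords() -> frozenset[str]:
    """The packaged Snowball-style English stopword list."""
    text = resources.files("extracteval.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-word-per-line stopword file."""
    words = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(w.strip().lower() for w in words if w.strip())


def load_synonyms(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Read a two-column (pattern, canonical) CSV synonym dictionary."""
    out: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() == "pattern":  # header
                continue
            if len(row) < 2:
                raise ValueError(f"synonym row needs two columns: {row!r}")
            out.append((row[0].strip(), row[1].strip()))
    return tuple(out)


@dataclass(frozen=True)
class NormalizationPolicy:
    """Parameters of the normalization pipeline.

    Defaults encode the study configuration: the three-entry synonym
    dictionary, English stopwords, removal of one- and two-character tokens,
    and Snowball stemming (gated per attribute).
    """

    synonym_map: tuple[tuple[str, str], ...] = DEFAULT_SYNONYMS
    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    min_token_length: int = 3
    stem: bool = True
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass(frozen=True)
class TokenMultiset:
    """Normalized tokens with integer multiplicities for one cell."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def flatten(self) -> list[str]:
        """All token instances, sorted, with multiplicity."""
        out: list[str] = []
        for tok in sorted(self.counts):
            out.extend([tok] * self.counts[tok])
        return out

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "TokenMultiset":
        return cls(dict(Counter(tokens)))


def apply_synonyms(text: str, policy: NormalizationPolicy) -> str:
    """Rewrite synonym phrases to their canonical form.

    Each pattern is applied once, longest pattern first, left to right, as a
    case-insensitive whole-word/phrase match; text with no pattern passes
    through byte-identical.
    """
    result = text
    for pattern, canonical in sorted(
        policy.synonym_map, key=lambda pc: len(pc[0]), reverse=True
    ):
        rx = re.compile(
            r"(?<![a-zA-Z0-9])" + re.escape(pattern) + r"(?![a-zA-Z0-9])",
            re.IGNORECASE,
        )
        result = rx.sub(canonical, result)
    return result


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def normalize_cell(
    values: Sequence[str],
    policy: NormalizationPolicy,
    *,
    stemmed: bool = False,
) -> TokenMultiset:
    """Normalize all raw values of one article-attribute cell into a multiset.

    ``stemmed`` is the attribute-level flag; stemming runs only when both the
    policy and the attribute ask for it.  The length filter runs before
    stemming so no sub-minimum stems are ever introduced.
    """
    tokens: list[str] = []
    for value in values:
        text = apply_synonyms(value, policy)
        toks = tokenize(text) if policy.lowercase else _TOKEN_SPLIT.split(text)
        toks = [t for t in toks if t and t not in policy.stopword_list]
        toks = [t for t in toks if len(t) >= policy.min_token_length]
        if policy.stem and stemmed:
            toks = [_snowball_stem(t) for t in toks]
        tokens.extend(toks)
    return TokenMultiset.from_tokens(tokens)
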