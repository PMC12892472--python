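"""Seeded generator of paired extraction corpora with known ground truth.

The generator emulates the structure of a manual-vs-automated extraction
study over the 11 coastal-wetland restoration attributes: per-article entry
counts follow the observed per-attribute rates, and the automated side is
derived from the manual side value by value through explicit perturbation
channels — exact copies, near-miss typos that stay inside the same-prefix
fuzzy threshold, synonym swaps, compound terms split into single words,
omissions, spurious additions, duplicate inflation, coordinate jitter
(within or beyond the ±0.01° tolerance), year drift, and jointly empty
cells.

Because each channel's confusion contribution is known at generation time,
the generator emits an exact expected confusion table per cell; running the
evaluation pipeline over the corpus must reproduce those counts exactly.
To keep the bookkeeping exact, the distinct base terms drawn for one cell
are rejection-sampled so that their normalized tokens are pairwise
ineligible under the fuzzy thresholds — no accidental cross-term matches
can occur.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .metrics import ConfusionTable
from .normalization import NormalizationPolicy, normalize_cell
from .records_io import (
    AttributeKind,
    AttributeRegistry,
    Dataset,
    ExtractionRecord,
    Source,
    default_registry,
)
from .term_matching import MatchPolicy, eligible

__all__ = [
    "ChannelNotApplicableError",
    "GroundTruth",
    "PerturbationRates",
    "SyntheticSpec",
    "default_mean_entries",
    "generate_corpus",
    "load_lexicon",
    "perturb_term",
]


class ChannelNotApplicableError(ValueError):
    """A perturbation channel cannot be applied to the given term."""


#: Mean manual entries per article for each attribute (the observed rates
#: of the 80-article study sample).
def default_mean_entries() -> dict[str, float]:
    return {
        "study site": 1.7,
        "latitude/longitude": 1.4,
        "ecosystem type": 1.4,
        "restoration actions": 1.9,
        "restoration start date": 1.3,
        "restoration end date": 1.0,
        "sampling and monitoring methods": 3.7,
        "monitoring start date": 1.2,
        "monitoring end date": 1.1,
        "focal species": 3.5,
        "response variables": 5.3,
    }


#: Which lexicon category feeds each term attribute.
_CATEGORY_FOR_ATTRIBUTE = {
    "study site": "site",
    "ecosystem type": "ecosystem",
    "restoration actions": "action",
    "sampling and monitoring methods": "method",
    "focal species": "species",
    "response variables": "response",
}


@dataclass(frozen=True)
class PerturbationRates:
    """Per-value channel probabilities; the remainder is an exact copy.

    Defaults are set so the corpus is false-negative heavy with a sizeable
    false-positive load, the regime observed when an LLM extractor is scored
    against a careful human baseline.
    """

    near_typo: float = 0.08
    synonym_swap: float = 0.04
    split_compound: float = 0.06
    omission: float = 0.30
    spurious_addition: float = 0.25
    duplicate_inflation: float = 0.08
    both_none_reported: float = 0.10
    coordinate_jitter_within: float = 0.20
    coordinate_jitter_beyond: float = 0.10
    year_drift: float = 0.15

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1], got {v}")
        if self.near_typo + self.synonym_swap + self.split_compound + self.omission > 1:
            raise ValueError("term channel probabilities sum above 1")
        if self.coordinate_jitter_within + self.coordinate_jitter_beyond + self.omission > 1:
            raise ValueError("coordinate channel probabilities sum above 1")
        if self.year_drift + self.omission > 1:
            raise ValueError("date channel probabilities sum above 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic corpus."""

    n_articles: int = 80
    registry: AttributeRegistry = field(default_factory=default_registry)
    mean_entries: Mapping[str, float] = field(default_factory=default_mean_entries)
    rates: PerturbationRates = PerturbationRates()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        for attr in self.registry:
            if attr in _CATEGORY_FOR_ATTRIBUTE or self.registry[attr].kind in (
                AttributeKind.COORDINATE,
                AttributeKind.DATE,
            ):
                continue
            raise ValueError(f"no lexicon category for term attribute {attr!r}")


@dataclass
class GroundTruth:
    """Expected confusion counts recorded while generating the corpus."""

    cells: dict[tuple[str, str], ConfusionTable] = field(default_factory=dict)

    def per_attribute(self) -> dict[str, ConfusionTable]:
        pooled: dict[str, ConfusionTable] = {}
        for (_, attr), table in self.cells.items():
            pooled[attr] = pooled.get(attr, ConfusionTable()) + table
        return pooled

    def pooled(self) -> ConfusionTable:
        total = ConfusionTable()
        for table in self.cells.values():
            total = total + table
        return total


def load_lexicon() -> dict[str, list[str]]:
    """The packaged lexicon, grouped by category."""
    text = resources.files("extracteval.data").joinpath("lexicon.txt").read_text()
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        category, term = line.split("\t", 1)
        out.setdefault(category, []).append(term)
    return out


# ---------------------------------------------------------------------------
# term perturbation


def perturb_term(
    term: str,
    channel: str,
    rng: np.random.Generator,
    match_policy: MatchPolicy = MatchPolicy(),
    norm_policy: NormalizationPolicy | None = None,
    *,
    stemmed: bool = False,
    forbidden_tokens: frozenset[str] = frozenset(),
) -> str | list[str]:
    """Apply one perturbation channel to a raw term.

    ``near_typo`` guarantees the perturbed token is still eligible under the
    same-prefix threshold after normalization (or collapses back to the same
    normalized token) and collides with nothing in ``forbidden_tokens``;
    ``synonym_swap`` substitutes the paired dictionary variant;
    ``split_compound`` returns the words of a multi-word term as separate
    values.  Raises :class:`ChannelNotApplicableError` when the channel
    cannot apply so the caller can resample.
    """
    norm_policy = norm_policy or NormalizationPolicy()
    if channel == "exact_copy":
        return term
    if channel == "split_compound":
        words = term.split()
        if len(words) < 2:
            raise ChannelNotApplicableError(f"cannot split single word {term!r}")
        return words
    if channel == "synonym_swap":
        swaps = {
            "salt": "saline",
            "saline": "salt",
            "seagrass": "sea grass",
            "sea grass": "seagrass",
            "saltmarsh": "salt marsh",
            "salt marsh": "saltmarsh",
        }
        lower = term.lower()
        # longest pattern first so "salt marsh" wins over "salt"
        for pattern in sorted(swaps, key=len, reverse=True):
            idx = lower.find(pattern)
            if idx >= 0:
                return term[:idx] + swaps[pattern] + term[idx + len(pattern):]
        raise ChannelNotApplicableError(f"no synonym applies to {term!r}")
    if channel == "near_typo":
        return _typo(term, rng, match_policy, norm_policy, stemmed, forbidden_tokens)
    raise ValueError(f"unknown channel {channel!r}")


def _typo(
    term: str,
    rng: np.random.Generator,
    match_policy: MatchPolicy,
    norm_policy: NormalizationPolicy,
    stemmed: bool,
    forbidden: frozenset[str],
) -> str:
    words = term.split()
    candidates = [i for i, w in enumerate(words) if len(w) >= 5]
    if not candidates:
        raise ChannelNotApplicableError(f"no word in {term!r} long enough for a typo")
    original_ms = _token_set([term], norm_policy, stemmed)
    for _ in range(40):
        i = candidates[rng.integers(len(candidates))]
        word = words[i]
        op = rng.integers(4)
        if op == 0:  # duplicate final character
            mutated = word + word[-1]
        elif op == 1:  # drop final character
            mutated = word[:-1]
        elif op == 2:  # transpose final two characters
            mutated = word[:-2] + word[-1] + word[-2]
        else:  # substitute final character
            letter = "abcdefghijklmnopqrstuvwxyz"[rng.integers(26)]
            mutated = word[:-1] + letter
        if mutated.lower() == word.lower():
            continue
        out = list(words)
        out[i] = mutated
        mutated_term = " ".join(out)
        # validate on the whole term: the typo must leave the normalized
        # multiset intact apart from one token replaced by an eligible
        # variant (a typo inside a synonym phrase, e.g. "salt marsh",
        # would otherwise restructure the tokens entirely)
        mutated_ms = _token_set([mutated_term], norm_policy, stemmed)
        if sum(mutated_ms.values()) != sum(original_ms.values()):
            continue
        lost = original_ms - mutated_ms
        gained = mutated_ms - original_ms
        if not lost and not gained:
            return mutated_term  # collapsed back to the same tokens: still TP
        if sum(lost.values()) != 1 or sum(gained.values()) != 1:
            continue
        (orig_tok,) = lost
        (new_tok,) = gained
        if not eligible(orig_tok, new_tok, match_policy):
            continue
        # must not collide with (equal or be eligible to) any other cell token
        if any(
            new_tok == other
            or (other != orig_tok and eligible(new_tok, other, match_policy))
            for other in forbidden
        ):
            continue
        return mutated_term
    raise ChannelNotApplicableError(f"could not construct an eligible typo for {term!r}")


# ---------------------------------------------------------------------------
# corpus generation


def generate_corpus(
    spec: SyntheticSpec,
    norm_policy: NormalizationPolicy | None = None,
    match_policy: MatchPolicy = MatchPolicy(),
) -> tuple[Dataset, Dataset, GroundTruth]:
    """Generate a (manual, automated, ground truth) triple.

    Deterministic given ``spec.seed``; the returned datasets are complete
    over the article sample and the ground truth holds the exact confusion
    table the evaluation pipeline must reproduce for every cell.
    """
    norm_policy = norm_policy or NormalizationPolicy()
    rng = np.random.default_rng(spec.seed)
    lexicon = load_lexicon()
    manual = Dataset(Source.MANUAL, spec.registry)
    automated = Dataset(Source.AUTOMATED, spec.registry)
    truth = GroundTruth()

    articles = [f"A{i + 1:03d}" for i in range(spec.n_articles)]
    for article in articles:
        for attr in spec.registry:
            attr_spec = spec.registry[attr]
            if attr_spec.kind is AttributeKind.TERM:
                m_vals, a_vals, table = _term_cell(
                    attr, attr_spec.stemmed, spec, rng, lexicon, norm_policy, match_policy
                )
            elif attr_spec.kind is AttributeKind.COORDINATE:
                m_vals, a_vals, table = _coordinate_cell(attr, spec, rng)
            else:
                m_vals, a_vals, table = _date_cell(attr, spec, rng)
            manual.add(
                ExtractionRecord(article, attr, Source.MANUAL, tuple(m_vals),
                                 none_reported=not m_vals)
            )
            automated.add(
                ExtractionRecord(article, attr, Source.AUTOMATED, tuple(a_vals),
                                 none_reported=not a_vals)
            )
            truth.cells[(article, attr)] = table
    return manual, automated, truth


def _n_entries(mean: float, rng: np.random.Generator) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _token_set(
    values: Sequence[str], norm_policy: NormalizationPolicy, stemmed: bool
) -> Counter:
    return Counter(normalize_cell(values, norm_policy, stemmed=stemmed).counts)


def _compatible(tokens: Counter, accepted: frozenset[str], match_policy: MatchPolicy) -> bool:
    for tok in tokens:
        for other in accepted:
            if tok == other or eligible(tok, other, match_policy):
                return False
    return True


def _term_cell(
    attr: str,
    stemmed: bool,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    lexicon: dict[str, list[str]],
    norm_policy: NormalizationPolicy,
    match_policy: MatchPolicy,
) -> tuple[list[str], list[str], ConfusionTable]:
    rates = spec.rates
    if rng.random() < rates.both_none_reported:
        return [], [], ConfusionTable(tn=1)

    pool = lexicon[_CATEGORY_FOR_ATTRIBUTE[attr]]
    k = min(_n_entries(spec.mean_entries.get(attr, 1.0), rng), len(pool))
    order = rng.permutation(len(pool))
    chosen: list[tuple[str, Counter]] = []
    cell_tokens: set[str] = set()
    for idx in order:
        term = pool[idx]
        tokens = _token_set([term], norm_policy, stemmed)
        if not tokens:
            continue
        if _compatible(tokens, frozenset(cell_tokens), match_policy):
            chosen.append((term, tokens))
            cell_tokens.update(tokens)
            if len(chosen) == k:
                break

    tp = fp = fn = 0
    manual_values: list[str] = []
    auto_values: list[str] = []
    p_channels = (rates.near_typo, rates.synonym_swap, rates.split_compound, rates.omission)
    for term, tokens in chosen:
        manual_values.append(term)
        n_tok = sum(tokens.values())
        u = rng.random()
        edges = np.cumsum(p_channels)
        if u < edges[0]:
            channel = "near_typo"
        elif u < edges[1]:
            channel = "synonym_swap"
        elif u < edges[2]:
            channel = "split_compound"
        elif u < edges[3]:
            channel = "omission"
        else:
            channel = "exact_copy"

        if channel == "omission":
            fn += n_tok
            continue
        if channel in ("near_typo", "synonym_swap", "split_compound"):
            try:
                result = perturb_term(
                    term, channel, rng, match_policy, norm_policy,
                    stemmed=stemmed, forbidden_tokens=frozenset(cell_tokens),
                )
                if channel in ("synonym_swap", "split_compound"):
                    # the rewrite must be invisible after normalization; a
                    # split that severs a synonym phrase (e.g. "salt marsh")
                    # would change the token multiset and break the exact
                    # bookkeeping, so it falls back to an exact copy
                    out_values = result if isinstance(result, list) else [result]
                    if _token_set(out_values, norm_policy, stemmed) != tokens:
                        result = term
            except ChannelNotApplicableError:
                result = term  # fall back to an exact copy; still all TP
        else:
            result = term
        if isinstance(result, list):
            auto_values.extend(result)
        else:
            auto_values.append(result)
        tp += n_tok

    if auto_values and rng.random() < rates.duplicate_inflation:
        dup = auto_values[rng.integers(len(auto_values))]
        auto_values.append(dup)
        fp += sum(_token_set([dup], norm_policy, stemmed).values())

    if rng.random() < rates.spurious_addition:
        for idx in rng.permutation(len(pool)):
            term = pool[idx]
            tokens = _token_set([term], norm_policy, stemmed)
            if not tokens:
                continue
            # spurious tokens must not collide with anything already in the
            # cell on either side (including typo'd tokens)
            all_tokens = frozenset(
                _token_set(manual_values + auto_values, norm_policy, stemmed)
            )
            if _compatible(tokens, all_tokens, match_policy):
                auto_values.append(term)
                fp += sum(tokens.values())
                break

    return manual_values, auto_values, ConfusionTable(tp=tp, fp=fp, fn=fn)


_SEPARATION = 0.1  # degrees between distinct manual coordinates in a cell


def _coordinate_cell(
    attr: str, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[str], list[str], ConfusionTable]:
    rates = spec.rates
    if rng.random() < rates.both_none_reported:
        return [], [], ConfusionTable(tn=1)

    k = _n_entries(spec.mean_entries.get(attr, 1.0), rng)
    points: list[tuple[float, float]] = []
    while len(points) < k:
        lat = round(float(rng.uniform(-60, 60)), 4)
        lon = round(float(rng.uniform(-175, 175)), 4)
        if all(
            max(abs(lat - p[0]), abs(lon - p[1])) >= _SEPARATION for p in points
        ):
            points.append((lat, lon))

    tp = fp = fn = 0
    manual_values = [f"{lat}, {lon}" for lat, lon in points]
    auto_values: list[str] = []
    edges = np.cumsum(
        (rates.coordinate_jitter_within, rates.coordinate_jitter_beyond, rates.omission)
    )
    for lat, lon in points:
        u = rng.random()
        if u < edges[0]:  # jitter inside the ±0.01° tolerance: still a TP
            jlat = lat + float(rng.uniform(-0.009, 0.009))
            jlon = lon + float(rng.uniform(-0.009, 0.009))
            auto_values.append(f"{jlat:.4f}, {jlon:.4f}")
            tp += 1
        elif u < edges[1]:  # jitter beyond tolerance: FP + FN
            offset = float(rng.uniform(0.012, 0.04)) * (1 if rng.random() < 0.5 else -1)
            if rng.random() < 0.5:
                auto_values.append(f"{lat + offset:.4f}, {lon:.4f}")
            else:
                auto_values.append(f"{lat:.4f}, {lon + offset:.4f}")
            fp += 1
            fn += 1
        elif u < edges[2]:  # omitted
            fn += 1
        else:  # exact copy, sometimes re-formatted as DMS
            if rng.random() < 0.3:
                auto_values.append(_format_dms(lat, lon))
            else:
                auto_values.append(f"{lat}, {lon}")
            tp += 1

    if rng.random() < rates.spurious_addition:
        while True:
            lat = round(float(rng.uniform(-60, 60)), 4)
            lon = round(float(rng.uniform(-175, 175)), 4)
            if all(
                max(abs(lat - p[0]), abs(lon - p[1])) >= _SEPARATION for p in points
            ):
                auto_values.append(f"{lat}, {lon}")
                fp += 1
                break

    return manual_values, auto_values, ConfusionTable(tp=tp, fp=fp, fn=fn)


def _format_dms(lat: float, lon: float) -> str:
    def one(value: float, pos: str, neg: str) -> str:
        hemi = pos if value >= 0 else neg
        value = abs(value)
        deg = int(value)
        minutes_f = (value - deg) * 60
        minutes = int(minutes_f)
        seconds = (minutes_f - minutes) * 60
        return f"{deg}°{minutes}'{seconds:.2f}\"{hemi}"

    return f"{one(lat, 'N', 'S')}, {one(lon, 'E', 'W')}"


_MONTHS = ("January", "March", "May", "June", "August", "October", "")


def _date_cell(
    attr: str, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[str], list[str], ConfusionTable]:
    rates = spec.rates
    if rng.random() < rates.both_none_reported:
        return [], [], ConfusionTable(tn=1)

    k = _n_entries(spec.mean_entries.get(attr, 1.0), rng)
    years = list(rng.choice(np.arange(1980, 2024), size=min(k, 40), replace=False))
    years = [int(y) for y in years]

    def render(year: int) -> str:
        month = _MONTHS[rng.integers(len(_MONTHS))]
        return f"{month} {year}".strip()

    tp = fp = fn = 0
    manual_values = [render(y) for y in years]
    auto_values: list[str] = []
    used = set(years)
    edges = np.cumsum((rates.year_drift, rates.omission))
    for year in years:
        u = rng.random()
        if u < edges[0]:  # drift to a different year: FP + FN
            while True:
                drifted = year + int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                if drifted not in used:
                    break
            used.add(drifted)
            auto_values.append(render(drifted))
            fp += 1
            fn += 1
        elif u < edges[1]:  # omitted
            fn += 1
        else:
            auto_values.append(render(year))
            tp += 1

    if rng.random() < rates.spurious_addition:
        while True:
            extra = int(rng.integers(1950, 2031))
            if extra not in used:
                break
        used.add(extra)
        auto_values.append(render(extra))
        fp += 1

    return manual_values, auto_values, ConfusionTable(tp=tp, fp=fp, fn=fn)
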