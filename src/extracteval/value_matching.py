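"""Coordinate and date matching.

Geographic coordinates are parsed from the formats found in practice —
signed decimal degrees, degrees-minutes, degrees-minutes-seconds, with
hemisphere letters before or after the number — into decimal-degree pairs,
and matched one-to-one when both latitude and longitude agree within
±0.01°.  Date attributes are compared at year resolution: every four-digit
year found in a value counts, and a year range contributes both endpoints.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .term_matching import MatchOutcome

__all__ = [
    "CoordinateParseError",
    "CoordinatePair",
    "YEAR_RANGE",
    "extract_years",
    "format_decimal",
    "match_coordinates",
    "match_years",
    "parse_coordinate",
    "parse_coordinates",
]

#: Years outside this window are treated as non-date numerals.
YEAR_RANGE = (1500, 2100)

#: TP tolerance, in degrees, applied per axis.
COORDINATE_TOLERANCE = 0.01


class CoordinateParseError(ValueError):
    """Raised when a value cannot be read as a coordinate pair."""


@dataclass(frozen=True)
class CoordinatePair:
    """A location in decimal degrees (S and W negative)."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise CoordinateParseError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise CoordinateParseError(f"longitude {self.longitude} out of range")


_COMPONENT = re.compile(
    r"""^\s*
    (?P<hemi_pre>[NSEWnsew])?\s*
    (?P<sign>[-+])?\s*
    (?P<deg>\d+(?:\.\d+)?)\s*(?:°|º|d\b|\s)?\s*
    (?:(?P<min>\d+(?:\.\d+)?)\s*(?:'|′|m\b|\s)?\s*)?
    (?:(?P<sec>\d+(?:\.\d+)?)\s*(?:"|″|''|s\b)?\s*)?
    (?P<hemi_post>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def _parse_component(text: str) -> tuple[float, str | None]:
    """One coordinate component -> (decimal degrees, hemisphere letter or None)."""
    m = _COMPONENT.match(text)
    if m is None or (m.group("hemi_pre") and m.group("hemi_post")):
        raise CoordinateParseError(f"unparseable coordinate component: {text!r}")
    degrees = float(m.group("deg"))
    if m.group("min") is not None:
        minutes = float(m.group("min"))
        if minutes >= 60:
            raise CoordinateParseError(f"minutes >= 60 in {text!r}")
        degrees += minutes / 60.0
    if m.group("sec") is not None:
        seconds = float(m.group("sec"))
        if seconds >= 60:
            raise CoordinateParseError(f"seconds >= 60 in {text!r}")
        degrees += seconds / 3600.0
    hemi = (m.group("hemi_pre") or m.group("hemi_post") or "").upper() or None
    if m.group("sign") == "-":
        if hemi:
            raise CoordinateParseError(f"both sign and hemisphere in {text!r}")
        degrees = -degrees
    if hemi in ("S", "W"):
        degrees = -degrees
    return degrees, hemi


def parse_coordinate(text: str) -> CoordinatePair:
    """Parse one raw value holding a latitude/longitude pair.

    The two components may be separated by a comma or semicolon; with
    hemisphere letters a space-separated pair is also accepted.  Raises
    :class:`CoordinateParseError` on anything unparseable or out of range.
    """
    raw = text.strip()
    if not raw:
        raise CoordinateParseError("empty coordinate value")
    parts = re.split(r"\s*[;,]\s*", raw)
    if len(parts) == 1:
        # try to split a space-separated pair at a hemisphere letter boundary
        m = re.match(r"^(.*?[NSns])\s+(.*?[EWew])$", raw)
        if m:
            parts = [m.group(1), m.group(2)]
        else:
            fields = raw.split()
            if len(fields) == 2:
                parts = fields
            else:
                raise CoordinateParseError(f"cannot split {text!r} into lat/lon")
    if len(parts) != 2:
        raise CoordinateParseError(f"expected two components in {text!r}")
    lat, lat_hemi = _parse_component(parts[0])
    lon, lon_hemi = _parse_component(parts[1])
    if lat_hemi in ("E", "W") or lon_hemi in ("N", "S"):
        # letters say the order is lon, lat
        lat, lon = lon, lat
    return CoordinatePair(lat, lon)


def parse_coordinates(
    values: Iterable[str],
) -> tuple[list[CoordinatePair], list[str]]:
    """Parse many values; return (parsed pairs, unparseable raw values)."""
    parsed: list[CoordinatePair] = []
    failures: list[str] = []
    for value in values:
        try:
            parsed.append(parse_coordinate(value))
        except CoordinateParseError:
            failures.append(value)
    return parsed, failures


def format_decimal(pair: CoordinatePair, precision: int = 12) -> str:
    """Render a pair as "lat, lon" in fixed-point decimal degrees.

    The 12-decimal default round-trips through :func:`parse_coordinate`
    well within 1e-9; reports echo coordinates at 6 decimals.
    """
    return f"{pair.latitude:.{precision}f}, {pair.longitude:.{precision}f}"


def match_coordinates(
    manual: Sequence[CoordinatePair],
    auto: Sequence[CoordinatePair],
    tolerance: float = COORDINATE_TOLERANCE,
    *,
    both_none_reported: bool | None = None,
) -> MatchOutcome:
    """Greedy one-to-one pairing of coordinate pairs within tolerance.

    A manual/automated pair is matchable when both |Δlat| and |Δlon| are at
    most ``tolerance``; closest candidates (smallest max-axis delta) pair
    first.  Unmatched automated pairs are FP, unmatched manual pairs FN.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if both_none_reported is None:
        both_none_reported = not manual and not auto
    candidates = []
    for i, m in enumerate(manual):
        for j, a in enumerate(auto):
            dlat = abs(m.latitude - a.latitude)
            dlon = abs(m.longitude - a.longitude)
            if dlat <= tolerance and dlon <= tolerance:
                candidates.append((max(dlat, dlon), i, j))
    candidates.sort()
    used_m: set[int] = set()
    used_a: set[int] = set()
    matched = []
    for delta, i, j in candidates:
        if i in used_m or j in used_a:
            continue
        used_m.add(i)
        used_a.add(j)
        matched.append((format_decimal(manual[i], 6), format_decimal(auto[j], 6), 1.0 - delta))
    fn = Counter(format_decimal(m, 6) for i, m in enumerate(manual) if i not in used_m)
    fp = Counter(format_decimal(a, 6) for j, a in enumerate(auto) if j not in used_a)
    return MatchOutcome(tuple(matched), fp, fn, tn_flag=both_none_reported)


_YEAR = re.compile(r"(?<!\d)(\d{4})(?!\d)")


def extract_years(values: Iterable[str]) -> Counter:
    """Year multiset from raw values; any in-window 4-digit run counts."""
    years: Counter = Counter()
    for value in values:
        for match in _YEAR.finditer(value):
            year = int(match.group(1))
            if YEAR_RANGE[0] <= year <= YEAR_RANGE[1]:
                years[year] += 1
    return years


def match_years(
    manual: Counter,
    auto: Counter,
    *,
    both_none_reported: bool | None = None,
) -> MatchOutcome:
    """Year-level multiset matching: TP per year is min of the two counts."""
    if both_none_reported is None:
        both_none_reported = not manual and not auto
    matched = []
    fp: Counter = Counter()
    fn: Counter = Counter()
    for year in sorted(set(manual) | set(auto)):
        m, a = manual.get(year, 0), auto.get(year, 0)
        matched.extend([(str(year), str(year), 1.0)] * min(m, a))
        if a > m:
            fp[str(year)] = a - m
        elif m > a:
            fn[str(year)] = m - a
    return MatchOutcome(tuple(matched), fp, fn, tn_flag=both_none_reported)
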