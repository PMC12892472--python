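"""Shared fixtures for the extracteval test suite."""

from __future__ import annotations

import pytest

from extracteval.normalization import NormalizationPolicy
from extracteval.records_io import default_registry
from extracteval.term_matching import MatchPolicy


@pytest.fixture(scope="session")
def norm_policy() -> NormalizationPolicy:
    return NormalizationPolicy()


@pytest.fixture(scope="session")
def match_policy() -> MatchPolicy:
    return MatchPolicy()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


#: Published per-attribute confusion counts of the coastal-wetland
#: restoration case study (TP, FP, FN, TN), used as a worked example.
STUDY_CONFUSION = {
    "Latitude/longitude": (86, 18, 0, 29),
    "Monitoring end date": (63, 15, 8, 4),
    "Monitoring start date": (59, 23, 14, 1),
    "Restoration start date": (67, 36, 15, 6),
    "Response variables": (414, 304, 828, 0),
    "Study site": (163, 133, 496, 0),
    "Ecosystem type": (124, 123, 94, 0),
    "Restoration actions": (174, 205, 354, 1),
    "Sampling/monitoring methods": (209, 271, 664, 0),
    "Focal species": (225, 299, 332, 4),
    "Restoration end date": (23, 39, 12, 23),
}

#: Published per-attribute percentages (precision, recall, accuracy, F1).
STUDY_METRICS = {
    "Latitude/longitude": (82.7, 100.0, 86.5, 90.5),
    "Monitoring end date": (80.8, 88.7, 74.4, 84.6),
    "Monitoring start date": (72.0, 80.8, 61.9, 76.1),
    "Restoration start date": (65.0, 81.7, 58.9, 72.4),
    "Response variables": (57.7, 33.3, 26.8, 42.2),
    "Study site": (55.1, 24.7, 20.6, 34.1),
    "Ecosystem type": (50.2, 56.9, 36.4, 53.3),
    "Restoration actions": (45.9, 33.0, 23.8, 38.4),
    "Sampling/monitoring methods": (43.5, 23.9, 18.3, 30.9),
    "Focal species": (42.9, 40.4, 26.6, 41.6),
    "Restoration end date": (37.1, 65.7, 47.4, 47.4),
}

#: Published per-attribute agreement counts (full, partial, disagree) and
#: the resulting weighted percentage.
STUDY_AGREEMENT = {
    "Latitude/longitude": (73, 5, 2, 94.4),
    "Ecosystem type": (56, 14, 10, 78.8),
    "Monitoring start date": (48, 16, 16, 70.0),
    "Monitoring end date": (49, 13, 18, 69.4),
    "Restoration start date": (45, 16, 19, 66.3),
    "Response variables": (21, 58, 1, 62.5),
    "Restoration actions": (32, 36, 12, 62.5),
    "Focal species": (27, 39, 14, 58.1),
    "Study site": (25, 37, 18, 54.4),
    "Sampling/monitoring methods": (19, 43, 18, 50.6),
    "Restoration end date": (35, 10, 35, 50.0),
}
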