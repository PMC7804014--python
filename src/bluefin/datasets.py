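"""Published summary tables of the AcousticTrends_BlueFinLibrary resource.

The annotated library (https://data.aad.gov.au/metadata/records/
AcousticTrends_BlueFinLibrary) spans 11 site-years across the Atlantic,
Indian and Pacific sectors of the Southern Ocean and the Western Antarctic
Peninsula.  This module carries its published per-site annotation counts by
classification, plus small bookkeeping helpers used when checking totals and
per-site tallies.
"""

from __future__ import annotations

import pandas as pd

from .annotations import LABELS

_SITE_YEARS = (
    "Maud Rise 2014",
    "Greenwich 64S 2015",
    "S Kerguelen 2005",
    "S Kerguelen 2014",
    "S Kerguelen 2015",
    "Casey 2014",
    "Casey 2017",
    "Ross Sea 2014",
    "Balleny Islands 2015",
    "Elephant Island 2013",
    "Elephant Island 2014",
)

# rows follow _SITE_YEARS; columns follow LABELS
_COUNTS = (
    (2188, 37, 28, 70, 23, 5, 6, 465),
    (827, 157, 29, 66, 2, 1, 46, 325),
    (812, 237, 166, 435, 788, 78, 444, 3061),
    (2557, 1177, 563, 435, 1920, 1826, 344, 4961),
    (1970, 542, 236, 1180, 552, 718, 344, 1244),
    (3681, 1398, 1091, 679, 17, 0, 0, 5648),
    (1741, 558, 119, 553, 78, 214, 0, 130),
    (104, 0, 0, 0, 0, 0, 0, 255),
    (923, 44, 31, 47, 951, 148, 78, 18),
    (2625, 1786, 152, 299, 3662, 1859, 1042, 22927),
    (6935, 967, 100, 1034, 4940, 2912, 3660, 890),
)


def annotation_counts() -> pd.DataFrame:
    """Annotations per site-year (rows) and classification (columns)."""
    return pd.DataFrame(list(_COUNTS), index=list(_SITE_YEARS), columns=list(LABELS))


def class_totals(counts: pd.DataFrame | None = None) -> pd.Series:
    """Total annotations per classification across all site-years."""
    if counts is None:
        counts = annotation_counts()
    return counts.sum(axis=0)


def site_totals(counts: pd.DataFrame | None = None) -> pd.Series:
    """Total annotations per site-year across all classifications."""
    if counts is None:
        counts = annotation_counts()
    return counts.sum(axis=1)


def library_total(counts: pd.DataFrame | None = None) -> int:
    """Total number of annotations in the library."""
    if counts is None:
        counts = annotation_counts()
    return int(counts.to_numpy().sum())
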