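"""Interval arithmetic on 1-based inclusive genomic coordinates.

All public pipeline coordinates are 1-based inclusive (VCF convention).
BED input is converted on read (see :mod:`divscan.io`). Two length
conventions coexist in the genomics literature for a span ``start..end``:
the inclusive count ``end - start + 1`` and the plain difference
``end - start``; :func:`interval_length` computes either explicitly so
reports can state which one they used.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

LengthConvention = Literal["inclusive", "difference"]


def interval_length(start: int, end: int, convention: LengthConvention = "inclusive") -> int:
    """Length of ``start..end`` under an explicit convention.

    ``inclusive`` counts both endpoints (``end - start + 1``); ``difference``
    is the raw coordinate span (``end - start``).
    """
    if end < start:
        raise ValueError(f"end < start: {start}..{end}")
    if convention == "inclusive":
        return end - start + 1
    if convention == "difference":
        return end - start
    raise ValueError(f"unknown length convention: {convention!r}")


def intervals_overlap(start_a: int, end_a: int, start_b: int, end_b: int) -> bool:
    """True iff the 1-based inclusive intervals share at least one base."""
    return start_a <= end_b and start_b <= end_a


def overlapping_features(
    chrom: str,
    start: int,
    end: int,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Rows of ``features`` (columns chrom/start/end/name) overlapping a query.

    Overlap means >= 1 shared base on 1-based inclusive coordinates.
    """
    sub = features[features["chrom"] == chrom]
    if sub.empty:
        return sub
    hit = (sub["start"].to_numpy() <= end) & (sub["end"].to_numpy() >= start)
    return sub[hit]


def nearest_feature(
    chrom: str,
    start: int,
    end: int,
    features: pd.DataFrame,
) -> tuple[str, int, str] | None:
    """Nearest feature to a query interval on the same chromosome.

    Returns ``(name, distance, orientation)`` where distance is 0 for any
    overlap, otherwise the coordinate gap ``feature.start - end`` (feature
    after the query, orientation ``"downstream"``) or ``start - feature.end``
    (feature before the query, ``"upstream"``). Orientation is relative to
    the query interval, not gene strand. Ties prefer the downstream feature.
    Returns None when the chromosome has no features.
    """
    sub = features[features["chrom"] == chrom]
    if sub.empty:
        return None
    f_start = sub["start"].to_numpy()
    f_end = sub["end"].to_numpy()
    names = sub["name"].to_numpy()

    overlap = (f_start <= end) & (f_end >= start)
    if overlap.any():
        i = int(np.argmax(overlap))
        return str(names[i]), 0, "overlap"

    # gap to features lying after / before the query
    down = np.where(f_start > end, f_start - end, np.iinfo(np.int64).max)
    up = np.where(f_end < start, start - f_end, np.iinfo(np.int64).max)
    i_down = int(np.argmin(down))
    i_up = int(np.argmin(up))
    if down[i_down] <= up[i_up]:
        return str(names[i_down]), int(down[i_down]), "downstream"
    return str(names[i_up]), int(up[i_up]), "upstream"


def is_autosome(chrom: str) -> bool:
    """Heuristic autosome test: the name, minus a ``chr`` prefix, is an integer.

    ``X``/``Y``/``MT`` and unplaced scaffold names (e.g. ``scaffold_123``,
    ``NW_0042...``) return False.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.isdigit()
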