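"""SNP site filtering and mutation-type (transition/transversion) accounting.

A transition exchanges purine for purine or pyrimidine for pyrimidine
(A<->G, C<->T); every other base exchange is a transversion. Whole-genome
SNP call sets typically show a ts:tv ratio between 2 and 3, so the six
unordered-pair counts are a standard sanity check on a call set.

Site filters follow the common resequencing convention: site read depth
strictly greater than a floor (default 4) and phred site quality at least
a threshold (default 20, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .variants import VALID_BASES, BiallelicVariant

logger = logging.getLogger(__name__)

#: canonical unordered-pair labels, transitions first
MUTATION_TYPES = ("AG", "CT", "AT", "AC", "GT", "GC")
TRANSITIONS = frozenset({"AG", "CT"})


def classify_mutation(ref: str, alt: str) -> tuple[str, str]:
    """Classify a ref/alt exchange into its unordered pair and ts/tv class.

    Returns ``(pair, kind)`` with pair one of AG/CT/AT/AC/GT/GC and kind
    ``"ts"`` or ``"tv"``. Symmetric in its arguments: (A,G) and (G,A) both
    map to ("AG", "ts").
    """
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"invalid base pair ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    for pair in MUTATION_TYPES:
        if {ref, alt} == set(pair):
            kind = "ts" if pair in TRANSITIONS else "tv"
            return pair, kind
    raise AssertionError("unreachable")  # all 6 unordered ACGT pairs enumerated


@dataclass
class MutationTypeSummary:
    """Counts of the six unordered SNP mutation types and the ts/tv split.

    ``ts_fraction``/``tv_fraction`` are None when ``total`` is 0.
    """

    counts: dict[str, int]
    ts_count: int
    tv_count: int
    total: int
    ts_fraction: float | None
    tv_fraction: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"type": t, "class": "ts" if t in TRANSITIONS else "tv", "count": self.counts[t]}
            for t in MUTATION_TYPES
        ]
        return pd.DataFrame(rows)


def summary_from_counts(counts: dict[str, int]) -> MutationTypeSummary:
    """Build a :class:`MutationTypeSummary` from per-type counts.

    Accepts keys in either base order (``AG`` or ``GA``).
    """
    canon = {t: 0 for t in MUTATION_TYPES}
    for key, n in counts.items():
        pair, _ = classify_mutation(key[0], key[1])
        canon[pair] += int(n)
    ts = canon["AG"] + canon["CT"]
    tv = sum(canon[t] for t in MUTATION_TYPES if t not in TRANSITIONS)
    total = ts + tv
    if total == 0:
        return MutationTypeSummary(canon, 0, 0, 0, None, None)
    return MutationTypeSummary(canon, ts, tv, total, ts / total, tv / total)


def summarize_mutation_types(variants: Iterable[BiallelicVariant]) -> MutationTypeSummary:
    """Tally mutation types over a (pre-filtered) variant stream."""
    counts = {t: 0 for t in MUTATION_TYPES}
    for v in variants:
        pair, _ = classify_mutation(v.ref, v.alt)
        counts[pair] += 1
    return summary_from_counts(counts)


def filter_sites(
    variants: Iterable[BiallelicVariant],
    min_depth: int = 4,
    min_quality: float = 20.0,
) -> Iterator[BiallelicVariant]:
    """Retain sites with depth > min_depth and quality >= min_quality.

    The depth cut is strict ("reads > 4") and the quality cut inclusive,
    mirroring the usual statement of these thresholds. Malformed records
    (identical or non-ACGT alleles) are skipped and counted, not raised.
    """
    if min_depth < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    skipped = 0
    for v in variants:
        if v.ref not in VALID_BASES or v.alt not in VALID_BASES or v.ref == v.alt:
            skipped += 1
            continue
        if v.depth > min_depth and v.quality >= min_quality:
            yield v
    if skipped:
        logger.info("filter_sites: skipped %d malformed records", skipped)


def per_chromosome_counts(variants: Iterable[BiallelicVariant]) -> pd.DataFrame:
    """SNP count per chromosome, in order of first appearance."""
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.chromosome] = counts.get(v.chromosome, 0) + 1
    return pd.DataFrame({"chromosome": list(counts), "n_snps": list(counts.values())})


def percent_one_decimal(fraction: float) -> float:
    """Report helper: fraction -> percentage rounded to one decimal."""
    return round(fraction * 100.0, 1)
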