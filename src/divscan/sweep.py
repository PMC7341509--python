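"""Windowed case/control Fst scan with Z-transformation.

The scan tiles each chromosome with fixed non-overlapping windows
(default 150 kb, 1-based inclusive ends) starting at coordinate 1,
accumulates per-site Fst components window by window as a ratio of sums,
standardizes window Fst across the retained windows (ZFst), and flags
the top fraction (default 1%) as selective-sweep candidates.

Estimator
---------
The default per-site components follow Hudson's two-population estimator
in the ratio-of-averages form recommended for windowed scans:

    numerator   = (p1 - p2)^2 - p1 q1 / (n1 - 1) - p2 q2 / (n2 - 1)
    denominator = p1 q2 + p2 q1

with ``p_i`` the ALT-allele frequency, ``q_i = 1 - p_i`` and ``n_i`` the
number of called alleles in group *i*. Window Fst is the sum of
numerators over the sum of denominators across contained SNPs, which is
robust at very small sample sizes (two diploids per group). A
Weir–Cockerham variant is available behind ``estimator="wc"``; the two
coincide at fixed differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import overlapping_features
from .variants import BiallelicVariant

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 150_000
DEFAULT_TOP_FRACTION = 0.01
DEFAULT_MIN_SNPS = 10


@dataclass(frozen=True)
class PopulationSplit:
    """Disjoint, non-empty case and control sample name lists."""

    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.case_samples or not self.control_samples:
            raise ValueError("both groups must be non-empty")
        if set(self.case_samples) & set(self.control_samples):
            raise ValueError("case and control sample sets overlap")

    def indices(self, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = (set(self.case_samples) | set(self.control_samples)) - set(samples)
        if missing:
            raise ValueError(f"samples not present in data: {sorted(missing)}")
        pos = {s: i for i, s in enumerate(samples)}
        return (
            np.array([pos[s] for s in self.case_samples]),
            np.array([pos[s] for s in self.control_samples]),
        )

    def swapped(self) -> "PopulationSplit":
        return PopulationSplit(self.control_samples, self.case_samples)


@dataclass
class FstWindow:
    """A fixed-span genomic window with its Fst scan results."""

    chromosome: str
    start: int  # 1-based
    end: int  # inclusive; end = start + window_size - 1
    n_snps: int
    fst: float
    zfst: float = float("nan")
    is_candidate: bool = False
    _num: float = field(default=0.0, repr=False)
    _den: float = field(default=0.0, repr=False)


def per_site_fst_components(
    case_allele_counts: tuple[int, int],
    control_allele_counts: tuple[int, int],
    estimator: str = "hudson",
) -> tuple[float, float]:
    """Per-site Fst numerator/denominator for one biallelic site.

    Arguments are ``(alt_allele_count, total_called_alleles)`` per group.
    Sites with fewer than 2 called alleles in either group return
    ``(nan, nan)`` (skip); monomorphic-identical sites return ``(0, 0)``
    and contribute nothing to a window's ratio of sums.
    """
    a1, n1 = case_allele_counts
    a2, n2 = control_allele_counts
    if n1 < 2 or n2 < 2:
        return (float("nan"), float("nan"))
    p1, p2 = a1 / n1, a2 / n2
    q1, q2 = 1.0 - p1, 1.0 - p2
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * q1 / (n1 - 1) - p2 * q2 / (n2 - 1)
        den = p1 * q2 + p2 * q1
    elif estimator == "wc":
        # Weir–Cockerham (1984), two populations, allele-count (haploid) form;
        # r = 2 so the r-1 factors are 1
        n_bar = (n1 + n2) / 2.0
        n_c = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
        p_bar = (a1 + a2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        a_comp = n_bar / n_c * (s2 - (p_bar * (1 - p_bar) - s2 / 2.0) / (n_bar - 1))
        b_comp = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 / 2.0)
        num, den = a_comp, a_comp + b_comp
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if den == 0.0:
        return (0.0, 0.0)
    return (num, den)


def window_fst(
    variants: Iterable[BiallelicVariant],
    samples: list[str],
    split: PopulationSplit,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_snps: int = DEFAULT_MIN_SNPS,
    estimator: str = "hudson",
) -> list[FstWindow]:
    """Windowed Fst (ratio of sums) over a position-sorted variant stream.

    Windows tile each chromosome from coordinate 1; a window is emitted
    only if it contains at least one usable SNP. Windows with fewer than
    ``min_snps`` SNPs or a zero summed denominator carry ``fst = nan`` and
    are excluded from the later Z-transform.
    """
    case_idx, ctrl_idx = split.indices(samples)
    acc: dict[tuple[str, int], list[float]] = {}  # (chrom, window index) -> [num, den, n]
    last: tuple[str, int] | None = None
    seen_chroms: list[str] = []
    for v in variants:
        key = (v.chromosome, v.position)
        if last is not None and v.chromosome == last[0] and v.position < last[1]:
            raise ValueError(f"variants not sorted by position at {v.chromosome}:{v.position}")
        if last is not None and v.chromosome != last[0] and v.chromosome in seen_chroms:
            raise ValueError(f"variants not grouped by chromosome at {v.chromosome}:{v.position}")
        if last is None or v.chromosome != last[0]:
            seen_chroms.append(v.chromosome)
        last = key
        num, den = per_site_fst_components(
            v.allele_counts(case_idx), v.allele_counts(ctrl_idx), estimator=estimator
        )
        if np.isnan(num):
            continue
        widx = (v.position - 1) // window_size
        slot = acc.setdefault((v.chromosome, widx), [0.0, 0.0, 0])
        slot[0] += num
        slot[1] += den
        slot[2] += 1

    windows = []
    for (chrom, widx), (num, den, n) in acc.items():
        start = widx * window_size + 1
        fst = num / den if (den > 0 and n >= min_snps) else float("nan")
        windows.append(FstWindow(chrom, start, start + window_size - 1, n, fst, _num=num, _den=den))
    windows.sort(key=lambda w: (seen_chroms.index(w.chromosome), w.start))
    return windows


def zfst_and_candidates(
    windows: list[FstWindow],
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> list[FstWindow]:
    """Z-transform window Fst and flag the top fraction as candidates.

    ZFst = (Fst - mean) / sd over retained (finite-Fst) windows, sd with
    n-1. The candidate threshold is the k-th largest ZFst with
    k = max(1, floor(top_fraction * n)); ties at the threshold are all
    included. Modifies and returns the window list.
    """
    retained = [w for w in windows if np.isfinite(w.fst)]
    if len(retained) < 2:
        raise ValueError("need at least 2 retained windows for Z-transformation")
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    fst = np.array([w.fst for w in retained])
    mean, sd = fst.mean(), fst.std(ddof=1)
    if sd == 0:
        raise ValueError("no variance across windows")
    z = (fst - mean) / sd
    k = max(1, int(np.floor(top_fraction * len(retained))))
    threshold = np.sort(z)[::-1][k - 1]
    for w, zi in zip(retained, z):
        w.zfst = float(zi)
        w.is_candidate = bool(zi >= threshold)
    return windows


def annotate_windows(candidates: list[FstWindow], genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each candidate window by >= 1 bp.

    ``genes`` has columns chrom/start/end/name on 1-based inclusive
    coordinates. Returns one row per (window, gene) pair; windows with no
    overlap get a single row with gene NA. Chromosome names present in the
    windows but absent from the annotation are reported with a warning.
    """
    unmatched = sorted({w.chromosome for w in candidates} - set(genes["chrom"].astype(str)))
    if unmatched:
        logger.warning("annotate_windows: no annotation for chromosomes %s", unmatched)
    rows = []
    for w in candidates:
        hits = overlapping_features(w.chromosome, w.start, w.end, genes)
        if hits.empty:
            rows.append({"chromosome": w.chromosome, "start": w.start, "end": w.end, "gene": pd.NA})
        else:
            for name in hits["name"]:
                rows.append({"chromosome": w.chromosome, "start": w.start, "end": w.end, "gene": name})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])


def windows_to_frame(windows: list[FstWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "fst": [w.fst for w in windows],
            "zfst": [w.zfst for w in windows],
            "is_candidate": [w.is_candidate for w in windows],
        }
    )
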