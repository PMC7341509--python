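"""Read-depth CNV region calling and Vst case/control differentiation.

Copy number is estimated from read counts on sliding windows (800 bp
windows, 400 bp step by default): each sample's counts are scaled so its
genome-wide median sits at the diploid value 2. Runs of consecutive
windows where any sample departs from diploid become initial calls;
adjacent calls are merged when they are close (gap under 20% of their
combined length) and their per-sample depth profiles are correlated
(Pearson test significant at p = 0.01). Each merged region is genotyped
to integer copy number per sample and scored with the Vst statistic

    Vst = (Vt - Vs) / Vt

where Vt is the population variance of all samples' mean log2(CN/2)
over the region and Vs the size-weighted mean within-group variance.
With size weighting Vst lies in [0, 1] by the law of total variance.

Genotype codes follow the copy-number convention: D = zero copies,
Ad = one, AA = two (diploid), AB = three, BB = four, M = five or more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import is_autosome, nearest_feature
from .sweep import PopulationSplit

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 800
DEFAULT_STEP = 400
DEFAULT_GAIN_THRESHOLD = 2.75
DEFAULT_LOSS_THRESHOLD = 1.25
DEFAULT_MIN_WINDOWS = 3
DEFAULT_MAX_GAP_FRACTION = 0.2
DEFAULT_CORR_P = 0.01
DEFAULT_MIN_LENGTH = 2000
DEFAULT_MIN_VST = 0.25
LOG2_FLOOR = 0.05

GENOTYPE_CODES = {0: "D", 1: "Ad", 2: "AA", 3: "AB", 4: "BB"}


@dataclass
class DepthWindowMatrix:
    """Per-sample read counts (and normalized copy number) on sliding windows."""

    chroms: np.ndarray  # (W,) str
    starts: np.ndarray  # (W,) int, 1-based
    counts: np.ndarray  # (W, S) int
    samples: list[str]
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_STEP
    normalized: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, window_size: int = DEFAULT_WINDOW_SIZE, step: int = DEFAULT_STEP
    ) -> "DepthWindowMatrix":
        samples = [c for c in df.columns if c not in ("chrom", "window_start")]
        return cls(
            chroms=df["chrom"].astype(str).to_numpy(),
            starts=df["window_start"].astype(int).to_numpy(),
            counts=df[samples].to_numpy(),
            samples=samples,
            window_size=window_size,
            step=step,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"chrom": self.chroms, "window_start": self.starts})
        for j, s in enumerate(self.samples):
            out[s] = self.counts[:, j]
        return out


def normalize_depth(matrix: DepthWindowMatrix, gc: np.ndarray | None = None) -> DepthWindowMatrix:
    """Scale raw window counts to copy-number units (diploid = 2).

    normalized[w, s] = 2 * counts[w, s] / median_w(counts[., s]). When a
    per-window GC fraction track is supplied, each value is additionally
    divided by the median normalized value of its GC decile bin over 2,
    re-centering every bin at diploid.
    """
    counts = matrix.counts.astype(float)
    medians = np.median(counts, axis=0)
    zero = np.flatnonzero(medians <= 0)
    if zero.size:
        bad = ", ".join(matrix.samples[i] for i in zero)
        raise ValueError(f"sample(s) with non-positive median window count: {bad}")
    ncn = 2.0 * counts / medians
    if gc is not None:
        gc = np.asarray(gc, dtype=float)
        if gc.shape[0] != ncn.shape[0]:
            raise ValueError("GC track length does not match window count")
        bins = np.clip((gc * 10).astype(int), 0, 9)
        for b in np.unique(bins):
            mask = bins == b
            bin_med = np.median(ncn[mask], axis=0)
            safe = np.where(bin_med > 0, bin_med, 2.0)
            ncn[mask] = ncn[mask] / (safe / 2.0)
    matrix.normalized = ncn
    return matrix


@dataclass
class RawCall:
    """A maximal run of consecutive out-of-diploid windows (pre-merge)."""

    chromosome: str
    start: int  # first window start, 1-based
    end: int  # last window end, inclusive
    first_window: int  # row index into the matrix
    last_window: int  # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CNVRegion:
    """A merged copy-number-variable region with per-sample genotypes."""

    chromosome: str
    start: int
    end: int
    first_window: int
    last_window: int
    samples: list[str]
    per_sample_cn_estimate: np.ndarray
    per_sample_cn_integer: np.ndarray
    genotype_codes: list[str]
    mean_log2_ratio: np.ndarray
    vst: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def initial_calls(
    matrix: DepthWindowMatrix,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> list[RawCall]:
    """Maximal runs of >= min_windows consecutive out-of-diploid windows.

    A window is out-of-diploid when any sample's normalized copy number is
    >= gain_threshold or <= loss_threshold. Runs must be consecutive in
    window order on one chromosome (start positions step by the matrix
    step size).
    """
    if matrix.normalized is None:
        raise ValueError("matrix must be normalized first (normalize_depth)")
    ncn = matrix.normalized
    flagged = ((ncn >= gain_threshold) | (ncn <= loss_threshold)).any(axis=1)
    calls: list[RawCall] = []
    run_start: int | None = None
    for i in range(len(flagged) + 1):
        boundary = (
            i == len(flagged)
            or not flagged[i]
            or (
                i > 0
                and flagged[i - 1]
                and (
                    matrix.chroms[i] != matrix.chroms[i - 1]
                    or matrix.starts[i] - matrix.starts[i - 1] != matrix.step
                )
            )
        )
        if run_start is not None and boundary:
            if i - run_start >= min_windows:
                calls.append(
                    RawCall(
                        chromosome=str(matrix.chroms[run_start]),
                        start=int(matrix.starts[run_start]),
                        end=int(matrix.starts[i - 1]) + matrix.window_size - 1,
                        first_window=run_start,
                        last_window=i - 1,
                    )
                )
            run_start = None
        if i < len(flagged) and flagged[i] and run_start is None:
            run_start = i
    return calls


def _mean_cn_vector(matrix: DepthWindowMatrix, first: int, last: int) -> np.ndarray:
    return matrix.normalized[first : last + 1].mean(axis=0)


def should_merge(
    a: RawCall,
    b: RawCall,
    matrix: DepthWindowMatrix,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    corr_p: float = DEFAULT_CORR_P,
) -> bool:
    """Merge rule for two adjacent calls on one chromosome.

    Distance rule: the gap between the calls must be strictly less than
    ``max_gap_fraction`` of their combined length. Correlation rule: the
    two calls' per-sample mean copy-number vectors must be significantly
    correlated (two-sided Pearson test, p < corr_p). With fewer than 3
    samples the correlation test is undefined and the distance rule
    decides alone.
    """
    if a.chromosome != b.chromosome:
        return False
    gap = b.start - a.end - 1
    if gap < 0:
        gap = 0  # overlapping sliding-window calls
    if gap >= max_gap_fraction * (a.length + b.length):
        return False
    n_samples = matrix.counts.shape[1]
    if n_samples < 3:
        logger.warning("should_merge: <3 samples, correlation test skipped (distance rule only)")
        return True
    va = _mean_cn_vector(matrix, a.first_window, a.last_window)
    vb = _mean_cn_vector(matrix, b.first_window, b.last_window)
    if np.std(va) == 0 or np.std(vb) == 0:
        return False  # constant profile: correlation undefined, treat as not significant
    r, p = stats.pearsonr(va, vb)
    return bool(p < corr_p)


def merge_calls(
    calls: list[RawCall],
    matrix: DepthWindowMatrix,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    corr_p: float = DEFAULT_CORR_P,
) -> list[CNVRegion]:
    """Iteratively merge adjacent calls left-to-right until a fixed point.

    Input calls must be sorted by (chromosome, start). Merged region
    coordinates snap to the first call's first-window start and the last
    call's last-window end; the spanned window range (gap windows
    included) provides the region's per-sample copy-number estimates.
    """
    for a, b in zip(calls, calls[1:]):
        if a.chromosome == b.chromosome and b.start < a.start:
            raise ValueError("calls must be sorted by (chromosome, start)")
    merged = list(calls)
    changed = True
    while changed:
        changed = False
        out: list[RawCall] = []
        for call in merged:
            if out and should_merge(out[-1], call, matrix, max_gap_fraction, corr_p):
                prev = out[-1]
                out[-1] = RawCall(
                    chromosome=prev.chromosome,
                    start=prev.start,
                    end=call.end,
                    first_window=prev.first_window,
                    last_window=call.last_window,
                )
                changed = True
            else:
                out.append(call)
        merged = out
    return [region_from_span(matrix, c.first_window, c.last_window) for c in merged]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; copy numbers are >= 0 so floor(x + 0.5)
    return np.floor(x + 0.5).astype(int)


def genotype_code(copy_number: int) -> str:
    """Integer copy number -> genotype code (0 D, 1 Ad, 2 AA, 3 AB, 4 BB, >=5 M)."""
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    return GENOTYPE_CODES.get(copy_number, "M")


def region_from_span(matrix: DepthWindowMatrix, first_window: int, last_window: int) -> CNVRegion:
    """Build a genotyped CNVRegion from a contiguous window span."""
    if matrix.normalized is None:
        raise ValueError("matrix must be normalized first")
    est = _mean_cn_vector(matrix, first_window, last_window)
    integer = _round_half_away(est)
    ncn = matrix.normalized[first_window : last_window + 1]
    log2r = np.log2(np.maximum(ncn, LOG2_FLOOR) / 2.0).mean(axis=0)
    return CNVRegion(
        chromosome=str(matrix.chroms[first_window]),
        start=int(matrix.starts[first_window]),
        end=int(matrix.starts[last_window]) + matrix.window_size - 1,
        first_window=first_window,
        last_window=last_window,
        samples=matrix.samples,
        per_sample_cn_estimate=est,
        per_sample_cn_integer=integer,
        genotype_codes=[genotype_code(int(c)) for c in integer],
        mean_log2_ratio=log2r,
    )


def vst(values: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray, weighted: bool = True) -> float:
    """Vst = (Vt - Vs) / Vt over per-sample region intensities.

    ``values`` are the samples' mean log2(CN/2) for the region. Vt is the
    population variance (divide by N) over all samples in the two groups;
    Vs is the size-weighted mean of the within-group population variances
    (unweighted mean behind ``weighted=False``). Returns 0 when Vt = 0.
    Size weighting guarantees Vst in [0, 1].
    """
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError("both groups must be non-empty")
    v_case = values[case_idx]
    v_ctrl = values[ctrl_idx]
    all_v = np.concatenate([v_case, v_ctrl])
    vt = float(np.var(all_v))
    if vt == 0.0:
        return 0.0
    v1 = float(np.var(v_case))
    v2 = float(np.var(v_ctrl))
    if weighted:
        vs = (len(v_case) * v1 + len(v_ctrl) * v2) / len(all_v)
    else:
        vs = (v1 + v2) / 2.0
    return (vt - vs) / vt


def compute_vst(
    regions: list[CNVRegion], split: PopulationSplit, weighted: bool = True
) -> list[CNVRegion]:
    """Fill the ``vst`` field of each region from its mean log2 ratios."""
    for region in regions:
        case_idx, ctrl_idx = split.indices(region.samples)
        region.vst = vst(region.mean_log2_ratio, case_idx, ctrl_idx, weighted=weighted)
    return regions


def filter_candidates(
    regions: list[CNVRegion],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_vst: float = DEFAULT_MIN_VST,
    autosomes_only: bool = True,
) -> list[CNVRegion]:
    """Retain regions with length > min_length and Vst > min_vst (both strict).

    By default regions on sex chromosomes and unplaced scaffolds are
    excluded from candidate reporting (X copy number confounds with sex).
    """
    out = []
    for r in regions:
        if autosomes_only and not is_autosome(r.chromosome):
            continue
        if r.length > min_length and r.vst > min_vst:
            out.append(r)
    return out


def annotate_regions(regions: list[CNVRegion], genes: pd.DataFrame) -> pd.DataFrame:
    """Overlapping or nearest gene per region with signed distance.

    Distance 0 for overlap; otherwise the coordinate gap to the nearest
    gene with an upstream/downstream label relative to the region. With an
    empty annotation every region is reported intergenic.
    """
    rows = []
    for r in regions:
        if genes.empty:
            hit = None
        else:
            hit = nearest_feature(r.chromosome, r.start, r.end, genes)
        name, dist, orient = hit if hit is not None else (pd.NA, pd.NA, "intergenic")
        rows.append(
            {
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "vst": r.vst,
                "gene": name,
                "distance": 0 if orient == "overlap" else dist,
                "orientation": orient,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "length", "vst", "gene", "distance", "orientation"],
    )


def regions_to_frame(regions: list[CNVRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "vst": r.vst,
        }
        for s, cn, code in zip(r.samples, r.per_sample_cn_integer, r.genotype_codes):
            row[f"cn_{s}"] = int(cn)
            row[f"gt_{s}"] = code
        rows.append(row)
    return pd.DataFrame(rows)
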