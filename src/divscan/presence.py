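"""Region presence/absence genotyping from normalized per-base read depth.

Given a per-base depth track and a candidate interval, each sample's
depth over the interval is normalized by that sample's genome-wide mean
depth (computed excluding the interval itself, so a true deletion does
not dilute its own baseline). The mean normalized ratio is classified:

* ratio < absent_threshold (default 0.05, "essentially zero")  -> absent
* ratio < het_threshold (default 0.75)                         -> heterozygous_loss
* otherwise                                                    -> present

A diploid carrier of a hemizygous deletion sits near ratio 0.5; a sample
with both copies sits near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_ABSENT_THRESHOLD = 0.05
DEFAULT_HET_THRESHOLD = 0.75

VERDICTS = ("absent", "heterozygous_loss", "present")


@dataclass
class RegionPresenceReport:
    """Per-sample normalized depth summary and verdict for one interval."""

    chromosome: str
    start: int
    end: int
    samples: list[str]
    mean_raw_depth: np.ndarray
    genome_mean_depth: np.ndarray
    normalized_ratio: np.ndarray
    verdicts: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "mean_raw_depth": self.mean_raw_depth,
                "genome_mean_depth": self.genome_mean_depth,
                "normalized_ratio": self.normalized_ratio,
                "verdict": self.verdicts,
            }
        )


def region_depth_profile(
    track: pd.DataFrame,
    region: tuple[str, int, int],
) -> pd.DataFrame:
    """Per-base depth over a region, normalized by genome-wide sample means.

    ``track`` has columns chrom, pos, then one column per sample (the
    samtools-depth layout). Positions absent from the track within the
    region read as depth 0; the genome-wide mean excludes the region.
    Returns a (region length) x samples DataFrame of normalized depth.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError(f"region end < start: {start}..{end}")
    if chrom not in set(track["chrom"].astype(str)):
        raise ValueError(f"chromosome {chrom!r} not present in depth track")
    samples = [c for c in track.columns if c not in ("chrom", "pos")]

    in_region = (track["chrom"].astype(str) == chrom) & track["pos"].between(start, end)
    outside = track.loc[~in_region, samples]
    if outside.empty:
        raise ValueError("depth track has no positions outside the queried region")
    genome_mean = outside.mean(axis=0).to_numpy(dtype=float)
    if (genome_mean <= 0).any():
        bad = [s for s, m in zip(samples, genome_mean) if m <= 0]
        raise ValueError(f"sample(s) with zero genome-wide depth: {bad}")

    length = end - start + 1
    profile = np.zeros((length, len(samples)))
    sub = track.loc[in_region]
    idx = sub["pos"].to_numpy() - start
    profile[idx] = sub[samples].to_numpy(dtype=float)
    return pd.DataFrame(profile / genome_mean, columns=samples)


def presence_verdict(
    profile: pd.DataFrame,
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
) -> dict[str, str]:
    """Classify each sample from its mean normalized ratio over the region."""
    if not (0 < absent_threshold < het_threshold < 1):
        raise ValueError("require 0 < absent_threshold < het_threshold < 1")
    if profile.empty:
        raise ValueError("empty depth profile")
    verdicts = {}
    for s in profile.columns:
        ratio = float(profile[s].mean())
        if ratio < absent_threshold:
            verdicts[s] = "absent"
        elif ratio < het_threshold:
            verdicts[s] = "heterozygous_loss"
        else:
            verdicts[s] = "present"
    return verdicts


def region_presence_report(
    track: pd.DataFrame,
    region: tuple[str, int, int],
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
) -> RegionPresenceReport:
    """Full presence report: profile, ratios and verdict per sample."""
    chrom, start, end = region
    samples = [c for c in track.columns if c not in ("chrom", "pos")]
    profile = region_depth_profile(track, region)
    verdicts = presence_verdict(profile, absent_threshold, het_threshold)

    in_region = (track["chrom"].astype(str) == chrom) & track["pos"].between(start, end)
    length = end - start + 1
    mean_raw = track.loc[in_region, samples].sum(axis=0).to_numpy(dtype=float) / length
    genome_mean = track.loc[~in_region, samples].mean(axis=0).to_numpy(dtype=float)
    return RegionPresenceReport(
        chromosome=chrom,
        start=start,
        end=end,
        samples=samples,
        mean_raw_depth=mean_raw,
        genome_mean_depth=genome_mean,
        normalized_ratio=mean_raw / genome_mean,
        verdicts=[verdicts[s] for s in samples],
    )
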