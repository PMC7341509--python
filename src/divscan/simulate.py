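"""Synthetic cohort generator for the case/control divergence pipeline.

Emulates the statistical structure the downstream stages assume, at desk
scale, for a small resequencing cohort (default 2 cases vs 6 controls,
the study design for a rare phenotype with very few affected animals):

* biallelic SNP genotypes drawn under Hardy–Weinberg within group from a
  shared Beta-distributed baseline allele frequency, with planted
  high-divergence windows where case and control frequencies are set
  independently (selective-sweep signal);
* per-sample read counts on sliding windows (800 bp window, 400 bp step)
  drawn Poisson with mean proportional to the local copy number, with
  planted copy-number gains/losses restricted to one group;
* a per-base depth track carrying an optional full or partial deletion
  in a chosen subset of samples (region presence/absence signal).

Sites are independent (no linkage) because every consuming statistic
uses per-site frequencies only. One master seed drives labeled
sub-streams so each output file is reproducible in isolation;
identical (config, seed) pairs give byte-identical files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cnv import DEFAULT_STEP, DEFAULT_WINDOW_SIZE

BASES = np.array(list("ACGT"))
# transition partner of A,C,G,T and the two transversion partners of each
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class PlantedSweep:
    chromosome: str
    start: int
    end: int
    case_freq: float
    control_freq: float


@dataclass(frozen=True)
class PlantedCNV:
    chromosome: str
    start: int
    end: int
    case_copy_number: int
    control_copy_number: int


@dataclass(frozen=True)
class PlantedDeletion:
    chromosome: str
    start: int
    end: int
    affected_samples: tuple[str, ...]
    residual_depth_fraction: float


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    ``mean_depth_per_sample`` is the Poisson mean read count per 800 bp
    window at diploid copy number; ``track_mean_depth`` is the per-base
    Poisson mean for the deletion track (default 15, a realistic
    mid-range per-base coverage for a resequencing study). The baseline
    allele-frequency distribution Beta(0.8, 0.8) gives the U-shaped site
    frequency spectrum typical of population SNP data.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_cases: int = 2
    n_controls: int = 6
    snp_density: float = 5e-4
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    planted_sweeps: tuple[PlantedSweep, ...] = ()
    planted_cnvs: tuple[PlantedCNV, ...] = ()
    planted_deletion: PlantedDeletion | None = None
    mean_depth_per_sample: float = 100.0
    track_mean_depth: float = 15.0
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_STEP
    ts_probability: float = 0.694  # genome-scale SNP sets are ts-rich (~2-3:1)
    site_depth_mean: float = 20.0
    site_quality: float = 60.0
    low_qual_fraction: float = 0.0
    low_qual_value: float = 10.0
    gc_bias: bool = False
    random_seed: int = 0

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def case_samples(self) -> list[str]:
        return [f"case_{i + 1}" for i in range(self.n_cases)]

    @property
    def control_samples(self) -> list[str]:
        return [f"control_{i + 1}" for i in range(self.n_controls)]

    @property
    def samples(self) -> list[str]:
        return self.case_samples + self.control_samples

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control sample")
        planted: list[tuple[str, int, int, str]] = []
        for s in self.planted_sweeps:
            if not (0.0 <= s.case_freq <= 1.0 and 0.0 <= s.control_freq <= 1.0):
                raise ValueError(f"allele frequencies must be in [0,1]: {s}")
            planted.append((s.chromosome, s.start, s.end, f"sweep {s.chromosome}:{s.start}-{s.end}"))
        for c in self.planted_cnvs:
            if c.case_copy_number < 0 or c.control_copy_number < 0:
                raise ValueError(f"copy numbers must be non-negative integers: {c}")
            planted.append((c.chromosome, c.start, c.end, f"cnv {c.chromosome}:{c.start}-{c.end}"))
        if self.planted_deletion is not None:
            d = self.planted_deletion
            if not (0.0 <= d.residual_depth_fraction <= 1.0):
                raise ValueError("residual_depth_fraction must be in [0,1]")
            unknown = set(d.affected_samples) - set(self.samples)
            if unknown:
                raise ValueError(f"deletion affects unknown samples: {sorted(unknown)}")
            planted.append((d.chromosome, d.start, d.end, f"deletion {d.chromosome}:{d.start}-{d.end}"))
        chroms = set(self.chromosomes)
        for chrom, start, end, label in planted:
            if chrom not in chroms:
                raise ValueError(f"{label}: chromosome not in simulated genome")
            if not (1 <= start <= end <= self.chromosome_length):
                raise ValueError(f"{label}: interval outside chromosome bounds")
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in planted:
            by_chrom.setdefault(chrom, []).append((start, end, label))
        for chrom, items in by_chrom.items():
            items.sort()
            for (s1, e1, l1), (s2, e2, l2) in zip(items, items[1:]):
                if s2 <= e1:
                    raise ValueError(f"planted intervals overlap: {l1} and {l2}")


@dataclass
class GroundTruth:
    """Record of every planted feature, 1-based inclusive intervals."""

    sweep_intervals: list[dict] = field(default_factory=list)
    cnv_intervals: list[dict] = field(default_factory=list)
    deletion_interval: dict | None = None
    n_snps_per_chromosome: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedCohort:
    """Paths to one simulated cohort's files plus its ground truth."""

    vcf_path: Path
    depth_matrix_path: Path
    ground_truth: GroundTruth
    samples: list[str]
    gc_track_path: Path | None = None


def _stream(config: SimulationConfig, label: str) -> np.random.Generator:
    """Deterministic labeled sub-stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.random_seed, zlib.crc32(label.encode())])
    )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate the VCF, depth-window matrix and ground-truth record.

    Genotypes are binomial(2, p) per sample under within-group
    Hardy–Weinberg; window read counts are Poisson with mean
    ``mean_depth_per_sample * CN / 2`` (times a GC multiplier when GC
    bias simulation is on).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth(
        sweep_intervals=[asdict(s) for s in config.planted_sweeps],
        cnv_intervals=[asdict(c) for c in config.planted_cnvs],
        deletion_interval=asdict(config.planted_deletion) if config.planted_deletion else None,
    )

    vcf_path = out_dir / "cohort.vcf"
    _write_snps(config, vcf_path, truth)
    depth_path = out_dir / "depth_windows.tsv"
    gc_path = _write_depth_matrix(config, depth_path, out_dir)
    truth.to_json(out_dir / "ground_truth.json")
    return SimulatedCohort(
        vcf_path=vcf_path,
        depth_matrix_path=depth_path,
        ground_truth=truth,
        samples=config.samples,
        gc_track_path=gc_path,
    )


def _write_snps(config: SimulationConfig, path: Path, truth: GroundTruth) -> None:
    rng = _stream(config, "vcf")
    a, b = config.allele_freq_beta

    def records():
        for chrom in config.chromosomes:
            n_snps = int(round(config.snp_density * config.chromosome_length))
            truth.n_snps_per_chromosome[chrom] = n_snps
            pos = np.sort(rng.choice(config.chromosome_length, size=n_snps, replace=False)) + 1
            p_case = rng.beta(a, b, size=n_snps)
            p_ctrl = p_case.copy()
            for sw in config.planted_sweeps:
                if sw.chromosome != chrom:
                    continue
                mask = (pos >= sw.start) & (pos <= sw.end)
                p_case[mask] = sw.case_freq
                p_ctrl[mask] = sw.control_freq
            g_case = rng.binomial(2, p_case[:, None], size=(n_snps, config.n_cases))
            g_ctrl = rng.binomial(2, p_ctrl[:, None], size=(n_snps, config.n_controls))
            dosage = np.concatenate([g_case, g_ctrl], axis=1).astype(np.int8)

            ref_idx = rng.integers(0, 4, size=n_snps)
            is_ts = rng.random(n_snps) < config.ts_probability
            tv_pick = rng.integers(0, 2, size=n_snps)
            depth = rng.poisson(config.site_depth_mean, size=n_snps)
            low = rng.random(n_snps) < config.low_qual_fraction
            for i in range(n_snps):
                ref = BASES[ref_idx[i]]
                alt = _TS_PARTNER[ref] if is_ts[i] else _TV_PARTNERS[ref][tv_pick[i]]
                qual = config.low_qual_value if low[i] else config.site_quality
                yield (chrom, int(pos[i]), ref, alt, qual, int(depth[i]), dosage[i])

    contigs = [(c, config.chromosome_length) for c in config.chromosomes]
    io.write_vcf(path, config.samples, records(), contigs)


def _window_starts(config: SimulationConfig) -> np.ndarray:
    last = config.chromosome_length - config.window_size + 1
    return np.arange(1, last + 1, config.step)


def _write_depth_matrix(config: SimulationConfig, path: Path, out_dir: Path) -> Path | None:
    rng = _stream(config, "depth")
    n_samples = config.n_cases + config.n_controls
    frames = []
    gc_frames = []
    for chrom in config.chromosomes:
        starts = _window_starts(config)
        ends = starts + config.window_size - 1
        cn = np.full((len(starts), n_samples), 2.0)
        for c in config.planted_cnvs:
            if c.chromosome != chrom:
                continue
            inside = (starts >= c.start) & (ends <= c.end)
            cn[inside, : config.n_cases] = c.case_copy_number
            cn[inside, config.n_cases :] = c.control_copy_number
        if config.gc_bias:
            gc = rng.beta(5, 5, size=len(starts))
            mult = 0.6 + 0.8 * gc  # linear GC response centered on 1.0
            gc_frames.append(pd.DataFrame({"chrom": chrom, "window_start": starts, "gc": np.round(gc, 6)}))
        else:
            mult = np.ones(len(starts))
        mean = config.mean_depth_per_sample * (cn / 2.0) * mult[:, None]
        counts = rng.poisson(mean)
        df = pd.DataFrame({"chrom": chrom, "window_start": starts})
        for j, s in enumerate(config.samples):
            df[s] = counts[:, j]
        frames.append(df)
    io.write_depth_matrix(path, pd.concat(frames, ignore_index=True))
    if gc_frames:
        gc_path = out_dir / "gc_windows.tsv"
        pd.concat(gc_frames, ignore_index=True).to_csv(gc_path, sep="\t", index=False)
        return gc_path
    return None


def simulate_deletion_track(config: SimulationConfig, out_path: str | Path) -> Path:
    """Per-base depth track for the chromosome carrying the planted deletion.

    All samples draw Poisson per-base depth with mean ``track_mean_depth``
    outside the deletion; inside it, affected samples' mean is scaled by
    ``residual_depth_fraction`` (0 gives hard zeros).
    """
    config.validate()
    if config.planted_deletion is None:
        raise ValueError("config has no planted_deletion")
    d = config.planted_deletion
    rng = _stream(config, "track")
    samples = config.samples
    pos = np.arange(1, config.chromosome_length + 1)
    mean = np.full((len(pos), len(samples)), float(config.track_mean_depth))
    inside = (pos >= d.start) & (pos <= d.end)
    affected = [samples.index(s) for s in d.affected_samples]
    for j in affected:
        mean[inside, j] = d.residual_depth_fraction * config.track_mean_depth
    depth = rng.poisson(mean)
    df = pd.DataFrame({"chrom": d.chromosome, "pos": pos})
    for j, s in enumerate(samples):
        df[s] = depth[:, j]
    out_path = Path(out_path)
    io.write_depth_track(out_path, df)
    return out_path


def simulate_gene_annotation(
    config: SimulationConfig,
    out_path: str | Path,
    gene_length: int = 4_000,
    gene_spacing: int = 20_000,
) -> Path:
    """Deterministic tiled gene model (BED) covering the simulated genome.

    Genes are laid out every ``gene_spacing`` bp so every planted feature
    has nearby and overlapping genes to annotate against.
    """
    rows = []
    gene_id = 0
    for chrom in config.chromosomes:
        start = 1
        while start + gene_length - 1 <= config.chromosome_length:
            gene_id += 1
            # BED: 0-based half-open
            rows.append((chrom, start - 1, start + gene_length - 1, f"gene_{gene_id}"))
            start += gene_spacing
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    return out_path


def simulate_term_map(
    gene_names: list[str],
    out_path: str | Path,
    n_terms: int = 50,
    term_size: int = 10,
    seed: int = 0,
) -> Path:
    """Random term-to-gene TSV over a gene universe (uniform membership)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"terms")]))
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for t in range(n_terms):
            members = rng.choice(len(gene_names), size=min(term_size, len(gene_names)), replace=False)
            for m in sorted(members):
                fh.write(f"term_{t + 1}\t{gene_names[m]}\n")
    return out_path
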