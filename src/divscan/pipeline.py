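"""End-to-end orchestration: simulate -> snp-stats -> sweep -> cnv -> presence -> enrich.

A :class:`PipelineConfig` (YAML or JSON on disk) carries every stage
parameter with the pipeline's defaults: 150 kb sweep windows with a top-1%
ZFst cut, 800/400 bp depth windows, CNVR filters length > 2000 bp and
Vst > 0.25, SNP filters depth > 4 and quality >= 20. Each run writes its
stage outputs plus a ``summary.json`` and a resolved copy of the config
into the run directory; re-running with the same config and seed is
byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cnv as cnv_mod
from . import io
from . import presence as presence_mod
from . import sweep as sweep_mod
from . import variant_stats as vs
from .enrichment import TermMap, hypergeometric_enrichment
from .simulate import (
    PlantedCNV,
    PlantedDeletion,
    PlantedSweep,
    SimulationConfig,
    simulate_cohort,
    simulate_deletion_track,
    simulate_gene_annotation,
    simulate_term_map,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 4
    min_quality: float = 20.0
    sweep_window_size: int = sweep_mod.DEFAULT_WINDOW_SIZE
    sweep_top_fraction: float = sweep_mod.DEFAULT_TOP_FRACTION
    sweep_min_snps: int = sweep_mod.DEFAULT_MIN_SNPS
    cnv_gain_threshold: float = cnv_mod.DEFAULT_GAIN_THRESHOLD
    cnv_loss_threshold: float = cnv_mod.DEFAULT_LOSS_THRESHOLD
    cnv_min_windows: int = cnv_mod.DEFAULT_MIN_WINDOWS
    cnv_max_gap_fraction: float = cnv_mod.DEFAULT_MAX_GAP_FRACTION
    cnv_corr_p: float = cnv_mod.DEFAULT_CORR_P
    cnv_min_length: int = cnv_mod.DEFAULT_MIN_LENGTH
    cnv_min_vst: float = cnv_mod.DEFAULT_MIN_VST
    cnv_autosomes_only: bool = True
    absent_threshold: float = presence_mod.DEFAULT_ABSENT_THRESHOLD
    het_threshold: float = presence_mod.DEFAULT_HET_THRESHOLD
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = dict(raw.pop("simulation", {}))
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(sim_unknown)}")
        if "planted_sweeps" in sim_raw:
            sim_raw["planted_sweeps"] = tuple(PlantedSweep(**d) for d in sim_raw["planted_sweeps"])
        if "planted_cnvs" in sim_raw:
            sim_raw["planted_cnvs"] = tuple(PlantedCNV(**d) for d in sim_raw["planted_cnvs"])
        if sim_raw.get("planted_deletion") is not None:
            d = dict(sim_raw["planted_deletion"])
            d["affected_samples"] = tuple(d["affected_samples"])
            sim_raw["planted_deletion"] = PlantedDeletion(**d)
        if "allele_freq_beta" in sim_raw:
            sim_raw["allele_freq_beta"] = tuple(sim_raw["allele_freq_beta"])
        cfg = cls(simulation=SimulationConfig(**sim_raw), **raw)
        cfg.simulation.random_seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, (list, tuple)):
                return [listify(x) for x in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(dataclasses.asdict(self))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in dependency order; returns the summary dict.

    Writes into ``out_dir``: the simulated inputs, per-stage TSV outputs,
    ``summary.json`` and ``resolved_config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    sim.random_seed = config.seed

    summary: dict = {"seed": config.seed}

    logger.info("stage simulate")
    cohort = simulate_cohort(sim, out_dir / "simulated")
    annotation_path = simulate_gene_annotation(sim, out_dir / "simulated" / "genes.bed")
    genes = io.read_gene_annotation(annotation_path)
    term_path = simulate_term_map(list(genes["name"]), out_dir / "simulated" / "terms.tsv", seed=config.seed)
    split = sweep_mod.PopulationSplit(tuple(sim.case_samples), tuple(sim.control_samples))
    io.write_sample_groups(out_dir / "simulated" / "groups.tsv", sim.case_samples, sim.control_samples)

    logger.info("stage snp-stats")
    filtered = list(
        vs.filter_sites(io.read_vcf(cohort.vcf_path), config.min_depth, config.min_quality)
    )
    mts = vs.summarize_mutation_types(filtered)
    mts.to_frame().to_csv(out_dir / "mutation_types.tsv", sep="\t", index=False)
    vs.per_chromosome_counts(filtered).to_csv(out_dir / "snps_per_chromosome.tsv", sep="\t", index=False)
    summary["snp_total"] = mts.total
    summary["ts_fraction_pct"] = vs.percent_one_decimal(mts.ts_fraction) if mts.total else None
    summary["tv_fraction_pct"] = vs.percent_one_decimal(mts.tv_fraction) if mts.total else None

    logger.info("stage sweep")
    windows = sweep_mod.window_fst(
        iter(filtered), cohort.samples, split, config.sweep_window_size, config.sweep_min_snps
    )
    windows = sweep_mod.zfst_and_candidates(windows, config.sweep_top_fraction)
    sweep_mod.windows_to_frame(windows).to_csv(out_dir / "fst_windows.tsv", sep="\t", index=False)
    candidates = [w for w in windows if w.is_candidate]
    with open(out_dir / "candidate_windows.bed", "w") as fh:
        for w in candidates:
            fh.write(f"{w.chromosome}\t{w.start - 1}\t{w.end}\t{w.zfst:.4f}\n")
    window_genes = sweep_mod.annotate_windows(candidates, genes)
    window_genes.to_csv(out_dir / "candidate_window_genes.tsv", sep="\t", index=False)
    summary["n_windows"] = len(windows)
    summary["n_candidate_windows"] = len(candidates)

    logger.info("stage cnv")
    matrix = cnv_mod.DepthWindowMatrix.from_frame(
        io.read_depth_matrix(cohort.depth_matrix_path), sim.window_size, sim.step
    )
    cnv_mod.normalize_depth(matrix)
    calls = cnv_mod.initial_calls(
        matrix, config.cnv_gain_threshold, config.cnv_loss_threshold, config.cnv_min_windows
    )
    regions = cnv_mod.merge_calls(calls, matrix, config.cnv_max_gap_fraction, config.cnv_corr_p)
    cnv_mod.compute_vst(regions, split)
    cnv_candidates = cnv_mod.filter_candidates(
        regions, config.cnv_min_length, config.cnv_min_vst, config.cnv_autosomes_only
    )
    cnv_mod.regions_to_frame(regions).to_csv(out_dir / "cnv_regions.tsv", sep="\t", index=False)
    cand_frame = cnv_mod.annotate_regions(cnv_candidates, genes)
    cand_frame.to_csv(out_dir / "candidate_cnv_regions.tsv", sep="\t", index=False)
    summary["n_cnv_regions"] = len(regions)
    summary["n_candidate_cnv_regions"] = len(cnv_candidates)
    summary["candidate_cnv_regions"] = json.loads(
        cnv_mod.regions_to_frame(cnv_candidates).to_json(orient="records")
    )

    if sim.planted_deletion is not None:
        logger.info("stage presence")
        track_path = simulate_deletion_track(sim, out_dir / "simulated" / "deletion_track.tsv")
        track = io.read_depth_track(track_path)
        d = sim.planted_deletion
        report = presence_mod.region_presence_report(
            track, (d.chromosome, d.start, d.end), config.absent_threshold, config.het_threshold
        )
        report.to_frame().to_csv(out_dir / "region_presence.tsv", sep="\t", index=False)
        summary["presence_verdicts"] = dict(zip(report.samples, report.verdicts))

    logger.info("stage enrichment")
    query = sorted(set(window_genes["gene"].dropna()) | set(cand_frame["gene"].dropna()))
    if query:
        term_map = TermMap(io.read_term_map(term_path))
        table = hypergeometric_enrichment(query, term_map)
        table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        summary["n_significant_terms"] = int(table["significant"].sum())
        summary["n_significant_terms_fdr"] = int(table["significant_fdr"].sum())
    else:
        summary["n_significant_terms"] = 0
        summary["n_significant_terms_fdr"] = 0

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return summary
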