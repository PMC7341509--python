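"""Shared fixtures: small simulated cohorts and hand-built variant streams."""

from __future__ import annotations

import numpy as np
import pytest

import divscan as d


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    qual=60.0,
    depth=30,
    dosage=(0, 0, 1, 1, 2, 2, 0, 1),
) -> d.BiallelicVariant:
    return d.BiallelicVariant(
        chromosome=chrom,
        position=pos,
        ref=ref,
        alt=alt,
        quality=qual,
        depth=depth,
        genotypes=np.asarray(dosage, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def split_2v6() -> d.PopulationSplit:
    return d.PopulationSplit(
        ("case_1", "case_2"),
        tuple(f"control_{i + 1}" for i in range(6)),
    )


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory):
    """A 20 Mb single-chromosome cohort with no planted features (~20k SNPs)."""
    cfg = d.SimulationConfig(
        n_chromosomes=1,
        chromosome_length=20_000_000,
        snp_density=1e-3,
        random_seed=202,
    )
    out = tmp_path_factory.mktemp("null_cohort")
    return cfg, d.simulate_cohort(cfg, out)


@pytest.fixture(scope="session")
def cnv_cohort(tmp_path_factory):
    """Cohort with one case-only gain (CN 3) on a 200 kb chromosome."""
    cfg = d.SimulationConfig(
        n_chromosomes=1,
        chromosome_length=200_000,
        snp_density=1e-4,
        planted_cnvs=(d.PlantedCNV("chr1", 50_001, 90_000, 3, 2),),
        mean_depth_per_sample=100.0,
        random_seed=77,
    )
    out = tmp_path_factory.mktemp("cnv_cohort")
    return cfg, d.simulate_cohort(cfg, out)
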