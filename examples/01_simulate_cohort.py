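"""Simulate a small case/control resequencing cohort with planted signals.

Generates a VCF (2 cases + 6 controls), an 800/400 bp depth-window
matrix, and a ground-truth record of every planted feature.
"""

import tempfile

import divscan as d

config = d.SimulationConfig(
    n_chromosomes=1,
    chromosome_length=400_000,
    snp_density=1e-3,
    planted_sweeps=(d.PlantedSweep("chr1", 100_001, 110_000, case_freq=1.0, control_freq=0.0),),
    planted_cnvs=(d.PlantedCNV("chr1", 200_001, 203_200, case_copy_number=3, control_copy_number=2),),
    mean_depth_per_sample=100.0,
    random_seed=1,
)
cohort = d.simulate_cohort(config, tempfile.mkdtemp())

print(f"VCF:          {cohort.vcf_path}")
print(f"depth matrix: {cohort.depth_matrix_path}")
print(f"samples:      {cohort.samples}")
print(f"SNPs/chrom:   {cohort.ground_truth.n_snps_per_chromosome}")
print(f"planted:      {len(cohort.ground_truth.sweep_intervals)} sweep, "
      f"{len(cohort.ground_truth.cnv_intervals)} CNV")
# The sweep interval is a fixed difference (cases alt, controls ref) and the
# CNV gives cases three copies where controls keep two; downstream examples
# recover both from these files alone.
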