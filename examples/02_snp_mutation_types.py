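"""Site filtering and transition/transversion accounting on a simulated VCF."""

import tempfile

import divscan as d
from divscan import io
from divscan.variant_stats import percent_one_decimal

config = d.SimulationConfig(
    n_chromosomes=1, chromosome_length=2_000_000, snp_density=1e-3,
    low_qual_fraction=0.1, random_seed=2,
)
cohort = d.simulate_cohort(config, tempfile.mkdtemp())

# depth > 4 and quality >= 20, the usual resequencing site filter
filtered = list(d.filter_sites(io.read_vcf(cohort.vcf_path), min_depth=4, min_quality=20))
summary = d.summarize_mutation_types(filtered)

print(f"sites after filtering: {summary.total} (of {sum(cohort.ground_truth.n_snps_per_chromosome.values())})")
for pair, n in summary.counts.items():
    print(f"  {pair[0]}/{pair[1]}: {n}")
print(f"ts = {percent_one_decimal(summary.ts_fraction)}%  tv = {percent_one_decimal(summary.tv_fraction)}%")
# A genome-scale call set is transition-rich; a ts fraction near 2-3:1
# (~70%) indicates a call set without gross artefacts.
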