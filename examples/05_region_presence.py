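"""Presence/absence genotyping of a candidate interval from per-base depth.

Each sample's depth over the region is normalized by its genome-wide
mean; ratios near 0 mean the region is missing, near 0.5 a single-copy
loss, near 1 both copies present.
"""

import tempfile

import divscan as d
from divscan import io

config = d.SimulationConfig(
    n_chromosomes=1,
    chromosome_length=40_000,
    track_mean_depth=15.0,
    planted_deletion=d.PlantedDeletion(
        "chr1", 10_001, 18_787, affected_samples=("case_1",), residual_depth_fraction=0.0
    ),
    random_seed=5,
)
track_path = d.simulate_deletion_track(config, tempfile.mktemp(suffix=".tsv"))
track = io.read_depth_track(track_path)

report = d.region_presence_report(track, ("chr1", 10_001, 18_787))
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# case_1 carries the planted homozygous deletion: its normalized ratio is
# ~0 ("absent"); every other sample sits near 1 ("present").
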