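"""Core SNP record type shared by the VCF reader and all site-level stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGT")


@dataclass
class BiallelicVariant:
    """One biallelic SNP site.

    ``genotypes`` holds the per-sample ALT-allele dosage: 0 (hom ref),
    1 (het), 2 (hom alt) or -1 for a missing call. ``depth`` is the
    site-level read count (VCF INFO/DP); ``quality`` the phred-scaled
    site quality.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    quality: float
    depth: int
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chromosome}:{self.position}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def allele_counts(self, sample_idx: np.ndarray) -> tuple[int, int]:
        """(alt allele count, total called alleles) over a sample subset."""
        g = self.genotypes[sample_idx]
        called = g >= 0
        return int(g[called].sum()), int(2 * called.sum())
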