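"""Readers and writers for the pipeline's file formats.

Formats handled here:

* VCF (read via cyvcf2; written as minimal VCFv4.2 text by the simulator),
* depth-window matrix TSV: ``chrom  window_start  <sample columns>``
  with 1-based window starts,
* per-base depth track TSV in the samtools-depth layout
  (``chrom  pos  d1..dN``), optionally with a ``#``-prefixed header
  carrying sample names,
* gene annotation as BED (0-based half-open, converted on read) or GFF3
  ``gene`` records (1-based inclusive),
* sample-group TSV (``sample  group`` with group in {case, control}),
* term-to-gene maps as GMT or two-column TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .variants import VALID_BASES, BiallelicVariant

logger = logging.getLogger(__name__)

# cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_GT_TYPE_TO_DOSAGE = np.array([0, 1, -1, 2], dtype=np.int8)


def read_vcf_samples(path: str | Path) -> list[str]:
    return list(VCF(str(path)).samples)


def read_vcf(path: str | Path) -> Iterator[BiallelicVariant]:
    """Stream biallelic ACGT SNPs from a VCF.

    Multi-allelic records, indels and non-ACGT alleles are skipped with a
    single summary log line at the end of iteration.
    """
    vcf = VCF(str(path))
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in VALID_BASES or rec.ALT[0] not in VALID_BASES:
            skipped += 1
            continue
        dosage = _GT_TYPE_TO_DOSAGE[np.asarray(rec.gt_types, dtype=np.int64)]
        info_dp = rec.INFO.get("DP")
        depth = int(info_dp) if info_dp is not None else int(np.sum(rec.format("DP") or 0))
        yield BiallelicVariant(
            chromosome=rec.CHROM,
            position=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
            depth=depth,
            genotypes=dosage,
        )
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path: str | Path,
    samples: list[str],
    records: Iterator[tuple[str, int, str, str, float, int, np.ndarray]],
    contigs: list[tuple[str, int]],
) -> None:
    """Write a minimal VCFv4.2 with GT-only FORMAT and INFO/DP.

    ``records`` yields ``(chrom, pos, ref, alt, qual, depth, dosage)``.
    No file date is emitted so identical inputs give byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, depth, dosage in records:
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in dosage)
            qual_s = f"{qual:g}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual_s}\tPASS\tDP={depth}\tGT\t{gts}\n")


def read_depth_matrix(path: str | Path) -> pd.DataFrame:
    """Depth-window matrix TSV -> DataFrame with chrom, window_start, samples."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].lstrip("#") != df.columns[0]:
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    required = {"chrom", "window_start"}
    if not required <= set(df.columns):
        raise ValueError(f"depth matrix must have columns {sorted(required)}; got {list(df.columns)[:4]}")
    return df


def write_depth_matrix(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_depth_track(path: str | Path, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-base depth TSV (samtools-depth layout) -> DataFrame.

    A leading ``#chrom pos s1..sN`` header is honoured; otherwise samples
    are named ``sample_1..N`` unless names are supplied.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        n_s = df.shape[1] - 2
        names = samples if samples is not None else [f"sample_{i + 1}" for i in range(n_s)]
        df.columns = ["chrom", "pos"] + list(names)
    return df


def write_depth_track(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED or GFF3 -> DataFrame(chrom, start, end, name).

    Coordinates are returned 1-based inclusive. BED (0-based half-open
    start) is shifted by +1 on read; GFF3 is taken as-is, keeping only
    ``gene`` features and their Name (falling back to ID) attribute.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3_genes(path)
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    out = pd.DataFrame(
        {
            "chrom": bed[0].astype(str),
            "start": bed[1].astype(int) + 1,
            "end": bed[2].astype(int),
            "name": bed[3].astype(str) if bed.shape[1] > 3 else [f"feature_{i}" for i in range(len(bed))],
        }
    )
    return out


def _read_gff3_genes(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
            rows.append((f[0], int(f[3]), int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_sample_groups(path: str | Path) -> tuple[list[str], list[str]]:
    """Sample-group TSV -> (case sample names, control sample names)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    groups = df["group"].str.lower()
    cases = df.loc[groups == "case", "sample"].astype(str).tolist()
    controls = df.loc[groups == "control", "sample"].astype(str).tolist()
    unknown = sorted(set(groups) - {"case", "control"})
    if unknown:
        raise ValueError(f"unknown group labels in {path}: {unknown} (expected case/control)")
    return cases, controls


def write_sample_groups(path: str | Path, cases: list[str], controls: list[str]) -> None:
    with open(path, "w") as fh:
        for s in cases:
            fh.write(f"{s}\tcase\n")
        for s in controls:
            fh.write(f"{s}\tcontrol\n")


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Term-to-gene map from GMT (term, description, genes...) or 2-col TSV."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 3:
                    continue
                terms.setdefault(f[0], set()).update(g for g in f[2:] if g)
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
        for term, gene in zip(df["term"].astype(str), df["gene"].astype(str)):
            terms.setdefault(term, set()).add(gene)
    return terms


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` string (1-based inclusive)."""
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.replace(",", "").split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {region!r} (expected chrom:start-end)") from exc
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start, end
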