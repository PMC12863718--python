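"""Flat-file readers/writers for the CLI layer.

VCF parsing here is deliberately minimal (plain-text, GT-only phased
records) because the fixture bundles are uncompressed single-contig VCFs;
site lookup is by ID.  Coverage input follows the samtools-bedcov layout,
in long format with one row per (sample, window).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .c4 import CoverageProfile, WindowBed, window_depth
from .errors import MissingSiteError, WindowMismatchError
from .haplotypes import (
    B8Dosage,
    DEFAULT_TRISNP,
    TriSnpDefinition,
    TriSnpGenotype,
    call_trisnp,
    impute_b8_dosage,
)

__all__ = [
    "read_vcf_genotypes",
    "call_cohort_from_vcf",
    "read_coverage_long",
    "read_metadata",
]


def read_vcf_genotypes(path) -> tuple[list[str], dict[str, list]]:
    """Parse a plain-text VCF into (sample_ids, site_id -> site record).

    Each site record is a dict with 'ref', 'alt' and 'calls'; each call is
    ((alleleA, alleleB), phased) with nucleotide alleles, or None for
    missing genotypes.
    """
    samples: list[str] = []
    sites: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            _, _, site_id, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            alleles = [ref] + alt.split(",")
            calls = []
            for entry in fields[9:]:
                gt = entry.split(":")[gt_idx]
                phased = "|" in gt
                parts = gt.replace("|", "/").split("/")
                if "." in parts or len(parts) != 2:
                    calls.append(None)
                    continue
                pair = tuple(alleles[int(p)] for p in parts)
                calls.append((pair, phased))
            sites[site_id] = {"ref": ref, "alt": alt, "calls": calls}
    return samples, sites


def call_cohort_from_vcf(
    path,
    defn: TriSnpDefinition = DEFAULT_TRISNP,
    b8_site_prefix: str = "b8tag",
) -> pd.DataFrame:
    """Per-subject tri-SNP genotype and B8 dosage calls from a phased VCF."""
    samples, sites = read_vcf_genotypes(path)
    for sid in defn.site_ids:
        if sid not in sites:
            raise MissingSiteError(f"site {sid} absent from {path}")
    b8_sites = sorted(s for s in sites if s.startswith(b8_site_prefix))
    rows = []
    for i, sample in enumerate(samples):
        pairs, phased = [], []
        for sid in defn.site_ids:
            call = sites[sid]["calls"][i]
            pairs.append(None if call is None else call[0])
            phased.append(True if call is None else call[1])
        geno = call_trisnp(pairs, defn, phased)
        row = {
            "subject_id": sample,
            "hap_a": geno.hap_a,
            "hap_b": geno.hap_b,
            "genotype": geno.label,
            "trisnp_101_dosage": geno.dosage("101"),
        }
        if b8_sites:
            alt_counts = []
            for sid in b8_sites:
                call = sites[sid]["calls"][i]
                if call is None:
                    alt_counts.append(None)
                    continue
                pair, _ = call
                ref = sites[sid]["ref"]
                alt_counts.append(sum(1 for a in pair if a != ref))
            b8 = impute_b8_dosage(alt_counts)
            row["b8_dosage"] = b8.dosage
            row["b8_sites_used"] = b8.n_sites_used
        rows.append(row)
    return pd.DataFrame(rows)


def read_coverage_long(path, windows: WindowBed) -> list[CoverageProfile]:
    """Long-format coverage TSV -> per-sample profiles.

    Expected columns: sample_id, chrom, start, end, sum_all, sum_uniq,
    with one row per window per sample in window order.
    """
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        if len(grp) != len(windows) or not (
            (grp["start"].to_numpy() == windows.starts).all()
            and (grp["end"].to_numpy() == windows.ends).all()
        ):
            raise WindowMismatchError(
                f"{sample_id}: coverage rows do not match the window BED"
            )
        profiles.append(window_depth(
            str(sample_id), windows,
            grp["sum_all"].to_numpy(float), grp["sum_uniq"].to_numpy(float),
        ))
    return profiles


def read_metadata(path) -> pd.DataFrame:
    """Subject metadata TSV (header required, one row per subject)."""
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError("metadata must contain a subject_id column")
    return df
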