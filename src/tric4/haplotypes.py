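"""Tri-SNP haplotype calling and HLA x tri-SNP cross-tabulation.

The exposure of interest is a three-site haplotype in intron 1 of
*HLA-DRA* (rs3135394, rs9268645, rs3129877), written as a binary string
with '0' for the reference and '1' for the alternate allele.  With the
default site alleles the nucleotide haplotype AGG encodes as "010" and
GCA as "101".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .association import ContingencyTable
from .errors import (
    AlleleMismatchError,
    LabelParseError,
    MissingSiteError,
    NoDataError,
    PhasingError,
)

__all__ = [
    "TriSnpSite",
    "TriSnpDefinition",
    "DEFAULT_TRISNP",
    "TriSnpGenotype",
    "HlaGenotype",
    "B8Dosage",
    "call_trisnp",
    "decode_haplotype",
    "impute_b8_dosage",
    "crosstab_hla_trisnp",
    "decompose_genotype_label",
    "chromosome_haplotype_counts",
    "chromosomes_by_hla_within_trisnp",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class TriSnpSite:
    snp_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"{self.snp_id}: invalid allele {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are equal")

    def encode(self, allele: str) -> str:
        if allele == self.ref_allele:
            return "0"
        if allele == self.alt_allele:
            return "1"
        raise AlleleMismatchError(
            f"{self.snp_id}: allele {allele!r} is neither ref "
            f"({self.ref_allele}) nor alt ({self.alt_allele})"
        )

    def decode(self, code: str) -> str:
        return self.ref_allele if code == "0" else self.alt_allele


@dataclass(frozen=True)
class TriSnpDefinition:
    """Ordered site triple defining the haplotype encoding."""

    sites: tuple[TriSnpSite, TriSnpSite, TriSnpSite]

    def __post_init__(self) -> None:
        if len(self.sites) != 3:
            raise ValueError("exactly 3 sites required")

    @property
    def site_ids(self) -> tuple[str, str, str]:
        return tuple(s.snp_id for s in self.sites)  # type: ignore[return-value]

    @classmethod
    def from_yaml(cls, path) -> "TriSnpDefinition":
        """Load a site configuration: a ``sites`` list of mappings with
        snp_id, ref and alt keys, in haplotype order."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = tuple(
            TriSnpSite(s["snp_id"], s["ref"], s["alt"]) for s in raw["sites"]
        )
        return cls(sites)


#: Default allele configuration.  Chosen so the two exemplar haplotypes
#: map as AGG -> "010" and GCA -> "101".
DEFAULT_TRISNP = TriSnpDefinition(
    (
        TriSnpSite("rs3135394", "A", "G"),
        TriSnpSite("rs9268645", "C", "G"),
        TriSnpSite("rs3129877", "G", "A"),
    )
)


def _validate_code(code: str) -> str:
    if len(code) != 3 or set(code) - {"0", "1"}:
        raise ValueError(f"haplotype code must be 3 chars over {{0,1}}: {code!r}")
    return code


@dataclass(frozen=True)
class TriSnpGenotype:
    """Unordered pair of tri-SNP haplotype codes."""

    hap_a: str
    hap_b: str

    def __post_init__(self) -> None:
        a, b = sorted((_validate_code(self.hap_a), _validate_code(self.hap_b)))
        object.__setattr__(self, "hap_a", a)
        object.__setattr__(self, "hap_b", b)

    @property
    def label(self) -> str:
        return f"{self.hap_a}/{self.hap_b}"

    def dosage(self, code: str = "101") -> int:
        """Number of chromosomes carrying ``code`` (0, 1 or 2)."""
        return int(self.hap_a == code) + int(self.hap_b == code)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.label


#: Genotype label vocabulary of the reference cross-tabulation.
HLA_LABELS = (
    "DR3/DR3", "DR3/DR4", "DR4/DR4", "DR4/DR8", "DR1/DR4", "DR4/DR13",
    "DR3/DR9", "DR4/DR9", "DR4/DR4*030X/020X", "DR4/DR4*030X/0304",
)


@dataclass(frozen=True)
class HlaGenotype:
    """An HLA genotype label plus its two per-chromosome haplotype labels."""

    label: str

    @property
    def haplotype_pair(self) -> tuple[str, str]:
        return decompose_genotype_label(self.label)


@dataclass(frozen=True)
class B8Dosage:
    dosage: int
    n_sites_used: int
    tie: bool = False

    def __post_init__(self) -> None:
        if self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2, got {self.dosage}")
        if self.n_sites_used < 1:
            raise ValueError("n_sites_used must be >= 1")


# ---------------------------------------------------------------------------
# haplotype calling
# ---------------------------------------------------------------------------

def call_trisnp(
    phased_gt_pairs: Sequence[tuple[str, str] | None],
    defn: TriSnpDefinition = DEFAULT_TRISNP,
    phased: Sequence[bool] | None = None,
) -> TriSnpGenotype:
    """Call a tri-SNP genotype from per-site phased allele pairs.

    ``phased_gt_pairs`` holds one (alleleA, alleleB) nucleotide pair per
    site, in the definition's site order; the first element of every pair
    belongs to the same chromosome.  ``phased`` marks per-site phase
    status (default: all phased).  Unphased sites are tolerated only when
    the genotype is resolvable without phase, i.e. heterozygous at no more
    than one unphased site.
    """
    if len(phased_gt_pairs) != 3:
        raise MissingSiteError(
            f"expected 3 sites, got {len(phased_gt_pairs)}"
        )
    if phased is None:
        phased = (True, True, True)
    unphased_hets = 0
    for site, pair, ph in zip(defn.sites, phased_gt_pairs, phased):
        if pair is None:
            raise MissingSiteError(f"site {site.snp_id} is missing")
        if len(pair) != 2:
            raise MissingSiteError(f"site {site.snp_id}: need two alleles")
        if not ph and pair[0] != pair[1]:
            unphased_hets += 1
    # the genotype is still resolvable if at most one site is het overall
    total_hets = sum(1 for p in phased_gt_pairs if p[0] != p[1])
    if unphased_hets and total_hets >= 2:
        raise PhasingError(
            "unphased heterozygous calls at >= 2 tri-SNP sites cannot be "
            "resolved into haplotypes"
        )
    hap_a = "".join(
        site.encode(pair[0]) for site, pair in zip(defn.sites, phased_gt_pairs)
    )
    hap_b = "".join(
        site.encode(pair[1]) for site, pair in zip(defn.sites, phased_gt_pairs)
    )
    return TriSnpGenotype(hap_a, hap_b)


def decode_haplotype(code: str, defn: TriSnpDefinition = DEFAULT_TRISNP) -> str:
    """Inverse of the per-site encoding: "010" -> "AGG" under defaults."""
    _validate_code(code)
    return "".join(site.decode(c) for site, c in zip(defn.sites, code))


def impute_b8_dosage(alt_allele_counts: Sequence[int]) -> B8Dosage:
    """B8-DR3 dosage as the mode of alternate-allele counts over a tag panel.

    Missing sites must be removed by the caller (``None`` entries are
    dropped here for convenience).  On a tie between two equally modal
    dosages the smaller one is returned with ``tie=True``.
    """
    counts = [c for c in alt_allele_counts if c is not None]
    if not counts:
        raise NoDataError("no non-missing panel sites")
    for c in counts:
        if c not in (0, 1, 2):
            raise ValueError(f"allele counts must be in {{0,1,2}}, got {c}")
    freq = Counter(counts)
    top = max(freq.values())
    modal = sorted(d for d, f in freq.items() if f == top)
    return B8Dosage(dosage=modal[0], n_sites_used=len(counts),
                    tie=len(modal) > 1)


# ---------------------------------------------------------------------------
# cross-tabulation and chromosome accounting
# ---------------------------------------------------------------------------

def crosstab_hla_trisnp(
    subjects: Iterable[tuple[HlaGenotype | str, TriSnpGenotype | str]],
    hla_labels: Sequence[str] | None = None,
    trisnp_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate subjects by HLA genotype (rows) and tri-SNP genotype
    (columns)."""
    pairs = []
    for hla, tri in subjects:
        h = hla.label if isinstance(hla, HlaGenotype) else str(hla)
        t = tri.label if isinstance(tri, TriSnpGenotype) else str(tri)
        pairs.append((h, t))
    return ContingencyTable.from_pairs(pairs, hla_labels, trisnp_labels)


def decompose_genotype_label(label: str) -> tuple[str, str]:
    """Split a genotype label into its two chromosome labels.

    Plain labels split at the first "/".  Starred DR4-subtype labels
    (e.g. "DR4/DR4*030X/020X") decompose as two DR4-class chromosomes.
    """
    if "*" in label:
        head = label.split("*")[0]
        a, _, b = head.partition("/")
        if not a.startswith("DR") or not b.startswith("DR"):
            raise LabelParseError(f"cannot decompose starred label {label!r}")
        return a, b
    a, sep, b = label.partition("/")
    if not sep or not a or not b:
        raise LabelParseError(f"cannot decompose label {label!r}")
    return a, b


def _chromosome_counts(
    labels: Sequence[str], counts: np.ndarray, query: frozenset[str]
) -> tuple[int, int]:
    hit = 0
    total = 0
    for label, n in zip(labels, counts):
        a, b = decompose_genotype_label(label)
        hit += int(n) * (int(a in query) + int(b in query))
        total += 2 * int(n)
    return hit, total


def chromosome_haplotype_counts(
    table: ContingencyTable,
    query: Iterable[str],
    hla_row: str | None = None,
    trisnp_col: str | None = None,
) -> tuple[int, int]:
    """Count chromosomes bearing any of the queried haplotype labels.

    Exactly one of ``hla_row`` / ``trisnp_col`` selects the scope:
    restricting to an HLA row counts tri-SNP haplotypes over the column
    genotypes; restricting to a tri-SNP column counts HLA haplotypes over
    the row genotypes.  Every subject contributes two chromosomes.
    """
    q = frozenset(query)
    if (hla_row is None) == (trisnp_col is None):
        raise ValueError("specify exactly one of hla_row / trisnp_col")
    if hla_row is not None:
        return _chromosome_counts(table.col_labels, table.row(hla_row), q)
    return _chromosome_counts(table.row_labels, table.col(trisnp_col), q)


def chromosomes_by_hla_within_trisnp(
    table: ContingencyTable,
    trisnp_genotype: TriSnpGenotype | str,
    hla_haplotype: str,
) -> tuple[int, int]:
    """Chromosomes bearing an HLA haplotype among subjects with a given
    tri-SNP genotype.  Returns (0, 0) for an absent genotype column."""
    label = (
        trisnp_genotype.label
        if isinstance(trisnp_genotype, TriSnpGenotype)
        else str(trisnp_genotype)
    )
    if label not in table.col_labels:
        return 0, 0
    return _chromosome_counts(
        table.row_labels, table.col(label), frozenset({hla_haplotype})
    )
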