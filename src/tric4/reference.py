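"""Bundled reference summary tables from the ascertained pediatric cohort.

These are published aggregate tables (no individual-level data): the
HLA x tri-SNP genotype cross-tabulation, the C4A/C4B copy-number by
101-dosage tables for the DR3-homozygous WGS subset, per-endpoint
event/censor totals, and the GWAS covariate panel with its published
hazard ratios.  They serve two purposes: validation oracles for the table
utilities, and default parameter sources for the synthetic cohort
generator.
"""

from __future__ import annotations

import numpy as np

from .association import ContingencyTable

__all__ = [
    "hla_trisnp_table",
    "c4a_dosage_table",
    "c4b_dosage_table",
    "endpoint_totals",
    "gwas_panel",
    "reference_hazard_ratios",
]

_TRISNP_COLS = (
    "010/010", "010/101", "101/101", "000/010", "001/010", "000/101",
    "000/000", "000/001", "001/101", "011/101", "010/011",
)

_HLA_TRISNP_COUNTS = {
    "DR3/DR3":           (62, 348, 1177, 13, 2, 11, 0, 0, 2, 1, 0),
    "DR3/DR4":           (408, 2550, 3, 19, 8, 30, 0, 1, 1, 1, 1),
    "DR4/DR4":           (1480, 5, 3, 39, 3, 1, 0, 0, 0, 0, 0),
    "DR4/DR8":           (14, 0, 0, 1297, 5, 0, 17, 1, 0, 0, 0),
    "DR1/DR4":           (0, 0, 0, 15, 143, 0, 0, 2, 0, 0, 0),
    "DR4/DR13":          (0, 0, 0, 0, 56, 0, 0, 1, 0, 0, 0),
    "DR3/DR9":           (2, 16, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "DR4/DR9":           (13, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "DR4/DR4*030X/020X": (4, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "DR4/DR4*030X/0304": (3, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
}


def hla_trisnp_table() -> ContingencyTable:
    """Reference HLA genotype x tri-SNP genotype cross-tab (n = 7759)."""
    rows = tuple(_HLA_TRISNP_COUNTS)
    counts = np.array([_HLA_TRISNP_COUNTS[r] for r in rows], dtype=np.int64)
    return ContingencyTable(rows, _TRISNP_COLS, counts)


def c4a_dosage_table() -> ContingencyTable:
    """C4A copy number (rows 0-3) by 101-dosage (cols 0-2), n = 188."""
    counts = np.array(
        [[0, 0, 107],
         [0, 44, 10],
         [9, 9, 7],
         [1, 0, 1]], dtype=np.int64)
    return ContingencyTable(("0", "1", "2", "3"), ("0", "1", "2"), counts)


def c4b_dosage_table() -> ContingencyTable:
    """C4B copy number (rows 0-3) by 101-dosage (cols 0-2), n = 188."""
    counts = np.array(
        [[1, 0, 0],
         [5, 34, 4],
         [4, 17, 119],
         [0, 2, 2]], dtype=np.int64)
    return ContingencyTable(("0", "1", "2", "3"), ("0", "1", "2"), counts)


#: Per-endpoint (events, total) in the filtered analysis cohort.
_ENDPOINT_TOTALS = {
    "T1D": (397, 7703),
    "IA": (858, 7703),
    "GADA_first": (382, 7703),
    "IAA_first": (313, 7703),
    "CD": (617, 7703),
    "CDA": (1294, 6709),
}


def endpoint_totals(endpoint: str) -> tuple[int, int]:
    """(event count, cohort size) for one endpoint in the reference cohort."""
    return _ENDPOINT_TOTALS[endpoint]


#: GWAS covariate panel: snp_id -> (endpoints using it, published HR per
#: endpoint where significant).  Endpoint keys follow the endpoint names
#: above; the first-antibody endpoints reuse the IA panel.
_GWAS_PANEL = {
    "rs4851575":   ({"CD": 1.45},),
    "rs114569351": ({"CD": 2.64},),
    "rs12493471":  ({"CD": 1.40},),
    "rs1054091":   ({"CD": 1.59},),
    "rs72704176":  ({"CD": 2.26},),
    "rs3771689":   ({"CD": 0.56},),
    "rs13014907":  ({"CD": 2.46},),
    "rs11739460":  ({"CD": 1.41},),
    "rs77532435":  ({"CD": 2.05},),
    "rs6967298":   ({"CD": 0.61},),
    "rs61751041":  ({"CD": 2.23},),
    "rs2409747":   ({"CD": 1.58, "CDA": 1.37},),
    "rs12990970":  ({"CDA": 0.76},),
    "rs11709472":  ({"CDA": 0.80},),
    "rs72717025":  ({"CDA": 1.84},),
    "rs114157400": ({"CDA": 1.62},),
    "rs117561283": ({"CDA": 1.81},),
    "rs8013918":   ({"CDA": 0.80},),
    "rs73043122":  ({"T1D": 3.35},),
    "rs113306148": ({"T1D": 3.06},),
    "rs428595":    ({"T1D": 3.42, "IA": 2.46},),
    "rs1004446":   ({"T1D": 0.55, "IA": 0.67},),
    "rs2476601":   ({"T1D": 1.91, "IA": 1.73},),
    "rs2292239":   ({"T1D": 1.68, "IA": 1.45},),
    "rs3184504":   ({"IA": 1.40},),
    "rs9934817":   ({"IA": 2.66},),
    "rs11705721":  ({"IA": 1.41},),
}


def gwas_panel(endpoint: str | None = None) -> dict[str, float]:
    """SNP -> published HR for one endpoint (or all SNPs when None).

    The first-antibody endpoints (IAA_first, GADA_first) share the IA
    covariate set.
    """
    key = endpoint
    if endpoint in ("IAA_first", "GADA_first"):
        key = "IA"
    out: dict[str, float] = {}
    for snp, (hrs,) in _GWAS_PANEL.items():
        if endpoint is None:
            out[snp] = next(iter(hrs.values()))
        elif key in hrs:
            out[snp] = hrs[key]
    return out


#: Published per-endpoint hazard ratios for the non-SNP covariates
#: (full-cohort fits; tri-SNP HRs are per additional 101 allele).
_REFERENCE_HRS = {
    "T1D": {"trisnp_101": 0.54, "hla:DR3/DR4": 3.20, "fdr": 3.11,
            "country:FIN": 1.34},
    "IA": {"trisnp_101": 0.71, "fdr": 2.16, "hla:DR3/DR4": 1.83,
           "sex:male": 1.19, "country:FIN": 1.34, "country:SWE": 1.25},
    "IAA_first": {"trisnp_101": 0.64},
    "GADA_first": {"trisnp_101": 0.87},
    "CD": {"trisnp_101": 1.32, "ancestry:AMR": 0.62},
    "CDA": {"trisnp_101": 1.23},
}

#: Published tri-SNP HRs within the DR3-homozygous restriction.
_REFERENCE_HRS_DR3 = {
    "T1D": 0.35, "IA": 0.58, "IAA_first": 0.48, "GADA_first": 0.71,
    "CD": 1.32, "CDA": 1.23,
}


def reference_hazard_ratios(endpoint: str, scope: str = "all"):
    """Published HR point estimates used as simulation-truth defaults."""
    if scope == "all":
        return dict(_REFERENCE_HRS[endpoint])
    if scope == "DR3_homozygous":
        return {"trisnp_101": _REFERENCE_HRS_DR3[endpoint]}
    raise KeyError(scope)
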