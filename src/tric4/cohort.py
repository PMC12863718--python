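"""Self-contained synthetic study generator.

Produces phased genotypes (HLA label + tri-SNP code + C4 structure + B8
flag per chromosome), demographic covariates, proportional-hazards event
times for six endpoints, windowed MHC coverage with diploid-scale C4
signal, and negative-binomial expression counts — everything the pipeline
stages consume, with no external data.

All randomness flows from a single master seed through named substreams;
identical (config, seed) pairs give identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .c4 import C4RegionConfig, CoverageProfile, DEFAULT_C4_CONFIG, WindowBed, make_windows
from .errors import ConfigError
from .haplotypes import DEFAULT_TRISNP, decode_haplotype, decompose_genotype_label

__all__ = [
    "HaplotypeAllele",
    "CoverageModel",
    "ExpressionModel",
    "EndpointModel",
    "SimulationConfig",
    "sample_genotypes",
    "simulate_outcomes",
    "simulate_coverage",
    "simulate_expression",
    "simulate_cohort",
    "calibrate_baseline_scale",
    "write_fixture_bundle",
]

_SUBSTREAMS = {
    "genotypes": 1,
    "covariates": 2,
    "outcomes": 3,
    "coverage": 4,
    "expression": 5,
    "b8_panel": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_SUBSTREAMS[stream],))
    )


@dataclass(frozen=True)
class HaplotypeAllele:
    """One chromosome: HLA class, tri-SNP code, C4 structure, B8 status."""

    hla_label: str
    trisnp_code: str
    n_c4a: int
    n_c4b: int
    b8_flag: bool = False

    def __post_init__(self) -> None:
        if min(self.n_c4a, self.n_c4b) < 0:
            raise ValueError("per-chromosome C4 copies must be >= 0")
        if self.n_c4a + self.n_c4b not in (1, 2):
            raise ValueError("per-chromosome C4 module count must be 1 or 2")


# -- per-chromosome C4 structure conditionals -------------------------------
# Fitted by maximum likelihood so that independent pairing reproduces the
# reference diploid copy-number x dosage tables.  Keys are (n_c4a, n_c4b).
DEFAULT_C4_STRUCTURE = {
    "101": {(0, 1): 0.9218, (1, 1): 0.0493, (2, 0): 0.0201, (0, 2): 0.0088},
    "other": {(1, 0): 0.4741, (1, 1): 0.4172, (2, 0): 0.0951, (0, 2): 0.0136},
}


@dataclass(frozen=True)
class CoverageModel:
    flank_depth_mean: float = 30.0
    flank_depth_sd: float = 3.0
    per_copy_unique: float = 0.3      # unique-region norm units per copy
    noise_cv: float = 0.05            # per-window multiplicative CV
    ambient_uniq: float = 0.05        # multi-mapping floor inside C4
    herv_factor: float = 0.3          # depressed signal in HERV windows
    full_mhc: bool = False            # tile the whole MHC vs C4 +/- flanks


@dataclass(frozen=True)
class ExpressionModel:
    n_null_genes: int = 100
    c4a_like_log2_per_allele: float = -1.0
    c4b_like_log2_per_allele: float = 0.75
    dispersion: float = 0.3
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.5
    n_batches: int = 3
    batch_log2_sd: float = 0.2
    age_log2_effect: float = 0.3
    sex_log2_effect: float = 0.1
    samples_per_individual: tuple[int, int] = (1, 5)
    library_size_mean: float = 2.0e6
    library_size_cv: float = 0.2


@dataclass(frozen=True)
class EndpointModel:
    """Weibull proportional-hazards time model for one latent endpoint."""

    shape: float = 1.3
    scale: float = 2000.0             # months; tuned per endpoint
    log_hrs: Mapping[str, float] = field(default_factory=dict)
    # extra per-allele tri-SNP effect applied within DR3/DR3 subjects,
    # mirroring the stronger restricted-scope association
    trisnp_dr3_extra: float = 0.0


def _loghr(hr: float) -> float:
    return float(np.log(hr))


def _default_endpoints() -> dict[str, EndpointModel]:
    """Per-endpoint defaults: published HR point estimates as truth, with
    baseline scales tuned so event fractions approximate the reference
    cohort at the default censoring scheme."""
    gw = reference.gwas_panel
    hr = reference.reference_hazard_ratios

    def hrs(endpoint: str, extra: Mapping[str, float] = ()) -> dict[str, float]:
        d = {}
        for key, v in hr(endpoint).items():
            d[key] = _loghr(v)
        for snp, v in gw(endpoint).items():
            d[snp] = _loghr(v)
        d.update(extra or {})
        return d

    dr3_extra = {
        ep: _loghr(hr(ep, "DR3_homozygous")["trisnp_101"])
        - _loghr(hr(ep)["trisnp_101"])
        for ep in ("T1D", "IA", "IAA_first", "GADA_first", "CD", "CDA")
    }
    gluten = {"gluten_intake": _loghr(1.3)}
    # scales calibrated against the reference event fractions (see
    # calibrate_baseline_scale); frozen here for reproducibility
    return {
        "T1D": EndpointModel(1.3, 14197.0, hrs("T1D"), dr3_extra["T1D"]),
        "IAA": EndpointModel(1.3, 4963.0, hrs("IAA_first"), dr3_extra["IAA_first"]),
        "GADA": EndpointModel(1.3, 4857.0, hrs("GADA_first"), dr3_extra["GADA_first"]),
        "OTHER_AB": EndpointModel(1.3, 3019.0, {}),
        "CD": EndpointModel(1.3, 10466.0, hrs("CD", gluten), dr3_extra["CD"]),
        "CDA": EndpointModel(1.3, 987.0, hrs("CDA", gluten), dr3_extra["CDA"]),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 2000
    sampling_mode: str = "genotype_table"   # or "hardy_weinberg"
    haplotype_freqs: Mapping[tuple[str, str], float] | None = None
    eligible_hla_genotypes: frozenset[str] | None = None
    c4_structure: Mapping[str, Mapping[tuple[int, int], float]] = field(
        default_factory=lambda: DEFAULT_C4_STRUCTURE)
    b8_given_trisnp: Mapping[str, float] = field(
        default_factory=lambda: {"101": 0.72, "other": 0.04})
    b8_panel_size: int = 20
    b8_panel_concordance: float = 0.9
    sex_p_male: float = 0.51
    country_probs: Mapping[str, float] = field(default_factory=lambda: {
        "US": 0.413, "SWE": 0.300, "FIN": 0.220, "GER": 0.067})
    ancestry_probs: Mapping[str, float] = field(default_factory=lambda: {
        "EUR": 0.8961, "AMR": 0.0911, "AFR": 0.0106,
        "SAS": 0.0018, "EAS": 0.0004})
    fdr_p: float = 0.111
    gwas_allele_freq: float = 0.2
    endpoints: Mapping[str, EndpointModel] = field(
        default_factory=_default_endpoints)
    admin_censor_months: float = 180.0
    dropout_rate_per_month: float = 1.0 / 900.0
    coverage: CoverageModel = field(default_factory=CoverageModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)

    def validate(self) -> None:
        for name, probs in (("country_probs", self.country_probs),
                            ("ancestry_probs", self.ancestry_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1")
        if self.haplotype_freqs is not None:
            if abs(sum(self.haplotype_freqs.values()) - 1.0) > 1e-6:
                raise ConfigError("haplotype_freqs must sum to 1")
        for code, probs in self.c4_structure.items():
            if abs(sum(probs.values()) - 1.0) > 1e-3:
                raise ConfigError(f"c4_structure[{code}] must sum to 1")
            for (na, nb) in probs:
                if na + nb not in (1, 2):
                    raise ConfigError("per-chromosome C4 modules must be 1 or 2")


# -- haplotype frequencies fitted to the reference cross-tab ----------------
# Conditional (post-eligibility) maximum-likelihood estimates; used to
# phase genotype-table draws and as the Hardy-Weinberg-mode default.
DEFAULT_HAPLOTYPE_FREQS: dict[tuple[str, str], float] = {
    ("DR4", "010"): 0.38657, ("DR3", "101"): 0.34149, ("DR8", "000"): 0.17157,
    ("DR3", "010"): 0.05799, ("DR1", "001"): 0.01893, ("DR13", "001"): 0.00745,
    ("DR4", "000"): 0.00488, ("DR3", "000"): 0.00250, ("DR9", "010"): 0.00200,
    ("DR1", "000"): 0.00196, ("DR8", "010"): 0.00185, ("DR4", "101"): 0.00082,
    ("DR3", "001"): 0.00080, ("DR8", "001"): 0.00066, ("DR4", "001"): 0.00028,
    ("DR3", "011"): 0.00012, ("DR9", "101"): 0.00007, ("DR4", "011"): 0.00005,
}
_total = sum(DEFAULT_HAPLOTYPE_FREQS.values())
DEFAULT_HAPLOTYPE_FREQS = {k: v / _total for k, v in DEFAULT_HAPLOTYPE_FREQS.items()}


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------

def _phase_cell(hla_genotype: str, trisnp_genotype: str,
                freqs: Mapping[tuple[str, str], float],
                rng: np.random.Generator) -> tuple[tuple[str, str], tuple[str, str]]:
    """Assign tri-SNP codes to the two HLA chromosomes of a genotype cell,
    choosing between the two phasings with probability proportional to the
    product of haplotype frequencies."""
    h1, h2 = decompose_genotype_label(hla_genotype)
    t1, t2 = trisnp_genotype.split("/")
    eps = 1e-9
    w1 = (freqs.get((h1, t1), eps)) * (freqs.get((h2, t2), eps))
    w2 = (freqs.get((h1, t2), eps)) * (freqs.get((h2, t1), eps))
    if (h1, t1) == (h2, t2) or (t1 == t2):
        return (h1, t1), (h2, t2)
    if rng.random() < w1 / (w1 + w2):
        return (h1, t1), (h2, t2)
    return (h1, t2), (h2, t1)


def draw_c4_structure(code: str, structure: Mapping[str, Mapping[tuple[int, int], float]],
                      rng: np.random.Generator) -> tuple[int, int]:
    """Draw one chromosome's (n_c4a, n_c4b) given its tri-SNP code."""
    probs = structure.get(code, structure["other"])
    keys = list(probs)
    p = np.array([probs[k] for k in keys], float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


_draw_structure = draw_c4_structure


def sample_genotypes(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Draw per-subject chromosome pairs with linked attributes.

    Default mode draws (HLA genotype, tri-SNP genotype) cells from the
    reference cross-tab — matching the cohort's genotype-based
    ascertainment — and phases them with the fitted haplotype
    frequencies.  ``hardy_weinberg`` mode instead draws two haplotypes
    independently from ``haplotype_freqs`` with optional rejection to an
    eligible HLA-genotype set.
    """
    config.validate()
    rng = _rng(seed, "genotypes")
    freqs = dict(config.haplotype_freqs or DEFAULT_HAPLOTYPE_FREQS)
    n = config.n_subjects
    chroms: list[tuple[tuple[str, str], tuple[str, str]]] = []

    if config.sampling_mode == "genotype_table":
        table = reference.hla_trisnp_table()
        cells = [(r, c) for r in table.row_labels for c in table.col_labels]
        p = table.counts.flatten().astype(float)
        p /= p.sum()
        idx = rng.choice(len(cells), size=n, p=p)
        for i in idx:
            hg, tg = cells[i]
            chroms.append(_phase_cell(hg, tg, freqs, rng))
    elif config.sampling_mode == "hardy_weinberg":
        haps = list(freqs)
        p = np.array([freqs[h] for h in haps], float)
        p /= p.sum()
        eligible = config.eligible_hla_genotypes
        while len(chroms) < n:
            take = max(64, int((n - len(chroms)) * 1.5))
            draws = rng.choice(len(haps), size=(take, 2), p=p)
            for a, b in draws:
                ha, hb = haps[a], haps[b]
                if eligible is not None:
                    lab = "/".join(sorted((ha[0], hb[0])))
                    if lab not in eligible:
                        continue
                chroms.append((ha, hb))
                if len(chroms) == n:
                    break
    else:
        raise ConfigError(f"unknown sampling_mode {config.sampling_mode!r}")

    rows = []
    for i, ((h1, t1), (h2, t2)) in enumerate(chroms):
        a1_a, a1_b = _draw_structure(t1, config.c4_structure, rng)
        a2_a, a2_b = _draw_structure(t2, config.c4_structure, rng)
        b8_1 = rng.random() < config.b8_given_trisnp.get(
            t1, config.b8_given_trisnp["other"])
        b8_2 = rng.random() < config.b8_given_trisnp.get(
            t2, config.b8_given_trisnp["other"])
        hla_label = "/".join(sorted((h1, h2)))
        tri_label = "/".join(sorted((t1, t2)))
        rows.append({
            "subject_id": f"S{i:06d}",
            "hla_genotype": hla_label,
            "trisnp_genotype": tri_label,
            "hap1_hla": h1, "hap1_trisnp": t1,
            "hap1_c4a": a1_a, "hap1_c4b": a1_b, "hap1_b8": b8_1,
            "hap2_hla": h2, "hap2_trisnp": t2,
            "hap2_c4a": a2_a, "hap2_c4b": a2_b, "hap2_b8": b8_2,
            "trisnp_101_dosage": int(t1 == "101") + int(t2 == "101"),
            "b8_dosage": int(b8_1) + int(b8_2),
            "gcn_a": a1_a + a2_a,
            "gcn_b": a1_b + a2_b,
            "total_gcn": a1_a + a2_a + a1_b + a2_b,
        })
    df = pd.DataFrame(rows)
    return _assign_covariates(df, config, seed)


def _assign_covariates(df: pd.DataFrame, config: SimulationConfig,
                       seed: int) -> pd.DataFrame:
    rng = _rng(seed, "covariates")
    n = len(df)
    df = df.copy()
    df["sex"] = np.where(rng.random(n) < config.sex_p_male, "male", "female")
    for col, probs in (("country", config.country_probs),
                       ("ancestry", config.ancestry_probs)):
        labels = list(probs)
        p = np.array([probs[k] for k in labels], float)
        df[col] = np.array(labels)[rng.choice(len(labels), size=n, p=p / p.sum())]
    df["fdr"] = (rng.random(n) < config.fdr_p).astype(int)
    df["gluten_intake"] = rng.normal(0.0, 1.0, n)
    for snp in reference.gwas_panel(None):
        q = config.gwas_allele_freq
        df[snp] = rng.binomial(2, q, n)
    return df


def haplotype_alleles(row: pd.Series) -> tuple[HaplotypeAllele, HaplotypeAllele]:
    """Materialize the two chromosome objects for one cohort row."""
    return (
        HaplotypeAllele(row["hap1_hla"], row["hap1_trisnp"],
                        int(row["hap1_c4a"]), int(row["hap1_c4b"]),
                        bool(row["hap1_b8"])),
        HaplotypeAllele(row["hap2_hla"], row["hap2_trisnp"],
                        int(row["hap2_c4a"]), int(row["hap2_c4b"]),
                        bool(row["hap2_b8"])),
    )


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------

def _linear_predictor(df: pd.DataFrame, model: EndpointModel) -> np.ndarray:
    lp = np.zeros(len(df))
    for key, beta in model.log_hrs.items():
        if key == "trisnp_101":
            lp += beta * df["trisnp_101_dosage"].to_numpy(float)
        elif key.startswith("hla:"):
            lp += beta * (df["hla_genotype"] == key[4:]).to_numpy(float)
        elif key.startswith("sex:"):
            lp += beta * (df["sex"] == key[4:]).to_numpy(float)
        elif key.startswith("country:"):
            lp += beta * (df["country"] == key[8:]).to_numpy(float)
        elif key.startswith("ancestry:"):
            lp += beta * (df["ancestry"] == key[9:]).to_numpy(float)
        elif key in ("fdr", "gluten_intake"):
            lp += beta * df[key].to_numpy(float)
        elif key in df.columns:  # GWAS dosages
            lp += beta * df[key].to_numpy(float)
        else:
            raise ConfigError(f"unknown covariate key {key!r}")
    if model.trisnp_dr3_extra:
        mask = (df["hla_genotype"] == "DR3/DR3").to_numpy(float)
        lp += model.trisnp_dr3_extra * mask * df["trisnp_101_dosage"].to_numpy(float)
    return lp


def _weibull_times(model: EndpointModel, lp: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    # hazard h(t) = (shape/scale) (t/scale)^(shape-1) exp(lp)
    e = rng.exponential(1.0, len(lp))
    return model.scale * (e / np.exp(lp)) ** (1.0 / model.shape)


def simulate_outcomes(df: pd.DataFrame, config: SimulationConfig,
                      seed: int) -> pd.DataFrame:
    """Attach latent event times, censoring, and observed endpoint columns.

    First-antibody endpoints arise from competing latent antibody times
    (IAA, GADA, plus a nuisance 'other'); the earliest determines the
    antibody identity.  Diagnosis endpoints (T1D, CD) censor at the last
    clinic visit, serology endpoints (IA, CDA) at the last negative
    sample.
    """
    rng = _rng(seed, "outcomes")
    df = df.copy()
    n = len(df)
    dropout = rng.exponential(1.0 / config.dropout_rate_per_month, n)
    censor = np.minimum(config.admin_censor_months, dropout)
    df["last_visit_time"] = censor
    # serum sampling happens a little before the last visit
    df["last_neg_sample_time"] = np.maximum(1.0, censor - rng.uniform(0, 3, n))

    latent: dict[str, np.ndarray] = {}
    for name, model in config.endpoints.items():
        latent[name] = _weibull_times(model, _linear_predictor(df, model), rng)

    ab_names = [k for k in ("IAA", "GADA", "OTHER_AB") if k in latent]
    ab_times = np.column_stack([latent[k] for k in ab_names])
    first_idx = np.argmin(ab_times, axis=1)
    first_time = ab_times[np.arange(n), first_idx]
    seen = first_time <= df["last_neg_sample_time"].to_numpy()
    df["first_ab"] = np.where(
        seen, np.array(ab_names)[first_idx], "none")
    for ab in ("IAA", "GADA", "OTHER_AB"):
        t = latent.get(ab)
        if t is None:
            continue
        col = ab.lower() + "_pos_time"
        pos = seen & (np.array(ab_names)[first_idx] == ab)
        # later-appearing antibodies are irrelevant to first-ab endpoints;
        # only the first appearance is recorded
        df[col] = np.where(pos, first_time, np.nan)

    for name, col in (("T1D", "t1d_diag_time"), ("CD", "cd_diag_time")):
        t = latent[name]
        event = t <= censor
        df[col] = np.where(event, t, np.nan)
    cda_t = latent["CDA"]
    cda_event = cda_t <= df["last_neg_sample_time"].to_numpy()
    df["cda_pos_time"] = np.where(cda_event, cda_t, np.nan)
    return df


def calibrate_baseline_scale(
    config: SimulationConfig,
    endpoint: str,
    target_fraction: float,
    n: int = 20_000,
    seed: int = 0,
    tol: float = 0.002,
    max_iter: int = 30,
) -> float:
    """Find the Weibull scale giving an expected event fraction close to
    ``target_fraction`` under the configured censoring, by bisection on
    simulated cohorts."""
    from .survival import prepare_endpoint  # local import: avoid cycle

    base = dataclasses.replace(config, n_subjects=n)

    def event_frac(scale: float) -> float:
        eps = {k: (dataclasses.replace(v, scale=scale) if k == endpoint else v)
               for k, v in base.endpoints.items()}
        cfg = dataclasses.replace(base, endpoints=eps)
        df = simulate_outcomes(sample_genotypes(cfg, seed), cfg, seed)
        ep_key = {"T1D": "T1D", "CD": "CD", "CDA": "CDA",
                  "IAA": "IAA_first", "GADA": "GADA_first"}.get(endpoint, endpoint)
        frame, _ = prepare_endpoint(df, ep_key)
        return float(frame["event"].mean())

    lo, hi = 50.0, 50_000.0
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        f = event_frac(mid)
        if abs(f - target_fraction) < tol:
            return float(mid)
        if f > target_fraction:   # too many events -> hazard too high -> scale up
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage_windows(config: SimulationConfig,
                     c4_config: C4RegionConfig = DEFAULT_C4_CONFIG) -> WindowBed:
    if config.coverage.full_mhc:
        return make_windows()
    (flo, _), (_, fhi) = c4_config.flank_regions
    return make_windows(start=flo, end=fhi)


def simulate_coverage(
    df: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    c4_config: C4RegionConfig = DEFAULT_C4_CONFIG,
) -> list[CoverageProfile]:
    """Windowed depth profiles whose normalized signal encodes each
    subject's true C4 copy numbers."""
    cov = config.coverage
    rng = _rng(seed, "coverage")
    windows = coverage_windows(config, c4_config)
    n_w = len(windows)

    c4_mask = windows.mask(c4_config.c4_total_region)
    herv_mask = np.zeros(n_w, bool)
    for r in c4_config.herv_regions:
        herv_mask |= windows.mask(r)
    a_mask = windows.mask(c4_config.c4a_unique_region)
    b_mask = windows.mask(c4_config.c4b_unique_region)

    profiles = []
    for _, row in df.iterrows():
        total, gcn_a, gcn_b = row["total_gcn"], row["gcn_a"], row["gcn_b"]
        depth = max(5.0, rng.normal(cov.flank_depth_mean, cov.flank_depth_sd))
        mult_all = np.ones(n_w)
        mult_all[c4_mask] = total / 4.0
        mult_all[herv_mask] = cov.herv_factor * total / 4.0
        mult_uniq = np.full(n_w, 0.95)
        mult_uniq[c4_mask] = cov.ambient_uniq
        mult_uniq[a_mask] = cov.per_copy_unique * gcn_a / 2.0
        mult_uniq[b_mask] = cov.per_copy_unique * gcn_b / 2.0
        mean_all = depth * mult_all
        mean_uniq = depth * mult_uniq
        if cov.noise_cv > 0:
            shape = 1.0 / cov.noise_cv ** 2
            d_all = rng.gamma(shape, mean_all / shape)
            d_uniq = rng.gamma(shape, np.maximum(mean_uniq, 1e-12) / shape)
            d_uniq[mean_uniq == 0] = 0.0
        else:
            d_all, d_uniq = mean_all, mean_uniq.copy()
        profiles.append(CoverageProfile(row["subject_id"], windows, d_all, d_uniq))
    return profiles


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(df: pd.DataFrame, config: SimulationConfig,
                        seed: int):
    """Negative-binomial count matrix with designated C4A-like/C4B-like
    genes carrying opposite-sign tri-SNP dosage effects.

    Returns an :class:`tric4.expression.ExpressionMatrix` over multiple
    samples per individual with batch/age/sex nuisance structure.
    """
    from .expression import ExpressionMatrix  # avoid import cycle

    ex = config.expression
    rng = _rng(seed, "expression")
    individuals = df["subject_id"].tolist()
    dosages = df["trisnp_101_dosage"].to_numpy(int)
    sexes = df["sex"].to_numpy()

    sample_rows = []
    for ind, dose, sex in zip(individuals, dosages, sexes):
        k = rng.integers(ex.samples_per_individual[0],
                         ex.samples_per_individual[1] + 1)
        for j in range(k):
            sample_rows.append({
                "sample_id": f"{ind}_r{j}",
                "individual_id": ind,
                "batch": f"B{rng.integers(ex.n_batches)}",
                "age_category": "<1y" if rng.random() < 0.3 else ">=1y",
                "sex": sex,
                "trisnp_101_dosage": int(dose),
            })
    samples = pd.DataFrame(sample_rows)
    n_s = len(samples)

    genes = ["C4A_like", "C4B_like"] + [
        f"NULL{g:04d}" for g in range(ex.n_null_genes)]
    betas = np.zeros(len(genes))
    betas[0] = ex.c4a_like_log2_per_allele
    betas[1] = ex.c4b_like_log2_per_allele
    base = rng.normal(ex.base_log2_mean, ex.base_log2_sd, len(genes))
    batch_fx = rng.normal(0, ex.batch_log2_sd, (len(genes), ex.n_batches))

    batch_idx = samples["batch"].str[1:].astype(int).to_numpy()
    age = (samples["age_category"] == "<1y").to_numpy(float)
    male = (samples["sex"] == "male").to_numpy(float)
    dose_s = samples["trisnp_101_dosage"].to_numpy(float)

    log2_mu = (base[:, None]
               + batch_fx[:, batch_idx]
               + ex.age_log2_effect * age[None, :]
               + ex.sex_log2_effect * male[None, :]
               + betas[:, None] * dose_s[None, :])
    lib = rng.lognormal(np.log(ex.library_size_mean),
                        ex.library_size_cv, n_s)
    rel = 2.0 ** log2_mu
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    r = 1.0 / ex.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes,
                            columns=samples["sample_id"].tolist()),
        samples=samples,
    )


def simulate_cohort(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Genotypes + covariates + outcomes in one call."""
    df = sample_genotypes(config, seed)
    return simulate_outcomes(df, config, seed)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _write_vcf(df: pd.DataFrame, config: SimulationConfig, seed: int,
               path: Path) -> None:
    """Phased VCF: the three tri-SNP sites plus a noisy B8 tag panel."""
    rng = _rng(seed, "b8_panel")
    sites = DEFAULT_TRISNP.sites
    positions = (32_433_167, 32_435_332, 32_433_441)  # within DRA intron 1
    subjects = df["subject_id"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr6>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(subjects),
    ]
    recs = []
    for k, (site, pos) in enumerate(zip(sites, sorted(positions))):
        gts = [
            f"{row['hap1_trisnp'][k]}|{row['hap2_trisnp'][k]}"
            for _, row in df.iterrows()
        ]
        recs.append((pos, site.snp_id, site.ref_allele, site.alt_allele, gts))
    b8_dose = df["b8_dosage"].to_numpy(int)
    conc = config.b8_panel_concordance
    for j in range(config.b8_panel_size):
        pos = 31_000_000 + 1000 * j
        gts = []
        for d in b8_dose:
            dj = d if rng.random() < conc else rng.integers(0, 3)
            gts.append({0: "0|0", 1: "0|1", 2: "1|1"}[int(dj)])
        recs.append((pos, f"b8tag{j:03d}", "A", "C", gts))
    for pos, sid, ref, alt, gts in sorted(recs):
        lines.append(
            f"chr6\t{pos}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


_META_COLUMNS = [
    "subject_id", "sex", "country", "ancestry", "fdr", "hla_genotype",
    "trisnp_genotype", "trisnp_101_dosage", "b8_dosage", "gluten_intake",
    "last_visit_time", "last_neg_sample_time", "iaa_pos_time",
    "gada_pos_time", "other_ab_pos_time", "first_ab", "t1d_diag_time",
    "cd_diag_time", "cda_pos_time",
]


def write_fixture_bundle(config: SimulationConfig, seed: int, out_dir) -> dict:
    """Simulate everything and emit the text fixture files.

    Writes a phased VCF, subject metadata TSV, windows BED, long-format
    coverage TSV, expression counts TSV + sample covariates TSV, and a
    manifest JSON recording config and seed.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = simulate_cohort(config, seed)
    profiles = simulate_coverage(df, config, seed)
    expr = simulate_expression(df[df["hla_genotype"] == "DR3/DR3"], config, seed)

    _write_vcf(df, config, seed, out / "genotypes.vcf")

    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    gwas_cols = sorted(reference.gwas_panel(None))
    df[meta_cols + gwas_cols].to_csv(out / "meta.tsv", sep="\t", index=False)

    windows = profiles[0].windows
    windows.to_bed(out / "windows.bed")
    cov_rows = []
    lengths = windows.lengths
    for p in profiles:
        cov_rows.append(pd.DataFrame({
            "sample_id": p.sample_id,
            "chrom": windows.chrom,
            "start": windows.starts,
            "end": windows.ends,
            "sum_all": np.round(p.depth_all * lengths, 1),
            "sum_uniq": np.round(p.depth_uniq * lengths, 1),
        }))
    pd.concat(cov_rows).to_csv(out / "coverage.tsv", sep="\t", index=False)

    expr.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    expr.samples.to_csv(out / "covars.tsv", sep="\t", index=False)

    manifest = {
        "seed": int(seed),
        "n_subjects": config.n_subjects,
        "sampling_mode": config.sampling_mode,
        "files": ["genotypes.vcf", "meta.tsv", "windows.bed",
                  "coverage.tsv", "counts.tsv", "covars.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
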