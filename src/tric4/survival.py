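"""Covariate encoding, cohort filtering and Cox proportional-hazards fits.

Six endpoints are modelled: T1D, IA, IAA_first, GADA_first, CD, CDA; each
can be fitted on the full cohort or restricted to DR3 homozygotes.
Dosage covariates (tri-SNP 101, B8, GWAS SNPs) enter numerically (per
allele); HLA genotype, sex, country and ancestry are categorical with
baselines DR4/DR8, female, US and EUR.  Partial-likelihood optimization
is delegated to lifelines (Efron tie handling); the module's own logic is
the endpoint censoring rules and the iterated category filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from . import reference
from .errors import ConvergenceError, EmptyFrameError, MissingDataError

__all__ = [
    "ENDPOINTS",
    "CoxModelSpec",
    "CoxFit",
    "prepare_endpoint",
    "encode_design",
    "filter_model_frame",
    "fit_cox",
    "run_paper_models",
]

ENDPOINTS = ("T1D", "IA", "IAA_first", "GADA_first", "CD", "CDA")

_CATEGORICAL_BASELINES = {
    "hla_genotype": "DR4/DR8",
    "sex": "female",
    "country": "US",
    "ancestry": "EUR",
}


@dataclass(frozen=True)
class CoxModelSpec:
    endpoint: str
    cohort_scope: str = "all"                  # or "DR3_homozygous"
    numeric_covariates: tuple[str, ...] = ("trisnp_101_dosage", "fdr")
    categorical_covariates: tuple[str, ...] = (
        "hla_genotype", "sex", "country", "ancestry")
    gwas_covariates: tuple[str, ...] = ()
    baselines: Mapping[str, str] = field(
        default_factory=lambda: dict(_CATEGORICAL_BASELINES))
    min_category_size: int = 20

    def all_covariates(self) -> tuple[str, ...]:
        return (self.numeric_covariates + self.categorical_covariates
                + self.gwas_covariates)


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate estimates from one proportional-hazards fit."""

    endpoint: str
    cohort_scope: str
    coefficients: pd.DataFrame   # index covariate; log_hr, hr, ci_*, p
    n_used: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.coefficients.loc[covariate, "hr"])

    def log_hr(self, covariate: str) -> float:
        return float(self.coefficients.loc[covariate, "log_hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.coefficients.loc[covariate]
        return float(row["ci95_low"]), float(row["ci95_high"])

    def p_value(self, covariate: str) -> float:
        return float(self.coefficients.loc[covariate, "p_value"])


# ---------------------------------------------------------------------------
# endpoint preparation
# ---------------------------------------------------------------------------

_AB_TIME_COLS = ("iaa_pos_time", "gada_pos_time", "other_ab_pos_time")


def prepare_endpoint(records: pd.DataFrame,
                     endpoint: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive (time, event) per subject for one endpoint.

    Censoring follows the study rules: diagnosis endpoints (T1D, CD)
    censor at the last clinic visit; serology endpoints (IA, CDA) at the
    last negative serum sample.  For first-antibody endpoints a subject
    whose first autoantibody is a *different* one is right-censored at
    its appearance.  Subjects with missing censor times are dropped and
    logged.  Returns (frame with 'time'/'event' columns, drop log).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = records.copy()

    if endpoint in ("T1D", "CD"):
        ev_col = "t1d_diag_time" if endpoint == "T1D" else "cd_diag_time"
        event_time = df[ev_col]
        censor_time = df["last_visit_time"]
    elif endpoint == "CDA":
        event_time = df["cda_pos_time"]
        censor_time = df["last_neg_sample_time"]
    else:  # IA and first-antibody endpoints
        ab_times = df.reindex(columns=list(_AB_TIME_COLS))
        first_time = ab_times.min(axis=1)
        if endpoint == "IA":
            event_time = first_time
        else:
            target = "iaa_pos_time" if endpoint == "IAA_first" else "gada_pos_time"
            is_target_first = df[target].notna() & (df[target] <= first_time)
            event_time = df[target].where(is_target_first)
            # a different first antibody right-censors at its appearance
            censor_override = first_time.where(~is_target_first)
        censor_time = df["last_neg_sample_time"]
        if endpoint != "IA":
            censor_time = censor_override.fillna(censor_time)

    event = event_time.notna()
    time = event_time.where(event, censor_time)
    dropped = df[time.isna() | (time <= 0)]
    log = pd.DataFrame({
        "subject_id": dropped.get("subject_id", dropped.index),
        "reason": "missing or non-positive time",
    })
    keep = time.notna() & (time > 0)
    out = df.loc[keep].copy()
    out["time"] = time[keep].astype(float)
    out["event"] = event[keep].astype(int)
    return out, log


# ---------------------------------------------------------------------------
# filtering and encoding
# ---------------------------------------------------------------------------

def filter_model_frame(records: pd.DataFrame,
                       spec: CoxModelSpec) -> tuple[pd.DataFrame, dict]:
    """Iterated complete-case + category filter, run to a fixed point.

    Each pass drops subjects with missing covariates, then subjects in
    any categorical level with fewer members than ``min_category_size``,
    then subjects in levels with zero events or zero non-events.  The
    fixed point makes the result independent of step order.
    """
    df = records
    if spec.cohort_scope == "DR3_homozygous":
        df = df[df["hla_genotype"] == "DR3/DR3"]
    dropped = {"missing_covariates": 0, "small_category": 0,
               "no_event_variation": 0}
    covs = list(spec.all_covariates())
    for _ in range(100):
        n0 = len(df)
        cc = df.dropna(subset=[c for c in covs if c in df.columns])
        dropped["missing_covariates"] += n0 - len(cc)
        df = cc
        for col in spec.categorical_covariates:
            if col not in df.columns or df[col].nunique() <= 1:
                continue
            sizes = df[col].value_counts()
            small = sizes[sizes < spec.min_category_size].index
            if len(small):
                before = len(df)
                df = df[~df[col].isin(small)]
                dropped["small_category"] += before - len(df)
        if "event" in df.columns:
            for col in spec.categorical_covariates:
                if col not in df.columns or df[col].nunique() <= 1:
                    continue
                ev = df.groupby(col, observed=True)["event"].agg(["sum", "count"])
                bad = ev[(ev["sum"] == 0) | (ev["sum"] == ev["count"])].index
                if len(bad):
                    before = len(df)
                    df = df[~df[col].isin(bad)]
                    dropped["no_event_variation"] += before - len(df)
        if len(df) == n0:
            break
    if df.empty:
        raise EmptyFrameError("filtering removed every subject")
    return df.copy(), dropped


def encode_design(records: pd.DataFrame, spec: CoxModelSpec) -> pd.DataFrame:
    """Numeric + dummy-encoded design matrix (baseline levels dropped)."""
    cols = {}
    for c in spec.numeric_covariates + spec.gwas_covariates:
        if c not in records.columns:
            raise MissingDataError(f"covariate {c!r} absent from frame")
        cols[c] = records[c].astype(float)
    for c in spec.categorical_covariates:
        if c not in records.columns:
            raise MissingDataError(f"covariate {c!r} absent from frame")
        baseline = spec.baselines.get(c)
        levels = [l for l in pd.unique(records[c]) if l != baseline]
        for level in sorted(map(str, levels)):
            cols[f"{c}[{level}]"] = (records[c].astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=records.index)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_cox(records: pd.DataFrame, spec: CoxModelSpec) -> CoxFit:
    """Fit the Cox model on a prepared, filtered frame.

    ``records`` must carry 'time' and 'event' plus the spec covariates.
    Efron tie handling; Wald 95% CIs; numeric covariates are per unit
    (per additional allele for dosages).
    """
    if records["event"].sum() < 1:
        raise EmptyFrameError("no events in scope")
    design = encode_design(records, spec)
    # constant columns carry no information and break the optimizer
    design = design.loc[:, design.std() > 0]
    frame = design.assign(time=records["time"].to_numpy(),
                          event=records["event"].to_numpy())
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
    except _LLConvergenceError as exc:
        raise ConvergenceError(str(exc)) from exc
    summ = cph.summary
    coef = pd.DataFrame({
        "log_hr": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci95_low": np.exp(summ["coef lower 95%"]),
        "ci95_high": np.exp(summ["coef upper 95%"]),
        "p_value": summ["p"],
    })
    coef.index.name = "covariate"
    return CoxFit(spec.endpoint, spec.cohort_scope, coef,
                  n_used=len(frame), n_events=int(frame["event"].sum()))


def run_paper_models(
    cohort: pd.DataFrame,
    scopes: Sequence[str] = ("all", "DR3_homozygous"),
    endpoints: Sequence[str] = ENDPOINTS,
) -> dict[tuple[str, str], CoxFit | str]:
    """All endpoint x scope fits with endpoint-appropriate GWAS covariates.

    Fits that cannot run (no events after filtering) are recorded as a
    reason string instead of a CoxFit.
    """
    results: dict[tuple[str, str], CoxFit | str] = {}
    for endpoint in endpoints:
        gwas = tuple(sorted(reference.gwas_panel(endpoint)))
        for scope in scopes:
            numeric = ("trisnp_101_dosage", "fdr")
            if endpoint in ("CD", "CDA"):
                numeric = numeric + ("gluten_intake",)
            cats = ("hla_genotype", "sex", "country", "ancestry")
            if scope == "DR3_homozygous":
                cats = ("sex", "country", "ancestry")
            spec = CoxModelSpec(
                endpoint=endpoint,
                cohort_scope=scope,
                numeric_covariates=numeric,
                categorical_covariates=cats,
                gwas_covariates=tuple(g for g in gwas if g in cohort.columns),
            )
            try:
                frame, _ = prepare_endpoint(cohort, endpoint)
                frame, _ = filter_model_frame(frame, spec)
                results[(endpoint, scope)] = fit_cox(frame, spec)
            except (EmptyFrameError, ConvergenceError) as exc:
                results[(endpoint, scope)] = f"skipped: {exc}"
    return results


def fits_to_frame(results: Mapping[tuple[str, str], CoxFit | str]) -> pd.DataFrame:
    """Long-format coefficient table across all completed fits."""
    rows = []
    for (endpoint, scope), fit in results.items():
        if not isinstance(fit, CoxFit):
            continue
        tab = fit.coefficients.reset_index()
        tab.insert(0, "endpoint", endpoint)
        tab.insert(1, "scope", scope)
        tab["n"] = fit.n_used
        tab["n_events"] = fit.n_events
        rows.append(tab)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
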