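"""CPM computation, per-individual aggregation, and dosage-trend testing.

The trend stage regresses log2(CPM + 0.5), aggregated to one value per
individual (median over that individual's samples), on batch, age
category, sex and the numeric tri-SNP 101 dosage, and reports a two-sided
t-test on the dosage coefficient with Benjamini-Hochberg adjustment
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, LibrarySizeError

__all__ = [
    "ExpressionMatrix",
    "compute_cpm",
    "aggregate_per_individual",
    "dosage_trend",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample counts plus per-sample covariates.

    ``samples`` must carry sample_id, individual_id, batch, age_category,
    sex and trisnp_101_dosage; every counts column maps to exactly one
    individual.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples table lacks {sorted(missing)[:3]}...")
        dup = self.samples["sample_id"].duplicated()
        if dup.any():
            raise ValueError("duplicate sample ids in covariate table")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def compute_cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million per sample: count / library_size * 1e6."""
    lib = matrix.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise LibrarySizeError(f"zero library size for {bad[:3]}")
    return matrix.counts / lib * 1e6


def aggregate_per_individual(cpm: pd.DataFrame,
                             sample_to_individual: pd.Series | dict) -> pd.DataFrame:
    """Median CPM over each individual's samples (genes x individuals)."""
    mapping = pd.Series(sample_to_individual)
    groups = cpm.T.groupby(cpm.columns.map(mapping))
    return groups.median().T


def _individual_covariates(samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse sample-level covariates to one row per individual.

    Sex and dosage are individual-level by construction; batch and age
    category take the per-individual mode (documented simplification of
    sample-level blocking).
    """
    def mode(s: pd.Series):
        return s.mode().iloc[0]

    return samples.groupby("individual_id").agg(
        batch=("batch", mode),
        age_category=("age_category", mode),
        sex=("sex", mode),
        trisnp_101_dosage=("trisnp_101_dosage", "first"),
    )


def dosage_trend(matrix: ExpressionMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene least-squares dosage trend on aggregated log2 CPM.

    Returns a frame indexed by gene with columns coefficient (log2-CPM
    per 101 allele), p_value, bh_adjusted_p and significant (BH at
    ``alpha``).
    """
    cpm = compute_cpm(matrix)
    mapping = matrix.samples.set_index("sample_id")["individual_id"]
    agg = aggregate_per_individual(cpm, mapping)
    cov = _individual_covariates(matrix.samples).loc[agg.columns]

    if cov["trisnp_101_dosage"].nunique() < 2:
        raise DesignError("need >= 2 dosage levels")

    y = np.log2(agg.to_numpy(float) + 0.5)        # genes x individuals
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for level in sorted(cov["batch"].unique())[1:]:
        cols.append((cov["batch"] == level).to_numpy(float))
        names.append(f"batch[{level}]")
    cols.append((cov["age_category"] == "<1y").to_numpy(float))
    names.append("age_lt_1y")
    cols.append((cov["sex"] == "male").to_numpy(float))
    names.append("sex_male")
    cols.append(cov["trisnp_101_dosage"].to_numpy(float))
    names.append("dosage")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(f"design matrix rank {rank} < {X.shape[1]} columns")
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T                       # genes x p
    resid = y - beta @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    j = names.index("dosage")
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, j] / se
    p_values = 2.0 * stats.t.sf(np.abs(t), dof)
    p_values = np.nan_to_num(p_values, nan=1.0)
    _, bh, _, _ = multipletests(p_values, method="fdr_bh")
    return pd.DataFrame({
        "coefficient": beta[:, j],
        "t_statistic": t,
        "p_value": p_values,
        "bh_adjusted_p": bh,
        "significant": bh < alpha,
    }, index=cpm.index)
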