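"""Cohort-level statistics: covariate-adjusted group effects, correlations,
and descriptive summaries.

For each LV flow parameter an ordinary least-squares model

    outcome ~ group + age + sex + heart_rate

is fitted with the group indicator coded AMI = 1 / control = 0 and sex coded
M = 1 / F = 0, so a flow reduction in the infarct group appears as a negative
group coefficient (the adjusted difference "delta").  Confidence intervals
and p-values come from the t distribution on the residual degrees of
freedom.  No multiple-testing correction is applied across the 11 parameters
(each model is tested separately at alpha = 0.05); see the methods note.

Correlations use Spearman's rank statistic; descriptive summaries report
median +/- IQR (linear-interpolation quartiles) or mean +/- sample SD, and
demographics are compared with Welch two-sample t-tests plus a chi-squared
test (no continuity correction) for sex proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import islice, permutations
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupEffect",
    "CorrelationResult",
    "Descriptives",
    "group_model",
    "spearman_corr",
    "describe",
    "compare_demographics",
]


@dataclass
class GroupEffect:
    """Adjusted AMI-minus-control difference for one flow parameter."""

    parameter: str
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


@dataclass
class Descriptives:
    center: float
    spread: float
    style: str  # "median_iqr" or "mean_sd"
    n: int


def _design(cohort: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "group_ami": (cohort["group"] == "AMI").astype(float),
            "age": cohort["age"].astype(float),
            "sex_m": (cohort["sex"] == "M").astype(float),
            "heart_rate": cohort["heart_rate"].astype(float),
        },
        index=cohort.index,
    )
    return sm.add_constant(X, has_constant="add")


def group_model(cohort: pd.DataFrame, outcome_name: str) -> GroupEffect:
    """OLS of the outcome on group + age + sex + heart rate.

    Requires at least 6 complete cases and both groups represented.  A
    singular design (e.g. a single-sex cohort) raises with the collinear
    column named.
    """
    cols = ["group", "age", "sex", "heart_rate", outcome_name]
    data = cohort[cols].dropna()
    if len(data) < 6:
        raise ValueError(f"need >= 6 complete cases, have {len(data)}")
    if data["group"].nunique() < 2:
        raise ValueError("both groups must be represented")
    X = _design(data)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a column whose removal restores full rank
        for col in X.columns[1:]:
            reduced = X.drop(columns=col)
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"design matrix is singular: column '{col}' is collinear")
        raise ValueError("design matrix is singular")
    y = data[outcome_name].astype(float)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05).loc["group_ami"]
    return GroupEffect(
        parameter=outcome_name,
        delta=float(fit.params["group_ami"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["group_ami"]),
        n=int(fit.nobs),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n).

    Enumerates all n! pairings in vectorized chunks; rho per pairing is the
    mean product of standardized mid-ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    perm_iter = permutations(range(n))
    chunk_size = 200_000
    while True:
        chunk = list(islice(perm_iter, chunk_size))
        if not chunk:
            break
        idx = np.asarray(chunk, dtype=np.int8)
        rhos = rx[idx] @ ry / n
        count += int(np.count_nonzero(np.abs(rhos) >= thresh))
        total += len(chunk)
    return count / total


def spearman_corr(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    For n > 10 the p-value uses the t approximation; for n <= 10 it is an
    exact permutation test over all n! pairings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if n <= 10:
        p = _exact_spearman_p(x, y, rho)
    return CorrelationResult(pair=names, rho=float(rho), p_value=float(p), n=n)


def describe(values, style: str = "median_iqr") -> Descriptives:
    """Median +/- IQR (Q3-Q1, linear-interpolation quartiles) or mean +/- SD (n-1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty vector")
    if style == "median_iqr":
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return Descriptives(center=float(med), spread=float(q3 - q1), style=style, n=v.size)
    if style == "mean_sd":
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return Descriptives(center=float(v.mean()), spread=sd, style=style, n=v.size)
    raise ValueError(f"unknown style {style!r}")


def compare_demographics(
    cohort: pd.DataFrame, continuous: Optional[list[str]] = None
) -> pd.DataFrame:
    """Welch t-tests for continuous demographics and chi-squared for sex.

    Returns one row per variable with group means/SDs (or counts) and the
    p-value; zero-variance variables yield p = NaN with a warning.
    """
    if continuous is None:
        continuous = [
            c
            for c in cohort.columns
            if c not in ("subject", "group", "sex") and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    a = cohort[cohort["group"] == "control"]
    b = cohort[cohort["group"] == "AMI"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for var in continuous:
        xa = a[var].dropna().to_numpy(dtype=float)
        xb = b[var].dropna().to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            warnings.warn(f"variable {var!r} has zero variance; p-value undefined")
            p = np.nan
            stat = np.nan
        else:
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "variable": var,
                "control_mean": xa.mean(),
                "control_sd": xa.std(ddof=1) if len(xa) > 1 else 0.0,
                "ami_mean": xb.mean(),
                "ami_sd": xb.std(ddof=1) if len(xb) > 1 else 0.0,
                "statistic": float(stat) if np.isfinite(stat) else np.nan,
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "test": "welch_t",
            }
        )
    if "sex" in cohort.columns:
        table = np.array(
            [
                [(a["sex"] == "M").sum(), (a["sex"] == "F").sum()],
                [(b["sex"] == "M").sum(), (b["sex"] == "F").sum()],
            ]
        )
        if np.any(table.sum(axis=0) == 0):
            warnings.warn("sex is constant across the cohort; chi-squared undefined")
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "variable": "sex_male",
                "control_mean": table[0, 0] / table[0].sum(),
                "control_sd": np.nan,
                "ami_mean": table[1, 0] / table[1].sum(),
                "ami_sd": np.nan,
                "statistic": float(chi2) if np.isfinite(chi2) else np.nan,
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "test": "chi_squared",
            }
        )
    return pd.DataFrame(rows)
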