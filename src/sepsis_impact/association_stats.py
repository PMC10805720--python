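"""Adjusted linear model for antibiotic timing and descriptive cohort tests.

The association model regresses time from ED triage to antibiotic
administration (hours) on age, sex, Elixhauser index, baseline SOFA,
monthly ED volume (thousands) and alert-acknowledgement indicators
(reference level: no acknowledgement), restricted to alerted septic
encounters that received antibiotics.  Descriptive comparisons use
Kruskal-Wallis rank-sum tests for continuous variables and Pearson
chi-squared tests for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ACK_LEVELS = ("no_infection", "workup", "notify_md")  # "none" is the reference


@dataclass
class OlsFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df_resid: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "coefficient": self.coef,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> OlsFit:
    """Ordinary least squares with classical t-based inference."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    if n <= k:
        raise ValueError("more columns than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    q, r = np.linalg.qr(X)
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - k
    s2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = s2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    tcrit = stats.t.ppf(0.975, df)
    return OlsFit(
        names=list(names),
        coef=coef,
        se=se,
        t=tstat,
        p=p,
        ci_low=coef - tcrit * se,
        ci_high=coef + tcrit * se,
        df_resid=df,
    )


def fit_time_to_abx_model(
    outcomes: pd.DataFrame, encounters: pd.DataFrame, labels: pd.DataFrame
) -> OlsFit:
    """OLS of time-to-antibiotics on confounders and acknowledgement category.

    Only alerted encounters with an observed antibiotic administration enter;
    monthly ED volume (all comers, in thousands) is attached by arrival month.
    """
    enc = encounters.copy()
    enc["month"] = pd.to_datetime(enc["arrival"]).dt.to_period("M")
    volume = enc.groupby("month").size().rename("monthly_volume")
    enc = enc.join(volume, on="month")

    df = outcomes.merge(
        labels[["encounter_id", "baseline_sofa"]], on="encounter_id"
    ).merge(
        enc[["encounter_id", "age", "sex", "elixhauser", "monthly_volume"]], on="encounter_id"
    )
    df = df[(df["ack_category"] != "no_alert") & df["time_to_abx_hours"].notna()]
    if len(df) < 12:
        raise ValueError("too few alerted encounters with antibiotics to fit the model")

    names = ["intercept", "age", "male", "elixhauser", "baseline_sofa", "ed_volume_thousands"]
    cols = [
        np.ones(len(df)),
        df["age"].to_numpy(float),
        (df["sex"] == "male").to_numpy(float),
        df["elixhauser"].to_numpy(float),
        df["baseline_sofa"].to_numpy(float),
        df["monthly_volume"].to_numpy(float) / 1000.0,
    ]
    for level in ACK_LEVELS:
        names.append(f"ack_{level}")
        cols.append((df["ack_category"] == level).to_numpy(float))
    X = np.column_stack(cols)
    return ols(df["time_to_abx_hours"].to_numpy(float), X, names)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared with k-1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)  # average ranks for ties
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    dfree = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, dfree))


def chi_squared_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.rint(obs)):
        raise ValueError("counts must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    total = obs.sum()
    expected = np.outer(rows, cols) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    dfree = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, float(stats.chi2.sf(statistic, dfree))
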