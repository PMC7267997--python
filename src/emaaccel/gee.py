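"""Marginal linear models for clustered observations.

Estimating equations with a Gaussian variance family, identity link, and
independence working correlation reduce to the least-squares normal
equations, so the coefficient estimates here are exact linear algebra; what
distinguishes the fit is the Huber/White cluster-robust (sandwich)
covariance

    V = (X'X)^{-1} ( sum_c X_c' r_c r_c' X_c ) (X'X)^{-1},

with residual vectors r_c per cluster c (clusters are participants: the
repeated surveys of one dyad share unmodelled error).  Wald chi-square
tests and stratum contrasts with normal-quantile 95% CIs are built on V.

The sandwich is the uncorrected HC0-type cluster sum by default; a
CR1-style small-sample factor G/(G-1) * (N-1)/(N-p) is available behind
``dof_correction=True``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DesignSpec

__all__ = [
    "GEEFit",
    "WaldResult",
    "StratumEstimate",
    "build_design_matrix",
    "fit_gee_independence",
    "wald_test",
    "stratum_estimates",
    "fit_design",
]

Z_95 = 1.96  # large-cluster normal quantile for 95% CIs


@dataclasses.dataclass
class GEEFit:
    """Coefficients, cluster-robust covariance, and fit metadata."""

    beta: np.ndarray
    robust_cov: np.ndarray
    column_names: list[str]
    n_clusters: int
    n_obs: int
    outcome: str = ""
    exposure: str = ""
    modifier: str = "none"

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.column_names.index(name)])


@dataclasses.dataclass
class WaldResult:
    statistic: float
    df: int
    p_value: float


@dataclasses.dataclass
class StratumEstimate:
    """Exposure contrast (min/hr difference) within one modifier stratum."""

    level: str
    estimate: float
    ci_low: float
    ci_high: float


_MODIFIER_COLUMN = {"weekend": "weekend", "sex": "sex", "season": "season"}
_MODIFIER_STRATA = {
    "weekend": ("weekday", "weekend"),
    "sex": ("girl", "boy"),
    "season": ("school_year", "summer"),
}


def _modifier_indicator(table: pd.DataFrame, modifier: str) -> np.ndarray:
    """0/1 indicator of the non-reference stratum (weekend, boy, summer)."""
    if modifier == "weekend":
        return table["weekend"].astype(int).to_numpy()
    if modifier == "sex":
        return (table["sex"] == "boy").astype(int).to_numpy()
    if modifier == "season":
        return (table["season"] == "summer").astype(int).to_numpy()
    raise ValueError(f"unknown modifier {modifier!r}")


def build_design_matrix(
    table: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Expand an analysis table into (y, X, cluster ids, column names).

    Categorical covariates become indicator columns against the spec's
    reference levels; booleans become 0/1; numeric covariates pass through.
    With a modifier, X gains the exposure-by-modifier product column.  A
    rank-deficient design raises with the offending columns named.
    """
    used = [spec.outcome, spec.exposure, *spec.covariates]
    if table[used].isna().any().any():
        bad = [c for c in used if table[c].isna().any()]
        raise ValueError(f"missing values in model columns: {bad}")
    y = table[spec.outcome].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    cols[spec.exposure] = table[spec.exposure].astype(int).to_numpy()
    for cov in spec.covariates:
        series = table[cov]
        if series.dtype == bool or str(series.dtype) == "boolean":
            cols[cov] = series.astype(int).to_numpy()
        elif series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            ref = spec.reference_levels.get(cov)
            levels = sorted(series.unique())
            if ref is None:
                ref = levels[0]
            for level in levels:
                if level == ref:
                    continue
                cols[f"{cov}[{level}]"] = (series == level).astype(int).to_numpy()
        else:
            cols[cov] = series.to_numpy(dtype=float)
    if spec.modifier != "none":
        ind = _modifier_indicator(table, spec.modifier)
        cols[f"{spec.exposure}:{spec.modifier}"] = cols[spec.exposure] * ind
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; collinear columns: {collinear}")
    clusters = table["participant_id"].to_numpy()
    return y, X, clusters, names


def fit_gee_independence(
    y: np.ndarray,
    X: np.ndarray,
    clusters: Sequence,
    column_names: list[str] | None = None,
    dof_correction: bool = False,
) -> GEEFit:
    """Solve the independence estimating equations and form the sandwich.

    Requires at least two clusters and a full-rank design.  With one
    observation per cluster the sandwich reduces to the HC0
    heteroskedasticity-robust covariance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    clusters = np.asarray(clusters)
    codes, uniques = pd.factorize(clusters)
    if len(uniques) < 2:
        raise ValueError("at least two clusters are required")
    xtx = X.T @ X
    try:
        bread = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular X'X; design is rank deficient") from err
    beta = bread @ (X.T @ y)
    resid = y - X @ beta
    p = X.shape[1]
    meat = np.zeros((p, p))
    # sum_c (X_c' r_c)(X_c' r_c)'
    xr = np.zeros((len(uniques), p))
    np.add.at(xr, codes, X * resid[:, None])
    meat = xr.T @ xr
    V = bread @ meat @ bread
    if dof_correction:
        G, N = len(uniques), len(y)
        V = V * (G / (G - 1)) * ((N - 1) / (N - p))
    V = (V + V.T) / 2.0
    return GEEFit(
        beta=beta,
        robust_cov=V,
        column_names=column_names or [f"x{i}" for i in range(p)],
        n_clusters=len(uniques),
        n_obs=len(y),
    )


def wald_test(fit: GEEFit, L: np.ndarray) -> WaldResult:
    """Wald chi-square test of H0: L @ beta = 0.

    ``L`` is a full-row-rank contrast matrix with one column per
    coefficient; the statistic is (Lb)' (L V L')^{-1} (Lb) on rows(L)
    degrees of freedom.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != fit.beta.size:
        raise ValueError("contrast matrix has wrong number of columns")
    lb = L @ fit.beta
    if not lb.any() and not L.any():
        return WaldResult(statistic=0.0, df=L.shape[0], p_value=1.0)
    lvl = L @ fit.robust_cov @ L.T
    try:
        middle = np.linalg.solve(lvl, lb)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular L V L' in Wald test") from err
    stat = float(lb @ middle)
    df = L.shape[0]
    return WaldResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def interaction_wald(fit: GEEFit) -> WaldResult:
    """Wald test of the exposure-by-modifier product coefficient."""
    name = f"{fit.exposure}:{fit.modifier}"
    if name not in fit.column_names:
        raise ValueError(f"fit has no interaction column {name!r}")
    L = np.zeros((1, fit.beta.size))
    L[0, fit.column_names.index(name)] = 1.0
    return wald_test(fit, L)


def stratum_estimates(fit: GEEFit) -> list[StratumEstimate]:
    """Exposure effect and 95% CI within each modifier stratum.

    Reference stratum: the exposure coefficient alone; the other stratum
    adds the product coefficient.  Standard errors come from a'Va for the
    stratum's contrast vector a; CIs use estimate +/- 1.96 SE.
    """
    if fit.modifier == "none" or fit.modifier not in _MODIFIER_STRATA:
        raise ValueError("fit was specified without a modifier")
    inter = f"{fit.exposure}:{fit.modifier}"
    if inter not in fit.column_names:
        raise ValueError(f"fit has no interaction column {inter!r}")
    i_exp = fit.column_names.index(fit.exposure)
    i_int = fit.column_names.index(inter)
    ref_level, alt_level = _MODIFIER_STRATA[fit.modifier]
    out = []
    for level, idxs in ((ref_level, [i_exp]), (alt_level, [i_exp, i_int])):
        a = np.zeros(fit.beta.size)
        a[idxs] = 1.0
        est = float(a @ fit.beta)
        se = float(np.sqrt(a @ fit.robust_cov @ a))
        out.append(
            StratumEstimate(level=level, estimate=est, ci_low=est - Z_95 * se, ci_high=est + Z_95 * se)
        )
    return out


def fit_design(table: pd.DataFrame, spec: DesignSpec, dof_correction: bool = False) -> GEEFit:
    """Convenience wrapper: design construction + fit, tagged with the spec."""
    y, X, clusters, names = build_design_matrix(table, spec)
    fit = fit_gee_independence(y, X, clusters, names, dof_correction=dof_correction)
    fit.outcome = spec.outcome
    fit.exposure = spec.exposure
    fit.modifier = spec.modifier
    return fit
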