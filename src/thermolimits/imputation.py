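"""Multiple imputation by predictive mean matching (PMM), with Rubin pooling.

Each of M imputations bootstraps the rows, regresses every incomplete
covariate on the remaining covariates (ordinary least squares on the
bootstrap's complete cases), and fills each missing cell with the observed
value of a donor drawn from the k nearest predictions.  Imputed values are
therefore always observed values of the variable.  Estimates fit on the M
completed datasets are combined with Rubin's rules: total variance
T = W + (1 + 1/M) B, where W is the mean within-imputation variance and B
the between-imputation variance of the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["ImputationSet", "PooledEstimate", "pmm_multiple_impute", "pool_rubin", "pool_fits"]


@dataclass
class ImputationSet:
    datasets: list          # M completed DataFrames
    M: int
    k_donors: int
    seed: int
    variables: list


@dataclass
class PooledEstimate:
    names: list
    estimate: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    M: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total_var)

    def table(self) -> pd.DataFrame:
        se = self.se
        z = self.estimate / se
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimate,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _design_for(df: pd.DataFrame, target: str, predictors: list) -> np.ndarray:
    """Mean-filled numeric predictor matrix with an intercept column."""
    X = df[predictors].to_numpy(dtype=float)
    col_means = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])
    return np.column_stack([np.ones(len(df)), X])


def pmm_multiple_impute(
    data: pd.DataFrame,
    variables: list | None = None,
    M: int = 20,
    k_donors: int = 3,
    seed: int = 0,
    min_donors: int = 10,
) -> ImputationSet:
    """Multiply impute missing numeric covariates by PMM.

    Parameters
    ----------
    data : DataFrame
        Analysis table; only the named ``variables`` (default: all numeric
        columns with missing cells) are imputed.
    M : int
        Number of completed datasets (study default 20).
    k_donors : int
        Donor-pool size per missing cell; one donor is drawn uniformly.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    numeric = data.select_dtypes(include=[np.number]).columns
    if variables is None:
        variables = [c for c in numeric if data[c].isna().any()]
    for v in variables:
        if v not in data.columns:
            raise KeyError(f"no such column: {v!r}")
        n_obs = data[v].notna().sum()
        if n_obs == 0:
            raise ValueError(f"variable {v!r} has no observed values")
        if n_obs < min_donors:
            raise ValueError(
                f"variable {v!r} has only {n_obs} observed donors "
                f"(need >= {min_donors})"
            )
    predictors_all = [c for c in numeric]
    rng = np.random.default_rng(seed)
    n = len(data)
    completed = []
    for _ in range(M):
        boot_idx = rng.integers(0, n, n)
        boot = data.iloc[boot_idx]
        filled = data.copy()
        for v in variables:
            miss_mask = data[v].isna().to_numpy()
            if not miss_mask.any():
                continue
            preds = [c for c in predictors_all if c != v]
            yb = boot[v].to_numpy(dtype=float)
            ok = np.isfinite(yb)
            Xb = _design_for(boot, v, preds)[ok]
            yb = yb[ok]
            X_full = _design_for(data, v, preds)
            coef = None
            if len(yb) > Xb.shape[1]:
                try:
                    coef, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
                    if not np.all(np.isfinite(coef)):
                        coef = None
                except np.linalg.LinAlgError:  # pragma: no cover
                    coef = None
            obs_mask = ~miss_mask
            obs_values = data.loc[obs_mask, v].to_numpy(dtype=float)
            if coef is None:
                warnings.warn(
                    f"degenerate regression for {v!r}; drawing random donors",
                    RuntimeWarning,
                )
                draw = rng.choice(obs_values, miss_mask.sum())
                filled.loc[miss_mask, v] = draw
                continue
            pred = X_full @ coef
            pred_obs = pred[obs_mask]
            pred_mis = pred[miss_mask]
            k = min(k_donors, len(obs_values))
            # nearest-k observed predictions per missing cell, one drawn
            order = np.argsort(
                np.abs(pred_obs[None, :] - pred_mis[:, None]), axis=1
            )[:, :k]
            pick = order[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
            filled.loc[miss_mask, v] = obs_values[pick]
        completed.append(filled)
    return ImputationSet(
        datasets=completed, M=M, k_donors=k_donors, seed=seed,
        variables=list(variables),
    )


def pool_rubin(estimates, variances, names=None) -> PooledEstimate:
    """Rubin's rules for M repeated estimates.

    Parameters
    ----------
    estimates : (M, p) array-like
        Per-imputation coefficient estimates (identically specified models).
    variances : (M, p) array-like
        Per-imputation squared standard errors.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances have mismatched shapes")
    M = est.shape[0]
    if M < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = est.mean(axis=0)
    W = var.mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / M) * B
    if names is None:
        names = [f"b{i}" for i in range(est.shape[1])]
    return PooledEstimate(
        names=list(names), estimate=qbar, within_var=W,
        between_var=B, total_var=T, M=M,
    )


def pool_fits(fits, names=None) -> PooledEstimate:
    """Pool a list of CPMFit objects (same specification) by Rubin's rules."""
    first = fits[0].beta_names
    for f in fits:
        if f.beta_names != first:
            raise ValueError("fits have mismatched coefficient sets")
    est = np.array([f.betas for f in fits])
    var = np.array([np.diag(f.vcov_beta) for f in fits])
    return pool_rubin(est, var, names=names or first)
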