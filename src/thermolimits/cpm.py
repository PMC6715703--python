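"""Cumulative probability models (CPMs) for continuous outcomes.

A CPM is a semi-parametric proportional-odds regression in which every
distinct outcome value defines an ordered category:

    P(Y >= y_j | X) = expit(alpha_j + X beta),   j = 2..J

With no covariates the model is saturated on the outcome's marginal
distribution, and with one binary covariate its score/LR test tracks the
Wilcoxon-Mann-Whitney test; beta is invariant to strictly monotone
transformations of Y.  Fitting is by damped Newton iteration on the joint
(alpha, beta) parameterization, where the log-likelihood is concave, with
step-halving to preserve positive category probabilities.

Model selection across candidate predictor subsets uses BIC weights
w_m proportional to exp(-Delta BIC / 2); Nagelkerke's R^2 normalizes the
likelihood-ratio gain over the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "CPMFit",
    "ModelFitStats",
    "ModelSelection",
    "ConvergenceError",
    "fit_cpm",
    "null_cpm",
    "model_inference",
    "best_subset_bic",
    "hierarchical_models",
]


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration diverges (e.g. complete separation)."""


@dataclass
class CPMFit:
    """A fitted cumulative probability model."""

    intercepts: np.ndarray          # alpha_j for P(Y >= v_j), j = 2..J
    betas: np.ndarray
    beta_names: list
    vcov_beta: np.ndarray           # covariance of the slope estimates
    loglik: float
    loglik_null: float
    n: int
    n_categories: int
    converged: bool
    n_iter: int
    y_values: np.ndarray = field(repr=False, default=None)

    @property
    def k_params(self) -> int:
        return len(self.intercepts) + len(self.betas)

    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * np.log(self.n)

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))


@dataclass
class ModelFitStats:
    lr_chi2: float
    df: int
    p: float
    nagelkerke_r2: float
    coef_table: pd.DataFrame        # beta, se, aOR, CI, Wald chi2, p


@dataclass
class ModelSelection:
    table: pd.DataFrame             # one row per candidate subset
    inclusion_probs: dict
    best_id: int
    fits: list


def _prepare(y, X):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X have incompatible lengths")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in y or X")
    values, codes = np.unique(y, return_inverse=True)
    J = values.size
    if J < 2:
        raise ValueError("outcome must have at least 2 distinct values")
    if p > 0:
        if n <= p:
            raise ValueError("need n > number of predictors")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < p:
            raise ValueError("design matrix is rank deficient")
    return y, X, values, codes, n, p, J


def _loglik_parts(alpha, beta, X, codes, J):
    """Per-observation category probabilities and logistic terms."""
    eta = X @ beta if beta.size else np.zeros(X.shape[0])
    # gamma_hi = P(Y >= value of own category), gamma_lo = next category up
    hi_idx = codes - 1          # alpha index of own category (valid if >= 0)
    lo_idx = codes              # alpha index of next category (valid if <= J-2)
    hi_valid = hi_idx >= 0
    lo_valid = lo_idx <= J - 2
    g_hi = np.ones_like(eta)
    g_lo = np.zeros_like(eta)
    g_hi[hi_valid] = expit(alpha[hi_idx[hi_valid]] + eta[hi_valid])
    g_lo[lo_valid] = expit(alpha[lo_idx[lo_valid]] + eta[lo_valid])
    probs = g_hi - g_lo
    return probs, g_hi, g_lo, hi_valid, lo_valid, hi_idx, lo_idx


def _start_values(codes, J, p):
    counts = np.bincount(codes, minlength=J)
    n = counts.sum()
    tail = np.cumsum(counts[::-1])[::-1]    # #{y >= v_j}
    frac = tail[1:] / n
    alpha = np.log(frac / (1.0 - frac))
    return alpha, np.zeros(p)


def fit_cpm(
    y,
    X=None,
    beta_names=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CPMFit:
    """Fit a cumulative probability model by damped Newton iteration.

    Parameters
    ----------
    y : array-like
        Continuous (or ordinal) outcome; ties share a category.
    X : array-like or DataFrame, optional
        Design matrix without intercept column; omit for the
        intercept-only model (whose MLE is the empirical exceedance
        logits, obtained in closed form).
    """
    if isinstance(X, pd.DataFrame):
        beta_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    if X is None:
        X = np.empty((np.asarray(y).size, 0))
    y, X, values, codes, n, p, J = _prepare(y, X)
    if beta_names is None:
        beta_names = [f"x{i+1}" for i in range(p)]
    counts = np.bincount(codes, minlength=J)
    ll_null = float(np.sum(counts * np.log(counts / n)))

    alpha, beta = _start_values(codes, J, p)
    if p == 0:
        return CPMFit(
            intercepts=alpha, betas=beta, beta_names=[],
            vcov_beta=np.empty((0, 0)), loglik=ll_null, loglik_null=ll_null,
            n=n, n_categories=J, converged=True, n_iter=0, y_values=values,
        )

    theta = np.concatenate([alpha, beta])
    nA = J - 1

    def loglik(theta):
        probs, *_ = _loglik_parts(theta[:nA], theta[nA:], X, codes, J)
        if np.any(probs <= 0):
            return -np.inf
        return float(np.sum(np.log(probs)))

    def grad_hess(theta):
        alpha, beta = theta[:nA], theta[nA:]
        probs, g_hi, g_lo, hv, lv, hi_idx, lo_idx = _loglik_parts(
            alpha, beta, X, codes, J
        )
        w_hi = np.where(hv, g_hi * (1 - g_hi), 0.0) / probs
        w_lo = np.where(lv, g_lo * (1 - g_lo), 0.0) / probs
        # gradient
        g = np.zeros(nA + p)
        np.add.at(g, hi_idx[hv], w_hi[hv])
        np.add.at(g, lo_idx[lv], -w_lo[lv])
        g[nA:] = X.T @ (w_hi - w_lo)
        # per-observation 2x2 curvature blocks in (u_hi, u_lo)
        h_hi = np.where(hv, g_hi * (1 - g_hi) * (1 - 2 * g_hi), 0.0)
        h_lo = np.where(lv, g_lo * (1 - g_lo) * (1 - 2 * g_lo), 0.0)
        W_hh = h_hi / probs - w_hi**2
        W_ll = -h_lo / probs - w_lo**2
        W_hl = w_hi * w_lo
        H = np.zeros((nA + p, nA + p))
        np.add.at(H, (hi_idx[hv], hi_idx[hv]), W_hh[hv])
        np.add.at(H, (lo_idx[lv], lo_idx[lv]), W_ll[lv])
        both = hv & lv
        np.add.at(H, (hi_idx[both], lo_idx[both]), W_hl[both])
        np.add.at(H, (lo_idx[both], hi_idx[both]), W_hl[both])
        # alpha-beta and beta-beta blocks
        c_hi = np.where(hv, W_hh, 0.0) + np.where(both, W_hl, 0.0)
        c_lo = np.where(lv, W_ll, 0.0) + np.where(both, W_hl, 0.0)
        AB = np.zeros((nA, p))
        np.add.at(AB, hi_idx[hv], c_hi[hv, None] * X[hv])
        np.add.at(AB, lo_idx[lv], c_lo[lv, None] * X[lv])
        H[:nA, nA:] = AB
        H[nA:, :nA] = AB.T
        w_bb = (
            np.where(hv, W_hh, 0.0)
            + np.where(lv, W_ll, 0.0)
            + 2 * np.where(both, W_hl, 0.0)
        )
        H[nA:, nA:] = X.T @ (w_bb[:, None] * X)
        return g, H

    ll = loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g, H = grad_hess(theta)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            ll_new = loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        else:
            break  # no improving damped step: stop with current estimate
        theta, ll = cand, ll_new
    if np.max(np.abs(theta[nA:])) > 35:
        raise ConvergenceError(
            "slope estimate diverged; data are likely completely separated"
        )
    g, H = grad_hess(theta)
    if np.max(np.abs(g)) < 1e-4:
        converged = True
    # slope covariance by block inversion of the observed information
    info = -H
    A = info[:nA, :nA]
    Bm = info[:nA, nA:]
    D = info[nA:, nA:]
    schur = D - Bm.T @ np.linalg.solve(A, Bm)
    vcov_beta = np.linalg.inv(schur)
    return CPMFit(
        intercepts=theta[:nA].copy(), betas=theta[nA:].copy(),
        beta_names=list(beta_names), vcov_beta=vcov_beta,
        loglik=float(ll), loglik_null=ll_null, n=n, n_categories=J,
        converged=converged, n_iter=it, y_values=values,
    )


def null_cpm(y) -> CPMFit:
    """Intercept-only CPM (closed form: empirical exceedance logits)."""
    return fit_cpm(y, None)


def model_inference(fit: CPMFit, null_fit: CPMFit | None = None) -> ModelFitStats:
    """Likelihood-ratio test, Nagelkerke R^2, and per-coefficient Wald stats.

    ``null_fit`` defaults to the intercept-only model on the same data; any
    nested fit with fewer slopes may be supplied instead.
    """
    if null_fit is None:
        ll0 = fit.loglik_null
        df = len(fit.betas)
    else:
        if null_fit.n != fit.n:
            raise ValueError("models are not fit to the same data")
        df = len(fit.betas) - len(null_fit.betas)
        if df < 0 or not set(null_fit.beta_names) <= set(fit.beta_names):
            raise ValueError("null model is not nested in the fitted model")
        ll0 = null_fit.loglik
    lr = 2.0 * (fit.loglik - ll0)
    lr = max(lr, 0.0)
    p = float(chi2_dist.sf(lr, df)) if df > 0 else np.nan
    # Nagelkerke normalization uses the intercept-only likelihood
    lr_from_null = 2.0 * (fit.loglik - fit.loglik_null)
    denom = 1.0 - np.exp(2.0 * fit.loglik_null / fit.n)
    r2 = float((1.0 - np.exp(-lr_from_null / fit.n)) / denom) if denom > 0 else 0.0
    se = fit.se_beta()
    wald = (fit.betas / se) ** 2
    zc = norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "predictor": fit.beta_names,
            "beta": fit.betas,
            "se": se,
            "aOR": np.exp(fit.betas),
            "aOR_low": np.exp(fit.betas - zc * se),
            "aOR_high": np.exp(fit.betas + zc * se),
            "wald_chi2": wald,
            "p": chi2_dist.sf(wald, 1),
        }
    )
    return ModelFitStats(
        lr_chi2=float(lr), df=int(df), p=p, nagelkerke_r2=r2,
        coef_table=table,
    )


def best_subset_bic(y, base: pd.DataFrame, candidates: pd.DataFrame) -> ModelSelection:
    """Exhaustive best-subset search over candidate predictors by BIC.

    Base predictors are forced into every model.  BIC weights
    w_m = exp(-Delta BIC_m / 2) / sum exp(-Delta BIC / 2) approximate
    posterior model probabilities; a predictor's inclusion probability is
    the summed weight of models containing it.
    """
    cand_names = list(candidates.columns)
    if not cand_names:
        raise ValueError("candidate set is empty")
    rows, fits = [], []
    for r in range(len(cand_names) + 1):
        for subset in combinations(cand_names, r):
            Xm = pd.concat([base, candidates[list(subset)]], axis=1)
            try:
                fit = fit_cpm(y, Xm)
            except (ValueError, ConvergenceError) as exc:  # pragma: no cover
                import warnings

                warnings.warn(
                    f"subset {subset} excluded: {exc}", RuntimeWarning
                )
                continue
            rows.append({"subset": subset, "bic": fit.bic(), "loglik": fit.loglik})
            fits.append(fit)
    table = pd.DataFrame(rows)
    dbic = table["bic"] - table["bic"].min()
    w = np.exp(-0.5 * dbic)
    table["bic_weight"] = w / w.sum()
    best_id = int(table["bic_weight"].idxmax())
    table["evidence_ratio"] = (
        table.loc[best_id, "bic_weight"] / table["bic_weight"]
    )
    inclusion = {
        name: float(
            table.loc[
                table["subset"].apply(lambda s: name in s), "bic_weight"
            ].sum()
        )
        for name in cand_names
    }
    return ModelSelection(
        table=table, inclusion_probs=inclusion, best_id=best_id, fits=fits
    )


@dataclass
class HierarchicalResult:
    step1: CPMFit
    step2: CPMFit
    step3: CPMFit
    selection: ModelSelection
    stats: dict                    # per step ModelFitStats + between-step LRs


def hierarchical_models(
    y,
    data: pd.DataFrame,
    baseline: list,
    candidates: list,
    gmd_column: str,
) -> HierarchicalResult:
    """Three-step hierarchical CPM fit.

    Step 1 regresses the threshold on the baseline covariates; step 2 adds
    the BIC-best subset of the candidate predictors; step 3 appends the
    modality's GMD to quantify how much intra-individual trial variability
    explains, reported as the between-step LR tests and Delta R^2.
    """
    missing = [c for c in [*baseline, *candidates, gmd_column] if c not in data]
    if missing:
        raise KeyError(f"missing required columns: {missing}")

    def _drop_degenerate(cols):
        kept = []
        for c in cols:
            if np.std(data[c].to_numpy(dtype=float)) < 1e-12:
                import warnings

                warnings.warn(
                    f"predictor {c!r} is constant and was dropped",
                    RuntimeWarning,
                )
            else:
                kept.append(c)
        return kept

    baseline = _drop_degenerate(baseline)
    candidates = _drop_degenerate(candidates)
    base = data[baseline].astype(float)
    cand = data[candidates].astype(float)
    step1 = fit_cpm(y, base)
    selection = best_subset_bic(y, base, cand)
    chosen = list(selection.table.loc[selection.best_id, "subset"])
    X2 = pd.concat([base, cand[chosen]], axis=1)
    step2 = fit_cpm(y, X2)
    X3 = X2.copy()
    if _drop_degenerate([gmd_column]):
        X3[gmd_column] = data[gmd_column].astype(float)
    step3 = fit_cpm(y, X3)
    s1 = model_inference(step1)
    s2 = model_inference(step2)
    s3 = model_inference(step3)
    stats = {
        "step1": s1,
        "step2": s2,
        "step3": s3,
        "lr_step2_vs_step1": model_inference(step2, step1),
        "lr_step3_vs_step2": model_inference(step3, step2),
        "delta_r2_step2": s2.nagelkerke_r2 - s1.nagelkerke_r2,
        "delta_r2_step3": s3.nagelkerke_r2 - s2.nagelkerke_r2,
        "chosen_subset": chosen,
    }
    return HierarchicalResult(
        step1=step1, step2=step2, step3=step3,
        selection=selection, stats=stats,
    )
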