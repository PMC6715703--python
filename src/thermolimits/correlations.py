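"""Spearman rank-correlation inference and equivalence testing.

Rank correlations are tested with a Z-transformation whose standard error
follows the Caruso-Cliff / Bonett-Wright family, sqrt((1 + r^2/2)/(n - 3))
on the atanh scale.  Equivalence against +/-bound uses TOST on the same
scale, power is estimated by Monte Carlo from uncorrelated bivariate
normals, and differences between correlations get Zou's back-transformed
confidence intervals (independent and dependent-overlapping cases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .effect_sizes import PowerResult

__all__ = [
    "SpearmanResult",
    "CorrDiffResult",
    "spearman",
    "spearman_test",
    "corr_tost",
    "mc_power_corr",
    "zou_diff_independent",
    "zou_diff_dependent",
]


@dataclass(frozen=True)
class SpearmanResult:
    r_s: float
    n: int
    z: float
    se: float
    p_two_sided: float
    p_equiv: float
    bound: float


@dataclass(frozen=True)
class CorrDiffResult:
    diff: float
    ci_low: float
    ci_high: float
    kind: str
    conf: float
    inputs: dict


def spearman(x, y) -> float:
    """Spearman correlation: Pearson correlation of midranks."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("x and y must be paired")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values in input")
    rx = rankdata(xa)
    ry = rankdata(ya)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((rx * ry).sum() / denom)


def _caruso_cliff_se(r: float, n: int, variant: str = "rank") -> float:
    if variant == "rank":        # Caruso-Cliff / Bonett-Wright family
        return float(np.sqrt((1.0 + r**2 / 2.0) / (n - 3)))
    if variant == "fieller":     # classical 1.06/(n-3) alternative
        return float(np.sqrt(1.06 / (n - 3)))
    raise ValueError("variant must be 'rank' or 'fieller'")


def spearman_test(r_s: float, n: int, variant: str = "rank"):
    """Z-test of rho = 0 on the atanh scale.

    Returns ``(z, p_two_sided)``; |r_s| = 1 yields infinite z with p = 0.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= r_s <= 1.0:
        raise ValueError("r_s outside [-1, 1]")
    se = _caruso_cliff_se(r_s, n, variant)
    if abs(r_s) == 1.0:
        return float(np.sign(r_s) * np.inf), 0.0
    z = np.arctanh(r_s) / se
    return float(z), float(2 * norm.sf(abs(z)))


def corr_tost(
    r_s: float,
    n: int,
    bound: float = 0.30,
    alpha: float = 0.05,
    variant: str = "rank",
) -> SpearmanResult:
    """TOST equivalence test of |rho| >= bound on the atanh scale."""
    if not 0.0 < bound < 1.0:
        raise ValueError("equivalence bound must be in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    se = _caruso_cliff_se(r_s, n, variant)
    if abs(r_s) == 1.0:
        z, p = float(np.sign(r_s) * np.inf), 0.0
        p_equiv = 1.0
    else:
        zr = np.arctanh(r_s)
        zb = np.arctanh(bound)
        z = zr / se
        p = float(2 * norm.sf(abs(z)))
        p_upper = float(norm.cdf((zr - zb) / se))   # H0: rho >= +bound
        p_lower = float(norm.sf((zr + zb) / se))    # H0: rho <= -bound
        p_equiv = max(p_upper, p_lower)
    return SpearmanResult(
        r_s=float(r_s), n=n, z=z, se=se, p_two_sided=p,
        p_equiv=p_equiv, bound=bound,
    )


def mc_power_corr(
    n: int,
    true_rho: float = 0.0,
    bound: float = 0.30,
    alpha: float = 0.05,
    B: int = 10_000,
    seed: int | None = None,
    chunk: int = 5000,
) -> PowerResult:
    """Monte-Carlo power of the Spearman TOST under bivariate normal data.

    Each replicate draws n pairs from a bivariate normal with correlation
    ``true_rho``, computes the Spearman coefficient, and applies the TOST.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if n < 5:
        raise ValueError("need n >= 5")
    if not -1.0 < true_rho < 1.0:
        raise ValueError("true_rho must be inside (-1, 1)")
    if not 0.0 < bound < 1.0:
        raise ValueError("equivalence bound must be in (0, 1)")
    rng = np.random.default_rng(seed)
    zb = np.arctanh(bound)
    hits = 0
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        x = rng.standard_normal((b, n))
        e = rng.standard_normal((b, n))
        y = true_rho * x + np.sqrt(1 - true_rho**2) * e
        rx = rankdata(x, axis=1)
        ry = rankdata(y, axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        r = (rx * ry).sum(axis=1) / np.sqrt(
            (rx**2).sum(axis=1) * (ry**2).sum(axis=1)
        )
        se = np.sqrt((1.0 + r**2 / 2.0) / (n - 3))
        zr = np.arctanh(r)
        p_upper = norm.cdf((zr - zb) / se)
        p_lower = norm.sf((zr + zb) / se)
        hits += int(np.sum(np.maximum(p_upper, p_lower) < alpha))
    power = hits / B
    return PowerResult(
        power=power, B=B, mc_se=float(np.sqrt(power * (1 - power) / B)),
        n1=n, n2=None, true_effect=true_rho, bound=bound, alpha=alpha,
        seed=-1 if seed is None else int(seed),
    )


def _fisher_ci(r: float, n: int, conf: float):
    zc = norm.ppf(1 - (1 - conf) / 2)
    zr = np.arctanh(r)
    h = zc / np.sqrt(n - 3)
    return float(np.tanh(zr - h)), float(np.tanh(zr + h))


def zou_diff_independent(
    r1: float, n1: int, r2: float, n2: int, conf: float = 0.95
) -> CorrDiffResult:
    """Zou's CI for the difference of two independent correlations."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must be inside (-1, 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each sample")
    l1, u1 = _fisher_ci(r1, n1, conf)
    l2, u2 = _fisher_ci(r2, n2, conf)
    diff = r1 - r2
    low = diff - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    high = diff + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return CorrDiffResult(
        diff=float(diff), ci_low=float(low), ci_high=float(high),
        kind="independent", conf=conf,
        inputs={"r1": r1, "n1": n1, "r2": r2, "n2": n2},
    )


def _corr_between_overlapping(r_jk, r_jh, r_kh):
    # correlation between the estimates r_jk and r_jh sharing variable j
    num = (r_kh - 0.5 * r_jk * r_jh) * (
        1 - r_jk**2 - r_jh**2 - r_kh**2
    ) + r_kh**3
    den = (1 - r_jk**2) * (1 - r_jh**2)
    return num / den


def zou_diff_dependent(
    r_jk: float, r_jh: float, r_kh: float, n: int, conf: float = 0.95
) -> CorrDiffResult:
    """Zou's CI for the difference of two dependent overlapping correlations.

    ``r_jk`` and ``r_jh`` share variable j; ``r_kh`` correlates the two
    non-shared variables.  The triple must form a valid (PSD) correlation
    matrix.
    """
    mat = np.array(
        [[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]]
    )
    if np.min(np.linalg.eigvalsh(mat)) < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    if abs(r_jk) >= 1.0 or abs(r_jh) >= 1.0:
        raise ValueError("correlations must be inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    c = _corr_between_overlapping(r_jk, r_jh, r_kh)
    l1, u1 = _fisher_ci(r_jk, n, conf)
    l2, u2 = _fisher_ci(r_jh, n, conf)
    diff = r_jk - r_jh
    low = diff - np.sqrt(
        (r_jk - l1) ** 2 + (u2 - r_jh) ** 2
        - 2 * c * (r_jk - l1) * (u2 - r_jh)
    )
    high = diff + np.sqrt(
        (u1 - r_jk) ** 2 + (r_jh - l2) ** 2
        - 2 * c * (u1 - r_jk) * (r_jh - l2)
    )
    return CorrDiffResult(
        diff=float(diff), ci_low=float(low), ci_high=float(high),
        kind="dependent_overlapping", conf=conf,
        inputs={"r_jk": r_jk, "r_jh": r_jh, "r_kh": r_kh, "n": n},
    )


def correlation_matrix(
    df, columns=None, bound: float = 0.30, alpha: float = 0.05
):
    """Pairwise Spearman matrix with p and p_equiv per pair.

    Returns a long-format DataFrame (var1, var2, n, r_s, p, p_equiv) over
    complete pairs; pairs with fewer than 4 complete observations are
    skipped.
    """
    import pandas as pd

    cols = list(columns) if columns is not None else list(df.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = df[[a, b]].dropna()
            if len(sub) < 4:
                continue
            r = spearman(sub[a], sub[b])
            res = corr_tost(r, len(sub), bound=bound, alpha=alpha)
            rows.append(
                {
                    "var1": a, "var2": b, "n": len(sub), "r_s": r,
                    "p": res.p_two_sided, "p_equiv": res.p_equiv,
                }
            )
    return pd.DataFrame(rows)
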