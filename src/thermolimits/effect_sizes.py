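"""Cliff's delta inference, TOST equivalence tests, and Monte-Carlo power.

Cliff's delta is P(X > Y) - P(X < Y) for independent draws from two groups,
estimated by the mean of the dominance matrix d_ij = sign(x_i - y_j).  The
sampling variance uses Cliff's consistent estimator built from between-row,
between-column, and within-cell dominance variability.  Confidence intervals
and the two one-sided equivalence tests (TOST) use Cliff's asymmetric
bounded transformation, which keeps intervals inside [-1, 1] and respects
the statistic's skewed sampling distribution near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats import norm

__all__ = [
    "DeltaResult",
    "EquivalenceResult",
    "PowerResult",
    "ContingencyResult",
    "cliffs_delta",
    "delta_tost",
    "mc_power_delta",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "delta_to_normal_shift",
]


@dataclass(frozen=True)
class DeltaResult:
    delta: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    row_means: np.ndarray
    col_means: np.ndarray

    def to_dict(self) -> dict:
        return {
            "delta": self.delta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_level": self.ci_level, "z": self.z,
            "p_two_sided": self.p_two_sided, "n1": self.n1, "n2": self.n2,
        }


@dataclass(frozen=True)
class EquivalenceResult:
    bound: float
    alpha: float
    p_lower: float
    p_upper: float
    p_equiv: float
    equivalent: bool
    delta: float
    se: float

    def to_dict(self) -> dict:
        return {
            "bound": self.bound, "alpha": self.alpha,
            "p_lower": self.p_lower, "p_upper": self.p_upper,
            "p_equiv": self.p_equiv, "equivalent": self.equivalent,
            "delta": self.delta, "se": self.se,
        }


@dataclass(frozen=True)
class PowerResult:
    power: float
    B: int
    mc_se: float
    n1: int
    n2: int | None
    true_effect: float
    bound: float
    alpha: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "power": self.power, "B": self.B, "mc_se": self.mc_se,
            "n1": self.n1, "n2": self.n2, "true_effect": self.true_effect,
            "bound": self.bound, "alpha": self.alpha, "seed": self.seed,
        }


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    phi: float


def delta_to_normal_shift(delta: float, sigma: float = 1.0) -> float:
    """Mean shift between homoskedastic normals yielding population delta.

    Under normality, delta = 2 Phi(shift / (sigma sqrt(2))) - 1, so
    shift = sqrt(2) * Phi^-1((delta + 1) / 2) * sigma.
    """
    if not -1.0 < delta < 1.0:
        raise ValueError("population delta must be inside (-1, 1)")
    return float(np.sqrt(2.0) * norm.ppf((delta + 1.0) / 2.0) * sigma)


def _dominance_stats(x: np.ndarray, y: np.ndarray):
    """delta-hat, consistent variance, row and column dominance means.

    x, y have shape (B, n1) and (B, n2); broadcasting over the leading axis
    serves the Monte-Carlo power loop.
    """
    n1, n2 = x.shape[-1], y.shape[-1]
    d = np.sign(x[..., :, None] - y[..., None, :])
    delta = d.mean(axis=(-1, -2))
    di = d.mean(axis=-1)
    dj = d.mean(axis=-2)
    dd = delta[..., None]
    sdi2 = ((di - dd) ** 2).sum(axis=-1)
    sdj2 = ((dj - dd) ** 2).sum(axis=-1)
    sdij2 = ((d - delta[..., None, None]) ** 2).sum(axis=(-1, -2))
    # Cliff's consistent estimator (component form), floored at the minimum
    # positive value (1 - delta^2) / (n1 n2 - 1) recommended for |delta| -> 1.
    var = (
        sdi2 / (n1 * (n1 - 1))
        + sdj2 / (n2 * (n2 - 1))
        + sdij2 / (n1 * n2 * (n1 - 1) * (n2 - 1))
    )
    var = np.maximum(var, (1.0 - delta**2) / (n1 * n2 - 1))
    return delta, var, di, dj


def _transform_endpoint(delta, s, z):
    """Cliff's asymmetric bounded CI endpoint at normal deviate z.

    Monotone increasing in z, maps z -> (-1, 1); at z = 0 returns delta.
    """
    c = 1.0 - delta**2
    t = z * s
    return (delta * c + t * np.sqrt(c * c + t * t)) / (c + t * t)


def _shrink_boundary(delta: float, n1: int, n2: int) -> float:
    # complete dominance: Cliff's convention, back |delta| off to
    # (n1 n2 - 1)/(n1 n2) so the bounded CI is defined
    nn = n1 * n2
    if abs(delta) == 1.0:
        return np.sign(delta) * (nn - 1) / nn
    return delta


def cliffs_delta(x, y, ci_level: float = 0.90) -> DeltaResult:
    """Cliff's delta with consistent SE, bounded CI, and a two-sided test.

    Ties contribute d_ij = 0.  The two-sided p-value is the normal test of
    delta = 0 using z = delta / se; the CI uses the asymmetric bounded
    transformation.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values in input")
    n1, n2 = xa.size, ya.size
    delta, var, di, dj = _dominance_stats(xa[None, :], ya[None, :])
    delta = float(delta[0])
    se = float(np.sqrt(var[0]))
    d_ci = _shrink_boundary(delta, n1, n2)
    s_ci = se if se > 0 else np.sqrt((1 - d_ci**2) / (n1 * n2 - 1))
    zc = norm.ppf(1 - (1 - ci_level) / 2)
    ci_low = float(_transform_endpoint(d_ci, s_ci, -zc))
    ci_high = float(_transform_endpoint(d_ci, s_ci, zc))
    z = delta / se if se > 0 else np.inf * np.sign(delta)
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return DeltaResult(
        delta=delta, se=se, ci_low=ci_low, ci_high=ci_high,
        ci_level=ci_level, z=float(z), p_two_sided=p, n1=n1, n2=n2,
        row_means=di[0], col_means=dj[0],
    )


def _one_sided_p(delta: float, s: float, target: float, side: str) -> float:
    """One-sided p on the bounded-transform scale.

    Solves for the normal deviate z* at which Cliff's CI endpoint equals the
    target delta; by test/CI duality this yields the one-sided p-value of
    H0: delta >= target (side='upper') or H0: delta <= target (side='lower').
    """
    f = lambda z: _transform_endpoint(delta, s, z) - target
    lo, hi = -40.0, 40.0
    if f(lo) > 0:       # even the far-left endpoint exceeds target
        zstar = lo
    elif f(hi) < 0:
        zstar = hi
    else:
        zstar = optimize.brentq(f, lo, hi, xtol=1e-12)
    if side == "upper":
        return float(norm.sf(zstar))
    return float(norm.cdf(zstar))


def delta_tost(
    x, y, bound: float = 0.33, alpha: float = 0.05, method: str = "transform"
) -> EquivalenceResult:
    """Two one-sided tests of |delta| >= bound against |delta| < bound.

    ``method='transform'`` (default) performs the one-sided tests on Cliff's
    bounded asymmetric scale, so rejection at level alpha coincides exactly
    with the 1-2*alpha bounded CI lying inside (-bound, bound).
    ``method='delta'`` is the plain normal approximation on the delta scale.
    """
    if not 0.0 < bound < 1.0:
        raise ValueError("equivalence bound must be in (0, 1)")
    res = cliffs_delta(x, y, ci_level=1 - 2 * alpha)
    d = _shrink_boundary(res.delta, res.n1, res.n2)
    s = res.se if res.se > 0 else np.sqrt(
        (1 - d**2) / (res.n1 * res.n2 - 1)
    )
    if method == "transform":
        p_upper = _one_sided_p(d, s, bound, "upper")
        p_lower = _one_sided_p(d, s, -bound, "lower")
    elif method == "delta":
        p_upper = float(norm.cdf((res.delta - bound) / s))
        p_lower = float(norm.sf((res.delta + bound) / s))
    else:
        raise ValueError("method must be 'transform' or 'delta'")
    p_equiv = max(p_lower, p_upper)
    return EquivalenceResult(
        bound=bound, alpha=alpha, p_lower=p_lower, p_upper=p_upper,
        p_equiv=p_equiv, equivalent=bool(p_equiv < alpha),
        delta=res.delta, se=res.se,
    )


def mc_power_delta(
    n1: int,
    n2: int,
    true_delta: float = 0.0,
    bound: float = 0.33,
    alpha: float = 0.05,
    B: int = 10_000,
    seed: int | None = None,
    chunk: int = 2000,
) -> PowerResult:
    """Monte-Carlo power of the delta TOST under homoskedastic normal data.

    Each replicate draws n1 and n2 standard-normal observations whose means
    differ by the shift that induces the population ``true_delta``,
    re-estimates delta and its SE, and applies the TOST at ``alpha``.
    Power is the fraction of the B replicates declaring equivalence.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0.0 < bound < 1.0:
        raise ValueError("equivalence bound must be in (0, 1)")
    shift = delta_to_normal_shift(true_delta)
    rng = np.random.default_rng(seed)
    zc = norm.ppf(1 - alpha)
    nn = n1 * n2
    hits = 0
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        x = rng.standard_normal((b, n1)) + shift
        y = rng.standard_normal((b, n2))
        delta, var, _, _ = _dominance_stats(x, y)
        delta = np.where(
            np.abs(delta) == 1.0, np.sign(delta) * (nn - 1) / nn, delta
        )
        s = np.sqrt(var)
        lo = _transform_endpoint(delta, s, -zc)
        hi = _transform_endpoint(delta, s, zc)
        hits += int(np.sum((lo > -bound) & (hi < bound)))
    power = hits / B
    return PowerResult(
        power=power, B=B, mc_se=float(np.sqrt(power * (1 - power) / B)),
        n1=n1, n2=n2, true_effect=true_delta, bound=bound, alpha=alpha,
        seed=-1 if seed is None else int(seed),
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); phi = sqrt(chi2 / N).
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("table has a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(np.array(margins, dtype=float))
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(
        chi2=float(chi2), df=1, p=p, phi=float(np.sqrt(chi2 / n))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration)."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
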