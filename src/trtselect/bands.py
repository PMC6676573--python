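"""Confidence bands for theta(x) and delta-method root intervals.

Pointwise band
    theta_hat(x) ± t_{df, 1−gamma/2} · se(x) at every x; controls coverage
    separately at each marker value.

Simultaneous band
    theta_hat(x) ± c · se(x) with a single critical value c calibrated so
    that the whole function theta(·) is covered on the marker domain with
    probability 1−gamma.  c is computed by the sup-t method: the band
    deviation process is a(x)'Z / sqrt(a(x)' Sigma a(x)) with
    Z ~ N(0, Sigma), whose supremum over a grid of the domain is simulated
    from a large fixed set of Gaussian draws; c is the level-quantile of
    the simulated suprema.  This is exact up to Monte Carlo and grid error
    for any design, and is bracketed by the pointwise t quantile (below)
    and the Scheffé bound sqrt(d · F_{d, df; level}) (above).

Root confidence intervals
    theta_hat is a polynomial of degree <= 2, so its roots are closed
    form.  A first-order delta-method interval root ± z_{1−gamma/2}·SE is
    attached to each root, with the gradient of the root with respect to
    the coefficients g given by  d r/d g_k = −r^k / theta_hat'(r).  When
    the derivative vanishes at a root the interval is undefined and a
    :class:`DegenerateRootError` is raised; callers treat the interval as
    the whole domain (maximally conservative).

A pointwise band can also be read horizontally: the x-values at which a
threshold line lies inside the band form a confidence set for the
preimage of the threshold under theta.  That set is computed exactly as a
polynomial sign set (squaring the band condition removes the square
root).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import stats

from .sets import DOMAIN, SelectionSet, polynomial_nonneg_set

#: Fixed sub-seed for the shared sup-t Gaussian draws (deterministic
#: critical values independent of the simulation's own random stream).
SUPT_SEED = 186283
SUPT_DRAWS = 100_000
SUPT_GRID = 201

_draw_cache: dict[tuple[int, int, int], np.ndarray] = {}


class DegenerateRootError(ValueError):
    """theta_hat'(r) = 0 at a root: delta-method interval undefined."""


@dataclass(frozen=True)
class ConfidenceBand:
    """A symmetric band theta_hat(x) ± critical_value · se(x)."""

    results: object  # TreatmentEffectResults
    kind: str  # "pointwise" | "simultaneous"
    level: float
    critical_value: float

    def lower(self, x):
        est, se = self.results.predict_effect(x)
        return est - self.critical_value * se

    def upper(self, x):
        est, se = self.results.predict_effect(x)
        return est + self.critical_value * se

    def evaluate(self, x):
        """(estimate, lower, upper) on a grid, for plotting/export."""
        est, se = self.results.predict_effect(x)
        h = self.critical_value * se
        return est, est - h, est + h


def pointwise_band(results, level: float = 0.95) -> ConfidenceBand:
    """Pointwise t-band at confidence level ``level`` (= 1−gamma)."""
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    c = float(stats.t.ppf(0.5 + level / 2.0, results.df_resid))
    return ConfidenceBand(results, "pointwise", level, c)


def _standard_draws(d: int, draws: int, seed: int) -> np.ndarray:
    key = (d, draws, seed)
    if key not in _draw_cache:
        rng = np.random.default_rng(seed)
        _draw_cache[key] = rng.standard_normal((draws, d)).astype(np.float32)
    return _draw_cache[key]


def simultaneous_critical_value(
    results,
    level: float = 0.95,
    domain: tuple[float, float] = DOMAIN,
    draws: int = SUPT_DRAWS,
    grid_size: int = SUPT_GRID,
    seed: int = SUPT_SEED,
) -> float:
    """Sup-t critical value for a simultaneous band over ``domain``.

    Simulates sup_x |a(x)'Z| / sqrt(a(x)' Sigma a(x)), Z ~ N(0, Sigma),
    on a ``grid_size``-point grid and returns the ``level`` quantile of
    the suprema.  The Gaussian draws are generated once from a fixed
    sub-seed and shared across calls with the same dimension, so critical
    values are deterministic and replicate-to-replicate differences
    reflect only the fitted covariance.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    Sigma = np.asarray(results.effect_cov, dtype=float)
    d = Sigma.shape[0]
    grid = np.linspace(domain[0], domain[1], grid_size)
    A = np.stack([grid**k for k in range(d)], axis=-1)  # (m, d)
    L = np.linalg.cholesky(Sigma + 1e-14 * np.trace(Sigma) * np.eye(d))
    B = A @ L  # a(x)'Z = (A L) u with u ~ N(0, I)
    norms = np.linalg.norm(B, axis=1)
    G = (B / norms[:, None]).astype(np.float32)  # unit directions, (m, d)
    U = _standard_draws(d, draws, seed)  # (draws, d)
    S = U @ G.T  # (draws, m)
    np.abs(S, out=S)
    sups = S.max(axis=1)
    return float(np.quantile(sups.astype(np.float64), level))


def simultaneous_band(
    results,
    level: float = 0.95,
    domain: tuple[float, float] = DOMAIN,
    draws: int = SUPT_DRAWS,
    grid_size: int = SUPT_GRID,
    seed: int = SUPT_SEED,
) -> ConfidenceBand:
    """Simultaneous sup-t band at confidence level ``level``."""
    c = simultaneous_critical_value(
        results, level, domain, draws=draws, grid_size=grid_size, seed=seed
    )
    return ConfidenceBand(results, "simultaneous", level, c)


def scheffe_bound(results, level: float = 0.95) -> float:
    """Scheffé upper bound sqrt(d · F_{d, df; level}) for the sup-t value."""
    d = len(results.effect_coefs)
    return float(np.sqrt(d * stats.f.ppf(level, d, results.df_resid)))


@dataclass(frozen=True)
class RootCI:
    """A root of theta_hat with its delta-method confidence interval."""

    root: float
    se: float
    lower: float
    upper: float

    def as_set(self) -> SelectionSet:
        return SelectionSet(((self.lower, self.upper),))


def effect_roots(coefs: np.ndarray) -> list[float]:
    """Real roots of the degree-<=2 polynomial g0 + g1 x (+ g2 x²).

    Closed-form; a double root (discriminant 0) is reported once.  The
    identically-zero polynomial has no isolated roots and returns [].
    """
    g = np.asarray(coefs, dtype=float)
    scale = np.max(np.abs(g)) or 1.0
    tiny = 1e-13 * scale
    if len(g) == 3 and abs(g[2]) > tiny:
        disc = g[1] ** 2 - 4.0 * g[2] * g[0]
        if disc < 0:
            return []
        sq = float(np.sqrt(disc))
        r1 = (-g[1] - sq) / (2 * g[2])
        r2 = (-g[1] + sq) / (2 * g[2])
        return [r1] if sq <= tiny else sorted((r1, r2))
    if abs(g[1]) > tiny:
        return [-g[0] / g[1]]
    return []  # constant (possibly zero) effect: no isolated root


def _root_gradient(r: float, g: np.ndarray) -> np.ndarray:
    """d r / d g_k = −r^k / theta_hat'(r) for the degree-<=2 polynomial."""
    deriv = g[1] + (2.0 * g[2] * r if len(g) == 3 else 0.0)
    scale = np.max(np.abs(g)) or 1.0
    if abs(deriv) <= 1e-12 * scale:
        raise DegenerateRootError(f"theta_hat'(r) = 0 at root r = {r:.6g}")
    powers = np.array([r**k for k in range(len(g))])
    return -powers / deriv


def root_cis_delta(
    results, level: float = 0.95, domain: tuple[float, float] = DOMAIN
) -> list[RootCI]:
    """Delta-method confidence intervals for the roots of theta_hat.

    Roots outside ``domain`` are dropped; intervals use normal quantiles
    and are clipped to the domain.  No real roots -> empty list.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    g = np.asarray(results.effect_coefs, dtype=float)
    if np.max(np.abs(g)) == 0.0:
        # theta_hat identically zero: every x is a root
        raise DegenerateRootError("estimated effect is identically zero")
    Sigma = np.asarray(results.effect_cov, dtype=float)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    out = []
    for r in effect_roots(g):
        if not domain[0] <= r <= domain[1]:
            continue
        grad = _root_gradient(r, g)
        se = float(np.sqrt(max(grad @ Sigma @ grad, 0.0)))
        lo = max(domain[0], r - z * se)
        hi = min(domain[1], r + z * se)
        out.append(RootCI(root=float(r), se=se, lower=lo, upper=hi))
    return out


def band_sign_polynomial(band: ConfidenceBand, threshold: float = 0.0) -> np.ndarray:
    """Ascending coefficients of q(x) = (theta_hat(x) − threshold)² −
    c² · a(x)' Sigma a(x).

    q < 0 exactly where the horizontal line at ``threshold`` lies strictly
    inside the band; the zeros of the band's lower (or upper) bound are
    zeros of q.  Degree <= 4.
    """
    res = band.results
    g = np.asarray(res.effect_coefs, dtype=float).copy()
    g[0] -= threshold
    Sigma = np.asarray(res.effect_cov, dtype=float)
    d = len(g)
    est_sq = P.polymul(g, g)
    var_poly = np.zeros(2 * d - 1)
    for i in range(d):
        for j in range(d):
            var_poly[i + j] += Sigma[i, j]
    q = np.zeros(2 * d - 1)
    q[: len(est_sq)] += est_sq
    q -= band.critical_value**2 * var_poly
    return q


def invert_band_horizontally(
    band: ConfidenceBand,
    threshold: float = 0.0,
    domain: tuple[float, float] = DOMAIN,
) -> SelectionSet:
    """{x : lower(x) <= threshold <= upper(x)} as an interval union.

    Reading a level-(1−gamma) pointwise band horizontally gives a
    level-(1−gamma) confidence set for theta^{-1}(threshold).
    """
    q = -band_sign_polynomial(band, threshold)  # q >= 0 inside the band

    def inside(x: float) -> float:
        return float(
            band.critical_value * band.results.predict_effect(x)[1]
            - abs(band.results.predict_effect(x)[0] - threshold)
        )

    return polynomial_nonneg_set(q, domain, refine=inside)
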