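"""True worlds for the treatment-selection simulation and their RCT data.

A :class:`Scenario` is a fully specified data-generating process for a
two-arm randomized trial with a continuous biomarker X on [0, 1]:

* a treatment-effect function ``theta(x)`` — the difference in expected
  outcome between the new and the standard treatment at marker value x —
  of linear, concave or convex shape, scaled by a steepness parameter
  ``beta`` (since the error SD is 1, theta is on an effect-size scale);
* a marker distribution, uniform on [0, 1] or triangular T(0, 1, 1/3);
* a normal error model  Y = alpha(X) + theta(X)·T + eps,  eps ~ N(0, 1),
  with treatment T ~ Bernoulli(1/2) and alpha ≡ 0 by default (estimates
  of theta from a correctly specified analysis model are invariant under
  Y' = Y + a(X), so the prognostic part can be set to zero without loss).

The four standard scenarios are the (shape, distribution) pairs

=========  =========  ====================  =========================
scenario   shape      theta(x)              marker distribution
=========  =========  ====================  =========================
1          linear     beta·(x − 0.5)        uniform on [0, 1]
2          linear     beta·(x − 0.5)        triangular T(0, 1, 1/3)
3          concave    beta·(0.3 − 0.9(x−1)²)  uniform on [0, 1]
4          convex     beta·(−0.3 + 0.9x²)   uniform on [0, 1]
=========  =========  ====================  =========================

Markers are confined to a bounded interval because the simultaneous
confidence-band theory used downstream applies only there.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sets import DOMAIN, SelectionSet, polynomial_nonneg_set

SHAPES = ("linear", "concave", "convex")
MARKER_DISTS = ("uniform", "triangular")

#: (shape, marker_dist) pairs of the four standard scenarios, by id.
SCENARIO_TABLE: dict[int, tuple[str, str]] = {
    1: ("linear", "uniform"),
    2: ("linear", "triangular"),
    3: ("concave", "uniform"),
    4: ("convex", "uniform"),
}

@lru_cache(maxsize=None)
def _marker_rv(marker_dist: str):
    """Frozen marker distribution (freezing is costly; cache it)."""
    if marker_dist == "uniform":
        return stats.uniform(0.0, 1.0)
    return stats.triang(c=1.0 / 3.0, loc=0.0, scale=1.0)


# theta(x)/beta as ascending polynomial coefficients
_SHAPE_POLY: dict[str, tuple[float, ...]] = {
    "linear": (-0.5, 1.0),
    "concave": (-0.6, 1.8, -0.9),  # 0.3 - 0.9(x-1)^2 expanded
    "convex": (-0.3, 0.0, 0.9),
}


@dataclass(frozen=True)
class TrialData:
    """One simulated RCT: (marker, arm, outcome) triples."""

    marker: np.ndarray
    arm: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.marker, dtype=float)
        a = np.asarray(self.arm)
        y = np.asarray(self.outcome, dtype=float)
        if not (len(m) == len(a) == len(y)):
            raise ValueError("marker, arm and outcome must have equal length")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("arm must contain only 0/1")
        object.__setattr__(self, "marker", m)
        object.__setattr__(self, "arm", a.astype(int))
        object.__setattr__(self, "outcome", y)

    @property
    def n(self) -> int:
        return len(self.marker)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "arm": self.arm, "outcome": self.outcome}
        )


@dataclass(frozen=True)
class Scenario:
    """A true world: effect shape, steepness, marker law and noise.

    Parameters
    ----------
    shape : {"linear", "concave", "convex"}
        Shape of the treatment-effect function theta(x).
    beta : float
        Steepness scaling, >= 0.  theta scales linearly in beta.
    marker_dist : {"uniform", "triangular"}
        Marker law on [0, 1]; "triangular" is T(0, 1, 1/3).
    alpha : callable, optional
        Prognostic part alpha(x); identically 0 by default.
    error_sd : float
        Outcome noise SD.  The standard model fixes this to 1 (theta is
        then an effect size); it is settable for exact-recovery tests.
    """

    shape: str
    beta: float
    marker_dist: str = "uniform"
    alpha: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )
    error_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.marker_dist not in MARKER_DISTS:
            raise ValueError(f"unknown marker_dist {self.marker_dist!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.error_sd < 0:
            raise ValueError("error_sd must be >= 0")

    # -- treatment-effect function ------------------------------------
    @property
    def effect_poly(self) -> np.ndarray:
        """Ascending coefficients of theta(x) on [0, 1]."""
        return self.beta * np.asarray(_SHAPE_POLY[self.shape])

    def effect(self, x) -> np.ndarray | float:
        """theta(x); raises for x outside [0, 1]."""
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("marker value outside [0, 1]")
        val = np.polynomial.polynomial.polyval(x, self.effect_poly)
        return float(val) if val.ndim == 0 else val

    def positive_region(self) -> SelectionSet:
        """{x : theta(x) >= 0} — the oracle selection set.

        For beta = 0 theta is identically zero, which satisfies the
        closed inequality, so the whole domain is returned.
        """
        return polynomial_nonneg_set(self.effect_poly, DOMAIN)

    @property
    def correct_degree(self) -> int:
        """Polynomial degree of the correctly specified analysis model."""
        return 1 if self.shape == "linear" else 2

    # -- marker law ----------------------------------------------------
    @property
    def marker_rv(self):
        """Frozen scipy distribution of the marker."""
        return _marker_rv(self.marker_dist)

    def marker_density(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("marker value outside [0, 1]")
        val = self.marker_rv.pdf(x)
        return float(val) if np.ndim(x) == 0 else val

    def marker_cdf(self, x) -> np.ndarray | float:
        val = self.marker_rv.cdf(x)
        return float(val) if np.ndim(x) == 0 else val

    # -- sampling ------------------------------------------------------
    def sample_trial(self, n: int, rng: np.random.Generator) -> TrialData:
        """Draw one RCT of size ``n``.

        Markers are drawn by the inverse-CDF transform of a uniform
        stream (exact and reproducible), arms as Bernoulli(1/2), and the
        outcome as alpha(x) + theta(x)·t + error_sd·N(0, 1).  The random
        stream is consumed in the fixed order (marker, arm, noise), so
        changing ``alpha`` or ``error_sd`` leaves the realised marker,
        arm and noise values untouched.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        marker = self.marker_rv.ppf(rng.random(n))
        arm = (rng.random(n) < 0.5).astype(int)
        noise = rng.standard_normal(n)
        base = self.alpha(marker) if self.alpha is not None else 0.0
        outcome = base + self.effect(marker) * arm + self.error_sd * noise
        return TrialData(marker=marker, arm=arm, outcome=outcome)

    # -- convenience ---------------------------------------------------
    def with_(self, **changes) -> "Scenario":
        """A copy with the given fields replaced."""
        return replace(self, **changes)


def get_scenario(scenario_id: int, beta: float, **kwargs) -> Scenario:
    """The standard scenario with the given id (1-4) and steepness."""
    try:
        shape, dist = SCENARIO_TABLE[int(scenario_id)]
    except (KeyError, ValueError):
        raise ValueError(f"scenario id must be 1-4, got {scenario_id!r}") from None
    return Scenario(shape=shape, beta=beta, marker_dist=dist, **kwargs)


def scenario_from_config(source) -> Scenario:
    """Build a Scenario from a mapping or a YAML/key-value file.

    Recognised keys: ``scenario`` (id 1-4) or ``shape``/``marker_dist``,
    plus ``beta`` and optionally ``error_sd``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    cfg = dict(source)
    beta = float(cfg.pop("beta"))
    sid = cfg.pop("scenario", None)
    cfg.pop("n", None)  # sample size belongs to the study config
    if sid is not None:
        return get_scenario(int(sid), beta, **cfg)
    return Scenario(beta=beta, **cfg)
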