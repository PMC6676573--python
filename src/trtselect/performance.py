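"""Quality measures of a selection set against the true scenario.

For a future patient with marker X* distributed like the trial marker,
and a selection set C:

    sensitivity   P(X* in C | theta(X*) >= 0)
    specificity   P(X* not in C | theta(X*) < 0)
    overall gain  E[ theta(X*) · 1{X* in C} ]

The overall gain is the change in the population mean outcome when the
rule is applied to future patients; its benchmark is the maximal gain,
attained by the oracle set {x : theta(x) >= 0}.  All three are computed
by integration against the true marker density (closed-form CDF masses
for the probabilities, adaptive quadrature for the gain) rather than by
resampling future patients, which removes one layer of Monte Carlo
noise.

Conventions: an empty set has sensitivity 0, specificity 1 and gain 0.
At beta = 0 there are no patients with a negative effect, and
specificity is defined as 1 (nothing to misclassify).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import integrate

from .scenarios import Scenario
from .sets import DOMAIN, SelectionSet

logger = logging.getLogger(__name__)

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class PerformanceSummary:
    """Quality measures of one selection set under one true scenario."""

    sensitivity: float
    specificity: float
    overall_gain: float
    nonempty: bool


def sensitivity(sel: SelectionSet, scenario: Scenario) -> float:
    """P(X* in C | theta(X*) >= 0)."""
    pos = scenario.positive_region()
    denom = pos.measure(scenario.marker_cdf)
    if denom <= _MASS_TOL:
        raise ValueError("positive-effect region has zero marker mass")
    num = sel.intersection(pos).measure(scenario.marker_cdf)
    return min(num / denom, 1.0)


def specificity(sel: SelectionSet, scenario: Scenario) -> float:
    """P(X* not in C | theta(X*) < 0); 1 when no-one has theta < 0."""
    neg = scenario.positive_region().complement(DOMAIN)
    denom = neg.measure(scenario.marker_cdf)
    if denom <= _MASS_TOL:
        logger.debug("no negative-effect mass (beta = 0?); specificity := 1")
        return 1.0
    num = sel.intersection(neg).measure(scenario.marker_cdf)
    return max(1.0 - num / denom, 0.0)


def overall_gain(
    sel: SelectionSet, scenario: Scenario, epsabs: float = 1e-9
) -> float:
    """E[theta(X*) 1{X* in C}] by adaptive quadrature over the set.

    Intervals are split at the triangular density's kink (x = 1/3) so
    the integrand is smooth on every quadrature cell.
    """
    kinks = (1.0 / 3.0,) if scenario.marker_dist == "triangular" else ()

    def integrand(x):
        return scenario.effect(x) * scenario.marker_density(x)

    total = 0.0
    for lo, hi in sel.intervals:
        cuts = [lo] + [k for k in kinks if lo < k < hi] + [hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a <= _MASS_TOL:
                continue
            val, _ = integrate.quad(integrand, a, b, epsabs=epsabs)
            total += val
    return total


def max_gain(scenario: Scenario) -> float:
    """The maximal possible overall gain, at the oracle set {theta >= 0}."""
    return overall_gain(scenario.positive_region(), scenario)


def evaluate(sel: SelectionSet, scenario: Scenario) -> PerformanceSummary:
    """All quality measures of one set; "nonempty" means positive measure
    (a measure-zero set selects no patients)."""
    nonempty = sel.measure() > _MASS_TOL
    if not nonempty:
        return PerformanceSummary(
            sensitivity=0.0, specificity=1.0, overall_gain=0.0, nonempty=False
        )
    return PerformanceSummary(
        sensitivity=sensitivity(sel, scenario),
        specificity=specificity(sel, scenario),
        overall_gain=overall_gain(sel, scenario),
        nonempty=True,
    )
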