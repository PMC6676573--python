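"""The four construction principles for treatment selection rules.

Given a fitted interaction model, each principle turns the estimated
treatment-effect function theta_hat into a set C of marker values at
which future patients are recommended the new treatment (threshold 0,
closed ">=" convention throughout):

    EST   C = {x : theta_hat(x) >= 0}
    POI   C = {x : lower bound of the pointwise band >= 0}
    SIM   C = {x : lower bound of the simultaneous band >= 0}
    CIR   C = {x : theta_hat(x) >= 0} minus the union of delta-method
              confidence intervals around the roots of theta_hat

EST ignores estimation uncertainty; POI/SIM/CIR trade sensitivity for
specificity by excising marker values where a zero treatment effect is
plausible.  By construction C_SIM ⊆ C_POI ⊆ C_EST and C_CIR ⊆ C_EST on
every fit.  All rules are gated by the interaction pretest: without a
significant interaction every set is empty.
"""

from __future__ import annotations

import logging

import numpy as np

from . import bands as _bands
from .bands import ConfidenceBand, DegenerateRootError, RootCI
from .sets import DOMAIN, SelectionSet, polynomial_nonneg_set

logger = logging.getLogger(__name__)

RULES = ("est", "poi", "sim", "cir")


def rule_est(results, domain: tuple[float, float] = DOMAIN) -> SelectionSet:
    """{x : theta_hat(x) >= 0} from the closed-form polynomial roots."""
    return polynomial_nonneg_set(results.effect_coefs, domain)


def rule_band(band: ConfidenceBand, domain: tuple[float, float] = DOMAIN) -> SelectionSet:
    """{x : lower(x) >= 0} for a pointwise or simultaneous band.

    Boundary points satisfy (theta_hat(x))² = c²·a(x)'Sigma a(x) with
    theta_hat(x) >= 0 — a polynomial equation of degree <= 4 solved by
    companion-matrix root finding, with sign classification (and Brent
    refinement of crossings) done on the actual lower-bound function so
    that spurious roots of the squared equation (zeros of the upper
    bound) are discarded.
    """
    q = _bands.band_sign_polynomial(band, 0.0)

    def lower(x: float) -> float:
        return float(band.lower(x))

    return polynomial_nonneg_set(q, domain, refine=lower)


def rule_cir(
    results,
    root_cis: list[RootCI],
    domain: tuple[float, float] = DOMAIN,
) -> SelectionSet:
    """EST set minus the union of root confidence intervals."""
    est = rule_est(results, domain)
    excised = SelectionSet([(ci.lower, ci.upper) for ci in root_cis])
    return est.difference(excised, domain)


def gate_by_pretest(sel: SelectionSet, significant: bool) -> SelectionSet:
    """Empty set unless the interaction pretest was significant."""
    return sel if significant else SelectionSet.empty()


def build_rules(
    results,
    level: float = 0.95,
    which: tuple[str, ...] = RULES,
    domain: tuple[float, float] = DOMAIN,
    band_kwargs: dict | None = None,
) -> dict[str, SelectionSet]:
    """Construct the requested selection sets from one fitted model.

    A degenerate root (vanishing derivative of theta_hat at a root) makes
    the delta-method interval undefined; CIR then excises the whole
    domain (maximally conservative) and the event is logged.
    """
    band_kwargs = band_kwargs or {}
    out: dict[str, SelectionSet] = {}
    for name in which:
        if name == "est":
            out[name] = rule_est(results, domain)
        elif name == "poi":
            out[name] = rule_band(_bands.pointwise_band(results, level), domain)
        elif name == "sim":
            out[name] = rule_band(
                _bands.simultaneous_band(results, level, domain=domain, **band_kwargs),
                domain,
            )
        elif name == "cir":
            try:
                cis = _bands.root_cis_delta(results, level, domain)
            except DegenerateRootError as exc:
                logger.warning("degenerate root, CIR set emptied: %s", exc)
                out[name] = SelectionSet.empty()
                continue
            out[name] = rule_cir(results, cis, domain)
        else:
            raise ValueError(f"unknown rule {name!r}")
    return out
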