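"""OLS treatment–marker interaction model and its Results object.

The analysis model for a trial (Y, X, T) is ordinary least squares on

    linear:     Y = a0 + a1·X           + T·(g0 + g1·X)           + eps
    quadratic:  Y = a0 + a1·X + a2·X²   + T·(g0 + g1·X + g2·X²)   + eps

so the estimated treatment-effect function is the polynomial
``theta_hat(x) = g0 + g1·x (+ g2·x²)`` built from the coefficients of the
treatment main effect and the treatment–marker interactions (the
"treatment block").  Everything downstream — pointwise and simultaneous
confidence bands, delta-method root intervals, the four selection rules —
is a functional of the treatment-block coefficient vector g, its
covariance submatrix, and the residual degrees of freedom, all carried by
:class:`TreatmentEffectResults`.

The interaction pretest is the F-test that the interaction coefficients
(g1, and g2 when quadratic) are jointly zero; a non-significant pretest
forces every selection rule to return the empty set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scenarios import TrialData
from .sets import DOMAIN


class SingularFitError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient (e.g. all markers equal)."""


def design_matrix(marker: np.ndarray, arm: np.ndarray, degree: int):
    """Design columns for the interaction model of the given degree.

    Returns ``(X, names, treatment_block)`` where ``treatment_block`` are
    the column indices of the treatment main effect and the interactions.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 (linear) or 2 (quadratic)")
    marker = np.asarray(marker, dtype=float)
    arm = np.asarray(arm, dtype=float)
    powers = [marker**k for k in range(1, degree + 1)]
    cols = [np.ones_like(marker), *powers, arm, *[arm * p for p in powers]]
    names = (
        ["const"]
        + [f"x^{k}" if k > 1 else "x" for k in range(1, degree + 1)]
        + ["t"]
        + [f"t:x^{k}" if k > 1 else "t:x" for k in range(1, degree + 1)]
    )
    X = np.column_stack(cols)
    treatment_block = list(range(degree + 1, 2 * (degree + 1)))
    return X, names, treatment_block


class PretestResult(NamedTuple):
    """Outcome of the interaction pretest (F-test on g1 [, g2])."""

    statistic: float
    p_value: float
    df_num: int
    df_den: int
    level: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.level


class TreatmentEffectModel:
    """Interaction model for a randomized trial with a continuous marker.

    Parameters
    ----------
    outcome, marker, arm : array-like
        Trial data; ``arm`` must be 0/1.
    degree : {1, 2}
        1 fits the linear, 2 the quadratic analysis model.
    """

    def __init__(self, outcome, marker, arm, degree: int = 1) -> None:
        self.data = TrialData(
            marker=np.asarray(marker, dtype=float),
            arm=np.asarray(arm),
            outcome=np.asarray(outcome, dtype=float),
        )
        self.degree = int(degree)
        self.exog, self.exog_names, self.treatment_block = design_matrix(
            self.data.marker, self.data.arm, self.degree
        )

    @classmethod
    def from_trial(cls, trial: TrialData, degree: int = 1) -> "TreatmentEffectModel":
        return cls(trial.outcome, trial.marker, trial.arm, degree=degree)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "outcome",
        marker: str = "marker",
        arm: str = "arm",
        degree: int = 1,
    ) -> "TreatmentEffectModel":
        return cls(df[outcome], df[marker], df[arm], degree=degree)

    def fit(self) -> "TreatmentEffectResults":
        """OLS fit; raises :class:`SingularFitError` on rank deficiency."""
        n, k = self.exog.shape
        if n <= k:
            raise SingularFitError(f"need n > {k} observations, got {n}")
        res = sm.OLS(self.data.outcome, self.exog).fit()
        if res.df_resid != n - k:  # statsmodels fell back to a pinv fit
            raise SingularFitError("rank-deficient design matrix")
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise SingularFitError("unusable coefficient covariance")
        return TreatmentEffectResults(self, res)


@dataclass
class TreatmentEffectResults:
    """Fitted interaction model: coefficients, covariance, inference.

    Wraps the underlying statsmodels OLS results and exposes the
    treatment-effect function theta_hat(x) = a(x)'g with pointwise
    standard errors, the interaction pretest, confidence bands, root
    confidence intervals and the selection rules.
    """

    model: TreatmentEffectModel
    _ols: object

    # -- raw fit -------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._ols.params)

    @property
    def cov_params(self) -> np.ndarray:
        return np.asarray(self._ols.cov_params())

    @property
    def df_resid(self) -> int:
        return int(self._ols.df_resid)

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    @property
    def scale(self) -> float:
        """Unbiased residual variance estimate."""
        return float(self._ols.scale)

    # -- treatment block ----------------------------------------------
    @property
    def effect_coefs(self) -> np.ndarray:
        """g = coefficients of theta_hat (ascending: g0, g1 [, g2])."""
        return self.params[self.model.treatment_block]

    @property
    def effect_cov(self) -> np.ndarray:
        """Covariance submatrix of the treatment block."""
        idx = np.asarray(self.model.treatment_block)
        return self.cov_params[np.ix_(idx, idx)]

    def _basis(self, x) -> np.ndarray:
        """a(x) = (1, x [, x²]); shape (..., d)."""
        x = np.asarray(x, dtype=float)
        return np.stack(
            [x**k for k in range(self.model.degree + 1)], axis=-1
        )

    def predict_effect(self, x):
        """Estimate and standard error of theta(x).

        Returns ``(estimate, stderr)`` with the shapes of ``x``;
        ``estimate = a(x)'g`` and ``stderr = sqrt(a(x)' Sigma a(x))``.
        """
        a = self._basis(x)
        est = a @ self.effect_coefs
        var = np.einsum("...i,ij,...j->...", a, self.effect_cov, a)
        se = np.sqrt(np.maximum(var, 0.0))
        if np.ndim(x) == 0:
            return float(est), float(se)
        return est, se

    # -- interaction pretest ------------------------------------------
    def interaction_pretest(self, level: float = 0.05) -> PretestResult:
        """F-test of H0: all treatment–marker interactions are zero.

        One numerator df for the linear model (equivalent to the squared
        t-test of the t:x coefficient), two for the quadratic model.
        """
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        idx = np.asarray(self.model.treatment_block[1:])  # g1 [, g2]
        g = self.params[idx]
        V = self.cov_params[np.ix_(idx, idx)]
        q = len(idx)
        stat = float(g @ np.linalg.solve(V, g)) / q
        p = float(stats.f.sf(stat, q, self.df_resid))
        return PretestResult(stat, p, q, self.df_resid, level)

    # -- downstream objects (delegated) -------------------------------
    def conf_band(self, level: float = 0.95, kind: str = "pointwise", **kw):
        from . import bands

        if kind == "pointwise":
            return bands.pointwise_band(self, level)
        if kind == "simultaneous":
            return bands.simultaneous_band(self, level, **kw)
        raise ValueError(f"unknown band kind {kind!r}")

    def root_cis(self, level: float = 0.95, domain=DOMAIN):
        from . import bands

        return bands.root_cis_delta(self, level, domain)

    def selection_set(
        self,
        rule: str = "est",
        level: float = 0.95,
        pretest_level: float | None = 0.05,
        **kw,
    ):
        """The selection set of one construction principle.

        rule : {"est", "poi", "sim", "cir"}; ``pretest_level=None``
        skips the gatekeeping interaction pretest.
        """
        from . import rules

        sel = rules.build_rules(self, level=level, which=(rule,), **kw)[rule]
        if pretest_level is not None:
            sel = rules.gate_by_pretest(
                sel, self.interaction_pretest(pretest_level).significant
            )
        return sel

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text coefficient table plus the interaction pretest."""
        se = np.sqrt(np.diag(self.cov_params))
        tvals = self.params / se
        pvals = 2 * stats.t.sf(np.abs(tvals), self.df_resid)
        lines = [
            "Treatment-effect interaction model (OLS)",
            f"  degree: {self.model.degree}   nobs: {self.nobs}   "
            f"df_resid: {self.df_resid}   sigma2_hat: {self.scale:.4f}",
            "",
            f"  {'term':<8} {'coef':>10} {'stderr':>10} {'t':>8} {'P>|t|':>9}",
        ]
        for name, b, s, t, p in zip(
            self.model.exog_names, self.params, se, tvals, pvals
        ):
            lines.append(f"  {name:<8} {b:>10.4f} {s:>10.4f} {t:>8.2f} {p:>9.4f}")
        pre = self.interaction_pretest()
        lines += [
            "",
            f"  interaction pretest: F({pre.df_num}, {pre.df_den}) = "
            f"{pre.statistic:.3f}, p = {pre.p_value:.4g} "
            f"({'significant' if pre.significant else 'not significant'} "
            f"at {pre.level:g})",
        ]
        return "\n".join(lines)
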