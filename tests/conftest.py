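"""Shared fixtures: stub fitted results and heavy Monte Carlo runs.

The expensive replicated simulations (coverage checks and the operating
characteristics at the study's standard settings: n = 1500, 5% pretest)
are session-scoped so several tests can read different facts from one
run of common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import trtselect as ts
from trtselect.study import StudyConfig, run_study


# ---------------------------------------------------------------------
# lightweight stand-in for a fitted model with prescribed (g, Sigma)
# ---------------------------------------------------------------------
@dataclass
class StubResults:
    """Synthetic fitted-model stub: prescribed treatment-block
    coefficients and covariance with the TreatmentEffectResults
    interface needed by bands and rules."""

    g: np.ndarray
    Sigma: np.ndarray
    df_resid: int = 1496

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)

    @property
    def effect_coefs(self):
        return self.g

    @property
    def effect_cov(self):
        return self.Sigma

    def predict_effect(self, x):
        x = np.asarray(x, dtype=float)
        a = np.stack([x**k for k in range(len(self.g))], axis=-1)
        est = a @ self.g
        var = np.einsum("...i,ij,...j->...", a, self.Sigma, a)
        se = np.sqrt(np.maximum(var, 0.0))
        if np.ndim(x) == 0:
            return float(est), float(se)
        return est, se


@pytest.fixture
def stub_results():
    return StubResults


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def scenario1():
    return ts.get_scenario(1, 0.8)


@pytest.fixture(scope="session")
def fitted_s1(scenario1):
    """One fitted linear interaction model on a scenario-1 trial."""
    trial = scenario1.sample_trial(1500, np.random.default_rng(7))
    return ts.TreatmentEffectModel.from_trial(trial, degree=1).fit()


@pytest.fixture(scope="session")
def fitted_s3():
    """One fitted quadratic model on a concave-scenario trial."""
    scen = ts.get_scenario(3, 0.8)
    trial = scen.sample_trial(1500, np.random.default_rng(8))
    return ts.TreatmentEffectModel.from_trial(trial, degree=2).fit()


# ---------------------------------------------------------------------
# heavy Monte Carlo fixtures
# ---------------------------------------------------------------------
S1_REPS = 2000
_SUPT_KW = dict(draws=20_000)


@pytest.fixture(scope="session")
def s1_montecarlo(scenario1):
    """2000 replicates of scenario 1 (beta=0.8, n=1500, level 0.95).

    Records, per replicate, the band-coverage indicators, the root-CI and
    horizontal-inversion coverage of the true root 0.5, rule nesting, the
    gated selection sets' quality measures and membership of x=0.5 in the
    POI set.
    """
    theta_grid_x = np.linspace(0.0, 1.0, 101)
    theta_true_grid = scenario1.effect(theta_grid_x)
    theta_025 = scenario1.effect(0.25)
    out = {
        "pointwise_cover_025": [],
        "simultaneous_cover": [],
        "root_ci_covers": [],
        "horizontal_covers": [],
        "nesting_ok": [],
        "sim_nonempty": [],
        "est_specificity": [],
        "poi_includes_05": [],
        "pretest_significant": [],
    }
    for rep in range(S1_REPS):
        rep_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=901, spawn_key=(rep,))
        )
        trial = scenario1.sample_trial(1500, rep_rng)
        res = ts.TreatmentEffectModel.from_trial(trial, degree=1).fit()
        pre = res.interaction_pretest(0.05)

        pband = ts.pointwise_band(res, 0.95)
        est, se = res.predict_effect(0.25)
        out["pointwise_cover_025"].append(
            abs(est - theta_025) <= pband.critical_value * se
        )
        sband = ts.simultaneous_band(res, 0.95, **_SUPT_KW)
        est_g, se_g = res.predict_effect(theta_grid_x)
        out["simultaneous_cover"].append(
            np.max(np.abs(est_g - theta_true_grid) / se_g) <= sband.critical_value
        )
        cis = ts.root_cis_delta(res, 0.95)
        out["root_ci_covers"].append(
            any(ci.lower <= 0.5 <= ci.upper for ci in cis)
        )
        out["horizontal_covers"].append(
            ts.invert_band_horizontally(pband, 0.0).contains(0.5)
        )

        sets = ts.build_rules(res, level=0.95, band_kwargs=_SUPT_KW)
        nest = (
            sets["sim"].difference(sets["poi"]).is_empty
            and sets["poi"].difference(sets["est"]).is_empty
            and sets["cir"].difference(sets["est"]).is_empty
        )
        out["nesting_ok"].append(nest)
        gated = {
            k: ts.gate_by_pretest(s, pre.significant) for k, s in sets.items()
        }
        out["sim_nonempty"].append(gated["sim"].measure() > 0)
        out["est_specificity"].append(
            ts.evaluate(gated["est"], scenario1).specificity
        )
        out["poi_includes_05"].append(gated["poi"].contains(0.5))
        out["pretest_significant"].append(pre.significant)
    return {k: np.asarray(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def s2_study():
    """Scenario 2 (triangular marker) at beta=0.8, level 0.95, 1000 reps."""
    cfg = StudyConfig(
        scenario=2, beta_grid=(0.8,), n=1500, replicates=1000, level=0.95,
        seed=902,
    )
    return run_study(cfg)


@pytest.fixture(scope="session")
def level80_studies():
    """All four scenarios at beta=0.8, confidence level 0.80, 1000 reps."""
    out = {}
    for sid in (1, 2, 3, 4):
        cfg = StudyConfig(
            scenario=sid, beta_grid=(0.8,), n=1500, replicates=1000,
            level=0.8, seed=910 + sid,
        )
        out[sid] = run_study(cfg)
    return out
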