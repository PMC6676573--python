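"""Replicated simulation study of the four construction principles.

For each steepness value beta (and optionally each confidence level of a
(1−gamma) sweep) the engine simulates trials from the true scenario, fits
the analysis model, applies the 5% interaction pretest, constructs the
EST / POI / SIM / CIR selection sets, and evaluates their quality
measures against the true scenario.  Aggregates are the expected
sensitivity, expected specificity, expected overall gain and the power —
the probability that the constructed set is non-empty, i.e. that the
investigation recommends the new treatment to anyone at all.

Common random numbers: within a replicate all rules share the same trial,
and all confidence levels of a sweep share the same replicate stream, so
EST is exactly constant across levels and method comparisons are paired.
Replicate streams are spawned from the master seed by counter-based
SeedSequence keys, so results are reproducible and extending the
replicate count leaves earlier replicates unchanged.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import performance as perf
from .model import SingularFitError, TreatmentEffectModel
from .rules import RULES, build_rules, gate_by_pretest
from .scenarios import Scenario, get_scenario
from .sets import SelectionSet

logger = logging.getLogger(__name__)

def power_mc_se(p: float, replicates: int) -> float:
    """Binomial Monte Carlo standard error sqrt(p(1-p)/R) of a power
    (or any proportion) estimated from R replicates."""
    return float(np.sqrt(p * (1.0 - p) / replicates))


DEFAULT_BETA_GRID = (0.4, 0.6, 0.8, 1.0, 1.2)
DEFAULT_LEVEL_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)
_METRICS = ("sensitivity", "specificity", "overall_gain", "power")


@dataclass
class StudyConfig:
    """Configuration of one simulation study.

    ``scenario`` is a standard scenario id (1-4) or an explicit
    :class:`Scenario` (whose beta is then overridden along
    ``beta_grid``).  ``degree=None`` selects the correctly specified
    analysis model for the scenario shape; setting it explicitly allows
    misspecification experiments.  ``probe_points`` are marker values
    whose per-replicate membership in each selection set is recorded as
    an ``inclusion@x`` metric.
    """

    scenario: int | Scenario = 1
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    n: int = 1500
    replicates: int = 2500
    level: float = 0.95
    level_grid: tuple[float, ...] | None = None
    degree: int | None = None
    pretest_level: float = 0.05
    seed: int = 0
    probe_points: tuple[float, ...] = ()
    band_draws: int = 20_000
    band_grid: int = 201

    def __post_init__(self) -> None:
        self.beta_grid = tuple(float(b) for b in np.atleast_1d(self.beta_grid))
        if self.level_grid is not None:
            self.level_grid = tuple(float(l) for l in np.atleast_1d(self.level_grid))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for lev in self.levels:
            if not 0 < lev < 1:
                raise ValueError("confidence levels must be in (0, 1)")

    @property
    def levels(self) -> tuple[float, ...]:
        return self.level_grid if self.level_grid is not None else (self.level,)

    def make_scenario(self, beta: float) -> Scenario:
        if isinstance(self.scenario, Scenario):
            return self.scenario.with_(beta=beta)
        return get_scenario(self.scenario, beta)

    def analysis_degree(self, scenario: Scenario) -> int:
        return self.degree if self.degree is not None else scenario.correct_degree

    def to_manifest(self) -> dict:
        from . import __version__

        d = asdict(self)
        if isinstance(d["scenario"], dict):
            d["scenario"] = {
                k: v for k, v in d["scenario"].items() if k != "alpha"
            }
        return {"config": d, "package": "trtselect", "version": __version__}

    @classmethod
    def from_file(cls, path, **overrides) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _replicate_rng(seed: int, cell: int, rep: int, redraw: int = 0):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell, rep, redraw))
    return np.random.default_rng(ss)


def run_replicate(
    scenario: Scenario,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[dict[float, dict[str, perf.PerformanceSummary]], dict]:
    """One trial: sample, fit, pretest, build and score all rules.

    Returns ``(summaries, diagnostics)`` where ``summaries[level][rule]``
    is a :class:`~trtselect.performance.PerformanceSummary` and
    diagnostics carries the pretest outcome, per-level selection sets and
    a degenerate-root flag.  Raises :class:`SingularFitError` for a
    rank-deficient draw (the study loop redraws and counts those).
    """
    trial = scenario.sample_trial(config.n, rng)
    degree = config.analysis_degree(scenario)
    results = TreatmentEffectModel.from_trial(trial, degree=degree).fit()
    pretest = results.interaction_pretest(config.pretest_level)
    band_kwargs = {"draws": config.band_draws, "grid_size": config.band_grid}

    summaries: dict[float, dict[str, perf.PerformanceSummary]] = {}
    sets: dict[float, dict[str, SelectionSet]] = {}
    degenerate = False
    for level in config.levels:
        if pretest.significant:
            rule_sets = build_rules(results, level=level, band_kwargs=band_kwargs)
            degenerate = degenerate or (
                rule_sets["cir"].is_empty and not rule_sets["est"].is_empty
            ) and _cir_degenerate(results)
        else:
            rule_sets = {name: SelectionSet.empty() for name in RULES}
        rule_sets = {
            name: gate_by_pretest(s, pretest.significant)
            for name, s in rule_sets.items()
        }
        sets[level] = rule_sets
        summaries[level] = {
            name: perf.evaluate(s, scenario) for name, s in rule_sets.items()
        }
    diag = {
        "pretest": pretest,
        "sets": sets,
        "degenerate_root": degenerate,
    }
    return summaries, diag


def _cir_degenerate(results) -> bool:
    from .bands import DegenerateRootError, root_cis_delta

    try:
        root_cis_delta(results)
    except DegenerateRootError:
        return True
    return False


class StudyResult:
    """Aggregated simulation results in tidy form.

    ``frame`` has one row per (scenario, beta, level, rule, metric) with
    the Monte Carlo estimate, its standard error and the replicate
    count; the oracle rows (rule="oracle", metric="max_gain") carry the
    maximal-possible-gain benchmark per (scenario, beta).
    """

    def __init__(self, frame: pd.DataFrame, config: StudyConfig, diagnostics: dict):
        self.frame = frame
        self.config = config
        self.diagnostics = diagnostics

    def get(self, metric: str, rule: str, beta=None, level=None) -> float:
        """One aggregated value (unique row selection required)."""
        df = self.frame
        mask = (df["metric"] == metric) & (df["rule"] == rule)
        if beta is not None:
            mask &= np.isclose(df["beta"], beta)
        if level is not None:
            mask &= np.isclose(df["level"], level)
        sel = df.loc[mask, "estimate"]
        if len(sel) != 1:
            raise KeyError(
                f"selection ({metric}, {rule}, beta={beta}, level={level}) "
                f"matched {len(sel)} rows"
            )
        return float(sel.iloc[0])

    def pivot(self, metric: str) -> pd.DataFrame:
        df = self.frame[self.frame["metric"] == metric]
        return df.pivot_table(
            index=["beta", "level"], columns="rule", values="estimate"
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def manifest(self) -> dict:
        m = self.config.to_manifest()
        m["diagnostics"] = self.diagnostics
        return m

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)

    def summary(self) -> str:
        lines = []
        for metric in _METRICS:
            lines.append(f"== {metric} ==")
            lines.append(self.pivot(metric).round(4).to_string())
            lines.append("")
        return "\n".join(lines)


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Run the full replicated study defined by ``config``."""
    rows = []
    diagnostics = {"redraws": 0, "degenerate_roots": 0}
    scen_label = (
        config.scenario
        if not isinstance(config.scenario, Scenario)
        else f"{config.scenario.shape}/{config.scenario.marker_dist}"
    )
    for bi, beta in enumerate(config.beta_grid):
        scenario = config.make_scenario(beta)
        mg = perf.max_gain(scenario)
        # accumulators: per (level, rule) lists of per-replicate values
        acc = {
            (lev, rule): {m: [] for m in ("sensitivity", "specificity", "overall_gain", "nonempty")}
            for lev in config.levels
            for rule in RULES
        }
        probes = {
            (lev, rule, x): []
            for lev in config.levels
            for rule in RULES
            for x in config.probe_points
        }
        for rep in range(config.replicates):
            redraw = 0
            while True:
                rng = _replicate_rng(config.seed, bi, rep, redraw)
                try:
                    summaries, diag = run_replicate(scenario, config, rng)
                    break
                except SingularFitError:
                    redraw += 1
                    diagnostics["redraws"] += 1
                    if redraw > 100:
                        raise
            if diag["degenerate_root"]:
                diagnostics["degenerate_roots"] += 1
            for lev in config.levels:
                for rule in RULES:
                    s = summaries[lev][rule]
                    a = acc[(lev, rule)]
                    a["sensitivity"].append(s.sensitivity)
                    a["specificity"].append(s.specificity)
                    a["overall_gain"].append(s.overall_gain)
                    a["nonempty"].append(s.nonempty)
                    for x in config.probe_points:
                        probes[(lev, rule, x)].append(
                            diag["sets"][lev][rule].contains(x)
                        )
        R = config.replicates
        for lev in config.levels:
            for rule in RULES:
                a = acc[(lev, rule)]
                for metric_name, values in (
                    ("sensitivity", a["sensitivity"]),
                    ("specificity", a["specificity"]),
                    ("overall_gain", a["overall_gain"]),
                ):
                    v = np.asarray(values, dtype=float)
                    rows.append(
                        _row(scen_label, beta, lev, rule, metric_name,
                             v.mean(), v.std(ddof=1) / np.sqrt(R), R, config.seed)
                    )
                p = float(np.mean(a["nonempty"]))
                rows.append(
                    _row(scen_label, beta, lev, rule, "power",
                         p, power_mc_se(p, R), R, config.seed)
                )
                for x in config.probe_points:
                    q = float(np.mean(probes[(lev, rule, x)]))
                    rows.append(
                        _row(scen_label, beta, lev, rule, f"inclusion@{x:g}",
                             q, power_mc_se(q, R), R, config.seed)
                    )
            rows.append(
                _row(scen_label, beta, lev, "oracle", "max_gain",
                     mg, 0.0, R, config.seed)
            )
        if progress:
            print(
                f"[trtselect] beta={beta:g} done "
                f"(redraws={diagnostics['redraws']}, "
                f"degenerate_roots={diagnostics['degenerate_roots']})",
                file=sys.stderr,
            )
        logger.info("cell beta=%g finished (%d replicates)", beta, R)
    frame = pd.DataFrame(rows)
    return StudyResult(frame, config, diagnostics)


def _row(scenario, beta, level, rule, metric, estimate, mc_se, reps, seed):
    return {
        "scenario": scenario,
        "beta": beta,
        "level": level,
        "rule": rule,
        "metric": metric,
        "estimate": float(estimate),
        "mc_se": float(mc_se),
        "replicates": reps,
        "seed": seed,
    }


def run_level_sweep(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Study across a grid of confidence levels (the (1−gamma) sweep).

    Uses ``config.level_grid`` (default {0.5, ..., 0.99}); trials are
    shared across levels, so EST rows are identical across levels.
    """
    if config.level_grid is None:
        config = replace(config, level_grid=DEFAULT_LEVEL_GRID)
    return run_study(config, progress=progress)
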