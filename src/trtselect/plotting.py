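"""Minimal plotting helpers for fitted bands and study results."""

from __future__ import annotations

import numpy as np


def plot_band(results, level: float = 0.95, scenario=None, ax=None, n_grid: int = 201):
    """Estimated effect with pointwise and simultaneous bands.

    Overlays the true theta(x) when a scenario is given.  Returns the axis.
    """
    import matplotlib.pyplot as plt

    from .bands import pointwise_band, simultaneous_band

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(0, 1, n_grid)
    est, lo_p, hi_p = pointwise_band(results, level).evaluate(x)
    _, lo_s, hi_s = simultaneous_band(results, level).evaluate(x)
    ax.fill_between(x, lo_s, hi_s, alpha=0.15, label=f"simultaneous {level:.0%}")
    ax.fill_between(x, lo_p, hi_p, alpha=0.3, label=f"pointwise {level:.0%}")
    ax.plot(x, est, label=r"$\hat\theta(x)$")
    if scenario is not None:
        ax.plot(x, scenario.effect(x), "k--", lw=1, label=r"true $\theta(x)$")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("marker value x")
    ax.set_ylabel("treatment effect")
    ax.legend()
    return ax


def plot_metric(result, metric: str, level: float | None = None, ax=None):
    """One quality measure versus beta, one line per rule.

    For ``overall_gain`` the maximal-possible-gain benchmark is drawn as
    a thin grey line.  Returns the axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = result.frame
    if level is None:
        level = df["level"].iloc[0]
    df = df[np.isclose(df["level"], level)]
    for rule, grp in df[df["metric"] == metric].groupby("rule"):
        if rule == "oracle":
            continue
        ax.plot(grp["beta"], grp["estimate"], marker="o", label=rule.upper())
    if metric == "overall_gain":
        bench = df[(df["metric"] == "max_gain") & (df["rule"] == "oracle")]
        ax.plot(bench["beta"], bench["estimate"], color="grey", lw=1,
                label="max gain")
    ax.set_xlabel(r"$\beta$")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend()
    return ax
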