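"""Ensemble statistics over uncorrelated configurations.

One row per liquid configuration (binding energies in meV, dipole in
Debye, annihilation rates in ns^-1); columns follow the names produced by
the pipeline.  Failed configurations are excluded upstream with logged
reasons, never silently dropped here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ensemble_mean", "regress", "critical_dipole"]


def ensemble_mean(table: pd.DataFrame, column: str):
    """Mean and standard error of the mean of a column."""
    x = table[column].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 rows for a standard error")
    return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))


def regress(table: pd.DataFrame, x: str, y: str):
    """Ordinary least squares y = a x + b.

    Returns dict(slope, intercept, r2)."""
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if len(xv) < 3:
        raise ValueError("need at least 3 rows for a regression")
    if np.var(xv) == 0:
        raise ValueError(f"zero variance in x column {x!r}")
    res = stats.linregress(xv, yv)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2)}


def critical_dipole(table: pd.DataFrame, method: str = "regression",
                    pbe_column: str = "pbe_hf",
                    dipole_column: str = "dipole") -> float:
    """Critical dipole moment (Debye) above which the positron binds.

    method="regression": x-intercept of the PBE vs dipole OLS line;
    method="ensemble": smallest dipole among bound (PBE > 0) rows.
    """
    if method == "regression":
        fit = regress(table, dipole_column, pbe_column)
        if fit["slope"] == 0:
            raise ValueError("flat regression has no x-intercept")
        return -fit["intercept"] / fit["slope"]
    if method == "ensemble":
        bound = table[table[pbe_column] > 0]
        if bound.empty:
            raise ValueError("no bound configurations in the ensemble")
        return float(bound[dipole_column].min())
    raise ValueError(f"unknown method {method!r}")


def plot_regression(table: pd.DataFrame, x: str, y: str, path,
                    xlabel: str | None = None, ylabel: str | None = None):
    """Scatter + OLS fit line, written to ``path`` (publication style)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = regress(table, x, y)
    fig, ax = plt.subplots(figsize=(4.0, 3.2), dpi=150)
    ax.scatter(table[x], table[y], s=18, color="k", zorder=3)
    xs = np.linspace(table[x].min(), table[x].max(), 50)
    ax.plot(xs, fit["slope"] * xs + fit["intercept"], color="crimson",
            label=f"$R^2$ = {fit['r2']:.2f}")
    ax.set_xlabel(xlabel or x)
    ax.set_ylabel(ylabel or y)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fit
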