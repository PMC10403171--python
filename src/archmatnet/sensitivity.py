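"""One-factor-at-a-time (OFAT) sensitivity harness.

A sweep varies a single configuration parameter across ordered levels while
holding everything else at a baseline, runs several replicate simulations
per level with distinct seeds, collects the 13 summary metrics per run, and
summarizes each parameter-metric pair with a Spearman rank correlation, its
r^2, a two-sided p-value and a 95% confidence interval (Fisher z transform
with the Bonett-Wright standard error for rank correlations).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import run_model
from .metrics import METRIC_NAMES, metrics_report
from .world_model import ConfigurationError, ModelConfig


@dataclass
class SweepDesign:
    """An OFAT experiment for one parameter."""

    parameter: str
    levels: list
    replicates: int
    base_config: ModelConfig
    base_seed: int = 1

    def __post_init__(self) -> None:
        field_names = {f.name for f in dataclasses.fields(ModelConfig)}
        if self.parameter not in field_names:
            raise ConfigurationError(
                f"unknown parameter {self.parameter!r}")
        if len(self.levels) < 2:
            raise ConfigurationError("a sweep needs at least 2 levels")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


@dataclass
class CorrelationSummary:
    """Spearman summary for one parameter-metric pair."""

    parameter: str
    metric: str
    rho: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    n_runs: int
    note: str = ""


def _numeric(value) -> float:
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        raise ConfigurationError(
            "categorical levels must be encoded numerically for correlation;"
            " pass e.g. 0/1")
    return float(value)


def run_ofat(design: SweepDesign, progress: bool = False) -> pd.DataFrame:
    """Run the sweep: one simulation per level x replicate.

    Seeds are ``base_seed + level_index * replicates + replicate`` so the
    whole sweep is reproducible from the design alone.  Returns one row per
    run with the parameter value, the seed and the 13 metrics.
    """
    rows = []
    for li, level in enumerate(design.levels):
        for rep in range(design.replicates):
            seed = (design.base_seed + li * design.replicates + rep) % (2 ** 31)
            cfg = design.base_config.replace(
                **{design.parameter: level, "randomSeed": seed})
            world = run_model(cfg)
            row = {"parameter": design.parameter,
                   "level": level,
                   "level_value": _numeric(level) if not isinstance(level, str)
                   else float(li),
                   "replicate": rep,
                   "seed": seed}
            row.update(metrics_report(world).to_dict())
            rows.append(row)
            if progress:  # pragma: no cover - console feedback only
                print(f"  {design.parameter}={level} rep={rep} done",
                      flush=True)
    return pd.DataFrame(rows)


def spearman_ci(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% CI for a Spearman correlation via Fisher z with the
    Bonett-Wright standard error sqrt((1 + rho^2/2) / (n - 3))."""
    if n <= 3 or abs(rho) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(rho)
    se = math.sqrt((1.0 + rho ** 2 / 2.0) / (n - 3))
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se))


def correlate(sweep: pd.DataFrame) -> list[CorrelationSummary]:
    """Per-metric Spearman summaries for one sweep result.

    A constant parameter or a constant metric makes the correlation
    undefined; such cells are returned with NaN statistics and an
    explanatory note rather than dropped.
    """
    parameter = sweep["parameter"].iloc[0]
    x = sweep["level_value"].to_numpy(dtype=float)
    n = len(x)
    summaries = []
    x_constant = np.all(x == x[0])
    for metric in METRIC_NAMES:
        y = sweep[metric].to_numpy(dtype=float)
        note = ""
        if n < 3:
            note = "fewer than 3 runs"
        elif x_constant:
            note = "constant parameter: correlation undefined"
        elif np.all(y == y[0]) or np.isnan(y).any():
            note = "constant or undefined metric: correlation undefined"
        if note:
            summaries.append(CorrelationSummary(
                parameter, metric, float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), n, note))
            continue
        rho, p = stats.spearmanr(x, y)
        rho = float(rho)
        lo, hi = spearman_ci(rho, n)
        summaries.append(CorrelationSummary(
            parameter, metric, rho, rho ** 2, float(p), lo, hi, n))
    return summaries


def correlation_matrix(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    """Parameter x metric matrix of Spearman rho values.

    Cells with no summary (or an undefined correlation) are NaN, never 0 —
    absence of evidence is not a zero correlation.
    """
    params = sorted({s.parameter for s in summaries})
    mat = pd.DataFrame(np.nan, index=params, columns=list(METRIC_NAMES))
    for s in summaries:
        mat.loc[s.parameter, s.metric] = s.rho
    return mat


def summaries_frame(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def plot_correlation_matrix(matrix: pd.DataFrame, path: str | None = None):
    """Red/blue heatmap of a parameter x metric rho matrix (optional;
    requires matplotlib). Returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.6 * len(matrix.columns) + 2, 0.4 * len(matrix) + 2))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="RdBu_r",
                   vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns,
                  rotation=90, fontsize=8)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
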