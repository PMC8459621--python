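"""Cross-cage ordinary least-squares relationships.

Across a cohort of cages the feed supplied is an almost perfect linear
predictor of the C, N and P losses (the loss equations are affine in feed
for fixed fish terms), and production covariates — stocking density,
feeding level, cycle length — predict the net fish yield to very different
degrees.  This module fits the straight lines and reports slope, intercept
and r-squared; no p-values or intervals, matching how such farm surveys are
usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .balance import MassBasis, balances_to_frame, cage_nutrient_loss
from .metrics import compute_metrics
from .records import CageRecord, NutrientComposition

__all__ = [
    "RegressionFit",
    "fit_least_squares",
    "predict",
    "cage_table",
    "relationship_report",
    "plot_relationship",
    "DEFAULT_PAIRS",
    "SURVIVAL_PAIR",
]

#: The seven standard cross-cage relationships: feed vs each nutrient loss,
#: then feed / stocking density / cycle length / feeding rate vs net yield.
DEFAULT_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("feed_vs_c_loss", "feed_supplied_kg", "c_loss_kg"),
    ("feed_vs_n_loss", "feed_supplied_kg", "n_loss_kg"),
    ("feed_vs_p_loss", "feed_supplied_kg", "p_loss_kg"),
    ("feed_vs_net_yield", "feed_supplied_kg", "net_yield_kg_m3"),
    ("stocking_vs_net_yield", "stocking_density", "net_yield_kg_m3"),
    ("cycle_vs_net_yield", "cycle_days", "net_yield_kg_m3"),
    ("feeding_rate_vs_net_yield", "feeding_rate_pct_per_day", "net_yield_kg_m3"),
)

#: Optional extra pair: feed supply vs survival (reported without a figure
#: in the source surveys; weaker than the yield relationships).
SURVIVAL_PAIR: tuple[str, str, str] = ("feed_vs_survival", "feed_supplied_kg", "survival_pct")


@dataclass(frozen=True)
class RegressionFit:
    """A fitted line y = slope * x + intercept with its r² and sample size."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a line fit needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


def fit_least_squares(xs: Sequence[float], ys: Sequence[float]) -> RegressionFit:
    """OLS line fit with intercept; r² = 1 - SSres/SStot.

    Degenerate designs (fewer than 2 points, all x identical) are errors.
    A constant y with varying x fits exactly (r² = 1 by the SSres = 0
    convention).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("xs and ys must be one-dimensional")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} x vs {y.size} y")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: degenerate design")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 1.0, int(x.size))
    result = stats.linregress(x, y)
    residuals = y - (result.slope * x + result.intercept)
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)
    return RegressionFit(float(result.slope), float(result.intercept), r_squared, int(x.size))


def predict(fit: RegressionFit, x: float) -> float:
    """Evaluate the fitted line at x."""
    return fit.slope * x + fit.intercept


def cage_table(
    records: Iterable[CageRecord],
    comp: NutrientComposition,
    basis: MassBasis = MassBasis.AS_RECORDED,
    log_base: str = "natural",
    feeding_mode: str = "total_gain",
) -> pd.DataFrame:
    """Per-cage covariate table feeding the regressions.

    One row per cage with the record covariates (feed, stocking density,
    cycle length), the computed performance metrics and the C/N/P losses.
    """
    records = list(records)
    balances = balances_to_frame(
        [cage_nutrient_loss(r, comp, basis) for r in records]
    ).pivot(index="cage_id", columns="nutrient", values="loss")
    rows = []
    for record in records:
        perf = compute_metrics(record, log_base=log_base, feeding_mode=feeding_mode)
        rows.append(
            {
                "cage_id": record.cage_id,
                "feed_supplied_kg": record.feed_supplied_kg,
                "stocking_density": record.stocking_density,
                "cycle_days": record.cycle_days,
                "c_loss_kg": balances.loc[record.cage_id, "C"],
                "n_loss_kg": balances.loc[record.cage_id, "N"],
                "p_loss_kg": balances.loc[record.cage_id, "P"],
                "sgr_pct_per_day": perf.sgr_pct_per_day,
                "gross_yield_kg_m3": perf.gross_yield_kg_m3,
                "net_yield_kg_m3": perf.net_yield_kg_m3,
                "fcr": perf.fcr,
                "fce": perf.fce,
                "feeding_rate_pct_per_day": perf.feeding_rate_pct_per_day,
                "survival_pct": perf.survival_pct,
            }
        )
    return pd.DataFrame(rows)


def relationship_report(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]] = DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Fit every requested (name, x-column, y-column) pair on a cage table."""
    if len(table) < 2:
        raise ValueError("need at least 2 cages to fit relationships")
    rows = []
    for name, xcol, ycol in pairs:
        fit = fit_least_squares(table[xcol], table[ycol])
        rows.append(
            {
                "pair_name": name,
                "x": xcol,
                "y": ycol,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)


def plot_relationship(
    table: pd.DataFrame,
    xcol: str,
    ycol: str,
    fit: RegressionFit,
    path: str | Path,
) -> None:
    """Scatter of cages with the fitted line; written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = table[xcol].to_numpy(dtype=float)
    ax.scatter(x, table[ycol], s=25, color="tab:blue")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.slope * grid + fit.intercept, color="tab:red")
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.set_title(f"{ycol} = {fit.slope:.4g} x {xcol} + {fit.intercept:.4g}  (r² = {fit.r_squared:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
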