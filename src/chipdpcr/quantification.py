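"""Poisson absolute quantification and performance analyses.

At limiting dilution the number of template molecules per chamber is
Poisson distributed, so the fraction of positive chambers ``d/n`` relates
to the per-chamber mean ``lambda`` by ``d/n = 1 - exp(-lambda)``.
Inverting and dividing by the chamber volume gives the sample
concentration (the maximum-likelihood estimate under the binomial
likelihood of ``d`` positives in ``n`` chambers):

    C = -ln(1 - d/n) / Vd        [copies/µL, Vd in µL]

Confidence intervals use the Wilson score interval on the binomial
proportion ``d/n`` transformed through the (monotone) concentration map —
chosen for its good behaviour at very small and very large ``d``.

This module also provides the two standard performance analyses for a
digital assay: log-log linearity over a dilution series, and detection
power over a rare-mutation fraction series (the limit-of-detection
simulation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .chip_model import ChipLayout, PanelConfig, DEFAULT_LAYOUT, DEFAULT_PANEL
from .synthetic_chip import (
    DEFAULT_DILUTION_FACTOR,
    simulate_mixture_series,
)

__all__ = [
    "QuantResult",
    "LinearityResult",
    "poisson_concentration",
    "concentration_from_calls",
    "pool_counts",
    "dilution_linearity",
    "lod_power",
    "plot_linearity",
]


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification result for one channel.

    ``concentration`` is in copies/µL of the in-chamber (final mix)
    reaction; multiply by the inverse dilution factor for the stock value.
    When every chamber is positive the estimate is reported as the lower
    bound obtained with ``d = n - 1`` and ``saturated`` is set (the
    estimator is undefined at ``d = n``); the upper confidence limit is
    then unbounded.
    """

    d: int
    n: int
    vd_ul: float
    concentration: float
    ci_low: float
    ci_high: float
    saturated: bool = False

    @property
    def positive_fraction(self) -> float:
        return self.d / self.n

    def to_dict(self) -> dict:
        return {
            "d": self.d, "n": self.n, "vd_ul": self.vd_ul,
            "concentration": self.concentration,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "saturated": self.saturated,
        }


def _conc(p: float, vd: float) -> float:
    return -math.log1p(-p) / vd


def poisson_concentration(d: int, n: int, vd_ul: float,
                          alpha: float = 0.05) -> QuantResult:
    """Concentration estimate from ``d`` positive of ``n`` chambers.

    Parameters
    ----------
    d, n : int
        Positive and total counted chambers, ``0 <= d <= n``, ``n >= 1``.
    vd_ul : float
        Single-chamber volume in µL.
    alpha : float
        1 - confidence level for the Wilson interval (default 95%).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= d <= n:
        raise ValueError(f"d must satisfy 0 <= d <= n, got d={d}, n={n}")
    if not vd_ul > 0:
        raise ValueError("chamber volume must be > 0")
    d, n = int(d), int(n)

    p_lo, p_hi = proportion_confint(d, n, alpha=alpha, method="wilson")
    ci_low = _conc(min(p_lo, 1 - 1e-15), vd_ul) if p_lo > 0 else 0.0

    if d == 0:
        return QuantResult(d, n, vd_ul, 0.0, 0.0, _conc(p_hi, vd_ul))
    if d == n:
        c = _conc((n - 1) / n, vd_ul)  # lower-bound convention
        return QuantResult(d, n, vd_ul, c, ci_low, math.inf, saturated=True)
    c = _conc(d / n, vd_ul)
    ci_high = _conc(p_hi, vd_ul) if p_hi < 1 else math.inf
    return QuantResult(d, n, vd_ul, c, ci_low, ci_high)


def concentration_from_calls(table, channel: str, layout: ChipLayout,
                             count_unfilled: bool = False,
                             alpha: float = 0.05) -> QuantResult:
    """Quantify one channel of a :class:`~chipdpcr.image_analysis.ChamberCallTable`.

    Unfilled chambers never contribute to ``d``; they are excluded from
    ``n`` as well unless ``count_unfilled`` is set.
    """
    d = table.positives(channel)
    n = table.counted(count_unfilled=count_unfilled)
    return poisson_concentration(d, n, layout.chamber_volume_ul, alpha=alpha)


def pool_counts(results) -> tuple:
    """Pool replicate chips by summing counts: (sum d, sum n).

    All replicates must share the chamber volume; pooling then treats the
    replicates as one larger partition set.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to pool")
    vd = results[0].vd_ul
    if any(abs(r.vd_ul - vd) > 1e-12 * vd for r in results):
        raise ValueError("cannot pool results with differing chamber volumes")
    return sum(r.d for r in results), sum(r.n for r in results)


@dataclass(frozen=True)
class LinearityResult:
    """OLS fit of log10(estimated) on log10(true) concentration."""

    slope: float
    intercept: float
    r_squared: float
    r_squared_linear: float   # same fit on the linear scale, for reference
    n_levels: int
    dropped_levels: tuple = ()


def dilution_linearity(series) -> LinearityResult:
    """Linearity of a dilution series on the log-log scale.

    Parameters
    ----------
    series : list of (true_concentration, estimate)
        One entry per dilution level.  ``estimate`` may be a float, a
        :class:`QuantResult`, or a list of replicate ``QuantResult`` —
        replicates are combined by pooling counts (sum d, sum n) before
        the concentration is recomputed.

    The fit is ordinary least squares on log10-transformed values; the
    series typically spans several decades, where a linear-scale fit would
    be dominated by the top level (the linear-scale R² is reported
    alongside for reference).  Levels with a non-positive estimate are
    dropped with a warning.
    """
    series = list(series)
    levels, dropped = [], []
    for true_c, est in series:
        if isinstance(est, (list, tuple)):
            d, n = pool_counts(est)
            est = poisson_concentration(d, n, est[0].vd_ul)
        value = est.concentration if isinstance(est, QuantResult) else float(est)
        if value <= 0 or true_c <= 0:
            dropped.append(true_c)
            warnings.warn(
                f"dropping dilution level {true_c}: non-positive estimate",
                stacklevel=2,
            )
            continue
        levels.append((true_c, value))
    if len(levels) < 3:
        raise ValueError("need at least 3 usable dilution levels")
    x = np.log10([t for t, _ in levels])
    y = np.log10([v for _, v in levels])
    fit = stats.linregress(x, y)
    xl = np.array([t for t, _ in levels])
    yl = np.array([v for _, v in levels])
    fit_lin = stats.linregress(xl, yl)
    return LinearityResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        r_squared_linear=float(fit_lin.rvalue**2),
        n_levels=len(levels), dropped_levels=tuple(dropped),
    )


def lod_power(fractions, total_stock_concentration: float, reps: int,
              seed: int, mutation: str = "G12D",
              layout: ChipLayout = DEFAULT_LAYOUT,
              panel: PanelConfig = DEFAULT_PANEL,
              dilution_factor: float = DEFAULT_DILUTION_FACTOR,
              min_double_positive: int = 1,
              **sim_kwargs) -> dict:
    """Detection probability per mutation fraction.

    For each fraction, ``reps`` chips are simulated at the given total
    stock concentration and a chip counts as a detection when at least
    ``min_double_positive`` chambers are positive in *both* the reference
    channel and the mutation channel (the reference-gated rule).  Returns
    ``{fraction: detected_chips / reps}``.
    """
    runs = simulate_mixture_series(
        fractions, total_stock_concentration, reps=reps, seed=seed,
        mutation=mutation, layout=layout, panel=panel,
        dilution_factor=dilution_factor, render=False, **sim_kwargs,
    )
    power = {}
    for f, level in zip(fractions, runs):
        hits = sum(
            truth.double_positives(mutation) >= min_double_positive
            for truth, _ in level
        )
        power[f] = hits / len(level)
    return power


def plot_linearity(series, result: LinearityResult, out_path) -> None:
    """Scatter + fit line of the dilution series on log-log axes (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys = [], []
    for true_c, est in series:
        if isinstance(est, (list, tuple)):
            d, n = pool_counts(est)
            est = poisson_concentration(d, n, est[0].vd_ul)
        v = est.concentration if isinstance(est, QuantResult) else float(est)
        if true_c > 0 and v > 0:
            xs.append(true_c)
            ys.append(v)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.loglog(xs, ys, "o", label="measured")
    grid = np.logspace(np.log10(min(xs)), np.log10(max(xs)), 50)
    ax.loglog(grid, 10**result.intercept * grid**result.slope, "-",
              label=f"fit: slope={result.slope:.3f}, R²={result.r_squared:.4f}")
    ax.set_xlabel("theoretical concentration (copies/µL)")
    ax.set_ylabel("measured concentration (copies/µL)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
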