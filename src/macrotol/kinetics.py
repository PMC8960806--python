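"""Sigmoid pupation kinetics: curve fitting and timing comparisons.

Cumulative daily pupae counts per vial are fitted to the three-parameter
logistic curve

    I(t) = I_max / (1 + exp(-a1 (t - t_mid)))

where I_max is the asymptotic number of pupae, a1 the slope (per day)
and t_mid the midpoint day (dAEL).  The day on which a vial reaches a
given pupae count k < I_max follows in closed form,

    t = t_mid - ln(I_max / k - 1) / a1,

so that I(t) = k exactly.  The default threshold is a fixed count of 15
(half of a 30-larva vial); a relative "half-of-max" mode (k = I_max/2,
giving t = t_mid) is also provided.

Group comparisons use Welch (unequal-variance) two-sample t-tests for
half-pupation times and paired t-tests for line-level overall pupation
between diet pairs, each with Bonferroni correction over the tested
pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import sigmoid_curve

__all__ = [
    "SigmoidFit",
    "fit_sigmoid",
    "time_to_threshold",
    "compare_half_times",
    "paired_diet_comparison",
]

_log = logging.getLogger(__name__)


@dataclass
class SigmoidFit:
    """Least-squares logistic fit of a cumulative pupation time course."""

    i_max: float
    a1: float
    t_mid: float
    residual_sse: float
    converged: bool
    seeded: int | None = None
    message: str = ""

    def predict(self, t):
        return sigmoid_curve(t, self.i_max, self.a1, self.t_mid)


def _initial_guess(days: np.ndarray, counts: np.ndarray) -> tuple[float, float, float]:
    """Deterministic initialization: I_max0 = max count; t_mid0 = first day
    reaching half of it; a1_0 = 4 / (10%-to-90% rise interval)."""
    i0 = counts.max()
    half_idx = int(np.argmax(counts >= i0 / 2.0))
    t0 = days[half_idx]
    lo = int(np.argmax(counts >= 0.1 * i0))
    hi = int(np.argmax(counts >= 0.9 * i0))
    rise = days[hi] - days[lo]
    a0 = 4.0 / rise if rise > 0 else 1.0
    return float(i0), float(a0), float(t0)


def fit_sigmoid(
    days: Sequence[float],
    counts: Sequence[float],
    seeded: int | None = None,
) -> SigmoidFit:
    """Fit the logistic curve to one vial's cumulative counts.

    Requires at least 4 observations spanning the rise of the curve.
    I_max is softly bounded at 1.1 x larvae seeded (when known) to
    prevent runaway asymptotes on truncated curves.  All-zero counts or
    optimizer failure return ``converged=False`` with a reason.
    """
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if days.shape != counts.shape:
        raise ValueError("days and counts must have the same length")
    if len(days) < 4:
        raise ValueError("at least 4 observations required")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if counts.max() <= 0:
        return SigmoidFit(0.0, np.nan, np.nan, np.nan, False, seeded, "all counts zero")

    i0, a0, t0 = _initial_guess(days, counts)
    upper_imax = 1.1 * seeded if seeded is not None else 2.0 * counts.max()
    i0 = min(i0, upper_imax)
    span = days[-1] - days[0]
    bounds = (
        [1e-9, 1e-9, days[0] - span],
        [upper_imax, np.inf, days[-1] + span],
    )
    try:
        popt, _ = optimize.curve_fit(
            sigmoid_curve,
            days,
            counts,
            p0=[i0, a0, t0],
            bounds=bounds,
            maxfev=10000,
        )
    except RuntimeError as exc:  # no convergence
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, False, seeded, str(exc))
    sse = float(np.sum((counts - sigmoid_curve(days, *popt)) ** 2))
    i_max, a1, t_mid = map(float, popt)
    msg = ""
    if not days[0] - span <= t_mid <= days[-1] + span:
        msg = "midpoint outside the observation window"
    return SigmoidFit(i_max, a1, t_mid, sse, True, seeded, msg)


def time_to_threshold(fit: SigmoidFit, threshold: float = 15, mode: str = "count"):
    """Day at which the fitted curve reaches a pupae count threshold.

    ``mode="count"`` uses the fixed ``threshold`` (default 15 pupae);
    ``mode="half-of-max"`` uses I_max/2, which returns t_mid exactly.
    Raises when the asymptote never reaches the threshold.
    """
    if not fit.converged:
        raise ValueError("cannot extract a threshold time from a non-converged fit")
    if mode == "half-of-max":
        threshold = fit.i_max / 2.0
    elif mode != "count":
        raise ValueError("mode must be 'count' or 'half-of-max'")
    if fit.i_max <= threshold:
        raise ValueError(
            f"threshold unreachable: fitted asymptote {fit.i_max:.3g} <= "
            f"threshold {threshold:.3g} (this vial never reaches it)"
        )
    return fit.t_mid - math.log(fit.i_max / threshold - 1.0) / fit.a1


def compare_half_times(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups of half-pupation times.

    Bonferroni correction multiplies each raw p by the number of tested
    pairs (capped at 1).  Groups with fewer than 2 values are skipped
    with a log notice.
    """
    usable = {}
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            _log.info("group %r skipped: fewer than 2 half-times", label)
            continue
        usable[label] = vals
    pairs = list(itertools.combinations(usable, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind(usable[a], usable[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": usable[a].mean(),
                "mean_b": usable[b].mean(),
                "t": float(res.statistic),
                "df": float(res.df),
                "p_raw": float(res.pvalue),
                "p_bonferroni": min(1.0, m * float(res.pvalue)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "mean_a", "mean_b", "t", "df", "p_raw", "p_bonferroni"],
    )


def paired_diet_comparison(line_table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of line-level overall pupation between diet pairs.

    ``line_table`` is lines x diets (e.g. ``LinePhenotypeMatrix.table``).
    Each pair uses the lines complete on both diets; pairs with fewer
    than 2 complete lines are skipped.  Bonferroni multiplies by the
    number of tested pairs (15 for six diets).
    """
    diets = list(line_table.columns)
    tested = []
    for a, b in itertools.combinations(diets, 2):
        sub = line_table[[a, b]].dropna()
        if len(sub) < 2:
            _log.info("diet pair (%s, %s) skipped: fewer than 2 complete lines", a, b)
            continue
        tested.append((a, b, sub))
    m = len(tested)
    rows = []
    for a, b, sub in tested:
        if np.allclose(sub[a], sub[b]):
            t, p, df = 0.0, 1.0, float(len(sub) - 1)
        else:
            res = stats.ttest_rel(sub[a], sub[b])
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append(
            {
                "diet_a": a,
                "diet_b": b,
                "n_lines": len(sub),
                "mean_difference": float((sub[a] - sub[b]).mean()),
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": min(1.0, m * p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["diet_a", "diet_b", "n_lines", "mean_difference", "t", "df", "p_raw", "p_bonferroni"],
    )
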