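"""Exactly-specified bench-assay computations.

Small, pure helpers for the wet-lab side calculations: bomb calorimetry
gross heat, trehalose and triglyceride background subtraction, dye-based
food-intake quantification, and starvation time-of-death from activity
monitor traces.  Subtraction results that come out negative (assay
noise) are preserved and flagged, never clipped.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gross_heat",
    "SubtractionResult",
    "trehalose_relative",
    "triglyceride_net",
    "food_intake",
    "time_of_death",
]


def gross_heat(delta_t: float, energy_equivalent: float, wet_weight: float) -> float:
    """Gross heat of combustion Hg = Δt·E/w.

    ``delta_t`` is the heat lost by the sample, ``energy_equivalent`` the
    calibration constant of the benzoic-acid standard (instrument units,
    carried through symbolically), and ``wet_weight`` the sample wet
    weight in g.
    """
    if wet_weight <= 0:
        raise ValueError("wet weight must be positive")
    if energy_equivalent <= 0:
        raise ValueError("energy equivalent must be positive")
    return delta_t * energy_equivalent / wet_weight


class SubtractionResult(NamedTuple):
    """A background-subtracted assay value; ``negative`` flags values
    below zero (assay noise) that are reported unclipped."""

    value: float
    negative: bool


def _subtract(total: float, background: float, what: str) -> SubtractionResult:
    if total < 0 or background < 0:
        raise ValueError(f"{what} inputs must be non-negative")
    value = total - background
    return SubtractionResult(value, value < 0)


def trehalose_relative(total_glucose_after_digest: float, free_glucose: float) -> SubtractionResult:
    """Relative trehalose: glucose after trehalase digestion minus free glucose."""
    return _subtract(total_glucose_after_digest, free_glucose, "glucose")


def triglyceride_net(total_glycerol: float, free_glycerol: float) -> SubtractionResult:
    """TAG-derived glycerol: glycerol after lipase conversion minus free glycerol."""
    return _subtract(total_glycerol, free_glycerol, "glycerol")


def food_intake(
    absorbance: float,
    standard_curve: tuple[float, float],
    larval_weight: float,
) -> float:
    """Weight-normalized food intake from dye absorbance.

    ``standard_curve`` is (slope, intercept) of the linear
    absorbance-vs-amount calibration; the recovered amount is divided by
    the larval weight.
    """
    slope, intercept = standard_curve
    if slope == 0:
        raise ValueError("standard-curve slope must be non-zero")
    if larval_weight <= 0:
        raise ValueError("larval weight must be positive")
    return ((absorbance - intercept) / slope) / larval_weight


def time_of_death(series: pd.DataFrame | Sequence[tuple]) -> object | None:
    """Starvation time of death: timestamp of the last activity bout.

    ``series`` is a DataFrame with ``timestamp`` and ``count`` columns
    (or an iterable of (timestamp, count) pairs) with strictly increasing
    timestamps.  Returns the timestamp of the last bin with a non-zero
    count, or None when the fly showed no activity at all.
    """
    if not isinstance(series, pd.DataFrame):
        series = pd.DataFrame(series, columns=["timestamp", "count"])
    if len(series) < 1:
        raise ValueError("activity series must contain at least one bin")
    ts = series["timestamp"].to_numpy()
    if len(ts) > 1 and not np.all(ts[1:] > ts[:-1]):
        raise ValueError("timestamps must be strictly increasing")
    active = series.loc[series["count"] > 0]
    if active.empty:
        return None
    return active["timestamp"].iloc[-1]
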