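"""Banded rates to single-age schedules and back.

Model inputs arrive on 5-year age bands; the illness-death core runs on a
single-year-of-age grid 0..99.  Banded values are interpolated with a
natural cubic spline through (band midpoint, band value) knots — the open
terminal band contributes a knot at lo + 5 — with constant extrapolation
beyond the outer knots and a final clamp to the measure's admissible range
(prevalence to [0, 1], rates to >= 0).  ``band_means`` collapses a schedule
back onto reporting bands by (optionally population-weighted) averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .tables import AgeBand, Measure, RateTable

__all__ = ["AGE_GRID", "SingleAgeSchedule", "to_single_ages", "band_means"]

AGE_GRID = np.arange(100)


@dataclass
class SingleAgeSchedule:
    """Per-single-year-of-age values on the fixed grid 0..99."""

    measure: Measure
    sex: str
    year: int
    values: np.ndarray
    disease: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (100,):
            raise ValueError("schedule must have exactly one value per age 0..99")
        if not np.isfinite(self.values).all():
            raise ValueError("schedule contains non-finite values")
        lo, hi = self.measure.admissible_range
        if (self.values < lo).any() or (self.values > hi).any():
            raise ValueError(f"{self.measure.value} schedule outside [{lo}, {hi}]")


def to_single_ages(
    table: RateTable,
    clamp: tuple[float, float] | None = None,
    match_band_means: bool = False,
    n_sweeps: int = 3,
) -> SingleAgeSchedule:
    """Interpolate a banded table to single ages with a natural cubic spline.

    Knots sit at band midpoints; ages outside the outer knots take the
    nearest knot value; the result is clamped to ``clamp`` (defaulting to
    the measure's admissible range).

    Banded inputs are averages over their band, not point values at the
    midpoint; for a convex age pattern the plain spline is therefore
    biased low within each band.  ``match_band_means`` applies the
    standard grouped-data graduation correction: the knot values are
    adjusted over ``n_sweeps`` fixed-point sweeps until the schedule's own
    band means reproduce the input band values.  Constant and linear
    inputs are fixed points, so the correction leaves them untouched.
    """
    if len(table) < 2:
        raise ValueError("interpolation requires at least two bands")
    knots_x = np.array([b.midpoint for b in table.bands])
    target = table.values
    knots_y = target.astype(float).copy()
    ages = np.clip(AGE_GRID.astype(float), knots_x[0], knots_x[-1])
    lo, hi = clamp if clamp is not None else table.measure.admissible_range
    for sweep in range(n_sweeps if match_band_means else 0):
        vals = CubicSpline(knots_x, knots_y, bc_type="natural")(ages)
        means = np.array([vals[b.ages()].mean() for b in table.bands])
        knots_y = knots_y + (target - means)
    vals = CubicSpline(knots_x, knots_y, bc_type="natural")(ages)
    vals = np.clip(vals, lo, hi)
    return SingleAgeSchedule(
        measure=table.measure, sex=table.sex, year=table.year,
        values=vals, disease=table.disease,
    )


def band_means(
    schedule: SingleAgeSchedule,
    bands: list[AgeBand],
    weights: np.ndarray | None = None,
) -> RateTable:
    """Average a single-age schedule over reporting bands.

    ``weights`` is an optional per-age population (person-years) on the same
    0..99 grid; without it bands use plain arithmetic means.
    """
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (100,):
            raise ValueError("weights must cover ages 0..99")
    out = np.empty(len(bands))
    for k, band in enumerate(bands):
        ages = band.ages()
        if ages.size == 0:
            raise ValueError(f"band {band.label()} covers no ages on the grid")
        if weights is None:
            out[k] = schedule.values[ages].mean()
        else:
            w = weights[ages]
            if w.sum() <= 0:
                raise ValueError(f"band {band.label()} has zero population weight")
            out[k] = schedule.values[ages] @ w / w.sum()
    return RateTable(
        disease=schedule.disease, sex=schedule.sex, year=schedule.year,
        measure=schedule.measure, bands=list(bands), values=out,
    )
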