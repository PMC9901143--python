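"""Rate tables, age bands and direct age standardization.

The package works throughout with age-band x sex x year tables of
epidemiological measures: hazards and rates per person-year, point
prevalence as a proportion, and the all-cause mortality relative risk of
cases versus non-cases.  Rates are stored per person-year internally;
"per 100,000" scaling belongs to I/O and report formatting only.

This module provides the :class:`RateTable` container with CSV round-trip,
direct age standardization against a bundled WHO World Standard Population,
Byar's confidence interval for observed Poisson rates, prevalence-weighted
aggregation of stroke subtypes, and the survey-year approximation rule used
when model inputs are only available for nearby estimation years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeBand",
    "Measure",
    "RateTable",
    "StandardPopulation",
    "StandardizedRate",
    "SchemaError",
    "read_rate_table",
    "write_rate_table",
    "age_standardize",
    "poisson_rate_ci",
    "aggregate_stroke_subtypes",
    "approximate_year_inputs",
]

CSV_COLUMNS = [
    "disease", "sex", "year", "age_lo", "age_hi", "measure",
    "value", "se", "ci_lo", "ci_hi", "count", "person_years",
]


class SchemaError(ValueError):
    """Raised when a rate-table file or container violates its schema."""


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval [lo, hi) in whole years of age.

    The terminal band of a table may be open-ended (e.g. 95+), in which
    case ``hi`` is ``None`` and ``open_ended`` is True.
    """

    lo: int
    hi: int | None = None
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lo}")
        if self.open_ended:
            if self.hi is not None:
                raise ValueError("open-ended band must not set hi")
        else:
            if self.hi is None:
                raise ValueError("closed band requires hi")
            if self.hi <= self.lo:
                raise ValueError(f"band upper bound must exceed lower: [{self.lo}, {self.hi})")

    @property
    def midpoint(self) -> float:
        """Representative single age: band centre, or lo + 5 for an open tail."""
        if self.open_ended:
            return self.lo + 5.0
        return self.lo + (self.hi - self.lo) / 2.0

    def ages(self, max_age: int = 99) -> np.ndarray:
        """Integer ages covered by the band, capping an open tail at max_age."""
        hi = max_age + 1 if self.open_ended else min(self.hi, max_age + 1)
        return np.arange(self.lo, hi)

    def contains(self, other: "AgeBand") -> bool:
        if self.open_ended:
            return other.lo >= self.lo
        if other.open_ended:
            return False
        return other.lo >= self.lo and other.hi <= self.hi

    def label(self) -> str:
        return f"{self.lo}+" if self.open_ended else f"{self.lo}-{self.hi - 1}"


class Measure(str, Enum):
    """Epidemiological measure carried by a table, with its admissible range."""

    incidence = "incidence"
    prevalence = "prevalence"
    remission = "remission"
    csmr = "csmr"
    all_cause_mortality = "all_cause_mortality"
    relative_risk = "relative_risk"

    @property
    def admissible_range(self) -> tuple[float, float]:
        if self is Measure.prevalence:
            return (0.0, 1.0)
        return (0.0, math.inf)

    def check_value(self, value: float) -> bool:
        lo, hi = self.admissible_range
        return lo <= value <= hi


def _check_bands(bands: Sequence[AgeBand]) -> None:
    """Bands must be sorted, non-overlapping, with any open band terminal."""
    for k, band in enumerate(bands):
        if band.open_ended and k != len(bands) - 1:
            raise SchemaError("open-ended band must be the last band")
    for a, b in zip(bands, bands[1:]):
        if a.open_ended or b.lo < a.hi:
            raise SchemaError(f"bands overlap or are unsorted: {a.label()} then {b.label()}")


@dataclass
class RateTable:
    """One measure for one disease/sex/year on a set of age bands.

    ``value`` is per person-year for rates/hazards, a proportion for
    prevalence, unitless for relative risk.  ``se``, ``ci_lo``/``ci_hi``,
    ``count`` and ``person_years`` are optional per-band annotations
    (NaN where absent).
    """

    disease: str
    sex: str
    year: int
    measure: Measure
    bands: list[AgeBand]
    values: np.ndarray
    se: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    count: np.ndarray | None = None
    person_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bands) != self.values.size:
            raise SchemaError("one value per band required")
        _check_bands(self.bands)
        lo, hi = self.measure.admissible_range
        for band, v in zip(self.bands, self.values):
            if not np.isfinite(v) or v < lo or v > hi:
                raise SchemaError(
                    f"{self.measure.value} value {v} out of range [{lo}, {hi}] "
                    f"in band {band.label()}"
                )
        for name in ("se", "ci_lo", "ci_hi", "count", "person_years"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != self.values.size:
                    raise SchemaError(f"{name} must align with bands")
                setattr(self, name, arr)
        if self.count is not None and self.person_years is not None:
            both = np.isfinite(self.count) & np.isfinite(self.person_years)
            v, c, py = self.values[both], self.count[both], self.person_years[both]
            bad = np.abs(v * py - c) > 1e-9 * np.maximum(c, 1.0)
            if bad.any():
                k = int(np.flatnonzero(both)[np.argmax(bad)])
                raise SchemaError(
                    f"value != count/person_years in band {self.bands[k].label()}"
                )

    def __len__(self) -> int:
        return len(self.bands)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RateTable):
            return NotImplemented
        if (self.disease, self.sex, self.year, self.measure, self.bands) != (
            other.disease, other.sex, other.year, other.measure, other.bands
        ):
            return False

        def same(a, b):
            if a is None and b is None:
                return True
            if a is None or b is None:
                return False
            return np.array_equal(a, b, equal_nan=True)

        return all(
            same(getattr(self, n), getattr(other, n))
            for n in ("values", "se", "ci_lo", "ci_hi", "count", "person_years")
        )

    def variance(self) -> np.ndarray:
        """Per-band variance of the value, from se, CI half-width, or counts."""
        var = np.full(len(self), np.nan)
        if self.se is not None:
            var = np.where(np.isfinite(self.se), self.se**2, var)
        if self.ci_lo is not None and self.ci_hi is not None:
            half = (self.ci_hi - self.ci_lo) / (2 * 1.959963984540054)
            var = np.where(np.isnan(var) & np.isfinite(half), half**2, var)
        if self.count is not None and self.person_years is not None:
            pois = self.count / self.person_years**2
            var = np.where(np.isnan(var) & np.isfinite(pois), pois, var)
        return var

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        opt = lambda a: a if a is not None else np.full(n, np.nan)
        return pd.DataFrame(
            {
                "disease": self.disease,
                "sex": self.sex,
                "year": self.year,
                "age_lo": [b.lo for b in self.bands],
                "age_hi": [np.nan if b.open_ended else b.hi for b in self.bands],
                "measure": self.measure.value,
                "value": self.values,
                "se": opt(self.se),
                "ci_lo": opt(self.ci_lo),
                "ci_hi": opt(self.ci_hi),
                "count": opt(self.count),
                "person_years": opt(self.person_years),
            }
        )[CSV_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: Measure | None = None) -> "RateTable":
        missing = [c for c in ("disease", "sex", "year", "age_lo", "measure", "value") if c not in df]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if df.empty:
            raise SchemaError("empty table")
        for col in ("disease", "sex", "year", "measure"):
            if df[col].nunique() != 1:
                raise SchemaError(f"mixed {col} in one table")
        measure = Measure(df["measure"].iloc[0])
        if schema is not None and measure is not schema:
            raise SchemaError(f"expected measure {schema.value}, found {measure.value}")
        df = df.sort_values("age_lo", kind="stable").reset_index(drop=True)
        bands = []
        for _, row in df.iterrows():
            hi = row.get("age_hi", np.nan)
            if pd.isna(hi):
                bands.append(AgeBand(int(row["age_lo"]), open_ended=True))
            else:
                bands.append(AgeBand(int(row["age_lo"]), int(hi)))

        def col(name):
            if name not in df or df[name].isna().all():
                return None
            return df[name].to_numpy(dtype=float)

        return cls(
            disease=str(df["disease"].iloc[0]),
            sex=str(df["sex"].iloc[0]),
            year=int(df["year"].iloc[0]),
            measure=measure,
            bands=bands,
            values=df["value"].to_numpy(dtype=float),
            se=col("se"),
            ci_lo=col("ci_lo"),
            ci_hi=col("ci_hi"),
            count=col("count"),
            person_years=col("person_years"),
        )


def read_rate_table(path: str | Path, schema: Measure | None = None) -> RateTable:
    """Read and validate a single rate table from CSV.

    Raises :class:`SchemaError` on a missing column, overlapping bands or an
    out-of-range value, naming the offending band.
    """
    df = pd.read_csv(path)
    try:
        return RateTable.from_frame(df, schema=schema)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from None


def write_rate_table(table: RateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


@dataclass
class StandardPopulation:
    """Fixed reference age structure for direct standardization."""

    bands: list[AgeBand]
    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _check_bands(self.bands)
        if (self.weights < 0).any():
            raise ValueError("standard-population weights must be >= 0")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    @classmethod
    def who_world(cls) -> "StandardPopulation":
        """WHO World Standard Population (average world population 2000-2025)."""
        src = resources.files("ascertain") / "data" / "who_standard_population.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
        bands = [
            AgeBand(int(lo), open_ended=True) if pd.isna(hi) else AgeBand(int(lo), int(hi))
            for lo, hi in zip(df["age_lo"], df["age_hi"])
        ]
        w = df["weight"].to_numpy(dtype=float)
        return cls(bands=bands, weights=w / w.sum(), name="WHO World Standard 2000-2025")


@dataclass(frozen=True)
class StandardizedRate:
    value: float
    se: float | None = None

    @property
    def ci(self) -> tuple[float, float] | None:
        if self.se is None:
            return None
        z = 1.959963984540054
        return (max(self.value - z * self.se, 0.0), self.value + z * self.se)


def _map_weights(table_bands: Sequence[AgeBand], std: StandardPopulation) -> np.ndarray:
    """Aggregate the standard's weights onto the table's (coarser) bands."""
    weights = np.zeros(len(table_bands))
    assigned = np.zeros(len(std.bands), dtype=bool)
    for i, tb in enumerate(table_bands):
        for j, sb in enumerate(std.bands):
            if tb.contains(sb) or (tb.open_ended and sb.open_ended and sb.lo >= tb.lo):
                weights[i] += std.weights[j]
                assigned[j] = True
    if not assigned.all():
        left = [std.bands[j].label() for j in np.flatnonzero(~assigned)]
        raise ValueError(
            "table bands do not cover standard-population bands: " + ", ".join(left)
        )
    return weights


def age_standardize(table: RateTable, std: StandardPopulation | None = None) -> StandardizedRate:
    """Directly age-standardized rate: sum of w_k * rate_k over bands.

    Standard weights are aggregated onto the table's bands when the table is
    coarser (e.g. a 65+ tail).  When per-band variances are available the
    standard error is propagated as sqrt(sum w_k^2 var_k).
    """
    if std is None:
        std = StandardPopulation.who_world()
    w = _map_weights(table.bands, std)
    value = float(w @ table.values)
    var = table.variance()
    se = float(np.sqrt(w**2 @ var)) if np.isfinite(var).all() else None
    return StandardizedRate(value=value, se=se)


def poisson_rate_ci(count: float, py: float, level: float = 0.95) -> tuple[float, float]:
    """Byar's approximation interval for a Poisson rate (count / person-years)."""
    if py <= 0:
        raise ValueError("person-years must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2)
    if count == 0:
        lo = 0.0
    else:
        lo = count * (1 - 1 / (9 * count) - z / (3 * math.sqrt(count))) ** 3 / py
    cu = count + 1
    hi = cu * (1 - 1 / (9 * cu) + z / (3 * math.sqrt(cu))) ** 3 / py
    return (max(lo, 0.0), hi)


def aggregate_stroke_subtypes(
    prevalence: Sequence[RateTable],
    remission: Sequence[RateTable],
    relative_risk: Sequence[RateTable],
) -> tuple[RateTable, RateTable, RateTable]:
    """Combine stroke subtypes: total prevalence is the sum over subtypes;
    remission and relative risk are prevalence-weighted means, the weight of
    each subtype being its fraction of all-stroke prevalence per band.
    """
    if not (len(prevalence) == len(remission) == len(relative_risk) >= 1):
        raise ValueError("need aligned subtype tables for all three measures")
    ref = prevalence[0]
    for t in (*prevalence, *remission, *relative_risk):
        if t.bands != ref.bands or t.sex != ref.sex or t.year != ref.year:
            raise ValueError("subtype tables must share bands, sex and year")
    prev = np.vstack([t.values for t in prevalence])
    prev_all = prev.sum(axis=0)
    combined = {}
    for measure, tables in ((Measure.remission, remission), (Measure.relative_risk, relative_risk)):
        vals = np.vstack([t.values for t in tables])
        out = np.empty(len(ref))
        for k in range(len(ref)):
            if prev_all[k] > 0:
                out[k] = prev[:, k] @ vals[:, k] / prev_all[k]
            elif np.allclose(vals[:, k], 0):
                out[k] = 0.0
            else:
                raise ValueError(
                    f"zero total prevalence with nonzero {measure.value} "
                    f"in band {ref.bands[k].label()}"
                )
        combined[measure] = out

    def mk(measure, values):
        return RateTable(
            disease="stroke", sex=ref.sex, year=ref.year,
            measure=measure, bands=list(ref.bands), values=values,
        )

    return (
        mk(Measure.prevalence, prev_all),
        mk(Measure.remission, combined[Measure.remission]),
        mk(Measure.relative_risk, combined[Measure.relative_risk]),
    )


def approximate_year_inputs(
    est_a: RateTable,
    est_b: RateTable | None = None,
    *,
    rule: str = "mean",
    target_year: int,
) -> RateTable:
    """Approximate a survey year's model input from nearby estimation years.

    rule="mean" averages two estimates element-wise (e.g. 2005 and 2010
    standing in for 2007); rule="take" relabels a single estimate (e.g. a
    2016 estimate used for 2015).
    """
    if rule == "take":
        return replace(est_a, year=target_year)
    if rule != "mean":
        raise ValueError(f"unknown rule {rule!r}")
    if est_b is None:
        raise ValueError("rule='mean' requires two tables")
    if est_a.bands != est_b.bands or est_a.measure is not est_b.measure or est_a.sex != est_b.sex:
        raise ValueError("tables must share bands, measure and sex")
    return RateTable(
        disease=est_a.disease, sex=est_a.sex, year=target_year,
        measure=est_a.measure, bands=list(est_a.bands),
        values=(est_a.values + est_b.values) / 2.0,
    )
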