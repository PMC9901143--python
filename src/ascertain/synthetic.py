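"""Synthetic epidemiological worlds with known hazards and under-reporting.

A :class:`SyntheticWorld` holds ground-truth age-specific hazards (per sex),
a secular incidence trend, per-band registry reporting fractions rho, and a
population age structure.  From it the generator emits exactly the input
bundle the back-calculation pipeline consumes:

* GBD-style banded prevalence, remission, relative-risk (and CSMR) tables,
  band-averaged from the world's own forward solution so the bundle is
  internally consistent by construction;
* a surveillance extract: registry incidence degraded by rho (Poisson
  thinning of incident events) and fully-reported cause-specific mortality.

Because rho is known, the pipeline's completeness estimate can be compared
against the truth, which is what makes every downstream stage testable
without any external data.

Presets are shaped to the magnitudes of urban-China AMI and stroke
surveillance: incidence rising steeply with age (roughly log-linear above
age 30), AMI with substantial resolution of the acute phase and a declining
secular trend, stroke with near-zero chronic remission and a rising trend,
and reporting fractions around 0.3-0.55 with men ascertained better than
women.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backcalc import StratumInputs
from .illness_death import HazardSet, TrendSpec, forward_prevalence_trended
from .interpolation import AGE_GRID, band_means, SingleAgeSchedule
from .tables import AgeBand, Measure, RateTable

__all__ = [
    "SyntheticWorld",
    "default_bands",
    "make_world",
    "emit_model_inputs",
    "emit_surveillance",
    "true_completeness",
]

SEXES = ("male", "female")


def default_bands(width: int = 5, terminal: int = 95) -> list[AgeBand]:
    """Standard 5-year reporting bands 0-4 ... 90-94, 95+."""
    bands = [AgeBand(lo, lo + width) for lo in range(0, terminal, width)]
    bands.append(AgeBand(terminal, open_ended=True))
    return bands


@dataclass
class SyntheticWorld:
    """Ground truth for one disease: hazards, trend, reporting and population."""

    disease: str
    hazards: dict[str, HazardSet]
    trend: dict[str, TrendSpec]
    bands: list[AgeBand]
    reporting_fraction: dict[str, np.ndarray]
    population: dict[str, np.ndarray]  # person-years per single age
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in SEXES:
            rho = np.asarray(self.reporting_fraction[sex], dtype=float)
            if rho.shape != (len(self.bands),):
                raise ValueError("reporting fraction must have one value per band")
            if (rho < 0).any() or (rho > 1).any():
                raise ValueError("reporting fractions must lie in [0, 1]")
            self.reporting_fraction[sex] = rho
            pop = np.asarray(self.population[sex], dtype=float)
            if pop.shape != (100,) or (pop <= 0).any():
                raise ValueError("population must be positive on ages 0..99")
            self.population[sex] = pop

    def prevalence_cross_section(self, sex: str) -> np.ndarray:
        """True cross-sectional prevalence at the survey year (trend-aware)."""
        return forward_prevalence_trended(self.hazards[sex], self.trend[sex])

    def csmr_cross_section(self, sex: str) -> np.ndarray:
        return self.hazards[sex].f * self.prevalence_cross_section(sex)


def _smooth_onset(center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(AGE_GRID - center) / scale))


_PRESETS = {
    "ami_like": dict(
        i50={"male": 2.0e-3, "female": 1.2e-3},
        i_slope=0.070,
        onset=(27.0, 3.5),
        remission=0.25,
        f50=0.020,
        f_slope=0.050,
        trend_delta={"male": -0.02, "female": -0.02},
        rho={"male": 0.42, "female": 0.30},
    ),
    "stroke_like": dict(
        i50={"male": 5.0e-3, "female": 3.6e-3},
        i_slope=0.065,
        onset=(27.0, 3.5),
        remission=0.02,
        f50=0.030,
        f_slope=0.040,
        trend_delta={"male": 0.03, "female": 0.02},
        rho={"male": 0.55, "female": 0.53},
    ),
}


def make_world(
    preset: str = "ami_like",
    params: dict | None = None,
    seed: int = 0,
    survey_year: int = 2015,
    base_year: int = 2000,
    band_person_years: float = 1e7,
) -> SyntheticWorld:
    """Build a deterministic synthetic world from a named preset.

    ``params`` overrides individual preset entries (see the keys of the
    built-in presets); ``preset='custom'`` starts from ``ami_like`` shapes
    and relies entirely on overrides.  ``band_person_years`` is the
    population denominator per 5-year band, spread uniformly over single
    ages.  The construction itself is deterministic; ``seed`` feeds the
    stochastic emitters downstream.
    """
    if preset not in (*_PRESETS, "custom"):
        raise ValueError(f"unknown preset {preset!r}")
    cfg = dict(_PRESETS["ami_like" if preset == "custom" else preset])
    cfg.update(params or {})
    bands = default_bands()
    a = AGE_GRID.astype(float)
    onset = _smooth_onset(*cfg["onset"])
    m = np.minimum(2.0e-4 * np.exp(0.085 * a), 0.5)  # Gompertz other-cause mortality
    hazards, trend, rho, pop = {}, {}, {}, {}
    for sex in SEXES:
        i = cfg["i50"][sex] * np.exp(cfg["i_slope"] * (a - 50.0)) * onset
        f = cfg["f50"] * np.exp(cfg["f_slope"] * (a - 50.0)) * onset
        h = HazardSet(i=i, r=np.full(100, float(cfg["remission"])), f=f, m=m)
        t = TrendSpec(delta=cfg["trend_delta"][sex], survey_year=survey_year, base_year=base_year)
        p = forward_prevalence_trended(h, t)
        if (p >= 1.0).any():
            raise ValueError("preset parameters imply prevalence >= 1")
        hazards[sex], trend[sex] = h, t
        r = cfg["rho"][sex]
        rho[sex] = np.full(len(bands), r) if np.isscalar(r) else np.asarray(r, dtype=float)
        pop[sex] = np.full(100, band_person_years / 5.0)
    return SyntheticWorld(
        disease=preset, hazards=hazards, trend=trend, bands=bands,
        reporting_fraction=rho, population=pop, seed=seed,
    )


def _band_table(world, sex, measure, values, bands, noise, rng) -> RateTable:
    schedule = SingleAgeSchedule(
        measure=measure, sex=sex, year=world.trend[sex].survey_year,
        values=values, disease=world.disease,
    )
    table = band_means(schedule, bands, weights=world.population[sex])
    sd = noise * table.values
    if rng is not None and noise > 0:
        lo, hi = measure.admissible_range
        table.values = np.clip(
            table.values + rng.normal(0.0, 1.0, sd.size) * sd, lo, min(hi, 1e12)
        )
        sd = noise * table.values  # SD reported for the value actually emitted
    table.se = sd
    return table


def emit_model_inputs(
    world: SyntheticWorld,
    sex: str,
    bands: list[AgeBand] | None = None,
    noise: float = 0.0,
    perturb: bool = False,
    rng: np.random.Generator | None = None,
    perturb_measures: tuple[str, ...] = ("prevalence",),
) -> StratumInputs:
    """Band-averaged model inputs (with SDs) from the world's forward solution.

    ``noise`` is a coefficient of variation attached as the per-band SD
    (noise * value); with ``perturb`` the emitted values of the measures in
    ``perturb_measures`` (by default prevalence only, mirroring the
    uncertainty model downstream) are additionally perturbed once with that
    same normal model, emulating input estimates that are themselves noisy.
    With noise 0 the inputs are exactly the band-averaged model quantities.
    """
    bands = bands if bands is not None else world.bands
    h = world.hazards[sex]
    p = world.prevalence_cross_section(sex)
    if perturb and noise > 0 and rng is None:
        rng = np.random.default_rng(world.seed)

    def draw_for(name):
        return rng if perturb and noise > 0 and name in perturb_measures else None

    with np.errstate(divide="ignore"):
        rr = np.where(h.m > 0, (h.m + h.f) / np.where(h.m > 0, h.m, 1.0), 1.0)
    return StratumInputs(
        prevalence=_band_table(
            world, sex, Measure.prevalence, p, bands, noise, draw_for("prevalence")
        ),
        remission=_band_table(
            world, sex, Measure.remission, h.r, bands, noise, draw_for("remission")
        ),
        csmr=_band_table(world, sex, Measure.csmr, h.f * p, bands, noise, draw_for("csmr")),
        relative_risk=_band_table(
            world, sex, Measure.relative_risk, rr, bands, noise, draw_for("relative_risk")
        ),
        all_cause_mortality=_band_table(
            world, sex, Measure.all_cause_mortality, h.m + h.f * p, bands, noise,
            draw_for("all_cause_mortality"),
        ),
    )


def emit_surveillance(
    world: SyntheticWorld,
    sex: str,
    seed: int | None = None,
    bands: list[AgeBand] | None = None,
) -> tuple[RateTable, RateTable]:
    """Registry incidence (thinned by rho) and fully-reported mortality.

    Expected incident counts per band are true incidence x person-years x
    rho; observed counts are Poisson draws (independent thinning).  Death
    counts are Poisson from CSMR x person-years with full completeness.
    Deterministic given ``seed`` (defaulting to the world's seed).
    """
    bands = bands if bands is not None else world.bands
    rho = world.reporting_fraction[sex]
    if len(rho) != len(bands):
        raise ValueError("reporting fraction not defined on the requested bands")
    rng = np.random.default_rng(world.seed if seed is None else seed)
    i_true = world.hazards[sex].i
    csmr = world.csmr_cross_section(sex)
    pop = world.population[sex]
    year = world.trend[sex].survey_year

    def draw_table(per_age_rate, measure, frac):
        counts = np.empty(len(bands))
        py = np.empty(len(bands))
        for k, band in enumerate(bands):
            ages = band.ages()
            py[k] = pop[ages].sum()
            counts[k] = rng.poisson(per_age_rate[ages] @ pop[ages] * frac[k])
        values = counts / py
        return RateTable(
            disease=world.disease, sex=sex, year=year, measure=measure,
            bands=list(bands), values=values,
            se=np.sqrt(counts) / py, count=counts, person_years=py,
        )

    incidence = draw_table(i_true, Measure.incidence, rho)
    mortality = draw_table(csmr, Measure.csmr, np.ones(len(bands)))
    return incidence, mortality


def true_completeness(world: SyntheticWorld, bands: list[AgeBand] | None = None) -> pd.DataFrame:
    """Ground-truth reporting fractions, one row per (sex, band)."""
    bands = bands if bands is not None else world.bands
    rows = []
    for sex in SEXES:
        rho = world.reporting_fraction[sex]
        if len(rho) != len(bands):
            raise ValueError("reporting fraction not defined on the requested bands")
        for band, r in zip(bands, rho):
            rows.append({"sex": sex, "age_lo": band.lo,
                         "age_hi": None if band.open_ended else band.hi, "rho": r})
    return pd.DataFrame(rows)
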