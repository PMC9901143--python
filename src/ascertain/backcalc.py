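"""Single-stratum back-calculation: band inputs -> modeled incidence.

Glues the pieces together for one (disease, sex, year) stratum: interpolate
the banded prevalence, remission and cause-specific mortality inputs to
single ages, derive case fatality as CSMR / prevalence, invert the
prevalence ODE (with or without a secular incidence trend), and report the
modeled incidence back on the requested bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .illness_death import (
    HazardSet,
    InversionResult,
    TrendSpec,
    case_fatality_from_csmr,
    invert_incidence,
    invert_incidence_trended,
)
from .interpolation import SingleAgeSchedule, band_means, to_single_ages
from .tables import AgeBand, Measure, RateTable

__all__ = ["StratumInputs", "ModelRun", "model_incidence"]


@dataclass
class StratumInputs:
    """Banded model inputs for one stratum.

    ``relative_risk`` and ``all_cause_mortality`` are optional: they provide
    the fallback case-fatality pathway at near-zero prevalence and the
    consistency diagnostic, but the primary pathway needs only prevalence,
    remission and CSMR.
    """

    prevalence: RateTable
    remission: RateTable
    csmr: RateTable
    relative_risk: RateTable | None = None
    all_cause_mortality: RateTable | None = None

    def __post_init__(self) -> None:
        ref = self.prevalence
        for t in (self.remission, self.csmr, self.relative_risk, self.all_cause_mortality):
            if t is not None and (t.bands != ref.bands or t.sex != ref.sex or t.year != ref.year):
                raise ValueError("stratum input tables must share bands, sex and year")

    def with_prevalence_values(self, values: np.ndarray) -> "StratumInputs":
        return StratumInputs(
            prevalence=replace(self.prevalence, values=np.asarray(values, dtype=float)),
            remission=self.remission,
            csmr=self.csmr,
            relative_risk=self.relative_risk,
            all_cause_mortality=self.all_cause_mortality,
        )


@dataclass
class ModelRun:
    """Modeled incidence for one stratum, on single ages and on bands."""

    incidence_single: SingleAgeSchedule
    incidence_bands: RateTable
    hazards: HazardSet
    inversion: InversionResult
    trend: TrendSpec | None


def model_incidence(
    inputs: StratumInputs,
    bands: list[AgeBand] | None = None,
    trend: TrendSpec | None = None,
    population: np.ndarray | None = None,
) -> ModelRun:
    """Back-calculate the stratum's incidence schedule from its inputs.

    ``bands`` defaults to the input tables' bands; ``population`` (per-age
    person-years) weights the band roll-up when given.  A ``trend`` with
    delta != 0 switches to the cohort-consistent trended inversion.
    """
    # banded inputs are band means; mean-matching interpolation avoids the
    # convexity bias a midpoint-value spline would introduce
    p = to_single_ages(inputs.prevalence, match_band_means=True).values
    # keep prevalence strictly below 1 for the inversion denominator
    p = np.minimum(p, 1.0 - 1e-9)
    r = to_single_ages(inputs.remission, match_band_means=True).values
    csmr = to_single_ages(inputs.csmr, match_band_means=True).values
    rr = m_all = None
    if inputs.relative_risk is not None and inputs.all_cause_mortality is not None:
        rr = to_single_ages(inputs.relative_risk).values
        m_all = to_single_ages(inputs.all_cause_mortality).values
    f = case_fatality_from_csmr(csmr, p, rr=rr, m_all=m_all)
    if trend is not None and trend.delta != 0.0:
        inv = invert_incidence_trended(p, r, f, trend)
    else:
        inv = invert_incidence(p, r, f)
    h = HazardSet(i=inv.i, r=r, f=f, m=np.zeros_like(r))
    schedule = SingleAgeSchedule(
        measure=Measure.incidence,
        sex=inputs.prevalence.sex,
        year=inputs.prevalence.year,
        values=inv.i,
        disease=inputs.prevalence.disease,
    )
    out_bands = bands if bands is not None else list(inputs.prevalence.bands)
    banded = band_means(schedule, out_bands, weights=population)
    return ModelRun(
        incidence_single=schedule,
        incidence_bands=banded,
        hazards=h,
        inversion=inv,
        trend=trend,
    )
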