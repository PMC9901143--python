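"""Registry completeness: observed vs modeled incidence.

The headline statistic is the incidence rate ratio (IRR) — the observed
registry incidence rate divided by the model-consistent incidence rate —
interpreted as the fraction of incident cases the surveillance system
captures.  Confidence intervals and between-year tests use a normal
approximation on the log-ratio scale:

    var(log IRR) = var_obs / obs^2 + var_mod / mod^2

with the modeled variance taken from bootstrap replicates.  Whether
completeness improved between survey years is tested one-sided:
z = (log IRR_2 - log IRR_1) / sqrt(se_1^2 + se_2^2), p = 1 - Phi(z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import RateTable

__all__ = [
    "CompletenessEntry",
    "CompletenessReport",
    "completeness_ratio",
    "ztest_irr_increase",
    "incidence_mortality_ratio",
    "build_report",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class Stratum:
    disease: str
    sex: str
    year: int
    age_group: str

    def key(self) -> str:
        return f"{self.disease}/{self.sex}/{self.year}/{self.age_group}"


@dataclass
class CompletenessEntry:
    """Observed/modeled incidence rate ratio for one stratum."""

    stratum: Stratum
    irr: float
    ci: tuple[float, float]
    trended: bool = False
    observed: float | None = None
    modeled: float | None = None

    def __post_init__(self) -> None:
        if self.irr < 0:
            raise ValueError("IRR must be non-negative")
        lo, hi = self.ci
        if not (lo <= self.irr <= hi):
            raise ValueError("IRR must lie inside its CI")

    @property
    def se_log(self) -> float:
        lo, hi = self.ci
        if lo <= 0 or hi <= lo:
            return 0.0
        return (np.log(hi) - np.log(lo)) / (2 * _Z95)


def completeness_ratio(
    observed: float,
    modeled: float,
    var_observed: float = 0.0,
    var_modeled: float = 0.0,
    stratum: Stratum | None = None,
    trended: bool = False,
    level: float = 0.95,
) -> CompletenessEntry:
    """IRR = observed / modeled with a log-normal confidence interval.

    Scale-invariant: multiplying both rates (and scaling the variances
    accordingly) leaves the ratio and its CI unchanged.
    """
    if modeled <= 0:
        raise ValueError("modeled rate must be positive")
    if observed < 0:
        raise ValueError("observed rate must be non-negative")
    irr = observed / modeled
    if observed > 0 and (var_observed > 0 or var_modeled > 0):
        se = np.sqrt(var_observed / observed**2 + var_modeled / modeled**2)
        z = stats.norm.ppf(0.5 + level / 2)
        ci = (irr * np.exp(-z * se), irr * np.exp(z * se))
    else:
        ci = (irr, irr)
    return CompletenessEntry(
        stratum=stratum or Stratum("unspecified", "unspecified", 0, "total"),
        irr=irr, ci=ci, trended=trended, observed=observed, modeled=modeled,
    )


def ztest_irr_increase(e1: CompletenessEntry, e2: CompletenessEntry) -> tuple[float, float]:
    """One-sided Z-test of H1: the later IRR exceeds the earlier one.

    Standard errors on the log scale are recovered from the entries' CIs.
    Returns (z, one-sided p).
    """
    se1, se2 = e1.se_log, e2.se_log
    denom = np.hypot(se1, se2)
    if denom == 0:
        raise ValueError("both entries have zero log-scale standard error")
    if e1.irr <= 0 or e2.irr <= 0:
        raise ValueError("IRRs must be positive for the log-scale test")
    z = (np.log(e2.irr) - np.log(e1.irr)) / denom
    return float(z), float(stats.norm.sf(z))


def incidence_mortality_ratio(
    incidence: RateTable, mortality: RateTable
) -> pd.DataFrame:
    """Observed incidence : mortality rate ratio per band, with log-normal CI.

    A diagnostic for registry completeness: with case fatality below 1 and
    complete reporting the ratio exceeds 1; values below 1 flag substantial
    under-ascertainment of incident cases.
    """
    if incidence.bands != mortality.bands:
        raise ValueError("incidence and mortality tables must share bands")
    if (mortality.values <= 0).any():
        raise ValueError("mortality rates must be positive")
    ratio = incidence.values / mortality.values
    var_i = incidence.variance()
    var_m = mortality.variance()
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            np.where(incidence.values > 0, var_i / incidence.values**2, np.nan)
            + var_m / mortality.values**2
        )
    lo = ratio * np.exp(-_Z95 * se)
    hi = ratio * np.exp(_Z95 * se)
    return pd.DataFrame(
        {
            "age_group": [b.label() for b in incidence.bands],
            "ratio": ratio,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )


@dataclass
class CompletenessReport:
    """Full completeness assessment: entries, between-year tests, metadata."""

    entries: list[CompletenessEntry]
    tests: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = {(e.stratum.key(), e.trended) for e in self.entries}
        for t in self.tests:
            for side in ("from", "to"):
                if (t[side], t["trended"]) not in keys:
                    raise ValueError(f"test references unknown stratum {t[side]}")
            if not 0.0 <= t["p"] <= 1.0:
                raise ValueError("p-value outside [0, 1]")

    def entry(self, key: str, trended: bool = True) -> CompletenessEntry:
        for e in self.entries:
            if e.stratum.key() == key and e.trended == trended:
                return e
        raise KeyError(key)

    def to_json_dict(self) -> dict:
        return {
            "entries": [
                {
                    **asdict(e.stratum),
                    "irr": e.irr,
                    "ci_lo": e.ci[0],
                    "ci_hi": e.ci[1],
                    "trended": e.trended,
                    "observed": e.observed,
                    "modeled": e.modeled,
                }
                for e in self.entries
            ],
            "tests": self.tests,
            "metadata": self.metadata,
        }

    # -- formatted tables ------------------------------------------------

    def rates_table(self, per: float = 1e5) -> pd.DataFrame:
        """Observed and modeled rates per `per` person-years, rounded to integers."""
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "disease": e.stratum.disease,
                    "sex": e.stratum.sex,
                    "year": e.stratum.year,
                    "age_group": e.stratum.age_group,
                    "trended": e.trended,
                    "observed": round(e.observed * per) if e.observed is not None else None,
                    "modeled": round(e.modeled * per) if e.modeled is not None else None,
                }
            )
        return pd.DataFrame(rows)

    def ratio_table(self) -> pd.DataFrame:
        """Completeness ratios rendered to 2 decimals with CIs."""
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "disease": e.stratum.disease,
                    "sex": e.stratum.sex,
                    "year": e.stratum.year,
                    "age_group": e.stratum.age_group,
                    "trended": e.trended,
                    "ratio": f"{e.irr:.2f}",
                    "ci": f"({e.ci[0]:.2f}, {e.ci[1]:.2f})",
                }
            )
        return pd.DataFrame(rows)


def build_report(
    entries: list[CompletenessEntry],
    year_pairs: list[tuple[int, int]] | None = None,
    metadata: dict | None = None,
    outdir: str | Path | None = None,
) -> CompletenessReport:
    """Assemble entries into a report and run between-year increase tests.

    For each (earlier, later) pair in ``year_pairs`` and each
    (disease, sex, age group, trended) combination present in both years,
    the one-sided Z-test of an IRR increase is added.  When ``outdir`` is
    given the report JSON and the two formatted CSV tables are written
    there deterministically.
    """
    tests: list[dict] = []
    index = {(e.stratum.disease, e.stratum.sex, e.stratum.year, e.stratum.age_group, e.trended): e
             for e in entries}
    for y1, y2 in year_pairs or []:
        for (dis, sex, year, ag, trended), e1 in sorted(index.items(), key=lambda kv: kv[0]):
            if year != y1:
                continue
            e2 = index.get((dis, sex, y2, ag, trended))
            if e2 is None or e1.se_log == 0 and e2.se_log == 0:
                continue
            z, p = ztest_irr_increase(e1, e2)
            tests.append(
                {
                    "from": e1.stratum.key(),
                    "to": e2.stratum.key(),
                    "trended": trended,
                    "z": z,
                    "p": p,
                }
            )
    report = CompletenessReport(entries=entries, tests=tests, metadata=metadata or {})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "completeness_report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        report.rates_table().to_csv(outdir / "rates_by_stratum.csv", index=False)
        report.ratio_table().to_csv(outdir / "completeness_ratios.csv", index=False)
    return report
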