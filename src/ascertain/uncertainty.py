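"""Bootstrap uncertainty for modeled incidence.

The modeled incidence inherits uncertainty from its prevalence input.
Mirroring the uncertainty analysis the back-calculation is paired with, the
banded prevalence values are perturbed i.i.d. with a normal distribution
(truncated to [0, 1]) and the whole back-calculation is re-run per
replicate; per-band percentile intervals summarise the replicate spread.
The point estimate always comes from the unperturbed run, so it is
invariant to the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backcalc import ModelRun, StratumInputs, model_incidence
from .illness_death import TrendSpec
from .tables import AgeBand, RateTable

__all__ = ["BootstrapSpec", "BootstrapResult", "bootstrap_incidence"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class BootstrapSpec:
    """Settings for the prevalence-perturbation bootstrap."""

    n_iter: int = 100
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass
class BootstrapResult:
    """Per-band modeled incidence with a percentile interval."""

    bands: list[AgeBand]
    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    replicates: np.ndarray  # n_iter x n_bands
    level: float
    n_failed: int = 0

    @property
    def variance(self) -> np.ndarray:
        """Replicate variance per band (ddof=1; zero when all SDs were zero)."""
        if self.replicates.shape[0] < 2:
            return np.zeros(self.replicates.shape[1])
        return self.replicates.var(axis=0, ddof=1)


def _prevalence_sd(prev: RateTable) -> np.ndarray:
    """Per-band SD: the se column, else CI half-width / 1.96, else zero."""
    sd = np.zeros(len(prev))
    if prev.se is not None:
        sd = np.where(np.isfinite(prev.se), prev.se, sd)
    if prev.ci_lo is not None and prev.ci_hi is not None:
        half = (prev.ci_hi - prev.ci_lo) / (2 * _Z95)
        need = (sd == 0) & np.isfinite(half)
        sd = np.where(need, half, sd)
    if (sd < 0).any():
        raise ValueError("prevalence SDs must be non-negative")
    return sd


def bootstrap_incidence(
    inputs: StratumInputs,
    spec: BootstrapSpec,
    bands: list[AgeBand] | None = None,
    trend: TrendSpec | None = None,
    population: np.ndarray | None = None,
) -> BootstrapResult:
    """Bootstrap the back-calculated incidence by perturbing prevalence.

    Each replicate redraws the banded prevalence from a normal distribution
    centred on the observed value with the per-band SD (truncated to
    [0, 1]) and re-runs interpolation, case-fatality derivation and
    inversion.  Deterministic given ``spec.seed``.
    """
    point_run: ModelRun = model_incidence(inputs, bands=bands, trend=trend, population=population)
    point = point_run.incidence_bands.values
    sd = _prevalence_sd(inputs.prevalence)
    rng = np.random.default_rng(spec.seed)
    reps = np.empty((spec.n_iter, point.size))
    failures: list[str] = []
    n_ok = 0
    for b in range(spec.n_iter):
        drawn = inputs.prevalence.values + rng.normal(0.0, 1.0, sd.size) * sd
        drawn = np.clip(drawn, 0.0, 1.0)
        try:
            run = model_incidence(
                inputs.with_prevalence_values(drawn),
                bands=bands, trend=trend, population=population,
            )
        except (ValueError, FloatingPointError) as err:  # pragma: no cover - rare
            failures.append(str(err))
            reps[b] = np.nan
            continue
        reps[b] = run.incidence_bands.values
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError(
            "all bootstrap replicates failed; first error: " + failures[0]
        )
    alpha = (1.0 - spec.level) / 2.0
    lo = np.nanpercentile(reps, 100 * alpha, axis=0)
    hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    return BootstrapResult(
        bands=point_run.incidence_bands.bands,
        point=point,
        lo=lo,
        hi=hi,
        replicates=reps[~np.isnan(reps).any(axis=1)],
        level=spec.level,
        n_failed=spec.n_iter - n_ok,
    )
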