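"""Self-validation studies: the package checking its own machinery.

Each study here exercises the full stack on problems with a known answer
and returns a scalar summary: the forward/inverse round trip on smooth
hazards, recovery of configured reporting fractions from synthetic worlds,
empirical coverage of the prevalence-perturbation bootstrap, type-I error
of the one-sided IRR increase test, and reproduction of the worked-example
completeness ratios from published surveillance totals.  The studies are
deterministic given their seed and are sized to run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .completeness import completeness_ratio, ztest_irr_increase
from .backcalc import model_incidence
from .illness_death import HazardSet, forward_solve, invert_incidence
from .interpolation import AGE_GRID, SingleAgeSchedule, band_means
from .synthetic import emit_model_inputs, emit_surveillance, make_world
from .tables import Measure
from .uncertainty import BootstrapSpec, bootstrap_incidence

__all__ = [
    "REFERENCE_RATE_PAIRS",
    "reference_ratios",
    "roundtrip_study",
    "recovery_study",
    "coverage_study",
    "ztest_calibration",
]

# Published total-row observed and trend-adjusted modeled incidence rates
# (per 100,000 person-years) from urban-China AMI/stroke surveillance,
# 2007-2015, used as worked-example inputs for the completeness ratio.
REFERENCE_RATE_PAIRS: dict[str, tuple[float, float]] = {
    "ami_men_2007": (69.0, 146.0),
    "ami_men_2015": (63.0, 126.0),
    "ami_women_2015": (34.0, 109.0),
    "stroke_men_2010": (364.0, 685.0),
    "stroke_men_2015": (458.0, 708.0),
    "stroke_women_2007": (215.0, 455.0),
    "stroke_women_2015": (278.0, 458.0),
}


def reference_ratios() -> dict[str, float]:
    """Completeness ratios (2 dp) for the worked-example rate pairs."""
    out = {}
    for key, (obs, mod) in REFERENCE_RATE_PAIRS.items():
        entry = completeness_ratio(obs / 1e5, mod / 1e5, trended=True)
        out[key] = round(entry.irr, 2)
    return out


def _smooth_hazard_sets() -> list[HazardSet]:
    a = AGE_GRID.astype(float)
    m = np.minimum(2e-4 * np.exp(0.085 * a), 0.5)
    sets = []
    # incidence growth up to ~0.06/yr (doubling per decade) and remission up
    # to 0.25/yr; steeper schedules leave the single-year discretization
    # regime in which the round trip resolves incidence to 1e-3
    for gi, i50, r0, f50, gf in (
        (0.03, 1.5e-3, 0.25, 8e-3, 0.04),
        (0.05, 2.0e-3, 0.20, 8e-3, 0.05),
        (0.06, 1.0e-3, 0.05, 5e-3, 0.04),
    ):
        sets.append(
            HazardSet(
                i=i50 * np.exp(gi * (a - 50.0)),
                r=np.full(100, r0),
                f=f50 * np.exp(gf * (a - 50.0)),
                m=m,
            )
        )
    return sets


def roundtrip_study() -> dict[str, float]:
    """Forward-solve then invert smooth hazard sets; also closed-form and
    probability-conservation checks.

    Returns the maximum relative incidence error at interior ages (2..97),
    the worst deviation from p(a) = 1 - exp(-i a) under constant hazards,
    and the worst probability-conservation violation.
    """
    worst_rt = 0.0
    worst_cons = 0.0
    for h in _smooth_hazard_sets():
        sol = forward_solve(h)
        inv = invert_incidence(sol.p, h.r, h.f)
        rel = np.abs(inv.i[2:98] - h.i[2:98]) / h.i[2:98]
        worst_rt = max(worst_rt, float(rel.max()))
        worst_cons = max(worst_cons, float(np.abs(sol.total() - 1.0).max()))
    h_const = HazardSet(i=0.02, r=0.0, f=0.0, m=0.0)
    sol = forward_solve(h_const)
    closed = 1.0 - np.exp(-0.02 * AGE_GRID)
    worst_cf = float(np.abs(sol.p - closed).max())
    worst_cons = max(worst_cons, float(np.abs(sol.total() - 1.0).max()))
    return {
        "roundtrip_max_rel_err": worst_rt,
        "closed_form_max_abs_err": worst_cf,
        "conservation_max_abs_err": worst_cons,
    }


def _recovery_bands(world):
    return [
        k for k, b in enumerate(world.bands)
        if b.lo >= 30 and not b.open_ended and b.hi <= 85
    ]


def recovery_study(
    seed: int = 0,
    n_seeds: int = 20,
    scenarios: tuple[tuple[str, str], ...] = (("ami_like", "male"), ("stroke_like", "female")),
    band_person_years: float = 1e7,
) -> dict:
    """Recover configured reporting fractions from noise-free synthetic worlds.

    For each scenario and seed: emit consistent inputs (noise 0) and a
    Poisson registry, back-calculate trended incidence, and take the
    observed/modeled ratio per band.  Reports the largest absolute bias
    (mean over seeds of estimate minus truth) across bands covering ages
    30-84, plus per-scenario mean estimates.
    """
    max_bias = 0.0
    estimates = {}
    for preset, sex in scenarios:
        irrs = []
        rho = None
        for s in range(n_seeds):
            world = make_world(
                preset, seed=seed + 1000 * s, band_person_years=band_person_years
            )
            sel = _recovery_bands(world)
            rho = world.reporting_fraction[sex][sel]
            inputs = emit_model_inputs(world, sex)
            observed, _ = emit_surveillance(world, sex, seed=seed + 1000 * s + 1)
            run = model_incidence(
                inputs,
                bands=world.bands,
                trend=world.trend[sex],
                population=world.population[sex],
            )
            irrs.append(observed.values[sel] / run.incidence_bands.values[sel])
        bias = np.mean(irrs, axis=0) - rho
        max_bias = max(max_bias, float(np.abs(bias).max()))
        estimates[f"{preset}_{sex}"] = {
            "mean_completeness": float(np.mean(irrs)),
            "true_rho": float(rho[0]),
        }
    return {"max_abs_bias": max_bias, "scenarios": estimates, "n_seeds": n_seeds}


def coverage_study(
    seed: int = 0,
    n_outer: int = 200,
    n_iter: int = 100,
    noise: float = 0.05,
) -> dict:
    """Empirical coverage of the bootstrap percentile interval.

    Outer loop: redraw the banded prevalence input with the known noise
    model; inner loop: the package's own bootstrap at ``n_iter`` replicates.
    Coverage is the share of outer replications whose interval contains the
    true band incidence, averaged over bands covering ages 30-84.  The
    world is untrended so the bootstrap exercises the plain inversion.
    """
    world = make_world("ami_like", params={"trend_delta": {"male": 0.0, "female": 0.0}}, seed=seed)
    sex = "male"
    sel = _recovery_bands(world)
    truth_schedule = SingleAgeSchedule(
        measure=Measure.incidence, sex=sex, year=world.trend[sex].survey_year,
        values=world.hazards[sex].i, disease=world.disease,
    )
    truth = band_means(truth_schedule, world.bands, weights=world.population[sex]).values[sel]
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(sel))
    for r in range(n_outer):
        inputs = emit_model_inputs(world, sex, noise=noise, perturb=True, rng=rng)
        boot = bootstrap_incidence(
            inputs,
            BootstrapSpec(n_iter=n_iter, seed=int(rng.integers(2**31 - 1))),
            bands=world.bands,
            population=world.population[sex],
        )
        hits += (boot.lo[sel] <= truth) & (truth <= boot.hi[sel])
    return {"coverage": float(hits.mean() / n_outer), "n_outer": n_outer, "n_iter": n_iter}


def ztest_calibration(
    seed: int = 0,
    n_sims: int = 2000,
    rate: float = 300e-5,
    py: float = 2e5,
    modeled: float = 600e-5,
    modeled_cv: float = 0.03,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the one-sided IRR increase test under the null.

    Two survey years share the same true rates; observed counts are Poisson
    and the modeled rate carries lognormal noise with known CV.  Returns
    the rejection rate at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        entries = []
        for _year in (1, 2):
            count = rng.poisson(rate * py)
            obs = count / py
            mod = modeled * np.exp(rng.normal(0.0, modeled_cv))
            entries.append(
                completeness_ratio(
                    obs, mod,
                    var_observed=count / py**2,
                    var_modeled=(modeled_cv * mod) ** 2,
                )
            )
        _z, p = ztest_irr_increase(entries[0], entries[1])
        rejections += p < alpha
    return {"type1_error": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}
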