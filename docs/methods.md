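# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `ascertain`. It is the companion to the README's overview:
the README says what the package does; this note says exactly how, and
what the validation results do and do not demonstrate.

## The illness–death consistency model

The population is described by a three-state continuous-time model —
healthy (S), diseased (C), dead — with dead split into cause-specific and
other-cause compartments so cause deaths can be accumulated. All four
hazards are per person-year and age-specific on a single-year grid 0–99:

| hazard | meaning | typical source |
|---|---|---|
| *i(a)* | incidence, S→C | the unknown being estimated |
| *r(a)* | remission, C→S | GBD-style estimates |
| *f(a)* | case fatality, C→cause death | CSMR / prevalence |
| *m(a)* | other-cause mortality | all-cause mortality + RR split |

The model's central identity is that the prevalence ODE,
`p′ = i(1−p) − rp − fp(1−p)`, contains no *m*: incidence is identified by
prevalence, remission and case fatality alone. Other-cause mortality
enters only the occupancy trajectories and the relative-risk consistency
check. Consequently the back-calculation pathway is
**prevalence + remission + CSMR**, with the relative risk (RR) and
all-cause mortality relegated to (a) a fallback for case fatality at ages
where prevalence is below 1e-6 (there `f = max(m·(RR−1), 0)`), and (b)
the `consistency_residuals` diagnostic comparing the implied RR
`(m+f)/m` against the RR input. CSMR is preferred over RR as the primary
pathway because it is typically the locally measured quantity, while RR is
a modelled import.

### Discretization

The forward solve treats hazards as constant on each one-year age interval
— the constant being the **mean of the two endpoint grid values** — and
advances the occupancy vector by the exact matrix exponential of the
4-state generator. The generator's columns sum to zero, so probability is
conserved to machine precision at every age. The endpoint-mean convention
matters: it makes the discrete solution second-order consistent with the
smooth ODE, whereas a left-endpoint convention would shift recovered
incidence by ~g/2 per year of hazard growth g (a 2–3 % bias at realistic
growth rates).

The inversion evaluates `p′` with a fourth-order five-point central
stencil in the interior (second-order one-sided at the grid ends): the
early-age transient in prevalence decays at rate λ = i+r+f, and a
second-order stencil leaves a visible λ²/6 relative error there. With
these choices the forward∘invert round trip recovers generating incidence
to ≲1e-3 relative at interior ages for schedules with incidence growth up
to ~0.06/yr and remission up to 0.25/yr; the residual error scales like
g²/4, so steeper schedules (e.g. g = 0.07/yr, ~1.2e-3) leave the regime
where the single-year grid resolves the round trip to 1e-3. Negative raw
inverted incidence (possible when prevalence falls faster than remission
and fatality explain) is floored at zero and flagged per age rather than
raised, since isolated negative estimates at extreme ages are an expected
feature of noisy inputs.

### Band-to-single-age interpolation

Inputs arrive as 5-year band tables. `to_single_ages` fits a natural cubic
spline through (band midpoint, band value) knots — an open-ended terminal
band contributes a knot at lo+5 — with constant extrapolation outside the
outer knots and a final clamp to the measure's admissible range
(prevalence to [0,1], rates to ≥0). Clamp-after-spline is deliberate:
monotone or shape-constrained splines would be a different interpolation
model.

Banded inputs are band *means*, not midpoint values, and for convex age
schedules a midpoint-value spline is biased low within each band (about
3–6 % on recovered incidence in the synthetic worlds). The
back-calculation workflow therefore uses **mean-matching** interpolation:
three fixed-point sweeps adjust the knot values until the schedule's own
band means reproduce the banded inputs. Constant and linear inputs are
fixed points of the sweep, so the correction never distorts data the plain
spline already handles exactly.

### Secular trend

"Incidence has changed by δ per year since the base year" is interpreted
along cohort lines: the cohort aged *a* at the survey experienced, at age
*u*, the hazard `i(u)·(1+δ)^−(a−u)`, frozen at the base-year level for
calendar years before the base year (default 2000). Remission and case
fatality are held at current levels. The trended forward map solves each
cohort's reduced 2-state (S,C) system — exact for prevalence, since *m*
cancels — with a closed-form 2×2 matrix exponential vectorised over all
100 cohorts.

Trended inversion has no closed form; it is a multiplicative fixed point
on the current-year incidence schedule, started from the untrended
inversion, with per-age updates `i ← i · clip(p_obs/p_model, 0.5, 2)`.
Convergence is declared when the maximum prevalence misfit, scaled by peak
observed prevalence, falls below 1e-4 (default; up to 100 iterations).
Two numerical facts shape those defaults: ages with vanishing prevalence
carry no information about incidence and must not drive the loop, and the
interval-mean forward map is blind to the age-alternating mode of the
incidence schedule, which caps the attainable misfit near 1e-5 — the
tolerance sits above that floor and far below reporting precision. δ = 0
short-circuits to the untrended path, so the two branches agree exactly in
that limit.

## Uncertainty

Mirroring the uncertainty analysis this pipeline is paired with, only the
prevalence input is perturbed: i.i.d. normal per band (truncated to
[0,1] rather than redrawn — at the prevalence magnitudes involved the
truncation bias is negligible), default 100 replicates, percentile
intervals, point estimate from the unperturbed run. Per-band SDs come
from the input's `se` column, else from CI half-width / 1.96. The
coverage study (below) shows the resulting intervals cover truth ~93 % at
nominal 95 %: the small shortfall is the usual percentile-interval
undercoverage at 100 replicates plus residual interpolation error, and is
within the 90–99 % band the package targets.

The between-year test is a one-sided Z-test on log IRR with
`var(log IRR) = var_obs/obs² + var_mod/mod²`, observed variance Poisson
(count/py²), modelled variance from bootstrap replicates. The calibration
study simulates Poisson observed counts (~600 per cell) and lognormal
modelled error with known CV under a true null, so it genuinely tests the
log-normal variance construction; the measured type-I error is ~0.05.

## Synthetic worlds

`make_world` builds deterministic ground-truth worlds with
exponential-in-age incidence and case fatality (log-linear above a smooth
logistic onset centred at age 27), constant remission, and Gompertz
other-cause mortality capped at 0.5/yr. Preset magnitudes follow urban
cardiovascular surveillance: the AMI-like preset has incidence
~2·10⁻³/yr at age 50 doubling every ~10 years, substantial acute-phase
resolution (r = 0.25/yr) and a −2 %/yr trend; the stroke-like preset has
higher incidence, near-zero chronic remission (0.02/yr) and rising trends
(+3 %/+2 %/yr men/women). Reporting fractions default to 0.42/0.30
(AMI-like, men/women) and 0.55/0.53 (stroke-like), the observed pattern of
better ascertainment in men. Populations default to 10⁷ person-years per
5-year band, uniform within bands.

The emitted inputs are band averages of the world's own trended
cross-sectional solution, so they are internally consistent by
construction; the registry is an independent Poisson thinning of incident
events by ρ per band, while deaths are fully reported. The generator
emulates the *structure* of real inputs, not their pathologies: it has no
inconsistency between prevalence and mortality sources, no age-misreporting,
no severity-differential ascertainment, and the 28-day recurrence
convention is representable only as a constant incidence-inflation factor.
Passing recovery tests therefore demonstrate that the pipeline machinery
is unbiased on self-consistent inputs — not that real-world inputs are
self-consistent.

## Validation studies and their problem sizes

All studies live in `ascertain.validation` and are re-run by
`scripts/acceptance.py`; sizes were chosen to give stable estimates in
about two minutes on one CPU:

* **Round trip / closed form / conservation** — three smooth hazard sets
  spanning growth 0.03–0.06/yr and remission 0.05–0.25/yr; constant-hazard
  closed form `p(a) = 1 − e^{−ia}`; conservation at every age.
* **Reporting-fraction recovery** — 20 seeds × two scenarios (AMI-like
  male, stroke-like female), noise-free inputs, 10⁷ py/band, trended
  analysis; bias assessed per band over ages 30–84 (max |bias| ≈ 0.004).
* **Bootstrap coverage** — 200 outer replications of 5 % CV prevalence
  noise × 100 bootstrap replicates, untrended AMI-like world, bands 30–84.
* **Z-test calibration** — 2000 null simulations.

## Known limitations

* The single-year grid limits round-trip accuracy to O(g²/4); very steep
  hazard schedules (growth ≳0.07/yr) should be modelled on a finer grid.
* The four-input system (prevalence, remission, CSMR, RR) is
  over-determined; the package resolves it by convention (CSMR primary)
  rather than by joint reconciliation, and reports the RR residual as a
  diagnostic only.
* Completeness CIs combine observed Poisson variance with modelled
  bootstrap variance; correlations between the two (both depend on the
  same population) are ignored.
* Reporting-band roll-ups use person-year-weighted means of band rates;
  with strongly non-uniform within-band populations the 5-year bands
  themselves are the resolution limit.
* The trended bootstrap converges here by construction; it cannot emulate
  the non-convergence modes of other implementations of this model class.
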