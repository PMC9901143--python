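"""The illness-death core: forward solve, hazard derivations, inversion, trend."""

import numpy as np
import pytest

from ascertain.illness_death import (
    HazardSet,
    TrendSpec,
    apply_trend,
    case_fatality_from_csmr,
    case_fatality_from_rr,
    consistency_residuals,
    forward_prevalence_trended,
    forward_solve,
    invert_incidence,
    invert_incidence_trended,
)
from ascertain.interpolation import AGE_GRID


def rk4_oracle(h, p0=0.0, substeps=100):
    """Fine-step explicit integrator of the occupancy ODEs with the same
    interval-constant hazards as the matrix-exponential stepper."""
    i = (h.i[:-1] + h.i[1:]) / 2
    r = (h.r[:-1] + h.r[1:]) / 2
    f = (h.f[:-1] + h.f[1:]) / 2
    m = (h.m[:-1] + h.m[1:]) / 2
    y = np.array([1.0 - p0, p0, 0.0, 0.0])
    out = np.empty((100, 4))
    out[0] = y
    dt = 1.0 / substeps

    def deriv(y, k):
        S, C, Dc, Do = y
        return np.array(
            [
                -(i[k] + m[k]) * S + r[k] * C,
                i[k] * S - (r[k] + f[k] + m[k]) * C,
                f[k] * C,
                m[k] * (S + C),
            ]
        )

    for k in range(99):
        for _ in range(substeps):
            k1 = deriv(y, k)
            k2 = deriv(y + dt / 2 * k1, k)
            k3 = deriv(y + dt / 2 * k2, k)
            k4 = deriv(y + dt * k3, k)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = y
    return out


class TestForwardSolve:
    def test_no_incidence_no_disease(self):
        sol = forward_solve(HazardSet(i=0.0, r=0.1, f=0.05, m=0.01), p0=0.0)
        assert np.allclose(sol.p, 0.0) and np.allclose(sol.csmr, 0.0)

    def test_zero_case_fatality_no_cause_deaths(self, smooth_hazards):
        h = HazardSet(i=smooth_hazards.i, r=smooth_hazards.r, f=0.0, m=smooth_hazards.m)
        assert np.allclose(forward_solve(h).D_cause, 0.0)

    def test_constant_hazard_closed_form(self):
        sol = forward_solve(HazardSet(i=0.02, r=0.0, f=0.0, m=0.0), p0=0.0)
        assert sol.p[20] == pytest.approx(1 - np.exp(-0.4), abs=1e-9)
        assert np.abs(sol.p - (1 - np.exp(-0.02 * AGE_GRID))).max() < 1e-9

    def test_probability_conserved(self, smooth_hazards):
        sol = forward_solve(smooth_hazards, p0=0.01)
        assert np.abs(sol.total() - 1.0).max() < 1e-9

    def test_alive_population_non_increasing(self, smooth_hazards):
        sol = forward_solve(smooth_hazards)
        alive = sol.S + sol.C
        assert (np.diff(alive) <= 1e-12).all()
        assert (np.diff(sol.D_cause) >= -1e-15).all()

    def test_agrees_with_fine_step_rk4_oracle(self, smooth_hazards):
        sol = forward_solve(smooth_hazards, p0=0.005)
        oracle = rk4_oracle(smooth_hazards, p0=0.005)
        assert np.abs(sol.S - oracle[:, 0]).max() < 1e-6
        assert np.abs(sol.C - oracle[:, 1]).max() < 1e-6
        assert np.abs(sol.D_cause - oracle[:, 2]).max() < 1e-6

    def test_monotone_in_incidence(self, smooth_hazards):
        sol_lo = forward_solve(smooth_hazards)
        h_hi = HazardSet(
            i=smooth_hazards.i * 1.5, r=smooth_hazards.r, f=smooth_hazards.f, m=smooth_hazards.m
        )
        sol_hi = forward_solve(h_hi)
        assert (sol_hi.p >= sol_lo.p - 1e-12).all()

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            HazardSet(i=-0.01, r=0.0, f=0.0, m=0.0)


class TestCaseFatalityDerivations:
    def test_zero_csmr_gives_zero_f(self):
        f = case_fatality_from_csmr(np.zeros(100), np.full(100, 0.1))
        assert np.allclose(f, 0.0)

    def test_simple_ratio(self):
        f = case_fatality_from_csmr(np.full(100, 0.001), np.full(100, 0.1))
        assert np.allclose(f, 0.01)

    def test_roundtrip_against_forward_solve(self, smooth_hazards):
        sol = forward_solve(smooth_hazards)
        ok = sol.p >= 1e-4
        f = case_fatality_from_csmr(sol.csmr, sol.p)
        assert np.abs(f[ok] / smooth_hazards.f[ok] - 1).max() < 1e-6

    def test_inconsistent_zero_prevalence_raises(self):
        csmr = np.full(100, 0.001)
        with pytest.raises(ValueError, match="zero prevalence"):
            case_fatality_from_csmr(csmr, np.zeros(100))

    def test_rr_pathway_unit_rr(self):
        m_all = np.full(100, 0.012)
        f, m = case_fatality_from_rr(np.ones(100), m_all, np.full(100, 0.1))
        assert np.allclose(f, 0.0) and np.allclose(m, m_all)

    def test_rr_pathway_solves_mixture_identity(self):
        p = np.full(100, 0.2)
        rr = np.full(100, 2.0)
        m_all = np.full(100, 0.012)
        f, m = case_fatality_from_rr(rr, m_all, p)
        assert np.allclose(m, 0.01) and np.allclose(f, 0.01)
        assert np.allclose(m * (1 - p) + (m + f) * p, m_all, atol=1e-15)

    def test_rr_pathway_zero_prevalence_limit(self):
        rr = np.full(100, 3.0)
        m_all = np.full(100, 0.01)
        f, m = case_fatality_from_rr(rr, m_all, np.zeros(100))
        assert np.allclose(m, m_all) and np.allclose(f, 0.02)


class TestInvertIncidence:
    def test_zero_world(self):
        res = invert_incidence(np.zeros(100), np.zeros(100), np.zeros(100))
        assert np.allclose(res.i, 0.0) and not res.floored.any()

    def test_constant_hazard_closed_form_inverse(self):
        p = 1 - np.exp(-0.01 * AGE_GRID)
        res = invert_incidence(p, np.zeros(100), np.zeros(100))
        assert np.abs(res.i[1:99] - 0.01).max() < 1e-4

    def test_steady_state_balance(self):
        p_star = 0.07
        r = np.full(100, 0.3)
        res = invert_incidence(np.full(100, p_star), r, np.zeros(100))
        assert np.allclose(res.i, 0.3 * p_star / (1 - p_star), atol=1e-12)

    def test_roundtrip_recovers_incidence(self, smooth_hazards):
        sol = forward_solve(smooth_hazards)
        res = invert_incidence(sol.p, smooth_hazards.r, smooth_hazards.f)
        rel = np.abs(res.i[2:98] / smooth_hazards.i[2:98] - 1)
        assert rel.max() < 1e-3

    def test_prevalence_one_rejected(self):
        p = np.full(100, 0.5)
        p[50] = 1.0
        with pytest.raises(ValueError):
            invert_incidence(p, np.zeros(100), np.zeros(100))

    def test_negative_raw_incidence_floored_and_flagged(self):
        # prevalence falling faster than remission/fatality can explain
        p = np.clip(0.2 - 0.01 * AGE_GRID, 0.0, 1.0)
        res = invert_incidence(p, np.zeros(100), np.zeros(100))
        assert (res.i >= 0).all() and res.floored.any()


class TestTrend:
    def test_multiplier_value(self):
        trend = TrendSpec(delta=-0.02, survey_year=2015)
        assert trend.multiplier(10.0) == pytest.approx(0.98**-10, rel=1e-12)
        assert 0.98**-10 == pytest.approx(1.2239, abs=1e-4)

    def test_multiplier_frozen_before_base_year(self):
        trend = TrendSpec(delta=0.03, survey_year=2015, base_year=2000)
        assert trend.multiplier(40.0) == trend.multiplier(15.0)

    def test_surface_shape_and_diagonal(self):
        i = np.full(100, 0.01)
        surf = apply_trend(i, TrendSpec(delta=-0.02, survey_year=2015))
        assert surf.i_cohort.shape == (100, 100)
        # at the survey age (lag 0) the cohort experiences the current rate
        assert np.allclose(np.diag(surf.i_cohort), 0.01)
        # strictly above the diagonal (future ages) the surface is zero
        assert np.allclose(np.triu(surf.i_cohort, k=1), 0.0)

    def test_zero_delta_is_bitwise_identical_to_untrended(self, smooth_hazards):
        trend = TrendSpec(delta=0.0, survey_year=2015)
        p_trended = forward_prevalence_trended(smooth_hazards, trend)
        p_plain = forward_solve(smooth_hazards).p
        assert np.array_equal(p_trended, p_plain)
        res_t = invert_incidence_trended(p_plain, smooth_hazards.r, smooth_hazards.f, trend)
        res_p = invert_incidence(p_plain, smooth_hazards.r, smooth_hazards.f)
        assert np.array_equal(res_t.i, res_p.i)

    def test_trended_cross_section_reflects_past_rates(self, smooth_hazards):
        # declining incidence (delta < 0) means past rates were higher, so
        # the cross-sectional prevalence exceeds the untrended solution
        trend = TrendSpec(delta=-0.02, survey_year=2015)
        p_trended = forward_prevalence_trended(smooth_hazards, trend)
        p_plain = forward_solve(smooth_hazards).p
        assert (p_trended[30:] > p_plain[30:]).all()

    def test_trended_inversion_roundtrip(self, smooth_hazards):
        trend = TrendSpec(delta=0.03, survey_year=2015)
        p_cross = forward_prevalence_trended(smooth_hazards, trend)
        res = invert_incidence_trended(
            p_cross, smooth_hazards.r, smooth_hazards.f, trend
        )
        assert res.converged
        rel = np.abs(res.i[25:95] / smooth_hazards.i[25:95] - 1)
        assert rel.max() < 0.02

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            TrendSpec(delta=-1.0, survey_year=2015)


class TestConsistencyResiduals:
    def test_self_consistent_world_has_tiny_residuals(self, smooth_hazards):
        sol = forward_solve(smooth_hazards)
        with np.errstate(divide="ignore"):
            rr_in = (smooth_hazards.m + smooth_hazards.f) / smooth_hazards.m
        res = consistency_residuals(sol.p, sol.csmr, sol, smooth_hazards, rr_in=rr_in)
        assert res.max_rel() < 1e-6

    def test_localized_perturbation_shows_up(self, smooth_hazards):
        sol = forward_solve(smooth_hazards)
        p_in = sol.p.copy()
        p_in[50:55] *= 1.1
        res = consistency_residuals(p_in, sol.csmr, sol, smooth_hazards)
        assert np.abs(res.prevalence_rel[50:55]).min() > 0.05
        assert np.abs(res.prevalence_rel[:45]).max() < 1e-9
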