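"""Weibull curves, per-cycle probabilities, occupancy, and subgroup PH rules."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.optimize import brentq

from escc_cea.parameters import ModelSettings, ParameterSet, WeibullParams
from escc_cea.survival import (
    SubgroupSpec,
    find_horizon,
    occupancy,
    per_cycle_event_prob,
    subgroup_curves,
    weibull_S,
    weibull_median,
)

SIDCHM_OS = WeibullParams(scale=0.010568, shape=1.284650)

weibulls = st.builds(
    WeibullParams,
    scale=st.floats(1e-4, 0.5),
    shape=st.floats(0.3, 3.0),
)


class TestWeibullS:
    def test_starts_at_one(self):
        assert weibull_S(SIDCHM_OS, 0.0) == 1.0

    def test_direct_evaluation(self):
        # S(1) = exp(-scale * 1^shape) = exp(-0.010568)
        assert weibull_S(SIDCHM_OS, 1.0) == pytest.approx(math.exp(-0.010568), abs=1e-12)

    def test_median_matches_root_find(self):
        # independent oracle: numeric root of S(m) = 1/2
        m_oracle = brentq(lambda t: weibull_S(SIDCHM_OS, t) - 0.5, 1.0, 100.0)
        assert weibull_median(SIDCHM_OS) == pytest.approx(m_oracle, rel=1e-9)
        assert m_oracle == pytest.approx(25.96, abs=0.05)
        # ~17.9 months, same magnitude as the trial's 16.7-month median OS
        assert m_oracle * 21 / 30.44 == pytest.approx(17.9, abs=0.1)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_S(SIDCHM_OS, -0.1)

    @given(p=weibulls)
    @hyp_settings(max_examples=50, derandomize=True)
    def test_monotone_nonincreasing_to_zero(self, p):
        t = np.linspace(0, 500, 400)
        s = weibull_S(p, t)
        assert np.all(np.diff(s) <= 1e-15)
        assert s[0] == 1.0
        t_far = (20.0 / p.scale) ** (1.0 / p.shape)  # cumulative hazard 20
        assert weibull_S(p, t_far) < 1e-6


class TestPerCycleEventProb:
    def test_first_cycle_value(self):
        assert per_cycle_event_prob(SIDCHM_OS, 1) == pytest.approx(
            1.0 - math.exp(-0.010568), abs=1e-12)

    def test_exponential_is_memoryless(self):
        p = WeibullParams(scale=0.05, shape=1.0)
        qs = {per_cycle_event_prob(p, t) for t in (1, 5, 50, 200)}
        assert max(qs) - min(qs) < 1e-12

    @given(p=weibulls, t=st.integers(1, 300))
    @hyp_settings(max_examples=100, derandomize=True)
    def test_is_a_probability(self, p, t):
        q = per_cycle_event_prob(p, t)
        assert 0.0 <= q <= 1.0


class TestOccupancy:
    def test_cohort_starts_progression_free(self, ps):
        occ = occupancy(ps.weibull["sidchm_pfs"], ps.weibull["sidchm_os"],
                        ps.settings, 10)
        assert (occ.pfs[0], occ.pd[0], occ.dead[0]) == (1.0, 0.0, 0.0)

    @pytest.mark.parametrize("arm", ["sidchm", "plchm"])
    def test_mass_conserved_every_cycle(self, ps, arm):
        occ = occupancy(ps.weibull[f"{arm}_pfs"], ps.weibull[f"{arm}_os"],
                        ps.settings, 160)
        total = occ.pfs + occ.pd + occ.dead
        assert np.all(np.abs(total - 1.0) <= 1e-12)
        assert np.all(occ.pfs >= 0) and np.all(occ.pd >= -1e-15) and np.all(occ.dead >= 0)

    def test_horizon_hits_99pct_death_rule(self, ps):
        # oracle: root of S_OS(T) = 1 - 0.99 for the slower-dying arm,
        # rounded up to the first whole cycle
        wb = ps.weibull["sidchm_os"]
        t99 = brentq(lambda t: weibull_S(wb, t) - 0.01, 1.0, 300.0)
        horizon, capped = find_horizon(ps)
        assert not capped
        assert horizon == math.ceil(t99) == 114

    def test_crossing_curves_reconciled_by_capping(self):
        # PFS extrapolates above OS: occupancy must cap PFS at the alive mass
        st_ = ModelSettings(background_mortality_annual=0.0)
        pfs = WeibullParams(scale=0.01, shape=1.0)
        os_ = WeibullParams(scale=0.05, shape=1.0)
        occ = occupancy(pfs, os_, st_, 50)
        assert occ.reconciled_cycles > 0
        assert np.all(occ.pd >= 0)
        assert np.allclose(occ.pfs, 1.0 - occ.dead)  # fully capped here

    def test_exponential_closed_form(self):
        # shape = 1: dead(t) = 1 - exp(-lo*t), pfs(t) = exp(-max(lp,lo)*t)
        st_ = ModelSettings(background_mortality_annual=0.0)
        lp, lo = 0.08, 0.03
        occ = occupancy(WeibullParams(lp, 1.0), WeibullParams(lo, 1.0), st_, 100)
        t = np.arange(101.0)
        assert np.allclose(occ.dead, 1.0 - np.exp(-lo * t), atol=1e-10)
        assert np.allclose(occ.pfs, np.exp(-lp * t), atol=1e-10)
        assert np.allclose(occ.pd, np.exp(-lo * t) - np.exp(-lp * t), atol=1e-10)

    def test_background_mortality_floors_death_hazard(self, ps):
        # a huge background rate must dominate the OS-derived hazard
        st_ = dataclasses.replace(ps.settings, background_mortality_annual=0.9)
        occ = occupancy(ps.weibull["sidchm_pfs"], ps.weibull["sidchm_os"], st_, 20)
        per_cycle = 1.0 - (1.0 - 0.9) ** (21 / 365)
        assert occ.dead[1] >= per_cycle - 1e-12


class TestSubgroupCurves:
    def test_ph_identity_scale_times_hr(self, ps):
        # Weibull PH with shared shape: S'(t) = S(t)^hr exactly
        sg = SubgroupSpec(name="x", hr_os=0.70, hr_pfs=0.66)
        curves = subgroup_curves(ps, sg)
        base = ps.weibull["plchm_os"]
        assert curves["sidchm_os"].scale == pytest.approx(base.scale * 0.70)
        assert curves["sidchm_os"].shape == base.shape
        t = np.linspace(0, 120, 60)
        assert np.allclose(weibull_S(curves["sidchm_os"], t),
                           weibull_S(base, t) ** 0.70, atol=1e-14)

    def test_age_under_65_scale_arithmetic(self, ps):
        sg = SubgroupSpec(name="age<65", hr_os=0.70, hr_pfs=0.66)
        curves = subgroup_curves(ps, sg)
        assert curves["sidchm_os"].scale == pytest.approx(0.010993 * 0.70)
        assert curves["sidchm_os"].shape == pytest.approx(1.4354050)

    def test_unit_hr_reproduces_baseline(self, ps):
        sg = SubgroupSpec(name="null", hr_os=1.0, hr_pfs=1.0)
        curves = subgroup_curves(ps, sg)
        assert curves["sidchm_os"] == ps.weibull["plchm_os"]
        assert curves["sidchm_pfs"] == ps.weibull["plchm_pfs"]

    def test_protective_hr_orders_survival(self, ps):
        sg = SubgroupSpec(name="good", hr_os=0.5, hr_pfs=0.5)
        curves = subgroup_curves(ps, sg)
        t = np.linspace(0.0, 150, 100)
        assert np.all(weibull_S(curves["sidchm_os"], t)
                      >= weibull_S(ps.weibull["plchm_os"], t))

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            SubgroupSpec(name="bad", hr_os=0.0, hr_pfs=0.5)
        with pytest.raises(ValueError):
            SubgroupSpec(name="bad", hr_os=0.5, hr_pfs=0.5, hr_os_ci=(0.9, 0.2))
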