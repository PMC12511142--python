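"""One-compartment closed forms against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vancoauc.pk_core import (
    PEAK_SAMPLING_LAG_H,
    Concentration,
    DomainError,
    DosingRegimen,
    OneCompParams,
    auc24_1c,
    cpeak_first_1c,
    ctrough_ss_1c,
    one_comp_profile,
    regimen_dose_times,
)


def random_case(rng):
    tau = float(rng.choice([8.0, 12.0, 24.0]))
    t_in = float(rng.choice([1.0, 1.5, 2.0]))
    regimen = DosingRegimen(
        first_dose=float(rng.uniform(500, 2000)),
        maintenance_dose=float(rng.uniform(250, 1500)),
        tau=tau,
        t_in=t_in,
        t_in_first=float(rng.choice([1.0, 1.5, 2.0])),
    )
    params = OneCompParams(
        ke=float(rng.uniform(0.02, 0.4)), vd=float(rng.uniform(20, 90))
    )
    return regimen, params


class TestClosedFormsVsSuperposition:
    """Eqs. for peak, trough and AUC must match brute-force superposition."""

    def test_peak_matches_profile_at_sampling_time(self):
        regimen = DosingRegimen(
            first_dose=1500, maintenance_dose=1000, tau=12, t_in=1.5, t_in_first=1.5
        )
        params = OneCompParams(ke=0.1, vd=50)
        t = np.array([regimen.t_in_first + PEAK_SAMPLING_LAG_H])
        profile_value = one_comp_profile(
            [(0.0, regimen.first_dose, regimen.t_in_first)], params, t
        )[0]
        assert cpeak_first_1c(regimen, params).value == pytest.approx(
            profile_value, abs=1e-9
        )

    def test_trough_matches_multidose_superposition(self):
        regimen = DosingRegimen(
            first_dose=1000, maintenance_dose=1000, tau=12, t_in=1
        )
        params = OneCompParams(ke=0.1, vd=50)
        n_doses = 250
        doses = [
            (k * regimen.tau, regimen.maintenance_dose, regimen.t_in)
            for k in range(n_doses)
        ]
        t_end = n_doses * regimen.tau
        brute = one_comp_profile(doses, params, np.array([t_end]))[0]
        assert ctrough_ss_1c(regimen, params).value == pytest.approx(brute, abs=1e-9)

    def test_auc_matches_trapezoid_over_steady_interval(self):
        regimen = DosingRegimen(
            first_dose=750, maintenance_dose=750, tau=12, t_in=1
        )
        params = OneCompParams(ke=0.12, vd=45)
        n = 200
        doses = [
            (k * regimen.tau, regimen.maintenance_dose, regimen.t_in) for k in range(n)
        ]
        t0, t1 = (n - 2) * regimen.tau, (n - 1) * regimen.tau
        times = np.arange(t0, t1 + 0.005, 0.01)
        conc = one_comp_profile(doses, params, times)
        auc_interval = np.trapezoid(conc, times)
        assert auc24_1c(regimen, params) == pytest.approx(
            auc_interval * 24.0 / regimen.tau, rel=1e-3
        )

    def test_hundred_random_parameter_sets(self, rng):
        """All three closed forms within 0.1% of the numeric oracle."""
        for _ in range(100):
            regimen, params = random_case(rng)
            # peak: single-dose profile at the sampling instant
            t_peak = regimen.t_in_first + PEAK_SAMPLING_LAG_H
            peak_oracle = one_comp_profile(
                [(0.0, regimen.first_dose, regimen.t_in_first)],
                params,
                np.array([t_peak]),
            )[0]
            assert cpeak_first_1c(regimen, params).value == pytest.approx(
                peak_oracle, rel=1e-3
            )
            # trough: superpose enough doses to be at steady state
            n = max(250, int(20.0 / (params.ke * regimen.tau)) + 10)
            doses = [
                (k * regimen.tau, regimen.maintenance_dose, regimen.t_in)
                for k in range(n)
            ]
            trough_oracle = one_comp_profile(
                doses, params, np.array([n * regimen.tau])
            )[0]
            assert ctrough_ss_1c(regimen, params).value == pytest.approx(
                trough_oracle, rel=1e-3
            )
            # AUC: trapezoid over one steady-state interval, scaled to 24 h
            t0, t1 = (n - 2) * regimen.tau, (n - 1) * regimen.tau
            times = np.union1d(
                np.arange(t0, t1 + 0.005, 0.01),
                [t0 + regimen.t_in],
            )
            auc_oracle = (
                np.trapezoid(one_comp_profile(doses, params, times), times)
                * 24.0
                / regimen.tau
            )
            assert auc24_1c(regimen, params) == pytest.approx(auc_oracle, rel=1e-3)


class TestLimitsAndInvariants:
    def test_zero_elimination_peak_is_dose_over_volume(self):
        regimen = DosingRegimen(first_dose=1000, maintenance_dose=500, tau=12, t_in=1)
        params = OneCompParams(ke=1e-8, vd=50)
        assert cpeak_first_1c(regimen, params).value == pytest.approx(
            1000 / 50, rel=1e-6
        )

    def test_huge_interval_trough_converges_to_single_dose(self):
        params = OneCompParams(ke=0.1, vd=50)
        tau = 1e6
        regimen = DosingRegimen(
            first_dose=1000, maintenance_dose=1000, tau=tau, t_in=1
        )
        single = (
            1000
            / (0.1 * 50 * 1.0)
            * (1 - math.exp(-0.1 * 1.0))
            * math.exp(-0.1 * (tau - 1.0))
        )
        assert ctrough_ss_1c(regimen, params).value == pytest.approx(single, rel=1e-9)

    def test_trough_strictly_decreasing_in_ke(self):
        regimen = DosingRegimen(first_dose=1000, maintenance_dose=1000, tau=12, t_in=1)
        kes = np.linspace(0.02, 1.0, 40)
        troughs = [
            ctrough_ss_1c(regimen, OneCompParams(ke=k, vd=50)).value for k in kes
        ]
        assert np.all(np.diff(troughs) < 0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_dose_linearity(self, scale):
        base = DosingRegimen(first_dose=1000, maintenance_dose=750, tau=12, t_in=1)
        scaled = DosingRegimen(
            first_dose=1000 * scale, maintenance_dose=750 * scale, tau=12, t_in=1
        )
        params = OneCompParams(ke=0.15, vd=40)
        assert cpeak_first_1c(scaled, params).value == pytest.approx(
            scale * cpeak_first_1c(base, params).value, rel=1e-12
        )
        assert ctrough_ss_1c(scaled, params).value == pytest.approx(
            scale * ctrough_ss_1c(base, params).value, rel=1e-12
        )
        assert auc24_1c(scaled, params) == pytest.approx(
            scale * auc24_1c(base, params), rel=1e-12
        )

    def test_steady_state_mass_balance(self):
        """AUC over one interval times clearance equals the dose, exactly."""
        regimen = DosingRegimen(first_dose=500, maintenance_dose=500, tau=24, t_in=1)
        params = OneCompParams(ke=0.1, vd=50)
        auc_interval = auc24_1c(regimen, params) * regimen.tau / 24.0
        assert auc_interval * params.cl == pytest.approx(
            regimen.maintenance_dose, rel=1e-12
        )

    def test_auc_worked_examples(self):
        params = OneCompParams(ke=0.1, vd=50)  # CL = 5 L/h
        q24 = DosingRegimen(first_dose=500, maintenance_dose=500, tau=24, t_in=1)
        q12 = DosingRegimen(first_dose=500, maintenance_dose=500, tau=12, t_in=1)
        assert auc24_1c(q24, params) == pytest.approx(100.0)
        assert auc24_1c(q12, params) == pytest.approx(200.0)


class TestDomainValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(first_dose=-1, maintenance_dose=500, tau=12, t_in=1),
            dict(first_dose=500, maintenance_dose=0, tau=12, t_in=1),
            dict(first_dose=500, maintenance_dose=500, tau=12, t_in=12),
            dict(first_dose=500, maintenance_dose=500, tau=0, t_in=1),
        ],
    )
    def test_invalid_regimen_rejected(self, kwargs):
        with pytest.raises(DomainError):
            DosingRegimen(**kwargs)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            OneCompParams(ke=0.0, vd=50)
        with pytest.raises(DomainError):
            OneCompParams(ke=0.1, vd=-5)
        with pytest.raises(DomainError):
            Concentration(-0.1)

    def test_default_first_infusion_time(self):
        regimen = DosingRegimen(first_dose=1000, maintenance_dose=500, tau=12, t_in=1)
        assert regimen.t_in_first == 1.0

    def test_dose_schedule_layout(self):
        regimen = DosingRegimen(
            first_dose=1750, maintenance_dose=1000, tau=12, t_in=1, t_in_first=2
        )
        doses = regimen_dose_times(regimen, 120.0)
        assert doses[0] == (0.0, 1750.0, 2.0)
        assert doses[1] == (12.0, 1000.0, 1.0)
        assert len(doses) == 10  # loading dose plus maintenance at 12..108 h
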