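"""Forward kinetic models against closed forms and an independent ODE oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from dceleak import (
    ConcentrationCurve,
    TissueParams,
    default_vif_params,
    extended_parker_vif,
    mtofts_ct,
    patlak_ct,
    steady_state_ct,
    twocxm_ct,
)
from dceleak.errors import InvalidParameterError

VIF = default_vif_params()


def constant_cp(value=2.0, t_end=1200.0, dt=1.0):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return ConcentrationCurve(t, np.full_like(t, value))


def parker_cp(dt=0.1, t_end=1460.0):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return ConcentrationCurve(t, extended_parker_vif(t / 60.0, VIF))


def ode_twocxm(ca: ConcentrationCurve, p: TissueParams, t_eval_s):
    """Independent oracle: direct stiff integration of the mass-balance ODEs."""
    tm = ca.times / 60.0
    cai = interp1d(tm, ca.values, bounds_error=False, fill_value=(ca.values[0], ca.values[-1]))
    fp = p.fp_per_min

    def rhs(t, y):
        c_cap, c_e = y
        return [
            (fp * (cai(t) - c_cap) + p.ps * (c_e - c_cap)) / p.vp,
            p.ps * (c_cap - c_e) / p.ve,
        ]

    sol = solve_ivp(rhs, (tm[0], tm[-1]), [0.0, 0.0], t_eval=np.asarray(t_eval_s) / 60.0,
                    rtol=1e-8, atol=1e-13, method="LSODA")
    return p.vp * sol.y[0] + p.ve * sol.y[1]


class TestClosedForms:
    def test_steady_state_scaling(self):
        cp = constant_cp(2.0)
        assert np.all(steady_state_ct(cp, 0.0).values == 0.0)
        np.testing.assert_allclose(steady_state_ct(cp, 1.0).values, cp.values)
        np.testing.assert_allclose(steady_state_ct(cp, 0.006).values, 0.012)

    def test_patlak_constant_input_is_exact(self):
        cp = constant_cp(2.0)
        tm = cp.times / 60.0
        out = patlak_ct(cp, 0.006, 3e-4)
        np.testing.assert_allclose(out.values, 0.006 * 2.0 + 3e-4 * 2.0 * tm, rtol=1e-12)

    def test_patlak_reduces_to_steady_state(self):
        cp = parker_cp(dt=1.0)
        np.testing.assert_allclose(
            patlak_ct(cp, 0.006, 0.0).values, steady_state_ct(cp, 0.006).values
        )

    def test_mtofts_constant_input_closed_form(self):
        cp = constant_cp(2.0)
        tm = cp.times / 60.0
        kt, ve = 0.01, 0.2
        out = mtofts_ct(cp, 0.006, kt, ve)
        exact = 0.006 * 2.0 + ve * 2.0 * (1.0 - np.exp(-kt * tm / ve))
        np.testing.assert_allclose(out.values, exact, atol=1e-12)

    def test_mtofts_reduces_to_patlak_in_slow_leak_regime(self):
        # KTrans t / ve << 1: first-order backflux deficit is at most
        # KTrans * t / ve (exp kernel >= 1 - KTrans tau / ve), i.e. < 4%
        # at t = 24.3 min; the leakage terms must agree to that order.
        cp = parker_cp(dt=1.0)
        kt, ve, vp = 3e-4, 0.2, 0.006
        leak_p = patlak_ct(cp, vp, kt).values - vp * cp.values
        leak_m = mtofts_ct(cp, vp, kt, ve).values - vp * cp.values
        mask = leak_p > 1e-12
        rel = (leak_p[mask] - leak_m[mask]) / leak_p[mask]
        assert np.all(rel >= -1e-12)  # backflux only removes tracer
        assert np.max(rel) < kt * (cp.times[-1] / 60.0) / ve

    def test_twocxm_single_compartment_closed_form(self):
        cp = constant_cp(2.0, dt=0.1)
        p = TissueParams(fp=10.0, ps=0.0, vp=0.006, ve=0.2)
        tm = cp.times / 60.0
        exact = p.vp * 2.0 * (1.0 - np.exp(-p.fp_per_min * tm / p.vp))
        np.testing.assert_allclose(twocxm_ct(cp, p).values, exact, atol=1e-8)


class TestPatlakQuadrature:
    def test_fine_grid_integral_matches_adaptive_quadrature(self):
        """Patlak at t = 20 min on a 0.1-s grid vs adaptive quadrature of the VIF."""
        from scipy.integrate import quad

        fine = parker_cp(dt=0.1, t_end=1200.0)
        vp, kt = 0.006, 3e-4
        out = patlak_ct(fine, vp, kt)
        integral, _ = quad(lambda tm: extended_parker_vif(tm, VIF), 0.0, 20.0, limit=400)
        expected = vp * fine.values[-1] + kt * integral
        assert out.values[-1] == pytest.approx(expected, rel=1e-3)


class TestTwocxm:
    def test_zero_input_gives_zero_output(self):
        cp = ConcentrationCurve(np.arange(0.0, 100.0, 0.5), np.zeros(200))
        out = twocxm_ct(cp, TissueParams())
        np.testing.assert_array_equal(out.values, 0.0)

    def test_nonnegative_for_nonnegative_input(self):
        out = twocxm_ct(parker_cp(dt=0.5), TissueParams(fp=30, ps=1e-3, vp=0.01, ve=0.2))
        assert np.all(out.values >= -1e-15)

    def test_matches_ode_oracle_on_random_draws(self, rng):
        ca = parker_cp(dt=0.1, t_end=600.0)
        t_eval = 73.0 * np.arange(1, 9)
        for _ in range(20):
            p = TissueParams(
                fp=float(rng.uniform(10, 50)),
                ps=float(10 ** rng.uniform(-4, -2.5)),
                vp=float(rng.uniform(0.003, 0.05)),
                ve=float(rng.uniform(0.1, 0.4)),
            )
            idx = np.searchsorted(ca.times, t_eval)
            ana = twocxm_ct(ca, p).values[idx]
            ode = ode_twocxm(ca, p, t_eval)
            assert np.max(np.abs(ana - ode)) / np.max(np.abs(ode)) < 1e-3

    def test_high_flow_limit_matches_mtofts(self):
        ca = parker_cp(dt=0.1)
        p = TissueParams(fp=1e4, ps=3e-4, vp=0.006, ve=0.2)  # Fp = 100 min^-1
        # skip t = 0: the high-flow limit jumps to vp*Cp(0) instantaneously
        # while the 2CXM equilibrates over vp/Fp (milliseconds here)
        two = twocxm_ct(ca, p).values[1:]
        mt = mtofts_ct(ca, p.vp, p.ps, p.ve).values[1:]
        scale = np.max(np.abs(mt))
        assert np.max(np.abs(two - mt)) / scale < 0.005

    def test_invalid_volumes_raise(self):
        cp = constant_cp()
        with pytest.raises(InvalidParameterError):
            twocxm_ct(cp, TissueParams(fp=10, ps=1e-3, vp=0.0, ve=0.2))
        with pytest.raises(InvalidParameterError):
            mtofts_ct(cp, 0.01, 1e-3, 0.0)
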