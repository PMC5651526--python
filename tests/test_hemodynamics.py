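"""Reduced momentum solver vs Poiseuille/Womersley closed forms."""

import numpy as np
import pytest

import hemotherm as ht
from hemotherm.hemodynamics import relax_profile, solve_steady_profile
from hemotherm.oracles import womersley_profile
from hemotherm.waveforms import FlowWaveform

NEWTONIAN = ht.CarreauYasudaParams(mu0=0.0035, mu_inf=0.0035)
Q = 8.333e-5


def _ratio(grid, vf):
    w = grid.fluid.row_area
    return vf.u[:, 0].max() / (w @ vf.u[:, 0] / w.sum())


class TestSteady:
    def test_poiseuille_pipe_ratio(self):
        _, grid, _ = ht.build_design("base64", 6.0,
                                     {"mode": "axisymmetric_pipe",
                                      "n_transverse": 48})
        vf = solve_steady_profile(Q, grid, NEWTONIAN)
        assert _ratio(grid, vf) == pytest.approx(2.0, rel=5e-3)

    def test_poiseuille_channel_ratio(self):
        _, grid, _ = ht.build_design("base64", 6.0, {"n_transverse": 48})
        vf = solve_steady_profile(Q, grid, NEWTONIAN)
        assert _ratio(grid, vf) == pytest.approx(1.5, rel=5e-3)

    def test_flow_constraint_to_roundoff(self):
        _, grid, _ = ht.build_design("base64", 4.0)
        vf = solve_steady_profile(Q, grid, ht.BLOOD_CY)
        q = float(grid.fluid.row_area @ vf.u[:, 0])
        assert abs(q - Q) / Q < 1e-6

    def test_carreau_yasuda_blunted_profile(self):
        """Shear-thinning pipe flow vs a shooting oracle: the stress is
        linear in r, so mu(g)*g = |G| r/2 can be inverted per radius."""
        from scipy.optimize import brentq
        _, grid, _ = ht.build_design("base64", 6.0,
                                     {"mode": "axisymmetric_pipe",
                                      "n_transverse": 48})
        vf = solve_steady_profile(Q, grid, ht.BLOOD_CY)
        assert _ratio(grid, vf) < 2.0

        R = grid.fluid.yf[-1]
        G = abs(vf.g[0])

        def gamma_of(r):
            tau = G * r / 2.0
            if tau == 0:
                return 0.0
            return brentq(lambda g: ht.cy_viscosity(g) * g - tau,
                          0.0, tau / ht.BLOOD_CY.mu_inf * 1.01)

        # fine-grid integration of du/dr = -gamma from the wall inward
        rr = np.linspace(R, 0.0, 4001)
        gam = np.array([gamma_of(abs(r)) for r in rr])
        u_oracle = np.concatenate([[0.0], np.cumsum(
            0.5 * (gam[1:] + gam[:-1]) * -np.diff(rr))])
        u_interp = np.interp(grid.fluid.yc, rr[::-1], u_oracle[::-1])
        err = np.max(np.abs(vf.u[:, 0] - u_interp)) / u_oracle.max()
        assert err < 0.01

    def test_invalid_flow(self):
        _, grid, _ = ht.build_design("base64", 4.0)
        with pytest.raises(ValueError):
            solve_steady_profile(-1.0, grid, ht.BLOOD_CY)


class TestUnsteady:
    def test_constant_waveform_recovers_steady(self):
        _, grid, _ = ht.build_design("base64", 4.0, {"n_transverse": 24})
        t = np.arange(50) / 50.0
        wave = FlowWaveform(period=1.0, times=t, q=np.full(50, Q), mean_q=Q)
        vf = ht.solve_unsteady_profile(wave, grid, ht.BLOOD_CY, n_cycles=3,
                                       dt_bounds=(1e-8, 5e-3))
        steady = solve_steady_profile(Q, grid, ht.BLOOD_CY)
        assert np.max(np.abs(vf.u - steady.u[:, :1])) < 1e-6

    def test_womersley_profile_match(self, womersley_case):
        """alpha ~ 15 oscillatory pipe flow within 1% of the Bessel form."""
        c = womersley_case
        peak = np.max(np.abs(c["analytic"]))
        rms = np.sqrt(np.mean((c["vf"].u - c["analytic"]) ** 2, axis=0))
        assert np.max(rms) / peak < 0.01

    def test_continuity_at_every_saved_instant(self, base64_run):
        vf, wave = base64_run["vf"], base64_run["wave"]
        q = vf.flow()
        target = wave(vf.times)
        assert np.max(np.abs(q - target)) < 1e-3 * np.max(np.abs(target))

    def test_reversal_timing_matches_womersley(self):
        """Wall shear sign change within one output step of the oracle."""
        params = NEWTONIAN
        _, grid, _ = ht.build_design(
            "base64", 6.0, {"mode": "axisymmetric_pipe", "n_transverse": 32,
                            "lumen_diameter": 0.006})
        R = grid.fluid.yf[-1]
        period, q0, q1 = 1.0, 3.0e-6, 8.0e-6  # q1 > q0: reversing lobe
        omega0 = 2 * np.pi / period
        t = np.arange(100) / 100.0
        wave = FlowWaveform(period=period, times=t,
                            q=q0 + q1 * np.cos(omega0 * t), mean_q=q0)
        vf = ht.solve_unsteady_profile(wave, grid, params, n_cycles=12,
                                       dt_bounds=(1e-8, 1e-3), u_tol=1e-6)
        # numerical wall shear sign from the near-wall cell
        dy = R - grid.fluid.yc[-1]
        shear_num = -vf.u[-1, :] / dy
        eps = 1e-6
        shear_an = np.array([
            (womersley_profile({0: q0, 1: q1}, omega0,
                               np.array([R - eps]), R, 0.0035, 1050.0, tp)[0])
            / -eps for tp in vf.times])
        sign_flips_num = np.nonzero(np.diff(np.sign(shear_num)))[0]
        sign_flips_an = np.nonzero(np.diff(np.sign(shear_an)))[0]
        assert sign_flips_an.size == sign_flips_num.size > 0
        assert np.max(np.abs(sign_flips_an - sign_flips_num)) <= 1

    def test_viscous_dissipation_monotone(self):
        _, grid, _ = ht.build_design("base64", 4.0, {"n_transverse": 24})
        steady = solve_steady_profile(Q, grid, ht.BLOOD_CY)
        ke = relax_profile(steady.u[:, 0], grid, ht.BLOOD_CY, t_end=0.2)
        assert np.all(np.diff(ke) < 0)

    def test_second_order_transverse_convergence(self):
        """Error vs the Womersley oracle drops ~4x when n doubles."""
        params = NEWTONIAN
        period, q0, q1 = 1.0, 5.0e-6, 3.0e-6
        omega0 = 2 * np.pi / period
        t = np.arange(100) / 100.0
        errs = []
        for n in (12, 24):
            _, grid, _ = ht.build_design(
                "base64", 6.0, {"mode": "axisymmetric_pipe",
                                "n_transverse": n, "lumen_diameter": 0.006})
            R = grid.fluid.yf[-1]
            wave = FlowWaveform(period=period, times=t,
                                q=q0 + q1 * np.cos(omega0 * t), mean_q=q0)
            vf = ht.solve_unsteady_profile(wave, grid, params, n_cycles=10,
                                           dt_bounds=(1e-8, 5e-4),
                                           u_tol=1e-7)
            an = np.empty_like(vf.u)
            for s, tp in enumerate(vf.times):
                an[:, s] = womersley_profile({0: q0, 1: q1}, omega0,
                                             grid.fluid.yc, R, 0.0035,
                                             1050.0, tp)
            errs.append(np.max(np.abs(vf.u - an)))
        order = np.log2(errs[0] / errs[1])
        assert order > 1.5

    def test_bad_dt_bounds(self, base64_run):
        with pytest.raises(ValueError):
            ht.solve_unsteady_profile(base64_run["wave"],
                                      base64_run["grid"], ht.BLOOD_CY,
                                      dt_bounds=(1e-9, 1e-1))
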