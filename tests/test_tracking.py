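"""Lagrangian cell tracking: drag, reflection, seeding, containment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hemotherm as ht
from hemotherm.geometry import FluidRegion
from hemotherm.hemodynamics import VelocityField
from hemotherm.thermal import TemperatureField
from hemotherm.tracking import (Cell, reflect, response_time, seed_cells,
                                track)


def _cell(kind="platelet", d=None):
    d = d if d is not None else {"platelet": 3e-6, "rbc": 7e-6}[kind]
    return Cell(kind=kind, d_p=d, rho_p=1050.0,
                position=np.zeros(2), velocity=np.zeros(2))


class TestResponseTime:
    def test_platelet_value(self):
        # rho*d^2/(18 mu) = 1050 * 9e-12 / (18 * 0.0035)
        assert response_time(_cell("platelet"), 0.0035) == pytest.approx(
            1.500e-7, rel=1e-3)

    def test_rbc_value(self):
        assert response_time(_cell("rbc"), 0.0035) == pytest.approx(
            8.167e-7, rel=1e-3)

    def test_quadratic_in_diameter(self):
        t1 = response_time(_cell(d=3e-6), 0.0035)
        t2 = response_time(_cell(d=6e-6), 0.0035)
        assert t2 == pytest.approx(4.0 * t1, rel=1e-12)

    def test_mass_consistency(self):
        c = _cell("rbc")
        assert c.m_p == pytest.approx(1050.0 * np.pi * (7e-6) ** 3 / 6.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            response_time(_cell(), 0.0)
        with pytest.raises(ValueError):
            Cell(kind="platelet", d_p=-1.0, rho_p=1050.0,
                 position=np.zeros(2), velocity=np.zeros(2))


class TestReflect:
    def test_normal_incidence(self):
        assert np.allclose(reflect(np.array([0.0, -1.0]),
                                   np.array([0.0, 1.0])), [0.0, 1.0])

    def test_45_degree_incidence(self):
        assert np.allclose(reflect(np.array([1.0, -1.0]),
                                   np.array([0.0, 1.0])), [1.0, 1.0])

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            reflect(np.array([1.0, 0.0]), np.array([0.0, 2.0]))

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_speed_and_tangential_preserved(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(2)
        n = rng.standard_normal(2)
        n /= np.linalg.norm(n)
        w = reflect(v, n)
        assert abs(np.linalg.norm(w) - np.linalg.norm(v)) < 1e-12
        tang = np.array([-n[1], n[0]])
        assert abs(tang @ w - tang @ v) < 1e-12


@pytest.fixture(scope="module")
def pipe():
    return ht.build_design("base64", 4.0, {"mode": "axisymmetric_pipe"})


class TestSeeding:
    def test_empty(self, pipe):
        geom, grid, _ = pipe
        assert seed_cells("platelet", 0, grid, geom, 1) == []

    def test_platelet_margination_ks(self, pipe):
        geom, grid, _ = pipe
        cells = seed_cells("platelet", 100_000, grid, geom, 5)
        R = grid.fluid.yf[-1]
        r = np.array([c.position[1] for c in cells]) / R
        # areal density ~ r^3 -> radial CDF (r/R)^5
        assert np.mean(r <= 0.5) == pytest.approx(0.03125, abs=0.003)
        ks = stats.kstest(r, lambda x: x**5)
        assert ks.pvalue > 0.01

    def test_rbc_uniform_chi2(self, pipe):
        geom, grid, _ = pipe
        cells = seed_cells("rbc", 100_000, grid, geom, 6)
        R = grid.fluid.yf[-1]
        r = np.array([c.position[1] for c in cells]) / R
        # equal-area annuli have edges sqrt(k/K)
        K = 20
        edges = np.sqrt(np.arange(K + 1) / K)
        counts, _ = np.histogram(r, bins=edges)
        chi2 = np.sum((counts - len(r) / K) ** 2 / (len(r) / K))
        assert chi2 < stats.chi2.ppf(0.99, K - 1)

    def test_seeded_on_exchanger_inlet(self, pipe):
        geom, grid, _ = pipe
        cells = seed_cells("rbc", 10, grid, geom, 7)
        assert all(c.position[0] == geom.exchanger_start for c in cells)

    def test_deterministic(self, pipe):
        geom, grid, _ = pipe
        a = seed_cells("platelet", 50, grid, geom, 9)
        b = seed_cells("platelet", 50, grid, geom, 9)
        assert np.allclose([c.position[1] for c in a],
                           [c.position[1] for c in b])

    def test_planar_fins_avoids_splitter(self):
        geom, grid, _ = ht.build_design("fins64", 4.0)
        cells = seed_cells("rbc", 5000, grid, geom, 3)
        f = grid.fluid
        b_lo = f.yf[np.nonzero(f.band)[0][0]]
        b_hi = f.yf[np.nonzero(f.band)[0][-1] + 1]
        ys = np.array([c.position[1] for c in cells])
        assert not np.any((ys > b_lo) & (ys < b_hi))

    def test_negative_count(self):
        geom, grid, _ = ht.build_design("base64", 4.0)
        with pytest.raises(ValueError):
            seed_cells("rbc", -1, grid, geom, 1)


def _uniform_flow_setup(u0=0.25):
    """Minimal planar grid + uniform velocity + uniform 37 C field."""
    geom, grid, hss = ht.build_design("base64", 2.0, {"n_transverse": 12})
    f = grid.fluid
    u = np.full((f.n, 1), u0)
    vf = VelocityField(fluid=f, times=np.array([0.0]), u=u,
                       g=np.array([0.0]), wall_shear=np.zeros((2, 1)))
    nt = 1
    T = np.full(grid.zone.shape + (nt,), np.nan)
    T[grid.active] = 37.0
    Tf = TemperatureField(T=T, saved_times=np.array([0.01]))
    return geom, grid, vf, Tf


class TestTrack:
    def test_exponential_relaxation_against_closed_form(self):
        """Heavy tracer released at rest: position follows the analytic
        solution of the linear drag ODE to better than 0.1%."""
        geom, grid, vf, Tf = _uniform_flow_setup(u0=0.25)
        u0 = 0.25
        d = 1e-3  # heavy tracer: tau ~ 0.36 ms at mu0
        cell = Cell(kind="platelet", d_p=d, rho_p=1050.0,
                    position=np.array([geom.exchanger_start,
                                       geom.lumen_size / 2]),
                    velocity=np.zeros(2))
        tau = response_time(cell, ht.BLOOD_CY.mu0)  # zero shear -> mu0
        trajs = track([cell], vf, Tf, grid, geom, n_cycles=1,
                      discard_first=False, dt=5e-5)
        tr = trajs[0]
        x_an = geom.exchanger_start + u0 * tr.times \
            - u0 * tau * (1.0 - np.exp(-tr.times / tau))
        err = np.max(np.abs(tr.xs - x_an)) / (u0 * tr.times[-1])
        assert err < 1e-3

    def test_drag_equilibrium_tracer_limit(self):
        """A micron-scale cell tracks the fluid to within ~10 tau |u|."""
        geom, grid, vf, Tf = _uniform_flow_setup(u0=0.25)
        cell = _cell("platelet")
        cell.position = np.array([geom.exchanger_start,
                                  geom.lumen_size / 2])
        trajs = track([cell], vf, Tf, grid, geom, n_cycles=1,
                      discard_first=False)
        tr = trajs[0]
        tau = response_time(cell, ht.BLOOD_CY.mu0)
        bound = 10.0 * tau * 0.25 + 1e-12
        drift = np.abs(tr.xs - (geom.exchanger_start + 0.25 * tr.times))
        assert np.max(drift) < max(bound, 1e-9)

    def test_population_containment_and_exit(self, base64_run,
                                             base64_tracks):
        grid = base64_run["grid"]
        lo, hi = grid.fluid.yf[0], grid.fluid.yf[-1]
        for tr in base64_tracks["trajectories"]:
            assert tr.exit_status in ("outlet", "max_time")
            if tr.times.size:
                assert np.all(np.diff(tr.times) > 0)
                assert np.all((tr.ys >= lo - 1e-12) & (tr.ys <= hi + 1e-12))

    def test_platelets_sample_hotter_than_rbc(self, base64_tracks):
        """Margination exposes platelets to the hot near-wall layer."""
        maxT = {"platelet": [], "rbc": []}
        for tr in base64_tracks["trajectories"]:
            if tr.T.size:
                maxT[tr.kind].append(np.nanmax(tr.T))
        p = np.array(maxT["platelet"])
        r = np.array(maxT["rbc"])
        # stochastic dominance in the upper tail
        for q in (50, 75, 90):
            assert np.percentile(p, q) >= np.percentile(r, q) - 1e-6
        assert p.mean() > r.mean()
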