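"""Shared fixtures: desk-scale pipeline runs of the exchanger designs.

The heavy fixtures run each design once per session at a reduced test
resolution (4 axial cells/cm, 36 transverse fluid cells) and are shared by
the module tests and the acceptance suite.
"""

import numpy as np
import pytest

import hemotherm as ht

TEST_RES = 4.0
TEST_OVERRIDES = {"n_transverse": 36}
FLOW_DT = 5e-3
THERMAL_TOL = 0.02


def run_design(design: str, seed: int = 1, resolution: float = TEST_RES,
               overrides: dict | None = None) -> dict:
    """Steady+periodic conjugate solve of one design at test scale."""
    ov = dict(TEST_OVERRIDES)
    ov.update(overrides or {})
    geom, grid, hss = ht.build_design(design, resolution, ov)
    src = ht.map_power_to_surrogate(hss, geom, grid)
    wave = ht.descending_fraction(ht.make_inlet_waveform(seed=seed), 0.7)
    vf = ht.solve_unsteady_profile(wave, grid, ht.BLOOD_CY, n_cycles=30,
                                   dt_bounds=(1e-8, FLOW_DT))
    Tf, rep = ht.solve_transient(grid, vf, src, 37.0, max_cycles=40,
                                 tol=THERMAL_TOL)
    return dict(design=design, geom=geom, grid=grid, hss=hss, src=src,
                wave=wave, vf=vf, Tf=Tf, rep=rep)


def track_design(run: dict, n_plt: int = 500, n_rbc: int = 500) -> dict:
    plts = ht.seed_cells("platelet", n_plt, run["grid"], run["geom"], 11,
                         run["vf"])
    rbcs = ht.seed_cells("rbc", n_rbc, run["grid"], run["geom"], 12,
                         run["vf"])
    trajs = ht.track(plts + rbcs, run["vf"], run["Tf"], run["grid"],
                     run["geom"], n_cycles=10, discard_first=True)
    recs = ht.tei_records(trajs)
    return dict(trajectories=trajs, records=recs)


@pytest.fixture(scope="session")
def base64_run():
    return run_design("base64")


@pytest.fixture(scope="session")
def base24_run():
    return run_design("base24")


@pytest.fixture(scope="session")
def fins64_run():
    return run_design("fins64")


@pytest.fixture(scope="session")
def finsguide64_run():
    return run_design("finsguide64")


@pytest.fixture(scope="session")
def base64_tracks(base64_run):
    return track_design(base64_run)


@pytest.fixture(scope="session")
def fins64_tracks(fins64_run):
    return track_design(fins64_run)


@pytest.fixture(scope="session")
def finsguide64_tracks(finsguide64_run):
    return track_design(finsguide64_run)


@pytest.fixture(scope="session")
def womersley_case():
    """Newtonian sinusoidal pipe flow vs the Bessel-function closed form."""
    from hemotherm.oracles import womersley_profile
    from hemotherm.waveforms import FlowWaveform

    params = ht.CarreauYasudaParams(mu0=0.0035, mu_inf=0.0035)
    _, grid, _ = ht.build_design("base64", 6.0,
                                 {"mode": "axisymmetric_pipe",
                                  "n_transverse": 64})
    R = grid.fluid.yf[-1]
    period, q0, q1 = 1.0, 8.333e-5, 6.0e-5
    omega0 = 2.0 * np.pi / period
    t = np.arange(200) / 200.0
    wave = FlowWaveform(period=period, times=t,
                        q=q0 + q1 * np.cos(omega0 * t), mean_q=q0)
    vf = ht.solve_unsteady_profile(wave, grid, params, n_cycles=40,
                                   dt_bounds=(1e-8, 1e-3), u_tol=1e-5)
    analytic = np.empty_like(vf.u)
    for s, tp in enumerate(vf.times):
        analytic[:, s] = womersley_profile({0: q0, 1: q1}, omega0,
                                           grid.fluid.yc, R, 0.0035,
                                           1050.0, tp)
    return dict(grid=grid, vf=vf, analytic=analytic, R=R,
                params=params, wave=wave)
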