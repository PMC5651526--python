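"""Independent closed-form references used by the validation suite.

Every function here is a pure analytic (or brute-force quadrature) result
with no dependence on the solver modules, so tests never compare an
implementation against itself: Poiseuille and Womersley profiles for the
reduced momentum equation, developed-region Graetz Nusselt numbers for the
energy equation in the fluid, and the eigenfunction series for transient
slab conduction in the solids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

__all__ = ["OracleResult", "poiseuille_profile", "womersley_profile",
           "graetz_nusselt", "slab_conduction"]


@dataclass(frozen=True)
class OracleResult:
    """Outcome of one computed-vs-closed-form comparison."""

    name: str
    computed: float
    reference: float
    tolerance: float
    passed: bool


def poiseuille_profile(q: float, coords: np.ndarray, size: float,
                       mode: str = "axisymmetric_pipe",
                       depth: float | None = None) -> np.ndarray:
    """Newtonian fully developed profile carrying flow ``q``.

    ``coords`` are radii (pipe of radius ``size``) or transverse positions
    (planar channel of height ``size`` and out-of-plane ``depth``).
    Pipe: u = 2*u_mean*(1 - (r/R)^2); channel: u = 6*u_mean*(y/H)(1 - y/H).
    """
    if mode == "axisymmetric_pipe":
        R = size
        u_mean = q / (math.pi * R**2)
        return 2.0 * u_mean * (1.0 - (coords / R) ** 2)
    H = size
    u_mean = q / (H * depth)
    s = coords / H
    return 6.0 * u_mean * s * (1.0 - s)


def womersley_profile(q_harmonics: dict[int, complex], omega0: float,
                      coords: np.ndarray, R: float, mu: float, rho: float,
                      t: float) -> np.ndarray:
    """Pulsatile Newtonian pipe flow from a harmonic flow decomposition.

    ``q_harmonics`` maps harmonic index k -> complex amplitude Q_k of the
    flow expansion  Q(t) = Re( sum_k Q_k exp(i k omega0 t) )  (k = 0 is the
    steady component with real Q_0).  Each harmonic uses the Bessel-function
    solution of oscillatory laminar pipe flow, scaled so its flow integral
    matches Q_k exactly; the zero-frequency term is Poiseuille.
    """
    r = np.asarray(coords, dtype=float)
    u = np.zeros_like(r, dtype=complex)
    for k, Qk in q_harmonics.items():
        if k == 0:
            u += poiseuille_profile(float(np.real(Qk)), r, R)
            continue
        omega = k * omega0
        alpha = R * math.sqrt(omega * rho / mu)
        lam = alpha * np.exp(1j * 3.0 * math.pi / 4.0)  # i^{3/2} alpha
        j0w = jv(0, lam)
        shape = 1.0 - jv(0, lam * r / R) / j0w
        # flow integral of `shape` over the cross-section
        flow_shape = math.pi * R**2 * (1.0 - 2.0 * jv(1, lam) / (lam * j0w))
        u += (Qk / flow_shape) * shape * np.exp(1j * omega * t)
    return np.real(u)


def graetz_nusselt(geom_mode: str) -> float:
    """Developed-region Nusselt number for constant-flux heating.

    Pipe (uniform wall flux): Nu_D = 48/11 = 4.364 with D the diameter.
    Parallel plates, one side heated / one adiabatic: Nu = 5.385 with the
    hydraulic diameter 2H.  Both are flow-rate independent.
    """
    if geom_mode == "axisymmetric_pipe":
        return 48.0 / 11.0
    if geom_mode == "planar_channel":
        return 5.385
    raise ValueError(f"unknown geometry mode {geom_mode!r}")


def slab_conduction(x: np.ndarray, t: float, L: float, k: float, rho: float,
                    cp: float, flux: float, T0: float = 0.0,
                    n_terms: int = 200) -> np.ndarray:
    """Transient slab with constant flux at x = L, insulated at x = 0.

    Eigenfunction series (truncation error < 1e-8 for the returned times):

      T - T0 = (F L / k) [ a t / L^2 + (3 x^2 - L^2)/(6 L^2)
               - (2/pi^2) sum (-1)^n / n^2 exp(-a n^2 pi^2 t / L^2)
                 cos(n pi x / L) ]

    with thermal diffusivity a = k/(rho*cp).
    """
    x = np.asarray(x, dtype=float)
    a = k / (rho * cp)
    tau = a * t / L**2
    xi = x / L
    series = np.zeros_like(xi)
    for n in range(1, n_terms + 1):
        term = ((-1.0) ** n / n**2) * math.exp(-(n * math.pi) ** 2 * tau) \
            * np.cos(n * math.pi * xi)
        series += term
        if abs(term).max() < 1e-12 and n > 10:
            break
    theta = tau + (3.0 * xi**2 - 1.0) / 6.0 - (2.0 / math.pi**2) * series
    return T0 + flux * L / k * theta
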