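"""Blood rheology and thermal material properties.

Blood is treated as an incompressible shear-thinning fluid following the
Carreau–Yasuda law

    mu(gamma_dot) = mu_inf + (mu_0 - mu_inf) * [1 + (lam*gamma_dot)**a]**((n-1)/a)

which interpolates between the zero-shear viscosity ``mu_0`` and the
infinite-shear viscosity ``mu_inf`` with time constant ``lam`` and exponents
``n`` (power index) and ``a`` (transition sharpness).  The thermal side of the
model needs density, specific heat and conductivity for the four zone
materials (blood plus the titanium conduit, aluminum housing and copper heat
guide); those are kept in a small built-in table that a YAML config may
override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "MaterialProps",
    "BLOOD_CY",
    "cy_viscosity",
    "get_material",
    "MATERIALS",
]


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Carreau–Yasuda constants plus blood density.

    Units: viscosities in Pa*s, ``lam`` in s, ``n`` and ``a`` dimensionless,
    ``rho_b`` in kg/m^3.
    """

    mu0: float = 0.16
    mu_inf: float = 0.0035
    lam: float = 8.2
    n: float = 0.2128
    a: float = 0.64
    rho_b: float = 1050.0

    def __post_init__(self) -> None:
        if not (self.mu0 >= self.mu_inf > 0.0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam <= 0.0:
            raise ValueError("lam must be positive")
        if self.a <= 0.0:
            raise ValueError("a must be positive")
        if not (0.0 < self.n <= 1.0):
            raise ValueError("n must lie in (0, 1]")
        if self.rho_b <= 0.0:
            raise ValueError("rho_b must be positive")

    @property
    def newtonian(self) -> bool:
        return self.mu0 == self.mu_inf


#: Default human-blood constants.
BLOOD_CY = CarreauYasudaParams()


@dataclass(frozen=True)
class MaterialProps:
    """Density, specific heat and thermal conductivity of a zone material."""

    name: str
    rho: float  # kg/m^3
    cp: float  # J/(kg K)
    k: float  # W/(m K)

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.k) <= 0.0:
            raise ValueError("rho, cp and k must all be positive")


# Specific heats and conductivities for the exchanger materials; solid
# densities are handbook values (steady fields do not depend on them, they
# only set the transient heat storage of each zone).
MATERIALS: dict[str, MaterialProps] = {
    "aluminum": MaterialProps("aluminum", rho=2700.0, cp=900.0, k=238.0),
    "titanium": MaterialProps("titanium", rho=4506.0, cp=710.0, k=7.5),
    "copper": MaterialProps("copper", rho=8960.0, cp=385.0, k=400.0),
    "blood": MaterialProps("blood", rho=1050.0, cp=3650.0, k=0.5),
}


def cy_viscosity(gamma_dot, params: CarreauYasudaParams = BLOOD_CY):
    """Carreau–Yasuda viscosity at shear rate ``gamma_dot`` (1/s).

    Accepts scalars or arrays; returns Pa*s.  The law is continuous,
    non-increasing in shear rate and bounded by [mu_inf, mu0].
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    if np.isscalar(gamma_dot):
        return float(mu)
    return mu


def get_material(name: str, overrides: dict | None = None) -> MaterialProps:
    """Look up a zone material, optionally overriding fields from config.

    ``overrides`` maps material name -> dict of field overrides, e.g.
    ``{"aluminum": {"rho": 2710.0}}``.
    """
    try:
        base = MATERIALS[name]
    except KeyError:
        raise ValueError(
            f"unknown material {name!r}; expected one of {sorted(MATERIALS)}"
        ) from None
    if overrides and name in overrides:
        fields = {"rho": base.rho, "cp": base.cp, "k": base.k}
        fields.update(overrides[name])
        return MaterialProps(name, **fields)
    return base
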