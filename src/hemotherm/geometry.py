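"""Reduced-dimension zoned grids for the heat-exchanger designs.

The full 3-D aorta/exchanger assembly is replaced by two desk-scale
surrogates that keep every governing equation:

* ``planar_channel`` — a 2-D (axial x, transverse y) channel of height equal
  to the lumen diameter, with independent solid stacks on the near side
  (facing the heat source) and the far side.  An effective out-of-plane depth
  of half the lumen perimeter carries the full descending-aorta flow and the
  full source power, preserving the mixed (bulk) temperature rise
  P0/(rho_b*cp_b*Qbar).  This mode resolves the near/far asymmetry, the fin
  splitter and the copper heat guide.
* ``axisymmetric_pipe`` — a 2-D (x, r) pipe with annular solid layers; used
  for closed-form checks (Poiseuille/Womersley/Graetz) and as an alternative
  surrogate for the base designs.

Zones: blood lumen, titanium conduit wall (and fin splitter), aluminum
housing, copper heat guide.  The heat source is a uniform-flux band on the
outer boundary of the near-side solid, centred at 50% of the exchanger
length, of axial extent equal to the source diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialProps, get_material

__all__ = [
    "HeatSourceSpec",
    "SurrogateGeometry",
    "FluidRegion",
    "Grid",
    "DESIGNS",
    "build_design",
    "build_slab",
    "source_flux",
    "map_power_to_surrogate",
]

# zone codes
INACTIVE, BLOOD, TITANIUM, ALUMINUM, COPPER = 0, 1, 2, 3, 4
ZONE_NAMES = {BLOOD: "blood", TITANIUM: "titanium",
              ALUMINUM: "aluminum", COPPER: "copper"}
_CODES = {v: k for k, v in ZONE_NAMES.items()}


@dataclass(frozen=True)
class HeatSourceSpec:
    """Cylindrical waste-heat source: total power and emitting surface.

    ``area`` is the lateral cylinder surface pi*d*h by default; set
    ``include_caps`` to add the two end discs.
    """

    power: float  # W
    diameter: float  # m
    height: float  # m
    include_caps: bool = False

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("power must be non-negative")
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("diameter and height must be positive")

    @property
    def area(self) -> float:
        a = math.pi * self.diameter * self.height
        if self.include_caps:
            a += math.pi * self.diameter**2 / 2.0
        return a

    @property
    def flux(self) -> float:
        return self.power / self.area


def source_flux(spec: HeatSourceSpec) -> float:
    """Nominal source surface flux P0/A in W/m^2."""
    if spec.area <= 0:
        raise ValueError("source area must be positive")
    return spec.flux


@dataclass(frozen=True)
class SurrogateGeometry:
    """Dimensions and design flags of the reduced exchanger model (SI)."""

    mode: str  # "planar_channel" | "axisymmetric_pipe"
    lumen_size: float  # channel height (planar) or pipe radius (axisymmetric)
    domain_length: float
    exchanger_start: float
    exchanger_length: float
    near_layers: tuple  # ((material, thickness), ...) lumen -> outward
    far_layers: tuple
    source_band: tuple  # (x_lo, x_hi)
    fins: bool = False
    fin_thickness: float = 0.002
    heat_guide: bool = False
    guide_thickness: float = 0.0025
    guide_lumen_standoff: float = 0.0015
    guide_source_standoff: float = 0.0025
    guide_margin: float = 0.01
    depth: float | None = None  # effective out-of-plane depth (planar)

    def __post_init__(self) -> None:
        if self.mode not in ("planar_channel", "axisymmetric_pipe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.exchanger_length <= 0 or self.lumen_size <= 0:
            raise ValueError("lengths must be positive")
        x0, x1 = self.exchanger_window
        if not (self.source_band[0] >= x0 - 1e-12
                and self.source_band[1] <= x1 + 1e-12):
            raise ValueError("source band must lie inside the exchanger")
        if self.fins and self.mode == "axisymmetric_pipe":
            raise ValueError("fin splitter requires planar_channel mode")
        if self.heat_guide and not self.mode == "planar_channel":
            raise ValueError("heat guide requires planar_channel mode")
        for layers in (self.near_layers, self.far_layers):
            for _, t in layers:
                if t <= 0:
                    raise ValueError("layer thicknesses must be positive")

    @property
    def exchanger_window(self) -> tuple[float, float]:
        return (self.exchanger_start,
                self.exchanger_start + self.exchanger_length)

    @property
    def inlet_run(self) -> float:
        return self.exchanger_start

    @property
    def outlet_run(self) -> float:
        return self.domain_length - self.exchanger_window[1]

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "lumen_size_m": self.lumen_size,
            "domain_length_m": self.domain_length,
            "exchanger_start_m": self.exchanger_start,
            "exchanger_length_m": self.exchanger_length,
            "near_layers": [[m, t] for m, t in self.near_layers],
            "far_layers": [[m, t] for m, t in self.far_layers],
            "source_band_m": list(self.source_band),
            "fins": self.fins,
            "fin_thickness_m": self.fin_thickness,
            "heat_guide": self.heat_guide,
        }
        if self.heat_guide:
            d.update({
                "guide_thickness_m": self.guide_thickness,
                "guide_lumen_standoff_m": self.guide_lumen_standoff,
                "guide_source_standoff_m": self.guide_source_standoff,
                "guide_margin_m": self.guide_margin,
            })
        if self.depth is not None:
            d["effective_depth_m"] = self.depth
        return d


@dataclass(frozen=True)
class FluidRegion:
    """Transverse discretisation of the lumen span of the grid.

    Rows flagged in ``band`` belong to the fin-splitter band: solid inside
    the exchanger window, stagnant fluid elsewhere; the reduced velocity
    profile is zero there at all axial stations.
    """

    mode: str
    yc: np.ndarray  # row centres (y or r)
    yf: np.ndarray  # row faces
    band: np.ndarray  # bool per row
    depth: float | None

    @property
    def n(self) -> int:
        return self.yc.size

    @property
    def row_area(self) -> np.ndarray:
        """Flow cross-section area of each row (m^2, includes depth)."""
        if self.mode == "planar_channel":
            return np.diff(self.yf) * self.depth
        return math.pi * (self.yf[1:] ** 2 - self.yf[:-1] ** 2)

    @property
    def wall_faces(self) -> np.ndarray:
        """Indices (into yf) of no-slip faces bounding open fluid rows."""
        open_rows = ~self.band
        faces = []
        for j in range(self.n + 1):
            lo = open_rows[j - 1] if j > 0 else False
            hi = open_rows[j] if j < self.n else False
            if lo != hi:
                faces.append(j)
        if self.mode == "axisymmetric_pipe" and 0 in faces:
            faces.remove(0)  # centreline is a symmetry face, not a wall
        return np.asarray(faces, dtype=int)


@dataclass
class Grid:
    """Structured zoned finite-volume grid (axial x transverse)."""

    mode: str
    xf: np.ndarray
    yf: np.ndarray
    zone: np.ndarray  # (nx, ny) int codes, 0 = inactive
    depth: float | None
    j_fluid0: int  # first row of the lumen span
    j_fluid1: int  # one past last row of the lumen span
    fluid: FluidRegion
    zone_props: dict[int, MaterialProps]
    exchanger_window: tuple[float, float]
    source_side: str = "low"  # "low": y-min boundary; "high": y-max boundary
    guide_links: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 4)))  # (i, j_near, j_far, G)

    # -- coordinate helpers ------------------------------------------------
    @property
    def nx(self) -> int:
        return self.xf.size - 1

    @property
    def ny(self) -> int:
        return self.yf.size - 1

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[:-1] + self.xf[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yf[:-1] + self.yf[1:])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.yf)

    @property
    def axial_area(self) -> np.ndarray:
        """Axial-face (cross-flow) area of each row, length ny."""
        if self.mode == "planar_channel":
            return self.dy * self.depth
        return math.pi * (self.yf[1:] ** 2 - self.yf[:-1] ** 2)

    def trans_area(self, jf: int) -> np.ndarray:
        """Transverse-face area at face jf for every column, length nx."""
        if self.mode == "planar_channel":
            return self.dx * self.depth
        return 2.0 * math.pi * self.yf[jf] * self.dx

    @property
    def volumes(self) -> np.ndarray:
        """Cell volumes, shape (nx, ny)."""
        return np.outer(self.dx, self.axial_area / 1.0) \
            if self.mode == "axisymmetric_pipe" \
            else np.outer(self.dx, self.dy) * self.depth

    @property
    def active(self) -> np.ndarray:
        return self.zone != INACTIVE

    @property
    def is_fluid(self) -> np.ndarray:
        return self.zone == BLOOD

    def zone_field(self, name: str) -> np.ndarray:
        """Per-cell material property (rho/cp/k); zeros where inactive."""
        out = np.zeros_like(self.zone, dtype=float)
        for code, props in self.zone_props.items():
            out[self.zone == code] = getattr(props, name)
        return out

    def source_faces(self, band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        """Columns overlapping ``band`` and their boundary-face areas.

        Areas account for partial overlap of edge columns.  The face sits on
        the source-side external boundary of the active solid (or of the
        fluid itself when no solid layers exist).
        """
        lo, hi = band
        x0 = np.maximum(self.xf[:-1], lo)
        x1 = np.minimum(self.xf[1:], hi)
        overlap = np.clip(x1 - x0, 0.0, None)
        cols = np.nonzero(overlap > 1e-14)[0]
        jf = 0 if self.source_side == "low" else self.ny
        area = self.trans_area(jf)[cols] * (overlap[cols] / self.dx[cols])
        return cols, area

    def boundary_row(self, side: str) -> int:
        """Row index adjacent to the low/high transverse boundary."""
        return 0 if side == "low" else self.ny - 1


# --------------------------------------------------------------------------
# design catalogue (SI units)

DESIGNS = {
    # power W, source diameter m, conductor thickness m, fins, guide
    "base64": dict(power=64.0, source_d=0.046, conductor_t=0.031,
                   fins=False, guide=False),
    "base24": dict(power=24.0, source_d=0.028, conductor_t=0.031,
                   fins=False, guide=False),
    "fins64": dict(power=64.0, source_d=0.046, conductor_t=0.031,
                   fins=True, guide=False),
    "finsguide64": dict(power=64.0, source_d=0.046, conductor_t=0.043,
                        fins=True, guide=True),
}

_SOURCE_HEIGHT = 0.01  # m, Table-level source height
_WALL_T = 0.001  # titanium conduit wall thickness (not printed; see docs)


def _both_ends_cluster(a: float, b: float, n: int) -> np.ndarray:
    xi = np.linspace(0.0, 1.0, n + 1)
    return a + (b - a) * 0.5 * (1.0 - np.cos(math.pi * xi))


def _wall_cluster_pipe(R: float, n: int) -> np.ndarray:
    xi = np.linspace(0.0, 1.0, n + 1)
    return R * np.sin(0.5 * math.pi * xi)


def _layer_faces(start: float, layers, resolution: float, direction: float):
    """Face coordinates and zone codes for a solid stack.

    ``direction`` +1 grows away from ``start`` upward, -1 downward.
    Returns faces ordered in the growth direction (excluding ``start``).
    """
    faces, codes = [], []
    pos = start
    for mat, t in layers:
        if mat == "titanium" or t <= 0.004:
            n = 2
        elif mat == "copper":
            n = 2
        else:
            n = max(3, int(round(t * 100.0 * resolution / 2.0)))
        sub = pos + direction * np.linspace(0.0, t, n + 1)[1:]
        faces.extend(sub.tolist())
        codes.extend([_CODES[mat]] * n)
        pos = pos + direction * t
    return np.asarray(faces), codes


def build_design(design: str, resolution: float = 8.0,
                 overrides: dict | None = None):
    """Build geometry, grid and source spec for a named exchanger design.

    Parameters
    ----------
    design : one of ``base64``, ``base24``, ``fins64``, ``finsguide64``.
    resolution : axial cells per cm (>= 2); also scales the transverse
        fluid discretisation unless ``n_transverse`` is overridden.
    overrides : optional config dict; recognised keys include ``mode``,
        ``lumen_diameter``, ``domain_length``, ``exchanger_start``,
        ``n_transverse``, ``wall_thickness``, ``power``, ``source_diameter``,
        ``source_height``, ``include_caps``, ``materials`` (property
        overrides per material name).

    Returns ``(SurrogateGeometry, Grid, HeatSourceSpec)``.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; "
                         f"expected one of {sorted(DESIGNS)}")
    if resolution < 2:
        raise ValueError("resolution must be at least 2 cells per cm")
    ov = dict(overrides or {})
    spec = DESIGNS[design]

    mode = ov.get("mode", "planar_channel")
    D = float(ov.get("lumen_diameter", 0.022))
    L = float(ov.get("domain_length", 0.23))
    ex_len = float(ov.get("exchanger_length", 0.10))
    x0 = float(ov.get("exchanger_start", 0.5 * (L - ex_len)))
    wall_t = float(ov.get("wall_thickness", _WALL_T))
    power = float(ov.get("power", spec["power"]))
    src_d = float(ov.get("source_diameter", spec["source_d"]))
    src_h = float(ov.get("source_height", _SOURCE_HEIGHT))
    cond_t = float(ov.get("conductor_thickness", spec["conductor_t"]))
    fins = bool(ov.get("fins", spec["fins"]))
    guide = bool(ov.get("guide", spec["guide"]))
    mat_ov = ov.get("materials")

    hss = HeatSourceSpec(power=power, diameter=src_d, height=src_h,
                         include_caps=bool(ov.get("include_caps", False)))
    x_mid = x0 + 0.5 * ex_len
    band = (x_mid - 0.5 * src_d, x_mid + 0.5 * src_d)

    # solid stacks, lumen outward
    if guide:
        gap = 0.0015 - wall_t  # copper sheet 0.15 cm off the lumen
        if gap < 0:
            raise ValueError("wall thicker than the guide lumen standoff")
        rest = cond_t - wall_t - gap - 0.0025
        stack = [("titanium", wall_t)]
        if gap > 0:
            stack.append(("aluminum", gap))
        stack += [("copper", 0.0025), ("aluminum", rest)]
        layers = tuple(stack)
    else:
        layers = (("titanium", wall_t), ("aluminum", cond_t - wall_t))

    if mode == "planar_channel":
        lumen = D
        depth = float(ov.get("depth", math.pi * D / 2.0))
        geom = SurrogateGeometry(
            mode=mode, lumen_size=lumen, domain_length=L, exchanger_start=x0,
            exchanger_length=ex_len, near_layers=layers, far_layers=layers,
            source_band=band, fins=fins, heat_guide=guide, depth=depth)
    else:
        if fins:
            raise ValueError("fins are a planar-channel feature")
        lumen = D / 2.0
        geom = SurrogateGeometry(
            mode=mode, lumen_size=lumen, domain_length=L, exchanger_start=x0,
            exchanger_length=ex_len, near_layers=(), far_layers=layers,
            source_band=band, fins=False, heat_guide=False, depth=None)

    grid = _build_grid(geom, resolution, ov, mat_ov)
    return geom, grid, hss


def _build_grid(geom: SurrogateGeometry, resolution: float,
                ov: dict, mat_ov) -> Grid:
    L = geom.domain_length
    nx = max(4, int(round(L * 100.0 * resolution)))
    xf = np.linspace(0.0, L, nx + 1)
    n_tr = int(ov.get("n_transverse",
                      max(12, int(round(2.0 * resolution * geom.lumen_size
                                        * 100.0 * (2 if geom.mode ==
                                                   "planar_channel" else 1))))))

    # --- transverse fluid faces -----------------------------------------
    if geom.mode == "planar_channel":
        H = geom.lumen_size
        if geom.fins:
            tf = geom.fin_thickness
            c = H / 2.0
            n_sub = max(6, n_tr // 2)
            f1 = _both_ends_cluster(0.0, c - tf / 2.0, n_sub)
            fb = np.array([c, c + tf / 2.0])
            f2 = _both_ends_cluster(c + tf / 2.0, H, n_sub)[1:]
            yf_fluid = np.concatenate([f1, fb, f2])
            band = np.zeros(yf_fluid.size - 1, bool)
            band[n_sub:n_sub + 2] = True
        else:
            yf_fluid = _both_ends_cluster(0.0, H, max(8, n_tr))
            band = np.zeros(yf_fluid.size - 1, bool)
    else:
        R = geom.lumen_size
        yf_fluid = _wall_cluster_pipe(R, max(8, n_tr))
        band = np.zeros(yf_fluid.size - 1, bool)

    # --- solid stacks ----------------------------------------------------
    near_faces, near_codes = (np.array([]), [])
    far_faces, far_codes = (np.array([]), [])
    if geom.mode == "planar_channel":
        if geom.near_layers:
            nf, nc = _layer_faces(0.0, geom.near_layers, resolution, -1.0)
            near_faces, near_codes = nf[::-1], nc[::-1]
        if geom.far_layers:
            far_faces, far_codes = _layer_faces(
                geom.lumen_size, geom.far_layers, resolution, +1.0)
    else:
        if geom.far_layers:
            far_faces, far_codes = _layer_faces(
                geom.lumen_size, geom.far_layers, resolution, +1.0)

    yf = np.concatenate([near_faces, yf_fluid, far_faces])
    ny = yf.size - 1
    n_near = len(near_codes)
    n_flu = yf_fluid.size - 1
    j0, j1 = n_near, n_near + n_flu

    # --- zone map --------------------------------------------------------
    zone = np.zeros((nx, ny), dtype=np.int8)
    xc = 0.5 * (xf[:-1] + xf[1:])
    x0, x1 = geom.exchanger_window
    in_ex = (xc > x0) & (xc < x1)

    zone[:, j0:j1] = BLOOD
    band_rows = j0 + np.nonzero(band)[0]
    for j in band_rows:
        zone[in_ex, j] = TITANIUM  # fin splitter within the exchanger

    solid_codes = list(near_codes) + [None] * n_flu + list(far_codes)
    for j, code in enumerate(solid_codes):
        if code is None:
            continue
        zone[in_ex, j] = code

    # copper sheet exists only away from the exchanger ends
    guide_links = np.zeros((0, 4))
    if geom.heat_guide:
        g0, g1 = x0 + geom.guide_margin, x1 - geom.guide_margin
        in_guide = (xc > g0) & (xc < g1)
        cu_rows = [j for j, code in enumerate(solid_codes) if code == COPPER]
        for j in cu_rows:
            zone[in_ex & ~in_guide, j] = ALUMINUM
        # circumferential wrap: copper strip connects near and far sides
        near_cu = [j for j in cu_rows if j < j0]
        far_cu = [j for j in cu_rows if j >= j1]
        if near_cu and far_cu:
            k_cu = get_material("copper", mat_ov).k
            wrap_len = math.pi * geom.lumen_size / 2.0
            dxv = np.diff(xf)
            links = []
            cols = np.nonzero(in_guide & in_ex)[0]
            m = min(len(near_cu), len(far_cu))
            for i in cols:
                G = 2.0 * k_cu * (geom.guide_thickness * dxv[i]) / wrap_len
                for jn, jfar in zip(near_cu[:m], far_cu[:m]):
                    links.append((i, jn, jfar, G / m))
            guide_links = np.asarray(links, dtype=float)

    fluid = FluidRegion(mode=geom.mode, yc=0.5 * (yf_fluid[:-1] + yf_fluid[1:]),
                        yf=yf_fluid, band=band, depth=geom.depth)
    zone_props = {code: get_material(name, mat_ov)
                  for code, name in ZONE_NAMES.items()}
    return Grid(mode=geom.mode, xf=xf, yf=yf, zone=zone, depth=geom.depth,
                j_fluid0=j0, j_fluid1=j1, fluid=fluid, zone_props=zone_props,
                exchanger_window=(x0, x1),
                source_side="low" if geom.mode == "planar_channel" else "high",
                guide_links=guide_links)


def build_slab(material: str = "titanium", thickness: float = 0.03,
               n_cells: int = 60, face_area: float = 1.0):
    """One-dimensional solid slab grid for conduction benchmarks.

    A single axial column of ``n_cells`` solid rows; heat is applied on the
    low-y face, all other boundaries insulated.  ``face_area`` sets the slab
    cross-section (depth x width = face_area with unit column length).
    """
    yf = np.linspace(0.0, thickness, n_cells + 1)
    xf = np.array([0.0, 1.0])
    zone = np.full((1, n_cells), _CODES[material], dtype=np.int8)
    fluid = FluidRegion(mode="planar_channel", yc=np.zeros(0),
                        yf=np.array([0.0]), band=np.zeros(0, bool),
                        depth=face_area)
    zone_props = {code: get_material(name)
                  for code, name in ZONE_NAMES.items()}
    return Grid(mode="planar_channel", xf=xf, yf=yf, zone=zone,
                depth=face_area, j_fluid0=0, j_fluid1=0, fluid=fluid,
                zone_props=zone_props, exchanger_window=(0.0, 1.0),
                source_side="low")


def map_power_to_surrogate(spec: HeatSourceSpec, geom: SurrogateGeometry,
                           grid: Grid) -> dict:
    """Distribute the source power over the surrogate source band.

    Returns a flux table ``{"cols", "area", "flux"}`` with uniform flux
    normalised so that sum(flux * area) equals ``spec.power`` exactly
    (the 2-D reduction re-normalises the 3-D surface flux to conserve the
    total power through the effective depth).
    """
    cols, area = grid.source_faces(geom.source_band)
    if cols.size == 0:
        raise ValueError("empty source band on this grid")
    total = float(np.sum(area))
    flux = np.full(cols.size, spec.power / total)
    return {"cols": cols, "area": area, "flux": flux}
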