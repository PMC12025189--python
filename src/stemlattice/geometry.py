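"""Parametric 2D implant and proximal-femur geometry with quadrilateral meshing.

The femoral stem is described in a frontal-plane (x, y) frame, millimetres,
with the stem axis vertical at x = 0 and y increasing proximally.  Nine
geometric design variables define one implant instance:

====== ========= =========================================================
name   range     meaning
====== ========= =========================================================
L1      10-30 mm medial reach of the neck-base centre from the stem axis
Ltap    10-30 mm neck length along its axis
phi1    10-13 mm neck width (perpendicular to the neck axis)
phi2     5-20 mm distal stem width
theta   40-50 deg neck inclination above the horizontal (+x) axis
hdist   30-60 mm height of the solid distal block
hrem    70-100 mm height of the porous (remodeling) band
htap    10-30 mm height of the solid taper block on top of the neck
alpha   80-100 deg inclination of the remodeling band's lateral edge
                 (alpha = 90 deg -> vertical)
====== ========= =========================================================

The implant stacks four straight-edged quadrilateral patches (distal block,
remodeling band, neck parallelogram, taper block), each meshed with bilinear
quads by ruled interpolation between its bottom and top edges, so adjacent
patches share boundary nodes exactly.  The taper's top medial corner lands,
by construction, at the horizontal offset

    offset = L1 - phi2/2 + Ltap*cos(theta) + (phi1/2)*sin(theta).

Designs whose edges would cross (e.g. a strongly inclined lateral edge
running into the neck base) are reported as infeasible rather than raising.

The proximal-femur proxy is synthetic (the frame of reference gives only the
cortical-shell thickness and material constants): the bone outline is the
implant outline dilated by a bone margin plus a distal shaft extension, and
it is meshed as a single structured grid in which elements are tagged
implant / cortical / trabecular by centroid location.  Bone and implant
therefore share every interface node, and the intact and implanted variants
use the identical grid, so strain fields can be compared at exactly matched
material points.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = [
    "Region",
    "DesignVariables",
    "DESIGN_RANGES",
    "DESIGN_LEVELS",
    "design_grid_size",
    "QuadMesh",
    "LoadCase",
    "FemurConfig",
    "compute_offset",
    "build_conventional",
    "build_extended",
    "build_femur",
    "implant_load_case",
    "sample_designs",
]


class Region(enum.IntEnum):
    """Element region tags."""

    SOLID_TAPER = 0
    SOLID_DISTAL = 1
    REMODEL = 2
    CORTICAL = 3
    TRABECULAR = 4


#: (lo, hi) per design variable, in declaration order.
DESIGN_RANGES = {
    "L1": (10.0, 30.0),
    "Ltap": (10.0, 30.0),
    "phi1": (10.0, 13.0),
    "phi2": (5.0, 20.0),
    "theta": (40.0, 50.0),
    "hdist": (30.0, 60.0),
    "hrem": (70.0, 100.0),
    "htap": (10.0, 30.0),
    "alpha_angle": (80.0, 100.0),
}

#: number of evenly spaced levels per variable in the full-factorial grid.
DESIGN_LEVELS = {
    "L1": 5,
    "Ltap": 5,
    "phi1": 4,
    "phi2": 4,
    "theta": 3,
    "hdist": 4,
    "hrem": 4,
    "htap": 5,
    "alpha_angle": 5,
}


def design_grid_size() -> int:
    """Cardinality of the full-factorial design-variable level grid."""
    return int(np.prod(list(DESIGN_LEVELS.values())))


@dataclass(frozen=True)
class DesignVariables:
    """One implant instance; every field must lie within its published range."""

    L1: float
    Ltap: float
    phi1: float
    phi2: float
    theta: float
    hdist: float
    hrem: float
    htap: float
    alpha_angle: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in DESIGN_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside range [{lo}, {hi}]")

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]

    @classmethod
    def midrange(cls) -> "DesignVariables":
        return cls(**{k: 0.5 * (lo + hi) for k, (lo, hi) in DESIGN_RANGES.items()})

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DesignVariables":
        return cls(**dict(zip(cls.names(), np.asarray(arr, dtype=float))))


@dataclass
class LoadCase:
    """Boundary conditions: a fixed node set and one or more loaded nodes.

    ``mode`` is "force" (``value`` in N) or "displacement" (``value`` in mm,
    imposed at the load nodes).  ``load_node`` may be a single node index or
    an array of indices; ``value`` is one (x, y) pair broadcast to every
    load node, or an array of per-node pairs.
    """

    fixed_nodes: np.ndarray
    load_node: int | np.ndarray
    value: tuple[float, float] | np.ndarray
    mode: str = "force"


# 2x2 Gauss quadrature on the bilinear quad reference element.
_GP = np.array([-1.0, 1.0]) / math.sqrt(3.0)
_GAUSS_XI = np.array([[x, e] for e in _GP for x in _GP])  # (4, 2)


def _shape_derivs(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi,eta) for the 4-node quad, CCW node order; shape (2, 4)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
            [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
        ]
    )


@dataclass
class QuadMesh:
    """4-node quadrilateral mesh with region tags and a 2x2 Gauss-point table.

    ``ip_coords``/``ip_weights`` hold, per integration point, the physical
    position and the quadrature weight times the Jacobian determinant (i.e.
    its tributary area, mm^2); points are stored element-major, four per
    element, so ``ip_elem = repeat(arange(n_elem), 4)``.
    """

    nodes: np.ndarray          # (n_nodes, 2) float
    elements: np.ndarray       # (n_elem, 4) int, CCW
    region: np.ndarray         # (n_elem,) int (Region)
    outline: Optional[Polygon] = None
    meta: dict = field(default_factory=dict)
    ip_coords: np.ndarray = field(init=False)
    ip_weights: np.ndarray = field(init=False)
    ip_elem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        xy = self.nodes[self.elements]  # (n_elem, 4, 2)
        coords, weights = [], []
        for xi, eta in _GAUSS_XI:
            dN = _shape_derivs(xi, eta)              # (2, 4)
            J = np.einsum("ak,nkb->nab", dN, xy)      # (n_elem, 2, 2)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            N = 0.25 * np.array(
                [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                 (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
            )
            coords.append(np.einsum("k,nkb->nb", N, xy))
            weights.append(detJ)  # gauss weight = 1
        # interleave so points are element-major
        self.ip_coords = np.stack(coords, axis=1).reshape(-1, 2)
        self.ip_weights = np.stack(weights, axis=1).reshape(-1)
        self.ip_elem = np.repeat(np.arange(len(self.elements)), 4)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_ip(self) -> int:
        return len(self.ip_coords)

    @property
    def ip_region(self) -> np.ndarray:
        """Region tag per integration point."""
        return self.region[self.ip_elem]

    def region_area(self, tag: Region) -> float:
        return float(self.ip_weights[self.ip_region == tag].sum())

    def min_jacobian(self) -> float:
        return float(self.ip_weights.min())

    def nearest_node(self, x: float, y: float) -> int:
        return int(np.argmin(np.hypot(self.nodes[:, 0] - x, self.nodes[:, 1] - y)))


def compute_offset(dv: DesignVariables) -> float:
    """Horizontal offset of the taper's top medial corner from the stem axis.

    offset = L1 - phi2/2 + Ltap*cos(theta) + (phi1/2)*sin(theta), theta in
    degrees.  Monotone increasing in L1 and Ltap over the published ranges.
    """
    th = math.radians(dv.theta)
    return dv.L1 - dv.phi2 / 2 + dv.Ltap * math.cos(th) + dv.phi1 / 2 * math.sin(th)


def _layout(dv: DesignVariables) -> dict:
    """Key construction coordinates shared by both implant models."""
    th = math.radians(dv.theta)
    h2 = dv.phi2 / 2
    y_dist = dv.hdist
    y_band = dv.hdist + dv.hrem
    # neck-base chord on the band's top edge; its medial end is placed so the
    # taper's top medial corner sits exactly at compute_offset(dv)
    b1 = dv.L1 - h2 + dv.phi1 / 2 * math.sin(th)
    b0 = b1 - dv.phi1 / math.sin(th)
    # lateral edge inclined by (alpha - 90 deg) from vertical
    a_x = -h2 + dv.hrem * math.tan(math.radians(dv.alpha_angle - 90.0))
    neck = np.array([dv.Ltap * math.cos(th), dv.Ltap * math.sin(th)])
    return dict(
        h2=h2, y_dist=y_dist, y_band=y_band, b0=b0, b1=b1, a_x=a_x,
        neck=neck, y_neck_top=y_band + neck[1],
        y_top=y_band + neck[1] + dv.htap,
        taper_center_x=0.5 * (b0 + b1) + neck[0],
    )


class _Builder:
    """Accumulates ruled quad patches into one conforming mesh."""

    def __init__(self) -> None:
        self._index: dict[tuple, int] = {}
        self.nodes: list[tuple[float, float]] = []
        self.elements: list[list[int]] = []
        self.region: list[int] = []

    def _node(self, x: float, y: float) -> int:
        key = (round(float(x), 7), round(float(y), 7))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.nodes)
            self._index[key] = idx
            self.nodes.append((float(x), float(y)))
        return idx

    def add_patch(self, bottom: np.ndarray, top: np.ndarray, n_rows: int, tag: Region) -> None:
        """Ruled patch between matching bottom/top polylines (n_cols+1, 2)."""
        bottom = np.asarray(bottom, dtype=float)
        top = np.asarray(top, dtype=float)
        if bottom.shape != top.shape:
            raise ValueError("bottom and top edges must have matching node counts")
        rows = []
        for j in range(n_rows + 1):
            v = j / n_rows
            pts = (1 - v) * bottom + v * top
            rows.append([self._node(x, y) for x, y in pts])
        for j in range(n_rows):
            for i in range(len(bottom) - 1):
                self.elements.append(
                    [rows[j][i], rows[j][i + 1], rows[j + 1][i + 1], rows[j + 1][i]]
                )
                self.region.append(int(tag))

    def to_mesh(self, outline=None, meta=None) -> QuadMesh:
        return QuadMesh(
            nodes=np.array(self.nodes),
            elements=np.array(self.elements),
            region=np.array(self.region),
            outline=outline,
            meta=meta or {},
        )


def _edge(p0, p1, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return (1 - t) * np.asarray(p0, dtype=float) + t * np.asarray(p1, dtype=float)


def _ndiv(length: float, elem_size: float, minimum: int = 1) -> int:
    return max(minimum, int(round(length / elem_size)))


def _build_implant(dv: DesignVariables, elem_size: float, extended: bool,
                   ext_pad: float = 10.0) -> Optional[QuadMesh]:
    lay = _layout(dv)
    h2, b0, b1, a_x = lay["h2"], lay["b0"], lay["b1"], lay["a_x"]
    y_dist, y_band, neck = lay["y_dist"], lay["y_band"], lay["neck"]

    # feasibility: the band's top edge must run lateral -> neck base -> medial
    # with room for at least one element between the lateral corner and b0
    if b0 - a_x < 0.5 * elem_size or b1 - b0 < 0.5 * elem_size:
        return None

    k2 = _ndiv(b1 - b0, elem_size)
    k1 = _ndiv(b0 - a_x, elem_size)
    m_dist = _ndiv(dv.hdist, elem_size)
    m_band = _ndiv(dv.hrem, elem_size)
    m_neck = _ndiv(dv.Ltap, elem_size)
    m_tap = _ndiv(dv.htap, elem_size)

    # top edge of the remodeling band, with nodes exactly at b0 and b1
    lat_top = _edge((a_x, y_band), (b0, y_band), k1)
    base = _edge((b0, y_band), (b1, y_band), k2)
    if extended:
        a_e = min(a_x, -h2) - ext_pad
        b_e = max(b1, h2) + ext_pad
        k3 = _ndiv(b_e - b1, elem_size)
        lat_top = _edge((a_e, y_band), (b0, y_band), k1)
        med_top = _edge((b1, y_band), (b_e, y_band), k3)
        band_top = np.vstack([lat_top, base[1:], med_top[1:]])
    else:
        band_top = np.vstack([lat_top, base[1:]])
    n_cols = len(band_top) - 1

    bld = _Builder()
    dist_bot = _edge((-h2, 0.0), (h2, 0.0), n_cols)
    dist_top = _edge((-h2, y_dist), (h2, y_dist), n_cols)
    bld.add_patch(dist_bot, dist_top, m_dist, Region.SOLID_DISTAL)
    bld.add_patch(dist_top, band_top, m_band, Region.REMODEL)
    neck_top = base + neck
    bld.add_patch(base, neck_top, m_neck, Region.SOLID_TAPER)
    bld.add_patch(neck_top, neck_top + [0.0, dv.htap], m_tap, Region.SOLID_TAPER)

    # exterior boundary for feasibility / area checks (conventional outline)
    t0, t1 = base[0] + neck, base[-1] + neck
    ext_pts = [
        (-h2, 0.0), (h2, 0.0), (h2, y_dist), (b1, y_band),
        (t1[0], t1[1]), (t1[0], t1[1] + dv.htap),
        (t0[0], t0[1] + dv.htap), (t0[0], t0[1]),
        (b0, y_band), (a_x, y_band), (-h2, y_dist),
    ]
    outline = Polygon(ext_pts)
    if not outline.is_valid or not outline.is_simple:
        return None

    remodel_poly = Polygon(
        [(-h2, y_dist), (h2, y_dist)]
        + ([(b_e, y_band), (a_e, y_band)] if extended else [(b1, y_band), (a_x, y_band)])
    )
    if extended:
        outline = unary_union([outline, remodel_poly])
        if outline.geom_type != "Polygon" or not outline.is_valid:
            return None

    meta = dict(lay, dv=dv, elem_size=elem_size,
                model="extended" if extended else "conventional",
                remodel_poly=remodel_poly,
                distal_poly=box(-h2, 0.0, h2, y_dist))
    mesh = bld.to_mesh(outline=outline, meta=meta)
    if mesh.min_jacobian() <= 0:
        return None
    return mesh


def build_conventional(dv: DesignVariables, elem_size: float = 2.5) -> Optional[QuadMesh]:
    """Mesh the anatomically constrained implant; ``None`` if infeasible."""
    return _build_implant(dv, elem_size, extended=False)


def build_extended(dv: DesignVariables, elem_size: float = 2.5,
                   ext_pad: float = 10.0) -> Optional[QuadMesh]:
    """Mesh the enlarged-design-space implant; ``None`` if infeasible.

    The remodeling band is widened to a convex trapezoid bounding the
    conventional band (``ext_pad`` mm beyond it on both sides at the top);
    the solid neck/taper construction is shared with the conventional model.
    """
    return _build_implant(dv, elem_size, extended=True, ext_pad=ext_pad)


def implant_load_case(mesh: QuadMesh, force: tuple[float, float] = (0.0, -2300.0)) -> LoadCase:
    """Stand-alone implant loading: distal base pinned, force at the taper top."""
    y_min = mesh.nodes[:, 1].min()
    fixed = np.flatnonzero(mesh.nodes[:, 1] < y_min + 1e-9)
    load = mesh.nearest_node(mesh.meta["taper_center_x"], mesh.meta["y_top"])
    return LoadCase(fixed_nodes=fixed, load_node=load, value=force, mode="force")


@dataclass(frozen=True)
class FemurConfig:
    """Synthetic proximal-femur proxy dimensions (not anatomical data).

    ``bone_margin`` is the dilation of the implant outline that forms the
    bone envelope (cortical shell + trabecular interior); ``cortical``
    is the cortical-shell thickness; ``distal_extension`` lengthens the
    shaft below the implant tip for fixation.
    """

    bone_margin: float = 14.0
    cortical: float = 6.0
    distal_extension: float = 30.0
    elem_size: float = 3.0
    load_magnitude: float = 2300.0


def build_femur(
    dv: DesignVariables,
    variant: str = "intact",
    implant_mesh: Optional[QuadMesh] = None,
    implant_vf: Optional[np.ndarray] = None,
    config: FemurConfig = FemurConfig(),
) -> tuple[QuadMesh, LoadCase]:
    """Build the intact or implanted proximal-femur model.

    The implanted variant embeds the implant polygon in the bone grid; its
    per-integration-point volume fraction is stored in ``mesh.meta['ip_vf']``
    (1.0 everywhere for a solid implant).  ``implant_vf`` gives the density
    at the implant mesh's integration points (solid regions are forced to 1);
    omit it for a fully solid implant.  A uniform implant is obtained by
    passing a constant array.

    Both variants share the identical grid, so integration points match
    one-to-one between them.
    """
    if variant not in ("intact", "implanted"):
        raise ValueError("variant must be 'intact' or 'implanted'")
    if implant_mesh is None:
        implant_mesh = build_conventional(dv, elem_size=config.elem_size)
        if implant_mesh is None:
            raise ValueError("infeasible design variables")
    lay = implant_mesh.meta

    implant_poly = implant_mesh.outline
    envelope = implant_poly.buffer(config.bone_margin, join_style="mitre", mitre_limit=5.0)
    h2 = lay["h2"]
    shaft = box(-h2 - config.bone_margin, -config.distal_extension,
                h2 + config.bone_margin, lay["y_dist"])
    outline = unary_union([envelope, shaft])

    xmin, ymin, xmax, ymax = outline.bounds
    nx = int(math.ceil((xmax - xmin) / config.elem_size))
    ny = int(math.ceil((ymax - ymin) / config.elem_size))
    xs = np.linspace(xmin, xmax, nx + 1)
    ys = np.linspace(ymin, ymax, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    def nid(i, j):
        return j * (nx + 1) + i

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    ii, jj = ii.ravel(), jj.ravel()
    elems = np.column_stack([nid(ii, jj), nid(ii + 1, jj), nid(ii + 1, jj + 1), nid(ii, jj + 1)])
    cx = 0.5 * (xs[ii] + xs[ii + 1])
    cy = 0.5 * (ys[jj] + ys[jj + 1])

    inside = shapely.contains_xy(outline, cx, cy)
    elems, cx, cy = elems[inside], cx[inside], cy[inside]

    # region tagging by centroid
    region = np.full(len(elems), int(Region.TRABECULAR))
    d_surf = shapely.distance(shapely.points(np.column_stack([cx, cy])), outline.boundary)
    region[d_surf < config.cortical] = int(Region.CORTICAL)
    if variant == "implanted":
        in_implant = shapely.contains_xy(implant_poly, cx, cy)
        rem = in_implant & shapely.contains_xy(lay["remodel_poly"], cx, cy)
        dist = in_implant & shapely.contains_xy(lay["distal_poly"], cx, cy)
        region[in_implant] = int(Region.SOLID_TAPER)
        region[dist] = int(Region.SOLID_DISTAL)
        region[rem] = int(Region.REMODEL)

    # renumber kept nodes
    used = np.unique(elems)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = QuadMesh(
        nodes=nodes[used],
        elements=remap[elems],
        region=region,
        outline=outline,
        meta=dict(dv=dv, variant=variant, config=config, implant_outline=implant_poly),
    )

    if variant == "implanted":
        imp_ip = np.isin(mesh.ip_region, (Region.SOLID_TAPER, Region.SOLID_DISTAL, Region.REMODEL))
        vf = np.full(mesh.n_ip, np.nan)
        vf[imp_ip] = 1.0
        if implant_vf is not None:
            from scipy.spatial import cKDTree

            src_vf = np.asarray(implant_vf, dtype=float).copy()
            solid_src = np.isin(implant_mesh.ip_region, (Region.SOLID_TAPER, Region.SOLID_DISTAL))
            src_vf[solid_src] = 1.0
            tree = cKDTree(implant_mesh.ip_coords)
            _, nearest = tree.query(mesh.ip_coords[imp_ip])
            vf[imp_ip] = src_vf[nearest]
            # solid implant regions stay fully dense regardless of transfer
            solid_ip = np.isin(mesh.ip_region, (Region.SOLID_TAPER, Region.SOLID_DISTAL))
            vf[solid_ip] = 1.0
        mesh.meta["ip_vf"] = vf

    y_low = mesh.nodes[:, 1].min()
    fixed = np.flatnonzero(mesh.nodes[:, 1] < y_low + 1e-9)
    # head (intact) and taper (implanted) load share the same x-coordinate;
    # the grid is shared, so the very same node is used in both variants.
    load_node = mesh.nearest_node(lay["taper_center_x"], lay["y_top"])
    load = LoadCase(fixed_nodes=fixed, load_node=load_node,
                    value=(0.0, -config.load_magnitude), mode="force")
    return mesh, load


def sample_designs(n: int, seed: int) -> list[DesignVariables]:
    """Draw ``n`` unique designs uniformly from the full-factorial level grid.

    Sampling is without replacement over all level combinations (480,000),
    deterministic for a fixed seed.
    """
    total = design_grid_size()
    if n > total:
        raise ValueError(f"cannot draw {n} unique designs from a grid of {total}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n, replace=False)
    shape = tuple(DESIGN_LEVELS[k] for k in DESIGN_RANGES)
    level_values = {
        k: np.linspace(lo, hi, DESIGN_LEVELS[k]) for k, (lo, hi) in DESIGN_RANGES.items()
    }
    idx = np.unravel_index(flat, shape)
    out = []
    for row in zip(*idx):
        out.append(DesignVariables(**{
            k: float(level_values[k][i]) for k, i in zip(DESIGN_RANGES, row)
        }))
    return out
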