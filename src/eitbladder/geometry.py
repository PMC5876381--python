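"""Parametric pelvis/bladder geometry and finite-element meshing.

The measurement domain is an elliptical cylinder of the pelvic region
carrying a ring of 32 evenly spaced surface electrodes at mid-height.
The bladder is an axis-aligned ellipsoid whose semi-axes grow with the
urine volume; its *bottom* position is fixed relative to the domain
centroid, so a filling bladder ascends into the abdominal region.

Two mesh flavours are provided:

* ``"2d"`` (default) -- the electrode-plane reduction: an elliptical
  cross-section of the domain with the exact ellipse obtained by slicing
  the placed ellipsoid at the electrode plane.  First-order triangles.
* ``"3d"`` -- the full elliptical cylinder, meshed by extruding a graded
  in-plane triangulation into conforming tetrahedra.

All lengths are millimetres, volumes millilitres.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "GeometryError",
    "MeshingError",
    "RadiiModel",
    "PelvisBoundary",
    "BladderEllipsoid",
    "Mesh",
    "MeshDensity",
    "bladder_radii_from_volume",
    "fixed_bottom_z",
    "place_bladder",
    "build_pelvis_mesh",
]

N_ELECTRODES_DEFAULT = 32

#: volume for which the ellipsoid's major (axial) radius defines the fixed
#: bottom position of every bladder, measured from the domain centroid.
REFERENCE_VOLUME_ML = 240.0


class GeometryError(ValueError):
    """Invalid or infeasible geometric configuration."""


class MeshingError(RuntimeError):
    """The requested mesh could not be built (e.g. density too coarse)."""


# ---------------------------------------------------------------------------
# bladder radii model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiiModel:
    """Volume -> (axial, coronal, sagittal) semi-axis model.

    The default is *ellipsoid-consistent*: semi-axes keep fixed aspect
    ratios and are scaled so that ``4/3 pi a b c`` equals the requested
    volume exactly.  ``custom`` may hold any callable
    ``volume_ml -> (a, b, c)`` to plug in an alternative regression.
    """

    ratios: tuple[float, float, float] = (1.2, 1.0, 0.9)
    volume_range_ml: tuple[float, float] = (20.0, 500.0)
    custom: object | None = None

    def radii(self, volume_ml: float) -> tuple[float, float, float]:
        lo, hi = self.volume_range_ml
        if not (lo <= volume_ml <= hi):
            raise GeometryError(
                f"volume {volume_ml!r} ml outside supported range [{lo}, {hi}] ml"
            )
        if self.custom is not None:
            a, b, c = self.custom(volume_ml)
        else:
            ra, rc, rs = self.ratios
            # 4/3 pi (ra s)(rc s)(rs s) = V * 1000 mm^3
            s = (volume_ml * 1000.0 * 3.0 / (4.0 * math.pi * ra * rc * rs)) ** (1.0 / 3.0)
            a, b, c = ra * s, rc * s, rs * s
        if min(a, b, c) <= 0:
            raise GeometryError(f"radii model returned non-positive radii for {volume_ml} ml")
        return float(a), float(b), float(c)


def bladder_radii_from_volume(
    volume_ml: float, model: RadiiModel | None = None
) -> tuple[float, float, float]:
    """Semi-axes (axial, coronal, sagittal) in mm for a urine volume in ml."""
    if model is None:
        model = RadiiModel()
    return model.radii(volume_ml)


def fixed_bottom_z(model: RadiiModel | None = None) -> float:
    """Fixed bottom position (mm, below the domain centroid) of every bladder.

    By construction the reference-volume bladder has its centre at the
    domain centroid: the bottom sits one axial semi-axis below it.
    """
    a, _, _ = bladder_radii_from_volume(REFERENCE_VOLUME_ML, model)
    return -a


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_BASE_SEMIAXES = {"male": (170.0, 110.0), "female": (180.0, 120.0)}


@dataclass(frozen=True)
class PelvisBoundary:
    """Elliptical-cylinder pelvic domain.

    ``lateral_semiaxis``/``ap_semiaxis`` are the *base* horizontal
    semi-axes; the anterior-posterior one is additionally multiplied by
    ``ap_scale`` (boundary-variation factor, e.g. 0.90/1.10 for the
    +/-10% variants).
    """

    lateral_semiaxis: float = 170.0
    ap_semiaxis: float = 110.0
    height: float = 200.0
    sex_tag: str = "male"
    ap_scale: float = 1.0

    def __post_init__(self):
        if min(self.lateral_semiaxis, self.ap_semiaxis, self.height) <= 0:
            raise GeometryError("all pelvis dimensions must be positive")
        if not (0.8 <= self.ap_scale <= 1.2):
            raise GeometryError(f"ap_scale {self.ap_scale} outside [0.8, 1.2]")
        if self.sex_tag not in ("male", "female"):
            raise GeometryError(f"unknown sex_tag {self.sex_tag!r}")

    @classmethod
    def standard(cls, sex: str = "male", ap_scale: float = 1.0, height: float = 200.0):
        lat, ap = _BASE_SEMIAXES[sex]
        return cls(lateral_semiaxis=lat, ap_semiaxis=ap, height=height,
                   sex_tag=sex, ap_scale=ap_scale)

    @property
    def ap_semiaxis_scaled(self) -> float:
        return self.ap_semiaxis * self.ap_scale

    @property
    def boundary_id(self) -> str:
        return f"{self.sex_tag}x{self.ap_scale:.2f}"


@dataclass(frozen=True)
class BladderEllipsoid:
    """Axis-aligned ellipsoidal bladder placed inside a pelvis domain.

    Axes: coronal semi-axis along x (lateral), sagittal along y
    (anterior-posterior), axial along z (the cylinder/ascension axis).
    """

    r_axial: float
    r_coronal: float
    r_sagittal: float
    center: tuple[float, float, float]
    volume_ml: float
    bottom_z_fixed: float

    def __post_init__(self):
        if min(self.r_axial, self.r_coronal, self.r_sagittal) < 0:
            raise GeometryError("bladder radii must be non-negative")

    @property
    def top_z(self) -> float:
        return self.center[2] + self.r_axial

    @property
    def bottom_z(self) -> float:
        return self.center[2] - self.r_axial

    def ellipsoid_volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r_axial * self.r_coronal * self.r_sagittal / 1000.0

    def slice_at(self, z: float = 0.0) -> tuple[float, float, float, float] | None:
        """Cross-section ellipse at height ``z``.

        Returns ``(cx, cy, semi_x, semi_y)`` or ``None`` when the plane
        misses the ellipsoid (or the bladder is degenerate).
        """
        if self.r_axial <= 0:
            return None
        t = (z - self.center[2]) / self.r_axial
        if abs(t) >= 1.0:
            return None
        f = math.sqrt(1.0 - t * t)
        return (self.center[0], self.center[1],
                self.r_coronal * f, self.r_sagittal * f)

    def level(self, x, y, z):
        """Implicit ellipsoid function; < 1 inside, 1 on the surface."""
        return (((x - self.center[0]) / self.r_coronal) ** 2
                + ((y - self.center[1]) / self.r_sagittal) ** 2
                + ((z - self.center[2]) / self.r_axial) ** 2)


def place_bladder(
    radii: tuple[float, float, float],
    pelvis: PelvisBoundary,
    model: RadiiModel | None = None,
    anterior_frac: float = 0.5,
    bottom_z: float | None = None,
    volume_ml: float | None = None,
) -> BladderEllipsoid:
    """Place an ellipsoid with fixed bottom, halfway into the anterior region.

    The centre sits on the anterior-posterior axis at
    ``anterior_frac * ap_semiaxis_scaled`` (midpoint between centroid and
    anterior wall by default) and at the height that puts the lowest
    extent of the ellipsoid at the fixed bottom position.
    """
    a, b, c = radii
    if min(a, b, c) < 0:
        raise GeometryError("radii must be non-negative")
    if bottom_z is None:
        bottom_z = fixed_bottom_z(model)
    yc = anterior_frac * pelvis.ap_semiaxis_scaled
    center = (0.0, yc, bottom_z + a)
    if volume_ml is None:
        volume_ml = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
    bl = BladderEllipsoid(r_axial=a, r_coronal=b, r_sagittal=c, center=center,
                          volume_ml=volume_ml, bottom_z_fixed=bottom_z)
    if a > 0:
        _check_inside(bl, pelvis)
    return bl


def _check_inside(bl: BladderEllipsoid, pelvis: PelvisBoundary, margin: float = 1.0):
    """Raise GeometryError unless the ellipsoid lies strictly inside the domain."""
    hz = pelvis.height / 2.0
    if bl.top_z > hz - margin or bl.bottom_z < -hz + margin:
        raise GeometryError(
            f"bladder of {bl.volume_ml:.0f} ml exceeds the domain height "
            f"(z extent [{bl.bottom_z:.1f}, {bl.top_z:.1f}] mm)"
        )
    # xy-projection of the ellipsoid is the ellipse (r_coronal, r_sagittal)
    th = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    x = bl.center[0] + bl.r_coronal * np.cos(th)
    y = bl.center[1] + bl.r_sagittal * np.sin(th)
    rx = pelvis.lateral_semiaxis - margin
    ry = pelvis.ap_semiaxis_scaled - margin
    if np.any((x / rx) ** 2 + (y / ry) ** 2 >= 1.0):
        raise GeometryError(
            f"bladder of {bl.volume_ml:.0f} ml intersects the pelvic boundary "
            f"({pelvis.boundary_id})"
        )


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeshDensity:
    """Target mesh resolution.  ``scale`` < 1 refines everything."""

    scale: float = 1.0
    h_background: float = 13.0     # mm, coarse in-plane spacing
    h_inclusion: float = 5.0       # mm, in-plane spacing near the bladder
    #: in-plane spacing in the annular band along the electrode boundary
    #: (resolves the steep fields between adjacent electrodes)
    h_edge: float = 4.5
    boundary_per_electrode: int = 4  # boundary nodes per electrode interval
    h_z_coarse: float = 26.0       # 3-D: layer spacing away from the bladder
    h_z_fine: float = 8.0          # 3-D: layer spacing across the bladder
    #: shunt-electrode half-width as a fraction of the inter-electrode
    #: interval; 0 (default) selects the point-electrode model, whose
    #: measurement voltages converge markedly faster under refinement
    patch_frac: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise GeometryError("density scale must be positive")

    @property
    def hbg(self):
        return self.h_background * self.scale

    @property
    def hinc(self):
        return self.h_inclusion * self.scale

    @property
    def nb_per_electrode(self):
        return max(2, int(round(self.boundary_per_electrode / self.scale)))


@dataclass
class Mesh:
    """Conforming simplex mesh with electrode node groups and region tags."""

    dim: int
    nodes: np.ndarray              # (n_nodes, dim)
    elements: np.ndarray           # (n_elems, dim + 1) int
    element_tags: np.ndarray       # (n_elems,) 0 = background, 1 = bladder
    electrode_nodes: list          # 32 ordered arrays of node indices
    boundary: PelvisBoundary | None = None
    bladder: BladderEllipsoid | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def element_measures(self) -> np.ndarray:
        """Per-element area (2-D) or volume (3-D), in mm^2 / mm^3."""
        pts = self.nodes[self.elements]
        v = pts[:, 1:, :] - pts[:, :1, :]
        if self.dim == 2:
            return 0.5 * np.abs(np.linalg.det(v))
        return np.abs(np.linalg.det(v)) / 6.0

    def region_measure(self, tag: int) -> float:
        return float(self.element_measures()[self.element_tags == tag].sum())

    def bladder_volume_ml(self) -> float:
        """Measure of the bladder-tagged region in ml (3-D) -- 3-D meshes only."""
        if self.dim != 3:
            raise ValueError("bladder_volume_ml is defined for 3-D meshes")
        return self.region_measure(1) / 1000.0

    def to_msh(self, path) -> None:
        """Write the mesh in Gmsh MSH 2.2 ASCII for external inspection."""
        etype = 2 if self.dim == 2 else 4
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
            fh.write(f"{len(self.nodes)}\n")
            for i, p in enumerate(self.nodes, 1):
                x, y = p[0], p[1]
                z = p[2] if self.dim == 3 else 0.0
                fh.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
            fh.write("$EndNodes\n$Elements\n")
            fh.write(f"{len(self.elements)}\n")
            for i, (el, tag) in enumerate(zip(self.elements, self.element_tags), 1):
                conn = " ".join(str(int(v) + 1) for v in el)
                fh.write(f"{i} {etype} 2 {int(tag)} {int(tag)} {conn}\n")
            fh.write("$EndElements\n")


def _electrode_groups(n_electrodes: int, k: int, patch_frac: float,
                      node_offset: int = 0) -> list:
    """Boundary-node groups per electrode (shunted small-patch model).

    Each electrode covers boundary nodes within ``patch_frac`` of the
    inter-electrode interval on either side of its centre; the centre
    node comes first in each group.
    """
    nb = n_electrodes * k
    w = patch_frac * k + 1e-9
    half = int(w)
    groups = []
    for e in range(n_electrodes):
        offs = [0] + [s * m for m in range(1, half + 1) for s in (1, -1) if m <= w]
        idx = [node_offset + (e * k + m) % nb for m in offs]
        groups.append(np.array(idx))
    return groups


def _hex_lattice(xmin, xmax, ymin, ymax, h):
    """Deterministic hexagonal point lattice covering a bounding box."""
    dy = h * math.sqrt(3.0) / 2.0
    ny = max(1, int(math.ceil((ymax - ymin) / dy)) + 1)
    nx = max(1, int(math.ceil((xmax - xmin) / h)) + 2)
    rows = []
    for j in range(ny):
        y = ymin + j * dy
        off = 0.5 * h if j % 2 else 0.0
        x = xmin + off + np.arange(nx) * h
        rows.append(np.column_stack([x, np.full_like(x, y)]))
    pts = np.vstack(rows)
    keep = (pts[:, 0] <= xmax + 1e-9) & (pts[:, 1] <= ymax + 1e-9)
    return pts[keep]


def _ellipse_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _plane_points(
    pelvis: PelvisBoundary,
    density: MeshDensity,
    n_electrodes: int,
    inclusion: tuple[float, float, float, float] | None,
    conform_inclusion: bool,
    refine_window: tuple[float, float, float, float] | None = None,
    edge_band: bool = True,
):
    """Point cloud for the in-plane triangulation.

    Returns ``(points, electrode_index_stride, n_boundary, n_inclusion)``.
    Order: domain-boundary nodes (electrodes at stride ``k``), inclusion
    boundary nodes, interior fill.
    """
    rx, ry = pelvis.lateral_semiaxis, pelvis.ap_semiaxis_scaled
    k = density.nb_per_electrode
    nb = n_electrodes * k
    # electrode 0 on the anterior midline (+y); counter-clockwise ordering
    alpha = math.pi / 2.0 + 2.0 * math.pi * np.arange(nb) / nb
    bpts = np.column_stack([rx * np.cos(alpha), ry * np.sin(alpha)])

    hbg = density.hbg
    pts = [bpts]
    n_inc = 0
    hloc = density.hinc
    if inclusion is not None:
        cx, cy, bx, by = inclusion
        hloc = min(density.hinc, max(min(bx, by) / 2.5, 1.0))
        if conform_inclusion:
            per = _ellipse_perimeter(bx, by)
            n_inc = max(12, int(math.ceil(per / hloc)))
            t = 2.0 * math.pi * np.arange(n_inc) / n_inc
            pts.append(np.column_stack([cx + bx * np.cos(t), cy + by * np.sin(t)]))

    # coarse interior lattice
    coarse = _hex_lattice(-rx, rx, -ry, ry, hbg)
    # refinement window around the inclusion (or an explicit window in 3-D)
    win = None
    if inclusion is not None:
        cx, cy, bx, by = inclusion
        m = 1.6 * hbg
        win = (cx - bx - m, cx + bx + m, cy - by - m, cy + by + m)
    if refine_window is not None:
        win = refine_window
    sel = np.ones(len(coarse), bool)
    if win is not None:
        inwin = ((coarse[:, 0] > win[0]) & (coarse[:, 0] < win[1])
                 & (coarse[:, 1] > win[2]) & (coarse[:, 1] < win[3]))
        sel &= ~inwin
    interior = [coarse[sel]]
    if win is not None:
        fine = _hex_lattice(win[0], win[1], win[2], win[3], hloc)
        interior.append(fine)
    interior = np.vstack(interior)

    # graded band along the electrode boundary: the inter-electrode fields
    # are steep, so the coarse lattice stops short and a finer one fills in
    he = density.h_edge * density.scale
    band = 1.2 * hbg
    rmin_ax = min(rx, ry)

    def _edge_dist(p):
        r = np.sqrt((p[:, 0] / rx) ** 2 + (p[:, 1] / ry) ** 2)
        return (1.0 - r) * rmin_ax

    if edge_band:
        interior = interior[_edge_dist(interior) > band]
        edge = _hex_lattice(-rx, rx, -ry, ry, he)
        de = _edge_dist(edge)
        interior = np.vstack([interior,
                              edge[(de > 0.6 * he) & (de <= band + 0.4 * hbg)]])
    else:
        d = _edge_dist(interior)
        interior = interior[d > 0.62 * hbg]
    # keep a clear band around the inclusion curve so triangles conform to it
    if inclusion is not None and conform_inclusion:
        cx, cy, bx, by = inclusion
        r = np.sqrt(((interior[:, 0] - cx) / bx) ** 2 + ((interior[:, 1] - cy) / by) ** 2)
        d = np.abs(r - 1.0) * min(bx, by)
        interior = interior[d > 0.62 * hloc]
    pts.append(interior)
    allpts = np.vstack(pts)

    # dedupe: later (interior) points too close to earlier (feature) points go
    tree = cKDTree(allpts)
    pairs = tree.query_pairs(r=0.38 * min(hloc, he, hbg), output_type="ndarray")
    drop = np.zeros(len(allpts), bool)
    if len(pairs):
        drop[pairs.max(axis=1)] = True
    drop[: nb + n_inc] = False  # never drop boundary / inclusion nodes
    return allpts[~drop], k, nb, n_inc


def _build_mesh_2d(pelvis, bladder, density, n_electrodes) -> Mesh:
    inclusion = bladder.slice_at(0.0) if bladder is not None else None
    if inclusion is not None and density.hinc >= min(inclusion[2], inclusion[3]):
        raise MeshingError(
            f"mesh density too coarse to resolve the bladder inclusion "
            f"(spacing {density.hinc:.1f} mm vs slice semi-axes "
            f"{inclusion[2]:.1f} x {inclusion[3]:.1f} mm)")
    pts, k, nb, n_inc = _plane_points(pelvis, density, n_electrodes,
                                      inclusion, conform_inclusion=True)
    tri = Delaunay(pts)
    elems = tri.simplices.astype(np.int64)
    # orient all triangles counter-clockwise
    e1 = pts[elems[:, 1]] - pts[elems[:, 0]]
    e2 = pts[elems[:, 2]] - pts[elems[:, 0]]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = det < 0
    elems[flip, 1], elems[flip, 2] = elems[flip, 2].copy(), elems[flip, 1].copy()

    tags = np.zeros(len(elems), dtype=np.int8)
    if inclusion is not None:
        cx, cy, bx, by = inclusion
        cent = pts[elems].mean(axis=1)
        lvl = ((cent[:, 0] - cx) / bx) ** 2 + ((cent[:, 1] - cy) / by) ** 2
        tags[lvl < 1.0] = 1
        if not np.any(tags == 1):
            raise MeshingError(
                f"mesh density too coarse to resolve the bladder inclusion "
                f"(slice semi-axes {bx:.1f} x {by:.1f} mm)"
            )
    electrodes = _electrode_groups(n_electrodes, k, density.patch_frac)
    return Mesh(dim=2, nodes=pts, elements=elems, element_tags=tags,
                electrode_nodes=electrodes, boundary=pelvis, bladder=bladder,
                provenance={"density_scale": density.scale, "domain": "2d"})


def _z_levels(pelvis, bladder, density):
    hz = pelvis.height / 2.0
    zc = density.h_z_coarse * density.scale
    zf = density.h_z_fine * density.scale
    levels = set(np.round(np.linspace(-hz, hz, max(3, int(round(2 * hz / zc)) + 1)), 6))
    if bladder is not None and bladder.r_axial > 0:
        lo = max(-hz, bladder.bottom_z - zf)
        hi = min(hz, bladder.top_z + zf)
        n = max(2, int(round((hi - lo) / zf)) + 1)
        levels |= set(np.round(np.linspace(lo, hi, n), 6))
    levels.add(0.0)
    levels = np.array(sorted(levels))
    # merge near-duplicate planes, always keeping the ends and z = 0
    keep = [0]
    for i in range(1, len(levels)):
        if levels[i] - levels[keep[-1]] >= 0.45 * zf or i == len(levels) - 1:
            keep.append(i)
    levels = levels[keep]
    if 0.0 not in levels:
        levels = np.sort(np.append(levels, 0.0))
    return levels


def _prisms_to_tets(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split prisms into 3 tets each, conforming across shared quad faces.

    Diagonal choice follows the smallest-global-index rule: every quad
    face takes the diagonal emanating from its lowest-numbered vertex, so
    neighbouring prisms always agree.
    """
    m = len(bot)
    r = np.argmin(bot, axis=1)
    idx = np.arange(m)
    order = np.stack([r, (r + 1) % 3, (r + 2) % 3], axis=1)
    b = bot[idx[:, None], order]
    t = top[idx[:, None], order]
    v = np.concatenate([b, t], axis=1)  # columns: 0,1,2 bottom; 3,4,5 top
    caseA = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((m, 3, 4), dtype=np.int64)
    A = v[caseA]
    tets[caseA, 0] = A[:, [0, 1, 2, 5]]
    tets[caseA, 1] = A[:, [0, 1, 5, 4]]
    tets[caseA, 2] = A[:, [0, 4, 5, 3]]
    B = v[~caseA]
    tets[~caseA, 0] = B[:, [0, 1, 2, 4]]
    tets[~caseA, 1] = B[:, [0, 4, 2, 5]]
    tets[~caseA, 2] = B[:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def _build_mesh_3d(pelvis, bladder, density, n_electrodes) -> Mesh:
    refine = None
    if bladder is not None and bladder.r_axial > 0:
        m = 1.3 * density.hbg
        refine = (bladder.center[0] - bladder.r_coronal - m,
                  bladder.center[0] + bladder.r_coronal + m,
                  bladder.center[1] - bladder.r_sagittal - m,
                  bladder.center[1] + bladder.r_sagittal + m)
    pts2, k, nb, _ = _plane_points(pelvis, density, n_electrodes,
                                   inclusion=None, conform_inclusion=False,
                                   refine_window=refine, edge_band=False)
    tri = Delaunay(pts2)
    tris = tri.simplices.astype(np.int64)
    levels = _z_levels(pelvis, bladder, density)
    n2 = len(pts2)
    nz = len(levels)
    nodes = np.empty((n2 * nz, 3))
    for L, z in enumerate(levels):
        nodes[L * n2:(L + 1) * n2, :2] = pts2
        nodes[L * n2:(L + 1) * n2, 2] = z

    tets_all = []
    for L in range(nz - 1):
        bot = tris + L * n2
        top = tris + (L + 1) * n2
        tets_all.append(_prisms_to_tets(bot, top))
    tets = np.vstack(tets_all)

    # positive orientation
    p = nodes[tets]
    det = np.linalg.det(p[:, 1:] - p[:, :1])
    flip = det < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    tags = np.zeros(len(tets), dtype=np.int8)
    if bladder is not None and bladder.r_axial > 0:
        cent = nodes[tets].mean(axis=1)
        lvl = bladder.level(cent[:, 0], cent[:, 1], cent[:, 2])
        tags[lvl < 1.0] = 1
        if not np.any(tags == 1):
            raise MeshingError(
                f"mesh density too coarse to resolve the {bladder.volume_ml:.0f} ml bladder"
            )
    L0 = int(np.argmin(np.abs(levels)))
    electrodes = _electrode_groups(n_electrodes, k, density.patch_frac,
                                   node_offset=L0 * n2)
    return Mesh(dim=3, nodes=nodes, elements=tets, element_tags=tags,
                electrode_nodes=electrodes, boundary=pelvis, bladder=bladder,
                provenance={"density_scale": density.scale, "domain": "3d"})


def build_pelvis_mesh(
    pelvis: PelvisBoundary,
    bladder: BladderEllipsoid | None = None,
    density: MeshDensity | None = None,
    domain: str = "2d",
    n_electrodes: int = N_ELECTRODES_DEFAULT,
) -> Mesh:
    """Mesh the pelvic domain with the bladder inclusion tagged.

    ``domain="2d"`` meshes the electrode plane (triangles); ``"3d"``
    meshes the full cylinder (tetrahedra).  In 2-D a bladder whose
    ellipsoid does not reach the electrode plane yields a pure
    background mesh (the inclusion is invisible to the ring).
    """
    if density is None:
        density = MeshDensity()
    if bladder is not None and bladder.r_axial > 0:
        _check_inside(bladder, pelvis)
    if domain == "2d":
        return _build_mesh_2d(pelvis, bladder, density, n_electrodes)
    if domain == "3d":
        return _build_mesh_3d(pelvis, bladder, density, n_electrodes)
    raise ValueError(f"unknown domain kind {domain!r}")
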