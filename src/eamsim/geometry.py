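"""Idealized left-ventricular geometry, ventricular coordinates and EAM surfaces.

The left ventricle is modelled as a truncated prolate-ellipsoid shell
voxelized on a regular grid (millimetres throughout).  Each myocardial node
carries a tissue label, a fibre direction and normalized ventricular
coordinates (apicobasal, rotational, transmural), so that positions are
comparable across hearts of different size.  Triangulated endocardial and
epicardial surfaces at ~2 mm edge resolution stand in for the mapping-system
geometry on which electrograms are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import ConvexHull, cKDTree

NORMAL, BORDER_ZONE, DENSE_CORE = 0, 1, 2

#: undirected neighbour offsets of the 18-point stencil (3 axis + 6 face-diagonal)
AXIS_OFFSETS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
DIAG_OFFSETS = [(1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)]


class ConfigurationError(ValueError):
    """Raised when geometry parameters are inconsistent."""


@dataclass
class LvShape:
    """Truncated prolate ellipsoid: epicardial semi-axes, wall, truncation.

    ``truncation_fraction`` is the kept fraction of the long-axis extent
    measured from the apex; the base plane sits at
    ``z = -c + 2c * truncation_fraction``.
    """

    epi_semi_axes: tuple[float, float, float] = (34.0, 34.0, 70.0)
    wall_thickness: float = 10.0
    truncation_fraction: float = 0.7

    @property
    def endo_semi_axes(self) -> tuple[float, float, float]:
        w = self.wall_thickness
        a, b, c = self.epi_semi_axes
        return (a - w, b - w, c - w)

    @property
    def base_z(self) -> float:
        c = self.epi_semi_axes[2]
        return -c + 2.0 * c * self.truncation_fraction


@dataclass
class VentricularModel:
    """Voxelized LV shell with tissue labels, fibres and ventricular coordinates."""

    voxel_size: float
    shape: LvShape
    grid_shape: tuple[int, int, int]
    origin: np.ndarray                  # coords of voxel (0,0,0) centre, mm
    node_ijk: np.ndarray                # (n, 3) int voxel indices
    node_coords: np.ndarray             # (n, 3) mm
    node_index: np.ndarray              # (nx, ny, nz) int, -1 outside myocardium
    tissue: np.ndarray = None           # (n,) uint8
    fibres: np.ndarray = None           # (n, 3) unit vectors
    uvc: np.ndarray = None              # (n, 3): apicobasal, rotational deg, transmural
    is_endo_layer: np.ndarray = None    # (n,) bool — faces the cavity
    is_epi_layer: np.ndarray = None     # (n,) bool — faces the outside

    def __post_init__(self):
        if self.tissue is None:
            self.tissue = np.zeros(len(self.node_coords), dtype=np.uint8)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def neighbour_pairs(self, offsets=None) -> np.ndarray:
        """(m, 2) array of undirected node-index pairs for the given offsets."""
        if offsets is None:
            offsets = AXIS_OFFSETS
        idx = self.node_index
        pairs = []
        for off in offsets:
            ijk2 = self.node_ijk + np.asarray(off)
            ok = np.all((ijk2 >= 0) & (ijk2 < np.asarray(self.grid_shape)), axis=1)
            j = np.full(self.n_nodes, -1, dtype=np.int64)
            j[ok] = idx[ijk2[ok, 0], ijk2[ok, 1], ijk2[ok, 2]]
            keep = j >= 0
            pairs.append(np.column_stack([np.nonzero(keep)[0], j[keep]]))
        return np.concatenate(pairs, axis=0)

    def conducting_mask(self) -> np.ndarray:
        return self.tissue != DENSE_CORE


@dataclass
class EamSurface:
    """Triangulated endo+epi mapping surfaces with per-point volume linkage.

    Points of both sides are concatenated; ``side`` is 0 for endocardium and
    1 for epicardium, and triangles never span sides.  ``is_cap`` flags the
    artificial basal closure, which is excluded from pacing and analyses.
    """

    points: np.ndarray            # (p, 3) mm
    triangles: np.ndarray         # (t, 3) int
    side: np.ndarray              # (p,) 0 endo / 1 epi
    is_cap: np.ndarray            # (p,) bool
    uvc: np.ndarray               # (p, 3)
    volume_link: np.ndarray       # (p,) node id in the model
    voxel_size: float

    _geo_graph: sparse.csr_matrix = field(default=None, repr=False, compare=False)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def side_points(self, side: int) -> np.ndarray:
        return np.nonzero(self.side == side)[0]

    def edge_lengths(self) -> np.ndarray:
        e = unique_edges(self.triangles)
        return np.linalg.norm(self.points[e[:, 0]] - self.points[e[:, 1]], axis=1)

    def edge_graph(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of edge lengths (triangles never span sides,
        so geodesics computed on it are automatically per side)."""
        if self._geo_graph is None:
            e = unique_edges(self.triangles)
            w = np.linalg.norm(self.points[e[:, 0]] - self.points[e[:, 1]], axis=1)
            n = self.n_points
            g = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
            self._geo_graph = g.tocsr()
        return self._geo_graph

    def geodesic_from(self, indices, limit=np.inf) -> np.ndarray:
        """Geodesic (graph shortest-path) distances from the given points."""
        return csgraph.dijkstra(self.edge_graph(), directed=False,
                                indices=indices, limit=limit)


@dataclass
class PacingSite:
    id: int
    side: int
    point_index: int      # index into EamSurface.points
    uvc: np.ndarray
    position: np.ndarray


# ---------------------------------------------------------------------------
# model construction

def build_idealized_lv(shape: LvShape = None, voxel_size: float = 2.0) -> VentricularModel:
    """Voxelize a truncated prolate-ellipsoid LV shell.

    Myocardial voxels are those whose centres lie outside the endocardial
    ellipsoid, inside the epicardial ellipsoid and apical of the base plane.
    Raises :class:`ConfigurationError` when the wall is thinner than two
    voxels (the shell would disconnect).
    """
    shape = shape or LvShape()
    if shape.wall_thickness < 2.0 * voxel_size:
        raise ConfigurationError(
            f"wall thickness {shape.wall_thickness} mm must be >= 2 voxels "
            f"({2 * voxel_size} mm)")
    a, b, c = shape.epi_semi_axes
    h = voxel_size
    # grid covers the epicardial bounding box with one voxel of margin
    lo = np.array([-a - h, -b - h, -c - h])
    hi = np.array([a + h, b + h, shape.base_z + h])
    n = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo + h / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(m) for m in n], indexing="ij")
    coords = origin + np.stack([ii, jj, kk], axis=-1) * h

    f_epi = ellipsoid_value(coords.reshape(-1, 3), shape.epi_semi_axes)
    f_endo = ellipsoid_value(coords.reshape(-1, 3), shape.endo_semi_axes)
    z = coords.reshape(-1, 3)[:, 2]
    myo = (f_epi <= 1.0) & (f_endo >= 1.0) & (z <= shape.base_z)
    myo = myo.reshape(tuple(n))

    node_index = np.full(tuple(n), -1, dtype=np.int64)
    ijk = np.argwhere(myo)
    node_index[myo] = np.arange(len(ijk))
    model = VentricularModel(
        voxel_size=h, shape=shape, grid_shape=tuple(n), origin=origin,
        node_ijk=ijk, node_coords=origin + ijk * h, node_index=node_index)

    _keep_largest_component(model)
    _mark_boundary_layers(model)
    return model


def ellipsoid_value(x: np.ndarray, semi_axes) -> np.ndarray:
    s = np.asarray(semi_axes, dtype=float)
    return np.sum((np.atleast_2d(x) / s) ** 2, axis=1)


def truncated_shell_volume(shape: LvShape) -> float:
    """Closed-form volume of the truncated ellipsoid shell (mm^3)."""

    def trunc_vol(semi, z0):
        a, b, c = semi
        z0 = min(z0, c)
        if z0 <= -c:
            return 0.0
        return np.pi * a * b * ((z0 + c) - (z0 ** 3 + c ** 3) / (3 * c ** 2))

    return trunc_vol(shape.epi_semi_axes, shape.base_z) - \
        trunc_vol(shape.endo_semi_axes, shape.base_z)


def _keep_largest_component(model: VentricularModel) -> None:
    pairs = model.neighbour_pairs(AXIS_OFFSETS)
    n = model.n_nodes
    g = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, lab = csgraph.connected_components(g, directed=False)
    if ncomp == 1:
        return
    keep = lab == np.bincount(lab).argmax()
    model.node_ijk = model.node_ijk[keep]
    model.node_coords = model.node_coords[keep]
    model.tissue = model.tissue[keep]
    model.node_index[...] = -1
    model.node_index[model.node_ijk[:, 0], model.node_ijk[:, 1], model.node_ijk[:, 2]] = \
        np.arange(keep.sum())


def _mark_boundary_layers(model: VentricularModel) -> None:
    """Flag nodes whose 6-neighbourhood touches the cavity (endo) or outside (epi).

    Vacant neighbours apical of the base plane are classified by which
    analytic surface they lie beyond; vacant space above the base plane is
    the truncation and belongs to neither layer.
    """
    myo = model.node_index >= 0
    endo = np.zeros(model.n_nodes, dtype=bool)
    epi = np.zeros(model.n_nodes, dtype=bool)
    h = model.voxel_size
    for off in AXIS_OFFSETS + [(-1, 0, 0), (0, -1, 0), (0, 0, -1)]:
        ijk2 = model.node_ijk + np.asarray(off)
        inb = np.all((ijk2 >= 0) & (ijk2 < np.asarray(model.grid_shape)), axis=1)
        neigh_myo = np.zeros(model.n_nodes, dtype=bool)
        neigh_myo[inb] = myo[ijk2[inb, 0], ijk2[inb, 1], ijk2[inb, 2]]
        vacant = inb & ~neigh_myo
        npos = model.origin + ijk2 * h
        in_cavity = ellipsoid_value(npos, model.shape.endo_semi_axes) < 1.0
        above_base = npos[:, 2] > model.shape.base_z
        endo |= vacant & in_cavity & ~above_base
        epi |= vacant & ~in_cavity & ~above_base
    model.is_endo_layer = endo
    model.is_epi_layer = epi & ~endo


# ---------------------------------------------------------------------------
# ventricular coordinates and fibres

def assign_uvc(model: VentricularModel) -> VentricularModel:
    """Analytic ventricular coordinates on the ellipsoidal shell.

    apicobasal: 0 at the (epicardial) apex, 1 on the base plane, linear in z.
    rotational: angle about the long axis, degrees in [0, 360).
    transmural: 0 on the endocardial surface, 1 on the epicardial surface,
    defined by the interpolated ellipsoid through the point.
    """
    x = model.node_coords
    sh = model.shape
    c_epi = sh.epi_semi_axes[2]
    ab = (x[:, 2] + c_epi) / (sh.base_z + c_epi)
    rot = np.degrees(np.arctan2(x[:, 1], x[:, 0])) % 360.0
    tm = transmural_coordinate(x, sh)
    model.uvc = np.column_stack([np.clip(ab, 0.0, 1.0), rot, tm])
    return model


def transmural_coordinate(x: np.ndarray, shape: LvShape) -> np.ndarray:
    """Solve for s in [0, 1] with x on the ellipsoid of semi-axes endo + s*wall."""
    x = np.atleast_2d(x)
    endo = np.asarray(shape.endo_semi_axes)
    w = shape.wall_thickness
    lo = np.full(len(x), -0.45)
    hi = np.full(len(x), 1.5)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        f = np.sum((x / (endo + np.outer(mid, np.full(3, w)))) ** 2, axis=1)
        outside = f > 1.0  # point outside the trial ellipsoid -> s too small
        lo = np.where(outside, mid, lo)
        hi = np.where(outside, hi, mid)
    return np.clip(0.5 * (lo + hi), 0.0, 1.0)


def shell_normal(x: np.ndarray, shape: LvShape, tm: np.ndarray = None) -> np.ndarray:
    """Outward unit normal of the interpolated ellipsoid through each point."""
    x = np.atleast_2d(x)
    if tm is None:
        tm = transmural_coordinate(x, shape)
    endo = np.asarray(shape.endo_semi_axes)
    semi = endo + np.outer(tm, np.full(3, shape.wall_thickness))
    g = 2.0 * x / semi ** 2
    nrm = np.linalg.norm(g, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return g / nrm


def assign_fibres(model: VentricularModel, endo_helix: float = 60.0,
                  epi_helix: float = -60.0) -> VentricularModel:
    """Rule-based fibre field: helix angle linear in the transmural coordinate.

    The fibre lies in the local tangent plane of the shell, rotated from the
    circumferential direction towards the apex-base direction by the helix
    angle (+60 deg on the endocardium to -60 deg on the epicardium by
    default, the standard rule-based convention).
    """
    if model.uvc is None:
        raise ValueError("assign_uvc must run before assign_fibres")
    x = model.node_coords
    tm = model.uvc[:, 2]
    n = shell_normal(x, model.shape, tm)
    zhat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(zhat, n.shape), n)
    norm = np.linalg.norm(circ, axis=1, keepdims=True)
    degen = norm[:, 0] < 1e-6
    if degen.any():  # near the apex the long axis is parallel to the normal
        alt = np.cross(np.broadcast_to(np.array([1.0, 0.0, 0.0]), n.shape)[degen], n[degen])
        circ[degen] = alt
        norm = np.linalg.norm(circ, axis=1, keepdims=True)
    circ /= np.maximum(norm, 1e-12)
    longit = np.cross(n, circ)
    longit /= np.maximum(np.linalg.norm(longit, axis=1, keepdims=True), 1e-12)
    helix = np.radians(endo_helix + (epi_helix - endo_helix) * tm)
    f = np.cos(helix)[:, None] * circ + np.sin(helix)[:, None] * longit
    model.fibres = f / np.linalg.norm(f, axis=1, keepdims=True)
    return model


# ---------------------------------------------------------------------------
# EAM surface extraction

def unique_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = 2.0 * np.pi * i * (np.sqrt(5.0) - 1.0) / 2.0
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sample_truncated_ellipsoid(semi, base_z: float, n: int, dome: float = 0.25):
    """~n points on the boundary of {ellipsoid} ∩ {z <= base_z}.

    Points falling above the base plane are flattened onto it and lifted by a
    shallow convex dome (height ``dome`` mm) so that the convex hull keeps
    them as vertices — this closes the surface with a near-flat basal cap.
    """
    a, b, c = semi
    pts = _fibonacci_sphere(n) * np.asarray(semi)
    cap = pts[:, 2] > base_z
    if cap.any():
        # squeeze the spherical cap radially onto the base disk (continuous at
        # the rim, pole maps to the centre), then lift into a shallow dome
        cap_scale2 = max(1e-9, 1.0 - (base_z / c) ** 2)
        frac = np.clip((pts[cap, 2] - base_z) / (c - base_z), 0.0, 1.0)
        pts[cap, 0] *= np.sqrt(1.0 - frac)
        pts[cap, 1] *= np.sqrt(1.0 - frac)
        rho2n = pts[cap, 0] ** 2 / a ** 2 + pts[cap, 1] ** 2 / b ** 2
        bulge = 1.0 - rho2n / cap_scale2
        pts[cap, 2] = base_z + dome * np.clip(bulge, 0.0, 1.0)
    return pts, cap


def _triangulate_side(semi, base_z: float, target_edge: float):
    """Closed triangulation of one truncated-ellipsoid side at ~target edge length."""
    a, b, c = semi
    p = 1.6075  # Thomsen surface-area approximation
    area = 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
    n = max(64, int(1.155 * area / target_edge ** 2))
    for _ in range(10):
        pts, cap = _sample_truncated_ellipsoid(semi, base_z, n)
        hull = ConvexHull(pts, qhull_options="Qt")
        verts = np.unique(hull.simplices)
        remap = np.full(len(pts), -1, dtype=np.int64)
        remap[verts] = np.arange(len(verts))
        tri = remap[hull.simplices]
        points = pts[verts]
        capv = cap[verts]
        e = unique_edges(tri)
        mean_edge = float(np.mean(np.linalg.norm(points[e[:, 0]] - points[e[:, 1]], axis=1)))
        if abs(mean_edge - target_edge) <= 0.05 * target_edge:
            break
        n = max(64, int(n * (mean_edge / target_edge) ** 2))
    _check_closed_manifold(tri, len(points))
    return points, tri, capv


def _check_closed_manifold(triangles: np.ndarray, n_points: int) -> None:
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    e = np.sort(e, axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise RuntimeError("surface extraction produced a non-manifold or open mesh")
    euler = n_points - len(counts) + len(triangles)
    if euler != 2:
        raise RuntimeError(f"closed surface has Euler characteristic {euler} != 2")


def extract_eam_surfaces(model: VentricularModel, target_edge: float = 2.0) -> EamSurface:
    """Triangulated endo and epi surfaces linked to the myocardial volume."""
    sh = model.shape
    p_endo, t_endo, cap_endo = _triangulate_side(sh.endo_semi_axes, sh.base_z, target_edge)
    p_epi, t_epi, cap_epi = _triangulate_side(sh.epi_semi_axes, sh.base_z, target_edge)
    points = np.vstack([p_endo, p_epi])
    tri = np.vstack([t_endo, t_epi + len(p_endo)])
    side = np.concatenate([np.zeros(len(p_endo), dtype=np.int8),
                           np.ones(len(p_epi), dtype=np.int8)])
    is_cap = np.concatenate([cap_endo, cap_epi])

    ab = (points[:, 2] + sh.epi_semi_axes[2]) / (sh.base_z + sh.epi_semi_axes[2])
    rot = np.degrees(np.arctan2(points[:, 1], points[:, 0])) % 360.0
    tm = transmural_coordinate(points, sh)
    uvc = np.column_stack([np.clip(ab, 0.0, 1.0), rot, tm])

    tree = cKDTree(model.node_coords)
    _, link = tree.query(points)
    return EamSurface(points=points, triangles=tri, side=side, is_cap=is_cap,
                      uvc=uvc, volume_link=link.astype(np.int64),
                      voxel_size=model.voxel_size)


# ---------------------------------------------------------------------------
# rectangular slab (validation geometry for conduction benchmarks)

def build_slab(size_mm=(40.0, 20.0, 6.0), voxel_size: float = 1.0,
               fibre_dir=(1.0, 0.0, 0.0)) -> VentricularModel:
    """Homogeneous rectangular tissue slab with a uniform fibre field.

    Used for conduction-velocity benchmarks and refractoriness checks where
    an analytic planar geometry is wanted; carries no ventricular
    coordinates.
    """
    h = voxel_size
    n = tuple(max(1, int(round(s / h))) for s in size_mm)
    ii, jj, kk = np.meshgrid(*[np.arange(m) for m in n], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    node_index = np.arange(ijk.shape[0]).reshape(n)
    origin = np.zeros(3) + h / 2.0
    f = np.asarray(fibre_dir, dtype=float)
    f = f / np.linalg.norm(f)
    model = VentricularModel(
        voxel_size=h, shape=None, grid_shape=n, origin=origin,
        node_ijk=ijk, node_coords=origin + ijk * h, node_index=node_index)
    model.fibres = np.broadcast_to(f, (model.n_nodes, 3)).copy()
    return model


# ---------------------------------------------------------------------------
# pacing sites

def select_pacing_sites(surface: EamSurface, n_per_surface: int = 50,
                        seed: int = 0) -> list[PacingSite]:
    """Evenly spaced pacing sites per side by geodesic farthest-point sampling.

    The first site of each side is drawn with the seed; each subsequent site
    is the non-cap point farthest (surface geodesic) from all sites chosen so
    far on that side, ties broken by point index.  Endocardial sites get ids
    0..n-1, epicardial sites n..2n-1.
    """
    rng = np.random.default_rng(seed)
    sites: list[PacingSite] = []
    sid = 0
    for side in (0, 1):
        cand = np.nonzero((surface.side == side) & ~surface.is_cap)[0]
        if n_per_surface > len(cand):
            raise ValueError(f"n_per_surface={n_per_surface} exceeds {len(cand)} "
                             f"available points on side {side}")
        first = int(rng.choice(cand))
        chosen = [first]
        mind = surface.geodesic_from(first)
        for _ in range(n_per_surface - 1):
            d = mind[cand]
            d = np.where(np.isfinite(d), d, -1.0)
            nxt = int(cand[int(np.argmax(d))])
            chosen.append(nxt)
            mind = np.minimum(mind, surface.geodesic_from(nxt))
        for p in chosen:
            sites.append(PacingSite(id=sid, side=side, point_index=p,
                                    uvc=surface.uvc[p].copy(),
                                    position=surface.points[p].copy()))
            sid += 1
    return sites
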