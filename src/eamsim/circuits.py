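"""VT circuit localisation and decomposition in ventricular coordinates.

From a detected re-entrant episode: locate the exit site (where the
wavefront leaves the remodelled substrate into bulk myocardium), place an
exit-centred window in ventricular coordinates (0.4 apicobasal units, 72
degrees rotational, full transmural span), divide one VT cycle into eight
equal isochrones anchored at the exit activation, project the volumetric
isochrones onto the EAM surfaces, and split the projection into outer
(isochrones 1-4) and inner (5-8) endocardial/epicardial subregions whose
mean EAM features feed the circuit-detection analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import EamSurface, NORMAL, VentricularModel
from .propagation import VtEpisode

SUBREGIONS = ("endo_outer", "endo_inner", "epi_outer", "epi_inner")


@dataclass
class CircuitWindow:
    apicobasal: tuple[float, float]
    rotational: tuple[float, float]   # degrees; lo > hi means seam wrap-around

    def contains(self, uvc: np.ndarray) -> np.ndarray:
        ab = uvc[:, 0]
        rot = uvc[:, 1]
        lo, hi = self.rotational
        in_ab = (ab >= self.apicobasal[0]) & (ab <= self.apicobasal[1])
        if lo <= hi:
            in_rot = (rot >= lo) & (rot <= hi)
        else:                         # wraps across 0/360
            in_rot = (rot >= lo) | (rot <= hi)
        return in_ab & in_rot


@dataclass
class VtCircuit:
    episode: VtEpisode
    exit_node: int
    exit_uvc: np.ndarray
    window: CircuitWindow
    cycle_start: float
    isochrone: np.ndarray            # (n_model_nodes,) 1..8, 0 outside
    surface_isochrone: np.ndarray = None   # (n_points,) 1..8, 0 unassigned
    subregion_points: dict = field(default_factory=dict)
    subregion_features: dict = None  # (subregion, feature, site, beat) -> mean


def locate_exit_site(episode: VtEpisode, labels, model: VentricularModel,
                     boundary_mm: float = 2.0, entry_window_ms: float = 30.0) -> int:
    """Automatic exit-site heuristic for a re-entrant episode.

    Candidate nodes are remodelled nodes within ``boundary_mm`` of normal
    tissue.  For each re-entrant cycle, crossing events where a boundary
    node activates shortly *before* an adjacent normal node mark the
    wavefront entering bulk myocardium; the earliest such event per cycle
    nominates a node, and the majority vote across cycles (ties to the
    lowest node id) is the exit.
    """
    tissue = labels if isinstance(labels, np.ndarray) else labels.labels
    ep = episode
    acts = {int(ep.cond_nodes[i]): a for i, a in enumerate(ep.activations)
            if len(a)}
    ref_acts = acts.get(ep.reference_node)
    if ref_acts is None or len(ref_acts) < 3:
        raise ValueError("episode lacks a stable cycle phase at the reference node")
    cl = ep.cycle_length

    remod = np.nonzero(tissue != NORMAL)[0]
    normal = np.nonzero(tissue == NORMAL)[0]
    if len(remod) == 0 or len(normal) == 0:
        raise ValueError("exit localisation requires both remodelled and normal tissue")
    ntree = cKDTree(model.node_coords[normal])
    d, _ = ntree.query(model.node_coords[remod])
    boundary = remod[d <= boundary_mm]
    if len(boundary) == 0:
        raise ValueError("no remodelled-boundary nodes near normal tissue")

    near_normals = ntree.query_ball_point(model.node_coords[boundary],
                                          r=boundary_mm + model.voxel_size)
    cycles = [(ref_acts[k], ref_acts[k + 1]) for k in range(len(ref_acts) - 1)]
    votes = []
    for t0, t1 in cycles:
        best = None
        for bi, b in enumerate(boundary):
            ba = acts.get(int(b))
            if ba is None:
                continue
            tb = ba[(ba >= t0) & (ba < t1)]
            if len(tb) == 0:
                continue
            tb = tb[0]
            for nn in near_normals[bi]:
                na = acts.get(int(normal[nn]))
                if na is None:
                    continue
                after = na[(na >= tb) & (na <= tb + entry_window_ms)]
                if len(after):
                    phase = (tb - t0) / cl
                    if best is None or phase < best[0] or \
                            (phase == best[0] and b < best[1]):
                        best = (phase, int(b))
                    break
        if best is not None:
            votes.append(best[1])
    if not votes:
        raise ValueError("no wavefront crossing into normal tissue found")
    vals, counts = np.unique(votes, return_counts=True)
    return int(vals[np.argmax(counts)])


def define_circuit_window(exit_uvc: np.ndarray, ab_span: float = 0.4,
                          rot_span_deg: float = 72.0) -> CircuitWindow:
    """Exit-centred UVC window; apicobasal clamped shift-preserving width,
    rotational wrapping across the 0/360 seam."""
    ab, rot = float(exit_uvc[0]), float(exit_uvc[1])
    lo = ab - ab_span / 2.0
    hi = ab + ab_span / 2.0
    if lo < 0.0:
        hi = min(1.0, hi - lo)
        lo = 0.0
    elif hi > 1.0:
        lo = max(0.0, lo - (hi - 1.0))
        hi = 1.0
    rlo = (rot - rot_span_deg / 2.0) % 360.0
    rhi = (rot + rot_span_deg / 2.0) % 360.0
    return CircuitWindow(apicobasal=(lo, hi), rotational=(rlo, rhi))


def circuit_isochrones(episode: VtEpisode, window: CircuitWindow,
                       model: VentricularModel, exit_node: int,
                       n_bins: int = 8) -> tuple[np.ndarray, float]:
    """Bin one VT cycle (anchored at the exit activation) into 8 isochrones.

    Returns per-model-node isochrone indices 1..8 (0 outside the window or
    silent) and the cycle start time.
    """
    ep = episode
    sub = {int(ep.cond_nodes[i]): a for i, a in enumerate(ep.activations)}
    exit_acts = np.asarray(sub.get(exit_node, []))
    if exit_acts.size == 0:
        # fall back to the nearest active node's series
        raise ValueError("exit node has no post-stimulus activations")
    # choose a cycle fully inside the recording
    t_exit = float(exit_acts[0])
    cl = ep.cycle_length
    iso = np.zeros(model.n_nodes, dtype=np.int16)
    if model.uvc is None:
        raise ValueError("model requires ventricular coordinates")
    in_win = window.contains(model.uvc)
    for i, node in enumerate(ep.cond_nodes):
        if not in_win[node]:
            continue
        a = ep.activations[i]
        if len(a) == 0:
            continue
        t = a[(a >= t_exit) & (a < t_exit + cl)]
        if len(t) == 0:
            continue
        phase = (t[0] - t_exit) / cl
        iso[node] = 1 + min(n_bins - 1, int(phase * n_bins))
    return iso, t_exit


def project_circuit(surface: EamSurface, circuit_iso: np.ndarray,
                    model: VentricularModel, window: CircuitWindow,
                    radius_mm: float = 5.0) -> np.ndarray:
    """Modal volumetric isochrone within 5 mm of each in-window surface point.

    Ties break toward the lower isochrone index; points with no assigned
    node within the radius (or outside the window) get 0.
    """
    out = np.zeros(surface.n_points, dtype=np.int16)
    assigned = np.nonzero(circuit_iso > 0)[0]
    if len(assigned) == 0:
        return out
    tree = cKDTree(model.node_coords[assigned])
    in_win = window.contains(surface.uvc) & ~surface.is_cap
    idx = np.nonzero(in_win)[0]
    near = tree.query_ball_point(surface.points[idx], r=radius_mm)
    for k, lst in zip(idx, near):
        if not lst:
            continue
        iso_vals = circuit_iso[assigned[lst]]
        counts = np.bincount(iso_vals)
        out[k] = int(np.argmax(counts))  # argmax returns the lowest on ties
    return out


def split_inner_outer(circuit: VtCircuit, surface: EamSurface,
                      feature_maps: dict) -> VtCircuit:
    """Endo/epi x inner/outer subregions with per-feature, per-map means.

    Outer = surface isochrones 1-4, inner = 5-8.  Empty subregions are kept
    with an empty point set (some VTs have no endocardial or epicardial
    component).  ``feature_maps`` maps (site_id, beat_label) -> FeatureMap.
    """
    iso = circuit.surface_isochrone
    subsets = {
        "endo_outer": (surface.side == 0) & (iso >= 1) & (iso <= 4),
        "endo_inner": (surface.side == 0) & (iso >= 5),
        "epi_outer": (surface.side == 1) & (iso >= 1) & (iso <= 4),
        "epi_inner": (surface.side == 1) & (iso >= 5),
    }
    circuit.subregion_points = {k: np.nonzero(v)[0] for k, v in subsets.items()}
    feats = {}
    for key, fmap in feature_maps.items():
        for name, (vals, valid) in ((n, fmap.feature(n)) for n in fmap.values):
            for sub, pts in circuit.subregion_points.items():
                if len(pts) == 0:
                    feats[(sub, name) + tuple(key)] = np.nan
                    continue
                ok = pts[valid[pts]]
                feats[(sub, name) + tuple(key)] = \
                    float(np.mean(vals[ok])) if len(ok) else np.nan
    circuit.subregion_features = feats
    return circuit


def rank_sites_by_vt(sites, circuit: VtCircuit, surface: EamSurface,
                     model: VentricularModel, geodesic: bool = True) -> np.ndarray:
    """Rank pacing sites 1..P by distance to the VT exit projection.

    The exit node is projected to the nearest surface point of each side;
    each site's distance is the surface geodesic from its point to that
    side's projection (Euclidean fallback available).  Ranks are a
    permutation of 1..P, ties broken by site id.
    """
    exit_pos = model.node_coords[circuit.exit_node]
    dist = np.empty(len(sites))
    proj = {}
    for side in (0, 1):
        pts = np.nonzero((surface.side == side) & ~surface.is_cap)[0]
        proj[side] = int(pts[np.argmin(
            np.linalg.norm(surface.points[pts] - exit_pos, axis=1))])
    for k, site in enumerate(sites):
        if geodesic:
            d = surface.geodesic_from(proj[site.side])
            dist[k] = d[site.point_index]
        else:
            dist[k] = np.linalg.norm(surface.points[site.point_index] -
                                     surface.points[proj[site.side]])
    order = np.lexsort((np.array([s.id for s in sites]), dist))
    ranks = np.empty(len(sites), dtype=int)
    ranks[order] = np.arange(1, len(sites) + 1)
    return ranks


def build_circuit(episode: VtEpisode, labels, model: VentricularModel,
                  surface: EamSurface) -> VtCircuit:
    """End-to-end circuit construction for one episode."""
    exit_node = episode.exit_node
    if exit_node is None:
        exit_node = locate_exit_site(episode, labels, model)
        episode.exit_node = exit_node
    window = define_circuit_window(model.uvc[exit_node])
    iso, t0 = circuit_isochrones(episode, window, model, exit_node)
    circuit = VtCircuit(episode=episode, exit_node=exit_node,
                        exit_uvc=model.uvc[exit_node].copy(), window=window,
                        cycle_start=t0, isochrone=iso)
    circuit.surface_isochrone = project_circuit(surface, iso, model, window)
    return circuit
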