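"""Synthetic infarct substrates: dense core, border zone, conducting channels.

Emulates patchy post-infarct remodelling on the voxelized LV: randomly
seeded foci grown by stochastic dilation to a target volume fraction, a
dense (non-conducting) core surrounded by a border-zone rim, and carved
border-zone channels through the core so that re-entry is inducible.
Cohorts spread the remodelling fraction over a configurable range and split
hearts at the cohort median (hLIR above, hSIR below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .geometry import (AXIS_OFFSETS, DIAG_OFFSETS, BORDER_ZONE, DENSE_CORE,
                       NORMAL, LvShape, VentricularModel, build_idealized_lv,
                       assign_fibres, assign_uvc)

CORNER_OFFSETS = [(1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
ALL_OFFSETS = AXIS_OFFSETS + DIAG_OFFSETS + CORNER_OFFSETS  # 26-connectivity


@dataclass
class TissueLabels:
    """Per-node tissue labels plus bookkeeping for carved channels."""

    labels: np.ndarray                       # (n,) uint8: NORMAL / BORDER_ZONE / DENSE_CORE
    seed: int = 0
    channel_mouths: list = field(default_factory=list)  # (node_a, node_b) per channel
    channel_paths: list = field(default_factory=list)   # node-index arrays per channel

    @property
    def remodelling_fraction(self) -> float:
        return float(np.mean(self.labels != NORMAL))

    def copy(self) -> "TissueLabels":
        return TissueLabels(self.labels.copy(), self.seed,
                            list(self.channel_mouths),
                            [p.copy() for p in self.channel_paths])


@dataclass
class SyntheticCohort:
    hearts: list            # (VentricularModel, TissueLabels, seed) triples
    group: np.ndarray       # (n,) array of 'hLIR' / 'hSIR'
    fractions: np.ndarray   # achieved remodelling fraction per heart

    def __len__(self):
        return len(self.hearts)


def _adjacency(model: VentricularModel, offsets=ALL_OFFSETS) -> sparse.csr_matrix:
    pairs = model.neighbour_pairs(offsets)
    n = model.n_nodes
    g = sparse.coo_matrix(
        (np.ones(2 * len(pairs), dtype=np.int8),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))), shape=(n, n))
    return g.tocsr()


def generate_infarct(model: VentricularModel, target_fraction: float,
                     core_to_bz_ratio: float = 1.0, n_foci: int = None,
                     seed: int = 0, noise_amp: float = 0.35) -> TissueLabels:
    """Grow a patchy infarct covering a target fraction of the myocardium.

    The remodelled set is the sub-level set of a noisy distance field: for
    each node, w(x) = min over foci of |x - focus| * (1 + noise_amp * z(x)),
    where z is spatially smoothed white noise, and the threshold is the
    target quantile of w — the achieved fraction therefore matches the
    target exactly (well inside the ±2% contract).  Foci are seeded with a
    mild mid-wall bias so remodelling reaches both surfaces.  The dense core
    is the interior of the remodelled set (further than a rim distance from
    non-remodelled myocardium); the rim is chosen to approach
    ``core_to_bz_ratio``.
    """
    if not 0.0 <= target_fraction < 0.8:
        raise ValueError("target_fraction must be in [0, 0.8)")
    n = model.n_nodes
    labels = np.zeros(n, dtype=np.uint8)
    if target_fraction == 0.0:
        return TissueLabels(labels, seed)

    rng = np.random.default_rng(seed)
    if n_foci is None:
        n_foci = int(rng.integers(1, 5))
    target = max(int(round(target_fraction * n)), 1)

    if model.uvc is not None:
        tm = model.uvc[:, 2]
        w = 1.5 - np.abs(tm - 0.5)       # mild transmural (mid-wall) bias
    else:
        w = np.ones(n)
    foci = rng.choice(n, size=n_foci, replace=False, p=w / w.sum())

    z = rng.standard_normal(n)
    adj = _adjacency(model, AXIS_OFFSETS)
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    deg[deg == 0] = 1.0
    for _ in range(10):                   # spatially correlated roughness
        z = 0.5 * z + 0.5 * (adj @ z) / deg
    z = z / max(z.std(), 1e-12)

    d = np.min(np.linalg.norm(
        model.node_coords[:, None, :] - model.node_coords[foci][None, :, :],
        axis=2), axis=1)
    field = d * np.clip(1.0 + noise_amp * z, 0.3, None)
    order = np.argsort(field, kind="stable")
    remod = np.zeros(n, dtype=bool)
    remod[order[:target]] = True
    labels[remod] = BORDER_ZONE

    from scipy.spatial import cKDTree
    outside = np.nonzero(~remod)[0]
    if len(outside):
        dist_out, _ = cKDTree(model.node_coords[outside]).query(
            model.node_coords[remod])
        h = model.voxel_size
        # minimum rim exceeds the voxel diagonal so the core never touches
        # normal tissue even corner-to-corner (26-connectivity)
        best_rim, best_err = 1.8 * h, np.inf
        for rim in (1.8 * h, 2.2 * h, 3.1 * h):
            core_n = int(np.sum(dist_out > rim))
            bz_n = int(remod.sum()) - core_n
            ratio = core_n / bz_n if bz_n else np.inf
            err = abs(ratio - core_to_bz_ratio)
            if err < best_err:
                best_rim, best_err = rim, err
        ridx = np.nonzero(remod)[0]
        labels[ridx[dist_out > best_rim]] = DENSE_CORE
    return TissueLabels(labels, seed)


def carve_channels(labels: TissueLabels, model: VentricularModel,
                   n_channels: int = 1, width: float = 4.0,
                   seed: int = 0) -> TissueLabels:
    """Carve border-zone corridors through the dense core.

    Each channel is the set of core nodes within ``width/2`` of a shortest
    path crossing the largest core component between two normal-tissue mouth
    nodes near the component's extremes; relabelling core -> border zone
    leaves the remodelling fraction unchanged.
    """
    out = labels.copy()
    if n_channels == 0:
        return out
    core = out.labels == DENSE_CORE
    if not core.any():
        warnings.warn("no dense core present; carve_channels is a no-op")
        return out

    rng = np.random.default_rng(seed)
    adj = _adjacency(model)
    ncomp, comp = csgraph.connected_components(
        adj[core][:, core], directed=False)
    core_ids = np.nonzero(core)[0]
    sizes = np.bincount(comp)
    order = np.argsort(sizes)[::-1]

    for ch in range(n_channels):
        comp_id = order[ch % ncomp]
        nodes = core_ids[comp == comp_id]
        x = model.node_coords[nodes]
        axis = _principal_axis(x)
        proj = (x - x.mean(0)) @ axis
        end_a, end_b = nodes[int(np.argmin(proj))], nodes[int(np.argmax(proj))]
        mouth_a = _nearest_with_label(model, out.labels, end_a, NORMAL)
        mouth_b = _nearest_with_label(model, out.labels, end_b, NORMAL)
        if mouth_a is None or mouth_b is None:
            warnings.warn("no normal tissue adjacent to core; channel skipped")
            continue
        path = _shortest_path_through(model, adj, out.labels, mouth_a, mouth_b,
                                      prefer=core)
        if path is None:
            warnings.warn("no route through the core component; channel skipped")
            continue
        d = np.min(np.linalg.norm(
            model.node_coords[:, None, :] - model.node_coords[path][None, :, :],
            axis=2), axis=1)
        corridor = core & (d <= width / 2.0)
        out.labels[corridor] = BORDER_ZONE
        out.channel_mouths.append((int(mouth_a), int(mouth_b)))
        out.channel_paths.append(np.asarray(path))
        core = out.labels == DENSE_CORE
    return out


def _principal_axis(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[0]


def _nearest_with_label(model, labels, node, wanted):
    d = np.linalg.norm(model.node_coords - model.node_coords[node], axis=1)
    cand = np.nonzero(labels == wanted)[0]
    if len(cand) == 0:
        return None
    return int(cand[int(np.argmin(d[cand]))])


def _shortest_path_through(model, adj, labels, a, b, prefer):
    """Shortest path a->b that prefers crossing the preferred (core) set."""
    # edge weights: geometric length, scaled down inside the preferred set so
    # the route tunnels through the core instead of around it
    coo = adj.tocoo()
    w = np.linalg.norm(model.node_coords[coo.row] - model.node_coords[coo.col], axis=1)
    bonus = prefer[coo.row] & prefer[coo.col]
    w = np.where(bonus, 0.2 * w, w)
    g = sparse.csr_matrix((w, (coo.row, coo.col)), shape=adj.shape)
    _, pred = csgraph.dijkstra(g, directed=False, indices=a,
                               return_predecessors=True)
    if pred[b] < 0 and a != b:
        return None
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            return None
        path.append(int(p))
    return path[::-1]


def engineered_channel_substrate(model: VentricularModel,
                                 rot_center: float = 200.0,
                                 rot_halfwidth: float = 55.0,
                                 channel_ab: tuple = (0.40, 0.60)) -> TissueLabels:
    """Deterministic single-channel substrate for induction studies.

    A dense-core sector spans ``rot_center`` ± ``rot_halfwidth`` over the full
    apicobasal and transmural extent; a border-zone corridor (the channel)
    crosses it rotationally in the ``channel_ab`` apicobasal band.  The only
    re-entrant path is therefore rotational: around the ventricle through
    normal myocardium and back through the slow channel.  Channel mouths
    (normal-tissue nodes at the two core-sector edges, adjacent to the
    corridor) are recorded for validating exit-site localisation.
    """
    if model.uvc is None:
        raise ValueError("model requires ventricular coordinates")
    ab = model.uvc[:, 0]
    rot = model.uvc[:, 1]

    def angdiff(a, b):
        return np.abs((a - b + 180.0) % 360.0 - 180.0)

    in_patch = angdiff(rot, rot_center) <= rot_halfwidth
    corridor = in_patch & (ab >= channel_ab[0]) & (ab <= channel_ab[1])
    labels = np.zeros(model.n_nodes, dtype=np.uint8)
    labels[in_patch] = DENSE_CORE
    labels[corridor] = BORDER_ZONE

    out = TissueLabels(labels)
    mid_ab = 0.5 * (channel_ab[0] + channel_ab[1])
    corridor_idx = np.nonzero(corridor)[0]
    for edge in ((rot_center - rot_halfwidth) % 360.0,
                 (rot_center + rot_halfwidth) % 360.0):
        cand = np.nonzero((labels == NORMAL) & (np.abs(ab - mid_ab) < 0.06) &
                          (angdiff(rot, edge) < 18.0))[0]
        if len(cand) == 0:
            continue
        d = np.min(np.linalg.norm(
            model.node_coords[cand][:, None, :] -
            model.node_coords[corridor_idx][None, :, :], axis=2), axis=1)
        out.channel_mouths.append(int(cand[int(np.argmin(d))]))
    return out


def generate_cohort(n_hearts: int, fraction_low: float = 0.10,
                    fraction_high: float = 0.50, seed: int = 0,
                    shape: LvShape = None, voxel_size: float = 2.0,
                    n_channels: int = 1, core_to_bz_ratio: float = 1.0,
                    share_geometry: bool = True) -> SyntheticCohort:
    """Cohort of hearts with remodelling fractions spread over a range.

    Target fractions are evenly spaced over [fraction_low, fraction_high];
    hearts above the cohort median are labelled hLIR, the rest hSIR.  All
    randomness derives from per-heart seeds spawned from the cohort seed.
    By default all hearts share one geometry object (infarcts differ).
    """
    if n_hearts < 2:
        raise ValueError("n_hearts must be >= 2")
    if not fraction_high > fraction_low >= 0:
        raise ValueError("degenerate remodelling-fraction range")
    targets = np.linspace(fraction_low, fraction_high, n_hearts)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_hearts)]

    base_model = None
    hearts = []
    for i in range(n_hearts):
        if base_model is None or not share_geometry:
            m = build_idealized_lv(shape, voxel_size)
            assign_uvc(m)
            assign_fibres(m)
            if share_geometry:
                base_model = m
        else:
            m = base_model
        lab = generate_infarct(m, float(targets[i]),
                               core_to_bz_ratio=core_to_bz_ratio,
                               seed=child_seeds[i])
        lab = carve_channels(lab, m, n_channels=n_channels,
                             seed=child_seeds[i] + 1)
        hearts.append((m, lab, child_seeds[i]))

    fractions = np.array([lab.remodelling_fraction for _, lab, _ in hearts])
    order = np.argsort(fractions, kind="stable")  # median split, sizes differ <= 1
    group = np.empty(n_hearts, dtype=object)
    half = n_hearts // 2
    group[order[:half]] = "hSIR"
    group[order[half:]] = "hLIR"
    return SyntheticCohort(hearts=hearts, group=group, fractions=fractions)
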