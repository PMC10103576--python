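"""Unipolar electrogram synthesis from transmembrane potential fields.

The extracellular potential at an observation point x follows the
infinite-volume-conductor solution of the Poisson coupling between
intracellular and extracellular domains:

    phi_e(x) = -(sigma_i / (4 pi sigma_e)) * integral  grad Vm(y) . (x - y) / |x - y|^3  dV

discretised as a sum over myocardial voxels (central-difference gradients,
voxel-volume weights).  Contributions from nodes within one voxel of the
observation point are excluded (singularity regularization).  For a fixed
geometry the whole map Vm -> potentials is a precomputed dense linear
operator reused across time samples and pacing sites.  Signals are sampled
at 400 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, signal

from .geometry import EamSurface, VentricularModel
from .propagation import VmTrace

EGM_FS_HZ = 400.0
EGM_DT_MS = 1000.0 / EGM_FS_HZ


@dataclass
class ElectrogramMap:
    """Unipolar signals over the EAM surface for one paced beat."""

    signals: np.ndarray          # (n_points, n_samples), mV
    times: np.ndarray            # ms, uniform at 400 Hz
    activation: np.ndarray       # (n_points,) ms, NaN when silent
    beat: str                    # 'S1' or 'S2'
    site_id: int
    valid: np.ndarray            # (n_points,) bool — False on cap points

    @property
    def fs_hz(self) -> float:
        return 1000.0 / (self.times[1] - self.times[0])


class UnipolarForwardOperator:
    """Dense linear map from conducting-node Vm to surface-point potentials."""

    def __init__(self, model: VentricularModel, surface: EamSurface,
                 cond_nodes: np.ndarray, conductivity_ratio: float = 0.4,
                 chunk: int = 512):
        self.model = model
        self.surface = surface
        self.cond_nodes = cond_nodes
        h = model.voxel_size
        scale = conductivity_ratio / (4.0 * np.pi) * h ** 3
        grads = _gradient_operators(model, cond_nodes)
        pts = surface.points
        nodes = model.node_coords[cond_nodes]
        excl = np.sqrt(3.0) * h  # one voxel diagonal around the electrode
        A = np.zeros((len(pts), len(cond_nodes)), dtype=np.float32)
        for lo in range(0, len(pts), chunk):
            p = pts[lo:lo + chunk]
            r = p[:, None, :] - nodes[None, :, :]
            d = np.linalg.norm(r, axis=2)
            np.maximum(d, 1e-6, out=d)
            k = -scale / d ** 3
            k[d < excl] = 0.0
            blk = np.zeros((len(p), len(cond_nodes)))
            for a in range(3):
                blk += (grads[a].T @ (k * r[:, :, a]).T).T
            A[lo:lo + chunk] = blk.astype(np.float32)
        self.matrix = A

    def apply(self, vm: np.ndarray) -> np.ndarray:
        """vm: (n_cond, n_t) mV -> potentials (n_points, n_t) mV.

        The spatial mean is removed first: the kernel annihilates constant
        fields analytically, and subtracting the constant mode keeps that
        exact in single precision.
        """
        vm = np.asarray(vm, dtype=np.float32)
        vm = vm - vm.mean(axis=0, keepdims=True)
        return self.matrix @ vm


def _gradient_operators(model: VentricularModel, cond_nodes: np.ndarray):
    """Sparse per-axis spatial-derivative operators over the conducting nodes.

    Central differences where both neighbours conduct, one-sided at
    boundaries and next to excluded scar, zero when isolated along the axis.
    """
    h = model.voxel_size
    sub = np.full(model.n_nodes, -1, dtype=np.int64)
    sub[cond_nodes] = np.arange(len(cond_nodes))
    ijk = model.node_ijk[cond_nodes]
    n = len(cond_nodes)
    ops = []
    gs = np.asarray(model.grid_shape)
    for a in range(3):
        nb = {}
        for s in (+1, -1):
            ijk2 = ijk.copy()
            ijk2[:, a] += s
            ok = (ijk2[:, a] >= 0) & (ijk2[:, a] < gs[a])
            j = np.full(n, -1, dtype=np.int64)
            idx = model.node_index[ijk2[ok, 0], ijk2[ok, 1], ijk2[ok, 2]]
            j[ok] = np.where(idx >= 0, sub[np.maximum(idx, 0)], -1)
            nb[s] = j
        fwd, bwd = nb[+1], nb[-1]
        rows, cols, vals = [], [], []
        both = (fwd >= 0) & (bwd >= 0)
        i = np.nonzero(both)[0]
        rows += [i, i]
        cols += [fwd[i], bwd[i]]
        vals += [np.full(len(i), 0.5 / h), np.full(len(i), -0.5 / h)]
        only_f = (fwd >= 0) & (bwd < 0)
        i = np.nonzero(only_f)[0]
        rows += [i, i]
        cols += [fwd[i], i]
        vals += [np.full(len(i), 1.0 / h), np.full(len(i), -1.0 / h)]
        only_b = (fwd < 0) & (bwd >= 0)
        i = np.nonzero(only_b)[0]
        rows += [i, i]
        cols += [i, bwd[i]]
        vals += [np.full(len(i), 1.0 / h), np.full(len(i), -1.0 / h)]
        ops.append(sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)))
    return ops


def resample_to_400hz(signals: np.ndarray, dt_ms: float) -> tuple[np.ndarray, float]:
    """Resample signals (…, n_t) from dt_ms to the 2.5 ms EAM sampling."""
    if abs(dt_ms - EGM_DT_MS) < 1e-9:
        return signals, EGM_DT_MS
    from fractions import Fraction
    frac = Fraction(dt_ms / EGM_DT_MS).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    return signal.resample_poly(signals, up, down, axis=-1), EGM_DT_MS


def compute_unipolar(trace: VmTrace, surface: EamSurface,
                     forward: UnipolarForwardOperator = None,
                     model: VentricularModel = None,
                     conductivity_ratio: float = 0.4,
                     beat: str = "S1") -> ElectrogramMap:
    """Unipolar electrogram map for one beat window of a simulated trace."""
    if forward is None:
        if model is None:
            raise ValueError("either a forward operator or the model is required")
        forward = UnipolarForwardOperator(model, surface, trace.cond_nodes,
                                          conductivity_ratio)
    t0, t1 = trace.beat_windows[beat]
    sel = (trace.sample_times >= t0) & (trace.sample_times < t1)
    vm = trace.vm[sel].T.astype(np.float32)          # (n_cond, n_t)
    phi = forward.apply(vm)
    dt = float(np.median(np.diff(trace.sample_times[sel])))
    phi, dt = resample_to_400hz(phi, dt)
    times = t0 + np.arange(phi.shape[1]) * dt

    act_cond = trace.activation_time_in(t0, t1)
    act_by_node = np.full(trace.n_model_nodes, np.nan)
    act_by_node[trace.cond_nodes] = act_cond
    activation = act_by_node[surface.volume_link]
    site_id = trace.site.id if trace.site is not None else -1
    return ElectrogramMap(signals=phi, times=times, activation=activation,
                          beat=beat, site_id=site_id,
                          valid=~surface.is_cap)


def assemble_map_set(model, labels, surface, sites, protocols,
                     sim_config=None, forward=None):
    """Run the pacing protocols for every site and build the EAM map set.

    ``protocols`` maps protocol name -> S2 coupling (None for S1-only, e.g.
    {'S1': None, 'S2_360': 360.0}); the S1 map comes from the S1-only run,
    matching one simulation per (site, protocol).  Non-captured beats are
    recorded as absent (missing key), and the dict is keyed by
    (site_id, beat_label).
    """
    from .propagation import deliver_s1s2

    maps = {}
    capture_log = []
    for site in sites:
        for name, coupling in protocols.items():
            trace = deliver_s1s2(model, labels, site, coupling, sim_config)
            if forward is None:
                forward = UnipolarForwardOperator(model, surface, trace.cond_nodes)
            if coupling is None:
                beats = [("S1", "S1")]
            else:
                beats = [(f"S2_{int(coupling)}", "S2")]
            for label, beat in beats:
                ok = trace.capture.get(beat, False)
                capture_log.append((site.id, label, bool(ok)))
                if ok:
                    maps[(site.id, label)] = compute_unipolar(
                        trace, surface, forward=forward, beat=beat)
    return maps, capture_log, forward


def export_signal_csv(egm_map: ElectrogramMap, point_index: int, path):
    """One point's unipolar signal as a two-column CSV (time_ms, phi_mv)."""
    import csv
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_ms", "phi_mv"])
        for t, v in zip(egm_map.times, egm_map.signals[point_index]):
            w.writerow([f"{t:.6g}", f"{v:.6g}"])
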