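"""Monodomain propagation with a modified Mitchell–Schaeffer ionic model.

The transmembrane potential is evolved on the voxel lattice with an
18-neighbour finite-difference operator whose second moments reproduce the
anisotropic conductivity tensor built from the fibre field (consistent for
longitudinal:transverse ratios up to 4:1).  The two-variable
Mitchell–Schaeffer kinetics are integrated explicitly; the normalized
potential u in [0, 1] maps to millivolts as Vm = -80 + 100 u.  Dense-core
scar is excluded from the conducting domain; border zone conducts with
reduced diffusivity, slower upstroke and prolonged recovery, reproducing
slow conduction and decremental behaviour to premature stimuli.

Units: mm, ms, mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .geometry import (AXIS_OFFSETS, DIAG_OFFSETS, DENSE_CORE, NORMAL,
                       BORDER_ZONE, PacingSite, VentricularModel)

VM_REST = -80.0
VM_SPAN = 100.0
ACT_THRESHOLD_MV = -20.0  # upstroke detection; u = 0.6
_U_ACT = (ACT_THRESHOLD_MV - VM_REST) / VM_SPAN


@dataclass
class MembraneParams:
    """Mitchell–Schaeffer parameters plus diffusivities for one tissue type.

    tau_in is deliberately slower than the classic 0.3 ms so that the
    depolarization front stays resolvable on the coarse (2 mm) lattices this
    package targets; CV is set by d_long/d_trans (mm^2/ms).
    """

    tau_in: float = 1.0
    tau_out: float = 12.0
    tau_open: float = 40.0
    tau_close: float = 90.0
    u_gate: float = 0.13
    d_long: float = 1.35
    d_trans: float = 0.3375       # 4:1 anisotropy


#: border zone: ~60% slower conduction, slowed upstroke, long recovery
DEFAULT_PARAMS = {
    NORMAL: MembraneParams(),
    BORDER_ZONE: MembraneParams(tau_in=2.0, tau_out=20.0, tau_open=120.0,
                                tau_close=200.0, d_long=0.55, d_trans=0.275),
}


@dataclass
class SimConfig:
    dt: float = 0.1                    # ms, explicit step
    output_dt: float = 2.5             # ms, Vm sampling (400 Hz)
    stim_radius: float = 2.0           # mm
    stim_duration: float = 2.0         # ms
    stim_amplitude: float = 3.2        # du/dt, ~2x surface-site diastolic threshold
    s1_time: float = 5.0               # ms
    beat_window: float = 300.0         # ms recorded after the last stimulus
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    record_vm: bool = True
    capture_min_fraction: float = 0.10
    capture_far_mm: float = 10.0


@dataclass
class StimulusProtocol:
    site: PacingSite
    s1_time: float = 5.0
    s2_coupling: float = None          # ms after S1, or None
    radius: float = 2.0
    duration: float = 2.0
    amplitude: float = 3.2


@dataclass
class VmTrace:
    """Simulation output restricted to the conducting nodes.

    ``activations[i]`` lists upstroke times (ms) of conducting node i;
    ``cond_nodes`` maps conducting order back to model node ids.  ``vm`` is
    (n_samples, n_cond) in mV or None when recording was disabled.
    """

    cond_nodes: np.ndarray
    node_coords: np.ndarray
    vm: np.ndarray
    sample_times: np.ndarray
    activations: list
    beat_windows: dict               # beat name -> (t0, t1)
    capture: dict                    # beat name -> bool
    site: PacingSite = None
    n_model_nodes: int = 0

    def activation_time_in(self, t0: float, t1: float) -> np.ndarray:
        """First upstroke in [t0, t1) per conducting node, NaN when silent."""
        out = np.full(len(self.cond_nodes), np.nan)
        for i, acts in enumerate(self.activations):
            for t in acts:
                if t0 <= t < t1:
                    out[i] = t
                    break
        return out

    def beat_activation(self, beat: str) -> np.ndarray:
        t0, t1 = self.beat_windows[beat]
        return self.activation_time_in(t0, t1)


@dataclass
class VtEpisode:
    site_id: int
    stage: str                       # 'S2' or 'S3'
    coupling: float
    cycle_length: float
    cycle_count: int
    reference_node: int              # model node id
    cond_nodes: np.ndarray
    node_coords: np.ndarray
    activations: list                # post-stimulus activation times per cond node
    stimulus_end: float
    exit_node: int = None


class NumericalInstability(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# operator assembly

def _tensor_components(model, labels, params):
    tissue = labels if isinstance(labels, np.ndarray) else labels.labels
    n = model.n_nodes
    d_l = np.zeros(n)      # labels without parameters (dense core) stay 0;
    d_t = np.zeros(n)      # they are excluded from the conducting domain
    for lab, p in params.items():
        m = tissue == lab
        d_l[m] = p.d_long
        d_t[m] = p.d_trans
    f = model.fibres
    comps = {}
    for a in range(3):
        for b in range(a, 3):
            c = (d_l - d_t) * f[:, a] * f[:, b]
            if a == b:
                c = c + d_t
            comps[(a, b)] = c
    return comps


def build_diffusion_operator(model: VentricularModel, labels,
                             params=None) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse monodomain diffusion operator over the conducting nodes.

    Uses an 18-point lattice stencil whose edge weights satisfy the
    second-moment condition sum w * delta delta^T = 2 D (with per-edge
    tensor averaging), i.e. it is a consistent discretisation of
    div(D grad u) with natural no-flux boundaries; dense core is simply
    absent from the domain.
    """
    params = params or DEFAULT_PARAMS
    tissue = labels if isinstance(labels, np.ndarray) else labels.labels
    cond = tissue != DENSE_CORE
    cond_nodes = np.nonzero(cond)[0]
    sub = np.full(model.n_nodes, -1, dtype=np.int64)
    sub[cond_nodes] = np.arange(len(cond_nodes))
    h = model.voxel_size
    comps = _tensor_components(model, labels, params)

    rows, cols, vals = [], [], []

    def add(pairs, w):
        keep = w > 0
        rows.append(pairs[keep, 0]); cols.append(pairs[keep, 1]); vals.append(w[keep])
        rows.append(pairs[keep, 1]); cols.append(pairs[keep, 0]); vals.append(w[keep])

    def mean(comp, pairs):
        return 0.5 * (comp[cond_nodes[pairs[:, 0]]] + comp[cond_nodes[pairs[:, 1]]])

    def restrict(pairs):
        i, j = sub[pairs[:, 0]], sub[pairs[:, 1]]
        keep = (i >= 0) & (j >= 0)
        return np.column_stack([i[keep], j[keep]])

    axis_pairs = [restrict(model.neighbour_pairs([off])) for off in AXIS_OFFSETS]
    for a, off in enumerate(AXIS_OFFSETS):
        pairs = axis_pairs[a]
        if len(pairs) == 0:
            continue
        w = mean(comps[(a, a)], pairs)
        for b in range(3):
            if b != a:
                key = (min(a, b), max(a, b))
                w = w - np.abs(mean(comps[key], pairs))
        add(pairs, np.maximum(w, 0.0) / h ** 2)
    for off in DIAG_OFFSETS:
        ax = [i for i, v in enumerate(off) if v != 0]
        a, b = ax
        sgn = off[a] * off[b]
        pairs = restrict(model.neighbour_pairs([off]))
        if len(pairs) == 0:
            continue
        dab = mean(comps[(a, b)], pairs)
        w = (np.abs(dab) + sgn * dab) / (2.0 * h ** 2)
        add(pairs, w)

    nsub = len(cond_nodes)
    if rows:
        W = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nsub, nsub)).tocsr()
    else:
        W = sparse.csr_matrix((nsub, nsub))
    L = W - sparse.diags(np.asarray(W.sum(axis=1)).ravel())
    return L.tocsr(), cond_nodes


# ---------------------------------------------------------------------------
# stepper

class MonodomainStepper:
    """Explicit time-stepper holding the full simulation state.

    Supports checkpoint/restore so that programmed-stimulation scans can
    branch from the end of a drive train without re-simulating it.
    """

    def __init__(self, model, labels, config: SimConfig = None):
        self.model = model
        self.config = config or SimConfig()
        self.L, self.cond_nodes = build_diffusion_operator(
            model, labels, self.config.params)
        self.coords = model.node_coords[self.cond_nodes]
        tissue = labels if isinstance(labels, np.ndarray) else labels.labels
        tis = tissue[self.cond_nodes]
        n = len(self.cond_nodes)
        self.tau_in = np.empty(n); self.tau_out = np.empty(n)
        self.tau_open = np.empty(n); self.tau_close = np.empty(n)
        self.u_gate = np.empty(n)
        for lab, p in self.config.params.items():
            m = tis == lab
            self.tau_in[m] = p.tau_in; self.tau_out[m] = p.tau_out
            self.tau_open[m] = p.tau_open; self.tau_close[m] = p.tau_close
            self.u_gate[m] = p.u_gate
        self.u = np.zeros(n)
        self.h = np.ones(n)
        self.t = 0.0
        self.stimuli = []            # (mask, t_on, t_off, amplitude)
        self.activations = [[] for _ in range(n)]
        self.vm_samples = []
        self.sample_times = []
        self._next_sample = 0.0

    # -- protocol construction ------------------------------------------------
    def add_stimulus(self, position, t_on, duration=None, radius=None,
                     amplitude=None):
        c = self.config
        duration = c.stim_duration if duration is None else duration
        radius = c.stim_radius if radius is None else radius
        amplitude = c.stim_amplitude if amplitude is None else amplitude
        d = np.linalg.norm(self.coords - np.asarray(position), axis=1)
        mask = np.nonzero(d <= radius)[0]
        # coarse-lattice electrode footprint: a physical 2 mm ball covers only
        # 0-4 voxel centres at 2 mm resolution, too few to source a wave, so
        # guarantee a minimum of 8 stimulated nodes (nearest conducting ones
        # within 2.5 radii)
        if len(mask) < 8:
            near = np.argsort(d, kind="stable")[:8]
            near = near[d[near] <= 2.5 * radius]
            mask = np.union1d(mask, near)
        self.stimuli.append((mask, float(t_on), float(t_on) + duration, amplitude))

    # -- state management -----------------------------------------------------
    def checkpoint(self):
        return (self.t, self.u.copy(), self.h.copy(),
                [list(a) for a in self.activations], self._next_sample)

    def restore(self, chk):
        self.t, u, h, acts, self._next_sample = chk
        self.u = u.copy(); self.h = h.copy()
        self.activations = [list(a) for a in acts]
        self.vm_samples = []; self.sample_times = []

    def is_quiescent(self, tol: float = 0.02) -> bool:
        return bool(np.max(self.u) < tol)

    # -- integration ----------------------------------------------------------
    def run(self, until_t: float, record_vm: bool = None,
            stop_if_quiescent_after: float = None):
        c = self.config
        record_vm = c.record_vm if record_vm is None else record_vm
        dt = c.dt
        check_every = max(1, int(round(25.0 / dt)))
        step = 0
        with np.errstate(over="ignore", invalid="ignore"):  # blow-ups are
            self._run_loop(until_t, record_vm, stop_if_quiescent_after,
                           dt, check_every, step)           # caught below

    def _run_loop(self, until_t, record_vm, stop_if_quiescent_after, dt,
                  check_every, step):
        c = self.config
        while self.t < until_t - 1e-9:
            if record_vm and self.t >= self._next_sample - 1e-9:
                self.vm_samples.append(
                    (VM_REST + VM_SPAN * self.u).astype(np.float32))
                self.sample_times.append(self.t)
                self._next_sample += c.output_dt
            u, h = self.u, self.h
            du = self.L @ u
            du += h * u * u * (1.0 - u) / self.tau_in
            du -= u / self.tau_out
            for mask, t_on, t_off, amp in self.stimuli:
                if t_on <= self.t < t_off:
                    du[mask] += amp
            dh = np.where(u < self.u_gate,
                          (1.0 - h) / self.tau_open, -h / self.tau_close)
            u_new = u + dt * du
            crossed = np.nonzero((u_new >= _U_ACT) & (u < _U_ACT))[0]
            t_new = self.t + dt
            for i in crossed:
                self.activations[i].append(t_new)
            self.h = h + dt * dh
            self.u = u_new
            self.t = t_new
            step += 1
            if step % check_every == 0:
                mx = float(np.max(np.abs(self.u)))
                if not np.isfinite(mx) or mx > 3.0:
                    raise NumericalInstability(
                        f"|u| = {mx:.2f} at t = {self.t:.1f} ms "
                        f"(dt = {dt}, voxel = {self.model.voxel_size} mm)")
                if (stop_if_quiescent_after is not None
                        and self.t > stop_if_quiescent_after
                        and self.is_quiescent()):
                    break

    def to_trace(self, beat_windows: dict, site: PacingSite = None) -> VmTrace:
        vm = np.asarray(self.vm_samples, dtype=np.float32) if self.vm_samples else None
        trace = VmTrace(
            cond_nodes=self.cond_nodes, node_coords=self.coords, vm=vm,
            sample_times=np.asarray(self.sample_times),
            activations=[np.asarray(a) for a in self.activations],
            beat_windows=dict(beat_windows), capture={}, site=site,
            n_model_nodes=self.model.n_nodes)
        for beat in beat_windows:
            trace.capture[beat] = detect_capture(trace, site, beat) if site is not None else None
        return trace


# ---------------------------------------------------------------------------
# protocols

def run_monodomain(model, labels, protocol: StimulusProtocol,
                   sim_config: SimConfig = None) -> VmTrace:
    """Single S1 (plus optional S2) pacing from one site."""
    c = sim_config or SimConfig()
    stepper = MonodomainStepper(model, labels, c)
    s1 = protocol.s1_time
    stepper.add_stimulus(protocol.site.position, s1, protocol.duration,
                         protocol.radius, protocol.amplitude)
    windows = {}
    if protocol.s2_coupling is None:
        end = s1 + c.beat_window
        windows["S1"] = (s1, end)
    else:
        s2 = s1 + protocol.s2_coupling
        stepper.add_stimulus(protocol.site.position, s2, protocol.duration,
                             protocol.radius, protocol.amplitude)
        end = s2 + c.beat_window
        windows["S1"] = (s1, s2)
        windows["S2"] = (s2, end)
    stepper.run(end)
    return stepper.to_trace(windows, protocol.site)


def deliver_s1s2(model, labels, site: PacingSite, s2_coupling: float = None,
                 sim_config: SimConfig = None) -> VmTrace:
    c = sim_config or SimConfig()
    proto = StimulusProtocol(site=site, s1_time=c.s1_time,
                             s2_coupling=s2_coupling, radius=c.stim_radius,
                             duration=c.stim_duration,
                             amplitude=c.stim_amplitude)
    return run_monodomain(model, labels, proto, c)


def detect_capture(trace: VmTrace, site, beat: str = "S1",
                   min_fraction: float = 0.10, far_mm: float = 10.0) -> bool:
    """A beat captured iff >=10% of conducting nodes beyond 10 mm of the
    site activate inside the beat window."""
    if beat not in trace.beat_windows:
        return False
    pos = site.position if hasattr(site, "position") else np.asarray(site)
    t0, t1 = trace.beat_windows[beat]
    far = np.linalg.norm(trace.node_coords - pos, axis=1) > far_mm
    if far.sum() == 0:
        return False
    act = trace.activation_time_in(t0, t1)
    frac = np.mean(np.isfinite(act[far]))
    return bool(frac >= min_fraction)


# ---------------------------------------------------------------------------
# re-entry detection and VT induction

def detect_reentry(trace: VmTrace, stimulus_end: float,
                   min_cycles: int = 2, site_id: int = -1, stage: str = "S2",
                   coupling: float = np.nan) -> list[VtEpisode]:
    """Detect sustained re-entrant activity after the last stimulus.

    A node re-activating periodically at least ``min_cycles`` full cycles
    (min_cycles + 1 upstrokes) after ``stimulus_end`` defines an episode;
    the cycle length is the median inter-activation interval at the
    reference node (the node with most post-stimulus activations, ties to
    the lowest index).
    """
    post = [a[a > stimulus_end] if len(a) else a for a in trace.activations]
    counts = np.array([len(a) for a in post])
    if counts.max(initial=0) < min_cycles + 1:
        return []
    ref = int(np.argmax(counts))
    intervals = np.diff(post[ref])
    cl = float(np.median(intervals))
    if cl <= 0:
        return []
    episode = VtEpisode(
        site_id=site_id, stage=stage, coupling=coupling, cycle_length=cl,
        cycle_count=int(counts[ref]) - 1,
        reference_node=int(trace.cond_nodes[ref]),
        cond_nodes=trace.cond_nodes, node_coords=trace.node_coords,
        activations=post, stimulus_end=stimulus_end)
    return [episode]


@dataclass
class InductionConfig:
    n_drive: int = 6
    drive_cl: float = 600.0
    s2_start: float = 400.0
    s2_step: float = 10.0
    s2_min: float = 150.0
    observe: float = 1000.0          # ms of observation after the last stimulus
    stop_after_first: bool = True    # stop scanning a site once VT is induced


def _induction_sites(model, labels, n_sites, seed):
    """Farthest-point sample of conducting nodes (Euclidean greedy)."""
    tissue = labels if isinstance(labels, np.ndarray) else labels.labels
    cand = np.nonzero(tissue != DENSE_CORE)[0]
    rng = np.random.default_rng(seed)
    first = int(rng.choice(cand))
    chosen = [first]
    d = np.linalg.norm(model.node_coords[cand] - model.node_coords[first], axis=1)
    while len(chosen) < min(n_sites, len(cand)):
        nxt = int(cand[int(np.argmax(d))])
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(
            model.node_coords[cand] - model.node_coords[nxt], axis=1))
    return chosen


def induce_vt(model, labels, n_induction_sites: int = 17,
              induction_config: InductionConfig = None,
              sim_config: SimConfig = None, seed: int = 0) -> list[VtEpisode]:
    """Programmed stimulation: drive train, then S2 (then S2+S3) scans.

    From each farthest-point-sampled site a drive train is delivered; an
    extra-stimulus is scanned downward until block or re-entry, and on block
    a second extra-stimulus is scanned.  Distinct episodes (exit sites
    farther than 10 mm apart or cycle lengths differing by >10%) are
    returned.
    """
    ic = induction_config or InductionConfig()
    c = sim_config or SimConfig()
    c = replace(c, record_vm=False)
    sites = _induction_sites(model, labels, n_induction_sites, seed)
    episodes: list[VtEpisode] = []

    for snum, node in enumerate(sites):
        pos = model.node_coords[node]
        stepper = MonodomainStepper(model, labels, c)
        t_last = c.s1_time + (ic.n_drive - 1) * ic.drive_cl
        for b in range(ic.n_drive):
            stepper.add_stimulus(pos, c.s1_time + b * ic.drive_cl)
        stepper.run(t_last + c.stim_duration + 1.0, record_vm=False)
        chk = stepper.checkpoint()
        # quick capture check of the drive itself
        drive_acts = sum(len(a) for a in stepper.activations)
        if drive_acts < 0.1 * len(stepper.u):
            continue

        found = _scan_extra_stimuli(stepper, chk, pos, t_last, ic, c,
                                    snum, model, labels)
        for ep in found:
            if not _is_duplicate(ep, episodes, model, labels):
                episodes.append(ep)
        if episodes and ic.stop_after_first:
            # keep scanning remaining sites for *distinct* circuits
            continue
    return episodes


def _scan_extra_stimuli(stepper, chk, pos, t_last, ic, c, site_num,
                        model, labels):
    last_captured = None
    for coupling in np.arange(ic.s2_start, ic.s2_min - 1e-9, -ic.s2_step):
        stepper.restore(chk)
        t_s2 = t_last + coupling
        stepper.stimuli = [(stepper.stimuli[0][0], t_s2, t_s2 + c.stim_duration,
                            c.stim_amplitude)]
        stim_end = t_s2 + c.stim_duration
        stepper.run(stim_end + ic.observe, record_vm=False,
                    stop_if_quiescent_after=stim_end + 50.0)
        trace = stepper.to_trace({}, None)
        eps = detect_reentry(trace, stim_end, site_id=site_num, stage="S2",
                             coupling=coupling)
        if eps:
            return eps
        captured = _any_far_activation(stepper, pos, t_s2)
        if captured:
            last_captured = coupling
        elif last_captured is not None:
            break  # block reached; move on to S2+S3
    if last_captured is None:
        return []
    s2c = last_captured
    for coupling in np.arange(ic.s2_start, ic.s2_min - 1e-9, -ic.s2_step):
        stepper.restore(chk)
        t_s2 = t_last + s2c
        t_s3 = t_s2 + coupling
        mask = stepper.stimuli[0][0] if stepper.stimuli else None
        stepper.stimuli = [(mask, t_s2, t_s2 + c.stim_duration, c.stim_amplitude),
                           (mask, t_s3, t_s3 + c.stim_duration, c.stim_amplitude)]
        stim_end = t_s3 + c.stim_duration
        stepper.run(stim_end + ic.observe, record_vm=False,
                    stop_if_quiescent_after=stim_end + 50.0)
        trace = stepper.to_trace({}, None)
        eps = detect_reentry(trace, stim_end, site_id=site_num, stage="S3",
                             coupling=coupling)
        if eps:
            return eps
        if not _any_far_activation(stepper, pos, t_s3):
            break
    return []


def _any_far_activation(stepper, pos, t_after):
    far = np.linalg.norm(stepper.coords - pos, axis=1) > 10.0
    idx = np.nonzero(far)[0]
    hits = 0
    for i in idx:
        a = stepper.activations[i]
        if a and a[-1] > t_after:
            hits += 1
            if hits >= max(1, int(0.05 * len(idx))):
                return True
    return False


def _is_duplicate(ep: VtEpisode, episodes, model, labels) -> bool:
    """Episodes with exits within 10 mm and cycle lengths within 10% are one VT."""
    pos = _episode_anchor(ep, model, labels)
    for other in episodes:
        opos = _episode_anchor(other, model, labels)
        if (np.linalg.norm(pos - opos) <= 10.0 and
                abs(ep.cycle_length - other.cycle_length)
                <= 0.1 * other.cycle_length):
            return True
    return False


def _episode_anchor(ep: VtEpisode, model, labels) -> np.ndarray:
    if ep.exit_node is None:
        try:
            from .circuits import locate_exit_site
            ep.exit_node = locate_exit_site(ep, labels, model)
        except Exception:
            ep.exit_node = ep.reference_node
    return model.node_coords[ep.exit_node]


# ---------------------------------------------------------------------------
# persistence

def save_trace(trace: VmTrace, path):
    """Persist a trace as compressed arrays with a JSON-encoded header."""
    import json
    header = {"n_model_nodes": trace.n_model_nodes,
              "beat_windows": {k: list(v) for k, v in trace.beat_windows.items()},
              "capture": {k: bool(v) for k, v in trace.capture.items()
                          if v is not None},
              "site_id": trace.site.id if trace.site is not None else -1}
    acts_flat = np.concatenate([np.asarray(a, dtype=float)
                                for a in trace.activations]) \
        if trace.activations else np.array([])
    acts_len = np.array([len(a) for a in trace.activations], dtype=np.int64)
    np.savez_compressed(
        path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        cond_nodes=trace.cond_nodes, node_coords=trace.node_coords,
        vm=trace.vm if trace.vm is not None else np.zeros((0, 0), np.float32),
        sample_times=trace.sample_times, acts_flat=acts_flat,
        acts_len=acts_len)


def load_trace(path) -> VmTrace:
    import json
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["header"]).decode())
        acts_len = z["acts_len"]
        flat = z["acts_flat"]
        splits = np.cumsum(acts_len)[:-1]
        activations = [np.asarray(a) for a in np.split(flat, splits)]
        vm = z["vm"] if z["vm"].size else None
        return VmTrace(cond_nodes=z["cond_nodes"], node_coords=z["node_coords"],
                       vm=vm, sample_times=z["sample_times"],
                       activations=activations,
                       beat_windows={k: tuple(v) for k, v in
                                     header["beat_windows"].items()},
                       capture=dict(header["capture"]),
                       n_model_nodes=header["n_model_nodes"])
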