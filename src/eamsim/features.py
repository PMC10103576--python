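"""Extraction of the six electroanatomic-mapping features from unipolar maps.

Per surface point and per paced beat: voltage amplitude (V_amp, mV),
conduction velocity (CV, cm/s), isochronal crowding (IC, 1..16),
fractionation index (FI, deflection count), electrogram duration
(EGM_dur, ms) and frequency power (FP, mV^2/ms).  Each carries a validity
mask; cap points and silent points are invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree

from .electrogram import ElectrogramMap
from .geometry import EamSurface

FEATURE_NAMES = ("V_amp", "CV", "IC", "FI", "EGM_dur", "FP")


@dataclass
class FeatureMap:
    """Per-point features of one paced map, with validity masks."""

    site_id: int
    beat: str
    values: dict = field(default_factory=dict)   # name -> (n_points,) float
    valid: dict = field(default_factory=dict)    # name -> (n_points,) bool
    activation: np.ndarray = None

    def feature(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return self.values[name], self.valid[name]


# ---------------------------------------------------------------------------
# scalar signal features

def voltage_amplitude(signal: np.ndarray) -> float:
    """Peak-to-peak deflection: max(signal) - min(signal)."""
    signal = np.asarray(signal)
    if signal.size == 0:
        raise ValueError("empty signal")
    return float(np.max(signal) - np.min(signal))


def frequency_power(signal: np.ndarray, fs_hz: float = 400.0) -> float:
    """Area under the one-sided periodogram of the de-meaned signal, mV^2/ms.

    Convention: rectangular window, density scaling, integrated over
    frequency in kHz so that by Parseval the result equals
    mean((x - mean x)^2) / dt_ms exactly (testable identity).
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size == 1:
        return 0.0
    x = x - x.mean()
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2
    # one-sided sum that reproduces sum |X_k|^2 over the full circle
    w = np.full(spec.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    energy = float(np.sum(w * spec)) / n  # = sum x^2 (Parseval)
    dt_ms = 1000.0 / fs_hz
    return energy / n / dt_ms


def egm_duration(signal: np.ndarray, fs_hz: float = 400.0,
                 window_ms: float = 27.5, sd_fraction: float = 0.10) -> float:
    """Active duration from a sliding-window SD profile.

    An 11-sample (27.5 ms at 400 Hz) window slides one sample at a time;
    duration is the span between the centres of the first and last windows
    whose SD strictly exceeds ``sd_fraction`` of the maximum window SD
    (0 for a flat signal).
    """
    x = np.asarray(signal, dtype=float)
    nw = int(round(window_ms * fs_hz / 1000.0)) + 1
    if x.size < nw:
        raise ValueError(f"signal shorter than one {window_ms} ms window")
    sd = _sliding_sd(x, nw)
    mx = sd.max()
    if mx <= 0:
        return 0.0
    on = np.nonzero(sd > sd_fraction * mx)[0]
    dt_ms = 1000.0 / fs_hz
    return float((on[-1] - on[0]) * dt_ms)


def _sliding_sd(x: np.ndarray, nw: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x, nw)
    return win.std(axis=-1)


def fractionation_index(signal: np.ndarray, fs_hz: float = 400.0,
                        lowpass_hz: float = 30.0, floor_mv: float = 0.05,
                        mad_factor: float = 4.0,
                        rel_fraction: float = 0.25) -> int:
    """Count deflections left after removing a smoothed signal template.

    The template is a zero-phase 30 Hz low-pass of the signal; the residual's
    alternating extrema (signal ends included) define candidate deflections,
    and each negative-going extremum pair with peak-to-trough amplitude above
    max(``floor_mv``, ``mad_factor`` x median absolute residual,
    ``rel_fraction`` x the largest such pair) counts as one deflection.
    Counting only negative-going transitions reflects the negative-dominant
    morphology of unipolar deflections, so an isolated biphasic (or
    monophasic-negative) wave counts once; the relative gate suppresses the
    filter ringing that surrounds sharp deflections.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < 7 or np.ptp(x) == 0:
        return 0
    resid = x - _smooth_template(x, fs_hz, lowpass_hz)
    mad = np.median(np.abs(resid - np.median(resid)))
    ext = _alternating_extrema(resid)
    drops = [resid[a] - resid[b] for a, b in zip(ext[:-1], ext[1:])]
    neg = [d for d in drops if d > 0]
    if not neg:
        return 0
    thresh = max(floor_mv, mad_factor * mad, rel_fraction * max(neg))
    return int(sum(d > thresh for d in neg))


def _smooth_template(x: np.ndarray, fs_hz: float, lowpass_hz: float) -> np.ndarray:
    nyq = fs_hz / 2.0
    b, a = sps.butter(2, lowpass_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def _alternating_extrema(r: np.ndarray) -> np.ndarray:
    """Indices of local extrema of r including both endpoints, alternating."""
    d = np.diff(r)
    s = np.sign(d)
    # carry the sign over plateaus
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.nonzero(s[1:] * s[:-1] < 0)[0] + 1
    idx = np.concatenate([[0], turn, [len(r) - 1]])
    # enforce strict alternation (merge equal-direction runs, keep extreme)
    out = [idx[0]]
    for i in idx[1:]:
        if len(out) >= 2:
            prev_dir = np.sign(r[out[-1]] - r[out[-2]])
        else:
            prev_dir = 0
        cur_dir = np.sign(r[i] - r[out[-1]])
        if cur_dir == 0:
            continue
        if cur_dir == prev_dir:
            out[-1] = i if (cur_dir > 0) == (r[i] > r[out[-1]]) else out[-1]
        else:
            out.append(i)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# map-level features

def conduction_velocity_map(surface: EamSurface, activation: np.ndarray,
                            radius_mm: float = 5.0, cv_cap_cm_s: float = 200.0,
                            min_grad: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Per-point conduction velocity by the triangulation technique.

    Each triangle with three finite activation times gets a planar fit of
    activation over its vertices; its speed is 1/|in-plane gradient|
    (cm/s).  Point CV averages the element speeds whose centroids lie within
    ``radius_mm`` (Euclidean); elements above ``cv_cap_cm_s`` are treated as
    far-field fit artefacts and skipped, and points with no valid element in
    range are masked invalid.
    """
    tri = surface.triangles
    p = surface.points
    t = activation
    finite = np.isfinite(t[tri]).all(axis=1)
    speeds = np.full(len(tri), np.nan)
    e1 = p[tri[:, 1]] - p[tri[:, 0]]
    e2 = p[tri[:, 2]] - p[tri[:, 0]]
    dt1 = t[tri[:, 1]] - t[tri[:, 0]]
    dt2 = t[tri[:, 2]] - t[tri[:, 0]]
    g11 = np.sum(e1 * e1, axis=1)
    g12 = np.sum(e1 * e2, axis=1)
    g22 = np.sum(e2 * e2, axis=1)
    det = g11 * g22 - g12 ** 2
    ok = finite & (np.abs(det) > 1e-12)
    alpha = np.where(ok, (dt1 * g22 - dt2 * g12) / np.where(ok, det, 1.0), np.nan)
    beta = np.where(ok, (dt2 * g11 - dt1 * g12) / np.where(ok, det, 1.0), np.nan)
    grad = alpha[:, None] * e1 + beta[:, None] * e2
    gnorm = np.linalg.norm(grad, axis=1)
    valid_el = ok & (gnorm > min_grad)
    speeds[valid_el] = 100.0 / gnorm[valid_el]          # mm/ms -> cm/s
    valid_el &= speeds <= cv_cap_cm_s

    centroids = p[tri].mean(axis=1)
    el_idx = np.nonzero(valid_el)[0]
    cv = np.full(surface.n_points, np.nan)
    valid = np.zeros(surface.n_points, dtype=bool)
    if len(el_idx):
        tree = cKDTree(centroids[el_idx])
        near = tree.query_ball_point(p, r=radius_mm)
        for i, lst in enumerate(near):
            if lst:
                cv[i] = float(np.mean(speeds[el_idx[lst]]))
                valid[i] = True
    return cv, valid


def isochronal_crowding(surface: EamSurface, activation: np.ndarray,
                        n_bins: int = 16, radius_mm: float = 10.0,
                        geodesic: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Number of distinct isochrones within 1 cm of each point.

    Sixteen equal time windows span [min, max] activation of the map; each
    point counts the distinct isochrone indices among finite-activation
    points within the (geodesic by default) radius, itself included.
    """
    t = activation
    finite = np.isfinite(t)
    valid = finite.copy()
    ic = np.full(surface.n_points, np.nan)
    if finite.sum() == 0:
        return ic, np.zeros(surface.n_points, dtype=bool)
    tmin, tmax = np.min(t[finite]), np.max(t[finite])
    if tmax <= tmin:
        ic[finite] = 1.0
        return ic, valid
    tb = np.where(finite, t, tmin)
    bins = np.clip(((tb - tmin) / (tmax - tmin) * n_bins).astype(int),
                   0, n_bins - 1)
    if geodesic:
        dist = surface.geodesic_from(np.arange(surface.n_points), limit=radius_mm)
        within = dist <= radius_mm
    else:
        tree = cKDTree(surface.points)
        within = np.zeros((surface.n_points, surface.n_points), dtype=bool)
        for i, lst in enumerate(tree.query_ball_point(surface.points, r=radius_mm)):
            within[i, lst] = True
    for i in np.nonzero(finite)[0]:
        nb = within[i] & finite
        ic[i] = len(np.unique(bins[nb]))
    return ic, valid


# ---------------------------------------------------------------------------
# batched equivalents (vectorized across points; agree with the scalar
# reference implementations above, which the tests enforce)

def _batch_frequency_power(sig: np.ndarray, fs_hz: float) -> np.ndarray:
    x = sig - sig.mean(axis=1, keepdims=True)
    dt_ms = 1000.0 / fs_hz
    return np.mean(x * x, axis=1) / dt_ms


def _batch_egm_duration(sig: np.ndarray, fs_hz: float,
                        window_ms: float = 27.5,
                        sd_fraction: float = 0.10) -> np.ndarray:
    nw = int(round(window_ms * fs_hz / 1000.0)) + 1
    win = np.lib.stride_tricks.sliding_window_view(sig, nw, axis=1)
    sd = win.std(axis=-1)
    mx = sd.max(axis=1)
    dt_ms = 1000.0 / fs_hz
    out = np.zeros(len(sig))
    on = sd > sd_fraction * mx[:, None]
    any_on = mx > 0
    idx = np.arange(sd.shape[1])
    for i in np.nonzero(any_on)[0]:
        j = idx[on[i]]
        out[i] = (j[-1] - j[0]) * dt_ms
    return out


def _batch_fractionation_index(sig: np.ndarray, fs_hz: float,
                               lowpass_hz: float = 30.0,
                               floor_mv: float = 0.05,
                               mad_factor: float = 4.0,
                               rel_fraction: float = 0.25) -> np.ndarray:
    out = np.zeros(len(sig))
    if sig.shape[1] < 7:
        return out
    nyq = fs_hz / 2.0
    b, a = sps.butter(2, lowpass_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), sig.shape[1] - 1)
    smooth = sps.filtfilt(b, a, sig, axis=1, padlen=padlen)
    resid = sig - smooth
    flat = np.ptp(sig, axis=1) == 0
    mad = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)),
                    axis=1)
    for i in range(len(sig)):
        if flat[i]:
            continue
        ext = _alternating_extrema(resid[i])
        r = resid[i]
        drops = r[ext[:-1]] - r[ext[1:]]
        neg = drops[drops > 0]
        if len(neg) == 0:
            continue
        thresh = max(floor_mv, mad_factor * mad[i], rel_fraction * neg.max())
        out[i] = float(np.sum(neg > thresh))
    return out


def extract_features(egm_map: ElectrogramMap, surface: EamSurface,
                     ic_geodesic: bool = True,
                     geodesic_cache: np.ndarray = None) -> FeatureMap:
    """All six features for one electrogram map."""
    sig = np.asarray(egm_map.signals, dtype=float)
    fs = egm_map.fs_hz
    base_valid = egm_map.valid.copy()

    vamp = np.ptp(sig, axis=1).astype(float)
    fp = _batch_frequency_power(sig, fs)
    dur = _batch_egm_duration(sig, fs)
    fi = _batch_fractionation_index(sig, fs)
    act = egm_map.activation.copy()
    act[~base_valid] = np.nan
    cv, cv_valid = conduction_velocity_map(surface, act)
    if geodesic_cache is not None:
        within = geodesic_cache
        ic, ic_valid = _ic_from_cache(act, within)
    else:
        ic, ic_valid = isochronal_crowding(surface, act, geodesic=ic_geodesic)

    fm = FeatureMap(site_id=egm_map.site_id, beat=egm_map.beat, activation=act)
    fm.values = {"V_amp": vamp, "CV": cv, "IC": ic, "FI": fi,
                 "EGM_dur": dur, "FP": fp}
    fm.valid = {"V_amp": base_valid, "FI": base_valid, "EGM_dur": base_valid,
                "FP": base_valid,
                "CV": base_valid & cv_valid,
                "IC": base_valid & ic_valid}
    return fm


def geodesic_neighbourhoods(surface: EamSurface, radius_mm: float = 10.0) -> np.ndarray:
    """Boolean (n, n) matrix of geodesic balls, reusable across maps."""
    dist = surface.geodesic_from(np.arange(surface.n_points), limit=radius_mm)
    return dist <= radius_mm


def _ic_from_cache(activation: np.ndarray, within: np.ndarray,
                   n_bins: int = 16) -> tuple[np.ndarray, np.ndarray]:
    t = activation
    finite = np.isfinite(t)
    ic = np.full(len(t), np.nan)
    if finite.sum() == 0:
        return ic, np.zeros(len(t), dtype=bool)
    tmin, tmax = np.min(t[finite]), np.max(t[finite])
    if tmax <= tmin:
        ic[finite] = 1.0
        return ic, finite
    tb = np.where(finite, t, tmin)
    bins = np.clip(((tb - tmin) / (tmax - tmin) * n_bins).astype(int), 0, n_bins - 1)
    for i in np.nonzero(finite)[0]:
        nb = within[i] & finite
        ic[i] = len(np.unique(bins[nb]))
    return ic, finite


def features_to_frame(fmap: FeatureMap, surface: EamSurface):
    """Per-point tidy table: id, side, ventricular coordinates, the six
    features (NaN where invalid) and the activation time."""
    import pandas as pd
    cols = {"point": np.arange(surface.n_points),
            "side": surface.side,
            "apicobasal": surface.uvc[:, 0],
            "rotational": surface.uvc[:, 1],
            "transmural": surface.uvc[:, 2]}
    for name in FEATURE_NAMES:
        v, ok = fmap.feature(name)
        cols[name] = np.where(ok, v, np.nan)
    cols["activation_ms"] = fmap.activation
    return pd.DataFrame(cols)
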