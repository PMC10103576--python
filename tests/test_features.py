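"""The six EAM features against brute-force reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eamsim import features as ft

FS = 400.0
DT = 2.5


# ---------------------------------------------------------------------------
# brute-force oracles (written independently, explicit loops)

def oracle_egm_duration(x, window_ms=27.5, sd_fraction=0.10):
    nw = int(round(window_ms * FS / 1000.0)) + 1
    sds = []
    for i in range(len(x) - nw + 1):
        w = x[i:i + nw]
        sds.append(float(np.std(w)))
    mx = max(sds)
    if mx <= 0:
        return 0.0
    hits = [i for i, s in enumerate(sds) if s > sd_fraction * mx]
    return (hits[-1] - hits[0]) * (1000.0 / FS)


def oracle_fp(x):
    x = np.asarray(x, dtype=float)
    mu = sum(x) / len(x)
    energy = sum((v - mu) ** 2 for v in x)
    return energy / len(x) / DT


def oracle_ic(within, activation, n_bins=16):
    finite = np.isfinite(activation)
    tmin = activation[finite].min()
    tmax = activation[finite].max()
    out = np.full(len(activation), np.nan)
    for i in range(len(activation)):
        if not finite[i]:
            continue
        seen = set()
        for j in range(len(activation)):
            if within[i, j] and finite[j]:
                b = int((activation[j] - tmin) / (tmax - tmin) * n_bins)
                seen.add(min(b, n_bins - 1))
        out[i] = len(seen)
    return out


# ---------------------------------------------------------------------------
# voltage amplitude

class TestVoltageAmplitude:
    def test_worked_example(self):
        sig = np.array([0.0, 1.2, -0.8, 0.3])
        assert ft.voltage_amplitude(sig) == pytest.approx(2.0)

    def test_constant_is_zero(self):
        assert ft.voltage_amplitude(np.full(40, 3.3)) == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-5, 5))
    def test_baseline_shift_invariance(self, shift):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=60)
        assert ft.voltage_amplitude(sig + shift) == \
            pytest.approx(ft.voltage_amplitude(sig), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.voltage_amplitude(np.array([]))


# ---------------------------------------------------------------------------
# frequency power

class TestFrequencyPower:
    def test_flat_is_zero(self):
        assert ft.frequency_power(np.full(80, 1.5), FS) == pytest.approx(0.0)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=120)
        assert ft.frequency_power(2 * sig, FS) == \
            pytest.approx(4 * ft.frequency_power(sig, FS), rel=1e-9)

    def test_parseval_identity_on_random_signals(self):
        rng = np.random.default_rng(11)
        for n in rng.integers(12, 300, size=100):
            sig = rng.normal(size=int(n))
            assert ft.frequency_power(sig, FS) == \
                pytest.approx(oracle_fp(sig), rel=1e-9)


# ---------------------------------------------------------------------------
# electrogram duration

class TestEgmDuration:
    def test_flat_signal_zero(self):
        assert ft.egm_duration(np.zeros(160), FS) == 0.0

    def test_single_compact_deflection(self):
        t = np.arange(160) * DT
        sig = np.exp(-((t - 200.0) / 12.0) ** 2)       # ~40 ms active
        d = ft.egm_duration(sig, FS)
        assert 40.0 - 27.5 <= d <= 40.0 + 27.5 + 15.0
        assert d == pytest.approx(oracle_egm_duration(sig), abs=1e-9)

    def test_two_deflections_span(self):
        t = np.arange(200) * DT
        sig = np.exp(-((t - 150.0) / 8.0) ** 2) + \
            np.exp(-((t - 250.0) / 8.0) ** 2)
        d = ft.egm_duration(sig, FS)
        assert d >= 100.0 - 27.5
        assert d == pytest.approx(oracle_egm_duration(sig), abs=1e-9)

    def test_matches_oracle_on_random_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            sig = rng.normal(size=int(rng.integers(12, 220))) * \
                rng.uniform(0.1, 3.0)
            assert ft.egm_duration(sig, FS) == \
                pytest.approx(oracle_egm_duration(sig), abs=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ft.egm_duration(np.zeros(5), FS)


# ---------------------------------------------------------------------------
# fractionation index

def biphasic(t0, width, amp=1.0, n=200):
    # R-then-S orientation (positive lobe first), as in unipolar deflections
    t = np.arange(n) * DT
    return -amp * (t - t0) / width * np.exp(-((t - t0) / width) ** 2)


class TestFractionationIndex:
    def test_flat_zero(self):
        assert ft.fractionation_index(np.zeros(120), FS) == 0

    def test_single_biphasic_counts_once(self):
        assert ft.fractionation_index(biphasic(250.0, 10.0), FS) == 1

    def test_three_separated_deflections(self):
        sig = biphasic(100.0, 8.0) + biphasic(250.0, 8.0) + biphasic(400.0, 8.0)
        assert ft.fractionation_index(sig, FS) == 3

    def test_baseline_and_scale_invariance(self):
        sig = biphasic(150.0, 8.0) + biphasic(320.0, 8.0)
        base = ft.fractionation_index(sig, FS)
        assert ft.fractionation_index(sig + 2.5, FS) == base
        assert ft.fractionation_index(sig * 5.0, FS) == base

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(9)
        sigs = rng.normal(size=(50, 160)) * rng.uniform(0.02, 2.0, size=(50, 1))
        batch = ft._batch_fractionation_index(sigs, FS)
        scalar = [ft.fractionation_index(s, FS) for s in sigs]
        assert np.array_equal(batch, np.asarray(scalar, dtype=float))


# ---------------------------------------------------------------------------
# conduction velocity (triangulation technique)

class TestConductionVelocity:
    def test_planar_wave_speed(self, flat_patch):
        x = flat_patch.points[:, 0]
        act = x / 0.5                                   # 50 cm/s
        cv, valid = ft.conduction_velocity_map(flat_patch, act)
        interior = (x > 6) & (x < 34)
        assert np.all(valid[interior])
        assert np.allclose(cv[interior], 50.0, atol=2.5)

    def test_uniform_activation_masked(self, flat_patch):
        act = np.full(flat_patch.n_points, 25.0)
        cv, valid = ft.conduction_velocity_map(flat_patch, act)
        assert not valid.any()

    def test_radial_wave(self, flat_patch):
        centre = np.array([20.0, 20.0, 0.0])
        r = np.linalg.norm(flat_patch.points - centre, axis=1)
        act = r / 0.4                                   # 40 cm/s radial
        cv, valid = ft.conduction_velocity_map(flat_patch, act)
        far = r >= 3 * 2.0
        ok = valid & far
        assert ok.sum() > 50
        assert np.all(np.abs(cv[ok] - 40.0) / 40.0 < 0.10)

    def test_refinement_reduces_planar_error(self):
        import eamsim as es

        def patch(spacing):
            nx = int(40.0 / spacing) + 1
            xs = np.arange(nx) * spacing
            gx, gy = np.meshgrid(xs, xs, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(),
                                   np.zeros(nx * nx)])
            tris = []
            for i in range(nx - 1):
                for j in range(nx - 1):
                    a = i * nx + j
                    tris.append([a, a + nx, a + 1])
                    tris.append([a + 1, a + nx, a + nx + 1])
            return es.EamSurface(points=pts, triangles=np.asarray(tris),
                                 side=np.zeros(len(pts), dtype=np.int8),
                                 is_cap=np.zeros(len(pts), dtype=bool),
                                 uvc=np.zeros((len(pts), 3)),
                                 volume_link=np.zeros(len(pts), dtype=np.int64),
                                 voxel_size=spacing)

        errs = []
        for spacing in (4.0, 2.0):
            p = patch(spacing)
            # gentle curvature so the planar fit is not exact by construction
            act = p.points[:, 0] / 0.5 + 0.002 * p.points[:, 1] ** 2
            cv, valid = ft.conduction_velocity_map(p, act)
            x = p.points[:, 0]
            sel = valid & (x > 8) & (x < 32)
            errs.append(float(np.mean(np.abs(cv[sel] - 50.0))))
        assert errs[1] <= errs[0]


# ---------------------------------------------------------------------------
# isochronal crowding

class TestIsochronalCrowding:
    def test_uniform_activation_is_one(self, flat_patch):
        act = np.full(flat_patch.n_points, 10.0)
        ic, valid = ft.isochronal_crowding(flat_patch, act, geodesic=False)
        assert np.all(ic[valid] == 1.0)

    def test_never_exceeds_16(self, flat_patch):
        rng = np.random.default_rng(2)
        act = rng.uniform(0, 100, size=flat_patch.n_points)
        ic, valid = ft.isochronal_crowding(flat_patch, act, geodesic=False)
        assert np.nanmax(ic) <= 16

    def test_linear_ramp_matches_exhaustive_count(self, flat_patch):
        """1 cm disc spanning 2/16 of the range -> IC 2-3 interior, and the
        full map agrees with a brute-force bin count."""
        x = flat_patch.points[:, 0]
        y = flat_patch.points[:, 1]
        # shallow ramp (1 cm disc spans 2 time units) with one distant point
        # stretching the full range to 16 units -> bin width 1 unit
        act = x * 0.1
        act[int(np.argmax(x + y))] = 16.0
        from scipy.spatial import cKDTree
        tree = cKDTree(flat_patch.points)
        within = np.zeros((flat_patch.n_points,) * 2, dtype=bool)
        for i, lst in enumerate(tree.query_ball_point(flat_patch.points, 10.0)):
            within[i, lst] = True
        ic, valid = ft.isochronal_crowding(flat_patch, act, geodesic=False)
        expect = oracle_ic(within, act)
        assert np.array_equal(np.nan_to_num(ic), np.nan_to_num(expect))
        interior = (x > 12) & (x < 28) & (y > 12) & (y < 28)
        assert np.all((ic[interior] >= 2) & (ic[interior] <= 3))

    def test_random_maps_match_oracle(self, flat_patch):
        rng = np.random.default_rng(4)
        from scipy.spatial import cKDTree
        tree = cKDTree(flat_patch.points)
        within = np.zeros((flat_patch.n_points,) * 2, dtype=bool)
        for i, lst in enumerate(tree.query_ball_point(flat_patch.points, 10.0)):
            within[i, lst] = True
        for _ in range(20):
            act = rng.uniform(0, 80, size=flat_patch.n_points)
            act[rng.random(flat_patch.n_points) < 0.1] = np.nan
            ic, _ = ft.isochronal_crowding(flat_patch, act, geodesic=False)
            expect = oracle_ic(within, act)
            assert np.array_equal(np.nan_to_num(ic), np.nan_to_num(expect))


# ---------------------------------------------------------------------------
# full extraction

class TestExtractFeatures:
    def test_captured_map_mostly_valid(self, s1_map, lv_surface):
        fm = s1_map["features"]
        usable = ~lv_surface.is_cap
        for name in ("V_amp", "FI", "EGM_dur", "FP"):
            _, valid = fm.feature(name)
            assert valid[usable].mean() >= 0.95
        for name in ("CV", "IC"):
            _, valid = fm.feature(name)
            assert valid[usable].mean() >= 0.80

    def test_deterministic(self, s1_map, lv_surface):
        fm2 = ft.extract_features(s1_map["egm"], lv_surface,
                                  geodesic_cache=s1_map["geodesic"])
        for name in ft.FEATURE_NAMES:
            a, _ = s1_map["features"].feature(name)
            b, _ = fm2.feature(name)
            assert np.array_equal(np.nan_to_num(a), np.nan_to_num(b))

    def test_batch_duration_and_power_match_scalar(self, s1_map):
        sig = np.asarray(s1_map["egm"].signals, dtype=float)[:40]
        bd = ft._batch_egm_duration(sig, FS)
        bp = ft._batch_frequency_power(sig, FS)
        for i, s in enumerate(sig):
            assert bd[i] == pytest.approx(ft.egm_duration(s, FS), abs=1e-9)
            assert bp[i] == pytest.approx(ft.frequency_power(s, FS), rel=1e-9)
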