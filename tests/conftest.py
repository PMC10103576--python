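"""Shared fixtures: small LV models, simulated maps, and the cohort run.

Heavier fixtures (the 8-heart cohort experiment, the engineered-substrate
induction) are session-scoped so the acceptance tests share one computation.
"""

import numpy as np
import pytest

import eamsim as es
from eamsim import analysis as ana
from eamsim import electrogram as eg
from eamsim import features as ft
from eamsim import propagation as pp
from eamsim import substrate as sb

TEST_SHAPE = es.LvShape(epi_semi_axes=(22.0, 22.0, 44.0), wall_thickness=8.0,
                        truncation_fraction=0.7)


@pytest.fixture(scope="session")
def lv_model():
    m = es.build_idealized_lv(TEST_SHAPE, voxel_size=2.0)
    es.assign_uvc(m)
    es.assign_fibres(m)
    return m


@pytest.fixture(scope="session")
def lv_surface(lv_model):
    return es.extract_eam_surfaces(lv_model, target_edge=2.5)


@pytest.fixture(scope="session")
def lv_sites(lv_surface):
    return es.select_pacing_sites(lv_surface, n_per_surface=5, seed=1)


@pytest.fixture(scope="session")
def infarcted_labels(lv_model):
    lab = es.generate_infarct(lv_model, 0.30, seed=3)
    return es.carve_channels(lab, lv_model, n_channels=1, seed=4)


@pytest.fixture(scope="session")
def s1_map(lv_model, lv_surface, lv_sites, infarcted_labels):
    """One captured S1 electrogram map plus its feature map."""
    trace = pp.deliver_s1s2(lv_model, infarcted_labels, lv_sites[0], None)
    fwd = eg.UnipolarForwardOperator(lv_model, lv_surface, trace.cond_nodes)
    emap = eg.compute_unipolar(trace, lv_surface, forward=fwd, beat="S1")
    geo = ft.geodesic_neighbourhoods(lv_surface)
    fmap = ft.extract_features(emap, lv_surface, geodesic_cache=geo)
    return {"trace": trace, "egm": emap, "features": fmap, "forward": fwd,
            "geodesic": geo}


@pytest.fixture(scope="session")
def cohort_experiment(tmp_path_factory):
    """Seeded 8-heart cohort spanning remodelling 0.10-0.50 (desk scale)."""
    from eamsim.pipeline import preset, run_experiment
    out = tmp_path_factory.mktemp("cohort")
    cfg = preset("standard", seed=11, out_dir=str(out))
    return run_experiment(cfg, stages=("simulate", "concordance",
                                       "remodelling", "outputs"))


@pytest.fixture(scope="session")
def engineered_vt(lv_model):
    """Induced episodes on the deterministic single-channel substrate."""
    lab = sb.engineered_channel_substrate(lv_model)
    icfg = pp.InductionConfig(n_drive=3, drive_cl=450.0, s2_start=360.0,
                              s2_min=200.0, observe=2500.0)
    episodes = pp.induce_vt(lv_model, lab, n_induction_sites=4,
                            induction_config=icfg, seed=2)
    return {"labels": lab, "episodes": episodes}


@pytest.fixture(scope="session")
def flat_patch():
    """Regular triangulated flat patch (40 x 40 mm, 2 mm spacing) as an
    EamSurface, for analytic conduction-velocity and crowding checks."""
    nx = ny = 21
    xs = np.arange(nx) * 2.0
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            tris.append([a, a + ny, a + 1])
            tris.append([a + 1, a + ny, a + ny + 1])
    tris = np.asarray(tris)
    return es.EamSurface(points=pts, triangles=tris,
                         side=np.zeros(len(pts), dtype=np.int8),
                         is_cap=np.zeros(len(pts), dtype=bool),
                         uvc=np.zeros((len(pts), 3)),
                         volume_link=np.zeros(len(pts), dtype=np.int64),
                         voxel_size=2.0)
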