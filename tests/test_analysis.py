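"""Remodelling projection, concordance, metrics and regression ladders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eamsim import analysis as ana
from eamsim import features as ft
from eamsim.geometry import NORMAL


# ---------------------------------------------------------------------------
# metric oracles

def oracle_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_confusion(scores, labels, thr=0.5):
    tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
    fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
    fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
    tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return f1, sens, spec


class TestEvaluateMetrics:
    def test_worked_example(self):
        m = ana.evaluate_metrics([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert m["AUROC"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(0.5)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(0.5)

    def test_perfect_ranking(self):
        m = ana.evaluate_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["AUROC"] == 1.0

    def test_all_tied_scores(self):
        m = ana.evaluate_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert m["AUROC"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ana.evaluate_metrics([0.1, 0.9], [1, 1])

    def test_matches_pair_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)      # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            m = ana.evaluate_metrics(scores, labels)
            assert m["AUROC"] == pytest.approx(
                oracle_auroc(scores, labels), abs=1e-12)
            f1, sens, spec = oracle_confusion(scores, labels)
            assert m["F1"] == pytest.approx(f1, abs=1e-12)
            assert m["sensitivity"] == pytest.approx(sens, abs=1e-12)
            assert m["specificity"] == pytest.approx(spec, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 1)),
                    min_size=4, max_size=30))
    def test_auroc_property(self, pairs):
        scores = [p[0] / 10.0 for p in pairs]
        labels = [p[1] for p in pairs]
        if sum(labels) in (0, len(labels)):
            labels[0] = 1 - labels[0]
        m = ana.evaluate_metrics(scores, labels)
        assert m["AUROC"] == pytest.approx(oracle_auroc(scores, labels),
                                           abs=1e-12)


class TestGroupComparisons:
    def test_identical_groups(self):
        stat, p = ana.group_comparisons([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=30)
        b = rng.normal(5, 1, size=30)
        _, p = ana.group_comparisons(a, b)
        assert p < 0.001

    def test_paired_zero_differences(self):
        stat, p = ana.group_comparisons([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                        paired=True)
        assert stat == 0.0
        assert p == 1.0


# ---------------------------------------------------------------------------
# remodelling projection & ranking

class TestProjectRemodelling:
    def test_threshold_rule(self, lv_model, lv_surface):
        from scipy.spatial import cKDTree
        tree = cKDTree(lv_model.node_coords)
        point = int(np.nonzero(~lv_surface.is_cap)[0][0])
        ball = tree.query_ball_point(lv_surface.points[point], 5.0)
        labels = np.zeros(lv_model.n_nodes, dtype=np.uint8)
        k15 = max(1, int(round(0.15 * len(ball))))
        labels[np.asarray(ball[:k15])] = 1
        sl = ana.project_remodelling(lv_surface, labels, lv_model)
        assert sl.remodelled[point]
        labels[:] = 0
        k5 = max(1, int(round(0.05 * len(ball))))
        labels[np.asarray(ball[:k5])] = 1
        sl = ana.project_remodelling(lv_surface, labels, lv_model)
        if k5 / len(ball) < 0.10:
            assert not sl.remodelled[point]

    def test_fraction_is_recountable(self, lv_model, lv_surface,
                                     infarcted_labels):
        from scipy.spatial import cKDTree
        sl = ana.project_remodelling(lv_surface, infarcted_labels, lv_model)
        tree = cKDTree(lv_model.node_coords)
        rng = np.random.default_rng(0)
        for k in rng.choice(lv_surface.n_points, size=25, replace=False):
            ball = tree.query_ball_point(lv_surface.points[k], 5.0)
            expect = np.mean(infarcted_labels.labels[ball] != NORMAL) \
                if ball else 0.0
            assert sl.fraction[k] == pytest.approx(expect)


class TestRankSites:
    def test_permutation_and_tie_determinism(self, lv_model, lv_surface,
                                             lv_sites, infarcted_labels):
        sl = ana.project_remodelling(lv_surface, infarcted_labels, lv_model)
        sl = ana.rank_sites_by_infarct(lv_surface, lv_sites, sl)
        assert sorted(sl.site_ranks.tolist()) == \
            list(range(1, len(lv_sites) + 1))
        sl2 = ana.rank_sites_by_infarct(lv_surface, lv_sites, sl)
        assert np.array_equal(sl.site_ranks, sl2.site_ranks)

    def test_near_site_outranks_far_site(self, lv_model, lv_surface,
                                         lv_sites):
        """Single remodelled patch around one site: that site beats the
        most distant site on the same surface (brute-force comparison)."""
        target = lv_sites[0]
        labels = np.zeros(lv_model.n_nodes, dtype=np.uint8)
        d = np.linalg.norm(lv_model.node_coords -
                           target.position, axis=1)
        labels[d < 8.0] = 1
        sl = ana.project_remodelling(lv_surface, labels, lv_model)
        sl = ana.rank_sites_by_infarct(lv_surface, lv_sites, sl)
        same_side = [k for k, s in enumerate(lv_sites)
                     if s.side == target.side]
        far = max(same_side,
                  key=lambda k: np.linalg.norm(lv_sites[k].position -
                                               target.position))
        assert sl.site_ranks[0] < sl.site_ranks[far]

    def test_no_remodelling_rejected(self, lv_model, lv_surface, lv_sites):
        labels = np.zeros(lv_model.n_nodes, dtype=np.uint8)
        sl = ana.project_remodelling(lv_surface, labels, lv_model)
        with pytest.raises(ValueError):
            ana.rank_sites_by_infarct(lv_surface, lv_sites, sl)


# ---------------------------------------------------------------------------
# concordance

def fake_map(values, site_id=0, beat="S1"):
    n = len(values)
    fmap = ft.FeatureMap(site_id=site_id, beat=beat)
    for name in ft.FEATURE_NAMES:
        fmap.values[name] = np.asarray(values, dtype=float)
        fmap.valid[name] = np.ones(n, dtype=bool)
    return fmap


class TestConcordance:
    def test_identical_maps(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200)
        assert ana.feature_concordance(fake_map(v), fake_map(v), "V_amp") == \
            pytest.approx(1.0)

    def test_negated_map(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)
        assert ana.feature_concordance(fake_map(v), fake_map(-v), "CV") == \
            pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = fake_map(rng.normal(size=150)), fake_map(rng.normal(size=150))
        assert ana.feature_concordance(a, b, "IC") == \
            pytest.approx(ana.feature_concordance(b, a, "IC"))

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            a = fake_map(rng.normal(size=1000))
            b = fake_map(rng.normal(size=1000))
            if abs(ana.feature_concordance(a, b, "FP")) < 0.1:
                hits += 1
        assert hits >= 95

    def test_insufficient_points_sentinel(self):
        a, b = fake_map(np.arange(5.0)), fake_map(np.arange(5.0))
        assert np.isnan(ana.feature_concordance(a, b, "V_amp"))


# ---------------------------------------------------------------------------
# regression ladders

def ladder_inputs(n_points=400, n_sites=4, informative=True, seed=0):
    """Fake feature maps + surface labels with ranks 1..n_sites."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_points)
    maps = {}
    for sid in range(n_sites):
        if informative:
            v = y + rng.normal(0, 1.0, size=n_points)
        else:
            v = rng.normal(size=n_points)
        maps[(sid, "S1")] = fake_map(v, site_id=sid)
    sl = ana.RemodellingSurfaceLabels(
        remodelled=y.astype(bool), fraction=y.astype(float),
        threshold=0.1, radius_mm=5.0)
    sl.site_ranks = np.arange(1, n_sites + 1)

    class S:
        def __init__(self, id):
            self.id = id
            self.side = 0
    sites = [S(i) for i in range(n_sites)]
    return maps, sl, sites


class TestRemodellingLadder:
    def test_perfect_feature_saturates(self):
        maps, sl, sites = ladder_inputs()
        y = sl.remodelled.astype(float)
        maps[(0, "S1")] = fake_map(y)
        res = ana.fit_remodelling_models(maps, sl, sites, "V_amp", "S1",
                                         max_n=1)
        assert res[0].f1 == pytest.approx(1.0)
        assert res[0].auroc == pytest.approx(1.0)

    def test_constant_feature_is_chance(self):
        maps, sl, sites = ladder_inputs()
        maps[(0, "S1")] = fake_map(np.zeros(len(sl.remodelled)))
        res = ana.fit_remodelling_models(maps, sl, sites, "V_amp", "S1",
                                         max_n=1)
        assert res[0].auroc == pytest.approx(0.5, abs=1e-6)

    def test_duplicate_covariate_stable(self):
        maps, sl, sites = ladder_inputs(n_sites=2, seed=4)
        maps[(1, "S1")] = fake_map(maps[(0, "S1")].values["V_amp"].copy(),
                                   site_id=1)
        res = ana.fit_remodelling_models(maps, sl, sites, "V_amp", "S1")
        assert abs(res[1].auroc - res[0].auroc) < 1e-6

    def test_information_monotone_in_sample(self):
        maps, sl, sites = ladder_inputs(n_sites=6, seed=5)
        res = ana.fit_remodelling_models(maps, sl, sites, "V_amp", "S1")
        assert res[-1].auroc >= res[0].auroc - 1e-9

    def test_parameter_recovery_negative_voltage_coefficient(self):
        """Remodelled points constructed with lower V_amp: the N=1 logistic
        fit recovers a negative coefficient in >= 95% of synthetic hearts."""
        rng = np.random.default_rng(6)
        hits = 0
        n_hearts = 40
        for _ in range(n_hearts):
            y = rng.integers(0, 2, size=300)
            v = 1.0 - 0.6 * y + rng.normal(0, 0.3, size=300)
            coef = ana.logistic_coefficients(
                ana._zscore(v[:, None]), y)
            hits += coef[0] < 0
        assert hits >= 0.95 * n_hearts


class TestCircuitLadder:
    def _table(self, n_vt=50, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for vt in range(n_vt):
            for sub in ("endo_outer", "endo_inner"):
                inner = int(sub.endswith("inner"))
                for sid in (0, 1):
                    val = (inner + rng.normal(0, 0.1)) if informative \
                        else rng.normal()
                    rows.append({"vt": vt, "subregion": sub, "inner": inner,
                                 "site": sid, "beat": "S1",
                                 "feature": "V_amp", "value": val})
        return pd.DataFrame(rows)

    def test_discriminative_feature_gives_auroc_1(self):
        tab = self._table(informative=True)
        res = ana.fit_circuit_models(tab, [0, 1], "V_amp")
        assert res[0].auroc == pytest.approx(1.0)

    def test_random_feature_near_chance(self):
        tab = self._table(n_vt=100, informative=False, seed=3)
        res = ana.fit_circuit_models(tab, [0], "V_amp")
        assert 0.4 <= res[0].auroc <= 0.6
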