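"""Substrate-level analyses: remodelling projection, concordance, regressions.

Implements the evaluation ladder of the mapping study: project the
volumetric infarct remodelling onto the EAM surfaces (>=10% remodelled
myocardium within 5 mm), rank pacing sites by mean geodesic distance to the
remodelled zone, measure inter-map feature concordance (Pearson by
default), and fit incremental logistic-regression models whose N-th stage
uses features from the N most proximally paced maps, scored by AUROC, F1,
sensitivity and specificity at a 0.5 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_NAMES
from .geometry import EamSurface, NORMAL, VentricularModel

UNDEFINED = np.nan


@dataclass
class RemodellingSurfaceLabels:
    remodelled: np.ndarray        # (n_points,) bool
    fraction: np.ndarray          # (n_points,) local remodelled fraction
    threshold: float
    radius_mm: float
    site_mean_distance: np.ndarray = None  # (n_sites,)
    site_ranks: np.ndarray = None          # (n_sites,) permutation of 1..P


@dataclass
class EvaluationResult:
    feature: str
    variant: str
    n_covariates: int
    auroc: float
    f1: float
    sensitivity: float
    specificity: float

    def as_dict(self):
        return {"feature": self.feature, "variant": self.variant,
                "N": self.n_covariates, "AUROC": self.auroc, "F1": self.f1,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


# ---------------------------------------------------------------------------
# remodelling projection and site ranking

def project_remodelling(surface: EamSurface, labels, model: VentricularModel,
                        radius_mm: float = 5.0,
                        threshold: float = 0.10) -> RemodellingSurfaceLabels:
    """Label surface points overlying infarct remodelling.

    A point is remodelled when at least ``threshold`` of the myocardial
    nodes within ``radius_mm`` (Euclidean) carry an infarct label; the
    threshold is sweepable (the 10%..50% sensitivity band).
    """
    tissue = labels if isinstance(labels, np.ndarray) else labels.labels
    tree = cKDTree(model.node_coords)
    near = tree.query_ball_point(surface.points, r=radius_mm)
    frac = np.zeros(surface.n_points)
    for i, lst in enumerate(near):
        if lst:
            frac[i] = np.mean(tissue[lst] != NORMAL)
    remod = (frac >= threshold) & ~surface.is_cap
    return RemodellingSurfaceLabels(remodelled=remod, fraction=frac,
                                    threshold=threshold, radius_mm=radius_mm)


def rank_sites_by_infarct(surface: EamSurface, sites,
                          surf_labels: RemodellingSurfaceLabels) -> RemodellingSurfaceLabels:
    """Rank sites 1..P by mean geodesic distance to the remodelled zone.

    Distances are computed on each site's own surface; a side without any
    remodelled point yields infinite mean distance (such sites rank last,
    ties broken by site id).  Raises when no remodelled point exists at all.
    """
    if surf_labels.remodelled.sum() == 0:
        raise ValueError("no remodelled surface points to rank against")
    mean_d = np.empty(len(sites))
    for side in (0, 1):
        targets = np.nonzero(surf_labels.remodelled & (surface.side == side))[0]
        side_sites = [k for k, s in enumerate(sites) if s.side == side]
        if len(targets) == 0:
            for k in side_sites:
                mean_d[k] = np.inf
            continue
        for k in side_sites:
            d = surface.geodesic_from(sites[k].point_index)
            dt = d[targets]
            mean_d[k] = float(np.mean(dt[np.isfinite(dt)])) if np.isfinite(dt).any() else np.inf
    order = np.lexsort((np.array([s.id for s in sites]), mean_d))
    ranks = np.empty(len(sites), dtype=int)
    ranks[order] = np.arange(1, len(sites) + 1)
    surf_labels.site_mean_distance = mean_d
    surf_labels.site_ranks = ranks
    return surf_labels


# ---------------------------------------------------------------------------
# concordance

def feature_concordance(map_a, map_b, feature: str, subset: np.ndarray = None,
                        min_points: int = 10, spearman: bool = False) -> float:
    """Correlation of one feature between two maps over common valid points.

    ``subset`` restricts the comparison (e.g. remodelled or non-injured
    points).  Returns NaN when fewer than ``min_points`` common valid points
    remain or either side is constant.
    """
    va, ma = map_a.feature(feature)
    vb, mb = map_b.feature(feature)
    common = ma & mb & np.isfinite(va) & np.isfinite(vb)
    if subset is not None:
        common &= subset
    if common.sum() < min_points:
        return UNDEFINED
    x, y = va[common], vb[common]
    if np.std(x) == 0 or np.std(y) == 0:
        return UNDEFINED
    if spearman:
        return float(stats.spearmanr(x, y).statistic)
    return float(np.corrcoef(x, y)[0, 1])


def concordance_table(feature_maps: dict, sites, beat_label: str = "S1",
                      subset: np.ndarray = None,
                      surface: EamSurface = None) -> pd.DataFrame:
    """All map-pair concordances for one beat label.

    Returns a tidy frame (site_a, site_b, feature, r, pair_distance_mm);
    inter-site distance is geodesic when the two sites share a side,
    Euclidean otherwise.
    """
    keys = sorted([k for k in feature_maps if k[1] == beat_label])
    site_by_id = {s.id: s for s in sites}
    rows = []
    geod_cache = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            sa, sb = site_by_id[a[0]], site_by_id[b[0]]
            if surface is not None:
                if sa.side == sb.side:
                    if a[0] not in geod_cache:
                        geod_cache[a[0]] = surface.geodesic_from(sa.point_index)
                    d = float(geod_cache[a[0]][sb.point_index])
                else:
                    d = float(np.linalg.norm(sa.position - sb.position))
            else:
                d = float(np.linalg.norm(sa.position - sb.position))
            for feat in FEATURE_NAMES:
                r = feature_concordance(feature_maps[a], feature_maps[b],
                                        feat, subset)
                rows.append({"site_a": a[0], "site_b": b[0], "feature": feat,
                             "r": r, "pair_distance_mm": d})
    return pd.DataFrame(rows)


def concordance_summary(per_heart_tables: dict, fractions: dict) -> dict:
    """Cohort-level concordance summaries.

    per_heart_tables: heart id -> tidy pair table; fractions: heart id ->
    remodelling fraction.  Returns per-feature mean concordance per heart,
    the across-cohort correlation of mean concordance with remodelling
    fraction, and the within-heart correlation of pair concordance with
    inter-site distance (NaN sentinels when degenerate).
    """
    hearts = sorted(per_heart_tables)
    per_heart_mean = {}
    for hid in hearts:
        tab = per_heart_tables[hid]
        per_heart_mean[hid] = tab.groupby("feature")["r"].mean()
    trend = {}
    dist_corr = {}
    for feat in FEATURE_NAMES:
        means = np.array([per_heart_mean[h].get(feat, np.nan) for h in hearts])
        fr = np.array([fractions[h] for h in hearts])
        ok = np.isfinite(means) & np.isfinite(fr)
        if ok.sum() >= 3 and np.std(means[ok]) > 0 and np.std(fr[ok]) > 0:
            trend[feat] = float(np.corrcoef(fr[ok], means[ok])[0, 1])
        else:
            trend[feat] = UNDEFINED
        rs, ds = [], []
        for hid in hearts:
            tab = per_heart_tables[hid]
            sel = tab[tab["feature"] == feat]
            rs.append(sel["r"].to_numpy())
            ds.append(sel["pair_distance_mm"].to_numpy())
        rs = np.concatenate(rs) if rs else np.array([])
        ds = np.concatenate(ds) if ds else np.array([])
        ok = np.isfinite(rs) & np.isfinite(ds)
        if ok.sum() >= 3 and np.std(rs[ok]) > 0 and np.std(ds[ok]) > 0:
            dist_corr[feat] = float(np.corrcoef(ds[ok], rs[ok])[0, 1])
        else:
            dist_corr[feat] = UNDEFINED
    return {"per_heart_mean": per_heart_mean,
            "fraction_trend": trend,
            "distance_trend": dist_corr}


# ---------------------------------------------------------------------------
# evaluation metrics (hand-rolled, oracle-checked)

def evaluate_metrics(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> dict:
    """AUROC (pair counting with ties = 0.5), F1, sensitivity, specificity.

    AUROC uses the exact rank-statistic identity of exhaustive
    concordant-pair counting; the other metrics threshold the scores at
    ``threshold``.  Raises when labels contain a single class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    ranks = stats.rankdata(scores)
    auroc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    pred = scores >= threshold
    tp = int(np.sum(pred & pos))
    fn = n_pos - tp
    fp = int(np.sum(pred & ~pos))
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    return {"AUROC": float(auroc), "F1": float(f1),
            "sensitivity": float(sens), "specificity": float(spec)}


def group_comparisons(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sample (or paired) t-test; (0, 1) sentinel for all-zero paired
    differences, NaN sentinels for other degenerate-variance cases."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        if np.std(d, ddof=1) == 0:
            return np.nan, np.nan
        res = stats.ttest_rel(a, b)
    else:
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.nan, np.nan)
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# incremental logistic-regression ladders

def _zscore(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _fit_logistic(X: np.ndarray, y: np.ndarray, C: float = 1000.0) -> np.ndarray:
    """In-sample predicted probabilities of a weakly regularized logistic fit."""
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(X, y)
    return clf.predict_proba(X)[:, 1], clf


def logistic_coefficients(X, y, C: float = 1000.0):
    _, clf = _fit_logistic(np.asarray(X, dtype=float), np.asarray(y, int), C)
    return clf.coef_[0]


def fit_remodelling_models(feature_maps: dict, surf_labels: RemodellingSurfaceLabels,
                           sites, feature: str, variant: str = "S1",
                           max_n: int = None, C: float = 1000.0) -> list[EvaluationResult]:
    """Incremental per-heart remodelling-detection ladder for one feature.

    Maps are ordered by infarct-proximity rank; the N-th model's covariates
    are the feature values from the N most proximal available maps (plus,
    for the S2 variants, the matching S2 maps of those sites).  Non-captured
    maps are skipped with the ordering preserved.  Fits are in-sample with
    per-heart z-scored covariates and weak L2 regularization.
    """
    if surf_labels.site_ranks is None:
        raise ValueError("rank_sites_by_infarct must run first")
    y = surf_labels.remodelled.astype(int)
    beats = {"S1": ["S1"], "S1+S2_360": ["S1", "S2_360"],
             "S1+S2_310": ["S1", "S2_310"],
             "S1+both": ["S1", "S2_360", "S2_310"]}[variant]
    order = np.argsort(surf_labels.site_ranks)
    cols, col_valid = [], []
    n_maps_used = 0
    results = []
    for k in order:
        site = sites[k]
        site_cols = []
        got_s1 = (site.id, "S1") in feature_maps
        if not got_s1:
            continue
        for b in beats:
            key = (site.id, b)
            if key not in feature_maps:
                continue
            vals, valid = feature_maps[key].feature(feature)
            site_cols.append((vals, valid))
        if not site_cols:
            continue
        n_maps_used += 1
        for vals, valid in site_cols:
            cols.append(vals)
            col_valid.append(valid)
        X = np.column_stack(cols)
        ok = np.all(np.column_stack(col_valid), axis=1)
        yy = y[ok]
        if yy.sum() == 0 or yy.sum() == len(yy):
            continue
        prob, _ = _fit_logistic(_zscore(X[ok]), yy, C)
        m = evaluate_metrics(prob, yy)
        results.append(EvaluationResult(feature=feature, variant=variant,
                                        n_covariates=n_maps_used,
                                        auroc=m["AUROC"], f1=m["F1"],
                                        sensitivity=m["sensitivity"],
                                        specificity=m["specificity"]))
        if max_n is not None and n_maps_used >= max_n:
            break
    return results


def fit_circuit_models(subregion_table: pd.DataFrame, site_order: list,
                       feature: str, beats: list[str] = ("S1",),
                       max_n: int = None, C: float = 1000.0) -> list[EvaluationResult]:
    """Incremental inner-vs-outer circuit classification, pooled over VTs.

    ``subregion_table`` is tidy with columns (vt, subregion, inner, site,
    beat, feature..., value): one row per (VT, subregion, map); pivoted
    here so each observation is a (VT, subregion) with per-map covariates.
    ``site_order`` lists site ids from most to least proximal (or distal).
    """
    tab = subregion_table[subregion_table["feature"] == feature]
    results = []
    used_sites = []
    for sid in site_order:
        if not ((tab["site"] == sid) & (tab["beat"].isin(beats))).any():
            continue
        used_sites.append(sid)
        sel = tab[(tab["site"].isin(used_sites)) & (tab["beat"].isin(beats))]
        piv = sel.pivot_table(index=["vt", "subregion", "inner"],
                              columns=["site", "beat"], values="value")
        piv = piv.dropna(axis=0)
        if len(piv) < 4:
            continue
        y = piv.index.get_level_values("inner").to_numpy().astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            continue
        X = _zscore(piv.to_numpy())
        prob, _ = _fit_logistic(X, y, C)
        m = evaluate_metrics(prob, y)
        results.append(EvaluationResult(
            feature=feature, variant="+".join(beats),
            n_covariates=len(used_sites), auroc=m["AUROC"], f1=m["F1"],
            sensitivity=m["sensitivity"], specificity=m["specificity"]))
        if max_n is not None and len(used_sites) >= max_n:
            break
    return results


def results_frame(results: list[EvaluationResult], **extra) -> pd.DataFrame:
    rows = [dict(r.as_dict(), **extra) for r in results]
    return pd.DataFrame(rows)
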