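"""Cohort-scale experiment orchestration with caching and determinism.

A single :class:`ExperimentConfig` describes the cohort, geometry, pacing
design, induction protocol and analysis options; :func:`run_experiment`
executes the stages in dependency order (cohort -> surfaces/sites ->
pacing simulations -> features -> substrate and circuit analyses) with
per-job feature caching, and writes tidy CSV tables plus a JSON summary.
Identical config + seed give byte-identical result tables; per-job failures
are isolated and logged.

Resolution tiers: ``test`` (few coarse hearts, smoke-scale), ``standard``
(the desk-scale 8-heart study the analyses in this package are run at) and
``full`` (the 48 hearts x 100 sites x 3 protocols design).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as ana
from . import circuits as circ
from . import electrogram as egm
from . import features as feat
from . import propagation as prop
from . import substrate as sub
from .geometry import LvShape, extract_eam_surfaces, select_pacing_sites

PROTOCOL_COUPLINGS = {"S1": None, "S2_360": 360.0, "S2_310": 310.0}


@dataclass
class ExperimentConfig:
    tier: str = "test"
    seed: int = 0
    # cohort
    n_hearts: int = 4
    fraction_low: float = 0.10
    fraction_high: float = 0.50
    n_channels: int = 1
    # geometry
    epi_semi_axes: tuple = (22.0, 22.0, 44.0)
    wall_thickness: float = 8.0
    truncation_fraction: float = 0.7
    voxel_size: float = 2.0
    target_edge: float = 2.5
    # pacing design
    n_per_surface: int = 6
    protocols: tuple = ("S1", "S2_360")
    s2_sites: int = None            # S2 protocols only at the N most proximal sites
    # induction / circuits
    induction: bool = False
    n_induction_sites: int = 4
    n_drive: int = 3
    drive_cl: float = 450.0
    s2_start: float = 320.0
    s2_min: float = 150.0
    observe_ms: float = 800.0
    # analysis
    remodelling_threshold: float = 0.10
    remodelling_radius: float = 5.0
    max_ladder_n: int = 8
    regression_C: float = 1000.0
    out_dir: str = "results"

    def shape(self) -> LvShape:
        return LvShape(tuple(self.epi_semi_axes), self.wall_thickness,
                       self.truncation_fraction)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epi_semi_axes"] = list(d["epi_semi_axes"])
        d["protocols"] = list(d["protocols"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "epi_semi_axes" in d:
            d["epi_semi_axes"] = tuple(d["epi_semi_axes"])
        if "protocols" in d:
            d["protocols"] = tuple(d["protocols"])
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def cache_key(self, *parts) -> str:
        sim_fields = (self.seed, self.n_hearts, self.fraction_low,
                      self.fraction_high, self.n_channels,
                      tuple(self.epi_semi_axes), self.wall_thickness,
                      self.truncation_fraction, self.voxel_size,
                      self.target_edge, self.n_per_surface)
        blob = json.dumps([sim_fields, parts], sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:24]


def preset(tier: str, seed: int = 0, out_dir: str = "results") -> ExperimentConfig:
    """Named resolution tiers (see module docstring)."""
    if tier == "test":
        return ExperimentConfig(tier="test", seed=seed, out_dir=out_dir,
                                n_hearts=4, n_per_surface=6,
                                protocols=("S1", "S2_360"), s2_sites=1)
    if tier == "standard":
        return ExperimentConfig(tier="standard", seed=seed, out_dir=out_dir,
                                n_hearts=8, n_per_surface=5,
                                protocols=("S1", "S2_360", "S2_310"),
                                s2_sites=2, max_ladder_n=8)
    if tier == "full":
        return ExperimentConfig(tier="full", seed=seed, out_dir=out_dir,
                                n_hearts=48,
                                epi_semi_axes=(34.0, 34.0, 70.0),
                                wall_thickness=10.0, target_edge=2.0,
                                n_per_surface=50,
                                protocols=("S1", "S2_360", "S2_310"),
                                s2_sites=None, induction=True,
                                n_induction_sites=17, n_drive=6,
                                drive_cl=600.0, s2_start=400.0,
                                max_ladder_n=100)
    raise ValueError(f"unknown tier {tier!r}")


# ---------------------------------------------------------------------------
# job enumeration

def enumerate_jobs(config: ExperimentConfig) -> list[tuple[int, int, str]]:
    """Deterministic cartesian enumeration heart x site x protocol."""
    _validate(config)
    n_sites = 2 * config.n_per_surface
    return [(h, s, p)
            for h in range(config.n_hearts)
            for s in range(n_sites)
            for p in config.protocols]


def _validate(config: ExperimentConfig):
    problems = []
    if config.n_hearts < 1:
        problems.append("n_hearts must be >= 1")
    if config.n_per_surface < 1:
        problems.append("n_per_surface must be >= 1")
    unknown = [p for p in config.protocols if p not in PROTOCOL_COUPLINGS]
    if unknown:
        problems.append(f"unknown protocols: {unknown}")
    if not config.fraction_high > config.fraction_low >= 0:
        problems.append("remodelling fraction range is degenerate")
    if config.wall_thickness < 2 * config.voxel_size:
        problems.append("wall thinner than two voxels")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# experiment

class Experiment:
    """Materialized experiment state (models, surfaces, features, results)."""

    def __init__(self, config: ExperimentConfig):
        _validate(config)
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.cache_dir = self.out_dir / "cache"
        self.log_path = self.out_dir / "log.jsonl"
        self.cohort = None
        self.surface = None
        self.sites = None
        self.geodesic_cache = None
        self.heart_data = {}          # hid -> dict with labels, ranks, maps...
        self.tables = {}

    # -- logging -----------------------------------------------------------
    def log(self, **kv):
        self.out_dir.mkdir(parents=True, exist_ok=True)
        with open(self.log_path, "a") as f:
            f.write(json.dumps(kv, sort_keys=True, default=str) + "\n")

    # -- stages ------------------------------------------------------------
    def generate_cohort(self):
        c = self.config
        self.cohort = sub.generate_cohort(
            c.n_hearts, c.fraction_low, c.fraction_high, seed=c.seed,
            shape=c.shape(), voxel_size=c.voxel_size,
            n_channels=c.n_channels)
        model = self.cohort.hearts[0][0]
        self.surface = extract_eam_surfaces(model, c.target_edge)
        self.sites = select_pacing_sites(self.surface, c.n_per_surface,
                                         seed=c.seed)
        self.geodesic_cache = feat.geodesic_neighbourhoods(self.surface)
        self.log(stage="cohort", n_hearts=len(self.cohort),
                 fractions=[round(f, 4) for f in self.cohort.fractions],
                 surface_points=self.surface.n_points)
        return self.cohort

    def _rank_hearts(self):
        for hid, (model, labels, _) in enumerate(self.cohort.hearts):
            surf_labels = ana.project_remodelling(
                self.surface, labels, model,
                radius_mm=self.config.remodelling_radius,
                threshold=self.config.remodelling_threshold)
            if surf_labels.remodelled.sum():
                ana.rank_sites_by_infarct(self.surface, self.sites, surf_labels)
            self.heart_data[hid] = {"model": model, "labels": labels,
                                    "surf_labels": surf_labels,
                                    "feature_maps": {}, "capture": []}

    def _site_protocols(self, hid) -> list[tuple[int, str]]:
        """(site index, protocol) jobs for one heart, honouring s2_sites."""
        c = self.config
        surf_labels = self.heart_data[hid]["surf_labels"]
        jobs = []
        ranks = surf_labels.site_ranks
        for k, site in enumerate(self.sites):
            for p in c.protocols:
                if (p != "S1" and c.s2_sites is not None and ranks is not None
                        and ranks[k] > c.s2_sites):
                    continue
                jobs.append((k, p))
        return jobs

    def simulate(self):
        c = self.config
        if self.cohort is None:
            self.generate_cohort()
        self._rank_hearts()
        sim_cfg = prop.SimConfig()
        for hid, (model, labels, _) in enumerate(self.cohort.hearts):
            hd = self.heart_data[hid]
            forward = None                # conducting set differs per heart
            for k, pname in self._site_protocols(hid):
                site = self.sites[k]
                coupling = PROTOCOL_COUPLINGS[pname]
                beat_label = "S1" if coupling is None else pname
                key = self.config.cache_key("map", hid, site.id, pname,
                                            c.remodelling_threshold)
                cached = self._load_map(key)
                if cached is not None:
                    fmap, captured = cached
                    if captured:
                        hd["feature_maps"][(site.id, beat_label)] = fmap
                    hd["capture"].append((site.id, beat_label, captured))
                    continue
                t0 = time.time()
                try:
                    trace = prop.deliver_s1s2(model, labels, site, coupling,
                                              sim_cfg)
                except prop.NumericalInstability as e:
                    self.log(stage="simulate", heart=hid, site=site.id,
                             protocol=pname, status="failed", error=str(e))
                    continue
                beat = "S1" if coupling is None else "S2"
                captured = bool(trace.capture.get(beat, False))
                fmap = None
                if captured:
                    if forward is None:
                        forward = egm.UnipolarForwardOperator(
                            model, self.surface, trace.cond_nodes)
                    emap = egm.compute_unipolar(trace, self.surface,
                                                forward=forward, beat=beat)
                    emap.beat = beat_label
                    fmap = feat.extract_features(
                        emap, self.surface, geodesic_cache=self.geodesic_cache)
                    fmap.beat = beat_label
                    hd["feature_maps"][(site.id, beat_label)] = fmap
                hd["capture"].append((site.id, beat_label, captured))
                self._store_map(key, fmap, captured)
                self.log(stage="simulate", heart=hid, site=site.id,
                         protocol=pname,
                         status="captured" if captured else "not captured",
                         seconds=round(time.time() - t0, 2))

    # -- cache -------------------------------------------------------------
    def _store_map(self, key, fmap, captured):
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        path = self.cache_dir / f"{key}.npz"
        if fmap is None:
            np.savez_compressed(path, captured=np.array([captured]))
            return
        arrays = {"captured": np.array([captured]),
                  "activation": fmap.activation,
                  "site_id": np.array([fmap.site_id]),
                  "beat": np.array([fmap.beat])}
        for name in feat.FEATURE_NAMES:
            arrays[f"v_{name}"] = fmap.values[name]
            arrays[f"m_{name}"] = fmap.valid[name]
        np.savez_compressed(path, **arrays)

    def _load_map(self, key):
        path = self.cache_dir / f"{key}.npz"
        if not path.exists():
            return None
        with np.load(path, allow_pickle=False) as z:
            captured = bool(z["captured"][0])
            if not captured:
                return None, False
            fmap = feat.FeatureMap(site_id=int(z["site_id"][0]),
                                   beat=str(z["beat"][0]),
                                   activation=z["activation"])
            for name in feat.FEATURE_NAMES:
                fmap.values[name] = z[f"v_{name}"]
                fmap.valid[name] = z[f"m_{name}"]
        return fmap, True

    # -- analyses ----------------------------------------------------------
    def analyze_concordance(self):
        tabs = {}
        for hid, hd in self.heart_data.items():
            tab = ana.concordance_table(hd["feature_maps"], self.sites,
                                        "S1", surface=self.surface)
            remod = hd["surf_labels"].remodelled
            tab_r = ana.concordance_table(hd["feature_maps"], self.sites, "S1",
                                          subset=remod, surface=self.surface)
            tab_n = ana.concordance_table(hd["feature_maps"], self.sites, "S1",
                                          subset=~remod & ~self.surface.is_cap,
                                          surface=self.surface)
            tab["subset"] = "all"
            tab_r["subset"] = "remodelled"
            tab_n["subset"] = "non_injured"
            tabs[hid] = pd.concat([tab, tab_r, tab_n], ignore_index=True)
        frames = []
        for hid, t in tabs.items():
            t = t.copy()
            t.insert(0, "heart", hid)
            t.insert(1, "remodelling_fraction", self.cohort.fractions[hid])
            frames.append(t)
        self.tables["concordance_pairs"] = pd.concat(frames, ignore_index=True)
        summary = ana.concordance_summary(
            {h: t[t["subset"] == "all"] for h, t in tabs.items()},
            {h: self.cohort.fractions[h] for h in tabs})
        rows = [{"feature": f,
                 "fraction_trend_r": summary["fraction_trend"][f],
                 "distance_trend_r": summary["distance_trend"][f]}
                for f in feat.FEATURE_NAMES]
        self.tables["concordance_summary"] = pd.DataFrame(rows)
        return summary

    def analyze_remodelling(self):
        c = self.config
        frames = []
        variants = ["S1"]
        if any(p.startswith("S2_360") for p in c.protocols):
            variants.append("S1+S2_360")
        if any(p.startswith("S2_310") for p in c.protocols):
            variants.append("S1+S2_310")
        if len(variants) == 3:
            variants.append("S1+both")
        for hid, hd in self.heart_data.items():
            sl = hd["surf_labels"]
            if sl.site_ranks is None or sl.remodelled.sum() == 0:
                continue
            for feature in feat.FEATURE_NAMES:
                for variant in variants:
                    res = ana.fit_remodelling_models(
                        hd["feature_maps"], sl, self.sites, feature, variant,
                        max_n=c.max_ladder_n, C=c.regression_C)
                    df = ana.results_frame(res, heart=hid,
                                           group=self.cohort.group[hid])
                    frames.append(df)
        self.tables["remodelling_models"] = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
        return self.tables["remodelling_models"]

    def analyze_circuits(self):
        c = self.config
        rows = []
        eval_frames = []
        for hid, hd in self.heart_data.items():
            model, labels = hd["model"], hd["labels"]
            icfg = prop.InductionConfig(
                n_drive=c.n_drive, drive_cl=c.drive_cl, s2_start=c.s2_start,
                s2_min=c.s2_min, observe=c.observe_ms)
            episodes = prop.induce_vt(model, labels, c.n_induction_sites,
                                      icfg, seed=c.seed + 17 * hid)
            self.log(stage="induce", heart=hid, episodes=len(episodes))
            for vt_id, ep in enumerate(episodes):
                try:
                    circuit = circ.build_circuit(ep, labels, model, self.surface)
                    circ.split_inner_outer(circuit, self.surface,
                                           hd["feature_maps"])
                except ValueError as e:
                    self.log(stage="circuit", heart=hid, vt=vt_id,
                             status="failed", error=str(e))
                    continue
                for (sub_name, fname, sid, beat), val in \
                        circuit.subregion_features.items():
                    rows.append({"heart": hid, "vt": f"{hid}:{vt_id}",
                                 "subregion": sub_name,
                                 "inner": int(sub_name.endswith("inner")),
                                 "side": sub_name.split("_")[0],
                                 "feature": fname, "site": sid, "beat": beat,
                                 "value": val,
                                 "cycle_length": ep.cycle_length})
        table = pd.DataFrame(rows)
        self.tables["circuit_subregions"] = table
        if len(table):
            site_ids = sorted({r["site"] for r in rows})
            for feature in feat.FEATURE_NAMES:
                res = ana.fit_circuit_models(table, site_ids, feature,
                                             beats=("S1",),
                                             max_n=c.max_ladder_n,
                                             C=c.regression_C)
                eval_frames.append(ana.results_frame(res, ordering="proximal"))
        self.tables["circuit_models"] = (
            pd.concat(eval_frames, ignore_index=True) if eval_frames
            else pd.DataFrame())
        return self.tables["circuit_subregions"]

    # -- output ------------------------------------------------------------
    def write_outputs(self):
        self.out_dir.mkdir(parents=True, exist_ok=True)
        digests = {}
        for name, df in sorted(self.tables.items()):
            path = self.out_dir / f"{name}.csv"
            df = df.copy()
            df.to_csv(path, index=False, float_format="%.9g",
                      lineterminator="\n")
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        capture = [
            {"heart": hid, "site": s, "beat": b, "captured": bool(cap)}
            for hid, hd in self.heart_data.items()
            for (s, b, cap) in hd["capture"]]
        summary = {
            "config": self.config.to_dict(),
            "fractions": [float(f) for f in (self.cohort.fractions
                                             if self.cohort is not None else [])],
            "groups": list(self.cohort.group) if self.cohort is not None else [],
            "capture": capture,
            "table_digests": digests,
        }
        (self.out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str))
        return digests


def run_experiment(config: ExperimentConfig, stages=("simulate", "concordance",
                                                     "remodelling", "circuits",
                                                     "outputs")) -> Experiment:
    """Execute the experiment stages in dependency order."""
    exp = Experiment(config)
    exp.generate_cohort()
    if "simulate" in stages or {"concordance", "remodelling",
                                "circuits"} & set(stages):
        exp.simulate()
    if "concordance" in stages:
        exp.analyze_concordance()
    if "remodelling" in stages:
        exp.analyze_remodelling()
    if "circuits" in stages and config.induction:
        exp.analyze_circuits()
    if "outputs" in stages:
        exp.write_outputs()
    return exp
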