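"""End-to-end orchestration: simulate -> preprocess -> roi -> connect -> stats.

A run directory contains one numbered subfolder per stage plus a provenance
manifest (config hash, seed, stage status).  Stages are cached: a stage whose
done-marker matches the current config hash is skipped on resume, so partial
reruns pick up where they left off.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .behavior import score_log
from .connectivity import WindowSpec, build_block_measure_table
from .preprocess import preprocess_session
from .roi import define_roi, extract_timecourse, fit_localizer_glm
from .simulate import (ClusterSpec, SimulationConfig, generate_localizer_volume,
                       simulate_session)
from .stats import stats_report

log = logging.getLogger(__name__)

STAGES = ("01_simulate", "02_preprocess", "03_roi", "04_connect", "05_stats")


@dataclass
class PipelineConfig:
    """Serialisable configuration for one pipeline run."""

    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {"k_discard": 5, "n_cycles": 3})
    roi: dict = field(default_factory=lambda: {
        "enabled": True, "threshold_p": 0.001, "max_voxels": 20,
        "grid_shape": [12, 12, 6], "n_blocks": 6,
        "clusters": [{"label": "left_M1", "center": [3, 3, 3],
                      "n_voxels": 30, "amplitude": 3.0},
                     {"label": "right_M1", "center": [8, 8, 3],
                      "n_voxels": 30, "amplitude": 3.0}]})
    windows: dict = field(default_factory=lambda: {
        "full_task": [2.0, 28.0], "steady_state": [10.0, 22.0], "rest": [-12.0, 0.0]})
    stats: dict = field(default_factory=lambda: {
        "alpha": 0.05, "scopes": ["subject"], "pairs": None, "bonferroni": False})

    def to_dict(self) -> dict:
        return {"simulation": self.simulation, "preprocess": self.preprocess,
                "roi": self.roi, "windows": self.windows, "stats": self.stats}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for key in ("simulation", "preprocess", "roi", "windows", "stats"):
            if key in d:
                merged = dict(getattr(cfg, key))
                merged.update(d[key] or {})
                setattr(cfg, key, merged)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        kw = dict(self.simulation)
        for tup_key in ("sequences", "speeds_hz"):
            if tup_key in kw:
                kw[tup_key] = tuple(kw[tup_key])
        return SimulationConfig(**kw)

    def window_specs(self) -> dict[str, WindowSpec]:
        return {name: WindowSpec(name, float(lo), float(hi))
                for name, (lo, hi) in self.windows.items()}


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, sep: str = ",") -> None:
    out = df.copy()
    out["config_hash"] = config_hash
    out.to_csv(path, sep=sep, index=False)


def _marker(stage_dir: Path) -> Path:
    return stage_dir / ".done.json"


def _stage_done(stage_dir: Path, config_hash: str) -> bool:
    m = _marker(stage_dir)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == config_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, config_hash: str) -> None:
    _marker(stage_dir).write_text(json.dumps({"config_hash": config_hash}))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.simulation_config()
    design, tap, tcs, truth = simulate_session(sim)
    bio.save_events(design, out / "events.tsv")
    bio.save_tapping_log(tap, out / "tapping.tsv", out / "tapping_injected.tsv")
    bio.save_timecourses(tcs, out / "timecourses.tsv")
    (out / "ground_truth.json").write_text(json.dumps({
        "rois": list(truth.rois),
        "coupling": {f"{a}-{b}": v for (a, b), v in truth.coupling.items()},
        "beta": truth.beta, "error_prob": truth.error_prob,
        "noise_sd": truth.noise_sd, "ar1_phi": truth.ar1_phi,
    }, indent=2, default=float))


def stage_preprocess(cfg: PipelineConfig, out: Path, run_dir: Path) -> None:
    sim = cfg.simulation_config()
    design = bio.load_events(run_dir / "01_simulate" / "events.tsv", sim.tr_ms,
                             sim.run_volumes, sim.block_rest_s)
    tcs = bio.load_timecourses(run_dir / "01_simulate" / "timecourses.tsv", sim.tr_ms)
    clean, shifted = preprocess_session(tcs, design, **cfg.preprocess)
    bio.save_timecourses(clean, out / "timecourses.tsv")
    bio.save_events(shifted, out / "events.tsv")


def stage_roi(cfg: PipelineConfig, out: Path) -> None:
    """Localizer demonstration: simulate a small 4D run, fit the GLM, define
    ROIs at each configured cluster's coordinate, extract mean time courses."""
    rc = cfg.roi
    if not rc.get("enabled", True):
        (out / "skipped.txt").write_text("roi stage disabled in config\n")
        return
    sim = cfg.simulation_config()
    specs = [ClusterSpec(tuple(c["center"]), int(c["n_voxels"]), float(c["amplitude"]))
             for c in rc["clusters"]]
    vol = generate_localizer_volume(tuple(rc["grid_shape"]), specs, seed=sim.seed,
                                    n_blocks=int(rc.get("n_blocks", 6)))
    tmap = fit_localizer_glm(vol.data, vol.events, tr_ms=vol.tr_ms)
    rois = []
    for c in rc["clusters"]:
        roi = define_roi(tmap, rc["threshold_p"], c["center"],
                         max_voxels=rc["max_voxels"], label=c["label"])
        rois.append(roi)
    bio.save_roi_definitions(rois, out / "roi_definitions.json")
    tc = pd.DataFrame({r.label: extract_timecourse(vol.data, r) for r in rois})
    tc.to_csv(out / "localizer_roi_timecourses.tsv", sep="\t", index=False)


def stage_connect(cfg: PipelineConfig, out: Path, run_dir: Path) -> None:
    sim = cfg.simulation_config()
    k = cfg.preprocess.get("k_discard", 5)
    design = bio.load_events(run_dir / "02_preprocess" / "events.tsv", sim.tr_ms,
                             sim.run_volumes - k, sim.block_rest_s)
    tcs = bio.load_timecourses(run_dir / "02_preprocess" / "timecourses.tsv", sim.tr_ms)
    tap = bio.load_tapping_log(run_dir / "01_simulate" / "tapping.tsv")
    behavior = score_log(tap, design)
    pairs = cfg.stats.get("pairs")
    table = build_block_measure_table(
        tcs, design, windows=cfg.window_specs(),
        pairs=[tuple(p) for p in pairs] if pairs else None, behavior=behavior)
    _write_table(behavior, out / "behavior.csv", cfg.config_hash)
    _write_table(table, out / "block_measures.csv", cfg.config_hash)


def stage_stats(cfg: PipelineConfig, out: Path, run_dir: Path) -> None:
    table = pd.read_csv(run_dir / "04_connect" / "block_measures.csv")
    tidy, report = stats_report(table, alpha=cfg.stats.get("alpha", 0.05),
                                scopes=tuple(cfg.stats.get("scopes", ["subject"])),
                                bonferroni=bool(cfg.stats.get("bonferroni", False)))
    _write_table(tidy, out / "results.csv", cfg.config_hash)
    (out / "report.txt").write_text(report + "\n")


_STAGE_FUNCS = {
    "01_simulate": lambda cfg, d, run_dir: stage_simulate(cfg, d),
    "02_preprocess": lambda cfg, d, run_dir: stage_preprocess(cfg, d, run_dir),
    "03_roi": lambda cfg, d, run_dir: stage_roi(cfg, d),
    "04_connect": lambda cfg, d, run_dir: stage_connect(cfg, d, run_dir),
    "05_stats": lambda cfg, d, run_dir: stage_stats(cfg, d, run_dir),
}


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = True,
                 stages=STAGES) -> dict:
    """Run (or resume) the pipeline; returns the provenance manifest."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest = {"config_hash": config.config_hash,
                "seed": config.simulation_config().seed,
                "stages": {}}
    for stage in stages:
        stage_dir = run_dir / stage
        if resume and _stage_done(stage_dir, config.config_hash):
            log.info("stage %s cached, skipping", stage)
            manifest["stages"][stage] = "cached"
            continue
        stage_dir.mkdir(exist_ok=True)
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, stage_dir, run_dir)
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc
        _mark_done(stage_dir, config.config_hash)
        manifest["stages"][stage] = "completed"
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
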