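"""Study orchestration: config-driven simulate -> track -> analyze -> report.

A :class:`StudyConfig` declares conditions (each a preset with explicit
seeds), acquisition settings, and analysis parameters; :func:`run_pipeline`
executes every stage per condition and writes per-stage CSV/JSON artifacts
plus a per-condition summary table. Outputs are a pure function of the
config and seeds, and every file records the config hash.
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

from . import dwell as dwell_mod
from . import io as io_mod
from .kinetics import collect_jumps, fit_two_state, summarize_condition
from .msd import analyze_tracks, filter_results
from .presets import KineticPreset, preset_catalog
from .simulate import (
    AcquisitionConfig,
    NucleusGeometry,
    simulate_condition,
)
from .tracking import link_recording

__all__ = ["StudyConfig", "ConditionSpec", "run_pipeline", "load_config"]

logger = logging.getLogger("nucspt")


@dataclass
class ConditionSpec:
    label: str
    preset: str
    n_cells: int
    n_molecules: int
    seed: int
    modes: tuple[str, ...] = ("fast",)


@dataclass
class StudyConfig:
    conditions: list[ConditionSpec]
    output_dir: Path
    geometry: NucleusGeometry = field(default_factory=NucleusGeometry)
    fast_acquisition: dict = field(default_factory=dict)
    slow_acquisition: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        catalog = preset_catalog()
        for c in self.conditions:
            if c.preset not in catalog:
                raise ValueError(f"unknown preset {c.preset!r} in condition {c.label!r}")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location is not
        part of the study identity)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "conditions": [vars(c) | {"modes": list(c.modes)} for c in self.conditions],
            "output_dir": str(self.output_dir),
            "geometry": {"radius_um": self.geometry.radius_um},
            "fast_acquisition": self.fast_acquisition,
            "slow_acquisition": self.slow_acquisition,
            "analysis": self.analysis,
        }


def load_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    conditions = [
        ConditionSpec(
            label=c["label"], preset=c["preset"], n_cells=int(c["n_cells"]),
            n_molecules=int(c["n_molecules"]), seed=int(c["seed"]),
            modes=tuple(c.get("modes", ["fast"])),
        )
        for c in raw["conditions"]
    ]
    geometry = NucleusGeometry(**raw.get("geometry", {}))
    return StudyConfig(
        conditions=conditions,
        output_dir=Path(raw.get("output_dir", "nucspt_out")),
        geometry=geometry,
        fast_acquisition=raw.get("fast_acquisition", {}),
        slow_acquisition=raw.get("slow_acquisition", {}),
        analysis=raw.get("analysis", {}),
    )


def _run_fast(cond: ConditionSpec, cfg: StudyConfig, preset: KineticPreset, out: Path) -> dict:
    acq = AcquisitionConfig.fast_tracking(**cfg.fast_acquisition)
    analysis = cfg.analysis
    d_max = float(analysis.get("D_max_fast", 5.0))
    recs = simulate_condition(preset, cond.n_cells, cfg.geometry, acq,
                              base_seed=cond.seed, n_molecules=cond.n_molecules,
                              keep_ground_truth=False)
    fits = []
    all_tracks = []
    all_msd = []
    for rec in recs:
        ts = link_recording(rec, D_max=d_max)
        all_tracks.append(ts.tracks.assign(cell_id=rec.cell_id))
        msd_table = analyze_tracks(ts)
        all_msd.append(msd_table)
        jumps = collect_jumps(ts, max_lag=int(analysis.get("max_lag", 4)),
                              cell_id=rec.cell_id)
        fits.append(fit_two_state(
            jumps,
            d_bound_max=float(analysis.get("D_bound_max", 0.08)),
            d_free_min=float(analysis.get("D_free_min", 0.15)),
        ))
    pd.concat(all_tracks, ignore_index=True).to_csv(out / f"{cond.label}_tracks.csv", index=False)
    msd_all = pd.concat(all_msd, ignore_index=True)
    msd_all.to_csv(out / f"{cond.label}_msd.csv", index=False)
    dist = filter_results(msd_all, label=cond.label,
                          min_r2=float(analysis.get("min_r2", 0.8)))
    fit_table = pd.DataFrame([
        {"cell_id": f.cell_id, "F_bound": f.F_bound_hat, "D_free": f.D_free_hat,
         "D_bound": f.D_bound_hat, "residual": f.residual, "n_jumps": f.n_jumps,
         "flags": ";".join(f.flags)}
        for f in fits
    ])
    fit_table.to_csv(out / f"{cond.label}_twostate_fits.csv", index=False)
    summary = summarize_condition(fits) if len(fits) >= 2 else {}
    summary["n_molecules_retained"] = dist.counts.get("retained", 0)
    return {"two_state": summary, "fits": fits, "diffusion_counts": dist.counts}


def _run_slow(cond: ConditionSpec, cfg: StudyConfig, preset: KineticPreset, out: Path) -> dict:
    acq = AcquisitionConfig.slow_dwell(**cfg.slow_acquisition)
    analysis = cfg.analysis
    # distinct seed stream from the fast stage of the same condition
    recs = simulate_condition(preset, cond.n_cells, cfg.geometry, acq,
                              base_seed=cond.seed + 10_000,
                              n_molecules=cond.n_molecules,
                              keep_ground_truth=False)
    durations = []
    for rec in recs:
        ts = dwell_mod.extract_immobile_tracks(
            rec, D_max=float(analysis.get("D_max_dwell", 0.05)))
        durations.append(dwell_mod.track_durations(ts))
    durations = np.concatenate(durations) if durations else np.array([])
    if len(durations) < 5:
        return {"dwell": None, "n_events": int(len(durations))}
    curve = dwell_mod.survival_curve(durations)
    fit = dwell_mod.fit_double_exponential(curve)
    pd.DataFrame({"t_s": curve.grid, "S": curve.S,
                  "N": np.full(len(curve.grid), curve.n_tracks)}
                 ).to_csv(out / f"{cond.label}_survival.csv", index=False)
    dwell_json = {"f_long": fit.f_long, "tau_short_s": fit.tau_short_s,
                  "tau_long_s": fit.tau_long_s, "residual": fit.residual,
                  "flags": fit.flags, "n_events": curve.n_tracks}
    (out / f"{cond.label}_dwell.json").write_text(json.dumps(dwell_json, indent=1))
    return {"dwell": dwell_json, "n_events": curve.n_tracks}


def run_pipeline(config: StudyConfig) -> dict:
    """Execute all conditions; returns (and writes) the study summary.

    A stage failure aborts that condition with a logged reason; other
    conditions proceed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.json").write_text(json.dumps(config.to_dict() | {"hash": chash}, indent=1))
    catalog = preset_catalog()

    summary_rows = []
    report: dict = {"config_hash": chash, "conditions": {}}
    for cond in config.conditions:
        preset = catalog[cond.preset]
        entry: dict = {}
        try:
            if "fast" in cond.modes:
                entry.update(_run_fast(cond, config, preset, out))
            if "slow" in cond.modes:
                entry.update(_run_slow(cond, config, preset, out))
        except Exception as exc:  # noqa: BLE001 - isolate per-condition failures
            logger.error("condition %s failed: %s", cond.label, exc)
            entry["error"] = str(exc)
            report["conditions"][cond.label] = entry
            continue
        report["conditions"][cond.label] = entry
        row = {"label": cond.label, "preset": cond.preset, "n_cells": cond.n_cells,
               "config_hash": chash}
        two = entry.get("two_state") or {}
        row["F_bound_mean"] = two.get("F_bound_mean", np.nan)
        row["F_bound_sd"] = two.get("F_bound_sd", np.nan)
        row["D_free_mean"] = two.get("D_free_mean", np.nan)
        row["D_free_sd"] = two.get("D_free_sd", np.nan)
        dw = entry.get("dwell") or {}
        row["f_long"] = dw.get("f_long", np.nan)
        row["tau_short_s"] = dw.get("tau_short_s", np.nan)
        row["tau_long_s"] = dw.get("tau_long_s", np.nan)
        summary_rows.append(row)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    serializable = {
        k: {kk: vv for kk, vv in v.items() if kk not in ("fits",)}
        for k, v in report["conditions"].items()
    }
    (out / "summary.json").write_text(
        json.dumps({"config_hash": chash, "conditions": serializable},
                   indent=1, default=str))
    report["summary"] = summary
    return report
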