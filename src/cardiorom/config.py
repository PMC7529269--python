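"""Run configuration, manifest and pipeline orchestration.

A run is described by a single YAML/dict config:

.. code-block:: yaml

    scenario: test1-mini
    overrides: {}
    seed: 7
    dlrom: {n: 3, max_epochs: 500, conv_channels: [4, 8, 16], kernel: 5}
    pod: {n_modes: 3, n_clusters: 1}
    evaluate: true

Stages (snapshot generation, DL-ROM training, POD-ROM construction,
evaluation) are idempotent: each stage is skipped when its artifact is
already present in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dlrom import DLROM, TrainedDLROM
from .fom import SnapshotSet, solve_fom
from .io import load_snapshots, save_snapshots
from .metrics import error_report
from .pod import PODGalerkinROM
from .scenarios import Scenario, get_scenario

_DEFAULTS = {"overrides": {}, "seed": 0, "evaluate": True}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    cfg = {**_DEFAULTS, **cfg}
    if "scenario" not in cfg:
        raise ValueError("config must name a scenario preset")
    get_scenario(cfg["scenario"])  # raises KeyError with the preset list
    return cfg


def manifest_for(cfg: dict) -> dict:
    """Reproducibility manifest: config, version, timestamp, content hash."""
    payload = json.dumps(
        {k: v for k, v in cfg.items() if k != "timestamp"},
        sort_keys=True, default=str,
    )
    return {
        "config": cfg,
        "version": __version__,
        "hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def scenario_from_config(cfg: dict) -> Scenario:
    return get_scenario(cfg["scenario"], **cfg.get("overrides", {}))


def generate_snapshots(scenario: Scenario, params: np.ndarray,
                       record_ionic: bool = True) -> SnapshotSet:
    """Run the FOM over a parameter set and stack the snapshot sets."""
    sets = [
        solve_fom(scenario, mu, record_ionic=record_ionic)
        for mu in np.atleast_2d(params)
    ]
    return SnapshotSet.concatenate(sets)


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """generate-snapshots -> train-dlrom / build-pod-rom -> evaluate -> report.

    Returns the report dict; artifacts land in ``outdir`` (snapshots.h5,
    dlrom/, report.json, manifest.json).
    """
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest_for(cfg)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    scenario = scenario_from_config(cfg)
    grid_params = scenario.parameter_grid()

    snap_path = outdir / "snapshots.h5"
    if snap_path.exists():
        snapshots = load_snapshots(snap_path)
    else:
        snapshots = generate_snapshots(scenario, grid_params.train)
        save_snapshots(snap_path, snapshots, manifest=manifest)

    report: dict = {"manifest_hash": manifest["hash"],
                    "scenario": scenario.name}
    truth = None
    if cfg.get("evaluate", True):
        truth = [
            solve_fom(scenario, mu, record_ionic=False).S
            for mu in grid_params.test
        ]

    if "dlrom" in cfg:
        model_dir = outdir / "dlrom"
        if (model_dir / "model.json").exists():
            model = TrainedDLROM.load(model_dir)
        else:
            est = DLROM(**cfg["dlrom"], seed=cfg["seed"])
            est.fit(snapshots, param_box=scenario.param_box)
            model = est.model_
            model.save(model_dir)
        if truth is not None:
            times = scenario.time.sample_times()
            preds = [model.predict(times, mu).T for mu in grid_params.test]
            rep = error_report(truth, preds, model="dlrom")
            report["dlrom_eps_rel"] = rep.eps_rel
            report["dlrom_eps_rel_per_instance"] = rep.per_instance.tolist()

    if "pod" in cfg:
        rom = PODGalerkinROM(**cfg["pod"])
        rom.fit(snapshots, scenario=scenario)
        if truth is not None:
            preds = [rom.predict(mu).U for mu in grid_params.test]
            rep = error_report(truth, preds, model="pod_galerkin")
            report["pod_eps_rel"] = rep.eps_rel
            report["pod_eps_rel_per_instance"] = rep.per_instance.tolist()

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
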