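"""Persistence of simulation runs and assembly of analysis reports.

Array data (rate maps, weights, checkpoints) live in one HDF5 file per run;
per-cell metrics go to CSV; topology/configuration reports to JSON.  A run
manifest records the config snapshot, seeds and a checksum inventory of every
file written, so stale or corrupted artifacts are detectable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SimulationConfig, save_config
from .network import NetworkState, RateMapStack

__all__ = ["save_run", "load_run", "write_manifest", "verify_manifest",
           "assemble_report"]

RUN_FILE = "run.h5"
MANIFEST_FILE = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_run(run_dir, config: SimulationConfig, state: NetworkState,
             stack: RateMapStack, checkpoints=()) -> Path:
    """Write maps, weights and checkpoints to `<run_dir>/run.h5`, the config
    to YAML, and a checksum manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    h5path = run_dir / RUN_FILE
    with h5py.File(h5path, "w") as f:
        f.create_dataset("maps", data=stack.maps)
        f.create_dataset("W_in", data=state.W_in)
        f.create_dataset("W_rec", data=state.W_rec)
        meta = f.create_group("meta")
        meta.attrs["config"] = json.dumps(config.to_dict())
        meta.attrs["pixel_size"] = stack.pixel_size
        if checkpoints:
            g = f.create_group("checkpoints")
            g.create_dataset("steps",
                             data=np.array([s for s, _ in checkpoints]))
            g.create_dataset("maps",
                             data=np.stack([m for _, m in checkpoints]))
    save_config(config, run_dir / "config.yaml")
    write_manifest(run_dir)
    return h5path


def load_run(run_dir):
    """Read back (config, maps, W_in, W_rec, checkpoints) from a run dir."""
    run_dir = Path(run_dir)
    with h5py.File(run_dir / RUN_FILE, "r") as f:
        config = SimulationConfig.from_dict(
            json.loads(f["meta"].attrs["config"]))
        maps = f["maps"][:]
        W_in = f["W_in"][:]
        W_rec = f["W_rec"][:]
        ckpts = []
        if "checkpoints" in f:
            steps = f["checkpoints/steps"][:]
            cmaps = f["checkpoints/maps"][:]
            ckpts = [(int(s), m) for s, m in zip(steps, cmaps)]
    return config, RateMapStack(maps), W_in, W_rec, ckpts


def write_manifest(run_dir) -> Path:
    """Inventory every file in the run directory with its SHA-256."""
    run_dir = Path(run_dir)
    files = sorted(p for p in run_dir.rglob("*")
                   if p.is_file() and p.name != MANIFEST_FILE)
    manifest = {
        "files": {str(p.relative_to(run_dir)): _sha256(p) for p in files},
    }
    path = run_dir / MANIFEST_FILE
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def verify_manifest(run_dir) -> list:
    """Return the list of missing or corrupted files (empty = all good)."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / MANIFEST_FILE).read_text())
    bad = []
    for rel, digest in manifest["files"].items():
        p = run_dir / rel
        if not p.is_file() or _sha256(p) != digest:
            bad.append(rel)
    return bad


def assemble_report(run_dir, out_path=None) -> dict:
    """Merge metrics.csv, topology.json and configuration.json (whichever
    exist in `run_dir`) into a single report; missing pieces are recorded as
    explicit gaps.  Given several runs' reports, downstream code can count
    Betti patterns; for one run the tables have one row."""
    run_dir = Path(run_dir)
    report: dict = {"run_dir": str(run_dir), "gaps": []}

    metrics_path = run_dir / "metrics.csv"
    if metrics_path.is_file():
        df = pd.read_csv(metrics_path)
        report["metrics"] = df.to_dict(orient="records")
        cells = df[df["cell_id"] != "population"] \
            if "cell_id" in df else df
        num = cells.select_dtypes("number")
        report["metrics_summary"] = {c: float(num[c].mean()) for c in num}
    else:
        report["gaps"].append("metrics.csv")

    topo_path = run_dir / "topology.json"
    if topo_path.is_file():
        report["topology"] = json.loads(topo_path.read_text())
    else:
        report["gaps"].append("topology.json")

    conf_path = run_dir / "configuration.json"
    if conf_path.is_file():
        report["configuration"] = json.loads(conf_path.read_text())
    else:
        report["gaps"].append("configuration.json")

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report


def betti_frequency_table(reports: list) -> dict:
    """Frequency of Betti patterns across several runs' topology reports
    (the per-condition pie counts)."""
    counts: dict = {}
    for rep in reports:
        topo = rep.get("topology")
        if not topo or "betti" not in topo:
            continue
        key = ",".join(str(int(b)) for b in topo["betti"])
        counts[key] = counts.get(key, 0) + 1
    return counts
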