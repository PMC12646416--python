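"""Run outputs: tidy CSV tables, JSON event metadata, config echo, manifest.

Every output directory is self-describing: the resolved-config echo plus
the manifest are sufficient to re-run the computation, and re-running from
the echo reproduces byte-identical tables (the engine is deterministic).
Trait values round-trip through CSV at 17 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, save_config
from .core import CommunityState
from .equilibrium import EquilibriumResult
from .evolution import EventLog, EvoTrajectory

__all__ = ["write_outputs"]

_FLOAT_FMT = "%.17g"

_MANIFEST_COLUMNS = {
    "trajectory.csv": {
        "evo_time": "evolutionary time at the start of the step",
        "ecomorph_id": "unique ecomorph identifier",
        "lineage_id": "ancestral lineage label",
        "eta": "feeding niche trait",
        "ell": "offspring size (mass)",
        "N": "equilibrium total density J*+A*",
        "C": "equilibrium adult fraction A*/N*",
        "g_eta": "selection gradient in the niche trait",
        "g_ell": "selection gradient in offspring size",
        "curvature_eta": "fitness curvature in the niche trait (only when evaluated)",
    },
    "events.csv": {
        "evo_time": "evolutionary time of the event",
        "kind": "branch | extinction | cessation | merge | stop",
        "ecomorph_ids": "ids involved (branch: parent, child1, child2)",
    },
    "resources.csv": {
        "evo_time": "evolutionary time of the checkpoint",
        "resource_index": "resource number (0-based)",
        "theta": "optimal niche trait of the resource",
        "F_star": "equilibrium resource density",
    },
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_outputs(trajectory: EvoTrajectory, events: EventLog,
                  outdir, config: RunConfig | None = None,
                  resource_checkpoints: pd.DataFrame | None = None,
                  final: CommunityState | None = None) -> dict[str, Path]:
    """Write the products of a run to ``outdir``; returns {name: path}.

    Writes trajectory.csv, events.csv, resources.csv (when checkpoints were
    collected), final_community.json, the resolved-config echo
    (config_echo.yaml) and manifest.json.  Partial runs write valid files
    with whatever rows exist (possibly headers only).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    traj_df = trajectory.to_frame()
    _write_csv(traj_df, out / "trajectory.csv")
    written["trajectory"] = out / "trajectory.csv"

    ev_df = events.to_frame()
    if "ecomorph_ids" in ev_df.columns:
        ev_df = ev_df.copy()
        ev_df["ecomorph_ids"] = ev_df["ecomorph_ids"].map(
            lambda ids: ";".join(str(i) for i in ids))
    _write_csv(ev_df, out / "events.csv")
    written["events"] = out / "events.csv"
    with open(out / "events.json", "w") as fh:
        json.dump(_jsonable(events.events), fh, indent=1)
    written["events_json"] = out / "events.json"

    if resource_checkpoints is not None:
        _write_csv(resource_checkpoints, out / "resources.csv")
        written["resources"] = out / "resources.csv"

    if final is not None:
        payload = {
            "t": final.t,
            "resources": list(map(float, final.resources.F)),
            "ecomorphs": [
                {"id": e.id, "lineage_id": e.lineage_id,
                 "parent_id": e.parent_id, "eta": e.eta, "ell": e.ell,
                 "J": e.J, "A": e.A}
                for e in final.ecomorphs
            ],
        }
        with open(out / "final_community.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        written["final_community"] = out / "final_community.json"

    if config is not None:
        save_config(config, out / "config_echo.yaml")
        written["config_echo"] = out / "config_echo.yaml"
        with open(out / "provenance.json", "w") as fh:
            json.dump(config.provenance, fh, indent=1, sort_keys=True)
        written["provenance"] = out / "provenance.json"

    manifest = {
        "files": sorted(p.name for p in written.values()),
        "columns": {k: v for k, v in _MANIFEST_COLUMNS.items()
                    if (out / k).exists()},
        "float_format": _FLOAT_FMT,
        "note": "deterministic engine: re-running from config_echo.yaml "
                "reproduces these tables byte-identically",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    written["manifest"] = out / "manifest.json"
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
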