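"""HDF5 experiment bundles, CSV sidecars and YAML configuration.

On-disk layout (schema version 1)::

    /                      attrs: schema_version, provenance (JSON)
    /cells/<id>/traces     (n_sites, n_trials, n_samples) float32, pA
                           attrs: dt_ms, stim_onset_ms
    /cells/<id>/sites      per-site table (site_id, depth_row, ml_um, rel_um)
    /cells/<id>            attrs: cell_type, soma_position_um, band,
                           archetype_id, grid geometry fields
    /cells/<id>/truth      optional ground-truth arrays (counts, burst_size)
                           attrs: q_u_pC
    /derived/<name>        derived product tables (columns as datasets)

Trace round trips are lossless at the stored precision; derived tables are
exact to serialisation.  Ground truth can also be written as a CSV sidecar
for quick inspection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .geometry import GridGeometry
from .synth import CellRecording, GroundTruthMap

SCHEMA_VERSION = "1"

_GEOM_ATTRS = ("half_extent_um", "step_um", "n_depth_rows", "midline_offset_um")


@dataclass
class ExperimentBundle:
    """Cells, traces, derived products and provenance of one experiment."""

    cells: dict = field(default_factory=dict)  # cell_id -> CellRecording
    derived: dict = field(default_factory=dict)  # name -> DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _write_frame(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    g.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype(h5py.string_dtype(encoding="utf-8"))
        g.create_dataset(col, data=data)


def _read_frame(g: h5py.Group) -> pd.DataFrame:
    cols = json.loads(g.attrs["columns"])
    out = {}
    for col in cols:
        data = g[col][...]
        if data.dtype.kind in ("S", "O"):
            data = np.array([v.decode() if isinstance(v, bytes) else v for v in data])
        out[col] = data
    return pd.DataFrame(out)


def write_bundle(bundle: ExperimentBundle, path: str | Path) -> Path:
    """Write an experiment bundle to HDF5; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(bundle.provenance, sort_keys=True)
        cells = f.create_group("cells")
        for cid, rec in bundle.cells.items():
            g = cells.create_group(cid)
            d = g.create_dataset(
                "traces", data=np.asarray(rec.samples, dtype=np.float64)
            )
            d.attrs["dt_ms"] = rec.dt_ms
            d.attrs["stim_onset_ms"] = rec.stim_onset_ms
            _write_frame(g, "sites", rec.sites)
            g.attrs["cell_type"] = rec.cell_type
            if rec.soma_position_um is not None:
                g.attrs["soma_position_um"] = rec.soma_position_um
            if rec.band is not None:
                g.attrs["band"] = rec.band
            if rec.archetype_id is not None:
                g.attrs["archetype_id"] = rec.archetype_id
            if rec.geometry is not None:
                for a in _GEOM_ATTRS:
                    g.attrs[f"geometry_{a}"] = getattr(rec.geometry, a)
            if rec.truth is not None:
                t = g.create_group("truth")
                t.create_dataset("counts", data=rec.truth.counts)
                t.create_dataset("burst_size", data=rec.truth.burst_size)
                t.attrs["q_u_pC"] = rec.truth.q_u_pC
        derived = f.create_group("derived")
        for name, df in bundle.derived.items():
            _write_frame(derived, name, df)
    return path


def read_bundle(path: str | Path) -> ExperimentBundle:
    """Read an experiment bundle from HDF5, validating the schema."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unknown schema version: found {version!r}, expected "
                f"{SCHEMA_VERSION!r}"
            )
        bundle = ExperimentBundle(
            provenance=json.loads(f.attrs.get("provenance", "{}"))
        )
        for cid, g in f.get("cells", {}).items():
            traces = g["traces"]
            for attr in ("dt_ms", "stim_onset_ms"):
                if attr not in traces.attrs:
                    raise SchemaError(
                        f"cell {cid!r}: required attribute {attr!r} missing "
                        "on the traces dataset"
                    )
            geometry = None
            if f"geometry_{_GEOM_ATTRS[0]}" in g.attrs:
                geometry = GridGeometry(
                    half_extent_um=float(g.attrs["geometry_half_extent_um"]),
                    step_um=float(g.attrs["geometry_step_um"]),
                    n_depth_rows=int(g.attrs["geometry_n_depth_rows"]),
                    midline_offset_um=float(g.attrs["geometry_midline_offset_um"]),
                )
            truth = None
            if "truth" in g:
                truth = GroundTruthMap(
                    counts=g["truth/counts"][...],
                    burst_size=g["truth/burst_size"][...],
                    q_u_pC=float(g["truth"].attrs["q_u_pC"]),
                )
            bundle.cells[cid] = CellRecording(
                cell_id=cid,
                samples=traces[...],
                dt_ms=float(traces.attrs["dt_ms"]),
                stim_onset_ms=float(traces.attrs["stim_onset_ms"]),
                sites=_read_frame(g["sites"]),
                geometry=geometry,
                truth=truth,
                cell_type=str(g.attrs.get("cell_type", "PC")),
                band=str(g.attrs["band"]) if "band" in g.attrs else None,
                soma_position_um=(
                    float(g.attrs["soma_position_um"])
                    if "soma_position_um" in g.attrs
                    else None
                ),
                archetype_id=(
                    int(g.attrs["archetype_id"]) if "archetype_id" in g.attrs else None
                ),
            )
        for name, g in f.get("derived", {}).items():
            bundle.derived[name] = _read_frame(g)
    return bundle


def write_ground_truth_csv(bundle: ExperimentBundle, path: str | Path) -> Path:
    """CSV sidecar of per-site ground truth for all cells that carry one."""
    rows = []
    for cid, rec in bundle.cells.items():
        if rec.truth is None:
            continue
        df = rec.truth.to_frame(rec.sites)
        df.insert(0, "cell_id", cid)
        df["archetype_id"] = rec.archetype_id
        rows.append(df)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    out.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "geometry": {
        "half_extent_um": 332.0,
        "step_um": 41.5,
        "n_depth_rows": 2,
    },
    "noise": {
        "current_sd_pA": 10.0,
        "duration_ms": 1000.0,
        "sampling_khz": 10.0,
        "stim_onset_ms": 200.0,
    },
    "population": {
        "n_cells": 49,
        "n_repeats": 2,
        "kind": "archetypes",  # or "independent"
    },
    "analysis": {
        "threshold": 3.09,
        "kernel_halfwidth_um": 18.0,
        "group_window_um": 100.0,
        "group_shift_um": 10.0,
        "correlation_step_um": 10.0,
        "n_clusters": 4,  # or "auto"
    },
    "plasticity": {
        "threshold": 3.09,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults; None gives the defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return _deep_merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
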