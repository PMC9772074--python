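"""Readers and writers for every on-disk artifact.

Plain-text formats throughout: TSV for matrices and labels, whitespace
columns for motion parameters, CSV for tidy result tables, GraphML/JSON for
shape graphs, YAML/JSON for configuration and manifests.  Frame indexing is
0-based everywhere.  Readers validate and reject rather than coerce; writers
are deterministic (stable column and key ordering).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .mapper import MapperGraph, MapperNode
from .preprocess import NETWORKS, CensorMask, ParcelTimeSeries
from .synthetic import ANXIETY_LEVELS, LOAD_LEVELS, TaskDesign

_PHASES = ("instruction", "letters", "fixation")


# ---------------------------------------------------------------- time series

def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=list(ts.parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    run_boundaries: Sequence[int],
    parcel_to_network: Mapping[str, str],
) -> ParcelTimeSeries:
    """TSV with a parcel-id header row and one row per frame."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric cell at row {int(bad.idxmax())}, column {col!r}"
                )
        raise ValueError(f"{path}: non-numeric data")
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"{path}: NaN at row {int(r)}, column {df.columns[int(c)]!r}")
    unmapped = [p for p in df.columns if p not in parcel_to_network]
    if unmapped:
        raise ValueError(
            f"{path}: {len(df.columns)}-column file does not match the "
            f"{len(parcel_to_network)}-entry parcel map (e.g. {unmapped[:3]})"
        )
    return ParcelTimeSeries(
        data=arr.astype(float),
        tr_seconds=tr_seconds,
        run_boundaries=list(run_boundaries),
        parcel_ids=list(df.columns),
        parcel_to_network=dict(parcel_to_network),
    )


# --------------------------------------------------------------------- labels

def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["frame", "run", "block", "load", "anxiety", "phase"]
    labels[cols].to_csv(path, sep="\t", index=False)
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    """Frame label TSV: frame, run, block, load, anxiety, phase."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"load": str, "anxiety": str, "phase": str})
    required = ["frame", "run", "block", "load", "anxiety", "phase"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col, allowed in [
        ("load", set(LOAD_LEVELS) | {"none"}),
        ("anxiety", set(ANXIETY_LEVELS) | {"none"}),
        ("phase", set(_PHASES)),
    ]:
        bad = sorted(set(df[col]) - allowed)
        if bad:
            raise ValueError(f"{path}: unknown {col} level(s) {bad}")
    for run, chunk in df.groupby("run"):
        frames = chunk["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames.min(), frames.min() + len(frames))):
            raise ValueError(f"{path}: frame indices of run {run} are not contiguous")
    return df


# --------------------------------------------------------------- motion / fd

def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.10g")
    return path


def read_motion(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(Path(path))
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 whitespace-delimited columns")
    return arr


def write_mask(mask: CensorMask, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, mask.flags.astype(int), fmt="%d")
    return path


def read_mask(path: str | Path, threshold_mm: float = 0.2,
              back: int = 1, forward: int = 2) -> CensorMask:
    flags = np.loadtxt(Path(path)).astype(int)
    if not np.isin(flags, [0, 1]).all():
        raise ValueError(f"{path}: mask entries must be 0 or 1")
    return CensorMask(flags=flags.astype(bool), threshold_mm=threshold_mm,
                      back=back, forward=forward)


# ----------------------------------------------------------------- parcel map

def write_parcel_map(parcel_map: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"parcel": list(parcel_map.keys()), "network": list(parcel_map.values())}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_parcel_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(Path(path), sep="\t")
    if list(df.columns) != ["parcel", "network"]:
        raise ValueError(f"{path}: expected columns ['parcel', 'network']")
    bad = sorted(set(df["network"]) - set(NETWORKS))
    if bad:
        raise ValueError(f"{path}: unknown network label(s) {bad}")
    return dict(zip(df["parcel"], df["network"]))


# ------------------------------------------------------------------ embedding

def write_embedding(coords: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(coords, columns=[f"dim{i}" for i in range(coords.shape[1])])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# --------------------------------------------------------------------- design

def write_design(design: TaskDesign, path: str | Path) -> Path:
    """Design summary (runs, TR, trials, shocks) as JSON."""
    path = Path(path)
    payload = {
        "n_runs": design.n_runs,
        "volumes_per_run": design.volumes_per_run,
        "tr_seconds": design.tr_seconds,
        "shock_events": [[int(r), int(f)] for r, f in design.shock_events],
        "trials": design.trials.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


# --------------------------------------------------------------------- graphs

def write_graph(graph: MapperGraph, path: str | Path, format: str = "graphml") -> Path:
    """Lossless shape-graph export (nodes with member lists, edges, provenance)."""
    path = Path(path)
    if format == "graphml":
        g = graph.to_networkx()
        # GraphML attributes must be scalars
        for key, val in list(g.graph.items()):
            if isinstance(val, (list, tuple)):
                g.graph[key] = ",".join(str(v) for v in val)
        nx.write_graphml(g, path)
    elif format == "json":
        payload = {
            "provenance": dict(graph.provenance),
            "nodes": [
                {
                    "id": node.node_id,
                    "members": [int(m) for m in node.members],
                    "bin": list(node.bin_index),
                }
                for node in graph.nodes
            ],
            "edges": [[int(u), int(v)] for u, v in graph.edges],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return path


def read_graph(path: str | Path, format: str = "graphml") -> MapperGraph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = []
        for nid, attrs in sorted(g.nodes(data=True), key=lambda kv: int(kv[0])):
            members = np.array([int(m) for m in str(attrs["members"]).split(",")])
            bin_index = tuple(int(b) for b in str(attrs["bin"]).split(","))
            nodes.append(MapperNode(int(nid), members, bin_index))
        edges = sorted((min(int(u), int(v)), max(int(u), int(v))) for u, v in g.edges())
        prov = dict(g.graph)
        return MapperGraph(nodes=nodes, edges=edges, provenance=prov)
    if format == "json":
        payload = json.loads(path.read_text())
        nodes = [
            MapperNode(int(n["id"]), np.array(n["members"], dtype=int), tuple(n["bin"]))
            for n in payload["nodes"]
        ]
        edges = sorted((min(u, v), max(u, v)) for u, v in payload["edges"])
        return MapperGraph(nodes=nodes, edges=edges, provenance=payload["provenance"])
    raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------- config etc.

def read_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def write_config(cfg: Mapping, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(dict(cfg), sort_keys=True))
    else:
        path.write_text(json.dumps(dict(cfg), indent=1, sort_keys=True))
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(files: Mapping[str, str | Path], path: str | Path,
                   parameters: Mapping | None = None,
                   version: str | None = None) -> Path:
    """Manifest of artifact paths with checksums and creation parameters."""
    from . import __version__

    path = Path(path)
    entries = {}
    for kind, fp in sorted(files.items()):
        fp = Path(fp)
        if not fp.exists():
            raise FileNotFoundError(f"manifest entry {kind!r}: {fp} does not exist")
        entries[kind] = {"path": str(fp), "sha256": _sha256(fp)}
    payload = {
        "files": entries,
        "parameters": dict(parameters or {}),
        "version": version or __version__,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def validate_manifest(path: str | Path) -> dict:
    """Re-read a manifest, checking existence and checksums of every entry."""
    path = Path(path)
    payload = json.loads(path.read_text())
    for kind, entry in payload["files"].items():
        fp = Path(entry["path"])
        if not fp.exists():
            raise FileNotFoundError(f"manifest entry {kind!r}: {fp} missing")
        if _sha256(fp) != entry["sha256"]:
            raise ValueError(f"manifest entry {kind!r}: checksum mismatch for {fp}")
    return payload
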