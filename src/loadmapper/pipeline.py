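"""Per-subject orchestration: cleaning -> contrast parameters -> shape graph
-> annotation -> participation-coefficient summaries, with file IO,
provenance and logging around the library calls."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as lio
from .annotate import annotate_and_score, check_community_balance
from .mapper import run_mapper
from .params import block_signal_strength, subject_params_table
from .preprocess import (
    CleanSeries,
    aggregate_networks,
    build_censor_mask,
    clean_timeseries,
    compute_fd_runs,
)
from .synthetic import Subject

log = logging.getLogger("loadmapper")


@dataclass
class PreprocessConfig:
    fd_threshold: float = 0.2
    back: int = 1
    forward: int = 2
    band: tuple[float, float] = (0.009, 0.08)


@dataclass
class MapperConfig:
    k: int | None = None
    resolution: int = 18
    gain: float = 0.70
    dim: int = 2
    metric: str = "euclidean"


@dataclass
class AnnotationConfig:
    axes: tuple[str, ...] = ("load", "anxiety")
    include_phases: tuple[str, ...] = ("letters",)
    aggregate: str = "mean"


@dataclass
class ParamsConfig:
    lag: int = 2
    estimator: str = "mean"
    epsilon: float = 0.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    params: ParamsConfig = field(default_factory=ParamsConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "PipelineConfig":
        def build(klass, section):
            data = dict(cfg.get(section, {}))
            if klass is PreprocessConfig and "band" in data:
                data["band"] = tuple(data["band"])
            for key in ("axes", "include_phases"):
                if klass is AnnotationConfig and key in data:
                    data[key] = tuple(data[key])
            return klass(**data)

        return cls(
            preprocess=build(PreprocessConfig, "preprocess"),
            mapper=build(MapperConfig, "mapper"),
            annotation=build(AnnotationConfig, "annotation"),
            params=build(ParamsConfig, "params"),
            seed=int(cfg.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(lio.read_config(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def clean_subject(subject: Subject, cfg: PipelineConfig) -> CleanSeries:
    """Cleaning chain on an in-memory subject (FD -> mask -> clean)."""
    pp = cfg.preprocess
    fd = compute_fd_runs(subject.motion)
    mask = build_censor_mask(fd, subject.timeseries.run_boundaries,
                             threshold=pp.fd_threshold, back=pp.back, forward=pp.forward)
    return clean_timeseries(subject.timeseries, subject.motion, mask,
                            band=pp.band, labels=subject.design.frame_labels)


def subject_alpha_beta(subject: Subject, cfg: PipelineConfig,
                       clean: CleanSeries | None = None) -> pd.DataFrame:
    """Tidy per-network alpha/beta table for one subject."""
    if clean is None:
        clean = clean_subject(subject, cfg)
    nets = aggregate_networks(clean)
    ss = block_signal_strength(nets, clean, lag=cfg.params.lag,
                               estimator=cfg.params.estimator)
    return subject_params_table(subject.record.subject_id, subject.record.group,
                                ss, epsilon=cfg.params.epsilon)


def process_subject(subject: Subject, cfg: PipelineConfig,
                    run_balance_check: bool = False) -> dict:
    """Full in-memory pipeline for one subject.

    Returns a dict with the cleaned series, the alpha/beta table, the Mapper
    graph, and per-axis annotation results (mean PC etc.).
    """
    clean = clean_subject(subject, cfg)
    ab = subject_alpha_beta(subject, cfg, clean=clean)
    m = cfg.mapper
    graph = run_mapper(clean, k=m.k, r=m.resolution, g=m.gain, d=m.dim, metric=m.metric)
    annotations = {}
    balance = {}
    for axis in cfg.annotation.axes:
        res = annotate_and_score(graph, clean.retained_labels, axis=axis,
                                 include_phases=cfg.annotation.include_phases,
                                 aggregate=cfg.annotation.aggregate)
        annotations[axis] = res
        if run_balance_check:
            balance[axis] = check_community_balance(graph, res.communities,
                                                    seed=cfg.seed)
    return {
        "clean": clean,
        "alpha_beta": ab,
        "graph": graph,
        "annotations": annotations,
        "balance": balance,
    }


def pc_summary_table(subjects_results: Mapping[str, dict]) -> pd.DataFrame:
    """Per-subject, per-axis mean-PC summary across processed subjects."""
    rows = []
    for sid, res in subjects_results.items():
        for axis, ann in res["annotations"].items():
            rows.append({
                "subject": sid,
                "group": res["group"],
                "axis": axis,
                "mean_pc": ann.mean_pc,
                "n_nodes": len(ann.node_table),
                "n_included": ann.n_included,
                "n_isolated": len(ann.isolated_nodes),
                "n_excluded": len(ann.excluded_nodes),
            })
    return pd.DataFrame(rows)


def run_subject_pipeline(
    ts_path: str | Path,
    labels_path: str | Path,
    motion_paths: list[str | Path],
    parcel_map_path: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig,
    tr_seconds: float = 2.0,
    subject_id: str = "sub-001",
    group: str = "NA",
) -> dict:
    """File-based pipeline for one subject; every artifact is written with a
    provenance manifest.  Raises with an explicit path on missing inputs."""
    for p in [ts_path, labels_path, parcel_map_path, *motion_paths]:
        if not Path(p).exists():
            raise FileNotFoundError(f"required input file not found: {p}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    parcel_map = lio.read_parcel_map(parcel_map_path)
    labels = lio.read_labels(labels_path)
    motion = [lio.read_motion(p) for p in motion_paths]
    n_per_run = [m.shape[0] for m in motion]
    boundaries = np.concatenate([[0], np.cumsum(n_per_run)]).tolist()
    ts = lio.read_timeseries(ts_path, tr_seconds, boundaries, parcel_map)

    log.info("subject %s: %d frames, %d parcels, %d runs",
             subject_id, ts.n_frames, ts.n_parcels, ts.n_runs)
    pp = cfg.preprocess
    fd = compute_fd_runs(motion)
    mask = build_censor_mask(fd, boundaries, threshold=pp.fd_threshold,
                             back=pp.back, forward=pp.forward)
    log.info("subject %s: %d/%d frames censored (FD > %.3g mm)",
             subject_id, mask.n_censored, ts.n_frames, pp.fd_threshold)
    clean = clean_timeseries(ts, motion, mask, band=pp.band, labels=labels)

    nets = aggregate_networks(clean)
    ss = block_signal_strength(nets, clean, lag=cfg.params.lag,
                               estimator=cfg.params.estimator)
    ab = subject_params_table(subject_id, group, ss, epsilon=cfg.params.epsilon)

    m = cfg.mapper
    graph = run_mapper(clean, k=m.k, r=m.resolution, g=m.gain, d=m.dim, metric=m.metric)

    files = {}
    files["mask"] = lio.write_mask(mask, out / "censor_mask.txt")
    files["alpha_beta"] = out / "alpha_beta.csv"
    ab.to_csv(files["alpha_beta"], index=False)
    files["graph_graphml"] = lio.write_graph(graph, out / "graph.graphml", "graphml")
    files["graph_json"] = lio.write_graph(graph, out / "graph.json", "json")

    summaries = []
    for axis in cfg.annotation.axes:
        res = annotate_and_score(graph, clean.retained_labels, axis=axis,
                                 include_phases=cfg.annotation.include_phases,
                                 aggregate=cfg.annotation.aggregate)
        node_path = out / f"nodes_{axis}.csv"
        res.node_table.to_csv(node_path, index=False)
        files[f"nodes_{axis}"] = node_path
        summaries.append({"subject": subject_id, "group": group, "axis": axis,
                          "mean_pc": res.mean_pc, "n_nodes": len(res.node_table),
                          "n_isolated": len(res.isolated_nodes)})
        log.info("subject %s: axis=%s mean PC=%.4f over %d nodes",
                 subject_id, axis, res.mean_pc, len(res.node_table))
    files["pc_summary"] = out / "pc_summary.csv"
    pd.DataFrame(summaries).to_csv(files["pc_summary"], index=False)

    provenance = {
        "subject": subject_id,
        "group": group,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    files["provenance"] = out / "provenance.json"
    lio.write_manifest(files, out / "manifest.json", parameters=cfg.to_dict())
    return {"alpha_beta": ab, "graph": graph, "pc_summary": pd.DataFrame(summaries),
            "mask": mask, "out_dir": out}
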