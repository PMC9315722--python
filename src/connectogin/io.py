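"""Readers and writers for the delimited-text interchange formats.

All on-disk formats are plain text for inspectability:

* time series — CSV per subject, header row of 1-based ROI ids, one row per
  timepoint;
* FC matrices — headerless N x N CSV plus a sidecar manifest CSV
  (``subject_id,file,label[,group]``);
* parcellation — CSV with columns ``roi_id,roi_name,network,x,y,z``;
* run configuration — YAML, strictly validated (unknown keys rejected) and
  echoed back fully resolved next to every run's outputs.

ROI ids are 1-based in every file; arrays are 0-based in memory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import BrainGraph, FCMatrix, Parcellation, RoiTimeSeries
from .nn import ModelConfig
from .simulate import SimConfig
from .training import TrainConfig

logger = logging.getLogger("connectogin")

SCHEMA_VERSION = "1"


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    file: str
    label: int
    group: str | None = None


def read_manifest(path, require_files: bool = True) -> list[SubjectRecord]:
    """Validated subject manifest; duplicate ids and bad labels are errors."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "file", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[SubjectRecord] = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.subject_id)
        if sid in seen:
            raise ValueError(
                f"{path}: duplicate subject_id {sid!r} at row {row_no} "
                f"(first seen at row {seen[sid]})")
        seen[sid] = row_no
        try:
            label = int(row.label)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {row_no}: unparseable label {row.label!r}") from None
        if label not in (0, 1):
            raise ValueError(
                f"{path}: row {row_no}: label must be 0 or 1, got {label}")
        fpath = path.parent / str(row.file)
        if require_files and not fpath.exists():
            raise ValueError(f"{path}: row {row_no}: file not found: {fpath}")
        group = getattr(row, "group", None)
        records.append(SubjectRecord(
            subject_id=sid, file=str(row.file), label=label,
            group=None if group is None or pd.isna(group) else str(group)))
    return records


def write_manifest(records: list[SubjectRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, index=False)


def read_timeseries(path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    try:
        roi_ids = [int(c) for c in df.columns]
    except ValueError:
        raise ValueError(
            f"{path}: header must be 1-based integer ROI ids, got "
            f"{list(df.columns)[:5]}") from None
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        t, r = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"{path}: NaN at timepoint {t + 1}, ROI {roi_ids[r]}")
    ts = RoiTimeSeries(subject_id=subject_id or path.stem, values=values,
                       roi_ids=roi_ids)
    ts.validate()
    return ts


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=[str(r) for r in ts.roi_ids]).to_csv(
        path, index=False)


def read_fc_matrix(path, subject_id: str | None = None,
                   n_rois: int | None = None) -> FCMatrix:
    """Headerless N x N CSV; symmetry enforced to 1e-8 then symmetrized."""
    path = Path(path)
    z = np.loadtxt(path, delimiter=",", ndmin=2)
    if z.shape[0] != z.shape[1]:
        raise ValueError(f"{path}: matrix is {z.shape[0]} x {z.shape[1]}, not square")
    if n_rois is not None and z.shape[0] != n_rois:
        raise ValueError(
            f"{path}: matrix has {z.shape[0]} ROIs, parcellation has {n_rois}")
    nan = np.argwhere(np.isnan(z))
    if nan.size:
        i, j = map(int, nan[0])
        raise ValueError(f"{path}: NaN at entry ({i + 1}, {j + 1})")
    asym = float(np.abs(z - z.T).max())
    if asym > 1e-8:
        raise ValueError(f"{path}: asymmetry {asym:.2e} exceeds 1e-8")
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    fc = FCMatrix(subject_id=subject_id or path.stem, z=z)
    fc.validate()
    return fc


def write_fc_matrix(fc: FCMatrix, path) -> None:
    np.savetxt(path, fc.z, delimiter=",", fmt="%.17g")


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path)
    required = ["roi_id", "roi_name", "network", "x", "y", "z"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return Parcellation(
        roi_ids=df["roi_id"].to_numpy(dtype=int),
        roi_names=df["roi_name"].astype(str).tolist(),
        networks=df["network"].astype(str).tolist(),
        coordinates=df[["x", "y", "z"]].to_numpy(dtype=float))


def write_parcellation(parc: Parcellation, path) -> None:
    pd.DataFrame({
        "roi_id": parc.roi_ids,
        "roi_name": parc.roi_names,
        "network": parc.networks,
        "x": parc.coordinates[:, 0],
        "y": parc.coordinates[:, 1],
        "z": parc.coordinates[:, 2],
    }).to_csv(path, index=False)


def write_graph(graph: BrainGraph, path) -> None:
    """Edge list CSV with 1-based node ids: columns i, j, weight."""
    pd.DataFrame({
        "i": graph.edges[:, 0] + 1,
        "j": graph.edges[:, 1] + 1,
        "weight": graph.edge_weights,
    }).to_csv(path, index=False)


def read_graph(path, label: int, n_nodes: int,
               subject_id: str | None = None) -> BrainGraph:
    df = pd.read_csv(Path(path))
    missing = {"i", "j", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return BrainGraph(
        subject_id=subject_id or Path(path).stem.removesuffix(".edges"),
        label=label,
        edges=np.column_stack([df["i"].to_numpy(int) - 1,
                               df["j"].to_numpy(int) - 1]),
        edge_weights=df["weight"].to_numpy(float),
        n_nodes=n_nodes)


def write_graph_dir(graphs: list[BrainGraph], out_dir) -> None:
    """One edge-list CSV per subject plus a graphs manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in graphs:
        fname = f"{g.subject_id}.edges.csv"
        write_graph(g, out_dir / fname)
        rows.append({"subject_id": g.subject_id, "file": fname,
                     "label": g.label, "n_nodes": g.n_nodes})
    pd.DataFrame(rows).to_csv(out_dir / "graphs_manifest.csv", index=False)


def read_graph_dir(graph_dir) -> list[BrainGraph]:
    graph_dir = Path(graph_dir)
    manifest = graph_dir / "graphs_manifest.csv"
    if not manifest.exists():
        raise ValueError(f"{graph_dir}: graphs_manifest.csv not found")
    df = pd.read_csv(manifest)
    return [read_graph(graph_dir / row.file, label=int(row.label),
                       n_nodes=int(row.n_nodes), subject_id=str(row.subject_id))
            for row in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# run configuration

_SECTIONS = {"sim": SimConfig, "model": ModelConfig, "train": TrainConfig}


@dataclasses.dataclass
class RunConfig:
    """Merged simulation / graph / model / training configuration."""

    sim: SimConfig
    model: ModelConfig
    train: TrainConfig
    density_m: float = 25.0
    edge_case: str = "abs"
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "density_m": self.density_m,
            "edge_case": self.edge_case,
            "sim": dataclasses.asdict(self.sim),
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
        }


def load_run_config(path) -> RunConfig:
    """Strict YAML loader: any key not named by a config dataclass is an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = set(_SECTIONS) | {"density_m", "edge_case", "schema_version"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        body = raw.get(section, {}) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(body) - fields
        if bad:
            raise ValueError(f"{path}: unknown key(s) in '{section}': {sorted(bad)}")
        if section == "sim" and "planted_rois" in body:
            body["planted_rois"] = tuple(body["planted_rois"])
        if section == "model" and "input_dim" not in body:
            body["input_dim"] = int(raw.get("sim", {}).get("n_rois",
                                                           SimConfig.n_rois))
        kwargs[section] = cls(**body)
    return RunConfig(
        density_m=float(raw.get("density_m", 25.0)),
        edge_case=str(raw.get("edge_case", "abs")),
        schema_version=str(raw.get("schema_version", SCHEMA_VERSION)),
        **kwargs)


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
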