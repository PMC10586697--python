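"""File formats, run configuration and batch processing.

All interchange is plain text: feature tables, links, tracks, lineages and
model series are CSV (UTF-8, '.' decimal separator, 0-based integer frames);
feature specs and run configurations are YAML.  Unknown configuration keys
are errors so that a saved configuration re-applied to another dataset
reproduces the original settings exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureSpec, FeatureTable
from .model import DisplacementModel
from .simulate import GroundTruthDataset, GrowDivideConfig, SimConfig
from .tracker import LINK_COLUMNS, LinkSet, TrackerConfig, TrackSet

log = logging.getLogger("featrack")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_tables(tables, spec: FeatureSpec, path) -> None:
    rows = []
    for t in sorted(tables, key=lambda t: t.frame):
        df = pd.DataFrame(t.X, columns=list(spec.names))
        df.insert(0, "object_id", t.ids)
        df.insert(0, "frame", t.frame)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_feature_tables(path, spec: FeatureSpec) -> list:
    """Read a features CSV into per-frame tables, validating against the spec."""
    df = pd.read_csv(path)
    required = ["frame", "object_id", *spec.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {missing}")
    for c in required:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any() or df[c].isna().any():
            line = int((bad | df[c].isna()).idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {c!r} at line {line}")
    if df.duplicated(["frame", "object_id"]).any():
        dup = df[df.duplicated(["frame", "object_id"])].iloc[0]
        raise ValueError(f"{path}: duplicate (frame, object_id) = "
                         f"({int(dup['frame'])}, {int(dup['object_id'])})")
    tables = []
    for frame, g in df.groupby("frame", sort=True):
        tables.append(FeatureTable(int(frame), g["object_id"].to_numpy(np.int64),
                                   g[list(spec.names)].to_numpy(float)))
    return tables


def write_spec(spec: FeatureSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_spec(path) -> FeatureSpec:
    return FeatureSpec.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# links, tracks, lineage, model series
# ---------------------------------------------------------------------------

def write_links(links: LinkSet, path) -> None:
    links.df[LINK_COLUMNS].to_csv(path, index=False)


def read_links(path) -> LinkSet:
    return LinkSet(pd.read_csv(path))


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.df.to_csv(path, index=False)


def read_tracks(path, spec: FeatureSpec) -> TrackSet:
    df = pd.read_csv(path)
    missing = [c for c in ("track_id", "frame", "object_id", "interpolated",
                           *spec.names) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track column(s) {missing}")
    return TrackSet(df, spec.names)


def write_lineage(lineage, path) -> None:
    df = lineage.df if hasattr(lineage, "df") else lineage
    df.to_csv(path, index=False)


def read_lineage(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_model_series(models, spec: FeatureSpec, path) -> None:
    """Per-frame model statistics with flattened mean/covariance columns."""
    rows = []
    for m in sorted(models, key=lambda m: m.frame_pair[0]):
        row = {
            "frame": m.frame_pair[0], "r_bits": m.r, "beta": m.beta,
            "n_objects": m.n_o, "n_train": m.n_train,
            "det_sigma_x": float(np.linalg.det(m.sigma_x)),
            "det_sigma_delta": float(np.linalg.det(m.sigma_delta)),
        }
        names = spec.names[:m.n_features] if len(spec.names) >= m.n_features else \
            [f"f{i}" for i in range(m.n_features)]
        for i, n in enumerate(names):
            row[f"mu_{n}"] = m.mu[i]
        for i, ni in enumerate(names):
            for j, nj in enumerate(names):
                row[f"sdelta_{ni}_{nj}"] = m.sigma_delta[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(dataset: GroundTruthDataset, outdir, extra_meta=None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_tables(dataset.frames, dataset.spec, out / "features.csv")
    write_spec(dataset.spec, out / "spec.yaml")
    write_links(dataset.gt_links, out / "gt_links.csv")
    if dataset.gt_lineage is not None:
        write_lineage(dataset.gt_lineage, out / "gt_lineage.csv")
    meta = {"config": dataclasses.asdict(dataset.config),
            "config_class": type(dataset.config).__name__}
    if extra_meta:
        meta.update(extra_meta)
    (out / "meta.json").write_text(json.dumps(meta, indent=2, default=float))


def read_dataset(path) -> GroundTruthDataset:
    p = Path(path)
    spec = read_spec(p / "spec.yaml")
    frames = read_feature_tables(p / "features.csv", spec)
    gt = read_links(p / "gt_links.csv") if (p / "gt_links.csv").exists() else LinkSet.empty()
    lineage = read_lineage(p / "gt_lineage.csv") if (p / "gt_lineage.csv").exists() else None
    meta = json.loads((p / "meta.json").read_text()) if (p / "meta.json").exists() else {}
    cfg_cls = {"SimConfig": SimConfig, "GrowDivideConfig": GrowDivideConfig}.get(
        meta.get("config_class"))
    config = cfg_cls(**meta["config"]) if cfg_cls else None
    return GroundTruthDataset(frames, gt, spec, config, gt_lineage=lineage)


# ---------------------------------------------------------------------------
# run configuration and batch processing
# ---------------------------------------------------------------------------

_TRACKER_KEYS = {f.name for f in dataclasses.fields(TrackerConfig)}


@dataclass
class RunConfig:
    """Complete, serializable description of a tracking run."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    seed: int = 0
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.tracker)
        d["features_used"] = None if d["features_used"] is None else list(d["features_used"])
        return {"tracker": d, "seed": self.seed, "version": self.version}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {"tracker", "seed", "version"}
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        t = dict(d.get("tracker", {}))
        bad = set(t) - _TRACKER_KEYS
        if bad:
            raise ValueError(f"unknown tracker keys: {sorted(bad)}")
        if t.get("features_used") is not None:
            t["features_used"] = tuple(t["features_used"])
        return cls(tracker=TrackerConfig(**t), seed=int(d.get("seed", 0)),
                   version=str(d.get("version", "0.1.0")))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True)
                              .encode()).hexdigest()[:12]


def run_tracking(dataset_dir, config: RunConfig, outdir) -> dict:
    """Track one dataset directory and write links/tracks/report CSVs."""
    from .tracker import track_dataset

    t0 = time.perf_counter()
    dataset = read_dataset(dataset_dir)
    tracks, links, report = track_dataset(dataset.frames, dataset.spec, config.tracker)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_links(links, out / "links.csv")
    write_tracks(tracks, out / "tracks.csv")
    report.to_frame().to_csv(out / "trackability.csv", index=False)
    summary = {
        "dataset": str(dataset_dir), "n_tracks": int(tracks.n_tracks),
        "n_links": int(len(links)),
        "mean_trackability": float(np.mean(report.r)),
        "runtime_s": time.perf_counter() - t0,
        "config_hash": config.hash(), "seed": config.seed, "status": "ok",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def batch_run(config: RunConfig, dataset_dirs, outdir) -> pd.DataFrame:
    """Process many datasets with identical settings.

    A dataset that fails does not abort the batch; the failure is recorded
    in the summary table.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in dataset_dirs:
        name = Path(d).name
        try:
            rows.append(run_tracking(d, config, out / name))
        except Exception as exc:  # noqa: BLE001 - batch must survive failures
            log.error("dataset %s failed: %s", d, exc)
            rows.append({"dataset": str(d), "status": f"failed: {exc}"})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "batch_summary.csv", index=False)
    return summary
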