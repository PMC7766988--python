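"""Workspace persistence (HDF5), configuration and plain-text signal I/O.

A workspace bundles everything one annotation session produces: the signal
tracks, fiducial series bound to tracks, partitions, the epoch grid and
metadata.  It is stored in a self-describing HDF5 layout:

    /meta                 attrs: schema_version, record_id, creator,
                          created_at, tool_version
    /tracks/<name>        dataset "values"; attrs fs, offset, units
    /annotations/<name>   datasets "t", "amplitude", "sublabel";
                          attrs track, min_distance
    /partitions           datasets "name", "start", "end"
    /epochs               dataset "labels" ("" = unset);
                          attrs epoch_length, label_set

Timestamps and amplitudes are float64, so save → load round-trips exactly.
The schema is versioned; loading a file written by a future major version
fails with a clear error.  Compatibility with any other tool's .h5 layout
is not claimed — this layout is this package's own contract.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import EpochGrid, FiducialSeries, Partition, PartitionSet, Track

__all__ = [
    "Workspace",
    "DatabaseConfig",
    "TrackSpec",
    "save_workspace",
    "load_workspace",
    "load_config",
    "read_signal_csv",
    "read_fiducial_csv",
    "write_fiducial_csv",
    "read_wfdb_record",
    "read_wfdb_annotations",
]

SCHEMA_VERSION = "1.0"
_STR = h5py.string_dtype(encoding="utf-8")


@dataclass
class Workspace:
    tracks: dict[str, Track] = field(default_factory=dict)
    fiducials: dict[str, FiducialSeries] = field(default_factory=dict)
    fiducial_tracks: dict[str, str] = field(default_factory=dict)  # series -> track
    partitions: PartitionSet = field(default_factory=PartitionSet)
    epochs: EpochGrid | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def add_track(self, track: Track) -> None:
        self.tracks[track.name] = track

    def add_fiducials(self, series: FiducialSeries, track: str) -> None:
        if track not in self.tracks:
            raise KeyError(f"fiducial series {series.name!r} references "
                           f"unknown track {track!r}")
        self.fiducials[series.name] = series
        self.fiducial_tracks[series.name] = track


class SchemaError(ValueError):
    """The file does not match the documented workspace layout."""


def save_workspace(ws: Workspace, path) -> None:
    """Write a workspace to ``path`` in the documented HDF5 layout."""
    for name, tr in ws.fiducial_tracks.items():
        if tr not in ws.tracks:
            raise ValueError(f"series {name!r} bound to missing track {tr!r}")
    try:
        f = h5py.File(path, "w")
    except OSError as e:
        raise OSError(f"cannot write workspace to {path}: {e}") from e
    with f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["created_at"] = ws.meta.get(
            "created_at", datetime.datetime.now().isoformat(timespec="seconds"))
        for key in ("record_id", "creator", "tool_version"):
            meta.attrs[key] = ws.meta.get(key, "")
        g = f.create_group("tracks")
        for name, tr in ws.tracks.items():
            tg = g.create_group(name)
            tg.create_dataset("values", data=tr.values)
            tg.attrs["fs"] = tr.fs
            tg.attrs["offset"] = tr.offset
            tg.attrs["units"] = tr.units
        g = f.create_group("annotations")
        for name, se in ws.fiducials.items():
            ag = g.create_group(name)
            t, a = se.as_arrays()
            ag.create_dataset("t", data=t)
            ag.create_dataset("amplitude", data=a)
            ag.create_dataset("sublabel", data=np.asarray(
                [s if s is not None else "" for s in se.sublabels], dtype=_STR))
            ag.attrs["track"] = ws.fiducial_tracks.get(name, "")
            ag.attrs["min_distance"] = se.min_distance
        g = f.create_group("partitions")
        parts = ws.partitions.partitions
        g.create_dataset("name", data=np.asarray([p.name for p in parts], dtype=_STR))
        g.create_dataset("start", data=np.asarray([p.start for p in parts]))
        g.create_dataset("end", data=np.asarray([p.end for p in parts]))
        if ws.epochs is not None:
            g = f.create_group("epochs")
            g.attrs["epoch_length"] = ws.epochs.epoch_length
            g.attrs["label_set"] = np.asarray(ws.epochs.label_set, dtype=_STR)
            g.create_dataset("labels", data=np.asarray(
                [x if x is not None else "" for x in ws.epochs.labels], dtype=_STR))


def _require(obj, key, path):
    if key not in obj:
        raise SchemaError(f"{path}: missing {key!r}")
    return obj[key]


def load_workspace(path) -> Workspace:
    """Inverse of :func:`save_workspace` (exact round trip)."""
    ws = Workspace()
    with h5py.File(path, "r") as f:
        meta = _require(f, "meta", path)
        version = str(meta.attrs.get("schema_version", ""))
        if not version:
            raise SchemaError(f"{path}: /meta missing schema_version")
        if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise SchemaError(
                f"{path}: schema version {version} not supported "
                f"(this reader handles major version {SCHEMA_VERSION.split('.')[0]})")
        for key in ("record_id", "creator", "created_at", "tool_version"):
            ws.meta[key] = str(meta.attrs.get(key, ""))
        for name, tg in _require(f, "tracks", path).items():
            vals = _require(tg, "values", f"/tracks/{name}")[()]
            for attr in ("fs", "offset", "units"):
                if attr not in tg.attrs:
                    raise SchemaError(f"/tracks/{name}: missing attr {attr!r}")
            ws.tracks[name] = Track(name, float(tg.attrs["fs"]), vals,
                                    float(tg.attrs["offset"]),
                                    str(tg.attrs["units"]))
        for name, ag in _require(f, "annotations", path).items():
            t = _require(ag, "t", f"/annotations/{name}")[()]
            a = _require(ag, "amplitude", f"/annotations/{name}")[()]
            subs = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in ag["sublabel"][()]]
            se = FiducialSeries(name, list(map(float, t)), list(map(float, a)),
                                [s or None for s in subs],
                                float(ag.attrs.get("min_distance", 0.0)))
            ws.fiducials[name] = se
            ws.fiducial_tracks[name] = str(ag.attrs.get("track", ""))
        pg = _require(f, "partitions", path)
        names = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in pg["name"][()]]
        for nm, s, e in zip(names, pg["start"][()], pg["end"][()]):
            ws.partitions.partitions.append(Partition(nm, float(s), float(e)))
        if "epochs" in f:
            g = f["epochs"]
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in g["labels"][()]]
            label_set = [s.decode() if isinstance(s, bytes) else str(s)
                         for s in g.attrs["label_set"]]
            ws.epochs = EpochGrid(float(g.attrs["epoch_length"]), label_set,
                                  len(labels), [x or None for x in labels])
    return ws


# --------------------------------------------------------------------------
# configuration

@dataclass
class TrackSpec:
    name: str
    column: str | int
    fs: float
    units: str = ""


@dataclass
class DatabaseConfig:
    """Declarative dataset description: where records live, which columns
    are signals, which detectors to run, and annotation/epoch settings."""

    source_dir: str
    output_dir: str = "."
    filename_template: str = "*.csv"
    tracks: list[TrackSpec] = field(default_factory=list)
    run_ecg: bool = False
    run_ppg: bool = False
    ecg_params: dict = field(default_factory=dict)
    ppg_params: dict = field(default_factory=dict)
    fiducial_names: list[str] = field(default_factory=lambda: ["R"])
    min_distance: float = 0.0
    pinning_mode: str = "nearest"
    epoch_length: float = 10.0
    epoch_labels: list[str] = field(default_factory=list)


_KNOWN_KEYS = {"source_dir", "output_dir", "filename_template", "tracks",
               "detectors", "annotation", "epochs"}


def load_config(path) -> DatabaseConfig:
    """Parse and validate a YAML dataset configuration.

    ``source_dir`` is the only field without a default and is mandatory;
    unknown top-level keys produce a warning, not an error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in set(raw) - _KNOWN_KEYS:
        warnings.warn(f"{path}: unknown config key {key!r} ignored")
    if "source_dir" not in raw:
        raise ValueError(f"{path}: 'source_dir' is mandatory (no default)")
    cfg = DatabaseConfig(source_dir=str(raw["source_dir"]))
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    cfg.filename_template = str(raw.get("filename_template", cfg.filename_template))
    for tr in raw.get("tracks", []):
        if "name" not in tr or "column" not in tr or "fs" not in tr:
            raise ValueError(f"{path}: each track needs name, column and fs")
        cfg.tracks.append(TrackSpec(str(tr["name"]), tr["column"],
                                    float(tr["fs"]), str(tr.get("units", ""))))
    det = raw.get("detectors", {}) or {}
    if "ecg" in det and det["ecg"] is not None:
        cfg.run_ecg = True
        cfg.ecg_params = dict(det["ecg"]) if isinstance(det["ecg"], dict) else {}
    if "ppg" in det and det["ppg"] is not None:
        cfg.run_ppg = True
        cfg.ppg_params = dict(det["ppg"]) if isinstance(det["ppg"], dict) else {}
    ann = raw.get("annotation", {}) or {}
    cfg.fiducial_names = list(ann.get("fiducial_names", cfg.fiducial_names))
    cfg.min_distance = float(ann.get("min_distance", cfg.min_distance))
    cfg.pinning_mode = str(ann.get("pinning_mode", cfg.pinning_mode))
    ep = raw.get("epochs", {}) or {}
    cfg.epoch_length = float(ep.get("length", cfg.epoch_length))
    cfg.epoch_labels = list(ep.get("label_set", cfg.epoch_labels))
    if ep and not cfg.epoch_labels:
        raise ValueError(f"{path}: epoch mode enabled but label_set is empty")
    return cfg


# --------------------------------------------------------------------------
# plain-text signal and fiducial I/O

def read_signal_csv(path, fs: float, column: str | int = 0,
                    name: str | None = None, units: str = "") -> Track:
    """Read one signal column from a CSV/TSV file with a declared rate."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(column, int):
        if column >= df.shape[1]:
            raise ValueError(f"{path}: column index {column} out of range "
                             f"({df.shape[1]} columns)")
        series = df.iloc[:, column]
    else:
        if column not in df.columns:
            raise ValueError(f"{path}: no column named {column!r} "
                             f"(have {list(df.columns)})")
        series = df[column]
    return Track(name or str(series.name), fs,
                 series.to_numpy(dtype=np.float64), units=units)


def read_fiducial_csv(path) -> dict[str, np.ndarray]:
    """Two-column fiducial CSV (fiducial, t_seconds) → name → timestamps."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    fcol = cols.get("fiducial", df.columns[0])
    tcol = cols.get("t_seconds", df.columns[1])
    return {str(k): np.sort(g[tcol].to_numpy(dtype=np.float64))
            for k, g in df.groupby(fcol)}


def write_fiducial_csv(path, series_map) -> None:
    rows = []
    for name, se in series_map.items():
        ts = se.timestamps if isinstance(se, FiducialSeries) else se
        rows.extend({"fiducial": name, "t_seconds": float(t)} for t in ts)
    pd.DataFrame(rows, columns=["fiducial", "t_seconds"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# optional standard waveform-database support (feature-flagged: requires the
# third-party `wfdb` package, which is not a hard dependency)

def _import_wfdb():
    try:
        import wfdb
    except ImportError as e:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading waveform-database records requires the optional 'wfdb' "
            "package (pip install wfdb)") from e
    return wfdb


def read_wfdb_record(record_path: str, channel: int = 0) -> Track:
    """Load one channel of a waveform-database record as a Track."""
    wfdb = _import_wfdb()
    rec = wfdb.rdrecord(str(record_path))
    sig = rec.p_signal[:, channel]
    name = rec.sig_name[channel] if rec.sig_name else Path(record_path).stem
    units = rec.units[channel] if rec.units else ""
    return Track(name, float(rec.fs), sig, units=units)


def read_wfdb_annotations(record_path: str, extension: str = "atr",
                          symbols: set[str] | None = None) -> np.ndarray:
    """Annotation timestamps (s), optionally filtered by symbol set.

    Pass e.g. ``symbols={"N", "V", "A", ...}`` to keep only beat labels;
    by default all annotations are returned and no exclusion is claimed.
    """
    wfdb = _import_wfdb()
    ann = wfdb.rdann(str(record_path), extension)
    t = np.asarray(ann.sample, dtype=np.float64) / ann.fs
    if symbols is not None:
        keep = np.asarray([s in symbols for s in ann.symbol])
        t = t[keep]
    return t
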