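"""HDF5 workspace persistence, configuration and text I/O."""

import importlib.util
import math

import h5py
import numpy as np
import pytest

from beatkit.model import EpochGrid, FiducialSeries, Track
from beatkit.workspace import (DatabaseConfig, SchemaError, Workspace,
                               load_config, load_workspace, read_fiducial_csv,
                               read_signal_csv, save_workspace,
                               write_fiducial_csv)


def random_workspace(rng, n_tracks=2, n_series=3):
    ws = Workspace(meta={"record_id": "rec1", "creator": "tester",
                         "tool_version": "0.1.0"})
    for i in range(n_tracks):
        n = int(rng.integers(10, 200))
        ws.add_track(Track(f"tr{i}", float(rng.uniform(50, 500)),
                           rng.normal(size=n), offset=float(rng.uniform(0, 5)),
                           units="mV"))
    names = list(ws.tracks)
    for j in range(n_series):
        ts = np.sort(rng.uniform(0, 100, size=int(rng.integers(0, 20))))
        if len(ts):
            ts = ts[np.concatenate([[True], np.diff(ts) > 1e-6])]
        se = FiducialSeries(f"fid{j}", list(ts), list(rng.normal(size=len(ts))),
                            [None if k % 2 else "s" for k in range(len(ts))],
                            min_distance=0.0)
        ws.add_fiducials(se, names[j % len(names)])
    ws.partitions.add("artifact", 1.0, 2.5)
    ws.partitions.add("clean", 2.5, 9.0)
    ws.epochs = EpochGrid(10.0, ["0", "1", "2"], 4, ["1", None, "2", "0"])
    return ws


def assert_workspace_equal(a: Workspace, b: Workspace):
    assert set(a.tracks) == set(b.tracks)
    for name in a.tracks:
        ta, tb = a.tracks[name], b.tracks[name]
        assert ta.fs == tb.fs and ta.offset == tb.offset and ta.units == tb.units
        np.testing.assert_array_equal(ta.values, tb.values)
    assert set(a.fiducials) == set(b.fiducials)
    for name in a.fiducials:
        sa, sb = a.fiducials[name], b.fiducials[name]
        assert sa.timestamps == sb.timestamps  # exact float equality
        assert [x for x in sa.amplitudes if not math.isnan(x)] == \
               [x for x in sb.amplitudes if not math.isnan(x)]
        assert sa.sublabels == sb.sublabels
        assert a.fiducial_tracks[name] == b.fiducial_tracks[name]
    pa, pb = a.partitions.partitions, b.partitions.partitions
    assert [(p.name, p.start, p.end) for p in pa] == \
           [(p.name, p.start, p.end) for p in pb]
    if a.epochs is None:
        assert b.epochs is None
    else:
        assert a.epochs.epoch_length == b.epochs.epoch_length
        assert a.epochs.label_set == b.epochs.label_set
        assert a.epochs.labels == b.epochs.labels


class TestRoundTrip:
    def test_empty_workspace(self, tmp_path):
        p = tmp_path / "empty.h5"
        save_workspace(Workspace(), p)
        ws = load_workspace(p)
        assert ws.tracks == {} and ws.fiducials == {}
        assert len(ws.partitions) == 0 and ws.epochs is None

    def test_track_and_series_exact(self, tmp_path, rng):
        ws = random_workspace(rng, n_tracks=1, n_series=3)
        p = tmp_path / "ws.h5"
        save_workspace(ws, p)
        assert_workspace_equal(ws, load_workspace(p))

    def test_generic_hdf5_reader_sees_layout(self, tmp_path, rng):
        ws = random_workspace(rng)
        p = tmp_path / "ws.h5"
        save_workspace(ws, p)
        with h5py.File(p, "r") as f:  # walk the documented contract directly
            assert "schema_version" in f["meta"].attrs
            for name in ws.tracks:
                g = f[f"tracks/{name}"]
                assert g.attrs["fs"] == ws.tracks[name].fs
                np.testing.assert_array_equal(g["values"][()],
                                              ws.tracks[name].values)
            for name in ws.fiducials:
                g = f[f"annotations/{name}"]
                assert {"t", "amplitude", "sublabel"} <= set(g)
            assert {"name", "start", "end"} <= set(f["partitions"])


class TestSchemaValidation:
    def test_future_major_version_rejected(self, tmp_path):
        p = tmp_path / "future.h5"
        save_workspace(Workspace(), p)
        with h5py.File(p, "a") as f:
            f["meta"].attrs["schema_version"] = "99.0"
        with pytest.raises(SchemaError, match="99.0"):
            load_workspace(p)

    def test_missing_group_named_in_error(self, tmp_path):
        p = tmp_path / "broken.h5"
        save_workspace(Workspace(), p)
        with h5py.File(p, "a") as f:
            del f["partitions"]
        with pytest.raises(SchemaError, match="partitions"):
            load_workspace(p)

    def test_binding_to_missing_track_rejected(self, tmp_path):
        ws = Workspace()
        ws.fiducials["x"] = FiducialSeries("x", [1.0])
        ws.fiducial_tracks["x"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            save_workspace(ws, tmp_path / "bad.h5")


class TestConfig:
    def test_minimal_config_resolves_defaults(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("source_dir: /data\n"
                     "tracks:\n - {name: ecg, column: 1, fs: 250}\n")
        cfg = load_config(p)
        assert cfg.source_dir == "/data"
        assert cfg.filename_template == "*.csv"
        assert cfg.epoch_length == 10.0
        assert cfg.tracks[0].fs == 250.0
        assert not cfg.run_ecg

    def test_missing_source_dir_is_hard_error(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("output_dir: /out\n")
        with pytest.raises(ValueError, match="source_dir"):
            load_config(p)

    def test_unknown_key_warns(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("source_dir: /data\nbogus_key: 1\n")
        with pytest.warns(UserWarning, match="bogus_key"):
            load_config(p)

    def test_incomplete_track_spec_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("source_dir: /data\ntracks:\n - {name: ecg}\n")
        with pytest.raises(ValueError):
            load_config(p)

    def test_epochs_need_label_set(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("source_dir: /data\nepochs: {length: 10}\n")
        with pytest.raises(ValueError, match="label_set"):
            load_config(p)

    def test_detector_toggles(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("source_dir: /d\ndetectors:\n  ecg: {threshold_scale: 0.3}\n")
        cfg = load_config(p)
        assert cfg.run_ecg and not cfg.run_ppg
        assert cfg.ecg_params == {"threshold_scale": 0.3}


class TestTextIO:
    def test_read_signal_csv_duration(self, tmp_path):
        p = tmp_path / "sig.csv"
        n = 500
        p.write_text("t,ecg\n" + "\n".join(f"{i/250},{i%7}" for i in range(n)))
        tr = read_signal_csv(p, fs=250.0, column="ecg")
        assert len(tr) == n
        assert tr.duration == pytest.approx(n / 250)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("t,ecg\n0,1\n")
        with pytest.raises(ValueError, match="ppg"):
            read_signal_csv(p, fs=250.0, column="ppg")

    def test_fiducial_csv_round_trip(self, tmp_path):
        p = tmp_path / "fid.csv"
        write_fiducial_csv(p, {"R": [1.0, 2.0], "foot": [0.5]})
        out = read_fiducial_csv(p)
        np.testing.assert_array_equal(out["R"], [1.0, 2.0])
        np.testing.assert_array_equal(out["foot"], [0.5])


@pytest.mark.skipif(importlib.util.find_spec("wfdb") is not None,
                    reason="wfdb installed: optional path exercised elsewhere")
def test_wfdb_reader_reports_missing_dependency():
    from beatkit.workspace import read_wfdb_record
    with pytest.raises(ImportError, match="wfdb"):
        read_wfdb_record("some/record")
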