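#!/usr/bin/env python
"""Minimal standalone example of reading a beatkit workspace file.

Uses only h5py — no beatkit import — to demonstrate that the HDF5 layout
is self-describing and readable by any generic HDF5 tool:

    /meta                 attrs: schema_version, record_id, creator, ...
    /tracks/<name>        dataset "values"; attrs fs, offset, units
    /annotations/<name>   datasets "t", "amplitude", "sublabel"; attr track
    /partitions           datasets "name", "start", "end"
    /epochs               dataset "labels"; attrs epoch_length, label_set

Usage: python scripts/load_workspace_example.py workspace.h5
"""

import sys

import h5py


def main(path: str) -> None:
    with h5py.File(path, "r") as f:
        print("schema:", f["meta"].attrs["schema_version"])
        for name, g in f["tracks"].items():
            v = g["values"]
            print(f"track {name}: {v.shape[0]} samples @ {g.attrs['fs']} Hz, "
                  f"offset {g.attrs['offset']} s, units {g.attrs['units']!r}")
        for name, g in f["annotations"].items():
            t = g["t"][()]
            print(f"annotation {name}: {len(t)} events on track "
                  f"{g.attrs['track']!r}"
                  + (f", first at {t[0]:.3f} s" if len(t) else ""))
        p = f["partitions"]
        for nm, s, e in zip(p["name"][()], p["start"][()], p["end"][()]):
            print(f"partition {nm.decode()}: [{s:.3f}, {e:.3f}] s")
        if "epochs" in f:
            g = f["epochs"]
            print(f"epochs: {len(g['labels'])} x {g.attrs['epoch_length']} s, "
                  f"labels {[x.decode() for x in g.attrs['label_set']]}")


if __name__ == "__main__":
    main(sys.argv[1])
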