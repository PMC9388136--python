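"""HDF5 trajectory serialization.

Layout (format version 1)::

    /meta            attrs: format_version, seed, linker_names (JSON),
                     config (YAML string, optional)
    /frames/000000   attrs: time
        nv           (nf,)    vertices per filament
        verts        (sum nv, 3)  unwrapped positions, concatenated
        link_spec    (NL,)
        link_fil     (NL, 2)
        link_abs     (NL, 2)

Round trip is exact: ``read_trajectory(write_trajectory(x)) == x`` on
every field.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .quantify import Frame, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def write_trajectory(traj: Trajectory, path: str) -> None:
    with h5py.File(path, "w") as h5:
        meta = h5.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["linker_names"] = json.dumps(traj.linker_names)
        meta.attrs["seed"] = int(traj.meta.get("seed", -1))
        if "config" in traj.meta:
            meta.attrs["config"] = yaml.safe_dump(traj.meta["config"])
        frames = h5.create_group("frames")
        for k, fr in enumerate(traj.frames):
            g = frames.create_group(f"{k:06d}")
            g.attrs["time"] = fr.time
            nv = np.array([v.shape[0] for v in fr.vertices], np.int64)
            g.create_dataset("nv", data=nv)
            verts = (np.concatenate(fr.vertices, axis=0) if fr.vertices
                     else np.zeros((0, 3)))
            g.create_dataset("verts", data=verts)
            g.create_dataset("link_spec", data=fr.link_spec)
            g.create_dataset("link_fil", data=fr.link_fil)
            g.create_dataset("link_abs", data=fr.link_abs)


def read_trajectory(path: str) -> Trajectory:
    with h5py.File(path, "r") as h5:
        if "meta" not in h5 or "frames" not in h5:
            raise IOError(f"{path}: not a trajectory file")
        meta = h5["meta"]
        ver = int(meta.attrs["format_version"])
        if ver != FORMAT_VERSION:
            raise IOError(
                f"{path}: trajectory format version {ver}, "
                f"this reader supports {FORMAT_VERSION}")
        names = json.loads(meta.attrs["linker_names"])
        tmeta: dict = {"seed": int(meta.attrs["seed"])}
        if "config" in meta.attrs:
            tmeta["config"] = yaml.safe_load(meta.attrs["config"])
        frames = []
        for key in sorted(h5["frames"]):
            g = h5["frames"][key]
            nv = g["nv"][...]
            verts = g["verts"][...]
            out = []
            off = 0
            for n in nv:
                out.append(verts[off:off + n].copy())
                off += n
            frames.append(Frame(
                time=float(g.attrs["time"]),
                vertices=out,
                link_spec=g["link_spec"][...],
                link_fil=g["link_fil"][...],
                link_abs=g["link_abs"][...]))
    return Trajectory(frames=frames, linker_names=names, meta=tmeta)
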