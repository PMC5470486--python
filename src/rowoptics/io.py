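"""Readers and writers for the pipeline's on-disk formats.

Point clouds travel as PLY (ASCII or binary little-endian, xyz vertices)
or plain 3-column XYZ text; plant estimates as a tidy CSV with one row per
(method, plant); configuration as a flat JSON document.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lidar import PointCloud
from .row_model import PlantEstimate

__all__ = [
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
    "read_point_cloud",
    "write_point_cloud",
    "read_estimates_csv",
    "write_estimates_csv",
    "read_config",
    "write_config",
]

_PLY_TYPES = {
    "float": ("<f4", "f"),
    "float32": ("<f4", "f"),
    "double": ("<f8", "d"),
    "float64": ("<f8", "d"),
    "int": ("<i4", "i"),
    "int32": ("<i4", "i"),
    "uint": ("<u4", "I"),
    "uint8": ("<u1", "B"),
    "uchar": ("<u1", "B"),
    "short": ("<i2", "h"),
    "ushort": ("<u2", "H"),
}


def read_ply(path) -> PointCloud:
    """Read xyz vertices from an ASCII or binary_little_endian PLY file."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise ValueError(f"{path}: not a PLY file")
    header_end = raw.index(b"\n", end) + 1
    header = raw[:header_end].decode("ascii", errors="replace").splitlines()

    fmt = None
    n_vertex = 0
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vertex = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            props.append((parts[1], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")
    names = [name for _, name in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise ValueError("PLY vertex element lacks x/y/z properties")

    if fmt == "ascii":
        body = raw[header_end:].decode("ascii").split()
        width = len(props)
        arr = np.array(body[: n_vertex * width], dtype=float).reshape(n_vertex, width)
    else:
        dtype = np.dtype([(name, _PLY_TYPES[t][0]) for t, name in props])
        arr_struct = np.frombuffer(raw, dtype=dtype, count=n_vertex, offset=header_end)
        arr = np.column_stack([arr_struct[name].astype(float) for name in names])
    cols = [names.index(a) for a in ("x", "y", "z")]
    return PointCloud(arr[:, cols])


def write_ply(cloud: PointCloud, path, *, binary: bool = True) -> None:
    """Write xyz vertices as PLY (binary little-endian by default)."""
    pts = np.asarray(cloud.points, dtype="<f8")
    header = (
        "ply\n"
        f"format {'binary_little_endian' if binary else 'ascii'} 1.0\n"
        f"element vertex {pts.shape[0]}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(pts.tobytes())
        else:
            for x, y, z in pts:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n".encode("ascii"))


def read_xyz(path) -> PointCloud:
    """Read a 3-column whitespace/comma-delimited XYZ text file."""
    arr = np.loadtxt(path, delimiter=None, ndmin=2)
    if arr.size == 0:
        return PointCloud(np.empty((0, 3)))
    return PointCloud(arr[:, :3])


def write_xyz(cloud: PointCloud, path) -> None:
    np.savetxt(path, cloud.points, fmt="%.6f")


def read_point_cloud(path) -> PointCloud:
    """Dispatch on extension: .ply -> PLY, anything else -> XYZ text."""
    if str(path).lower().endswith(".ply"):
        return read_ply(path)
    return read_xyz(path)


def write_point_cloud(cloud: PointCloud, path, **kw) -> None:
    if str(path).lower().endswith(".ply"):
        write_ply(cloud, path, **kw)
    else:
        write_xyz(cloud, path)


def write_estimates_csv(estimates: dict[str, Sequence[PlantEstimate]], path) -> None:
    rows = [
        {"method": method, "plant_id": i + 1, "x_mm": e.location}
        for method, lst in estimates.items()
        for i, e in enumerate(lst)
    ]
    pd.DataFrame(rows, columns=["method", "plant_id", "x_mm"]).to_csv(path, index=False)


def read_estimates_csv(path) -> dict[str, list[PlantEstimate]]:
    df = pd.read_csv(path)
    out: dict[str, list[PlantEstimate]] = {}
    for method, grp in df.groupby("method", sort=False):
        out[str(method)] = [
            PlantEstimate(float(r.x_mm), str(method), f"row-{int(r.plant_id)}")
            for r in grp.sort_values("x_mm").itertuples()
        ]
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat JSON object")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
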