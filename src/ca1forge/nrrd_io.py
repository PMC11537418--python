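"""Minimal NRRD reader/writer for dense scalar/vector grids.

Covers the subset of NRRD needed for region masks and coordinate fields:
3-D (or 3-D + small vector axis) arrays, ASCII or raw little-endian
encoding, voxel spacings and a space origin.  ASCII is the default so that
fixture files remain plain text.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_TYPE_MAP = {
    "uint8": np.uint8,
    "int32": np.int32,
    "int64": np.int64,
    "float": np.float32,
    "double": np.float64,
}
_INV_TYPE_MAP = {np.dtype(v): k for k, v in _TYPE_MAP.items()}


def write(path: str | Path, data: np.ndarray, voxel_size: float = 1.0,
          origin=(0.0, 0.0, 0.0), encoding: str = "ascii") -> None:
    """Write ``data`` as an NRRD file.

    Boolean arrays are stored as uint8.  For 4-D arrays the last axis is
    treated as a per-voxel vector and written as the fastest axis.
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if arr.dtype not in _INV_TYPE_MAP:
        arr = arr.astype(np.float64)
    # NRRD lists sizes fastest-axis-first; a C-order ravel of a numpy
    # array has its last axis fastest, so sizes are the reversed shape
    if arr.ndim not in (3, 4):
        raise ValueError("only 3-D or 4-D arrays supported")
    sizes = arr.shape[::-1]
    flat = arr.ravel(order="C")
    header = [
        "NRRD0004",
        f"type: {_INV_TYPE_MAP[arr.dtype]}",
        f"dimension: {len(sizes)}",
        f"sizes: {' '.join(str(s) for s in sizes)}",
        f"encoding: {encoding}",
        "endian: little",
        f"spacings: {'nan ' if arr.ndim == 4 else ''}"
        f"{voxel_size} {voxel_size} {voxel_size}".strip(),
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        if encoding == "ascii":
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.17g")
        elif encoding == "raw":
            fh.write(flat.astype(flat.dtype.newbyteorder("<")).tobytes())
        else:
            raise ValueError(f"unsupported encoding {encoding!r}")


def read(path: str | Path):
    """Read an NRRD file written by :func:`write` (or compatible).

    Returns ``(array, voxel_size, origin)`` with the array in numpy
    (slowest-first) axis order; a 4-D file comes back with the vector axis
    last.
    """
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rb") as fh:
        raw = fh.read()
    head_end = raw.index(b"\n\n")
    header_lines = raw[:head_end].decode().splitlines()
    body = raw[head_end + 2:]
    fields = {}
    for line in header_lines[1:]:
        if ":" in line:
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
    dtype = np.dtype(_TYPE_MAP[fields["type"]])
    sizes = [int(s) for s in fields["sizes"].split()]
    encoding = fields.get("encoding", "ascii")
    if encoding == "ascii":
        flat = np.array(body.decode().split(), dtype=dtype)
    elif encoding == "raw":
        flat = np.frombuffer(body, dtype=dtype.newbyteorder("<"))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
    flat = flat[:int(np.prod(sizes))]
    spacings = [float(s) for s in fields.get("spacings", "1 1 1").split()]
    voxel_size = next((s for s in spacings if np.isfinite(s)), 1.0)
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = tuple(
            float(x) for x in fields["space origin"].strip("()").split(","))
    arr = flat.reshape(sizes[::-1], order="C")
    return arr, voxel_size, origin
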