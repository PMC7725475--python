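"""Reading and writing volumes, label maps and result tables.

LAC volumes and label maps are exchanged as MRC 2014 files (mode 2 float32
for LAC, mode 6 uint16 for labels — the tomography community convention) or
as multi-page TIFF stacks.  The MRC codec here is a deliberately small
implementation of the MRC 2014 subset this package emits (single volume,
C-order, little-endian, isotropic voxel size in the cell-dimension header
words); TIFF goes through :mod:`tifffile` with the voxel size embedded in
the image description.

Tables are CSV with a stable column order and explicit float precision.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .volumes import DEFAULT_LEGEND, LabelMap, TomogramVolume, VolumeFormatError

_MRC_MODES = {2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(np.float32): 2, np.dtype(np.uint16): 6}


# ---------------------------------------------------------------------------
# MRC 2014
# ---------------------------------------------------------------------------

def write_mrc(data: np.ndarray, voxel_edge_nm: float, path: str | Path) -> None:
    """Write a 3D array as MRC 2014 (mode 2 or 6), voxel size in the header."""
    data = np.ascontiguousarray(data)
    if data.dtype not in _MRC_MODE_OF:
        data = data.astype(np.float32)
    mode = _MRC_MODE_OF[data.dtype]
    nz, ny, nx = data.shape
    cella = tuple(n * voxel_edge_nm * 10.0 for n in (nx, ny, nz))  # Å
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, *cella, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax, dmean = float(data.min()), float(data.max()), float(data.mean())
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg=1 (volume), nsymbt=0
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC 2014 volume; returns (array, voxel_edge_nm)."""
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise VolumeFormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if mode not in _MRC_MODES:
        raise VolumeFormatError(f"{path}: unsupported MRC mode {mode}")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise VolumeFormatError(f"{path}: missing 'MAP ' signature — corrupt header?")
    mx = struct.unpack_from("<i", raw, 28)[0]
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    if mx <= 0 or cella_x <= 0:
        raise VolumeFormatError(f"{path}: voxel size missing from MRC header")
    voxel_edge_nm = cella_x / mx / 10.0
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    dtype = np.dtype(_MRC_MODES[mode])
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=1024 + nsymbt)
    if data.size != count:
        raise VolumeFormatError(f"{path}: data block shorter than header promises")
    return data.reshape(nz, ny, nx).copy(), voxel_edge_nm


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_tiff(data: np.ndarray, voxel_edge_nm: float, path: str | Path) -> None:
    meta = json.dumps({"voxel_edge_nm": voxel_edge_nm})
    tifffile.imwrite(path, np.ascontiguousarray(data), description=meta)


def read_tiff(path: str | Path, voxel_edge_nm: float | None = None) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    edge = voxel_edge_nm
    if edge is None:
        try:
            edge = float(json.loads(desc)["voxel_edge_nm"])
        except (ValueError, KeyError, TypeError):
            raise VolumeFormatError(
                f"{path}: no voxel size in TIFF metadata and no override supplied"
            ) from None
    return np.asarray(data), float(edge)


# ---------------------------------------------------------------------------
# High-level volume / label-map API
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".mrc", ".map", ".rec"):
        return "mrc"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise VolumeFormatError(f"cannot infer volume format from {path!r}")


def write_volume(volume: TomogramVolume, path: str | Path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    data = volume.values.astype(np.float32)
    if fmt == "mrc":
        write_mrc(data, volume.voxel_edge_nm, path)
    elif fmt == "tiff":
        write_tiff(data, volume.voxel_edge_nm, path)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")


def read_volume(
    path: str | Path,
    fmt: str | None = None,
    voxel_edge_nm: float | None = None,
    name: str | None = None,
) -> TomogramVolume:
    """Read an LAC volume; dtype is widened to floating point.

    ``voxel_edge_nm`` overrides (TIFF) or replaces missing header metadata.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "mrc":
        data, edge = read_mrc(path)
        if voxel_edge_nm is not None:
            edge = voxel_edge_nm
    else:
        data, edge = read_tiff(path, voxel_edge_nm)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D stack, got {data.ndim}D data")
    return TomogramVolume(data.astype(np.float32), edge, name=name or Path(path).stem)


def write_labels(labels: LabelMap, path: str | Path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    data = labels.labels.astype(np.uint16)
    if fmt == "mrc":
        write_mrc(data, labels.voxel_edge_nm, path)
    else:
        write_tiff(data, labels.voxel_edge_nm, path)


def read_labels(
    path: str | Path,
    fmt: str | None = None,
    legend: dict[int, str] | None = None,
    voxel_edge_nm: float | None = None,
) -> LabelMap:
    fmt = _infer_format(path, fmt)
    if fmt == "mrc":
        data, edge = read_mrc(path)
    else:
        data, edge = read_tiff(path, voxel_edge_nm)
    if not np.issubdtype(data.dtype, np.integer):
        raise VolumeFormatError(f"{path}: label map must be integer typed")
    return LabelMap(data.astype(np.uint16), legend or dict(DEFAULT_LEGEND), edge)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path, float_format: str = "%.8g") -> None:
    """Write a result table as CSV; refuses non-finite numeric values."""
    df = pd.DataFrame(records)
    numeric = df.select_dtypes(include=[np.number])
    if not numeric.empty and not np.all(np.isfinite(numeric.to_numpy(dtype=float))):
        raise ValueError("table contains non-finite values; refusing to write")
    df.to_csv(path, index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
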