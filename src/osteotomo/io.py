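"""File I/O: MRC2014 volumes and stacks, TIFF fallback, ``.tlt`` sidecars,
phantom configuration files, and alignment tables.

The MRC reader/writer is deliberately minimal and self-contained: mode-2
(float32), mode-0 (int8), mode-1 (int16) and mode-6 (uint16) data, voxel size
in the header cell, and an optional raw float32 extended header holding tilt
angles. Tilt angles are additionally written to a plain-text ``.tlt`` sidecar
(one angle per line), which takes precedence on read.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
import yaml

from .volume import TiltSeries, Volume3D

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_volume_mrc",
    "read_volume_mrc",
    "write_tiltseries_mrc",
    "read_tiltseries_mrc",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_tlt",
    "read_tlt",
]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(v): k for k, v in _MODE_DTYPES.items()}

_HEADER_SIZE = 1024


def _pick_mode(dtype: np.dtype) -> Tuple[int, np.dtype]:
    dtype = np.dtype(dtype)
    if dtype in _DTYPE_MODES:
        return _DTYPE_MODES[dtype], dtype
    if dtype.kind == "f":
        return 2, np.dtype(np.float32)
    if dtype.kind in "iu":
        # widest supported integer container
        if np.dtype(dtype).itemsize == 1:
            return 0, np.dtype(np.int8)
        return 6, np.dtype(np.uint16)
    raise ValueError(f"unsupported dtype for MRC: {dtype}")


def write_mrc(
    path,
    data: np.ndarray,
    voxel_size: float,
    ext_floats: Optional[np.ndarray] = None,
) -> None:
    """Write a 3D array to MRC. ``data`` is indexed (x, y, z) or, for stacks,
    (section, x, y); it is stored in MRC section/row/column order."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D array")
    mode, dtype = _pick_mode(data.dtype)
    raw = np.ascontiguousarray(data.T.astype(dtype))  # (z, y, x) C-order
    nz, ny, nx = raw.shape
    ext = b""
    if ext_floats is not None:
        ext = np.asarray(ext_floats, dtype="<f4").tobytes()

    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)
    struct.pack_into("<i", hdr, 12, mode)
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)  # mx, my, mz
    cell = (nx * voxel_size * 10.0, ny * voxel_size * 10.0, nz * voxel_size * 10.0)
    struct.pack_into("<3f", hdr, 40, *cell)  # cella in Angstrom
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax, dmean = float(raw.min()), float(raw.max()), float(raw.mean())
    struct.pack_into("<3f", hdr, 76, dmin, dmax, dmean)
    struct.pack_into("<i", hdr, 92, len(ext))  # nsymbt
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", hdr, 216, float(raw.std()))

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(ext)
        fh.write(raw.tobytes())


def read_mrc(path) -> Tuple[np.ndarray, float, np.ndarray]:
    """Read an MRC file; returns (data indexed (x, y, z), voxel_size_nm,
    extended-header float32 block)."""
    with open(path, "rb") as fh:
        hdr = fh.read(_HEADER_SIZE)
        nx, ny, nz = struct.unpack_from("<3i", hdr, 0)
        (mode,) = struct.unpack_from("<i", hdr, 12)
        mx = struct.unpack_from("<3i", hdr, 28)[0]
        cella = struct.unpack_from("<3f", hdr, 40)
        (nsymbt,) = struct.unpack_from("<i", hdr, 92)
        if mode not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {mode}")
        ext = np.frombuffer(fh.read(nsymbt), dtype="<f4") if nsymbt else np.zeros(0, "f4")
        count = nx * ny * nz
        raw = np.frombuffer(fh.read(), dtype=np.dtype(_MODE_DTYPES[mode]).newbyteorder("<"), count=count)
    data = raw.reshape(nz, ny, nx).T  # back to (x, y, z)
    voxel_size = (cella[0] / mx / 10.0) if mx else 1.0
    return np.ascontiguousarray(data), float(voxel_size), ext


def write_volume_mrc(path, volume: Volume3D) -> None:
    write_mrc(path, volume.data, volume.voxel_size)


def read_volume_mrc(path) -> Volume3D:
    data, voxel_size, _ = read_mrc(path)
    return Volume3D(data, voxel_size)


def write_tlt(path, angles) -> None:
    Path(path).write_text("".join(f"{a:.2f}\n" for a in np.asarray(angles)))


def read_tlt(path) -> np.ndarray:
    return np.array([float(line) for line in Path(path).read_text().split()])


def _tlt_path(mrc_path) -> Path:
    return Path(mrc_path).with_suffix(".tlt")


def write_tiltseries_mrc(path, series: TiltSeries) -> None:
    """Stack written frame-by-frame as MRC sections, angles both in the
    extended header (raw float32) and in a ``.tlt`` sidecar."""
    write_mrc(path, np.transpose(series.frames, (2, 1, 0)), series.pixel_size,
              ext_floats=series.angles)
    write_tlt(_tlt_path(path), series.angles)


def read_tiltseries_mrc(path, modality: str = "HAADF") -> TiltSeries:
    data, pixel_size, ext = read_mrc(path)
    frames = np.transpose(data, (2, 1, 0))  # (n, nx, ny)
    tlt = _tlt_path(path)
    if tlt.exists():
        angles = read_tlt(tlt)
    elif ext.size == frames.shape[0]:
        angles = np.asarray(ext, dtype=float)
    else:
        raise ValueError(f"no tilt angles found for {path}")
    return TiltSeries(frames, angles, pixel_size, modality)


def write_volume_tiff(path, volume: Volume3D) -> None:
    """Multipage TIFF, one xy page per z index; voxel size kept in metadata."""
    pages = np.transpose(volume.data, (2, 1, 0)).astype(np.float32)
    # explicit photometric keeps small trailing dimensions from being
    # interpreted as color samples (which would collapse the stack to one page)
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        metadata={"axes": "QYX", "voxel_size_nm": volume.voxel_size},
    )


def read_volume_tiff(path, voxel_size: Optional[float] = None) -> Volume3D:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        if voxel_size is None:
            meta = tif.shaped_metadata or tif.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            voxel_size = float(meta.get("voxel_size_nm", 1.0))
    return Volume3D(np.transpose(pages, (2, 1, 0)), voxel_size)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
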