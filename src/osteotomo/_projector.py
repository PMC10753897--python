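"""Shared parallel-beam projector for on-axis geometry.

Because the tilt axis is y, every y-row is an independent 2D problem: the
projection of an xz slice onto a 1D detector. The forward operator is built
once per (grid, angles, axis offset) as a sparse matrix: each voxel center is
rotated into detector coordinates and its value split linearly between the two
nearest detector bins (pixel-driven splatting, i.e. rotation by bilinear
interpolation followed by summation along the beam). Its transpose is the
exact adjoint, which SIRT relies on.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp

_CACHE: Dict[Tuple, sp.csr_matrix] = {}
_CACHE_LIMIT = 8


def system_matrix(
    nx: int,
    nz: int,
    angles_deg: np.ndarray,
    n_det: int | None = None,
    axis_offset: float = 0.0,
) -> sp.csr_matrix:
    """Sparse forward projector, shape (n_angles * n_det, nx * nz).

    ``axis_offset`` displaces the rotation axis from the detector center by
    that many pixels (positive = axis sits right of center).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if n_det is None:
        n_det = nx
    key = (nx, nz, n_det, round(float(axis_offset), 6), angles_deg.tobytes())
    hit = _CACHE.get(key)
    if hit is not None:
        return hit

    cx = (nx - 1) / 2.0
    cz = (nz - 1) / 2.0
    det_c = (n_det - 1) / 2.0 + axis_offset
    xs = np.arange(nx) - cx
    zs = np.arange(nz) - cz
    n_vox = nx * nz
    cols = np.arange(n_vox)

    rows_all = []
    cols_all = []
    vals_all = []
    for a, ang in enumerate(np.deg2rad(angles_deg)):
        u = (np.cos(ang) * xs[:, None] + np.sin(ang) * zs[None, :]).ravel() + det_c
        i0 = np.floor(u).astype(np.int64)
        w1 = u - i0
        for off, w in ((0, 1.0 - w1), (1, w1)):
            det = i0 + off
            ok = (det >= 0) & (det < n_det) & (w > 0)
            rows_all.append(a * n_det + det[ok])
            cols_all.append(cols[ok])
            vals_all.append(w[ok])
    A = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(len(angles_deg) * n_det, n_vox),
    ).tocsr()
    if len(_CACHE) >= _CACHE_LIMIT:
        _CACHE.pop(next(iter(_CACHE)))
    _CACHE[key] = A
    return A


def volume_to_slices(data: np.ndarray) -> np.ndarray:
    """(nx, ny, nz) volume -> (nx*nz, ny) matrix of xz slices as columns of y."""
    nx, ny, nz = data.shape
    return np.ascontiguousarray(data.transpose(0, 2, 1).reshape(nx * nz, ny))


def slices_to_volume(x: np.ndarray, nx: int, nz: int) -> np.ndarray:
    ny = x.shape[1]
    return np.ascontiguousarray(x.reshape(nx, nz, ny).transpose(0, 2, 1))
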