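"""Forward simulation of on-axis tilt series.

Projects phantom volumes into HAADF-like tilt series (and, through the same
geometry operator, per-element EDX channels), derives BF-like frames, and
injects the imperfections the reconstruction stage has to cope with: counting
noise and per-frame misalignment. Acquisition presets mirror the experimental
conditions: tilt ranges of +/-90 deg (steps 2 or 5) or +/-85 deg (step 5) at
pixel sizes between 0.73 and 4.20 nm, with EDX channels binned relative to
HAADF.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np
from scipy import ndimage

from ._projector import system_matrix, volume_to_slices
from .volume import TiltSeries, Volume3D

__all__ = [
    "TILT_PRESETS",
    "tilt_angles",
    "project",
    "project_elements",
    "simulate_bf",
    "add_noise",
    "apply_misalignment",
    "smooth_edx_frames",
    "bin_series",
]

# preset -> (half range deg, step deg, HAADF pixel nm)
TILT_PRESETS: Dict[str, Tuple[float, float, float]] = {
    "i-a": (90.0, 2.0, 0.73),
    "i-b": (90.0, 5.0, 2.05),
    "ii-a": (85.0, 5.0, 1.05),
    "ii-b": (85.0, 5.0, 0.74),
}


def tilt_angles(preset_or_range, step: float | None = None) -> np.ndarray:
    """Angle list from a named preset ('i-a', ...) or (half_range, step)."""
    if isinstance(preset_or_range, str):
        half, step, _ = TILT_PRESETS[preset_or_range]
    else:
        half = float(preset_or_range)
        if step is None:
            raise ValueError("step required when giving an explicit half range")
    n = int(round(2 * half / step)) + 1
    return -half + step * np.arange(n)


def project(volume: Volume3D, angles: Iterable[float], modality: str = "HAADF") -> TiltSeries:
    """Parallel-beam line integrals along z of the volume rotated about y.

    Each frame pixel holds the ray sum in (density x nm) units; the detector
    spans the volume's x extent, one detector pixel per voxel.
    """
    angles = np.asarray(list(angles), dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    nx, ny, nz = volume.shape
    A = system_matrix(nx, nz, angles)
    sino = A @ volume_to_slices(np.asarray(volume.data, dtype=np.float64))
    frames = sino.reshape(len(angles), nx, ny) * volume.voxel_size
    return TiltSeries(frames, angles, volume.voxel_size, modality)


def project_elements(
    elements: Dict[str, Volume3D],
    angles: Iterable[float],
    binning: int = 2,
) -> Dict[str, TiltSeries]:
    """EDX channels projected with the same geometry operator as HAADF, then
    binned ``binning x binning`` (block mean) to emulate the coarser EDX
    sampling of the acquisitions."""
    out = {}
    for el, vol in elements.items():
        s = project(vol, angles, modality=f"EDX:{el}")
        out[el] = bin_series(s, binning) if binning > 1 else s
    return out


def bin_series(series: TiltSeries, factor: int) -> TiltSeries:
    """Block-mean binning of every frame; pixel size scales by the factor."""
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    n, nx, ny = series.frames.shape
    bx, by = nx // factor, ny // factor
    f = series.frames[:, : bx * factor, : by * factor]
    binned = f.reshape(n, bx, factor, by, factor).mean(axis=(2, 4))
    return TiltSeries(
        binned,
        series.angles.copy(),
        series.pixel_size * factor,
        series.modality,
        series.applied_shifts.copy() / factor,
        binning=series.binning * factor,
    )


def simulate_bf(haadf_series: TiltSeries, k: float) -> TiltSeries:
    """Bright-field-like contrast: BF = exp(-k * ray_sum)."""
    if k <= 0:
        raise ValueError("attenuation coefficient k must be > 0")
    return haadf_series.with_frames(np.exp(-k * haadf_series.frames), modality="BF")


def add_noise(
    series: TiltSeries,
    dose: float,
    read_sigma: float = 0.0,
    seed: int = 0,
    clip_negative: bool = True,
) -> TiltSeries:
    """Counting noise: Poisson(dose x intensity) + Gaussian read noise.

    ``dose`` is the mean number of counts per unit projected intensity, so
    frames come back in counts; dividing by ``dose`` recovers the intensity
    scale. Negative count values are clipped at zero by default (a physical
    detector cannot report them); disable ``clip_negative`` to study the raw
    additive model.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    rng = np.random.default_rng(seed)
    lam = np.clip(series.frames, 0, None) * dose
    counts = rng.poisson(lam).astype(np.float64)
    if read_sigma > 0:
        counts += rng.normal(0.0, read_sigma, size=counts.shape)
    if clip_negative:
        counts = np.clip(counts, 0, None)
    return series.with_frames(counts)


def _integer_shift(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Exact integer shift with zero padding (no wrap-around)."""
    out = np.zeros_like(frame)
    nx, ny = frame.shape
    xs_src = slice(max(0, -dx), min(nx, nx - dx))
    xs_dst = slice(max(0, dx), min(nx, nx + dx))
    ys_src = slice(max(0, -dy), min(ny, ny - dy))
    ys_dst = slice(max(0, dy), min(ny, ny + dy))
    out[xs_dst, ys_dst] = frame[xs_src, ys_src]
    return out


def apply_misalignment(series: TiltSeries, max_shift: int, seed: int = 0) -> TiltSeries:
    """Per-frame integer shifts drawn uniformly in [-max_shift, +max_shift]^2,
    recorded in ``applied_shifts`` as the alignment ground truth."""
    rng = np.random.default_rng(seed)
    n = series.n_frames
    shifts = rng.integers(-max_shift, max_shift + 1, size=(n, 2)) if max_shift > 0 else np.zeros((n, 2), int)
    frames = np.stack(
        [_integer_shift(series.frames[i], int(shifts[i, 0]), int(shifts[i, 1])) for i in range(n)]
    )
    return series.with_frames(frames, applied_shifts=shifts.astype(float))


def shift_frames(series: TiltSeries, shifts: np.ndarray) -> TiltSeries:
    """Apply per-frame (dx, dy) shifts with bilinear interpolation (used to
    undo measured misalignment)."""
    shifts = np.asarray(shifts, dtype=float)
    frames = np.stack(
        [
            ndimage.shift(series.frames[i], shifts[i], order=1, mode="constant", cval=0.0)
            for i in range(series.n_frames)
        ]
    )
    return series.with_frames(frames)


def smooth_edx_frames(series: TiltSeries, gaussian_sigma: float = 2.0, box_width: int = 5) -> TiltSeries:
    """Denoising applied to every EDX frame: Gaussian blur followed by a box
    average (defaults: sigma 2, 5 px). Reflective boundary handling keeps
    constant frames exactly constant."""
    if not series.modality.startswith("EDX"):
        raise ValueError(f"smooth_edx_frames expects an EDX series, got {series.modality!r}")
    frames = series.frames
    out = np.empty_like(frames)
    for i in range(series.n_frames):
        f = ndimage.gaussian_filter(frames[i], gaussian_sigma, mode="reflect")
        out[i] = ndimage.uniform_filter(f, box_width, mode="reflect")
    return series.with_frames(out)
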