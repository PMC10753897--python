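"""Core in-memory containers shared by every stage of the pipeline.

Axis convention (used throughout the package): arrays are indexed ``[x, y, z]``;
``y`` is the long axis of the rod-shaped sample *and* the tilt axis, the beam
travels along ``z`` at zero tilt, so ``xy`` is the image plane (banding motif)
and ``xz`` the cross-section plane ("holes" motif). Voxel indices are 0-based
and coordinates refer to voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["Volume3D", "TiltSeries", "BinaryMask", "LabelVolume"]


@dataclass
class Volume3D:
    """An isotropic 3D voxel grid with a physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values (density, element weight-density, labels, ...).
    voxel_size : float
        Edge length of a voxel in nanometres (isotropic).
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D data must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive and finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size)

    def physical_extent(self) -> Tuple[float, float, float]:
        """Edge lengths of the volume in nm."""
        return tuple(n * self.voxel_size for n in self.data.shape)


@dataclass
class TiltSeries:
    """An ordered stack of 2D projections with tilt-angle metadata.

    ``frames`` has shape ``(n_frames, nx, ny)`` where ``x`` is the detector
    coordinate perpendicular to the tilt axis and ``y`` runs along the tilt
    axis. ``applied_shifts`` records ground-truth per-frame (dx, dy) shifts in
    pixels injected by the simulator, for alignment-recovery tests.
    """

    frames: np.ndarray
    angles: np.ndarray
    pixel_size: float
    modality: str = "HAADF"
    applied_shifts: Optional[np.ndarray] = None
    binning: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D stack (n, nx, ny)")
        if len(self.angles) != self.frames.shape[0]:
            raise ValueError("number of angles must match number of frames")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.angles < -90.0) or np.any(self.angles > 90.0):
            raise ValueError("angles must lie within [-90, +90] degrees")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.applied_shifts is None:
            self.applied_shifts = np.zeros((self.frames.shape[0], 2))
        else:
            self.applied_shifts = np.asarray(self.applied_shifts, dtype=np.float64)
            if self.applied_shifts.shape != (self.frames.shape[0], 2):
                raise ValueError("applied_shifts must have shape (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.frames.copy(),
            self.angles.copy(),
            self.pixel_size,
            self.modality,
            self.applied_shifts.copy(),
            self.binning,
        )

    def with_frames(self, frames: np.ndarray, **kwargs) -> "TiltSeries":
        """New series sharing this one's metadata but different frame data."""
        out = TiltSeries(
            np.asarray(frames),
            self.angles.copy(),
            self.pixel_size,
            kwargs.pop("modality", self.modality),
            kwargs.pop("applied_shifts", self.applied_shifts.copy()),
            kwargs.pop("binning", self.binning),
        )
        return out


@dataclass
class BinaryMask:
    """A {0,1} voxel mask carrying the provenance of operations applied to it."""

    data: np.ndarray
    voxel_size: float = 1.0
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3D")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def derived(self, data: np.ndarray, op: str) -> "BinaryMask":
        """Child mask recording ``op`` at the end of the provenance chain."""
        return BinaryMask(data, self.voxel_size, self.provenance + [op])


@dataclass
class LabelVolume:
    """Integer-labelled components; 0 is background, labels are 1..label_count
    sorted by decreasing voxel count."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def label_count(self) -> int:
        return int(self.data.max())

    @property
    def voxel_counts(self) -> np.ndarray:
        """Voxel count per label, index 0 = label 1."""
        if self.label_count == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.data.ravel(), minlength=self.label_count + 1)[1:]
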