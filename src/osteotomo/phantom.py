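"""Synthetic phantoms of mineralized bone ultrastructure.

The phantom emulates the sample geometry an on-axis tomography experiment of
an osteonal-lamella rod sees: a slightly conical rod (long axis = y = tilt
axis) containing parallel collagen fibrils that carry the canonical ~67 nm
gap/overlap banding, extra-fibrillar mineral plates (~100 x 35 x 7 nm) placed
tangent to fibril surfaces, and an inter-fibril matrix that is by default a
continuous extra-fibrillar mineral phase (mature, fully mineralized tissue).
Density is a monotone class-level proxy for HAADF mass contrast; per-element
volumes carry weight fractions x density for EDX simulation.

Classes, darkest to brightest: vacuum < resin < unmineralized collagen <=
overlap-zone collagen < gap-zone mineral < extra-fibrillar mineral. Dark
"holes" in cross-section are fibril voxels (overlap zones darkest), exactly
the configuration the segmentation stage is designed to extract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .volume import Volume3D

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PackingError",
    "build_phantom",
    "axial_profile",
    "oriented_box_mask",
    "preset_literature_fibrils",
    "preset_cross_fibrillar",
    "preset_finite_segments",
]

# integer class ids used in the ground-truth label volume
VACUUM, RESIN, UNMINERALIZED, OVERLAP, GAP, MINERAL = range(6)

CLASS_NAMES = (
    "vacuum",
    "resin",
    "unmineralized_collagen",
    "overlap_collagen",
    "gap_mineral",
    "extra_fibrillar_mineral",
)

ELEMENTS = ("Ca", "P", "C", "N")

# relative scattering-density proxy per class (monotone in mass-thickness)
DEFAULT_CONTRAST: Dict[str, float] = {
    "vacuum": 0.0,
    "resin": 0.12,
    "unmineralized_collagen": 0.25,
    "overlap_collagen": 0.30,
    "gap_mineral": 0.55,
    "extra_fibrillar_mineral": 1.0,
}

# (Ca, P, C, N) weight fractions per class. Mineral is hydroxyapatite
# (39.9 wt% Ca, 18.5 wt% P, Ca/P atomic ratio 10/6); collagenous classes are
# C/N-rich; the gap zone mixes intra-fibrillar mineral with collagen.
DEFAULT_ELEMENT_WEIGHTS: Dict[str, Tuple[float, float, float, float]] = {
    "vacuum": (0.0, 0.0, 0.0, 0.0),
    "resin": (0.0, 0.0, 1.0, 0.0),
    "unmineralized_collagen": (0.0, 0.0, 0.55, 0.17),
    "overlap_collagen": (0.0, 0.0, 0.55, 0.17),
    "gap_mineral": (0.20, 0.0928, 0.40, 0.12),
    "extra_fibrillar_mineral": (0.399, 0.185, 0.0, 0.0),
}


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot reach the requested fibril fill."""


@dataclass
class PhantomSpec:
    """Full parametric description of a synthetic sample.

    Lengths are in nm. ``volume_shape`` is voxel counts ``(nx, ny, nz)`` with
    y the rod/tilt axis. The default geometry is a desk-scale rod: the real
    samples taper from ~200-300 nm diameter at the top to ~700 nm at the
    bottom; here the cone is shrunk to fit a 128 px field of view at 1 nm
    voxels while keeping the taper.
    """

    volume_shape: Tuple[int, int, int] = (128, 256, 128)
    voxel_size: float = 1.0
    rod_radius_top: float = 45.0
    rod_radius_bottom: float = 55.0
    fibril_diameter_mean: float = 23.0
    fibril_diameter_sd: float = 4.6
    d_spacing: float = 67.0
    overlap_fraction: float = 27.0 / 67.0
    fibril_fill_fraction: float = 0.30
    plate_length: float = 100.0
    plate_width: float = 35.0
    plate_thickness: float = 7.0
    plate_density_per_fibril: float = 2.0
    contrast_levels: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    element_weights: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_WEIGHTS)
    )
    matrix_mineralized: bool = True
    fibril_segment_length: Optional[float] = None  # break fibrils into <= this (nm)
    seed: int = 0

    def validate(self) -> None:
        nx, ny, nz = self.volume_shape
        if min(nx, ny, nz) < 1:
            raise ValueError("volume_shape must be positive")
        for name in (
            "voxel_size",
            "rod_radius_top",
            "rod_radius_bottom",
            "fibril_diameter_mean",
            "fibril_diameter_sd",
            "d_spacing",
            "plate_length",
            "plate_width",
            "plate_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.overlap_fraction <= 1.0):
            # 1.0 is the documented degenerate clamp (all-overlap fibril)
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if not (0.0 <= self.fibril_fill_fraction < 1.0):
            raise ValueError("fibril_fill_fraction must lie in [0, 1)")
        if self.plate_density_per_fibril < 0:
            raise ValueError("plate_density_per_fibril must be >= 0")
        half_extent = min(nx, nz) * self.voxel_size / 2.0
        if max(self.rod_radius_top, self.rod_radius_bottom) > half_extent:
            raise ValueError("rod radii must not exceed half the in-plane extent")
        c = self.contrast_levels
        ordered = (
            c["vacuum"] < c["resin"] < c["unmineralized_collagen"]
            <= c["gap_mineral"] < c["extra_fibrillar_mineral"]
        )
        if not ordered:
            raise ValueError(
                "contrast_levels must satisfy vacuum < resin < unmineralized "
                "collagen <= gap-zone mineral < extra-fibrillar mineral"
            )

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["element_weights"] = {k: list(v) for k, v in self.element_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "volume_shape" in d:
            d["volume_shape"] = tuple(d["volume_shape"])
        if "element_weights" in d:
            d["element_weights"] = {k: tuple(v) for k, v in d["element_weights"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        from .io import save_yaml

        save_yaml(path, self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        from .io import load_yaml

        return cls.from_dict(load_yaml(path))


@dataclass
class GroundTruth:
    """Ground-truth companion of a phantom (the test oracle).

    ``fibril_axes`` holds ``(center_x_nm, center_z_nm, radius_nm)`` per fibril
    (coordinates relative to the volume center); ``band_phase`` the axial
    offset (nm) of each fibril's gap/overlap pattern; ``plate_boxes`` one dict
    per plate with center, axis directions and dimensions.
    """

    class_labels: Volume3D
    fibril_axes: List[Tuple[float, float, float]]
    plate_boxes: List[dict]
    band_phase: List[float]
    fibril_labels: Volume3D
    plate_labels: Volume3D

    def rod_mask(self) -> np.ndarray:
        return self.class_labels.data != VACUUM

    def fibril_mask(self) -> np.ndarray:
        return self.fibril_labels.data > 0

    def mineral_mask(self) -> np.ndarray:
        return self.class_labels.data == MINERAL


def _inplane_coords(spec: PhantomSpec):
    nx, ny, nz = spec.volume_shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.voxel_size
    z = (np.arange(nz) - (nz - 1) / 2.0) * spec.voxel_size
    return x, z


def _pack_fibrils(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping parallel cylinders inside the rod.

    The fill fraction is defined against the narrowest (top) cross-section so
    fibrils stay inside the cone over the full rod length.
    """
    r_limit = min(spec.rod_radius_top, spec.rod_radius_bottom)
    target_area = spec.fibril_fill_fraction * np.pi * r_limit**2
    if target_area <= 0:
        return []
    min_radius = 2.0 * spec.voxel_size  # diameters truncated at > 4 voxels
    fibrils: List[Tuple[float, float, float]] = []
    area = 0.0
    redraws = 0
    expected_n = max(1, int(np.ceil(target_area / (np.pi * (spec.fibril_diameter_mean / 2) ** 2))))
    max_redraws = 200 + 100 * expected_n
    # Draw each diameter once and retry positions for it, so placement
    # difficulty does not bias the accepted size distribution toward small
    # fibrils; only redraw when a diameter is truncated or cannot be placed.
    position_tries = 400
    while area < target_area:
        if redraws >= max_redraws:
            raise PackingError(
                f"fibril packing failed after {redraws} diameter draws: achieved "
                f"fill fraction {area / (np.pi * r_limit ** 2):.3f} "
                f"< requested {spec.fibril_fill_fraction:.3f}"
            )
        redraws += 1
        r = rng.normal(spec.fibril_diameter_mean, spec.fibril_diameter_sd) / 2.0
        if r < min_radius or r >= r_limit:
            continue
        for _ in range(position_tries):
            # uniform center in the admissible disc
            rho = (r_limit - r) * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            cx, cz = rho * np.cos(phi), rho * np.sin(phi)
            if any(np.hypot(cx - fx, cz - fz) < r + fr for fx, fz, fr in fibrils):
                continue
            fibrils.append((cx, cz, r))
            area += np.pi * r**2
            break
    return fibrils


def _band_classes(spec: PhantomSpec, phase: float) -> np.ndarray:
    """Per-y-index band class (GAP or OVERLAP) for one fibril."""
    ny = spec.volume_shape[1]
    y = np.arange(ny) * spec.voxel_size
    overlap_len = min(spec.overlap_fraction, 1.0) * spec.d_spacing
    gap_len = spec.d_spacing - overlap_len
    s = np.mod(y + phase, spec.d_spacing)
    out = np.where(s < gap_len, GAP, OVERLAP).astype(np.int8)
    if gap_len < spec.voxel_size:  # degenerate clamp: constant-density fibril
        out[:] = OVERLAP
    return out


def _segment_keep(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean keep-mask along y implementing optional finite fibril segments."""
    ny = spec.volume_shape[1]
    keep = np.ones(ny, dtype=bool)
    if spec.fibril_segment_length is None:
        return keep
    max_len = max(1, int(round(spec.fibril_segment_length / spec.voxel_size)))
    gap = max(2, int(round(4.0 / spec.voxel_size)))  # small unmineralized break
    keep[:] = False
    pos = int(rng.integers(0, gap + 1))  # random offset so breaks de-correlate
    while pos < ny:
        seg = int(rng.integers(max(1, max_len // 2), max_len + 1))
        keep[pos : pos + seg] = True
        pos += seg + gap
    return keep


def oriented_box_mask(
    shape: Tuple[int, int, int],
    voxel_size: float,
    center: Sequence[float],
    axes: np.ndarray,
    half_sizes: Sequence[float],
) -> np.ndarray:
    """Voxel mask of an oriented box.

    ``center`` in nm relative to the volume center; ``axes`` rows are the box's
    orthonormal axis directions; ``half_sizes`` the half extents (nm) along
    them. Evaluated on voxel centers inside a bounding region only.
    """
    nx, ny, nz = shape
    ctr_idx = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    c_idx = np.asarray(center) / voxel_size + ctr_idx
    reach = float(np.sum(np.abs(axes) * np.asarray(half_sizes)[:, None], axis=0).max()) / voxel_size
    lo = np.maximum(np.floor(c_idx - reach - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + reach + 1).astype(int) + 1, [nx, ny, nz])
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = (np.stack([ii, jj, kk], axis=-1) - ctr_idx) * voxel_size - np.asarray(center)
    inside = np.ones(ii.shape, dtype=bool)
    for ax, h in zip(np.asarray(axes), half_sizes):
        inside &= np.abs(pts @ ax) <= h
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return mask


def _place_plates(spec, fibrils, rng, classes, plate_labels, rod):
    """Plates tangent to fibril surfaces: long axis along y, thickness radial.

    Plates never overwrite fibril voxels (priority fibril > plate > matrix)
    and are clipped to the rod interior; they may touch or span neighbouring
    fibrils, which is what makes the mineral phase cross-fibrillar.
    """
    boxes: List[dict] = []
    if not fibrils or spec.plate_density_per_fibril <= 0:
        return boxes
    n_plates = int(round(spec.plate_density_per_fibril * len(fibrils)))
    ny = spec.volume_shape[1]
    y_extent = ny * spec.voxel_size
    half = (spec.plate_length / 2, spec.plate_width / 2, spec.plate_thickness / 2)
    for p in range(n_plates):
        fi = int(rng.integers(0, len(fibrils)))
        fx, fz, fr = fibrils[fi]
        theta = rng.uniform(0, 2 * np.pi)
        u_rad = np.array([np.cos(theta), 0.0, np.sin(theta)])
        u_tan = np.array([-np.sin(theta), 0.0, np.cos(theta)])
        u_y = np.array([0.0, 1.0, 0.0])
        dist = fr + spec.plate_thickness / 2.0
        y_lo, y_hi = spec.plate_length / 2, max(y_extent - spec.plate_length / 2, spec.plate_length / 2)
        cy = rng.uniform(y_lo, y_hi) - y_extent / 2.0  # center-relative
        center = np.array([fx, 0.0, fz]) + dist * u_rad + cy * u_y
        axes = np.stack([u_y, u_tan, u_rad])  # length, width, thickness
        box = oriented_box_mask(spec.volume_shape, spec.voxel_size, center, axes, half)
        place = box & rod & (plate_labels == 0) & ~np.isin(classes, (GAP, OVERLAP))
        classes[place] = MINERAL
        plate_labels[place] = p + 1
        boxes.append(
            {
                "center_nm": center.tolist(),
                "axes": axes.tolist(),
                "dims_nm": [spec.plate_length, spec.plate_width, spec.plate_thickness],
                "fibril_index": fi,
            }
        )
    return boxes


def build_phantom(spec: PhantomSpec):
    """Generate (density, element volumes, ground truth) from a spec.

    Identical spec + seed give bit-identical output: a single seeded generator
    drives fibril packing, band phases, segment breaks and plate placement, in
    that order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.volume_shape
    x, z = _inplane_coords(spec)
    dist2 = x[:, None] ** 2 + z[None, :] ** 2  # (nx, nz)

    frac = np.linspace(0.0, 1.0, ny) if ny > 1 else np.zeros(1)
    r_y = spec.rod_radius_bottom + (spec.rod_radius_top - spec.rod_radius_bottom) * frac
    rod = dist2[:, None, :] <= (r_y**2)[None, :, None]

    classes = np.full(spec.volume_shape, VACUUM, dtype=np.int8)
    classes[rod] = MINERAL if spec.matrix_mineralized else RESIN

    fibrils = _pack_fibrils(spec, rng)
    fibril_labels = np.zeros(spec.volume_shape, dtype=np.uint16)
    phases: List[float] = []
    for i, (cx, cz, r) in enumerate(fibrils):
        phase = float(rng.uniform(0, spec.d_spacing))
        phases.append(phase)
        sect = (x[:, None] - cx) ** 2 + (z[None, :] - cz) ** 2 <= r**2  # (nx, nz)
        band = _band_classes(spec, phase)  # (ny,)
        keep = _segment_keep(spec, rng)
        col = sect[:, None, :] & keep[None, :, None]
        classes[col] = np.broadcast_to(band[None, :, None], col.shape)[col]
        fibril_labels[col] = i + 1

    plate_labels = np.zeros(spec.volume_shape, dtype=np.uint16)
    plate_boxes = _place_plates(spec, fibrils, rng, classes, plate_labels, rod)

    levels = np.array([spec.contrast_levels[name] for name in CLASS_NAMES])
    density = Volume3D(levels[classes].astype(np.float32), spec.voxel_size)

    weights = np.array([spec.element_weights[name] for name in CLASS_NAMES])  # (6, 4)
    elements = {
        el: Volume3D((weights[classes, k] * density.data).astype(np.float32), spec.voxel_size)
        for k, el in enumerate(ELEMENTS)
    }

    truth = GroundTruth(
        class_labels=Volume3D(classes, spec.voxel_size),
        fibril_axes=[(cx, cz, r) for cx, cz, r in fibrils],
        plate_boxes=plate_boxes,
        band_phase=phases,
        fibril_labels=Volume3D(fibril_labels, spec.voxel_size),
        plate_labels=Volume3D(plate_labels, spec.voxel_size),
    )
    return density, elements, truth


def axial_profile(truth: GroundTruth, density: Volume3D, fibril_index: int):
    """Density sampled along a fibril's axis at voxel-size steps.

    Returns ``(positions_nm, values)``; the axis column is the voxel column
    nearest the fibril center.
    """
    if not (0 <= fibril_index < len(truth.fibril_axes)):
        raise IndexError(
            f"fibril_index {fibril_index} out of range (0..{len(truth.fibril_axes) - 1})"
        )
    cx, cz, _ = truth.fibril_axes[fibril_index]
    nx, ny, nz = density.shape
    ix = int(round(cx / density.voxel_size + (nx - 1) / 2.0))
    iz = int(round(cz / density.voxel_size + (nz - 1) / 2.0))
    values = np.asarray(density.data[ix, :, iz], dtype=float)
    positions = np.arange(ny) * density.voxel_size
    return positions, values


# -- presets -----------------------------------------------------------------

def preset_literature_fibrils(**overrides) -> PhantomSpec:
    """Literature-sized (~100 nm) fibrils; needs a wider field of view."""
    base = dict(
        volume_shape=(256, 256, 256),
        voxel_size=2.0,
        rod_radius_top=200.0,
        rod_radius_bottom=240.0,
        fibril_diameter_mean=100.0,
        fibril_diameter_sd=20.0,
        fibril_fill_fraction=0.3,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def preset_cross_fibrillar(**overrides) -> PhantomSpec:
    """Resin matrix + dense tangent plates: the mineral phase is carried by
    plates alone, wrapping and bridging fibrils (cross-fibrillar model)."""
    base = dict(matrix_mineralized=False, plate_density_per_fibril=10.0)
    base.update(overrides)
    return PhantomSpec(**base)


def preset_finite_segments(segment_length: float = 500.0, **overrides) -> PhantomSpec:
    """Fibrils broken into segments no longer than ``segment_length`` nm."""
    base = dict(fibril_segment_length=segment_length, volume_shape=(128, 640, 128))
    base.update(overrides)
    return PhantomSpec(**base)
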