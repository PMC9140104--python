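"""Automatic carotid-artery voxel selection from early dynamic frames.

The carotids are the brightest structures in the first minute after injection,
before the tracer reaches tissue.  For every axial slice below the cerebellum
the brightest early-frame voxel on each patient side is taken as a seed and
dilated in-plane with a 5x5 diamond (Manhattan radius 2), sized for a roughly
6 mm carotid diameter at typical PET resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DegenerateGeometryError, ScheduleError
from .io import DynamicImage, LabelMap

__all__ = [
    "CarotidMask",
    "select_slice_range",
    "early_intensity_volume",
    "find_seed",
    "dilate_diamond",
    "segment_carotid",
]

#: In-plane offsets of the 5x5 diamond structuring element (|dx| + |dy| <= 2).
DIAMOND_OFFSETS = tuple(
    (dx, dy)
    for dx in range(-2, 3)
    for dy in range(-2, 3)
    if abs(dx) + abs(dy) <= 2
)


@dataclass
class CarotidMask:
    """Voxels selected as carotid, with per-slice seeds and the slice range used."""

    voxels: list[tuple[int, int, int]]
    seeds: dict[int, dict[str, tuple[int, int] | None]]
    slice_range: tuple[int, int]
    shape: tuple[int, int, int]
    side_convention: str = "image-left = patient side per orientation metadata"

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def as_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        for x, y, z in self.voxels:
            vol[x, y, z] = True
        return vol

    def save(self, path: str | Path,
             voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
        nib.save(
            nib.Nifti1Image(self.as_volume().astype(np.uint8), affine), str(path)
        )


def select_slice_range(label_map: LabelMap) -> tuple[int, int]:
    """Axial slices eligible for segmentation: FOV bottom up to just below the
    cerebellum.

    Returns the inclusive range ``(0, lowest_cerebellum_slice - 1)`` along the
    inferior-superior (third) axis.
    """
    cereb = label_map.mask_for("cerebellum")
    if not cereb.any():
        raise DegenerateGeometryError("cerebellum label present but empty")
    lowest_cereb = int(np.flatnonzero(cereb.any(axis=(0, 1)))[0])
    if lowest_cereb == 0:
        raise DegenerateGeometryError(
            "cerebellum reaches the bottom of the field of view; no slices to segment"
        )
    return (0, lowest_cereb - 1)


def early_intensity_volume(image: DynamicImage, window_s: float = 60.0) -> np.ndarray:
    """Duration-weighted mean activity over frames fully inside [0, window_s].

    With the default acquisition grid the first minute is exactly the six
    initial 10-second frames.
    """
    sched = image.schedule
    inside = (sched.starts_s >= -1e-9) & (sched.ends_s <= window_s + 1e-9)
    if not inside.any():
        raise ScheduleError(f"no frame lies within the first {window_s:g} s")
    durations = sched.durations_s[inside]
    frames = image.voxels[..., inside]
    return frames @ (durations / durations.sum())


def find_seed(
    early_volume: np.ndarray,
    slice_index: int,
    side: str,
    lr_axis: int = 0,
) -> tuple[int, int] | None:
    """Brightest voxel of one half of an axial slice, or None if the half is
    all zero.

    The slice is split at the midline column of the left-right axis; the
    midline column belongs to the left half.  Ties break to the lowest linear
    (C-order) index.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    plane = early_volume[:, :, slice_index]
    if lr_axis == 1:
        plane = plane.T
    n_lr = plane.shape[0]
    mid = n_lr // 2
    if side == "left":
        half = plane[: mid + 1, :]
        x_offset = 0
    else:
        half = plane[mid + 1:, :]
        x_offset = mid + 1
    if half.size == 0 or not np.any(half > 0):
        return None
    flat = int(np.argmax(half))
    x, y = np.unravel_index(flat, half.shape)
    coord = (int(x) + x_offset, int(y))
    if lr_axis == 1:
        coord = (coord[1], coord[0])
    return coord


def dilate_diamond(
    seed: tuple[int, int], plane_shape: tuple[int, int]
) -> set[tuple[int, int]]:
    """In-plane voxels at Manhattan distance <= 2 from the seed, clipped to
    bounds.

    13 voxels for an interior seed, fewer near edges (6 at a corner).
    """
    x0, y0 = seed
    nx, ny = plane_shape
    return {
        (x0 + dx, y0 + dy)
        for dx, dy in DIAMOND_OFFSETS
        if 0 <= x0 + dx < nx and 0 <= y0 + dy < ny
    }


def segment_carotid(image: DynamicImage, label_map: LabelMap) -> CarotidMask:
    """Full carotid segmentation: seed + dilate on every slice below the
    cerebellum, both sides, union of all dilations."""
    lo, hi = select_slice_range(label_map)
    early = early_intensity_volume(image)
    lr_axis = 0 if image.orientation[0] in ("LR", "RL") else 1
    voxel_set: set[tuple[int, int, int]] = set()
    seeds: dict[int, dict[str, tuple[int, int] | None]] = {}
    plane_shape = (image.spatial_shape[0], image.spatial_shape[1])
    for z in range(lo, hi + 1):
        seeds[z] = {}
        for side in ("left", "right"):
            seed = find_seed(early, z, side, lr_axis=lr_axis)
            seeds[z][side] = seed
            if seed is None:
                continue
            for x, y in dilate_diamond(seed, plane_shape):
                voxel_set.add((x, y, z))
    return CarotidMask(
        voxels=sorted(voxel_set),
        seeds=seeds,
        slice_range=(lo, hi),
        shape=image.spatial_shape,
    )
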