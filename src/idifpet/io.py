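"""Dynamic-PET containers and file I/O.

Dynamic scans are handled as a 4D activity array (x, y, z, frame) in kBq/mL
together with an explicit frame schedule.  NIfTI carries no reliable per-frame
timing, so the schedule is a mandatory two-column TSV sidecar (``start_s``,
``end_s``).  All activities are assumed decay-corrected upstream; no decay
handling happens anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyRegionError, FormatError, SchemaError

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "LabelMap",
    "TAC",
    "BloodSampleTable",
    "TARGET_REGIONS",
    "default_frame_schedule",
    "load_dynamic",
    "save_dynamic",
    "load_label_map",
    "save_label_map",
    "extract_tac",
    "load_blood_table",
    "save_blood_table",
]

#: The nine target regions evaluated by the pipeline, plus the cerebellum
#: which doubles as the reference region.
TARGET_REGIONS = (
    "putamen",
    "caudate",
    "thalamus",
    "hippocampus",
    "frontal",
    "temporal",
    "occipital",
    "parietal",
    "cerebellum",
)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered frame intervals ``(start_s, end_s)`` defining the dynamic grid."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self):
        prev_end = -np.inf
        prev_start = -np.inf
        for start, end in self.frames:
            if not start < end:
                raise SchemaError(f"frame ({start}, {end}) has non-positive duration")
            if start < prev_end or start <= prev_start:
                raise SchemaError("frames must be non-overlapping and increasing")
            prev_start, prev_end = start, end

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def ends_s(self) -> np.ndarray:
        return np.array([e for _, e in self.frames])

    @property
    def midpoints_s(self) -> np.ndarray:
        return (self.starts_s + self.ends_s) / 2.0

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"start_s": self.starts_s, "end_s": self.ends_s}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrameSchedule":
        df = pd.read_csv(path, sep="\t")
        missing = {"start_s", "end_s"} - set(df.columns)
        if missing:
            raise FormatError(f"timing table missing columns: {sorted(missing)}")
        return cls(tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float))))


def default_frame_schedule() -> FrameSchedule:
    """The 60-minute acquisition grid: 12 x 10 s, 9 x 20 s, 5 x 60 s, 10 x 300 s.

    36 contiguous frames from t = 0, totalling 3600 s.
    """
    durations = [10.0] * 12 + [20.0] * 9 + [60.0] * 5 + [300.0] * 10
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(tuple(zip(edges[:-1], edges[1:])))


@dataclass
class DynamicImage:
    """A 4D dynamic PET volume (kBq/mL, decay-corrected) with its schedule.

    ``orientation`` labels the three array axes; the default ``("LR", "PA", "IS")``
    means first axis runs patient left to right, third axis inferior to superior.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    orientation: tuple[str, str, str] = ("LR", "PA", "IS")

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise FormatError(f"expected 4D volume, got {self.voxels.ndim}D")
        if self.voxels.shape[3] != len(self.schedule):
            raise SchemaError(
                f"{self.voxels.shape[3]} frames in image but "
                f"{len(self.schedule)} rows in timing table"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("non-finite activity values in dynamic image")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class LabelMap:
    """Integer region labels aligned voxel-for-voxel with a DynamicImage.

    Label 0 is reserved for background.
    """

    labels: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label map must be integer-valued")
        if 0 in self.region_names:
            raise SchemaError("label 0 is reserved for background")

    def label_for(self, region_name: str) -> int:
        for lbl, name in self.region_names.items():
            if name == region_name:
                return lbl
        raise EmptyRegionError(f"region {region_name!r} not in label map")

    def mask_for(self, region_name: str) -> np.ndarray:
        return self.labels == self.label_for(region_name)


@dataclass
class TAC:
    """A region (or voxel) time-activity curve sampled on frame midpoints."""

    midpoints_s: np.ndarray
    values: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self):
        self.midpoints_s = np.asarray(self.midpoints_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if not (len(self.midpoints_s) == len(self.values) == len(self.durations_s)):
            raise SchemaError("TAC fields must have equal length")
        if np.any(np.diff(self.midpoints_s) <= 0):
            raise SchemaError("TAC midpoints must be strictly increasing")

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0


@dataclass
class BloodSampleTable:
    """Arterial blood samples: time, whole-blood and plasma activity, parent fraction.

    ``parent_fraction`` entries may be NaN where no metabolite assay was run.
    """

    time_s: np.ndarray
    whole_blood_kBq_mL: np.ndarray
    plasma_kBq_mL: np.ndarray
    parent_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.whole_blood_kBq_mL = np.asarray(self.whole_blood_kBq_mL, dtype=float)
        self.plasma_kBq_mL = np.asarray(self.plasma_kBq_mL, dtype=float)
        if self.parent_fraction is None:
            self.parent_fraction = np.full_like(self.time_s, np.nan)
        else:
            self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise SchemaError("blood sample times must be strictly increasing")
        if np.any(self.whole_blood_kBq_mL < 0) or np.any(self.plasma_kBq_mL < 0):
            raise SchemaError("blood activities must be non-negative")
        pf = self.parent_fraction[np.isfinite(self.parent_fraction)]
        if np.any(pf < 0) or np.any(pf > 1):
            raise SchemaError("parent fraction must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "wb_kBq_mL": self.whole_blood_kBq_mL,
                "plasma_kBq_mL": self.plasma_kBq_mL,
                "parent_fraction": self.parent_fraction,
            }
        ).to_csv(path, sep="\t", index=False)


def load_blood_table(path: str | Path) -> BloodSampleTable:
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "wb_kBq_mL", "plasma_kBq_mL"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"blood table missing columns: {sorted(missing)}")
    pf = df["parent_fraction"].to_numpy() if "parent_fraction" in df.columns else None
    return BloodSampleTable(
        df["time_s"].to_numpy(),
        df["wb_kBq_mL"].to_numpy(),
        df["plasma_kBq_mL"].to_numpy(),
        pf,
    )


def save_blood_table(table: BloodSampleTable, path: str | Path) -> None:
    table.to_tsv(path)


def load_dynamic(image_path: str | Path, timing_path: str | Path) -> DynamicImage:
    """Load a 4D NIfTI plus its frame-timing TSV into a DynamicImage."""
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D NIfTI, got {data.ndim}D")
    schedule = FrameSchedule.from_tsv(timing_path)
    if data.shape[3] != len(schedule):
        raise SchemaError(
            f"image has {data.shape[3]} frames but timing table has "
            f"{len(schedule)} rows"
        )
    zooms = img.header.get_zooms()[:3]
    orientation = _orientation_from_affine(img.affine)
    return DynamicImage(data, tuple(float(z) for z in zooms), schedule, orientation)


def save_dynamic(image: DynamicImage, image_path: str | Path,
                 timing_path: str | Path | None = None) -> None:
    """Write a DynamicImage as 4D NIfTI (+ timing TSV if a path is given)."""
    affine = np.diag(list(image.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels, affine), str(image_path))
    if timing_path is not None:
        image.schedule.to_tsv(timing_path)


def load_label_map(path: str | Path, region_names: dict[int, str]) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    return LabelMap(labels, dict(region_names))


def save_label_map(label_map: LabelMap, path: str | Path,
                   voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(label_map.labels.astype(np.int16), affine), str(path))


def _orientation_from_affine(affine: np.ndarray) -> tuple[str, str, str]:
    """Map array axes to patient axes from the NIfTI affine.

    Falls back to the array-index convention (first axis left-to-right) when the
    affine carries no rotation information.
    """
    try:
        codes = nib.orientations.aff2axcodes(affine)
    except Exception:
        return ("LR", "PA", "IS")
    mapping = {"R": "LR", "L": "RL", "A": "PA", "P": "AP", "S": "IS", "I": "SI"}
    # aff2axcodes returns the direction each axis points TOWARD; "R" means the
    # axis runs left -> right.
    return tuple(mapping.get(c, "LR") for c in codes)  # type: ignore[return-value]


def extract_tac(image: DynamicImage, label_map: LabelMap, region_name: str) -> TAC:
    """Unweighted mean time-activity curve over the named region's voxels."""
    if label_map.labels.shape != image.spatial_shape:
        raise SchemaError(
            f"label map shape {label_map.labels.shape} does not match "
            f"image spatial shape {image.spatial_shape}"
        )
    mask = label_map.mask_for(region_name)
    if not mask.any():
        raise EmptyRegionError(f"region {region_name!r} has no voxels")
    values = image.voxels[mask].mean(axis=0)
    sched = image.schedule
    return TAC(sched.midpoints_s, values, sched.durations_s)
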