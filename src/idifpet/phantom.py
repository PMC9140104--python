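"""Synthetic dynamic-PET phantom with known ground truth.

The phantom emulates the head-and-neck field of view of a 60-minute dynamic
brain scan: two parallel carotid tubes run through the inferior slices, the
cerebellum sits directly above them, and eight further labeled brain regions
fill the superior volume.  Every voxel's time course obeys the partial-volume
mixture model exactly,

    C_i(t) = alpha_i * C_AIF(t) + (1 - alpha_i) * C_TISSUE(t),

with ``alpha_i`` a radial-Gaussian mixing fraction inside the carotid tubes
(1 at the tube axis, 0 outside) and region-specific two-tissue-compartment
curves everywhere.  Frames report the time-average of the underlying
continuous curves, plus optional seeded Gaussian noise whose variance scales
with activity over frame duration (the usual post-reconstruction PET noise
behavior), calibrated so ``noise_cv`` is the coefficient of variation at the
image peak.

Presets: the high-affinity-binder-like (HAB) and mixed-affinity-binder-like
(MAB) parameter sets share one arterial input and differ only in the binding
rate k3, giving regional distribution volumes about 35% apart — the
genotype-driven contrast the method is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateGeometryError, IdifError
from .io import (
    BloodSampleTable,
    DynamicImage,
    FrameSchedule,
    LabelMap,
    TARGET_REGIONS,
    default_frame_schedule,
)
from .kinetics import (
    DEFAULT_DT_MIN,
    FengParams,
    TwoTCParams,
    closed_form_vt,
    feng_aif,
    fine_grid,
    frame_average,
    two_tc_tissue,
)
from .calibration import MetaboliteModel, POPULATION_METABOLITE_MODEL

__all__ = [
    "PhantomTruth",
    "BloodSampleSchedule",
    "default_blood_schedule",
    "default_truth",
    "cohort_truths",
    "simulate_phantom",
    "simulate_blood_samples",
    "PHANTOM_REGION_LABELS",
]

#: Region label codes used by the phantom label map (0 = background).
PHANTOM_REGION_LABELS: dict[int, str] = {
    i + 1: name for i, name in enumerate(TARGET_REGIONS)
}

#: The arterial input shared by every preset (binding class does not change
#: the blood curve): fast bolus peaking ~15 s after a 0.5 min delay, slow tail.
_DEFAULT_FENG = FengParams(
    tau=0.5, a1=600.0, a2=12.0, a3=8.0, l1=4.0, l2=0.5, l3=0.01
)

#: Regional total distribution volumes (mL/cm^3) for the high-affinity preset.
_HAB_VT: dict[str, float] = {
    "putamen": 2.44,
    "caudate": 1.91,
    "thalamus": 2.97,
    "hippocampus": 2.61,
    "frontal": 2.70,
    "temporal": 3.45,
    "occipital": 2.96,
    "parietal": 3.13,
    "cerebellum": 3.16,
}

#: HAB-to-MAB distribution-volume ratio built into the presets (~35% contrast).
_HAB_MAB_RATIO = 1.35

_K1, _K2, _K4 = 0.15, 0.15, 0.04


def _kinetics_for_vt(vt: float) -> TwoTCParams:
    """2TC rate constants with fixed K1, k2, k4 and k3 chosen to hit a V_T."""
    k3 = _K4 * (vt * _K2 / _K1 - 1.0)
    if k3 <= 0:
        raise IdifError(f"target V_T {vt} too small for the preset K1/k2")
    return TwoTCParams(_K1, _K2, k3, _K4)


@dataclass(frozen=True)
class BloodSampleSchedule:
    """Arterial draw times in seconds, strictly increasing, first sample > 0."""

    times_s: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times_s)
        if len(t) == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise IdifError("sample times must be strictly increasing and > 0")

    def __len__(self) -> int:
        return len(self.times_s)


def default_blood_schedule(scan_minutes: float = 60.0) -> BloodSampleSchedule:
    """The standard manual-draw protocol: every 6 s for the first minute, every
    10 s for the next, per-minute through 5 min, then every 5 min to scan end.

    Draws are end-of-interval (6, 12, ... s), which yields 30 samples for a
    60-minute scan.
    """
    if scan_minutes < 5:
        raise IdifError("blood schedule requires a scan of at least 5 minutes")
    end_s = scan_minutes * 60.0
    times: list[float] = []
    times += list(np.arange(6.0, 60.0 + 1e-9, 6.0))
    times += list(np.arange(70.0, 120.0 + 1e-9, 10.0))
    times += list(np.arange(180.0, 300.0 + 1e-9, 60.0))
    times += list(np.arange(600.0, end_s + 1e-9, 300.0))
    return BloodSampleSchedule(tuple(t for t in times if t <= end_s + 1e-9))


@dataclass
class PhantomTruth:
    """Full generative ground truth of one synthetic subject."""

    feng: FengParams
    region_kinetics: dict[str, TwoTCParams]
    alpha_map: np.ndarray
    labels: np.ndarray
    noise_cv: float
    seed: int
    schedule: FrameSchedule
    dose_MBq: float = 185.0
    weight_kg: float = 75.0
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    preset: str = "HAB-like"

    def __post_init__(self):
        if self.noise_cv < 0:
            raise IdifError("noise_cv must be non-negative")
        if self.alpha_map.shape != self.labels.shape:
            raise IdifError("alpha map and label map shapes must match")
        if np.any((self.alpha_map < 0) | (self.alpha_map > 1)):
            raise IdifError("mixing fractions must lie in [0, 1]")

    @property
    def label_map(self) -> LabelMap:
        return LabelMap(self.labels, dict(PHANTOM_REGION_LABELS))

    def true_vt(self, region: str) -> float:
        return closed_form_vt(self.region_kinetics[region])


def _build_geometry(
    shape: tuple[int, int, int],
    tube_top_z: int,
    tube_radius_vox: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha map (carotid tubes) and label map (cerebellum + 8 regions)."""
    nx, ny, nz = shape
    if nz < tube_top_z + 10 or nx < 24 or ny < 24:
        raise DegenerateGeometryError(
            f"grid {shape} too small for carotid tubes plus brain regions"
        )
    alpha = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)

    # two carotid tubes along z in the inferior slices, one per side
    centers = [(nx // 4, ny // 2), (3 * nx // 4, ny // 2)]
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sigma = tube_radius_vox / 2.0
    for cx, cy in centers:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        profile = np.where(r2 <= tube_radius_vox**2, np.exp(-r2 / (2 * sigma**2)), 0.0)
        for z in range(tube_top_z):
            alpha[:, :, z] = np.maximum(alpha[:, :, z], profile)

    region_codes = {name: code for code, name in PHANTOM_REGION_LABELS.items()}
    # cerebellum: a slab directly above the carotid slices
    cz0, cz1 = tube_top_z, tube_top_z + 5
    labels[nx // 4 : 3 * nx // 4, ny // 4 : 3 * ny // 4, cz0:cz1] = region_codes[
        "cerebellum"
    ]
    # eight target regions: 2 x 2 x 2 blocks of the supratentorial volume
    others = [r for r in TARGET_REGIONS if r != "cerebellum"]
    bz0 = cz1 + 1
    z_edges = [bz0, (bz0 + nz) // 2, nz]
    x_edges = [2, nx // 2, nx - 2]
    y_edges = [2, ny // 2, ny - 2]
    idx = 0
    for zi in range(2):
        for xi in range(2):
            for yi in range(2):
                name = others[idx]
                labels[
                    x_edges[xi] : x_edges[xi + 1],
                    y_edges[yi] : y_edges[yi + 1],
                    z_edges[zi] : z_edges[zi + 1],
                ] = region_codes[name]
                idx += 1
    return alpha, labels


def default_truth(
    preset: str = "HAB-like",
    seed: int = 0,
    noise_cv: float = 0.05,
    shape: tuple[int, int, int] = (48, 48, 40),
    schedule: FrameSchedule | None = None,
    subject_cv: float = 0.0,
) -> PhantomTruth:
    """Documented phantom presets for the two binding-affinity classes.

    Both presets share the same arterial input; only the binding rate k3
    differs, scaling every regional V_T by ~1.35 between classes.
    ``subject_cv`` adds seeded lognormal between-subject variation to K1 and
    k3 (used to build cohorts).
    """
    if preset not in ("HAB-like", "MAB-like"):
        raise IdifError(f"unknown preset {preset!r}")
    schedule = schedule or default_frame_schedule()
    kin: dict[str, TwoTCParams] = {}
    rng = np.random.default_rng(seed)
    for region in TARGET_REGIONS:
        vt = _HAB_VT[region]
        if preset == "MAB-like":
            vt = vt / _HAB_MAB_RATIO
        k = _kinetics_for_vt(vt)
        if subject_cv > 0:
            jitter = rng.lognormal(mean=0.0, sigma=subject_cv, size=2)
            k = TwoTCParams(k.k1 * jitter[0], k.k2, k.k3 * jitter[1], k.k4)
        kin[region] = k
    # surrounding neck tissue: low uptake, fast clearance
    kin["background"] = TwoTCParams(0.10, 0.25, 0.02, 0.04)
    alpha, labels = _build_geometry(shape, tube_top_z=16, tube_radius_vox=2.0)
    return PhantomTruth(
        feng=_DEFAULT_FENG,
        region_kinetics=kin,
        alpha_map=alpha,
        labels=labels,
        noise_cv=noise_cv,
        seed=seed,
        schedule=schedule,
        preset=preset,
    )


def cohort_truths(
    preset: str,
    n_subjects: int,
    seed: int = 0,
    subject_cv: float = 0.08,
    **kwargs,
) -> list[PhantomTruth]:
    """A cohort of phantom subjects with between-subject kinetic variation."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        default_truth(preset, seed=int(s), subject_cv=subject_cv, **kwargs)
        for s in seeds
    ]


def simulate_phantom(
    truth: PhantomTruth, dt_min: float = DEFAULT_DT_MIN
) -> tuple[DynamicImage, LabelMap, PhantomTruth]:
    """Render the phantom into a dynamic image (plus its label map).

    Noise-free voxel values are exactly the frame-averaged mixture curves;
    with ``noise_cv > 0`` seeded Gaussian noise is added with variance
    proportional to activity over frame duration.
    """
    sched = truth.schedule
    t_end = sched.ends_s[-1] / 60.0
    grid = fine_grid(t_end, dt_min)
    aif_frames = frame_average(grid, feng_aif(truth.feng, grid), sched)

    region_frames: dict[int, np.ndarray] = {}
    for code, name in PHANTOM_REGION_LABELS.items():
        curve = two_tc_tissue(truth.feng, truth.region_kinetics[name], grid)
        region_frames[code] = frame_average(grid, curve, sched)
    bg_curve = two_tc_tissue(truth.feng, truth.region_kinetics["background"], grid)
    region_frames[0] = frame_average(grid, bg_curve, sched)

    shape = truth.labels.shape
    m = len(sched)
    vol = np.empty(shape + (m,))
    for code, frames in region_frames.items():
        vol[truth.labels == code] = frames
    # carotid mixing: tube voxels blend the AIF with the surrounding neck tissue
    tube = truth.alpha_map > 0
    a = truth.alpha_map[tube][:, None]
    vol[tube] = a * aif_frames[None, :] + (1 - a) * region_frames[0][None, :]

    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        flat_peak = np.unravel_index(np.argmax(vol), vol.shape)
        v_peak = vol[flat_peak]
        dur_peak = sched.durations_s[flat_peak[-1]]
        c = truth.noise_cv * np.sqrt(v_peak * dur_peak)
        sd = c * np.sqrt(np.maximum(vol, 0.0) / sched.durations_s[None, None, None, :])
        vol = vol + rng.standard_normal(vol.shape) * sd
        vol = np.maximum(vol, 0.0)

    image = DynamicImage(vol, truth.voxel_size_mm, sched)
    return image, truth.label_map, truth


def simulate_blood_samples(
    truth: PhantomTruth,
    schedule: BloodSampleSchedule | None = None,
    metabolite_model: MetaboliteModel | None = None,
) -> BloodSampleTable:
    """Arterial samples drawn from the true input function.

    Whole blood is the Feng curve evaluated at the draw times (point draws,
    no frame averaging).  Plasma ratio and parent fraction are generated as
    equal square-root shares of the configured composite-fraction model, so
    their product reproduces it exactly.
    """
    schedule = schedule or default_blood_schedule(
        truth.schedule.ends_s[-1] / 60.0
    )
    mm = metabolite_model or POPULATION_METABOLITE_MODEL
    t_s = np.asarray(schedule.times_s)
    t_min = t_s / 60.0
    wb = np.asarray(feng_aif(truth.feng, t_min))
    composite = np.asarray(mm.multiplier(t_min))
    share = np.sqrt(composite)
    plasma = wb * share
    parent = share
    return BloodSampleTable(t_s, wb, plasma, parent)
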