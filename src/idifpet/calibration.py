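"""Unit restoration and metabolite correction of the extracted input function.

The factorization returns the arterial component in a normalized,
dimensionless form (frame values summing to one).  Because each voxel's true
activity is a convex mixture ``alpha * C_AIF + (1 - alpha) * C_TISSUE``, the
estimated per-voxel weights — once expressed against the *physical* component
curves — must sum to one.  The scaling step exploits exactly this: find the
pair of scalars ``(s_AIF, s_TISSUE)`` that brings the weight rows closest to
summing to one in least squares,

    min_{s} sum_i (w_i,AIF * s_AIF + w_i,TISSUE * s_TISSUE - 1)^2 .

This objective is linear least squares in the two scales and is solved in
closed form; a trust-region numerical path is kept for parity checks.  Note
the objective as written estimates the *reciprocal* of the multiplicative
scale that converts the normalized curve into physical units (substituting
u = 1/s turns it into the equivalent "divide the weights" form), so
:func:`scale_idif` inverts when given factors in the default convention; both
conventions produce the same physical input function.

The scaled curve is whole-blood activity.  A population metabolite model then
converts it to metabolite-corrected plasma concentration by the multiplier

    m(t) = 1 - a (1 - exp(-b t)),   t in minutes,

with population defaults a = 0.29, b = 0.03 /min, or with (a, b) refit from
cohort blood tables (parent fraction times plasma-to-whole-blood ratio,
averaged per time point, fitted by nonlinear least squares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import InsufficientDataError, NonIdentifiableError, StateError
from .io import BloodSampleTable
from .mbmf import MBMFResults

__all__ = [
    "ScalingFactors",
    "MetaboliteModel",
    "InputFunction",
    "POPULATION_METABOLITE_MODEL",
    "optimize_scaling",
    "scale_idif",
    "fit_composite_fraction",
    "apply_metabolite_correction",
]

#: States an InputFunction moves through, in order.
_STATES = ("normalized", "whole_blood", "metab_corrected_plasma")


@dataclass(frozen=True)
class ScalingFactors:
    """Optimal component scales from the weight-sum-to-one objective.

    ``convention`` records which side of the objective the scales sit on:
    ``"as_printed"`` multiplies the weights (the default objective above), in
    which case the multiplicative unit-restoring scale is ``1/s``;
    ``"reciprocal"`` divides the weights, making ``s`` itself the
    unit-restoring scale.  The two closed forms are exact reciprocals.
    """

    s_aif: float
    s_tissue: float
    objective_value: float
    convention: str = "as_printed"

    def __post_init__(self):
        if self.convention not in ("as_printed", "reciprocal"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def aif_multiplier(self) -> float:
        """The factor that converts the normalized arterial curve to physical
        whole-blood units."""
        return self.s_aif if self.convention == "reciprocal" else 1.0 / self.s_aif


@dataclass(frozen=True)
class MetaboliteModel:
    """Population composite-fraction model ``1 - a (1 - exp(-b t))``.

    ``a`` is the long-time deficit (dimensionless), ``b`` the approach rate in
    1/min.  The multiplier stays within ``[1 - a, 1]`` for all t >= 0.
    """

    a: float
    b: float
    source: str = "population-default"

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("amplitude a must lie in [0, 1]")
        if self.b < 0:
            raise ValueError("rate b must be non-negative")

    def multiplier(self, t_min: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_min, dtype=float)
        out = 1.0 - self.a * (1.0 - np.exp(-self.b * t))
        return float(out) if np.isscalar(t_min) else out


#: Shipped population defaults for the tracer's composite fraction.
POPULATION_METABOLITE_MODEL = MetaboliteModel(a=0.29, b=0.03)


@dataclass
class InputFunction:
    """A time-activity input curve with an explicit unit state.

    States advance only forward: normalized -> whole_blood ->
    metab_corrected_plasma.
    """

    times_min: np.ndarray
    values: np.ndarray
    state: str

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in _STATES:
            raise StateError(f"unknown input-function state {self.state!r}")
        if len(self.times_min) != len(self.values):
            raise StateError("times and values must have equal length")
        if np.any(self.values < -1e-12):
            raise StateError("input function values must be non-negative")

    def interp(self, t_min: np.ndarray) -> np.ndarray:
        """Linear interpolation, zero before the first sample's rise from 0."""
        return np.interp(np.asarray(t_min, dtype=float), self.times_min,
                         self.values, left=0.0)


def optimize_scaling(
    W: np.ndarray,
    convention: str = "as_printed",
    method: str = "closed_form",
    clip_range: tuple[float, float] = (0.01, 100.0),
    strict: bool = False,
) -> ScalingFactors:
    """Scales that bring per-voxel weight rows closest to summing to one.

    ``method="closed_form"`` solves the linear least-squares problem directly;
    ``method="numeric"`` runs a trust-region solver on the same objective and
    exists for parity testing.  Scales falling outside ``clip_range`` are
    flagged with a warning (error in ``strict`` mode).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != 2 or W.shape[0] < 2:
        raise NonIdentifiableError("W must be n x 2 with n >= 2")
    sv = np.linalg.svd(W, compute_uv=False)
    if sv[-1] <= 1e-10 * max(sv[0], 1e-300):
        raise NonIdentifiableError(
            "weight columns are proportional; scaling factors are not identifiable"
        )
    ones = np.ones(W.shape[0])
    if method == "closed_form":
        s, *_ = np.linalg.lstsq(W, ones, rcond=None)
    elif method == "numeric":
        s0 = np.linalg.lstsq(W, ones, rcond=None)[0]
        sol = least_squares(lambda s: W @ s - ones, 0.9 * s0 + 0.1,
                            method="trf", xtol=1e-14, ftol=1e-14)
        s = sol.x
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = float(np.sum((W @ s - ones) ** 2))
    s_aif, s_tis = float(s[0]), float(s[1])
    if convention == "reciprocal":
        if s_aif == 0 or s_tis == 0:
            raise NonIdentifiableError("zero scale cannot be inverted")
        s_aif, s_tis = 1.0 / s_aif, 1.0 / s_tis
    lo, hi = clip_range
    for name, val in (("s_aif", s_aif), ("s_tissue", s_tis)):
        if not (lo <= val <= hi):
            msg = f"implausible scaling factor {name} = {val:.4g} (outside [{lo}, {hi}])"
            if strict:
                raise NonIdentifiableError(msg)
            warnings.warn(msg, stacklevel=2)
    return ScalingFactors(s_aif, s_tis, resid, convention=convention)


def scale_idif(fr: MBMFResults, s: ScalingFactors) -> InputFunction:
    """Restore the normalized arterial component to whole-blood activity units."""
    values = s.aif_multiplier * fr.normalized_aif
    return InputFunction(
        times_min=fr.schedule.midpoints_s / 60.0,
        values=values,
        state="whole_blood",
    )


def fit_composite_fraction(
    tables: list[BloodSampleTable],
    sample_times_min: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0),
    time_tol_min: float = 0.51,
) -> MetaboliteModel:
    """Fit the population composite-fraction model from cohort blood tables.

    For each subject the composite fraction is parent_fraction times the
    plasma-to-whole-blood activity ratio at the standard assay times; subjects
    missing any assay time are dropped with a warning.  The per-time-point
    cohort means are fitted to ``1 - a (1 - exp(-b t))``.
    """
    targets = np.asarray(sample_times_min, dtype=float)
    per_subject = []
    for idx, tab in enumerate(tables):
        t_min = tab.time_s / 60.0
        row = np.full(len(targets), np.nan)
        for j, tt in enumerate(targets):
            hits = np.flatnonzero(np.abs(t_min - tt) <= time_tol_min)
            hits = [h for h in hits if np.isfinite(tab.parent_fraction[h])
                    and tab.whole_blood_kBq_mL[h] > 0]
            if hits:
                h = hits[0]
                row[j] = tab.parent_fraction[h] * (
                    tab.plasma_kBq_mL[h] / tab.whole_blood_kBq_mL[h]
                )
        if np.all(np.isfinite(row)):
            per_subject.append(row)
        else:
            warnings.warn(
                f"subject {idx}: missing metabolite assay time point; dropped",
                stacklevel=2,
            )
    if not per_subject:
        raise InsufficientDataError("no subject has a complete metabolite assay")
    mean_fraction = np.mean(per_subject, axis=0)
    if len(np.unique(targets)) < 2:
        raise InsufficientDataError("need at least two distinct assay times")

    def model(t, a, b):
        return 1.0 - a * (1.0 - np.exp(-b * t))

    (a, b), _ = curve_fit(
        model, targets, mean_fraction,
        p0=(0.3, 0.05), bounds=([0.0, 0.0], [1.0, 10.0]), maxfev=20000,
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    return MetaboliteModel(float(a), float(b), source="fitted")


def apply_metabolite_correction(
    idif: InputFunction, mm: MetaboliteModel | None = None
) -> InputFunction:
    """Convert a whole-blood input function to metabolite-corrected plasma."""
    if idif.state != "whole_blood":
        raise StateError(
            f"metabolite correction requires whole_blood state, got {idif.state!r}"
        )
    mm = mm or POPULATION_METABOLITE_MODEL
    values = idif.values * mm.multiplier(idif.times_min)
    return InputFunction(idif.times_min, values, "metab_corrected_plasma")
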