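"""Parametric kinetic models: Feng arterial input and two-tissue-compartment tissue.

These are the generative building blocks of the model-based matrix
factorization.  The arterial input function (AIF) follows the Feng 7-parameter
form — a linear-rise term times a fast exponential plus two slower decaying
exponentials, all delayed by ``tau``:

    C_AIF(t) = (A1 (t - tau) - A2 - A3) exp(-l1 (t - tau))
             + A2 exp(-l2 (t - tau)) + A3 exp(-l3 (t - tau)),   t > tau

and 0 for t <= tau (the curve is continuous at tau, where the terms cancel).

Tissue activity is the convolution of the AIF with the two-tissue-compartment
impulse response

    h(t) = K1 / (B2 - B1) [ (k3 + k4 - B1) exp(-B1 t) + (B2 - k3 - k4) exp(-B2 t) ]

where B1 <= B2 are the eigen-rates, the roots of
s^2 - (k2 + k3 + k4) s + k2 k4.  Convolution is evaluated numerically on a
uniform fine grid (default 0.1 s) with trapezoid quadrature; time is handled
internally in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import fftconvolve

from .errors import CoverageError, ParameterError
from .io import FrameSchedule

__all__ = [
    "FengParams",
    "TwoTCParams",
    "ParameterSet",
    "feng_aif",
    "eigenrates",
    "two_tc_impulse",
    "two_tc_tissue",
    "fine_grid",
    "convolve_fine",
    "frame_average",
    "sample_at_midpoints",
    "closed_form_vt",
]

#: Default fine-grid resolution for convolution and frame averaging, minutes.
DEFAULT_DT_MIN = 0.1 / 60.0

#: Tolerance on |B2 - B1| below which the repeated-root limit is used.
REPEATED_ROOT_TOL = 1e-9


@dataclass(frozen=True)
class FengParams:
    """Feng AIF parameters. Rates in 1/min, delay ``tau`` in minutes.

    ``a1`` carries units of activity/min (it scales the linear rise); ``a2``
    and ``a3`` carry activity units.
    """

    tau: float
    a1: float
    a2: float
    a3: float
    l1: float
    l2: float
    l3: float

    def __post_init__(self):
        if not (self.l1 > self.l2 > self.l3 >= 0):
            raise ParameterError(
                f"require l1 > l2 > l3 >= 0, got ({self.l1}, {self.l2}, {self.l3})"
            )
        if self.a1 <= 0:
            raise ParameterError("a1 must be positive")
        if self.tau < 0:
            raise ParameterError("tau must be non-negative")


@dataclass(frozen=True)
class TwoTCParams:
    """Two-tissue-compartment rate constants.

    ``k1`` in mL·cm^-3·min^-1 (plasma-to-tissue delivery); ``k2``, ``k3``,
    ``k4`` in 1/min.
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.k1 > 0 and self.k2 <= 0:
            raise ParameterError("k2 must be positive when k1 > 0")
        if self.discriminant < 0:
            raise ParameterError("negative eigen-rate discriminant")

    @property
    def discriminant(self) -> float:
        return (self.k2 + self.k3 + self.k4) ** 2 - 4.0 * self.k2 * self.k4


@dataclass(frozen=True)
class ParameterSet:
    """The full 11-parameter set of the factorization: AIF + tissue kinetics."""

    feng: FengParams
    tissue: TwoTCParams

    def to_dict(self) -> dict:
        return {"feng": asdict(self.feng), "tissue": asdict(self.tissue)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(FengParams(**d["feng"]), TwoTCParams(**d["tissue"]))


def feng_aif(p: FengParams, t_min: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the Feng AIF at time(s) ``t_min`` (minutes). Zero for t <= tau."""
    t = np.asarray(t_min, dtype=float)
    ts = t - p.tau
    with np.errstate(over="ignore"):
        out = np.where(
            ts > 0,
            (p.a1 * ts - p.a2 - p.a3) * np.exp(-p.l1 * np.maximum(ts, 0.0))
            + p.a2 * np.exp(-p.l2 * np.maximum(ts, 0.0))
            + p.a3 * np.exp(-p.l3 * np.maximum(ts, 0.0)),
            0.0,
        )
    if np.isscalar(t_min):
        return float(out)
    return out


def eigenrates(k: TwoTCParams) -> tuple[float, float]:
    """Eigen-rates (B1, B2) of the 2TC system, B1 <= B2.

    B1 + B2 = k2 + k3 + k4 and B1 * B2 = k2 * k4 (Vieta).
    """
    s = k.k2 + k.k3 + k.k4
    root = math.sqrt(k.discriminant)
    b1 = 0.5 * (s - root)
    b2 = 0.5 * (s + root)
    return (max(b1, 0.0), b2)


def two_tc_impulse(k: TwoTCParams, t_min: np.ndarray) -> np.ndarray:
    """The 2TC impulse response on a time grid (minutes).

    Uses the analytic repeated-root limit when B1 == B2 within tolerance.
    """
    t = np.asarray(t_min, dtype=float)
    b1, b2 = eigenrates(k)
    if abs(b2 - b1) < REPEATED_ROOT_TOL:
        b = 0.5 * (b1 + b2)
        return k.k1 * np.exp(-b * t) * (1.0 + (k.k3 + k.k4 - b) * t)
    c = k.k1 / (b2 - b1)
    return c * (
        (k.k3 + k.k4 - b1) * np.exp(-b1 * t) + (b2 - k.k3 - k.k4) * np.exp(-b2 * t)
    )


def fine_grid(t_end_min: float, dt_min: float = DEFAULT_DT_MIN) -> np.ndarray:
    """Uniform time grid [0, t_end] in minutes at resolution ``dt_min``."""
    n = int(round(t_end_min / dt_min))
    return np.linspace(0.0, n * dt_min, n + 1)


def convolve_fine(f: np.ndarray, g: np.ndarray, dt_min: float) -> np.ndarray:
    """Causal convolution (f * g)(t) on a shared uniform grid, trapezoid rule."""
    n = len(f)
    full = fftconvolve(f, g)[:n]
    # trapezoid end-point correction: subtract half of the two boundary terms
    out = dt_min * (full - 0.5 * (f[0] * g[:n] + g[0] * f[:n]))
    return out


def two_tc_tissue(
    feng: FengParams,
    k: TwoTCParams,
    t_min: np.ndarray,
) -> np.ndarray:
    """Tissue activity C_TISSUE on a uniform grid: AIF convolved with h(t)."""
    t = np.asarray(t_min, dtype=float)
    if len(t) < 2:
        raise CoverageError("tissue evaluation needs at least two grid points")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-8):
        raise CoverageError("two_tc_tissue requires a uniform time grid")
    if k.k1 == 0:
        return np.zeros_like(t)
    aif = feng_aif(feng, t)
    h = two_tc_impulse(k, t - t[0])
    out = convolve_fine(np.asarray(aif), h, dt)
    return np.maximum(out, 0.0)


def frame_average(
    t_min: np.ndarray, values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Per-frame time-average of a fine-grid curve over each frame interval.

    The fine grid must cover the whole schedule.  Integration is trapezoid on
    the grid with linear interpolation at frame edges.
    """
    t = np.asarray(t_min, dtype=float)
    v = np.asarray(values, dtype=float)
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    if starts[0] < t[0] - 1e-12 or ends[-1] > t[-1] + 1e-12:
        raise CoverageError(
            f"grid [{t[0]}, {t[-1]}] min does not cover schedule "
            f"[{starts[0]}, {ends[-1]}] min"
        )
    # running integral at grid nodes, then interpolate at frame edges
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    f_start = np.interp(starts, t, cum)
    f_end = np.interp(ends, t, cum)
    return (f_end - f_start) / (ends - starts)


def sample_at_midpoints(
    t_min: np.ndarray, values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Alternative to frame averaging: sample the curve at frame midpoints."""
    mids = schedule.midpoints_s / 60.0
    t = np.asarray(t_min, dtype=float)
    if mids[0] < t[0] - 1e-12 or mids[-1] > t[-1] + 1e-12:
        raise CoverageError("grid does not cover frame midpoints")
    return np.interp(mids, t, np.asarray(values, dtype=float))


def closed_form_vt(k: TwoTCParams) -> float:
    """Total distribution volume of the reversible 2TC model: K1/k2 (1 + k3/k4)."""
    if k.k2 <= 0:
        raise ParameterError("k2 must be positive for a distribution volume")
    if k.k3 == 0:
        return k.k1 / k.k2
    if k.k4 <= 0:
        raise ParameterError("k4 = 0 with k3 > 0: irreversible model has no V_T")
    return k.k1 / k.k2 * (1.0 + k.k3 / k.k4)
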