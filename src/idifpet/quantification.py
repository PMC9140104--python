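"""Logan graphical analysis, SUV, and the group-comparison statistics.

For reversible tracers the Logan plot linearizes kinetics after an
equilibration time t*: plotting

    y(t) = int_0^t C_tissue dt' / C_tissue(t)
    x(t) = int_0^t C_input  dt' / C_tissue(t)

the points fall on a line of slope V_T (total distribution volume) for
t >= t*.  With a reference-region curve in place of the blood input the slope
is the distribution volume ratio (here reported without a k2' correction
term).  The default linear window runs from the 30th to the 60th minute;
frames participate when their midpoint reaches t*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import InputFunction
from .errors import IdifError, InsufficientDataError
from .io import TAC, FrameSchedule

__all__ = [
    "LoganFit",
    "logan_vt",
    "logan_ref",
    "integrate_tac",
    "running_integral",
    "compute_suv",
    "percent_error",
    "compare_groups",
    "RegionResultTable",
]


@dataclass(frozen=True)
class LoganFit:
    """Result of a Logan linear fit: slope = distribution volume (mL/cm^3)."""

    vt: float
    intercept: float
    r_squared: float
    n_points: int
    t_star_min: float

    def __post_init__(self):
        if self.n_points < 3:
            raise InsufficientDataError("Logan fit needs at least 3 points")


def running_integral(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral from time 0 with a leading triangle.

    The first sample contributes a triangle from (0, 0) up to (t_0, v_0),
    the natural convention for decay-corrected activity that starts at zero
    at injection.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) == 0:
        return np.array([])
    out = np.empty_like(v)
    out[0] = 0.5 * t[0] * v[0]
    if len(t) > 1:
        out[1:] = out[0] + np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))
    return out


def integrate_tac(tac: TAC, t_min: float | None = None) -> float | np.ndarray:
    """Running integral of a TAC (minutes x activity).

    With ``t_min`` given, returns the integral up to that time (linear
    interpolation of the running integral); otherwise the full running
    integral at the TAC midpoints.
    """
    cum = running_integral(tac.midpoints_min, tac.values)
    if t_min is None:
        return cum
    return float(np.interp(t_min, tac.midpoints_min, cum))


def _logan_points(
    tissue: TAC, input_t: np.ndarray, input_v: np.ndarray, t_star_min: float
) -> tuple[np.ndarray, np.ndarray, int]:
    t_tis = tac_minutes = tissue.midpoints_min
    ct = tissue.values
    int_tis = running_integral(tac_minutes, ct)
    cum_inp = running_integral(input_t, input_v)
    int_inp = np.interp(t_tis, input_t, cum_inp)
    window = t_tis >= t_star_min - 1e-9
    n = int(window.sum())
    if n < 3:
        raise InsufficientDataError(
            f"only {n} frames with midpoint >= {t_star_min} min"
        )
    ct_w = ct[window]
    if np.any(ct_w <= 0):
        raise IdifError("zero or negative tissue activity inside the Logan window")
    y = int_tis[window] / ct_w
    x = int_inp[window] / ct_w
    return x, y, n


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return float(slope), float(intercept), r2


def logan_vt(
    tissue: TAC,
    input_function: InputFunction,
    t_star_min: float = 30.0,
    allow_whole_blood: bool = True,
) -> LoganFit:
    """Logan distribution volume of a tissue TAC against a blood input.

    The input is expected in the metabolite-corrected plasma state;
    whole-blood inputs are accepted for sensitivity analyses unless
    ``allow_whole_blood`` is False.
    """
    if input_function.state == "normalized":
        raise IdifError("input function must be scaled to activity units first")
    if input_function.state == "whole_blood" and not allow_whole_blood:
        raise IdifError("whole-blood input rejected (metabolite-corrected required)")
    x, y, n = _logan_points(
        tissue, input_function.times_min, input_function.values, t_star_min
    )
    slope, intercept, r2 = _line_fit(x, y)
    return LoganFit(slope, intercept, r2, n, t_star_min)


def logan_ref(tissue: TAC, reference: TAC, t_star_min: float = 30.0) -> LoganFit:
    """Reference-region Logan slope (distribution volume ratio, no k2' term)."""
    window = reference.midpoints_min >= t_star_min - 1e-9
    if np.any(reference.values[window] <= 0):
        raise IdifError("reference TAC must be strictly positive in the window")
    x, y, n = _logan_points(
        tissue, reference.midpoints_min, reference.values, t_star_min
    )
    slope, intercept, r2 = _line_fit(x, y)
    return LoganFit(slope, intercept, r2, n, t_star_min)


def compute_suv(
    tac: TAC,
    dose_MBq: float,
    weight_kg: float,
    window_min: tuple[float, float] = (40.0, 60.0),
) -> float:
    """Standardized uptake value over a late time window.

    Duration-weighted mean activity (kBq/mL) over frames whose midpoints fall
    in the window, divided by injected dose per body weight (kBq/g, tissue
    density 1 g/mL).
    """
    if dose_MBq <= 0 or weight_kg <= 0:
        raise IdifError("dose and weight must be positive")
    lo, hi = window_min
    mids = tac.midpoints_min
    inside = (mids >= lo - 1e-9) & (mids <= hi + 1e-9)
    if not inside.any():
        raise IdifError(f"no frame midpoint inside SUV window [{lo}, {hi}] min")
    w = tac.durations_s[inside]
    mean_activity = float(np.average(tac.values[inside], weights=w))
    dose_kBq = dose_MBq * 1000.0
    weight_g = weight_kg * 1000.0
    return mean_activity / (dose_kBq / weight_g)


def percent_error(vt_test: float, vt_ref: float) -> float:
    """Signed percent error of a test value against a gold-standard value."""
    if vt_ref <= 0:
        raise IdifError("reference value must be positive")
    return 100.0 * (vt_test - vt_ref) / vt_ref


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """Unpaired two-sample t-test plus percent difference of group means.

    Returns ``(t_statistic, p_value, 100 * (mean_a - mean_b) / mean_b)``.
    Equal-variance (pooled) test by default; pass ``equal_var=False`` for
    Welch.  Two degenerate zero-variance groups with equal means give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least two values")
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, pct
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, pct
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p_val), pct


class RegionResultTable:
    """Long-format per-region results: (subject, region, metric, value)."""

    METRICS = ("VT_AIF", "VT_IDIF", "VT_REF", "SUV")

    def __init__(self, rows: list[dict] | None = None):
        self._rows: list[dict] = list(rows or [])

    def add(self, subject: str, region: str, metric: str, value: float) -> None:
        if metric not in self.METRICS:
            raise IdifError(f"unknown metric {metric!r}")
        self._rows.append(
            {"subject": subject, "region": region, "metric": metric,
             "value": float(value)}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows,
                            columns=["subject", "region", "metric", "value"])

    def values(self, metric: str, region: str | None = None) -> np.ndarray:
        df = self.to_frame()
        sel = df["metric"] == metric
        if region is not None:
            sel &= df["region"] == region
        return df.loc[sel, "value"].to_numpy()

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self._rows)
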