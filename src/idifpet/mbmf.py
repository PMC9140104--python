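"""Model-based matrix factorization (MBMF) of the carotid voxel matrix.

The n x m matrix ``A`` of segmented-voxel activities (rows = voxels, columns =
frames) is factorized as ``A ~ W H`` where ``H`` is a 2 x m matrix whose rows
are the frame-averaged arterial input curve and surrounding-tissue curve, and
``W`` is an n x 2 weight matrix of per-voxel mixing weights.  Unlike blind
factorizations, both rows of ``H`` are generated by parametric physiological
models — the Feng arterial input function and the two-tissue-compartment
response it drives — so the factorization reduces to estimating the
11-parameter set {tau, A1, A2, A3, l1, l2, l3, K1, k2, k3, k4}.  For any
candidate parameter set, ``W`` is the exact least-squares solution given
``H``; the outer problem minimizes the squared Frobenius residual
``||W H - A||^2`` with a bound-constrained trust-region-reflective solver and
multi-start initialization.

After convergence both rows of ``H`` are normalized to unit frame-sum (with
``W`` rescaled so ``W H`` is unchanged), giving the normalized, dimensionless
component curves whose physical scale is restored downstream by the scaling
optimization.

The module follows the Model/Results convention: build an :class:`MBMF` model
from a :class:`VoxelMatrix`, call :meth:`MBMF.fit`, and read estimates off the
returned :class:`MBMFResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.stats import qmc

from .errors import ConvergenceError, DegenerateFactorError, IdifError
from .io import DynamicImage, FrameSchedule
from .kinetics import (
    DEFAULT_DT_MIN,
    FengParams,
    ParameterSet,
    TwoTCParams,
    feng_aif,
    fine_grid,
    frame_average,
    sample_at_midpoints,
    two_tc_tissue,
)
from .segmentation import CarotidMask

__all__ = [
    "VoxelMatrix",
    "MBMFConfig",
    "MBMF",
    "MBMFResults",
    "build_matrix",
    "solve_weights",
    "mbmf_objective",
    "fit_mbmf",
]


@dataclass
class VoxelMatrix:
    """Segmented-voxel activity matrix: rows = voxels, columns = frames."""

    A: np.ndarray
    coords: list[tuple[int, int, int]]
    schedule: FrameSchedule

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise IdifError("voxel matrix must be 2D")
        if self.A.shape[0] < 2:
            raise IdifError("need at least two segmented voxels")
        if self.A.shape[1] != len(self.schedule):
            raise IdifError("column count must equal schedule length")
        if not np.all(np.isfinite(self.A)):
            raise IdifError("non-finite entries in voxel matrix")

    @property
    def n_voxels(self) -> int:
        return self.A.shape[0]

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]


def build_matrix(image: DynamicImage, mask: CarotidMask) -> VoxelMatrix:
    """Stack the masked voxels' time courses into an n x m matrix.

    Row order follows the mask's voxel order.
    """
    if mask.n_voxels == 0:
        raise IdifError("carotid mask is empty")
    rows = np.stack([image.voxels[x, y, z, :] for x, y, z in mask.voxels])
    return VoxelMatrix(rows, list(mask.voxels), image.schedule)


def solve_weights(H: np.ndarray, A: np.ndarray, nonneg: bool = False) -> np.ndarray:
    """Per-voxel least-squares weights W minimizing ||W H - A||^2 (no sign
    constraint by default).

    Raises DegenerateFactorError when H is numerically rank-deficient.
    """
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    G = H @ H.T
    # relative rank check on the 2x2 Gram matrix
    sv = np.linalg.svd(G, compute_uv=False)
    if sv[-1] <= 1e-12 * max(sv[0], 1e-300):
        raise DegenerateFactorError("component matrix H is rank-deficient")
    if nonneg:
        W = np.empty((A.shape[0], H.shape[0]))
        for i in range(A.shape[0]):
            W[i], _ = nnls(H.T, A[i])
        return W
    return np.linalg.solve(G, H @ A.T).T


@dataclass
class MBMFConfig:
    """Tunable knobs of the factorization.

    ``n_starts`` multi-start count (seeded Latin hypercube after one
    data-driven start); ``dt_min`` fine-grid resolution in minutes for model
    evaluation; ``frame_sampling`` either ``"average"`` (time-average of the
    model over each frame) or ``"midpoint"``; ``frame_weighting`` either
    ``"inverse_variance"`` (default; per-frame weights from the PET noise
    model, sd proportional to sqrt(activity / duration), which anchors the
    low-noise late frames) or ``"none"`` for the plain Frobenius norm;
    ``ftol`` relative residual change declaring convergence; ``max_nfev``
    objective-evaluation cap per start.
    """

    n_starts: int = 8
    seed: int = 0
    dt_min: float = DEFAULT_DT_MIN
    frame_sampling: str = "average"
    frame_weighting: str = "inverse_variance"
    nonneg_weights: bool = False
    ftol: float = 1e-8
    max_nfev: int = 600
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_sampling not in ("average", "midpoint"):
            raise IdifError("frame_sampling must be 'average' or 'midpoint'")
        if self.frame_weighting not in ("inverse_variance", "none"):
            raise IdifError("frame_weighting must be 'inverse_variance' or 'none'")


# Internal optimization vector: the three decay rates are reparameterized as
# l3 plus positive gaps (l2 = l3 + d2, l1 = l2 + d1) so l1 > l2 > l3 holds by
# construction inside the box bounds.
_PARAM_NAMES = ("tau", "a1", "a2", "a3", "d1", "d2", "l3", "k1", "k2", "k3", "k4")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau": (0.0, 3.0),
    "a1": (1e-3, 1e6),
    "a2": (0.0, 1e3),
    "a3": (0.0, 1e3),
    "d1": (0.5, 49.0),
    "d2": (0.04, 4.5),
    "l3": (0.001, 0.5),
    "k1": (1e-3, 2.0),
    "k2": (0.01, 2.0),
    "k3": (0.001, 1.0),
    "k4": (0.001, 1.0),
}

# Latin-hypercube start ranges, deliberately narrower than the hard bounds.
_START_RANGES: dict[str, tuple[float, float]] = {
    "tau": (0.0, 2.0),
    "a1": (0.5, 2.0),
    "a2": (0.0, 0.5),
    "a3": (0.0, 0.5),
    "d1": (1.0, 20.0),
    "d2": (0.1, 2.0),
    "l3": (0.002, 0.2),
    "k1": (0.05, 0.5),
    "k2": (0.05, 1.0),
    "k3": (0.005, 0.3),
    "k4": (0.005, 0.3),
}


def _theta_to_params(theta: np.ndarray) -> ParameterSet:
    d = dict(zip(_PARAM_NAMES, theta))
    l3 = d["l3"]
    l2 = l3 + d["d2"]
    l1 = l2 + d["d1"]
    feng = FengParams(d["tau"], d["a1"], d["a2"], d["a3"], l1, l2, l3)
    tissue = TwoTCParams(d["k1"], d["k2"], d["k3"], d["k4"])
    return ParameterSet(feng, tissue)


def _params_to_theta(params: ParameterSet) -> np.ndarray:
    f, k = params.feng, params.tissue
    return np.array(
        [f.tau, f.a1, f.a2, f.a3, f.l1 - f.l2, f.l2 - f.l3, f.l3,
         k.k1, k.k2, k.k3, k.k4]
    )


class MBMF:
    """Model object for the factorization of one carotid voxel matrix."""

    def __init__(self, voxel_matrix: VoxelMatrix, config: MBMFConfig | None = None):
        self.voxel_matrix = voxel_matrix
        self.config = config or MBMFConfig()
        if voxel_matrix.n_frames < 12:
            raise IdifError("factorization needs at least 12 frames")
        t_end = voxel_matrix.schedule.ends_s[-1] / 60.0
        self._grid = fine_grid(t_end, self.config.dt_min)
        if self.config.frame_weighting == "inverse_variance":
            # sd_ij ~ sqrt(activity / duration): weight frames by the inverse
            # of their typical noise level, normalized to mean 1
            mean_frame = np.maximum(voxel_matrix.A.mean(axis=0), 0.0)
            floor = max(mean_frame.max(), 1e-300) * 1e-3
            w = np.sqrt(voxel_matrix.schedule.durations_s
                        / np.maximum(mean_frame, floor))
            self._frame_weights = w / w.mean()
        else:
            self._frame_weights = np.ones(voxel_matrix.n_frames)

    @classmethod
    def from_image(
        cls,
        image: DynamicImage,
        mask: CarotidMask,
        config: MBMFConfig | None = None,
    ) -> "MBMF":
        return cls(build_matrix(image, mask), config)

    # -- model evaluation ---------------------------------------------------

    def component_matrix(self, params: ParameterSet) -> np.ndarray:
        """The 2 x m matrix H implied by a parameter set (not normalized)."""
        aif = feng_aif(params.feng, self._grid)
        tis = two_tc_tissue(params.feng, params.tissue, self._grid)
        sched = self.voxel_matrix.schedule
        if self.config.frame_sampling == "average":
            h0 = frame_average(self._grid, aif, sched)
            h1 = frame_average(self._grid, tis, sched)
        else:
            h0 = sample_at_midpoints(self._grid, aif, sched)
            h1 = sample_at_midpoints(self._grid, tis, sched)
        return np.vstack([h0, h1])

    def _solve_w(self, H: np.ndarray) -> np.ndarray:
        """Weighted per-voxel least squares for W at the configured weights."""
        w = self._frame_weights
        return solve_weights(H * w, self.voxel_matrix.A * w,
                             nonneg=self.config.nonneg_weights)

    def _residual_vector(self, theta: np.ndarray) -> np.ndarray:
        try:
            params = _theta_to_params(theta)
            H = self.component_matrix(params)
            W = self._solve_w(H)
        except IdifError:
            return np.full(self.voxel_matrix.A.size, 1e6)
        return ((W @ H - self.voxel_matrix.A) * self._frame_weights).ravel()

    def objective(self, params: ParameterSet) -> float:
        """Squared Frobenius residual ||W H - A||^2 at a given parameter set."""
        r = self._residual_vector(_params_to_theta(params))
        return float(r @ r)

    # -- initialization -----------------------------------------------------

    def _initial_tau(self) -> float:
        """Earliest frame start whose mask-mean activity exceeds 10% of the
        mask-wide maximum frame mean."""
        means = self.voxel_matrix.A.mean(axis=0)
        thresh = 0.1 * means.max()
        idx = int(np.argmax(means > thresh))
        lo, hi = self._bounds()["tau"]
        return float(np.clip(self.voxel_matrix.schedule.starts_s[idx] / 60.0, lo, hi))

    def _bounds(self) -> dict[str, tuple[float, float]]:
        b = dict(_DEFAULT_BOUNDS)
        b.update(self.config.bounds)
        return b

    def _start_points(self) -> list[np.ndarray]:
        bounds = self._bounds()
        tau0 = self._initial_tau()
        heuristic = {
            "tau": tau0, "a1": 1.0, "a2": 0.05, "a3": 0.02,
            "d1": 4.0, "d2": 0.5, "l3": 0.02,
            "k1": 0.15, "k2": 0.2, "k3": 0.05, "k4": 0.05,
        }
        starts = [np.array([heuristic[n] for n in _PARAM_NAMES])]
        n_lhs = self.config.n_starts - 1
        if n_lhs > 0:
            sampler = qmc.LatinHypercube(d=len(_PARAM_NAMES), seed=self.config.seed)
            unit = sampler.random(n_lhs)
            for row in unit:
                theta = np.empty(len(_PARAM_NAMES))
                for j, name in enumerate(_PARAM_NAMES):
                    lo, hi = _START_RANGES[name]
                    theta[j] = lo + row[j] * (hi - lo)
                theta[0] = np.clip(
                    tau0 + (row[0] - 0.5), bounds["tau"][0], bounds["tau"][1]
                )
                starts.append(theta)
        # clip all starts into the hard bounds
        lo = np.array([self._bounds()[n][0] for n in _PARAM_NAMES])
        hi = np.array([self._bounds()[n][1] for n in _PARAM_NAMES])
        return [np.clip(s, lo, hi) for s in starts]

    # -- fitting ------------------------------------------------------------

    def fit(self, start_params: ParameterSet | None = None) -> "MBMFResults":
        """Run the multi-start bound-constrained factorization.

        ``start_params`` replaces the default start list with a single start
        (useful for seeding at a known truth).
        """
        bounds = self._bounds()
        lo = np.array([bounds[n][0] for n in _PARAM_NAMES])
        hi = np.array([bounds[n][1] for n in _PARAM_NAMES])
        if start_params is not None:
            starts = [np.clip(_params_to_theta(start_params), lo, hi)]
        else:
            starts = self._start_points()

        best = None
        best_cost = np.inf
        any_success = False
        for theta0 in starts:
            try:
                sol = least_squares(
                    self._residual_vector,
                    theta0,
                    bounds=(lo, hi),
                    method="trf",
                    ftol=self.config.ftol,
                    xtol=1e-10,
                    max_nfev=self.config.max_nfev,
                )
            except Exception:
                continue
            any_success = True
            if sol.cost < best_cost:
                best_cost = sol.cost
                best = sol
        if best is None:
            raise ConvergenceError("no optimizer start completed")

        params = _theta_to_params(best.x)
        H = self.component_matrix(params)
        W = self._solve_w(H)
        residual = float(np.sum((W @ H - self.voxel_matrix.A) ** 2))

        # component-label identifiability: the arterial row must peak earlier
        peak_aif = int(np.argmax(H[0]))
        peak_tis = int(np.argmax(H[1]))
        if peak_aif > peak_tis:
            raise ConvergenceError(
                "fitted arterial component peaks after the tissue component",
                best_residual=residual,
            )

        # normalize both rows to unit frame-sum, rescale W so W H is unchanged
        row_sums = H.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ConvergenceError("degenerate (non-positive) component row",
                                   best_residual=residual)
        H_norm = H / row_sums[:, None]
        W_norm = W * row_sums[None, :]

        return MBMFResults(
            model=self,
            params=params,
            H=H_norm,
            W=W_norm,
            residual=residual,
            n_starts_used=len(starts),
            converged=bool(any_success),
        )


@dataclass
class MBMFResults:
    """Estimates from a converged factorization.

    ``H`` rows are the normalized component curves (each sums to one over the
    frames); ``W`` columns carry the corresponding physical scales, so ``W @ H``
    reconstructs the voxel matrix.
    """

    model: MBMF
    params: ParameterSet
    H: np.ndarray
    W: np.ndarray
    residual: float
    n_starts_used: int
    converged: bool

    @property
    def normalized_aif(self) -> np.ndarray:
        """C_Norm,AIF: normalized arterial component per frame (sums to 1)."""
        return self.H[0]

    @property
    def normalized_tissue(self) -> np.ndarray:
        """C_Norm,TISSUE: normalized surrounding-tissue component per frame."""
        return self.H[1]

    @property
    def schedule(self) -> FrameSchedule:
        return self.model.voxel_matrix.schedule

    def reconstruction(self) -> np.ndarray:
        """The fitted voxel matrix W @ H."""
        return self.W @ self.H

    def relative_residual(self) -> float:
        A = self.model.voxel_matrix.A
        return float(np.sqrt(self.residual / np.sum(A**2)))

    def summary(self) -> str:
        f, k = self.params.feng, self.params.tissue
        lines = [
            "Model-based matrix factorization",
            "================================",
            f"voxels (n):            {self.model.voxel_matrix.n_voxels}",
            f"frames (m):            {self.model.voxel_matrix.n_frames}",
            f"starts used:           {self.n_starts_used}",
            f"converged:             {self.converged}",
            f"residual ||WH-A||^2:   {self.residual:.6g}",
            f"relative residual:     {self.relative_residual():.3e}",
            "",
            "Arterial input (Feng) parameters",
            f"  tau = {f.tau:.4f} min",
            f"  A1 = {f.a1:.4g}, A2 = {f.a2:.4g}, A3 = {f.a3:.4g}",
            f"  l1 = {f.l1:.4g}, l2 = {f.l2:.4g}, l3 = {f.l3:.4g} (1/min)",
            "",
            "Surrounding-tissue (2TC) parameters",
            f"  K1 = {k.k1:.4g} mL/cm^3/min, k2 = {k.k2:.4g}, "
            f"k3 = {k.k3:.4g}, k4 = {k.k4:.4g} (1/min)",
        ]
        return "\n".join(lines)

    def save(self, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
        """Write parameters + residual as JSON; H rows and W as TSV."""
        payload = {
            "params": self.params.to_dict(),
            "residual": self.residual,
            "relative_residual": self.relative_residual(),
            "n_starts_used": self.n_starts_used,
            "converged": self.converged,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
        if tsv_path is not None:
            import pandas as pd

            mids = self.schedule.midpoints_s
            df = pd.DataFrame(
                {
                    "midpoint_s": mids,
                    "c_norm_aif": self.H[0],
                    "c_norm_tissue": self.H[1],
                }
            )
            df.to_csv(tsv_path, sep="\t", index=False)

    def plot(self, ax=None):
        """Plot the two normalized component curves against frame midpoints."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.schedule.midpoints_s / 60.0
        ax.plot(t, self.H[0], "o-", label="arterial component (normalized)")
        ax.plot(t, self.H[1], "s-", label="tissue component (normalized)")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized activity")
        ax.legend()
        return ax


def mbmf_objective(params: ParameterSet, vm: VoxelMatrix,
                   config: MBMFConfig | None = None) -> float:
    """Squared Frobenius residual of the factorization at a parameter set."""
    return MBMF(vm, config).objective(params)


def fit_mbmf(vm: VoxelMatrix, config: MBMFConfig | None = None) -> MBMFResults:
    """Functional entry point: factorize a voxel matrix with default workflow."""
    return MBMF(vm, config).fit()
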