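"""One-tissue-compartment (1TC) kinetics via basis functions.

The 1TC model describes tracer exchange between arterial plasma and a single
tissue compartment:

    C_T(t) = K1 * exp(-k2 t) (x) C_p(t)

where ``(x)`` is temporal convolution, ``K1`` (ml min^-1 cm^-3) is the
plasma-to-tissue influx rate, ``k2`` (min^-1) the efflux rate, and
``C_p(t)`` the metabolite-corrected arterial plasma input function.  The
volume of distribution is ``V_T = K1 / k2`` (ml cm^-3).

Fitting uses the basis-function method: ``exp(-k2 t) (x) C_p`` is
precomputed on a geometric grid of ``k2`` values (default 500 bases between
0.005 and 1.0 min^-1), reducing each voxel/ROI fit to a weighted linear
regression through the origin plus a discrete grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

C11_HALF_LIFE_MIN = 20.36
C11_LAMBDA = np.log(2.0) / C11_HALF_LIFE_MIN

__all__ = [
    "InputFunction",
    "FrameSchedule",
    "BasisSet",
    "KineticParams",
    "ParametricImage",
    "convolve_exponential",
    "frame_average",
    "make_basis_set",
    "simulate_tac",
    "frame_weights",
    "fit_tac",
    "fit_parametric_image",
    "OneTissueBasisModel",
    "OneTissueResults",
]


@dataclass(frozen=True)
class InputFunction:
    """Arterial plasma input function C_p(t), piecewise linear between samples.

    Parameters
    ----------
    times : array
        Sample times in minutes, strictly increasing, starting at 0.
    concentrations : array
        Activity concentration (Bq ml^-1) at each time; must be >= 0 and 0 at t=0.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t[0] != 0.0:
            raise ValueError("input function must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if c[0] != 0.0:
            raise ValueError("concentration at t=0 must be 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __call__(self, t):
        """Piecewise-linear interpolation, 0 outside the sampled range start."""
        return np.interp(t, self.times, self.concentrations)

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def _default_frame_edges() -> np.ndarray:
    # 6 x 30 s, 3 x 1 min, 2 x 2 min, 10 x 5 min -> 21 frames over 60 min
    durations = np.concatenate([
        np.full(6, 0.5), np.full(3, 1.0), np.full(2, 2.0), np.full(10, 5.0),
    ])
    return np.concatenate([[0.0], np.cumsum(durations)])


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous acquisition frames in minutes, plus the fitting mask.

    The default is the 21-frame, 60-min schedule (6x30 s, 3x1 min, 2x2 min,
    10x5 min) with the first two frames excluded from kinetic fitting to
    minimise tracer-delivery and blood-volume effects.
    """

    frame_starts: np.ndarray
    frame_ends: np.ndarray
    fit_mask: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.frame_starts, dtype=float)
        e = np.asarray(self.frame_ends, dtype=float)
        m = np.asarray(self.fit_mask, dtype=bool)
        if not (s.shape == e.shape == m.shape) or s.ndim != 1:
            raise ValueError("frame arrays must be 1-D and equal length")
        if np.any(e <= s):
            raise ValueError("frame durations must be positive")
        if not np.allclose(e[:-1], s[1:]):
            raise ValueError("frames must be contiguous")
        object.__setattr__(self, "frame_starts", s)
        object.__setattr__(self, "frame_ends", e)
        object.__setattr__(self, "fit_mask", m)

    @classmethod
    def default(cls, skip_first: int = 2) -> "FrameSchedule":
        edges = _default_frame_edges()
        n = len(edges) - 1
        mask = np.ones(n, dtype=bool)
        mask[:skip_first] = False
        return cls(edges[:-1], edges[1:], mask)

    @property
    def n_frames(self) -> int:
        return len(self.frame_starts)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_ends - self.frame_starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1])


@dataclass(frozen=True)
class KineticParams:
    """Fitted or true 1TC parameters for one TAC/voxel."""

    K1: float
    k2: float
    VT: float
    hit_lower_bound: bool = False

    @classmethod
    def from_k1_k2(cls, K1: float, k2: float, hit_lower_bound: bool = False):
        VT = K1 / k2 if K1 > 0 else 0.0
        return cls(K1, k2, VT, hit_lower_bound)


@dataclass
class ParametricImage:
    """Voxel maps of K1, k2, VT plus lower-boundary-hit flags."""

    K1: np.ndarray
    k2: np.ndarray
    VT: np.ndarray
    hit_lower_bound: np.ndarray

    @property
    def shape(self):
        return self.K1.shape


def convolve_exponential(input_function: InputFunction, k2: float,
                         fine_dt: float = 0.01, t_end: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Analytic convolution exp(-k2 t) (x) C_p(t) on a uniform fine grid.

    C_p is treated as piecewise linear on the fine grid; within each step the
    integral of the exponential kernel against a linear segment is evaluated
    in closed form, so the only discretisation is the linear resampling of
    C_p itself (exact when the fine grid contains the C_p sample times).

    Returns ``(t_fine, values)``.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if fine_dt <= 0:
        raise ValueError("fine_dt must be positive")
    if t_end is None:
        t_end = input_function.duration
    n = int(round(t_end / fine_dt))
    t = np.arange(n + 1) * fine_dt
    cp = input_function(t)
    # per-step increment: Cp(tau) = a + b*(tau - t_i) on [t_i, t_{i+1})
    a = cp[:-1]
    b = (cp[1:] - cp[:-1]) / fine_dt
    E = np.exp(-k2 * fine_dt)
    alpha = (1.0 - E) / k2
    beta = (fine_dt - alpha) / k2
    g = a * alpha + b * beta
    # recurrence c_{i+1} = E*c_i + g_i  (c_0 = 0)
    out = np.empty_like(t)
    out[0] = 0.0
    out[1:] = lfilter([1.0], [1.0, -E], g)
    return t, out


def frame_average(fine_times: np.ndarray, fine_values: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid TAC over each frame (trapezoidal integration).

    Frame value i = (1/dt_i) * integral over [start_i, end_i) of the TAC.
    """
    if fine_times[-1] < schedule.frame_ends[-1] - 1e-9:
        raise ValueError("fine grid does not span the frame schedule")
    dt = fine_times[1] - fine_times[0]
    # cumulative trapezoid integral, then interpolate at frame edges
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (fine_values[1:] + fine_values[:-1]) * dt)])
    ints = np.interp(schedule.frame_ends, fine_times, cum) - \
        np.interp(schedule.frame_starts, fine_times, cum)
    return ints / schedule.durations


@dataclass(frozen=True)
class BasisSet:
    """Frame-averaged exponential-convolution basis TACs on a geometric k2 grid.

    ``basis_frames[b, i]`` is the frame-average over frame ``i`` of
    ``exp(-k2_b t) (x) C_p(t)`` (unit K1).
    """

    k2_grid: np.ndarray
    basis_frames: np.ndarray
    input_function: InputFunction
    schedule: FrameSchedule
    fine_dt: float = 0.01

    @property
    def n_bases(self) -> int:
        return len(self.k2_grid)

    @property
    def k2_min(self) -> float:
        return float(self.k2_grid[0])

    @property
    def k2_max(self) -> float:
        return float(self.k2_grid[-1])


def make_basis_set(input_function: InputFunction, schedule: FrameSchedule,
                   n_bases: int = 500, k2_min: float = 0.005,
                   k2_max: float = 1.0, fine_dt: float = 0.01) -> BasisSet:
    """Build the basis set: geometric k2 grid, analytic convolution, frame averaging."""
    if not (0 < k2_min < k2_max):
        raise ValueError("require 0 < k2_min < k2_max")
    if n_bases < 2:
        raise ValueError("need at least 2 bases")
    grid = np.geomspace(k2_min, k2_max, n_bases)
    frames = np.empty((n_bases, schedule.n_frames))
    for b, k2 in enumerate(grid):
        t, v = convolve_exponential(input_function, k2, fine_dt,
                                    t_end=schedule.total_duration)
        frames[b] = frame_average(t, v, schedule)
    return BasisSet(grid, frames, input_function, schedule, fine_dt)


def simulate_tac(K1: float, k2: float, input_function: InputFunction,
                 schedule: FrameSchedule, fine_dt: float = 0.01) -> np.ndarray:
    """Noiseless frame-averaged 1TC TAC at exact (K1, k2), not snapped to a grid."""
    if K1 < 0:
        raise ValueError("K1 must be nonnegative")
    if K1 == 0:
        return np.zeros(schedule.n_frames)
    t, v = convolve_exponential(input_function, k2, fine_dt,
                                t_end=schedule.total_duration)
    return K1 * frame_average(t, v, schedule)


def frame_weights(schedule: FrameSchedule, mode: str = "duration-decay",
                  frame_sd: np.ndarray | None = None,
                  decay_lambda: float = C11_LAMBDA) -> np.ndarray:
    """Per-frame fitting weights, normalised to sum 1 over all frames.

    Modes
    -----
    ``uniform``
        Equal weight per frame.
    ``duration-decay``
        w_i proportional to dt_i * exp(-lambda * t_mid,i): a frame-count proxy
        (longer frames and earlier frames carry more counts for a decaying
        tracer, C-11 half-life 20.36 min by default).
    ``inv-var``
        w_i = 1 / SD_i^2 from a supplied per-frame noise SD.
    """
    if mode == "uniform":
        w = np.ones(schedule.n_frames)
    elif mode == "duration-decay":
        w = schedule.durations * np.exp(-decay_lambda * schedule.midpoints)
    elif mode == "inv-var":
        if frame_sd is None:
            raise ValueError("inv-var weights need frame_sd")
        sd = np.asarray(frame_sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError(
                "inv-var weights undefined for SD=0 frames; use uniform weights instead")
        w = 1.0 / sd**2
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return w / w.sum()


def _prepare_fit(basis_set: BasisSet, weights, fit_mask):
    if fit_mask is None:
        fit_mask = basis_set.schedule.fit_mask
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if weights is None:
        weights = frame_weights(basis_set.schedule)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w * fit_mask
    if np.count_nonzero(w > 0) < 2:
        raise ValueError("need at least 2 frames with positive weight")
    B = basis_set.basis_frames
    Bw = B * w  # (n_bases, n_frames)
    den = np.einsum("bi,bi->b", Bw, B)  # sum_i w_i B^2
    return w, B, Bw, den


def _grid_fit(Y: np.ndarray, Bw: np.ndarray, den: np.ndarray):
    """Closed-form weighted regression through the origin for every basis.

    Y: (n_tacs, n_frames). Returns (best index, K1 at best, per-basis score).
    Ties in weighted SSE break to the smallest k2 index.
    """
    num = Y @ Bw.T  # (n_tacs, n_bases): sum_i w_i B_bi y_i
    K1 = np.clip(num / den, 0.0, None)
    # minimising SSE = sum w y^2 - 2 K1 num + K1^2 den  <=>  maximising
    # 2 K1 num - K1^2 den; argmax picks the first (smallest k2) on ties.
    score = 2.0 * K1 * num - K1 * K1 * den
    best = np.argmax(score, axis=1)
    rows = np.arange(Y.shape[0])
    return best, K1[rows, best], score


def fit_tac(tac: np.ndarray, basis_set: BasisSet, weights=None,
            fit_mask=None) -> KineticParams:
    """Weighted basis-function fit of a single TAC; returns the best-grid params."""
    y = np.asarray(tac, dtype=float)
    if y.ndim != 1 or len(y) != basis_set.schedule.n_frames:
        raise ValueError("TAC length must match the frame schedule")
    if not np.all(np.isfinite(y)):
        raise ValueError("TAC contains non-finite values")
    w, B, Bw, den = _prepare_fit(basis_set, weights, fit_mask)
    best, K1, _ = _grid_fit(y[None, :], Bw, den)
    b = int(best[0])
    k2 = float(basis_set.k2_grid[b])
    return KineticParams.from_k1_k2(float(K1[0]), k2, hit_lower_bound=(b == 0))


def fit_parametric_image(dynamic_frames: np.ndarray, basis_set: BasisSet,
                         weights=None, fit_mask=None) -> ParametricImage:
    """Voxel-wise basis fit of a dynamic image.

    ``dynamic_frames`` has the frame axis last: shape (..., n_frames).
    Voxels with nonpositive total signal over the fitted frames get K1 = 0.
    """
    X = np.asarray(dynamic_frames, dtype=float)
    if X.shape[-1] != basis_set.schedule.n_frames:
        raise ValueError("frame axis must match the schedule")
    spatial = X.shape[:-1]
    Y = X.reshape(-1, X.shape[-1])
    w, B, Bw, den = _prepare_fit(basis_set, weights, fit_mask)
    best, K1, _ = _grid_fit(Y, Bw, den)
    dead = (Y * (w > 0)).sum(axis=1) <= 0
    K1 = np.where(dead, 0.0, K1)
    best = np.where(dead | (K1 <= 0), 0, best)
    k2 = basis_set.k2_grid[best]
    K1c = np.where(K1 > 0, K1, 0.0)
    VT = np.where(K1c > 0, K1c / k2, 0.0)
    flags = best == 0
    return ParametricImage(
        K1=K1c.reshape(spatial), k2=k2.reshape(spatial),
        VT=VT.reshape(spatial), hit_lower_bound=flags.reshape(spatial))


class OneTissueBasisModel:
    """1TC basis-function model for a measured TAC (statsmodels-style).

    Parameters
    ----------
    endog : array, shape (n_frames,)
        Measured frame-averaged tissue TAC (Bq ml^-1).
    basis_set : BasisSet
        Precomputed basis (carries the input function and schedule).
    weights : array or None
        Per-frame nonnegative weights; default duration-decay weights.
    fit_mask : array of bool or None
        Frames used for fitting; defaults to the schedule's mask.
    """

    def __init__(self, endog, basis_set: BasisSet, weights=None, fit_mask=None):
        self.endog = np.asarray(endog, dtype=float)
        self.basis_set = basis_set
        self.weights = weights
        self.fit_mask = fit_mask

    def fit(self) -> "OneTissueResults":
        params = fit_tac(self.endog, self.basis_set, self.weights, self.fit_mask)
        return OneTissueResults(self, params)


class OneTissueResults:
    """Fit results: parameter estimates, fitted TAC, residuals, summary table."""

    def __init__(self, model: OneTissueBasisModel, params: KineticParams):
        self.model = model
        self.kinetic_params = params
        self.K1 = params.K1
        self.k2 = params.k2
        self.VT = params.VT
        self.hit_lower_bound = params.hit_lower_bound
        bs = model.basis_set
        b = int(np.argmin(np.abs(bs.k2_grid - params.k2)))
        self.fittedvalues = params.K1 * bs.basis_frames[b]
        self.resid = model.endog - self.fittedvalues

    @property
    def params(self) -> np.ndarray:
        return np.array([self.K1, self.k2])

    def weighted_sse(self) -> float:
        w, _, _, _ = _prepare_fit(self.model.basis_set, self.model.weights,
                                  self.model.fit_mask)
        return float(np.sum(w * self.resid**2))

    def summary(self) -> str:
        lines = [
            "One-tissue-compartment basis-function fit",
            "=" * 45,
            f"{'K1 (ml/min/cm3)':<25}{self.K1:>14.6g}",
            f"{'k2 (1/min)':<25}{self.k2:>14.6g}",
            f"{'VT (ml/cm3)':<25}{self.VT:>14.6g}",
            f"{'hit lower k2 bound':<25}{str(self.hit_lower_bound):>14}",
            f"{'weighted SSE':<25}{self.weighted_sse():>14.6g}",
            f"{'n bases':<25}{self.model.basis_set.n_bases:>14d}",
            f"{'k2 range (1/min)':<25}"
            f"{f'[{self.model.basis_set.k2_min:g}, {self.model.basis_set.k2_max:g}]':>14}",
        ]
        return "\n".join(lines)
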