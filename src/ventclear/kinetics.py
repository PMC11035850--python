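"""Closed-form forward kinetic models on a fine uniform time grid.

All models are driven by a plasma/blood input curve sampled on a fine grid
(default dt = 0.01 min over [0, 62] min) and reduce to sums of exponential
convolutions, evaluated analytically for a piecewise-linear input:

* ventricle clearance models (blood-only and dual-input):
  dCv/dt = k1_blood*Cp + k1_tissue*Ctis - k_clearance*Cv, Cv(0) = 0
* two-tissue compartment model for gray matter (free/nonspecific C1 and
  bound C2), whose C1 ("unbound") curve serves as the interstitial input of
  the dual ventricle model.

Rate constants are in 1/min (K1 in mL.cm^-3.min^-1).  Activities are
decay-corrected; physical decay is never modeled.  PET frames measure
time-averaged activity, so model outputs are averaged over each frame of a
:class:`~ventclear.tac_io.FrameSchedule` before comparison with data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .tac_io import FrameSchedule, TimeActivityCurve

__all__ = [
    "DEFAULT_DT_MIN",
    "DEFAULT_TMAX_MIN",
    "InputFunctionParams",
    "TwoTissueParams",
    "VentricleParams",
    "fine_time_grid",
    "feng_input",
    "convolve_exp",
    "frame_average",
    "ventricle_model",
    "two_tissue_model",
    "upsample_idif",
]

DEFAULT_DT_MIN = 0.01
DEFAULT_TMAX_MIN = 62.0


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-form arterial input: C(tau) = (A1*tau - A2 - A3)e^(-lam1*tau)
    + A2*e^(-lam2*tau) + A3*e^(-lam3*tau), tau = t - t0 (zero before t0).

    A1 in kBq/mL/min, A2 and A3 in kBq/mL, lam* in 1/min, t0 in min.
    """

    A1: float = 800.0
    A2: float = 25.0
    A3: float = 15.0
    lam1: float = 4.0
    lam2: float = 0.25
    lam3: float = 0.04
    t0: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lam1 > self.lam2 > self.lam3 > 0):
            raise ValueError("require lam1 > lam2 > lam3 > 0")
        if self.A2 < 0 or self.A3 < 0:
            raise ValueError("A2, A3 must be >= 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    def scaled(self, factor: float) -> "InputFunctionParams":
        return InputFunctionParams(self.A1 * factor, self.A2 * factor, self.A3 * factor,
                                   self.lam1, self.lam2, self.lam3, self.t0)


@dataclass(frozen=True)
class TwoTissueParams:
    """Two-tissue compartment rate constants (K1, k2, k3, k4)."""

    K1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("all rate constants must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")


@dataclass(frozen=True)
class VentricleParams:
    """Ventricle clearance model constants.

    ``k1_tissue is None`` selects the blood-only model; otherwise the
    dual-input model with delivery from both blood and gray-matter ISF.
    """

    k1_blood: float
    k_clearance: float
    k1_tissue: float | None = None

    def __post_init__(self) -> None:
        vals = [self.k1_blood, self.k_clearance]
        if self.k1_tissue is not None:
            vals.append(self.k1_tissue)
        if min(vals) < 0:
            raise ValueError("all rate constants must be >= 0")

    @property
    def model_id(self) -> str:
        return "blood_only" if self.k1_tissue is None else "dual_input"


def fine_time_grid(dt: float = DEFAULT_DT_MIN, t_max: float = DEFAULT_TMAX_MIN) -> np.ndarray:
    """Uniform grid [0, t_max] minutes with step dt."""
    n = int(round(t_max / dt))
    return np.arange(n + 1) * dt


def feng_input(params: InputFunctionParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the Feng input function; zero at and before t0, continuous."""
    t = np.asarray(t, dtype=float)
    tau = t - params.t0
    pos = tau > 0
    out = np.zeros_like(tau)
    tp = tau[pos]
    out[pos] = ((params.A1 * tp - params.A2 - params.A3) * np.exp(-params.lam1 * tp)
                + params.A2 * np.exp(-params.lam2 * tp)
                + params.A3 * np.exp(-params.lam3 * tp))
    return out


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("grid must have at least 2 points")
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("convolve_exp requires a uniform time grid")
    return float(dt[0])


def convolve_exp(t: np.ndarray, y: np.ndarray, k: float) -> np.ndarray:
    """out(t) = integral_0^t y(s) e^(-k(t-s)) ds, exact for piecewise-linear y.

    Treating ``y`` as linear between samples, each step's contribution is
    integrated analytically and accumulated with the one-step decay
    recurrence out[n] = e^(-k dt) out[n-1] + a*y[n-1] + b*y[n].  k = 0
    reduces to the cumulative trapezoidal integral.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    dt = _check_uniform(t)
    if k == 0.0:
        return cumulative_trapezoid(y, dx=dt, initial=0.0)
    kdt = k * dt
    if kdt < 1e-4:
        # series expansions avoid catastrophic cancellation for tiny k*dt
        i0 = dt * (1.0 - kdt / 2.0 + kdt * kdt / 6.0)
        i1 = dt * (0.5 - kdt / 6.0 + kdt * kdt / 24.0)
    else:
        c = np.exp(-kdt)
        i0 = -np.expm1(-kdt) / k
        i1 = i0 - (1.0 - c * (1.0 + kdt)) / (k * k * dt)
    a, b = i0 - i1, i1
    d = a * y[:-1] + b * y[1:]
    out = np.empty_like(y)
    out[0] = 0.0
    out[1:] = lfilter([1.0], [1.0, -np.exp(-kdt)], d)
    return out


def _convolve_t_exp(t: np.ndarray, y: np.ndarray, k: float) -> np.ndarray:
    """out(t) = integral_0^t y(s) (t-s) e^(-k(t-s)) ds (repeated-root kernel)."""
    return t * convolve_exp(t, y, k) - convolve_exp(t, t * y, k)


def _integrate_linear(t: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Integral of the piecewise-linear interpolant of (t, y) over [a, b]."""
    ya = np.interp(a, t, y)
    yb = np.interp(b, t, y)
    i0 = np.searchsorted(t, a, side="right")
    i1 = np.searchsorted(t, b, side="left")
    xs = np.concatenate(([a], t[i0:i1], [b]))
    vs = np.concatenate(([ya], y[i0:i1], [yb]))
    return float(np.trapezoid(vs, xs))


_FRAME_OP_CACHE: dict[tuple, np.ndarray] = {}


def _frame_average_operator(t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Matrix F with frame_average(y) = F @ y (frame means are linear in y).

    Row i holds the trapezoid weights (with end-point interpolation) of frame
    i, divided by the frame length.  Cached per (grid, schedule) because the
    fitting loop evaluates thousands of model curves on one fixed grid.
    """
    key = (len(t), float(t[0]), float(t[-1]), schedule.frames)
    op = _FRAME_OP_CACHE.get(key)
    if op is not None:
        return op
    dt = _check_uniform(t)
    n = len(t)
    rows = np.zeros((len(schedule), n))
    a_min = schedule.starts_s / 60.0
    b_min = schedule.ends_s / 60.0
    for i, (a, b) in enumerate(zip(a_min, b_min)):
        i0 = int(np.searchsorted(t, a, side="right"))
        i1 = int(np.searchsorted(t, b, side="left"))
        xs = np.concatenate(([a], t[i0:i1], [b]))
        # trapezoid weights over the knots xs
        tw = np.empty(len(xs))
        d = np.diff(xs)
        tw[0] = d[0] / 2.0
        tw[-1] = d[-1] / 2.0
        if len(xs) > 2:
            tw[1:-1] = (d[:-1] + d[1:]) / 2.0
        row = rows[i]
        # scatter the interpolated endpoints onto their bracketing knots
        ia = i0 - 1
        fa = (a - t[ia]) / dt
        row[ia] += tw[0] * (1.0 - fa)
        row[ia + 1] += tw[0] * fa
        ib = i1 - 1
        fb = (b - t[ib]) / dt
        row[ib] += tw[-1] * (1.0 - fb)
        row[min(ib + 1, n - 1)] += tw[-1] * fb
        row[i0:i1] += tw[1:-1]
        row /= b - a
    _FRAME_OP_CACHE[key] = rows
    return rows


def frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Trapezoidal mean of a fine-grid curve over each frame [start, end)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    a_min = schedule.starts_s / 60.0
    b_min = schedule.ends_s / 60.0
    tol = 1e-9
    if a_min.size and (a_min[0] < t[0] - tol or b_min[-1] > t[-1] + tol):
        raise ValueError(
            f"frames span [{a_min[0]:.4f}, {b_min[-1]:.4f}] min outside grid "
            f"[{t[0]:.4f}, {t[-1]:.4f}] min"
        )
    return _frame_average_operator(t, schedule) @ y


def ventricle_model(
    t: np.ndarray,
    cp: np.ndarray,
    c_tissue: np.ndarray | None,
    params: VentricleParams,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Forward ventricle TAC: Cv = k1_blood*(Cp (*) e^-kc) [+ k1_tissue*(Ctis (*) e^-kc)].

    ``c_tissue`` is required iff ``params`` selects the dual-input model.
    """
    if params.model_id == "dual_input" and c_tissue is None:
        raise ValueError("dual-input model requires a tissue input curve")
    cv = params.k1_blood * convolve_exp(t, cp, params.k_clearance)
    if params.model_id == "dual_input":
        cv = cv + params.k1_tissue * convolve_exp(t, np.asarray(c_tissue, float), params.k_clearance)
    return TimeActivityCurve(schedule, frame_average(t, cv, schedule), roi_label="ventricle_model")


def two_tissue_model(
    t: np.ndarray,
    cp: np.ndarray,
    params: TwoTissueParams,
    schedule: FrameSchedule,
) -> tuple[TimeActivityCurve, np.ndarray]:
    """Two-tissue compartment solution via eigen-decomposition.

    dC1/dt = K1*Cp - (k2+k3)*C1 + k4*C2;  dC2/dt = k3*C1 - k4*C2.
    Returns the frame-averaged total (C1+C2) TAC and the fine-grid C1
    ("unbound") curve.  The repeated-eigenvalue case is handled with the
    t*e^(-at) kernel rather than a numerical nudge.
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    if sq <= 1e-10 * max(s, 1e-30):
        alpha = s / 2.0
        conv = convolve_exp(t, cp, alpha)
        convt = _convolve_t_exp(t, cp, alpha)
        c1 = K1 * (conv + (k4 - alpha) * convt)
        c2 = K1 * k3 * convt
    else:
        a1 = (s - sq) / 2.0
        a2 = (s + sq) / 2.0
        conv1 = convolve_exp(t, cp, a1)
        conv2 = convolve_exp(t, cp, a2)
        c1 = K1 / sq * ((k4 - a1) * conv1 + (a2 - k4) * conv2)
        c2 = K1 * k3 / sq * (conv1 - conv2)
    total = frame_average(t, c1 + c2, schedule)
    return TimeActivityCurve(schedule, total, roi_label="gray_matter_model"), c1


_IDIF_OP_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def upsample_idif(tac: TimeActivityCurve, t: np.ndarray, mean_correction: bool = True) -> np.ndarray:
    """Up-sample a measured (frame-resolved) input TAC onto the fine grid.

    Piecewise-linear through knots at the frame midpoints, anchored at zero
    at injection (the curve ramps from 0 to the first midpoint value) and
    held at the last midpoint value afterwards.

    Measured frame values are time *averages*, not midpoint samples, so a
    plain midpoint interpolant flattens the input peak and systematically
    biases delivery constants.  With ``mean_correction`` (default) the knot
    values are obtained by solving the small linear system that makes the
    interpolant's own frame averages reproduce the measured frame means
    exactly; ``False`` restores plain midpoint interpolation.
    """
    t = np.asarray(t, dtype=float)
    mids = tac.schedule.mid_s / 60.0
    anchored = mids[0] > 0
    knots = np.concatenate(([0.0], mids)) if anchored else mids

    def interp(v: np.ndarray) -> np.ndarray:
        vv = np.concatenate(([0.0], v)) if anchored else v
        return np.interp(t, knots, vv)

    if not mean_correction:
        return interp(tac.activity.astype(float))

    key = (len(t), float(t[0]), float(t[-1]), tac.schedule.frames, anchored)
    cached = _IDIF_OP_CACHE.get(key)
    if cached is None:
        n = len(tac.schedule)
        # columns: frame averages of the interpolant of each unit knot value
        A = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            A[:, j] = frame_average(t, interp(e), tac.schedule)
        _IDIF_OP_CACHE[key] = (A, np.linalg.inv(A))
        cached = _IDIF_OP_CACHE[key]
    _, A_inv = cached
    return interp(A_inv @ tac.activity.astype(float))
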