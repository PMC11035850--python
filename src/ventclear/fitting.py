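"""Weighted least-squares and MAP estimation of kinetic rate constants.

Frames are weighted by the inverse square of a forecast standard deviation
(FSD): FSD_i = max(activity_i, floor) / duration_i(s), so short, hot frames
(high FSD, low statistical quality) are down-weighted.  Fits minimize

    WRSS(theta) = sum_i w_i (y_i - model_i(theta))^2            (WNLLS)
    WRSS(theta) + sum_j ((theta_j - mu_j) / sigma_j)^2          (MAP)

via a bounded trust-region least-squares solver started from a deterministic
Latin-hypercube (log-spaced over the bounds).  A fit is flagged as having
"converged to a single solution" only when the best multistart solutions
agree (objective within rel. 1e-4, parameters within rel. 5%) and the
optimum is interior to the bounds.  Models are compared by
AIC = n ln(WRSS/n) + 2p, valid for same-data comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import kinetics
from .tac_io import TimeActivityCurve

__all__ = [
    "MODEL_PARAM_NAMES",
    "WeightVector",
    "PriorSpec",
    "FitResult",
    "fsd_weights",
    "fit_wnlls",
    "fit_map",
    "fit_two_tissue",
    "aic_score",
    "aic",
    "select_model",
    "default_bounds",
]

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "blood_only": ("k1_blood", "k_clearance"),
    "dual_input": ("k1_blood", "k1_tissue", "k_clearance"),
    "two_tissue": ("K1", "k2", "k3", "k4"),
}

_RATE_BOUNDS = (1e-5, 1.0)
_K1_BOUNDS = (1e-4, 2.0)

WRSS_REL_TOL = 1e-4     # multistart agreement on the objective
PARAM_REL_TOL = 0.05    # multistart agreement on parameters
_BOUND_HIT_REL = 1e-3   # relative closeness to a bound that voids convergence


def default_bounds(model_id: str) -> dict[str, tuple[float, float]]:
    """Default box bounds per parameter (brackets plausible magnitudes >25x)."""
    return {name: (_K1_BOUNDS if name == "K1" else _RATE_BOUNDS)
            for name in MODEL_PARAM_NAMES[model_id]}


@dataclass(frozen=True)
class WeightVector:
    """Per-frame weights (mean-normalized) with the FSD they derive from."""

    weights: np.ndarray
    fsd: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "fsd", np.asarray(self.fsd, dtype=float))
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior means/SDs per parameter with provenance bookkeeping."""

    means: dict[str, float]
    sds: dict[str, float]
    group: str = ""
    excluded_subject: str = ""
    pooled_fallback: bool = False

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not (sd > 0):
                raise ValueError(f"prior SD for {name} must be > 0")


@dataclass
class FitResult:
    """One model's fit to one subject's TAC."""

    model_id: str
    estimates: dict[str, float]
    se: dict[str, float] | None
    wrss: float
    aic: float
    converged: bool
    n_frames: int
    multistart_spread: float
    objective: float
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(MODEL_PARAM_NAMES[self.model_id])

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "estimates": dict(self.estimates),
            "se": dict(self.se) if self.se is not None else None,
            "wrss": self.wrss,
            "aic": self.aic,
            "converged": self.converged,
            "n_frames": self.n_frames,
            "multistart_spread": self.multistart_spread,
            "objective": self.objective,
            "flags": list(self.flags),
        }


def fsd_weights(tac: TimeActivityCurve, floor_fraction: float = 0.05) -> WeightVector:
    """FSD-based frame weights: w_i = 1/FSD_i^2, normalized to mean 1.

    FSD_i = max(activity_i, floor) / duration_i(s) with
    floor = floor_fraction * max(activity); the floor guards the weight of
    near-zero (or negative, post-noise) frames from blowing up.
    """
    act = tac.activity
    dur = tac.schedule.durations_s
    peak = float(np.max(act)) if act.size else 0.0
    if peak <= 0:
        raise ValueError("cannot build FSD weights: TAC has no positive activity")
    floor = floor_fraction * peak
    fsd = np.maximum(act, floor) / dur
    if np.any(fsd <= 0):
        raise ValueError("FSD must be positive; increase floor_fraction")
    w = 1.0 / fsd**2
    return WeightVector(w / w.mean(), fsd)


def _predict(model_id: str, theta: np.ndarray, inputs: dict) -> np.ndarray:
    return _make_predictor(model_id, inputs)(np.asarray(theta, dtype=float))


def _make_predictor(model_id: str, inputs: dict):
    """Fast frame-space predictor for one fit.

    Every model is linear in its delivery constants (K1 / k1_blood /
    k1_tissue), so predictions decompose as amplitudes times *basis* frame
    vectors that depend only on the nonlinear constants.  Bases are memoized
    per fit: finite-difference jacobian steps along the linear constants then
    cost nothing, and repeated nonlinear values reuse their convolutions.
    """
    t = inputs["t"]
    schedule = inputs["schedule"]
    fa = kinetics._frame_average_operator(t, schedule)
    cp = inputs["cp"]
    cache: dict = {}

    def _conv_frames(curve: np.ndarray, k: float, tag: str) -> np.ndarray:
        key = (tag, float(k))
        out = cache.get(key)
        if out is None:
            if len(cache) > 512:
                cache.clear()
            out = fa @ kinetics.convolve_exp(t, curve, k)
            cache[key] = out
        return out

    def _dconv_frames(curve: np.ndarray, k: float, tag: str) -> np.ndarray:
        # d/dk of _conv_frames: the t*e^(-kt) kernel enters with a minus sign
        key = ("d" + tag, float(k))
        out = cache.get(key)
        if out is None:
            if len(cache) > 512:
                cache.clear()
            out = -(fa @ kinetics._convolve_t_exp(t, curve, k))
            cache[key] = out
        return out

    if model_id == "blood_only":
        def predict(theta: np.ndarray) -> np.ndarray:
            return theta[0] * _conv_frames(cp, theta[1], "cp")

        def jac(theta: np.ndarray) -> np.ndarray:
            return np.column_stack([
                _conv_frames(cp, theta[1], "cp"),
                theta[0] * _dconv_frames(cp, theta[1], "cp"),
            ])
        predict.jac = jac
        return predict

    if model_id == "dual_input":
        c_tissue = inputs.get("c_tissue")
        if c_tissue is None:
            raise ValueError("dual_input model requires a 'c_tissue' input curve")

        def predict(theta: np.ndarray) -> np.ndarray:
            return (theta[0] * _conv_frames(cp, theta[2], "cp")
                    + theta[1] * _conv_frames(c_tissue, theta[2], "ct"))

        def jac(theta: np.ndarray) -> np.ndarray:
            return np.column_stack([
                _conv_frames(cp, theta[2], "cp"),
                _conv_frames(c_tissue, theta[2], "ct"),
                theta[0] * _dconv_frames(cp, theta[2], "cp")
                + theta[1] * _dconv_frames(c_tissue, theta[2], "ct"),
            ])
        predict.jac = jac
        return predict

    if model_id == "two_tissue":
        def predict(theta: np.ndarray) -> np.ndarray:
            K1, k2, k3, k4 = theta
            key = ("tt", float(k2), float(k3), float(k4))
            basis = cache.get(key)
            if basis is None:
                s = k2 + k3 + k4
                disc = s * s - 4.0 * k2 * k4
                sq = np.sqrt(max(disc, 0.0))
                if sq <= 1e-10 * max(s, 1e-30):
                    alpha = s / 2.0
                    conv = _conv_frames(cp, alpha, "cp")
                    convt = fa @ kinetics._convolve_t_exp(t, cp, alpha)
                    basis = conv + (k4 - alpha) * convt + k3 * convt
                else:
                    a1 = (s - sq) / 2.0
                    a2 = (s + sq) / 2.0
                    c1 = ((k4 - a1) * _conv_frames(cp, a1, "cp")
                          + (a2 - k4) * _conv_frames(cp, a2, "cp")) / sq
                    c2 = k3 * (_conv_frames(cp, a1, "cp") - _conv_frames(cp, a2, "cp")) / sq
                    basis = c1 + c2
                if len(cache) > 512:
                    cache.clear()
                cache[key] = basis
            return K1 * basis
        return predict

    raise ValueError(f"unknown model_id {model_id!r}")


def _lhs_starts(lo: np.ndarray, hi: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Deterministic Latin-hypercube starts, log-spaced over the bounds."""
    sampler = qmc.LatinHypercube(d=len(lo), seed=int(seed))
    u = sampler.random(n)
    llo, lhi = np.log10(lo), np.log10(hi)
    return 10.0 ** (llo + u * (lhi - llo))


def _fit_core(
    tac: TimeActivityCurve,
    inputs: dict,
    model_id: str,
    bounds: dict[str, tuple[float, float]] | None,
    starts: int,
    seed: int,
    weights: WeightVector | None,
    priors: PriorSpec | None,
    error_scale: float | None = None,
) -> FitResult:
    names = MODEL_PARAM_NAMES[model_id]
    if starts < 1:
        raise ValueError("need at least one start")
    bmap = default_bounds(model_id)
    if bounds:
        bmap.update(bounds)
    lo = np.array([bmap[n][0] for n in names])
    hi = np.array([bmap[n][1] for n in names])
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with positive width")
    if weights is None:
        weights = fsd_weights(tac)
    sw = np.sqrt(weights.weights)
    y = tac.activity
    inputs = dict(inputs)
    inputs["schedule"] = tac.schedule

    if priors is not None:
        missing = [n for n in names if n not in priors.means or n not in priors.sds]
        if missing:
            raise ValueError(f"priors missing parameter(s) {missing}")
        mu = np.array([priors.means[n] for n in names])
        sig = np.array([priors.sds[n] for n in names])
        if error_scale is None:
            pre = _fit_core(tac, inputs, model_id, bounds, starts, seed, weights, None)
            error_scale = pre.wrss / max(pre.n_frames - len(names), 1)
        # floor keeps the prior active in the noise-free limit (dogmatic priors
        # must still win) without perturbing any realistically noisy fit
        scale = np.sqrt(max(float(error_scale), 1e-12 * float(np.mean((sw * y) ** 2))))
        sig = sig / scale

    predict = _make_predictor(model_id, inputs)

    def residuals(theta: np.ndarray) -> np.ndarray:
        r = sw * (y - predict(theta))
        if priors is not None:
            r = np.concatenate([r, (theta - mu) / sig])
        return r

    jac_arg = "2-point"
    model_jac = getattr(predict, "jac", None)
    if model_jac is not None:
        n_par = len(names)

        def jac_arg(theta: np.ndarray) -> np.ndarray:  # noqa: F811 - callable form
            j = -sw[:, None] * model_jac(theta)
            if priors is not None:
                j = np.vstack([j, np.diag(1.0 / sig)])
            return j

    solutions = []
    for x0 in _lhs_starts(lo, hi, starts, seed):
        try:
            res = least_squares(residuals, x0, jac=jac_arg, bounds=(lo, hi),
                                method="trf", x_scale="jac")
        except Exception as exc:  # model evaluation failure at this start
            solutions.append((np.inf, x0, None, str(exc)))
            continue
        solutions.append((float(2.0 * res.cost), res.x, res.jac, None))
    solutions.sort(key=lambda s: s[0])
    best_obj, best_x, best_jac, best_err = solutions[0]
    flags: list[str] = []
    if not np.isfinite(best_obj):
        raise RuntimeError(f"model {model_id} failed to evaluate from every start: {best_err}")

    n = len(y)
    p = len(names)
    data_resid = sw * (y - predict(best_x))
    wrss = float(data_resid @ data_resid)

    # multistart agreement among the top solutions
    top = [s for s in solutions[: min(3, starts)] if np.isfinite(s[0])]
    obj_scale = max(best_obj, 1e-12 * float((sw * y) @ (sw * y)) + 1e-300)
    agree_obj = all(s[0] - best_obj <= WRSS_REL_TOL * obj_scale for s in top)
    spread = 0.0
    agree_par = True
    for s in top:
        rel = np.abs(s[1] - best_x) / np.maximum(np.abs(best_x), 1e-12)
        spread = max(spread, float(rel.max()))
        if np.any(rel > PARAM_REL_TOL):
            agree_par = False
    converged = bool(agree_obj and agree_par and len(top) == min(3, starts))

    at_bound = (best_x <= lo * (1 + _BOUND_HIT_REL)) | (best_x >= hi * (1 - _BOUND_HIT_REL))
    if at_bound.any():
        converged = False
        flags.append("bound_hit:" + ",".join(np.array(names)[at_bound]))

    se: dict[str, float] | None = None
    if n > p and best_jac is not None:
        jtj = best_jac.T @ best_jac
        try:
            cov = np.linalg.pinv(jtj) * (wrss / (n - p))
            se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
        except np.linalg.LinAlgError:
            flags.append("covariance_singular")
    else:
        flags.append("underdetermined")

    return FitResult(
        model_id=model_id,
        estimates={nm: float(v) for nm, v in zip(names, best_x)},
        se=se,
        wrss=wrss,
        aic=aic_score(wrss, n, p),
        converged=converged,
        n_frames=n,
        multistart_spread=spread,
        objective=best_obj,
        flags=flags,
    )


def forecast_weights(
    tac: TimeActivityCurve,
    inputs: dict,
    model_id: str,
    floor_fraction: float = 0.05,
    starts: int = 4,
    seed: int = 0,
    rounds: int = 1,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> WeightVector:
    """FSD weights computed from a model forecast rather than the raw data.

    Weighting by the measured activity correlates the weights with the noise
    (downward-noise frames get inflated weights) and biases the fit at
    realistic noise levels; the *forecast* SD avoids this.  Each round fits
    ``model_id`` with the current weights and rebuilds the FSD from the
    fitted (noise-free) frame values.  The returned weights should be shared
    by every candidate model of the same TAC so that WRSS and AIC remain
    comparable across models.
    """
    w = fsd_weights(tac, floor_fraction)
    for r in range(rounds):
        fit = _fit_core(tac, inputs, model_id, bounds, starts, seed + r, w, priors=None)
        local = dict(inputs)
        local["schedule"] = tac.schedule
        pred = _predict(model_id, np.array([fit.estimates[n] for n in MODEL_PARAM_NAMES[model_id]]), local)
        w = fsd_weights(TimeActivityCurve(tac.schedule, pred, tac.roi_label), floor_fraction)
    return w


def fit_wnlls(
    tac: TimeActivityCurve,
    inputs: dict,
    model_id: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    starts: int = 10,
    seed: int = 0,
    weights: WeightVector | None = None,
) -> FitResult:
    """FSD-weighted nonlinear least-squares fit with multistart.

    ``inputs`` holds the fine grid ``t``, the blood input ``cp`` and, for the
    dual model, the tissue input ``c_tissue`` (all on the same fine grid).
    """
    return _fit_core(tac, inputs, model_id, bounds, starts, seed, weights, priors=None)


def fit_map(
    tac: TimeActivityCurve,
    inputs: dict,
    model_id: str,
    priors: PriorSpec,
    bounds: dict[str, tuple[float, float]] | None = None,
    starts: int = 10,
    seed: int = 0,
    weights: WeightVector | None = None,
    error_scale: float | None = None,
) -> FitResult:
    """MAP fit: WNLLS objective plus Gaussian prior penalties for all params.

    The prior penalty is expressed on the likelihood's scale: the normalized
    FSD weights define relative frame precision only, so the penalty is
    multiplied by the unit-weight residual variance ``error_scale``
    (estimated from an unconstrained fit when not supplied, e.g. WRSS/(n-p)
    of the first pass).  Without this, the prior's strength would depend on
    the arbitrary activity units.  The flat-prior limit still reproduces
    WNLLS and the dogmatic-prior limit still returns the prior means.
    """
    return _fit_core(tac, inputs, model_id, bounds, starts, seed, weights,
                     priors=priors, error_scale=error_scale)


def fit_two_tissue(
    gm_tac: TimeActivityCurve,
    inputs: dict,
    bounds: dict[str, tuple[float, float]] | None = None,
    starts: int = 10,
    seed: int = 0,
    weights: WeightVector | None = None,
) -> tuple[FitResult, np.ndarray]:
    """Fit the gray-matter 2TCM; return the fit and the fitted unbound C1 curve.

    The returned fine-grid C1 is the interstitial input of the dual-input
    ventricle model.  Weights default to the gray-matter FSD weights.
    """
    fit = _fit_core(gm_tac, inputs, "two_tissue", bounds, starts, seed,
                    weights=weights if weights is not None else fsd_weights(gm_tac),
                    priors=None)
    theta = kinetics.TwoTissueParams(**fit.estimates)
    _, c1 = kinetics.two_tissue_model(inputs["t"], inputs["cp"], theta, gm_tac.schedule)
    return fit, c1


def aic_score(wrss: float, n_frames: int, n_params: int) -> float:
    """AIC = n ln(WRSS/n) + 2p (constants dropped; same-data comparisons only)."""
    if wrss < 0:
        raise ValueError("wrss must be >= 0")
    if wrss == 0.0:
        return -np.inf
    return float(n_frames * np.log(wrss / n_frames) + 2 * n_params)


def aic(fit: FitResult) -> float:
    return aic_score(fit.wrss, fit.n_frames, fit.n_params)


def select_model(fits: list[FitResult]) -> str:
    """Lowest-AIC converged model; exact AIC ties go to fewer parameters.

    If no candidate converged, the lowest-AIC non-converged model is chosen
    (its ``converged`` flag remains False for downstream reporting).
    """
    if not fits:
        raise ValueError("select_model requires at least one candidate fit")
    pool = [f for f in fits if f.converged] or list(fits)
    best = min(pool, key=lambda f: (f.aic, f.n_params))
    return best.model_id
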