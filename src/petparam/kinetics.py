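"""Weighted non-linear compartment fitting and the shared convolution engine.

Two models are fitted by weighted non-linear least squares:

* the reversible one-tissue compartment model with fractional blood volume
  (``1T2k_VB``),

      C(t) = (1 - VB) * K1 * [Cp (*) exp(-k2 t)](t) + VB * C_wb(t),

  whose macro-parameter is the total volume of distribution VT = K1/k2; and

* the simplified reference tissue model (SRTM),

      C(t) = R1 C'(t) + R1 (k2' - k2a) [C' (*) exp(-k2a t)](t),

  whose macro-parameter is the binding potential BPND = R1 k2'/k2a - 1.

Frame values are modelled as the time-average of the instantaneous model
curve over each frame, matching how a tomograph bins counts.  Weights follow
the count-based frame-variance model

    sigma^2 = dcf^2 * T / L^2        (L = frame length in seconds,
                                      T = whole-scanner trues, dcf = decay
                                      correction factor)

with per-frame weight 1/sigma^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .schedule import FrameSchedule
from .inputfunc import InputFunction

__all__ = [
    "WeightVector",
    "KineticFit",
    "frame_weights",
    "convolve_exp",
    "frame_average",
    "fit_1t2kvb",
    "fit_srtm",
]


# ---------------------------------------------------------------------------
# frame weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    """Per-frame variance and weight (1/variance; 0 where trues are 0)."""

    sigma2: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma2", np.asarray(self.sigma2, dtype=float))
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))
        if np.any(self.weight < 0) or not np.all(np.isfinite(self.weight)):
            raise ValueError("weights must be finite and non-negative")

    @property
    def sqrt_weight(self) -> np.ndarray:
        return np.sqrt(self.weight)


def frame_weights(schedule: FrameSchedule) -> WeightVector:
    """Count-based frame variances and weights.

    sigma^2 = dcf^2 * T / L^2 with the frame length L in *seconds*; frames
    with zero trues get zero weight (and an undefined, zero variance).
    """
    if np.any(schedule.trues < 0):
        raise ValueError("negative true counts")
    L = schedule.duration_s
    T = schedule.trues
    sigma2 = schedule.dcf ** 2 * T / L ** 2
    weight = np.zeros_like(sigma2)
    nz = sigma2 > 0
    weight[nz] = 1.0 / sigma2[nz]
    return WeightVector(sigma2=sigma2, weight=weight)


# ---------------------------------------------------------------------------
# convolution engine
# ---------------------------------------------------------------------------

def convolve_exp(curve: np.ndarray, theta: float, time: np.ndarray) -> np.ndarray:
    """Convolution of a sampled curve with ``exp(-theta t)``.

    The curve is treated as piecewise linear between grid points and each
    segment integrated in closed form, so the result is exact for piecewise
    linear inputs.  ``theta = 0`` returns the running integral.

    Parameters
    ----------
    curve, time
        Sampled curve and its strictly increasing time grid (minutes).
    theta
        Decay rate of the kernel, min^-1, >= 0.
    """
    f = np.asarray(curve, dtype=float)
    t = np.asarray(time, dtype=float)
    if f.shape != t.shape:
        raise ValueError("curve and time grid must have the same shape")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")

    if theta == 0.0:
        out = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dt)])
        return out

    x = theta * dt
    # segment contribution with f linear on [t_i, t_{i+1}]:
    #   g_i = \int_0^{dt} (a + b s) exp(-theta (dt - s)) ds
    #       = (a + b dt) P/theta - b Q/theta^2,
    #   P = 1 - exp(-x),  Q = 1 - exp(-x)(1 + x)
    a = f[:-1]
    b = np.diff(f) / dt
    ex = np.exp(-x)
    P = -np.expm1(-x)
    small = x < 1e-6
    Q = np.where(small, 0.5 * x ** 2 - x ** 3 / 3.0, 1.0 - ex * (1.0 + x))
    g = (a + b * dt) * P / theta - b * Q / theta ** 2

    # y_{i+1} = y_i exp(-x_i) + g_i  =>  y_n = exp(-theta t_n) * sum_{j<n} g_j exp(theta t_{j+1})
    # (all-positive accumulation; exponent chunked to stay in range)
    out = np.zeros_like(f)
    n = f.size
    chunk = max(16, int(500.0 / (theta * max(dt.max(), 1e-12))))
    start = 0
    y0 = 0.0
    while start < n - 1:
        stop = min(start + chunk, n - 1)
        tseg = t[start : stop + 1]
        gseg = g[start:stop]
        w = np.exp(theta * (t[start + 1 : stop + 1] - tseg[0]))
        cs = np.cumsum(gseg * w)
        decay = np.exp(-theta * (tseg[1:] - tseg[0]))
        out[start + 1 : stop + 1] = decay * (cs + y0)
        y0 = out[stop]
        start = stop
    return out


def frame_average(curve: np.ndarray, time: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average of a fine-grid curve over each frame interval.

    Uses the cumulative trapezoid integral interpolated at frame boundaries.
    Raises if the schedule extends beyond the grid.
    """
    t = np.asarray(time, dtype=float)
    if schedule.end[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"schedule ends at {schedule.end[-1]:.3f} min but the input grid "
            f"stops at {t[-1]:.3f} min"
        )
    dt = np.diff(t)
    Y = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1]) * dt)])
    Ys = np.interp(schedule.start, t, Y)
    Ye = np.interp(schedule.end, t, Y)
    return (Ye - Ys) / schedule.duration


def sample_frames(curve: np.ndarray, time: np.ndarray, schedule: FrameSchedule,
                  convention: str = "average") -> np.ndarray:
    """Sample a fine-grid curve per frame: time-average (default) or mid-time."""
    if convention == "average":
        return frame_average(curve, time, schedule)
    if convention == "midpoint":
        return np.interp(schedule.mid, time, curve)
    raise ValueError(f"unknown frame-sampling convention {convention!r}")


def interp_tac_fine(values: np.ndarray, schedule: FrameSchedule,
                    time: np.ndarray, mode: str = "area") -> np.ndarray:
    """Continuous-time reconstruction of a frame-sampled TAC.

    ``mode='midpoint'`` anchors frame values at mid-times (zero at t = 0,
    constant extrapolation).  ``mode='area'`` (default) instead solves for
    knot values such that the piecewise-linear curve reproduces the observed
    frame averages exactly — the appropriate inverse of frame binning, and
    markedly more accurate around the peak.  Tiny negative undershoots of
    the area solve are clipped to zero.
    """
    values = np.asarray(values, dtype=float)
    if mode == "midpoint":
        knots = np.concatenate([[0.0], schedule.mid])
        vals = np.concatenate([[0.0], values])
        return np.interp(time, knots, vals)
    if mode != "area":
        raise ValueError(f"unknown TAC interpolation mode {mode!r}")
    mids = np.concatenate([[0.0], schedule.mid, [schedule.end[-1]]])
    n = len(schedule)
    nk = mids.size
    # frame-average of each piecewise-linear hat basis function
    fine = np.linspace(0.0, schedule.end[-1], 8 * int(schedule.end[-1] / schedule.duration.min()) + 1)
    A = np.empty((n, nk))
    for k in range(nk):
        hat = np.zeros(nk)
        hat[k] = 1.0
        A[:, k] = frame_average(np.interp(fine, mids, hat), fine, schedule)
    # fix v(0) = 0 and tie the end knot to the last mid-time knot
    A2 = A[:, 1 : n + 1].copy()
    A2[:, -1] += A[:, n + 1]
    v = np.linalg.solve(A2, values)
    knots = np.clip(np.concatenate([[0.0], v, [v[-1]]]), 0.0, None)
    return np.interp(time, mids, knots)


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class KineticFit:
    """Result of a non-linear (or basis) kinetic fit."""

    model: str
    params: dict
    wrss: float
    converged: bool
    n_iter: int = 0
    start_values: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wrss < -1e-12:
            raise ValueError("WRSS must be non-negative")
        p = self.params
        if "K1" in p and "k2" in p and "VT" in p and p["k2"] > 0:
            if not np.isclose(p["VT"], p["K1"] / p["k2"], rtol=1e-8, atol=1e-12):
                raise ValueError("inconsistent VT != K1/k2")
        if "BPND" in p and "DVR" in p:
            if not np.isclose(p["DVR"], p["BPND"] + 1.0, rtol=1e-8, atol=1e-10):
                raise ValueError("inconsistent DVR != BPND + 1")

    def __getitem__(self, key: str) -> float:
        return self.params[key]


# ---------------------------------------------------------------------------
# 1T2k_VB
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS_1T = {"K1": (0.0, 2.0), "k2": (1e-4, 1.0), "VB": (0.0, 0.2)}
_DEFAULT_START_1T = {"K1": 0.1, "k2": 0.05, "VB": 0.05}

# deterministic lattice of fallback starts (fractions of the bound range)
_MULTISTART_FRACS = [0.15, 0.35, 0.55, 0.75, 0.9]


def model_1t2kvb(
    K1: float,
    k2: float,
    VB: float,
    input_function: InputFunction,
    schedule: FrameSchedule,
    *,
    one_minus_vb: bool = True,
    convention: str = "average",
) -> np.ndarray:
    """Frame-sampled model TAC of the one-tissue model with blood volume."""
    conv = convolve_exp(input_function.plasma_parent, k2, input_function.time)
    tissue = K1 * sample_frames(conv, input_function.time, schedule, convention)
    blood = sample_frames(input_function.whole_blood, input_function.time, schedule, convention)
    scale = (1.0 - VB) if one_minus_vb else 1.0
    return scale * tissue + VB * blood


def _check_tac(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("TAC contains non-finite values")
    if np.allclose(values, 0.0):
        raise ValueError("degenerate TAC: all frames are zero")
    return values


def fit_1t2kvb(
    tac,
    input_function: InputFunction,
    schedule: FrameSchedule | None = None,
    weights: WeightVector | None = None,
    start_values: dict | None = None,
    bounds: dict | None = None,
    *,
    fit_vb: bool = True,
    one_minus_vb: bool = True,
    convention: str = "average",
) -> KineticFit:
    """Weighted NLR fit of the 1T2k_VB model to a frame-sampled TAC.

    ``tac`` may be a TissueTAC (its schedule is used) or a plain per-frame
    array with ``schedule`` given explicitly.  Without a whole-blood curve
    VB cannot be estimated; callers that have no blood data should pass
    ``fit_vb=False`` (VB is then forced to 0).
    """
    values, schedule = _coerce_tac(tac, schedule)
    values = _check_tac(values)
    if not np.all(np.isfinite(input_function.plasma_parent)):
        raise ValueError("input function contains non-finite values")
    if weights is None:
        weights = frame_weights(schedule)
    sw = weights.sqrt_weight
    start = dict(_DEFAULT_START_1T, **(start_values or {}))
    bnds = dict(_DEFAULT_BOUNDS_1T, **(bounds or {}))
    names = ["K1", "k2", "VB"] if fit_vb else ["K1", "k2"]

    # crude data-driven K1 start: late-frame ratio to the running input integral
    conv0 = convolve_exp(input_function.plasma_parent, start["k2"], input_function.time)
    ref = sample_frames(conv0, input_function.time, schedule, convention)
    if ref[-1] > 0:
        start["K1"] = float(np.clip(values[-1] / ref[-1], *bnds["K1"]))
        start["K1"] = max(start["K1"], 1e-3)

    def residuals(x):
        p = dict(zip(names, x))
        vb = p.get("VB", 0.0)
        model = model_1t2kvb(
            p["K1"], p["k2"], vb, input_function, schedule,
            one_minus_vb=one_minus_vb, convention=convention,
        )
        return sw * (model - values)

    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])
    x0 = np.clip(np.array([start[n] for n in names]), lo, hi)

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    best = sol
    if not sol.success:
        for frac in _MULTISTART_FRACS:
            x_alt = lo + frac * (hi - lo)
            x_alt[0] = max(x_alt[0], 1e-3)
            trial = least_squares(residuals, x_alt, bounds=(lo, hi), method="trf",
                                  xtol=1e-12, ftol=1e-12)
            if trial.success and trial.cost < best.cost:
                best = trial
    p = dict(zip(names, best.x))
    vb = p.get("VB", 0.0)
    params = {"K1": p["K1"], "k2": p["k2"], "VB": vb, "VT": p["K1"] / p["k2"]}
    return KineticFit(
        model="1T2k_VB",
        params=params,
        wrss=float(2.0 * best.cost),
        converged=bool(best.success),
        n_iter=int(best.nfev),
        start_values={n: float(v) for n, v in zip(names, x0)},
    )


# ---------------------------------------------------------------------------
# SRTM
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS_SRTM = {"R1": (0.0, 5.0), "k2p": (1e-4, 1.0), "k2a": (1e-4, 1.0)}
_DEFAULT_START_SRTM = {"R1": 1.0, "k2p": 0.05, "k2a": 0.02}


def model_srtm(
    R1: float,
    k2p: float,
    k2a: float,
    ref_fine: np.ndarray,
    time: np.ndarray,
    schedule: FrameSchedule,
    ref_frames: np.ndarray,
    *,
    convention: str = "average",
) -> np.ndarray:
    conv = convolve_exp(ref_fine, k2a, time)
    conv_frames = sample_frames(conv, time, schedule, convention)
    return R1 * ref_frames + R1 * (k2p - k2a) * conv_frames


def fit_srtm(
    tac,
    reference_tac,
    schedule: FrameSchedule | None = None,
    weights: WeightVector | None = None,
    start_values: dict | None = None,
    bounds: dict | None = None,
    *,
    time_fine: np.ndarray | None = None,
    convention: str = "average",
    ill_conditioned_tol: float = 0.05,
) -> KineticFit:
    """Weighted NLR fit of the simplified reference tissue model.

    The reference TAC is linearly interpolated onto a fine grid (zero anchor
    at t = 0) for the convolution term.  Fits in which the estimated
    ``k2' - k2a`` separation is below ``ill_conditioned_tol * k2'`` are
    flagged ``ill_conditioned`` — the regime where the three SRTM parameters
    degenerate (the model collapses to C = R1 C').
    """
    values, schedule = _coerce_tac(tac, schedule)
    values = _check_tac(values)
    ref_values, _ = _coerce_tac(reference_tac, schedule)
    if np.allclose(ref_values, 0.0):
        raise ValueError("reference TAC is all zeros")
    if weights is None:
        weights = frame_weights(schedule)
    sw = weights.sqrt_weight
    if time_fine is None:
        time_fine = np.arange(0.0, schedule.total_minutes + 0.005, 0.01)
    ref_fine = interp_tac_fine(ref_values, schedule, time_fine)

    start = dict(_DEFAULT_START_SRTM, **(start_values or {}))
    bnds = dict(_DEFAULT_BOUNDS_SRTM, **(bounds or {}))
    names = ["R1", "k2p", "k2a"]

    def residuals(x):
        model = model_srtm(x[0], x[1], x[2], ref_fine, time_fine, schedule,
                           ref_values, convention=convention)
        return sw * (model - values)

    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])
    x0 = np.clip(np.array([start[n] for n in names]), lo, hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    best = sol
    if not sol.success:
        for frac in _MULTISTART_FRACS:
            x_alt = lo + frac * (hi - lo)
            trial = least_squares(residuals, x_alt, bounds=(lo, hi), method="trf",
                                  xtol=1e-12, ftol=1e-12)
            if trial.success and trial.cost < best.cost:
                best = trial
    R1, k2p, k2a = best.x
    bpnd = R1 * k2p / k2a - 1.0
    flags = {}
    if abs(k2p - k2a) < ill_conditioned_tol * k2p:
        flags["ill_conditioned"] = True
    params = {"R1": R1, "k2p": k2p, "k2a": k2a, "BPND": bpnd, "DVR": bpnd + 1.0}
    return KineticFit(
        model="SRTM",
        params=params,
        wrss=float(2.0 * best.cost),
        converged=bool(best.success),
        n_iter=int(best.nfev),
        start_values={n: float(v) for n, v in zip(names, x0)},
        flags=flags,
    )


def _coerce_tac(tac, schedule: FrameSchedule | None):
    """Accept a TissueTAC-like object (``.values``/``.schedule``) or an array."""
    if hasattr(tac, "values") and hasattr(tac, "schedule"):
        return np.asarray(tac.values, dtype=float), tac.schedule
    if schedule is None:
        raise ValueError("a FrameSchedule is required with a bare array TAC")
    return np.asarray(tac, dtype=float), schedule
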