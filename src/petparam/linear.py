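"""Graphical and multilinear estimators with a configurable start time t*.

All methods regress transformed integrals of the frame-sampled curves after
a start time t* (frame mid-times >= t*):

* Logan (plasma input): int_0^T C / C(T) on int_0^T Cp / C(T); the slope is
  the total volume of distribution VT.
* Reference Logan: the same construction with the reference-region TAC in
  place of plasma; the slope is the distribution volume ratio DVR.  When a
  reference efflux rate k2' is supplied the operational equation adds the
  C'(T)/k2' term; by default it is omitted (k2' not fixed).
* MRTM family (multilinear rearrangements):
    MRTMo: int C / C  ~  b1 * int C'/C + b2 * C'/C + b3;   DVR = b1, k2' = b1/b2
    MRTM1: C(T)  ~  b1 * int C' + b2 * int C + b3 * C'(T);
           DVR = -b1/b2, k2' = b1/b3, R1 = b3
    MRTM2: C(T)  ~  b1 * (int C' + C'(T)/k2') + b2 * int C;
           DVR = -b1/b2, R1 = b1/k2'  (k2' must be supplied)
    MRTM3/MRTM4: non-canonical, clearly-labelled variants shipped as the
           MRTM1/MRTM2 designs solved with count-model weighted least
           squares instead of ordinary least squares.

Reference-tissue integrals are accumulated by the trapezoid rule on frame
mid-times with a zero anchor at t = 0; the two curves of a reference method
share the convention, so their discretization errors cancel in the ratio.
Plasma-input Logan instead pairs the exact fine-grid plasma integral with a
tissue integral from the area-preserving frame reconstruction, keeping both
axes accurate.  Regressions are unweighted by default; ``weights`` switches
to weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import FrameSchedule
from .inputfunc import InputFunction
from .kinetics import WeightVector, _coerce_tac

__all__ = ["LinearFitResult", "logan_vt", "rlogan_dvr", "mrtm", "MRTM_VARIANTS"]

MRTM_VARIANTS = ("MRTMo", "MRTM1", "MRTM2", "MRTM3", "MRTM4")

#: default start times (minutes), the package's operational settings
DEFAULT_TSTAR = {"Logan": 10.0, "RLogan": 30.0, "MRTM": 10.0}


@dataclass
class LinearFitResult:
    method: str
    tstar: float
    coefficients: np.ndarray
    params: dict
    r_squared: float
    n_frames_used: int
    flags: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


# ---------------------------------------------------------------------------
# integral helpers
# ---------------------------------------------------------------------------

def cumulative_frame_integral(values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Integral of a frame-sampled TAC from 0 to each frame mid-time:
    trapezoid on mid-times with a zero anchor at t = 0."""
    mid = np.concatenate([[0.0], schedule.mid])
    v = np.concatenate([[0.0], np.asarray(values, dtype=float)])
    return np.cumsum(np.diff(mid) * 0.5 * (v[1:] + v[:-1]))


def plasma_integral_at(times: np.ndarray, input_function: InputFunction) -> np.ndarray:
    """Exact (fine-grid trapezoid) running integral of the plasma-parent
    curve, evaluated at arbitrary times."""
    t = input_function.time
    c = input_function.plasma_parent
    Y = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
    return np.interp(times, t, Y)


def plasma_frame_integral(input_function: InputFunction, schedule: FrameSchedule) -> np.ndarray:
    """Plasma-parent integral to each frame mid-time, accumulated with the
    same frame-level trapezoid convention as the tissue curves, so that
    tissue/plasma integral ratios are discretization-consistent."""
    from .kinetics import sample_frames

    cp = sample_frames(input_function.plasma_parent, input_function.time,
                       schedule, "average")
    return cumulative_frame_integral(cp, schedule)


def _area_operator(schedule: FrameSchedule) -> np.ndarray:
    """Linear operator mapping frame values to the running tissue integral
    at frame mid-times, via the (unclipped) area-preserving piecewise-linear
    reconstruction.  Exactly linear in the TAC, so scale invariance and
    noise properties of the graphical estimators are preserved."""
    from .kinetics import frame_average

    n = len(schedule)
    mids = np.concatenate([[0.0], schedule.mid, [schedule.end[-1]]])
    fine = np.linspace(0.0, schedule.end[-1],
                       8 * int(schedule.end[-1] / schedule.duration.min()) + 1)
    nk = mids.size
    A = np.empty((n, nk))
    T = np.empty((n, nk))
    dt = np.diff(fine)
    for k in range(nk):
        hat = np.zeros(nk)
        hat[k] = 1.0
        curve = np.interp(fine, mids, hat)
        A[:, k] = frame_average(curve, fine, schedule)
        Y = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1]) * dt)])
        T[:, k] = np.interp(schedule.mid, fine, Y)
    A2 = A[:, 1 : n + 1].copy()
    A2[:, -1] += A[:, n + 1]
    T2 = T[:, 1 : n + 1].copy()
    T2[:, -1] += T[:, n + 1]
    return T2 @ np.linalg.inv(A2)


_AREA_OP_CACHE: dict[tuple, np.ndarray] = {}


def area_frame_integral(values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Running integral of a frame-sampled TAC at frame mid-times using the
    area-preserving reconstruction (cached linear operator per schedule)."""
    key = (tuple(schedule.start), tuple(schedule.duration))
    op = _AREA_OP_CACHE.get(key)
    if op is None:
        op = _area_operator(schedule)
        if len(_AREA_OP_CACHE) > 8:
            _AREA_OP_CACHE.clear()
        _AREA_OP_CACHE[key] = op
    return op @ np.asarray(values, dtype=float)


def _window(schedule: FrameSchedule, tstar: float, n_coef: int) -> np.ndarray:
    if tstar < 0 or tstar >= schedule.end[-1]:
        raise ValueError(f"t* = {tstar} min lies outside the scan")
    keep = schedule.mid >= tstar
    if keep.sum() < n_coef + 1:
        raise ValueError(
            f"only {int(keep.sum())} frames after t* = {tstar} min; "
            f"need at least {n_coef + 1}"
        )
    return keep


def _solve(X: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """(weighted) least squares; returns (beta, r^2 of the fit, singular flag)."""
    if w is not None:
        sw = np.sqrt(w)
        Xs, ys = X * sw[:, None], y * sw
    else:
        Xs, ys = X, y
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    singular = rank < X.shape[1]
    pred = X @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return beta, max(min(r2, 1.0), 0.0), singular


# ---------------------------------------------------------------------------
# Logan
# ---------------------------------------------------------------------------

def logan_vt(
    tac,
    input_function: InputFunction,
    tstar: float = DEFAULT_TSTAR["Logan"],
    schedule: FrameSchedule | None = None,
    weights: WeightVector | None = None,
) -> LinearFitResult:
    """Plasma-input graphical (Logan) estimate of VT."""
    values, schedule = _coerce_tac(tac, schedule)
    keep = _window(schedule, tstar, 2)
    if np.any(values[keep] <= 0):
        raise ValueError("non-positive tissue activity inside the t* window")
    int_c = area_frame_integral(values, schedule)
    int_p = plasma_integral_at(schedule.mid, input_function)
    y = int_c[keep] / values[keep]
    x = int_p[keep] / values[keep]
    X = np.column_stack([x, np.ones_like(x)])
    w = weights.weight[keep] if weights is not None else None
    beta, r2, singular = _solve(X, y, w)
    return LinearFitResult(
        method="Logan",
        tstar=tstar,
        coefficients=beta,
        params={"VT": float(beta[0]), "intercept": float(beta[1])},
        r_squared=r2,
        n_frames_used=int(keep.sum()),
        flags={"singular": singular} if singular else {},
    )


def rlogan_dvr(
    tac,
    reference_tac,
    tstar: float = DEFAULT_TSTAR["RLogan"],
    k2_prime: float | None = None,
    schedule: FrameSchedule | None = None,
    weights: WeightVector | None = None,
) -> LinearFitResult:
    """Reference-region graphical (reference Logan) estimate of DVR.

    With ``k2_prime`` the full operational regressor
    (int C' + C'/k2')/C is used; without it the C'/k2' term is omitted.
    """
    values, schedule = _coerce_tac(tac, schedule)
    ref, _ = _coerce_tac(reference_tac, schedule)
    keep = _window(schedule, tstar, 2)
    if np.any(values[keep] <= 0):
        raise ValueError("non-positive tissue activity inside the t* window")
    int_c = cumulative_frame_integral(values, schedule)
    int_r = cumulative_frame_integral(ref, schedule)
    num = int_r + (ref / k2_prime if k2_prime else 0.0)
    y = int_c[keep] / values[keep]
    x = num[keep] / values[keep]
    X = np.column_stack([x, np.ones_like(x)])
    w = weights.weight[keep] if weights is not None else None
    beta, r2, singular = _solve(X, y, w)
    dvr = float(beta[0])
    return LinearFitResult(
        method="RLogan",
        tstar=tstar,
        coefficients=beta,
        params={"DVR": dvr, "BPND": dvr - 1.0, "intercept": float(beta[1])},
        r_squared=r2,
        n_frames_used=int(keep.sum()),
        flags={"singular": singular} if singular else {},
    )


# ---------------------------------------------------------------------------
# MRTM family
# ---------------------------------------------------------------------------

def mrtm(
    tac,
    reference_tac,
    tstar: float = DEFAULT_TSTAR["MRTM"],
    variant: str = "MRTM1",
    k2_prime: float | None = None,
    schedule: FrameSchedule | None = None,
    weights: WeightVector | None = None,
) -> LinearFitResult:
    """Multilinear reference tissue model, variants MRTMo/1/2/3/4.

    MRTM3 and MRTM4 are non-canonical, documented stand-ins: the MRTM1 and
    MRTM2 designs solved with count-model weighted least squares (their
    results carry a ``non_canonical`` flag).
    """
    if variant not in MRTM_VARIANTS:
        raise ValueError(f"unknown MRTM variant {variant!r}")
    values, schedule = _coerce_tac(tac, schedule)
    ref, _ = _coerce_tac(reference_tac, schedule)
    int_c = cumulative_frame_integral(values, schedule)
    int_r = cumulative_frame_integral(ref, schedule)

    flags: dict = {}
    wls = weights
    base = variant
    if variant in ("MRTM3", "MRTM4"):
        base = "MRTM1" if variant == "MRTM3" else "MRTM2"
        flags["non_canonical"] = True
        if wls is None:
            from .kinetics import frame_weights
            wls = frame_weights(schedule)

    n_coef = 2 if base == "MRTM2" else 3
    keep = _window(schedule, tstar, n_coef)
    w = wls.weight[keep] if wls is not None else None

    if base == "MRTMo":
        if np.any(values[keep] <= 0):
            raise ValueError("non-positive tissue activity inside the t* window")
        y = int_c[keep] / values[keep]
        X = np.column_stack(
            [int_r[keep] / values[keep], ref[keep] / values[keep], np.ones(int(keep.sum()))]
        )
        beta, r2, singular = _solve(X, y, w)
        dvr = float(beta[0])
        k2p = float(beta[0] / beta[1]) if beta[1] != 0 else np.nan
        params = {"DVR": dvr, "BPND": dvr - 1.0, "k2p": k2p}
    elif base == "MRTM1":
        y = values[keep]
        X = np.column_stack([int_r[keep], int_c[keep], ref[keep]])
        beta, r2, singular = _solve(X, y, w)
        dvr = float(-beta[0] / beta[1]) if beta[1] != 0 else np.nan
        params = {
            "DVR": dvr,
            "BPND": dvr - 1.0,
            "k2p": float(beta[0] / beta[2]) if beta[2] != 0 else np.nan,
            "R1": float(beta[2]),
        }
    else:  # MRTM2
        if k2_prime is None:
            raise ValueError(f"{variant} requires k2_prime")
        y = values[keep]
        X = np.column_stack([int_r[keep] + ref[keep] / k2_prime, int_c[keep]])
        beta, r2, singular = _solve(X, y, w)
        dvr = float(-beta[0] / beta[1]) if beta[1] != 0 else np.nan
        params = {"DVR": dvr, "BPND": dvr - 1.0, "R1": float(beta[0] / k2_prime)}

    if singular:
        # rank-deficient design (e.g. target identical to reference): the
        # minimum-norm coefficients are kept, but derived parameters may be
        # indeterminate; callers must check the flag
        flags["singular"] = True
    return LinearFitResult(
        method=variant,
        tstar=tstar,
        coefficients=beta,
        params=params,
        r_squared=r2,
        n_frames_used=int(keep.sum()),
        flags=flags,
    )
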