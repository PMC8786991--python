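"""Basis-function estimators: RPM, SRTM2 and spectral analysis.

RPM solves the simplified reference tissue model on a grid of candidate
apparent efflux rates theta (= k2a).  For each theta the model is linear in
two coefficients,

    C = R1 * C' + phi * [C' (*) exp(-theta t)],

so a weighted linear solve per grid node plus a scan for the minimum
weighted residual sum of squares replaces the non-linear fit.  The reference
efflux rate follows as k2' = phi/R1 + theta and BPND = R1 k2'/theta - 1.

SRTM2 runs RPM twice over a voxel population: pass 1 estimates k2' per
voxel; a single k2'* (median over voxels with BPND above a threshold,
default 3) is then fixed, and pass 2 refits each voxel with one coefficient,

    C = R1 * [C' + (k2'* - theta) C' (*) exp(-theta t)],

halving the parameter count and the variance of noisy voxel estimates.

Spectral analysis decomposes a plasma-input TAC into a non-negative sum of
convolved exponentials plus a non-negative whole-blood component:

    C ~ sum_i alpha_i [Cp (*) exp(-beta_i t)] + VB * C_wb,  alpha_i >= 0,

solved by weighted non-negative least squares; VT = sum alpha_i/beta_i and
K1 = sum alpha_i.

Basis grids are logarithmically spaced; defaults are theta in [0.01, 0.1]
min^-1 with 30 nodes for RPM/SRTM2 and beta in [0.01, 0.1] min^-1 with 50
nodes for spectral analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .schedule import FrameSchedule
from .inputfunc import InputFunction
from .kinetics import (
    KineticFit,
    WeightVector,
    _coerce_tac,
    convolve_exp,
    frame_weights,
    interp_tac_fine,
    sample_frames,
)

__all__ = [
    "BasisGrid",
    "SpectralResult",
    "reference_basis",
    "plasma_basis",
    "rpm",
    "rpm_matrix",
    "srtm2",
    "spectral_analysis",
]


@dataclass(frozen=True)
class BasisGrid:
    """Logarithmic grid of exponential rates (min^-1)."""

    theta_min: float = 0.01
    theta_max: float = 0.1
    count: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.theta_min < self.theta_max):
            raise ValueError("need 0 < theta_min < theta_max")
        if self.count < 2:
            raise ValueError("need at least 2 basis functions")

    @property
    def thetas(self) -> np.ndarray:
        return np.geomspace(self.theta_min, self.theta_max, self.count)

    @classmethod
    def for_spectral(cls) -> "BasisGrid":
        return cls(0.01, 0.1, 50)


# ---------------------------------------------------------------------------
# precomputed bases
# ---------------------------------------------------------------------------

def reference_basis(
    ref_values: np.ndarray,
    schedule: FrameSchedule,
    grid: BasisGrid,
    *,
    time_fine: np.ndarray | None = None,
    convention: str = "average",
) -> np.ndarray:
    """Frame-sampled [C' (*) exp(-theta t)] for every grid node.

    Computed once per (reference TAC, grid) and reused across voxels;
    returns an array of shape (count, n_frames).
    """
    if time_fine is None:
        time_fine = np.arange(0.0, schedule.total_minutes + 0.005, 0.01)
    ref_fine = interp_tac_fine(np.asarray(ref_values, dtype=float), schedule, time_fine)
    return np.stack(
        [
            sample_frames(convolve_exp(ref_fine, th, time_fine), time_fine, schedule, convention)
            for th in grid.thetas
        ]
    )


def plasma_basis(
    input_function: InputFunction,
    schedule: FrameSchedule,
    grid: BasisGrid,
    *,
    convention: str = "average",
) -> np.ndarray:
    """Frame-sampled [Cp (*) exp(-beta t)] for every grid node."""
    t = input_function.time
    return np.stack(
        [
            sample_frames(convolve_exp(input_function.plasma_parent, b, t), t, schedule, convention)
            for b in grid.thetas
        ]
    )


# ---------------------------------------------------------------------------
# RPM
# ---------------------------------------------------------------------------

def rpm_matrix(
    tacs: np.ndarray,
    ref_values: np.ndarray,
    schedule: FrameSchedule,
    weights: WeightVector | None = None,
    grid: BasisGrid | None = None,
    *,
    basis: np.ndarray | None = None,
    k2p_fixed: float | None = None,
    convention: str = "average",
):
    """Vectorized RPM (or its k2'-fixed second pass) over a TAC matrix.

    Parameters
    ----------
    tacs
        Array (n_voxels, n_frames).
    k2p_fixed
        If given, run the one-coefficient SRTM2 form with k2' fixed.

    Returns
    -------
    dict of per-voxel arrays: R1, k2p, k2a (= best theta), BPND, wrss, and
    ``edge`` (True where the best theta sits on a grid boundary).
    """
    Y = np.atleast_2d(np.asarray(tacs, dtype=float))
    ref = np.asarray(ref_values, dtype=float)
    if np.allclose(ref, 0.0):
        raise ValueError("reference TAC is all zeros")
    grid = grid or BasisGrid()
    if weights is None:
        weights = frame_weights(schedule)
    w = weights.weight
    if basis is None:
        basis = reference_basis(ref, schedule, grid, convention=convention)
    thetas = grid.thetas
    n_vox = Y.shape[0]
    n_theta = thetas.size

    yw = Y * w  # (n_vox, F)
    yy = np.einsum("vf,vf->v", yw, Y)
    best = {
        "wrss": np.full(n_vox, np.inf),
        "R1": np.zeros(n_vox),
        "phi": np.zeros(n_vox),
        "theta_idx": np.zeros(n_vox, dtype=int),
    }
    rw = ref * w
    a11 = float(rw @ ref)
    for j in range(n_theta):
        b = basis[j]
        if k2p_fixed is None:
            # two-coefficient solve [ref, b] via 2x2 normal equations
            a12 = float(rw @ b)
            a22 = float((b * w) @ b)
            det = a11 * a22 - a12 * a12
            if det <= 0 or not np.isfinite(det):
                continue
            c1 = yw @ ref
            c2 = yw @ b
            R1 = (a22 * c1 - a12 * c2) / det
            phi = (a11 * c2 - a12 * c1) / det
            wrss = yy - (R1 * c1 + phi * c2)
        else:
            a = ref + (k2p_fixed - thetas[j]) * b
            denom = float((a * w) @ a)
            if denom <= 0:
                continue
            c = yw @ a
            R1 = c / denom
            phi = R1 * (k2p_fixed - thetas[j])
            wrss = yy - R1 * c
        better = wrss < best["wrss"]
        best["wrss"] = np.where(better, wrss, best["wrss"])
        best["R1"] = np.where(better, R1, best["R1"])
        best["phi"] = np.where(better, phi, best["phi"])
        best["theta_idx"] = np.where(better, j, best["theta_idx"])

    idx = best["theta_idx"]
    theta = thetas[idx]
    R1 = best["R1"]
    phi = best["phi"]
    with np.errstate(divide="ignore", invalid="ignore"):
        if k2p_fixed is None:
            k2p = np.where(R1 != 0, phi / R1 + theta, np.nan)
        else:
            k2p = np.full(n_vox, k2p_fixed)
        bpnd = np.where(theta > 0, R1 * k2p / theta - 1.0, np.nan)
    failed = ~np.isfinite(best["wrss"])
    return {
        "R1": R1,
        "k2p": k2p,
        "k2a": theta,
        "BPND": bpnd,
        "DVR": bpnd + 1.0,
        "wrss": np.clip(best["wrss"], 0.0, None),
        "edge": (idx == 0) | (idx == n_theta - 1),
        "failed": failed,
    }


def rpm(
    tac,
    reference_tac,
    weights: WeightVector | None = None,
    grid: BasisGrid | None = None,
    schedule: FrameSchedule | None = None,
    **kwargs,
) -> KineticFit:
    """Single-TAC RPM fit (basis-function SRTM)."""
    values, schedule = _coerce_tac(tac, schedule)
    ref, _ = _coerce_tac(reference_tac, schedule)
    res = rpm_matrix(values[None, :], ref, schedule, weights, grid, **kwargs)
    if res["failed"][0]:
        return KineticFit(model="RPM", params={}, wrss=0.0, converged=False,
                          flags={"singular": True})
    params = {k: float(res[k][0]) for k in ("R1", "k2p", "k2a", "BPND", "DVR")}
    flags = {"grid_edge": True} if res["edge"][0] else {}
    return KineticFit(
        model="RPM",
        params=params,
        wrss=float(res["wrss"][0]),
        converged=True,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# SRTM2
# ---------------------------------------------------------------------------

def srtm2(
    voxel_tacs: np.ndarray,
    reference_tac,
    weights: WeightVector | None = None,
    grid: BasisGrid | None = None,
    bp_threshold: float = 3.0,
    schedule: FrameSchedule | None = None,
    *,
    k2p_fixed: float | None = None,
    convention: str = "average",
):
    """Two-pass SRTM2 over a voxel population.

    Pass 1 is RPM per voxel; k2'* is the median k2' over voxels with
    pass-1 BPND above ``bp_threshold``.  If no voxel exceeds the threshold
    the median is taken over voxels with BPND > 0 instead and a warning is
    emitted.  Pass 2 refits every voxel with k2' fixed to k2'*.

    Returns (per-voxel result dict as in :func:`rpm_matrix`, k2p_star).
    ``k2p_fixed`` skips pass 1 and uses the supplied value directly.
    """
    if bp_threshold < 0:
        raise ValueError("bp_threshold must be >= 0")
    Y = np.atleast_2d(np.asarray(voxel_tacs, dtype=float))
    ref, schedule = _coerce_tac(reference_tac, schedule)
    grid = grid or BasisGrid()
    if weights is None:
        weights = frame_weights(schedule)
    basis = reference_basis(ref, schedule, grid, convention=convention)

    fallback = False
    if k2p_fixed is not None:
        k2p_star = float(k2p_fixed)
    else:
        pass1 = rpm_matrix(Y, ref, schedule, weights, grid, basis=basis,
                           convention=convention)
        ok = np.isfinite(pass1["k2p"]) & np.isfinite(pass1["BPND"])
        high = ok & (pass1["BPND"] > bp_threshold)
        if not np.any(high):
            fallback = True
            high = ok & (pass1["BPND"] > 0)
            warnings.warn(
                "SRTM2: no voxel with BPND above the threshold "
                f"({bp_threshold}); fixing k2' to the median over voxels "
                "with BPND > 0 instead",
                stacklevel=2,
            )
            if not np.any(high):
                raise ValueError("SRTM2: no voxel with positive BPND to fix k2'")
        k2p_star = float(np.median(pass1["k2p"][high]))

    pass2 = rpm_matrix(Y, ref, schedule, weights, grid, basis=basis,
                       k2p_fixed=k2p_star, convention=convention)
    pass2["fallback"] = fallback
    return pass2, k2p_star


# ---------------------------------------------------------------------------
# spectral analysis
# ---------------------------------------------------------------------------

@dataclass
class SpectralResult:
    """Non-negative spectrum of a plasma-input TAC."""

    betas: np.ndarray
    alphas: np.ndarray
    VB: float
    VT: float
    K1: float
    wrss: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.alphas < 0):
            raise ValueError("spectrum amplitudes must be non-negative")
        if self.VT < 0 or self.K1 < 0:
            raise ValueError("VT and K1 must be non-negative")

    @property
    def params(self) -> dict:
        return {"VT": self.VT, "K1": self.K1, "VB": self.VB}

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def spectral_analysis(
    tac,
    input_function: InputFunction,
    weights: WeightVector | None = None,
    grid: BasisGrid | None = None,
    schedule: FrameSchedule | None = None,
    *,
    basis: np.ndarray | None = None,
    blood_frames: np.ndarray | None = None,
    include_blood: bool = True,
    convention: str = "average",
) -> SpectralResult:
    """Weighted non-negative spectral decomposition of one TAC.

    The design holds one convolved-exponential column per grid node plus
    (by default) the whole-blood curve as an extra non-negative regressor
    whose coefficient is the fractional blood volume VB.
    """
    values, schedule = _coerce_tac(tac, schedule)
    grid = grid or BasisGrid.for_spectral()
    if weights is None:
        weights = frame_weights(schedule)
    if basis is None:
        basis = plasma_basis(input_function, schedule, grid, convention=convention)
    cols = [basis.T]
    if include_blood:
        if blood_frames is None:
            blood_frames = sample_frames(
                input_function.whole_blood, input_function.time, schedule, convention
            )
        cols.append(blood_frames[:, None])
    X = np.hstack(cols)
    sw = weights.sqrt_weight
    sol, rnorm = nnls(X * sw[:, None], values * sw)
    alphas = sol[: grid.count]
    vb = float(sol[grid.count]) if include_blood else 0.0
    flags = {}
    if np.all(sol == 0):
        flags["empty_spectrum"] = True
    return SpectralResult(
        betas=grid.thetas,
        alphas=alphas,
        VB=vb,
        VT=float(np.sum(alphas / grid.thetas)),
        K1=float(np.sum(alphas)),
        wrss=float(rnorm**2),
        flags=flags,
    )
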