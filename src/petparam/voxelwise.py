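"""Voxel-wise application of estimators and parametric-map handling.

Any regional estimator in the package can be applied independently to every
in-mask voxel of a 4D dynamic image to produce parametric maps (VT, K1,
DVR, BPND, R1, VB).  Reference-region methods use the mean TAC of the
reference mask; plasma-input methods require the input-function curves.
Failed voxels become NaN and are counted in the run report.  Maps inherit
the source image's affine; no resampling is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .schedule import FrameSchedule
from .inputfunc import InputFunction
from .kinetics import WeightVector, fit_1t2kvb, frame_weights
from .linear import logan_vt, mrtm, rlogan_dvr
from .basis import (
    BasisGrid,
    plasma_basis,
    rpm_matrix,
    spectral_analysis,
    srtm2,
)
from .tacgen import TissueTAC

__all__ = [
    "ParametricMap",
    "RegionTable",
    "extract_tacs",
    "reference_tac_from_mask",
    "fit_voxelwise",
    "clamp_map",
    "save_map",
    "load_dynamic",
]

#: map parameters produced by each method
METHOD_PARAMS = {
    "logan": ("VT",),
    "rlogan": ("DVR", "BPND"),
    "mrtmo": ("DVR", "BPND"),
    "mrtm1": ("DVR", "BPND", "R1"),
    "mrtm2": ("DVR", "BPND", "R1"),
    "mrtm3": ("DVR", "BPND", "R1"),
    "mrtm4": ("DVR", "BPND", "R1"),
    "rpm": ("BPND", "DVR", "R1"),
    "srtm2": ("BPND", "DVR", "R1"),
    "sa": ("VT", "K1", "VB"),
    "1t2kvb": ("VT", "K1", "k2", "VB"),
}

PLASMA_METHODS = {"logan", "sa", "1t2kvb"}
REFERENCE_METHODS = {"rlogan", "mrtmo", "mrtm1", "mrtm2", "mrtm3", "mrtm4", "rpm", "srtm2"}


@dataclass
class ParametricMap:
    """A 3D image of one kinetic parameter with provenance."""

    values: np.ndarray
    parameter: str
    method: str
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        # contract: voxels outside the mask carry no value
        self.values = np.where(self.mask, self.values, np.nan)

    def region_mean(self, region_mask: np.ndarray) -> float:
        sel = region_mask & self.mask
        return float(np.nanmean(self.values[sel]))

    @property
    def n_failed(self) -> int:
        return int(np.sum(~np.isfinite(self.values[self.mask])))


@dataclass
class RegionTable:
    """Per-region mean TACs extracted from a label image."""

    names: dict[int, str]
    tacs: dict[int, TissueTAC]
    voxel_counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, tac in self.tacs.items():
            for i, v in enumerate(tac.values):
                rows.append(
                    {
                        "label": label,
                        "name": self.names[label],
                        "frame": i,
                        "value_kBq_ml": v,
                    }
                )
        return pd.DataFrame(rows)


def extract_tacs(
    dynamic: np.ndarray,
    labels: np.ndarray,
    schedule: FrameSchedule,
    names: dict[int, str] | None = None,
) -> RegionTable:
    """Per-region mean TAC: unweighted mean over in-region voxels per frame.

    Labels present in the image but absent from ``names`` are kept with a
    numeric name (with a warning); empty regions named in ``names`` are
    omitted with a warning.
    """
    dynamic = np.asarray(dynamic, dtype=float)
    labels = np.asarray(labels)
    if dynamic.shape[:-1] != labels.shape:
        raise ValueError(
            f"spatial grids differ: dynamic {dynamic.shape[:-1]} vs labels {labels.shape}"
        )
    names = dict(names or {})
    present = [int(l) for l in np.unique(labels) if l != 0]
    for label in present:
        if label not in names:
            warnings.warn(f"label {label} has no name; keeping it as '{label}'",
                          stacklevel=2)
            names[label] = str(label)
    for label in list(names):
        if label not in present:
            warnings.warn(f"region '{names[label]}' (label {label}) is empty; omitted",
                          stacklevel=2)
            del names[label]
    tacs, counts = {}, {}
    for label in present:
        mask = labels == label
        counts[label] = int(mask.sum())
        tacs[label] = TissueTAC(
            values=dynamic[mask].mean(axis=0),
            schedule=schedule,
            provenance={"label": label, "name": names[label]},
        )
    return RegionTable(names=names, tacs=tacs, voxel_counts=counts)


def reference_tac_from_mask(
    dynamic: np.ndarray, reference_mask: np.ndarray, schedule: FrameSchedule
) -> TissueTAC:
    """Mean TAC over the reference mask (regional, not voxel-wise)."""
    mask = np.asarray(reference_mask, dtype=bool)
    if not mask.any():
        raise ValueError("reference mask is empty")
    return TissueTAC(
        values=np.asarray(dynamic, dtype=float)[mask].mean(axis=0),
        schedule=schedule,
        provenance={"role": "reference"},
    )


def fit_voxelwise(
    dynamic: np.ndarray,
    mask: np.ndarray,
    method: str,
    schedule: FrameSchedule,
    *,
    input_function: InputFunction | None = None,
    reference_tac=None,
    weights: WeightVector | None = None,
    grid: BasisGrid | None = None,
    tstar: float | None = None,
    k2_prime: float | None = None,
    bp_threshold: float = 3.0,
    seed_lineage: dict | None = None,
) -> dict[str, ParametricMap]:
    """Fit every in-mask voxel independently; one map per output parameter.

    Required curves are validated before any fitting: plasma-input methods
    (``logan``, ``sa``, ``1t2kvb``) need ``input_function``; reference
    methods need ``reference_tac``.  Voxels whose fit fails (singular
    design, non-positive activity in a graphical window, ...) become NaN
    and are counted in the maps' metadata.
    """
    method = method.lower()
    if method not in METHOD_PARAMS:
        raise ValueError(f"unknown method {method!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    dynamic = np.asarray(dynamic, dtype=float)
    if dynamic.shape[:-1] != mask.shape:
        raise ValueError("dynamic image and mask grids differ")
    if method in PLASMA_METHODS and input_function is None:
        raise ValueError(f"method {method!r} requires a plasma input function")
    if method in REFERENCE_METHODS and reference_tac is None:
        raise ValueError(f"method {method!r} requires a reference TAC")
    if weights is None:
        weights = frame_weights(schedule)

    Y = dynamic[mask]  # (n_voxels, n_frames)
    n_vox = Y.shape[0]
    out: dict[str, np.ndarray] = {p: np.full(n_vox, np.nan) for p in METHOD_PARAMS[method]}
    meta: dict = {
        "method": method,
        "tstar": tstar,
        "bp_threshold": bp_threshold if method == "srtm2" else None,
        "seed_lineage": seed_lineage or {},
    }
    if grid is not None:
        meta["grid"] = {"theta_min": grid.theta_min, "theta_max": grid.theta_max,
                        "count": grid.count}

    ref_values = None
    if reference_tac is not None:
        ref_values = (
            np.asarray(reference_tac.values, dtype=float)
            if hasattr(reference_tac, "values")
            else np.asarray(reference_tac, dtype=float)
        )

    if method in ("rpm", "srtm2"):
        grid = grid or BasisGrid()
        if method == "rpm":
            res = rpm_matrix(Y, ref_values, schedule, weights, grid)
        else:
            res, k2p_star = srtm2(
                Y, ref_values, weights, grid, bp_threshold, schedule=schedule,
                k2p_fixed=k2_prime,
            )
            meta["k2p_star"] = k2p_star
            meta["fallback"] = res.get("fallback", False)
        bad = res["failed"]
        for p in out:
            out[p] = np.where(bad, np.nan, res[p])
    elif method == "sa":
        grid = grid or BasisGrid.for_spectral()
        basis = plasma_basis(input_function, schedule, grid)
        from .kinetics import sample_frames

        blood = sample_frames(
            input_function.whole_blood, input_function.time, schedule, "average"
        )
        for i in range(n_vox):
            try:
                r = spectral_analysis(
                    Y[i], input_function, weights, grid, schedule=schedule,
                    basis=basis, blood_frames=blood,
                )
            except ValueError:
                continue
            for p in out:
                out[p][i] = r[p]
    else:
        kw: dict = {}
        for i in range(n_vox):
            try:
                if method == "logan":
                    r = logan_vt(Y[i], input_function,
                                 tstar if tstar is not None else 10.0,
                                 schedule=schedule, weights=None)
                elif method == "rlogan":
                    r = rlogan_dvr(Y[i], ref_values,
                                   tstar if tstar is not None else 30.0,
                                   k2_prime=k2_prime, schedule=schedule)
                elif method.startswith("mrtm"):
                    variant = {"mrtmo": "MRTMo"}.get(method, method.upper())
                    r = mrtm(Y[i], ref_values,
                             tstar if tstar is not None else 10.0,
                             variant=variant, k2_prime=k2_prime, schedule=schedule)
                else:  # 1t2kvb
                    r = fit_1t2kvb(Y[i], input_function, schedule, weights)
            except ValueError:
                continue
            for p in out:
                try:
                    out[p][i] = r[p]
                except KeyError:
                    pass

    maps: dict[str, ParametricMap] = {}
    for p, vec in out.items():
        vol = np.full(mask.shape, np.nan)
        vol[mask] = vec
        m = ParametricMap(values=vol, parameter=p, method=method, mask=mask,
                          metadata=dict(meta))
        m.metadata["n_failed"] = m.n_failed
        maps[p] = m
    return maps


def clamp_map(
    pmap: ParametricMap, bounds: tuple[float | None, float | None],
    policy: str = "clip",
) -> ParametricMap:
    """Clamp out-of-bounds voxels to the bound (``clip``) or NaN (``nan``);
    the number of affected voxels is recorded in metadata."""
    lo, hi = bounds
    v = pmap.values.copy()
    below = np.zeros_like(v, dtype=bool) if lo is None else (v < lo)
    above = np.zeros_like(v, dtype=bool) if hi is None else (v > hi)
    n = int(np.nansum(below | above))
    if policy == "clip":
        if lo is not None:
            v = np.where(below, lo, v)
        if hi is not None:
            v = np.where(above, hi, v)
    elif policy == "nan":
        v = np.where(below | above, np.nan, v)
    else:
        raise ValueError("policy must be 'clip' or 'nan'")
    meta = dict(pmap.metadata, clamp={"bounds": [lo, hi], "policy": policy, "n_clamped": n})
    return ParametricMap(values=v, parameter=pmap.parameter, method=pmap.method,
                         mask=pmap.mask, metadata=meta, affine=pmap.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _default_affine(voxel_size_mm=(2.0, 2.0, 2.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_dynamic(path, dynamic: np.ndarray, affine: np.ndarray | None = None,
                 sidecar: dict | None = None) -> None:
    affine = _default_affine() if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(dynamic, dtype=np.float32), affine), str(path))
    if sidecar is not None:
        with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)


def load_dynamic(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_map(path, pmap: ParametricMap) -> None:
    affine = pmap.affine if pmap.affine is not None else _default_affine()
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float32), affine), str(path))
    side = dict(pmap.metadata, parameter=pmap.parameter, method=pmap.method)
    with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
        json.dump(side, fh, indent=2, default=float)
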