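"""Synthetic dynamic-PET data with known ground truth.

The generator produces everything the analysis consumes: regional
time-activity curves (TACs) from the one-tissue forward model with blood
volume, a reference region with configurable efflux (including the
degenerate case where the reference efflux rate equals the targets' apparent
efflux rate), count-realistic frame noise, 4D digital phantoms, and paired
test-retest sessions with a configurable between-session effect.

Units throughout: minutes, kBq/mL, min^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schedule import FrameSchedule
from .inputfunc import FengParams, InputFunction, make_input_function
from .kinetics import (
    WeightVector,
    convolve_exp,
    frame_weights,
    sample_frames,
)

__all__ = [
    "GroundTruth",
    "TissueTAC",
    "PhantomSpec",
    "Phantom",
    "default_truths",
    "truth_grid",
    "make_tissue_tac",
    "make_reference_tac",
    "add_noise",
    "make_phantom",
    "make_trt_pair",
]


@dataclass(frozen=True)
class GroundTruth:
    """True kinetic parameters of one region.

    K1 in mL cm^-3 min^-1, k2 in min^-1, VB a unitless fraction in [0, 1).
    VT = K1/k2 follows; DVR/BPND/R1 are defined relative to a reference
    region's GroundTruth.
    """

    K1: float
    k2: float
    VB: float = 0.05

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError("K1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if not (0.0 <= self.VB < 1.0):
            raise ValueError("VB must lie in [0, 1)")

    @property
    def VT(self) -> float:
        return self.K1 / self.k2

    def dvr(self, reference: "GroundTruth") -> float:
        return self.VT / reference.VT

    def bpnd(self, reference: "GroundTruth") -> float:
        return self.dvr(reference) - 1.0

    def r1(self, reference: "GroundTruth") -> float:
        return self.K1 / reference.K1

    @classmethod
    def from_vt(cls, K1: float, VT: float, VB: float = 0.05) -> "GroundTruth":
        return cls(K1=K1, k2=K1 / VT, VB=VB)


@dataclass
class TissueTAC:
    """Frame-sampled, decay-corrected activity of one region or voxel."""

    values: np.ndarray
    schedule: FrameSchedule
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.schedule):
            raise ValueError("TAC length must match the schedule")


def default_truths() -> dict[str, GroundTruth]:
    """Physiologically plausible defaults for a high-binding tracer:
    two grey-matter regions (VT 15-22 mL/cm3) and a white-matter reference
    with VT ~ 5 whose efflux rate (k2' ~ 0.05 min^-1) is well separated
    from the targets' apparent efflux, so all reference-model parameters
    stay identifiable."""
    return {
        "grey_high": GroundTruth.from_vt(K1=0.35, VT=22.0, VB=0.05),
        "grey_low": GroundTruth.from_vt(K1=0.30, VT=15.0, VB=0.05),
        "reference": GroundTruth.from_vt(K1=0.25, VT=4.8, VB=0.04),
    }


def so_like_truths() -> dict[str, GroundTruth]:
    """The centrum-semi-ovale-like configuration: a slow-efflux white-matter
    reference whose k2' approximately equals the grey-matter apparent efflux
    rate k2a, which makes the (k2' - k2a) term of the reference model
    non-identifiable."""
    truths = default_truths()
    grey = truths["grey_high"]
    # reference k2' matched to the target's apparent efflux (= k2 for 1T)
    return dict(truths, reference=GroundTruth(K1=grey.k2 * 5.0, k2=grey.k2, VB=0.04))


def truth_grid(
    K1_values=(0.2, 0.3, 0.4),
    VT_values=(10.0, 15.0, 20.0),
    VB_values=(0.0, 0.05, 0.1),
) -> list[GroundTruth]:
    """The 27-combination parameter-recovery grid (K1 x VT x VB)."""
    return [
        GroundTruth.from_vt(K1=k1, VT=vt, VB=vb)
        for k1 in K1_values
        for vt in VT_values
        for vb in VB_values
    ]


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def make_tissue_tac(
    truth: GroundTruth,
    input_function: InputFunction,
    schedule: FrameSchedule,
    *,
    one_minus_vb: bool = True,
    convention: str = "average",
) -> TissueTAC:
    """Noiseless one-tissue TAC: (1-VB) K1 [Cp (*) e^-k2t] + VB C_wb,
    sampled as the time-average over each frame."""
    t = input_function.time
    if schedule.end[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"schedule extends to {schedule.end[-1]:.2f} min but the input "
            f"grid stops at {t[-1]:.2f} min"
        )
    conv = convolve_exp(input_function.plasma_parent, truth.k2, t)
    tissue = truth.K1 * sample_frames(conv, t, schedule, convention)
    scale = (1.0 - truth.VB) if one_minus_vb else 1.0
    values = scale * tissue
    if truth.VB > 0:
        blood = sample_frames(input_function.whole_blood, t, schedule, convention)
        values = values + truth.VB * blood
    values = np.clip(values, 0.0, None)
    return TissueTAC(
        values=values,
        schedule=schedule,
        provenance={"model": "1T2k_VB", "truth": asdict(truth), "noise": None},
    )


def make_reference_tac(
    truth: GroundTruth,
    input_function: InputFunction,
    schedule: FrameSchedule,
    *,
    target_k2a: float | None = None,
    degeneracy_rtol: float = 0.05,
    **kwargs,
) -> TissueTAC:
    """Noiseless reference-region TAC.

    Identical forward model to :func:`make_tissue_tac`; additionally records
    the reference efflux rate k2' in provenance and, when ``target_k2a`` is
    given, flags the configuration as degenerate if k2' is within
    ``degeneracy_rtol`` of the target's apparent efflux rate (the regime in
    which SRTM's k2' - k2a difference becomes non-identifiable).
    """
    tac = make_tissue_tac(truth, input_function, schedule, **kwargs)
    tac.provenance["k2_prime"] = truth.k2
    if target_k2a is not None:
        tac.provenance["target_k2a"] = float(target_k2a)
        tac.provenance["degenerate_k2p_equals_k2a"] = bool(
            abs(truth.k2 - target_k2a) <= degeneracy_rtol * truth.k2
        )
    return tac


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _noise_sd_per_frame(
    tac_values: np.ndarray,
    weights: WeightVector,
    level: float,
    reference_frame: int | None = None,
) -> tuple[np.ndarray, int]:
    """Per-frame noise SD: proportional to the count-model sigma, globally
    scaled so the reference frame (default: frame of peak activity) attains
    coefficient of variation ``level``."""
    if level < 0:
        raise ValueError("noise level must be >= 0")
    sigma = np.sqrt(weights.sigma2)
    if reference_frame is None:
        reference_frame = int(np.argmax(tac_values))
    ref_val = tac_values[reference_frame]
    ref_sigma = sigma[reference_frame]
    if level > 0 and (ref_val <= 0 or ref_sigma <= 0):
        raise ValueError("reference frame has zero activity or zero variance")
    scale = 0.0 if level == 0 else level * ref_val / ref_sigma
    return scale * sigma, reference_frame


def add_noise(
    tac: TissueTAC,
    weights: WeightVector | None = None,
    level: float = 0.05,
    seed: int | np.random.Generator = 0,
    *,
    reference_frame: int | None = None,
) -> TissueTAC:
    """Add zero-mean Gaussian frame noise with count-model structure.

    The per-frame SD follows sigma = dcf * sqrt(T)/L (the square root of the
    frame-variance model), scaled so the stated reference frame has the
    requested coefficient of variation.  ``level = 0`` returns an identical
    copy.  Reproducible given the seed.
    """
    if weights is None:
        weights = frame_weights(tac.schedule)
    sd, ref_frame = _noise_sd_per_frame(tac.values, weights, level, reference_frame)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = tac.values + sd * rng.standard_normal(tac.values.size)
    prov = dict(tac.provenance)
    prov["noise"] = {"level": level, "reference_frame": ref_frame}
    return TissueTAC(values=noisy, schedule=tac.schedule, provenance=prov)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and ground truth of a digital phantom.

    ``labels`` is a 3D integer array (0 = background); every non-zero label
    needs a GroundTruth entry in ``truths`` and exactly one label is the
    reference region.
    """

    labels: np.ndarray
    truths: dict[int, GroundTruth]
    reference_label: int
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_level: float = 0.05
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.truths)
        if missing:
            raise ValueError(f"labels without ground truth: {sorted(missing)}")
        if self.reference_label not in self.truths:
            raise ValueError("reference label has no ground-truth entry")

    @classmethod
    def three_region(
        cls,
        shape: tuple[int, int, int] = (20, 20, 10),
        truths: dict[str, GroundTruth] | None = None,
        noise_level: float = 0.05,
    ) -> "PhantomSpec":
        """Default phantom: three concentric slabs — reference region (1),
        low-binding grey (2), high-binding grey (3) — with background 0."""
        truths = truths or default_truths()
        nx, ny, nz = shape
        labels = np.zeros(shape, dtype=np.int16)
        labels[1 : nx - 1, 1 : ny - 1, :] = 2
        labels[nx // 4 : 3 * nx // 4, ny // 4 : 3 * ny // 4, :] = 3
        labels[1 : nx - 1, 1 : ny - 1, : max(1, nz // 4)] = 1
        mapping = {1: truths["reference"], 2: truths["grey_low"], 3: truths["grey_high"]}
        names = {1: "reference", 2: "grey_low", 3: "grey_high"}
        return cls(labels=labels, truths=mapping, reference_label=1,
                   noise_level=noise_level, region_names=names)


@dataclass
class Phantom:
    """A generated dynamic phantom: 4D data plus labels and truth table."""

    dynamic: np.ndarray  # (x, y, z, frames)
    labels: np.ndarray
    schedule: FrameSchedule
    input_function: InputFunction
    spec: PhantomSpec
    truth_table: pd.DataFrame
    seed: int | None = None

    def region_tac(self, label: int) -> TissueTAC:
        mask = self.labels == label
        return TissueTAC(
            values=self.dynamic[mask].mean(axis=0),
            schedule=self.schedule,
            provenance={"label": int(label)},
        )

    @property
    def reference_tac(self) -> TissueTAC:
        return self.region_tac(self.spec.reference_label)


def _truth_table(spec: PhantomSpec, reference: GroundTruth) -> pd.DataFrame:
    rows = []
    for label, gt in sorted(spec.truths.items()):
        rows.append(
            {
                "label": label,
                "name": spec.region_names.get(label, str(label)),
                "K1": gt.K1,
                "k2": gt.k2,
                "VB": gt.VB,
                "VT": gt.VT,
                "DVR": gt.dvr(reference),
                "BPND": gt.bpnd(reference),
                "R1": gt.r1(reference),
                "is_reference": label == spec.reference_label,
            }
        )
    return pd.DataFrame(rows)


def make_phantom(
    spec: PhantomSpec,
    input_function: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    seed: int = 0,
) -> Phantom:
    """Build a 4D dynamic phantom: each voxel is its label's noiseless TAC
    plus independent count-model noise; background voxels stay zero."""
    schedule = schedule or FrameSchedule.default()
    input_function = input_function or make_input_function(schedule=schedule)
    weights = frame_weights(schedule)
    rng = np.random.default_rng(seed)
    n_frames = len(schedule)
    dynamic = np.zeros(spec.labels.shape + (n_frames,), dtype=float)
    reference = spec.truths[spec.reference_label]
    for label, gt in sorted(spec.truths.items()):
        mask = spec.labels == label
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        clean = make_tissue_tac(gt, input_function, schedule)
        if spec.noise_level > 0:
            sd, _ = _noise_sd_per_frame(clean.values, weights, spec.noise_level)
            block = clean.values + sd * rng.standard_normal((n_vox, n_frames))
        else:
            block = np.tile(clean.values, (n_vox, 1))
        dynamic[mask] = block
    return Phantom(
        dynamic=dynamic,
        labels=spec.labels.copy(),
        schedule=schedule,
        input_function=input_function,
        spec=spec,
        truth_table=_truth_table(spec, reference),
        seed=seed,
    )


def _scaled_spec(spec: PhantomSpec, effect: float, effect_on: str) -> PhantomSpec:
    """Ground truth of session 2: target-region parameter scaled by (1+effect).

    ``effect_on='VT'`` scales VT by adjusting k2 (delivery unchanged);
    ``effect_on='K1'`` scales K1 (and hence VT).  The reference region is
    left untouched: the simulated intervention acts on specific binding.
    """
    new_truths = {}
    for label, gt in spec.truths.items():
        if label == spec.reference_label or effect == 0:
            new_truths[label] = gt
        elif effect_on == "VT":
            new_truths[label] = GroundTruth(K1=gt.K1, k2=gt.k2 / (1.0 + effect), VB=gt.VB)
        elif effect_on == "K1":
            new_truths[label] = GroundTruth(K1=gt.K1 * (1.0 + effect), k2=gt.k2, VB=gt.VB)
        else:
            raise ValueError("effect_on must be 'VT' or 'K1'")
    return PhantomSpec(
        labels=spec.labels,
        truths=new_truths,
        reference_label=spec.reference_label,
        voxel_size_mm=spec.voxel_size_mm,
        noise_level=spec.noise_level,
        region_names=spec.region_names,
    )


def make_trt_pair(
    spec: PhantomSpec,
    between_session_effect: float = 0.0,
    seeds: tuple[int, int] = (0, 1),
    *,
    effect_on: str = "VT",
    input_params: FengParams | None = None,
    input_jitter: float = 0.0,
    schedule: FrameSchedule | None = None,
) -> tuple[Phantom, Phantom]:
    """A paired test-retest session: session 2's target ground truth is
    scaled by (1 + effect), noise draws are independent, and the two
    sessions share the schedule and input-function family (session-2 input
    coefficients optionally jittered by ``input_jitter``)."""
    schedule = schedule or FrameSchedule.default()
    params = input_params or FengParams()
    input1 = make_input_function(params, schedule)
    if input_jitter > 0:
        rng = np.random.default_rng(seeds[1] + 2**20)
        params2 = params.jittered(input_jitter, rng)
    else:
        params2 = params
    input2 = make_input_function(params2, schedule)
    spec2 = _scaled_spec(spec, between_session_effect, effect_on)
    test = make_phantom(spec, input1, schedule, seed=seeds[0])
    retest = make_phantom(spec2, input2, schedule, seed=seeds[1])
    return test, retest
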