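"""End-to-end simulation studies: the package's validation experiments.

Each function builds its own synthetic data with known ground truth, runs
the estimators through the same public interfaces a user would, and returns
summary statistics.  They are the computational core of the numbered
analysis scripts and of the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import FrameSchedule
from .inputfunc import make_input_function
from .tacgen import (
    GroundTruth,
    PhantomSpec,
    TissueTAC,
    add_noise,
    default_truths,
    make_phantom,
    make_tissue_tac,
    make_trt_pair,
    truth_grid,
    _noise_sd_per_frame,
)
from .kinetics import fit_1t2kvb, fit_srtm, frame_weights
from .linear import logan_vt, mrtm, rlogan_dvr
from .basis import BasisGrid, rpm, rpm_matrix, spectral_analysis, srtm2
from .voxelwise import extract_tacs, fit_voxelwise
from .repeatability import agreement, icc_2way, trt

#: reference region used by all recovery studies: VT' = 5, k2' = 0.06
RECOVERY_REFERENCE = GroundTruth(K1=0.3, k2=0.06, VB=0.0)


def _setup(schedule=None):
    schedule = schedule or FrameSchedule.default()
    inp = make_input_function(schedule=schedule)
    return schedule, inp, frame_weights(schedule)


# ---------------------------------------------------------------------------
# noise-free recovery grid
# ---------------------------------------------------------------------------

def recovery_grid_study() -> pd.DataFrame:
    """Noise-free parameter recovery over the 27-combination truth grid.

    Every estimator is run on data its model can represent: the 1T2k_VB fit
    sees the full blood-volume data; plasma Logan and the reference-tissue
    methods see the same kinetics with VB = 0 (they do not model blood);
    spectral analysis sees data without the (1-VB) tissue scaling (its
    operational model).  RLogan uses the full operational equation with the
    true k2'.  Returns one row per method with the maximum relative error
    of its primary parameter (percent).
    """
    schedule, inp, weights = _setup()
    ref = make_tissue_tac(RECOVERY_REFERENCE, inp, schedule)
    k2p_true = RECOVERY_REFERENCE.k2
    vt_ref = RECOVERY_REFERENCE.VT
    errs: dict[str, list[float]] = {m: [] for m in (
        "1T2k_VB NLR VT", "SRTM NLR BPND", "Logan VT", "RLogan DVR",
        "MRTM1 DVR", "RPM BPND", "SRTM2 BPND", "SA VT",
    )}
    for gt in truth_grid():
        vt = gt.VT
        dvr = vt / vt_ref
        bp = dvr - 1.0
        tac_vb = make_tissue_tac(gt, inp, schedule)
        errs["1T2k_VB NLR VT"].append(
            abs(fit_1t2kvb(tac_vb, inp, schedule, weights)["VT"] - vt) / vt)
        tac_sa = make_tissue_tac(gt, inp, schedule, one_minus_vb=False)
        errs["SA VT"].append(
            abs(spectral_analysis(tac_sa, inp, weights).VT - vt) / vt)
        tac0 = make_tissue_tac(GroundTruth(gt.K1, gt.k2, 0.0), inp, schedule)
        errs["Logan VT"].append(abs(logan_vt(tac0, inp, 10.0)["VT"] - vt) / vt)
        errs["SRTM NLR BPND"].append(
            abs(fit_srtm(tac0, ref, weights=weights)["BPND"] - bp) / bp)
        errs["RLogan DVR"].append(
            abs(rlogan_dvr(tac0, ref, 30.0, k2_prime=k2p_true)["DVR"] - dvr) / dvr)
        errs["MRTM1 DVR"].append(
            abs(mrtm(tac0, ref, 10.0, "MRTM1")["DVR"] - dvr) / dvr)
        errs["RPM BPND"].append(abs(rpm(tac0, ref, weights)["BPND"] - bp) / bp)
        s2, _ = srtm2(tac0.values[None, :], ref, weights, schedule=schedule,
                      k2p_fixed=k2p_true)
        errs["SRTM2 BPND"].append(abs(s2["BPND"][0] - bp) / bp)
    return pd.DataFrame(
        {
            "method": list(errs),
            "max_rel_err_pct": [100.0 * max(v) for v in errs.values()],
            "mean_rel_err_pct": [100.0 * float(np.mean(v)) for v in errs.values()],
            "n_truths": len(truth_grid()),
        }
    )


def basis_grid_refinement_study() -> pd.DataFrame:
    """RPM recovery error as the basis grid is refined (30 -> 120 -> 240
    nodes): discretization-limited and shrinking."""
    schedule, inp, weights = _setup()
    ref = make_tissue_tac(RECOVERY_REFERENCE, inp, schedule)
    tac = make_tissue_tac(GroundTruth(0.36, 0.018, 0.0), inp, schedule)  # BPND 3
    rows = []
    for count in (30, 120, 240):
        fit = rpm(tac, ref, weights, BasisGrid(0.01, 0.1, count))
        rows.append({"n_basis": count,
                     "bpnd_rel_err_pct": 100.0 * abs(fit["BPND"] - 3.0) / 3.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# noise-induced bias (graphical methods) and variance reduction (SRTM2)
# ---------------------------------------------------------------------------

def noise_bias_study(seed: int = 0, n_replicates: int = 200,
                     noise_level: float = 0.10) -> dict:
    """Monte-Carlo noise properties at the regional level.

    Replicated noisy TACs are fitted with plasma Logan and reference Logan;
    the noise-induced negative bias of graphical methods predicts that the
    median estimate falls below the noise-free value (one-sided sign test).
    Also runs RPM vs SRTM2 (true k2' fixed) on the replicates to measure
    SRTM2's per-voxel variance reduction.
    """
    schedule, inp, weights = _setup()
    rng = np.random.default_rng(seed)
    ref = make_tissue_tac(RECOVERY_REFERENCE, inp, schedule)
    gt = GroundTruth(K1=0.36, k2=0.018, VB=0.0)  # VT 20, DVR 4
    tac = make_tissue_tac(gt, inp, schedule)
    logan_free = logan_vt(tac, inp, 10.0)["VT"]
    rlogan_free = rlogan_dvr(tac, ref, 30.0)["DVR"]
    sd, _ = _noise_sd_per_frame(tac.values, weights, noise_level)
    Y = tac.values + sd * rng.standard_normal((n_replicates, len(schedule)))
    logan_vals, rlogan_vals = [], []
    for row in Y:
        try:
            logan_vals.append(logan_vt(row, inp, 10.0, schedule=schedule)["VT"])
        except ValueError:
            pass
        try:
            rlogan_vals.append(rlogan_dvr(row, ref, 30.0, schedule=schedule)["DVR"])
        except ValueError:
            pass
    logan_vals = np.asarray(logan_vals)
    rlogan_vals = np.asarray(rlogan_vals)

    def sign_test_below(values, reference):
        k = int(np.sum(values < reference))
        return stats.binomtest(k, values.size, 0.5, alternative="greater").pvalue

    res_rpm = rpm_matrix(Y, ref.values, schedule, weights)
    res_s2, _ = srtm2(Y, ref, weights, schedule=schedule,
                      k2p_fixed=RECOVERY_REFERENCE.k2)
    return {
        "logan_vt_noise_free": float(logan_free),
        "logan_vt_median_noisy": float(np.median(logan_vals)),
        "logan_sign_test_p": float(sign_test_below(logan_vals, logan_free)),
        "rlogan_dvr_noise_free": float(rlogan_free),
        "rlogan_dvr_median_noisy": float(np.median(rlogan_vals)),
        "rlogan_sign_test_p": float(sign_test_below(rlogan_vals, rlogan_free)),
        "rpm_bpnd_var": float(np.var(res_rpm["BPND"])),
        "srtm2_bpnd_var": float(np.var(res_s2["BPND"])),
        "n_replicates": int(n_replicates),
        "noise_level": noise_level,
    }


# ---------------------------------------------------------------------------
# map-vs-ROI consistency
# ---------------------------------------------------------------------------

MAP_METHODS = ("logan", "rlogan", "mrtmo", "mrtm1", "mrtm2", "rpm", "srtm2", "sa")
PRIMARY_PARAM = {
    "logan": "VT", "sa": "VT", "rlogan": "DVR", "mrtmo": "DVR",
    "mrtm1": "DVR", "mrtm2": "DVR", "rpm": "BPND", "srtm2": "BPND",
}


def _regional_fit(method, tac, ref, inp, schedule, weights, k2p):
    if method == "logan":
        return logan_vt(tac, inp, 10.0)
    if method == "rlogan":
        return rlogan_dvr(tac, ref, 30.0)
    if method.startswith("mrtm"):
        variant = {"mrtmo": "MRTMo"}.get(method, method.upper())
        need_k2p = k2p if variant == "MRTM2" else None
        return mrtm(tac, ref, 10.0, variant, need_k2p)
    if method == "rpm":
        return rpm(tac, ref, weights)
    if method == "sa":
        return spectral_analysis(tac, inp, weights)
    raise ValueError(method)


def map_vs_roi_study(shape=(20, 20, 10)) -> pd.DataFrame:
    """Noise-free phantom: for every parametric method, compare the map's
    region means with the fit of the regional TAC (the voxel-vs-ROI
    validation logic, with truth known)."""
    schedule, inp, weights = _setup()
    spec = PhantomSpec.three_region(shape, noise_level=0.0)
    ph = make_phantom(spec, inp, schedule, seed=0)
    mask = ph.labels > 0
    ref = ph.reference_tac
    k2p = spec.truths[spec.reference_label].k2
    rows = []
    for method in MAP_METHODS:
        maps = fit_voxelwise(
            ph.dynamic, mask, method, schedule,
            input_function=inp, reference_tac=ref,
            k2_prime=k2p if method == "mrtm2" else None,
        )
        param = PRIMARY_PARAM[method]
        for label in (2, 3):
            roi_tac = ph.region_tac(label)
            if method == "srtm2":
                # regional counterpart: pass-2 fit with the map's own k2'*
                res, _ = srtm2(roi_tac.values[None, :], ref, weights,
                               schedule=schedule,
                               k2p_fixed=maps[param].metadata["k2p_star"])
                roi = float(res["BPND"][0])
            else:
                roi = _regional_fit(method, roi_tac, ref, inp,
                                    schedule, weights, k2p)[param]
            map_mean = maps[param].region_mean(ph.labels == label)
            rows.append({
                "method": method, "parameter": param, "label": label,
                "roi_value": float(roi), "map_mean": float(map_mean),
                "rel_diff_pct": 100.0 * abs(map_mean - roi) / abs(roi),
            })
    return pd.DataFrame(rows)


def noisy_slope_study(seed: int = 0, shape=(20, 20, 10),
                      noise_level: float = 0.05) -> dict:
    """Noisy phantom: regression slope of voxel estimates on ground truth
    for SRTM2 BPND and SA VT."""
    schedule, inp, weights = _setup()
    spec = PhantomSpec.three_region(shape, noise_level=noise_level)
    ph = make_phantom(spec, inp, schedule, seed=seed)
    mask = ph.labels > 0
    lab = ph.labels[mask]
    tt = ph.truth_table.set_index("label")
    out = {"noise_level": noise_level}
    maps = fit_voxelwise(ph.dynamic, mask, "srtm2", schedule,
                         reference_tac=ph.reference_tac)
    y = maps["BPND"].values[mask]
    x = tt.loc[lab, "BPND"].to_numpy()
    ok = np.isfinite(y)
    a = agreement(x[ok], y[ok])
    out["srtm2_bpnd_slope"] = a.slope
    out["srtm2_bpnd_r2"] = a.r_squared
    maps = fit_voxelwise(ph.dynamic, mask, "sa", schedule, input_function=inp)
    y = maps["VT"].values[mask]
    # SA's representable truth: the (1-VB)-scaled distribution volume
    x = (tt.loc[lab, "VT"] * (1.0 - tt.loc[lab, "VB"])).to_numpy()
    ok = np.isfinite(y)
    a = agreement(x[ok], y[ok])
    out["sa_vt_slope"] = a.slope
    out["sa_vt_r2"] = a.r_squared
    return out


# ---------------------------------------------------------------------------
# test-retest pipeline
# ---------------------------------------------------------------------------

def trt_pipeline_study(
    seed: int = 0,
    n_subjects: int = 8,
    effect: float = 0.0,
    noise_level: float = 0.05,
    shape=(20, 20, 10),
    subject_variability: float = 0.15,
) -> dict:
    """Simulated paired-scan cohort: per subject, two sessions with
    independent noise (and an optional between-session effect on target VT);
    whole-brain grey values are computed per session and summarised with
    the paired TRT statistics and the two-way absolute-agreement ICC.

    Between-subject biology is emulated by scaling every region's VT with a
    per-subject lognormal-ish factor (fractional SD ``subject_variability``),
    shared by both sessions, so the ICC has a real subject variance to
    resolve.  Whole-brain grey SA VT is the voxel-volume-weighted mean of
    the per-region spectral fits; whole-brain SRTM2 BPND is the grey mean
    of the voxel-wise SRTM2 map.
    """
    schedule = FrameSchedule.default()
    weights = frame_weights(schedule)
    base = default_truths()
    grey = [2, 3]
    sa_vt = np.zeros((n_subjects, 2))
    s2_bp = np.zeros((n_subjects, 2))
    rng = np.random.default_rng(seed)
    for subj in range(n_subjects):
        f = float(np.exp(subject_variability * rng.standard_normal()))
        truths = {name: GroundTruth(K1=gt.K1, k2=gt.k2 / f, VB=gt.VB)
                  for name, gt in base.items()}
        spec = PhantomSpec.three_region(shape, truths, noise_level)
        seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, 2))
        sessions = make_trt_pair(spec, effect, seeds=seeds)
        for sess_idx, ph in enumerate(sessions):
            grey_mask = np.isin(ph.labels, grey)
            vts, vols = [], []
            for label in grey:
                tac = ph.region_tac(label)
                vts.append(spectral_analysis(tac, ph.input_function, weights).VT)
                vols.append(int((ph.labels == label).sum()))
            sa_vt[subj, sess_idx] = float(np.average(vts, weights=vols))
            s2_maps = fit_voxelwise(ph.dynamic, ph.labels > 0, "srtm2", schedule,
                                    reference_tac=ph.reference_tac)
            s2_bp[subj, sess_idx] = s2_maps["BPND"].region_mean(grey_mask)
    res_sa = trt(sa_vt[:, 0], sa_vt[:, 1])
    res_s2 = trt(s2_bp[:, 0], s2_bp[:, 1])
    return {
        "effect": effect,
        "n_subjects": n_subjects,
        "sa_vt_trt_mean": res_sa.mean,
        "sa_vt_trt_sd": res_sa.sd,
        "sa_vt_abs_trt_mean": res_sa.abs_mean,
        "srtm2_bpnd_trt_mean": res_s2.mean,
        "srtm2_bpnd_trt_sd": res_s2.sd,
        "srtm2_bpnd_abs_trt_mean": res_s2.abs_mean,
        "sa_vt_icc": icc_2way(sa_vt).icc,
        "srtm2_bpnd_icc": icc_2way(s2_bp).icc,
        "expected_trt_for_effect": (((1.0 + effect) - 1.0) / ((1.0 + effect) + 1.0))
        * 200.0,
    }
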