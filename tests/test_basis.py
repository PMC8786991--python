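"""Basis-function estimators: RPM, two-pass SRTM2 and spectral analysis."""

import warnings

import numpy as np
import pytest

import petparam as pp
from petparam.basis import BasisGrid, rpm, rpm_matrix, spectral_analysis, srtm2
from petparam.kinetics import sample_frames
from petparam.tacgen import TissueTAC, _noise_sd_per_frame


def test_basis_grid_validation():
    with pytest.raises(ValueError):
        BasisGrid(0.1, 0.01, 30)
    with pytest.raises(ValueError):
        BasisGrid(0.01, 0.1, 1)
    g = BasisGrid(0.01, 0.1, 30)
    assert g.thetas[0] == pytest.approx(0.01)
    assert g.thetas[-1] == pytest.approx(0.1)
    # logarithmic spacing: constant ratio
    ratios = g.thetas[1:] / g.thetas[:-1]
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)


# ---------------------------------------------------------------------------
# RPM
# ---------------------------------------------------------------------------

def test_rpm_identity_when_target_equals_reference(ref_tac, weights):
    fit = rpm(ref_tac, ref_tac, weights)
    assert fit.converged
    assert fit["R1"] == pytest.approx(1.0, abs=1e-6)
    assert fit["BPND"] == pytest.approx(0.0, abs=1e-6)


def test_rpm_recovery_is_grid_limited_and_improves_on_refinement(
    target_tac, ref_tac, weights
):
    """True k2a = 0.018 sits between the 30-node grid points; the error is
    bounded by the node spacing and shrinks when the grid is refined 4x."""
    coarse = rpm(target_tac, ref_tac, weights, BasisGrid(0.01, 0.1, 30))
    fine = rpm(target_tac, ref_tac, weights, BasisGrid(0.01, 0.1, 120))
    err_c = abs(coarse["BPND"] - 3.0)
    err_f = abs(fine["BPND"] - 3.0)
    # half-node spacing in theta maps to ~5% on BPND at DVR = 4
    assert err_c / 3.0 < 0.05
    assert err_f < err_c
    assert err_f / 3.0 < 0.01


def test_rpm_flags_truth_outside_grid(inp, schedule, ref_tac, weights):
    # target k2a = 0.005 below the grid floor: estimate clamps and is flagged
    tac = pp.make_tissue_tac(pp.GroundTruth(K1=0.3, k2=0.005, VB=0.0), inp, schedule)
    fit = rpm(tac, ref_tac, weights, BasisGrid(0.01, 0.1, 30))
    assert fit.flags.get("grid_edge", False)
    assert fit["k2a"] == pytest.approx(0.01)


def test_rpm_matches_nlr_srtm_up_to_grid_spacing(target_tac, ref_tac, weights):
    nlr = pp.fit_srtm(target_tac, ref_tac, weights=weights)
    basis = rpm(target_tac, ref_tac, weights, BasisGrid(0.01, 0.1, 240))
    assert basis["BPND"] == pytest.approx(nlr["BPND"], rel=0.01)
    assert basis["R1"] == pytest.approx(nlr["R1"], rel=0.01)


@pytest.mark.parametrize("c", [0.25, 4.0])
def test_rpm_invariant_to_joint_rescaling(target_tac, ref_tac, schedule, weights, c):
    st = TissueTAC(values=c * target_tac.values, schedule=schedule)
    sr = TissueTAC(values=c * ref_tac.values, schedule=schedule)
    a = rpm(target_tac, ref_tac, weights)
    b = rpm(st, sr, weights)
    assert b["BPND"] == pytest.approx(a["BPND"], rel=1e-9)


# ---------------------------------------------------------------------------
# SRTM2
# ---------------------------------------------------------------------------

def test_srtm2_two_pass_consistent_on_homogeneous_noise_free(
    target_tac, ref_tac, weights, schedule
):
    """Identical noise-free voxels: pass-2 BPND equals pass-1 BPND within
    grid tolerance and k2'* equals each voxel's pass-1 k2'."""
    Y = np.tile(target_tac.values, (20, 1))
    pass1 = rpm_matrix(Y, ref_tac.values, schedule, weights)
    res, k2p_star = srtm2(Y, ref_tac, weights, schedule=schedule)
    np.testing.assert_allclose(pass1["k2p"], k2p_star, rtol=1e-9)
    np.testing.assert_allclose(res["BPND"], pass1["BPND"], rtol=0.05)
    assert not res["fallback"]


def test_srtm2_recovers_truth_with_true_k2prime(target_tac, ref_tac, weights, schedule):
    res, _ = srtm2(target_tac.values[None, :], ref_tac, weights,
                   schedule=schedule, k2p_fixed=0.06)
    assert res["BPND"][0] == pytest.approx(3.0, rel=0.05)  # grid-limited


def test_srtm2_fallback_triggers_iff_no_voxel_above_threshold(
    target_tac, ref_tac, weights, schedule
):
    Y = np.tile(target_tac.values, (10, 1))  # true BPND = 3
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        # threshold below the population: normal path, no warning
        srtm2(Y, ref_tac, weights, bp_threshold=2.0, schedule=schedule)
    with pytest.warns(UserWarning, match="fixing k2'"):
        res, _ = srtm2(Y, ref_tac, weights, bp_threshold=50.0, schedule=schedule)
    assert res["fallback"]


def test_srtm2_variance_reduction_vs_rpm_under_noise(
    target_tac, ref_tac, weights, schedule
):
    """With k2' fixed to its true value, SRTM2's per-voxel BPND variance is
    below RPM's across noisy replicates (the rationale for the method)."""
    rng = np.random.default_rng(21)
    sd, _ = _noise_sd_per_frame(target_tac.values, weights, 0.05)
    Y = target_tac.values + sd * rng.standard_normal((150, 19))
    res_rpm = rpm_matrix(Y, ref_tac.values, schedule, weights)
    res_s2, _ = srtm2(Y, ref_tac, weights, schedule=schedule, k2p_fixed=0.06)
    assert np.var(res_s2["BPND"]) < np.var(res_rpm["BPND"])


# ---------------------------------------------------------------------------
# spectral analysis
# ---------------------------------------------------------------------------

def test_sa_pure_blood_signal_yields_vb_only(inp, schedule, weights):
    blood = sample_frames(inp.whole_blood, inp.time, schedule, "average")
    tac = TissueTAC(values=0.05 * blood, schedule=schedule)
    res = spectral_analysis(tac, inp, weights)
    assert res.VB == pytest.approx(0.05, rel=1e-6)
    assert res.VT == pytest.approx(0.0, abs=1e-9)
    assert res.K1 == pytest.approx(0.0, abs=1e-9)


def test_sa_recovers_single_component_on_grid_node(inp, schedule, weights):
    """k2 placed exactly on a grid node: VT within 1%, K1 within 2%."""
    grid = BasisGrid(0.01, 0.06, 30)  # node at 0.06 exactly
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06, 0.0), inp, schedule)
    res = spectral_analysis(tac, inp, weights, grid)
    assert res.VT == pytest.approx(5.0, rel=0.01)
    assert res.K1 == pytest.approx(0.3, rel=0.02)
    assert res.VB == pytest.approx(0.0, abs=1e-3)


def test_sa_between_nodes_splits_energy_but_keeps_vt(inp, schedule, weights):
    """k2 between nodes: VT within 3%, K1 within 5%, improving with a
    denser grid."""
    tac = pp.make_tissue_tac(pp.GroundTruth(0.35, 0.0175, 0.0), inp, schedule)
    res50 = spectral_analysis(tac, inp, weights, BasisGrid(0.01, 0.1, 50))
    assert res50.VT == pytest.approx(20.0, rel=0.03)
    assert res50.K1 == pytest.approx(0.35, rel=0.05)
    res200 = spectral_analysis(tac, inp, weights, BasisGrid(0.01, 0.1, 200))
    assert abs(res200.VT - 20.0) <= abs(res50.VT - 20.0) + 1e-6


def test_sa_spectrum_nonnegative_on_noisy_data(inp, schedule, weights):
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06, 0.05), inp, schedule)
    rng = np.random.default_rng(3)
    for _ in range(10):
        noisy = pp.add_noise(tac, weights, 0.2, rng)
        res = spectral_analysis(noisy, inp, weights)
        assert np.all(res.alphas >= 0)
        assert res.VT >= 0 and res.K1 >= 0


def test_sa_superposition_of_two_components(inp, schedule, weights):
    a = pp.make_tissue_tac(pp.GroundTruth(0.2, 0.02, 0.0), inp, schedule)
    b = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.08, 0.0), inp, schedule)
    both = TissueTAC(values=a.values + b.values, schedule=schedule)
    res = spectral_analysis(both, inp, weights)
    assert res.VT == pytest.approx(0.2 / 0.02 + 0.3 / 0.08, rel=0.03)
    assert res.K1 == pytest.approx(0.5, rel=0.05)


@pytest.mark.parametrize("c", [0.1, 10.0])
def test_sa_vt_invariant_to_joint_rescaling(inp, schedule, weights, c):
    from petparam.inputfunc import InputFunction

    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06, 0.0), inp, schedule)
    scaled_inp = InputFunction(
        time=inp.time,
        plasma_parent=c * inp.plasma_parent,
        whole_blood=c * inp.whole_blood,
        parent_fraction=inp.parent_fraction,
        plasma_to_wholeblood=inp.plasma_to_wholeblood,
    )
    scaled_tac = TissueTAC(values=c * tac.values, schedule=schedule)
    r0 = spectral_analysis(tac, inp, weights)
    r1 = spectral_analysis(scaled_tac, scaled_inp, weights)
    assert r1.VT == pytest.approx(r0.VT, rel=1e-9)
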