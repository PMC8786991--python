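"""Forward model, noise model, phantoms and test-retest pairs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import petparam as pp
from petparam.inputfunc import InputFunction
from petparam.tacgen import PhantomSpec, so_like_truths
from petparam.kinetics import convolve_exp, frame_average


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def test_ground_truth_derived_ratios_exact():
    ref = pp.GroundTruth(K1=0.25, k2=0.05, VB=0.0)
    gt = pp.GroundTruth(K1=0.35, k2=0.0175, VB=0.05)
    assert gt.VT == pytest.approx(0.35 / 0.0175, rel=1e-15)
    assert gt.dvr(ref) == pytest.approx(gt.VT / ref.VT, rel=1e-15)
    assert gt.bpnd(ref) == pytest.approx(gt.dvr(ref) - 1.0, rel=1e-15)
    assert gt.r1(ref) == pytest.approx(0.35 / 0.25, rel=1e-15)


@pytest.mark.parametrize("bad", [dict(K1=-0.1, k2=0.05), dict(K1=0.3, k2=0.0),
                                 dict(K1=0.3, k2=0.05, VB=1.0)])
def test_invalid_ground_truth_rejected(bad):
    with pytest.raises(ValueError):
        pp.GroundTruth(**bad)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def test_tac_independent_of_whole_blood_when_vb_zero(inp, schedule):
    gt = pp.GroundTruth(K1=0.3, k2=0.06, VB=0.0)
    doubled_blood = InputFunction(
        time=inp.time,
        plasma_parent=inp.plasma_parent,
        whole_blood=2 * inp.whole_blood,
        parent_fraction=inp.parent_fraction,
        plasma_to_wholeblood=inp.plasma_to_wholeblood,
    )
    a = pp.make_tissue_tac(gt, inp, schedule)
    b = pp.make_tissue_tac(gt, doubled_blood, schedule)
    np.testing.assert_allclose(a.values, b.values, rtol=1e-14)


def test_zero_influx_gives_zero_tac(inp, schedule):
    gt = pp.GroundTruth(K1=0.0, k2=0.06, VB=0.0)
    tac = pp.make_tissue_tac(gt, inp, schedule)
    assert np.all(tac.values == 0)


def test_forward_model_linear_in_k1(inp, schedule):
    a = pp.make_tissue_tac(pp.GroundTruth(K1=0.2, k2=0.03, VB=0.0), inp, schedule)
    b = pp.make_tissue_tac(pp.GroundTruth(K1=0.6, k2=0.03, VB=0.0), inp, schedule)
    np.testing.assert_allclose(b.values, 3.0 * a.values, rtol=1e-12)


def test_tac_matches_brute_force_riemann_convolution(inp, schedule):
    """Frame values within 0.5% of an independent 0.01-min left-Riemann
    convolution of the plasma curve with the tissue response."""
    K1, k2, VB = 0.3, 0.06, 0.05
    gt = pp.GroundTruth(K1=K1, k2=k2, VB=VB)
    tac = pp.make_tissue_tac(gt, inp, schedule)
    dt = 0.01
    t = np.arange(0.0, schedule.total_minutes + dt / 2, dt)
    cp = np.interp(t, inp.time, inp.plasma_parent)
    conv = np.array(
        [
            (np.sum(cp[: i + 1] * np.exp(-k2 * (t[i] - t[: i + 1])))
             - 0.5 * cp[0] * np.exp(-k2 * t[i]) - 0.5 * cp[i]) * dt
            for i in range(t.size)
        ]
    )
    cwb = np.interp(t, inp.time, inp.whole_blood)
    model = (1 - VB) * K1 * conv + VB * cwb
    expected = frame_average(model, t, schedule)
    sel = expected > 0.01 * expected.max()
    np.testing.assert_allclose(tac.values[sel], expected[sel], rtol=5e-3)


def test_schedule_beyond_input_grid_raises(inp):
    long_sched = pp.FrameSchedule.from_durations([600.0] * 7)  # 70 min
    with pytest.raises(ValueError, match="stops at"):
        pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06), inp, long_sched)


# ---------------------------------------------------------------------------
# reference region
# ---------------------------------------------------------------------------

def test_reference_tac_identical_for_identical_truth(inp, schedule):
    gt = pp.GroundTruth(0.3, 0.06, 0.0)
    a = pp.make_tissue_tac(gt, inp, schedule)
    b = pp.make_reference_tac(gt, inp, schedule)
    np.testing.assert_allclose(a.values, b.values)
    assert b.provenance["k2_prime"] == 0.06


def test_degenerate_reference_configuration_flagged(inp, schedule):
    target = pp.GroundTruth(K1=0.35, k2=0.0175, VB=0.0)
    ref = pp.GroundTruth(K1=0.0875, k2=0.0175, VB=0.0)  # k2' == target k2a
    tac = pp.make_reference_tac(ref, inp, schedule, target_k2a=target.k2)
    assert tac.provenance["degenerate_k2p_equals_k2a"] is True
    well = pp.GroundTruth(K1=0.25, k2=0.052, VB=0.0)
    tac2 = pp.make_reference_tac(well, inp, schedule, target_k2a=target.k2)
    assert tac2.provenance["degenerate_k2p_equals_k2a"] is False


def test_so_like_defaults_give_dvr_above_one():
    truths = so_like_truths()
    assert truths["grey_high"].dvr(truths["reference"]) > 1
    # the defining property: reference efflux ~ grey apparent efflux
    assert truths["reference"].k2 == pytest.approx(truths["grey_high"].k2)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_zero_noise_level_is_identity(inp, schedule, weights):
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06), inp, schedule)
    out = pp.add_noise(tac, weights, level=0.0, seed=3)
    np.testing.assert_array_equal(out.values, tac.values)


def test_noise_reproducible_by_seed(inp, schedule, weights):
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06), inp, schedule)
    a = pp.add_noise(tac, weights, 0.1, seed=11)
    b = pp.add_noise(tac, weights, 0.1, seed=11)
    c = pp.add_noise(tac, weights, 0.1, seed=12)
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_negative_noise_level_rejected(inp, schedule, weights):
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06), inp, schedule)
    with pytest.raises(ValueError):
        pp.add_noise(tac, weights, level=-0.1, seed=0)


def test_empirical_cov_at_reference_frame_matches_level(inp, schedule, weights):
    """Monte-Carlo check of the global noise scaling: 1000 replicates at
    level 0.1 give an empirical COV of 10.0% +/- 0.5% at the reference frame."""
    tac = pp.make_tissue_tac(pp.GroundTruth(0.3, 0.06), inp, schedule)
    ref_frame = int(np.argmax(tac.values))
    rng = np.random.default_rng(2024)
    reps = np.array([pp.add_noise(tac, weights, 0.1, rng).values[ref_frame]
                     for _ in range(1000)])
    cov = reps.std(ddof=1) / tac.values[ref_frame]
    assert cov == pytest.approx(0.10, abs=0.005)


# ---------------------------------------------------------------------------
# phantoms and test-retest pairs
# ---------------------------------------------------------------------------

def test_noise_free_phantom_voxels_identical_within_label(inp, schedule):
    spec = PhantomSpec.three_region((8, 8, 4), noise_level=0.0)
    ph = pp.make_phantom(spec, inp, schedule, seed=0)
    for label in (1, 2, 3):
        block = ph.dynamic[ph.labels == label]
        np.testing.assert_array_equal(block, np.tile(block[0], (block.shape[0], 1)))
    assert np.all(ph.dynamic[ph.labels == 0] == 0)


def test_noisy_phantom_label_means_match_truth_within_se(inp, schedule, weights):
    spec = PhantomSpec.three_region((20, 20, 10), noise_level=0.05)
    ph = pp.make_phantom(spec, inp, schedule, seed=5)
    from petparam.tacgen import _noise_sd_per_frame

    for label, gt in spec.truths.items():
        clean = pp.make_tissue_tac(gt, inp, schedule).values
        block = ph.dynamic[ph.labels == label]
        sd, _ = _noise_sd_per_frame(clean, weights, 0.05)
        se = sd / np.sqrt(block.shape[0])
        # every frame mean within 5 standard errors of its truth
        assert np.all(np.abs(block.mean(axis=0) - clean) < 5 * se + 1e-12)


def test_phantom_label_without_truth_entry_rejected():
    labels = np.zeros((4, 4, 2), dtype=int)
    labels[0, 0, 0] = 7
    with pytest.raises(ValueError, match="without ground truth"):
        PhantomSpec(labels=labels, truths={1: pp.GroundTruth(0.3, 0.06)},
                    reference_label=1)


def test_trt_pair_null_effect_zero_noise_identical(inp, schedule):
    spec = PhantomSpec.three_region((6, 6, 4), noise_level=0.0)
    test, retest = pp.make_trt_pair(spec, 0.0, seeds=(0, 1))
    np.testing.assert_array_equal(test.dynamic, retest.dynamic)


def test_trt_pair_effect_scales_session2_vt():
    spec = PhantomSpec.three_region((6, 6, 4), noise_level=0.0)
    test, retest = pp.make_trt_pair(spec, -0.25, seeds=(0, 1))
    t1 = test.truth_table.set_index("label")
    t2 = retest.truth_table.set_index("label")
    for label in (2, 3):  # targets scale, reference untouched
        assert t2.loc[label, "VT"] == pytest.approx(0.75 * t1.loc[label, "VT"])
    assert t2.loc[1, "VT"] == pytest.approx(t1.loc[1, "VT"])


# ---------------------------------------------------------------------------
# convolution engine vs brute force (generator-level invariant)
# ---------------------------------------------------------------------------

@given(theta=st.floats(min_value=0.005, max_value=0.5))
def test_convolution_engine_matches_riemann_oracle(theta):
    rng = np.random.default_rng(99)
    t = np.arange(0.0, 30.0, 0.05)
    curve = np.abs(np.cumsum(rng.standard_normal(t.size))) / 10.0
    mine = convolve_exp(curve, theta, t)
    # brute-force Riemann at 0.01-min steps
    tf = np.arange(0.0, 30.0, 0.01)
    cf = np.interp(tf, t, curve)
    idx = np.searchsorted(tf, t)
    brute = np.array(
        [
            (np.sum(cf[: i + 1] * np.exp(-theta * (tf[i] - tf[: i + 1])))
             - 0.5 * cf[0] * np.exp(-theta * tf[i]) - 0.5 * cf[i]) * 0.01
            for i in idx
        ]
    )
    scale = np.max(np.abs(brute))
    np.testing.assert_allclose(mine, brute, atol=5e-3 * scale)
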