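"""HRF, design construction, filtering, smoothing, GLM and run pooling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from entrograd import behavior as bh
from entrograd import first_level as fl
from entrograd import synthetic as sy
from entrograd.volume import VolumeMap, default_affine


# ---------------------------------------------------------------- HRF

def test_hrf_shape_properties():
    t = np.arange(0, 32, 0.1)
    h = fl.hrf_double_gamma(t)
    assert h[0] == 0.0
    assert h.max() == pytest.approx(1.0)
    assert 4.5 <= t[np.argmax(h)] <= 6.5
    # exactly one sign change: positive lobe then undershoot
    signs = np.sign(h[np.abs(h) > 1e-6])
    changes = np.count_nonzero(np.diff(signs))
    assert changes == 1
    # undershoot trough in the canonical window
    assert 14.0 <= t[np.argmin(h)] <= 17.0


def test_hrf_is_zero_before_onset():
    assert np.all(fl.hrf_double_gamma(np.array([-2.0, -0.5])) == 0.0)


# ---------------------------------------------------------------- design

def _events(onsets, svs, ides, duration=4.0):
    return pd.DataFrame({"onset": onsets, "duration": duration,
                         "sv": svs, "ide": ides})


def test_constant_modulator_centres_to_zero_column():
    ev = _events([0.0, 10.0, 20.0], [3.0, 3.0, 3.0], [-0.5, -0.5, -0.5])
    design = fl.build_design(ev, None, tr=1.0, n_volumes=40)
    assert np.allclose(design.frame["SV_mod"], 0.0, atol=1e-12)
    assert np.allclose(design.frame["iDE_mod"], 0.0, atol=1e-12)


def test_shifting_all_sv_values_leaves_design_unchanged():
    ev1 = _events([0.0, 12.0, 25.0], [1.0, -2.0, 0.5], [-0.2, -0.9, -0.4])
    ev2 = ev1.copy()
    ev2["sv"] = ev2["sv"] + 7.3
    d1 = fl.build_design(ev1, None, tr=1.0, n_volumes=45)
    d2 = fl.build_design(ev2, None, tr=1.0, n_volumes=45)
    assert np.allclose(d1.frame["SV_mod"], d2.frame["SV_mod"], atol=1e-8)
    assert np.allclose(d1.frame["trial_intercept"], d2.frame["trial_intercept"], atol=1e-12)
    assert d2.modulator_means["SV_mod"] == pytest.approx(d1.modulator_means["SV_mod"] + 7.3)


def test_single_event_column_matches_independent_convolution_oracle():
    """Compare the convolved trial regressor against a fine-grid quadrature."""
    ev = _events([0.0], [1.0], [-0.5])
    n_vol, tr = 30, 1.0
    design = fl.build_design(ev, None, tr=tr, n_volumes=n_vol)
    col = design.frame["trial_intercept"].to_numpy()
    # oracle: y(t) = integral_0^4 h(t - s) ds on a 1 ms grid
    dt = 0.001
    tt = np.arange(0, n_vol * tr, dt)
    u = (tt < 4.0).astype(float)
    h = fl.hrf_double_gamma(np.arange(0, 32, dt))
    y = np.convolve(u, h)[:len(tt)] * dt
    oracle = y[np.round(np.arange(n_vol) * tr / dt).astype(int)]
    assert 6.0 <= np.argmax(col) * tr <= 8.0
    assert np.max(np.abs(col - oracle)) < 0.02 * np.max(np.abs(oracle))


def test_identical_events_give_identical_designs(rng):
    ev = _events([0.0, 9.0, 21.0], [1.0, 2.0, -1.0], [-0.3, -0.8, -0.1])
    motion = sy.simulate_motion(40, rng)
    d1 = fl.build_design(ev, motion, tr=1.0, n_volumes=40)
    d2 = fl.build_design(ev.copy(), motion.copy(), tr=1.0, n_volumes=40)
    pd.testing.assert_frame_equal(d1.frame, d2.frame)


def test_design_rejects_empty_or_disordered_events():
    with pytest.raises(ValueError):
        fl.build_design(_events([], [], []), None, tr=1.0, n_volumes=10)
    with pytest.raises(ValueError, match="increasing"):
        fl.build_design(_events([5.0, 1.0], [1, 2], [-1, -1]), None, tr=1.0, n_volumes=30)


def test_design_column_layout():
    ev = _events([0.0, 10.0], [1.0, 2.0], [-0.1, -0.9])
    motion = sy.simulate_motion(30, np.random.default_rng(0))
    d = fl.build_design(ev, motion, tr=1.0, n_volumes=30)
    assert d.columns[:3] == list(fl.TASK_COLUMNS)
    assert d.columns[-1] == "constant"
    assert set(fl.MOTION_COLUMNS) <= set(d.columns)


# ---------------------------------------------------------------- high-pass

def test_highpass_removes_linear_trend():
    t = np.arange(300)
    y = 0.5 * t + 3.0
    out = fl.highpass(y, tr=1.0, cutoff=100.0)
    assert np.linalg.norm(out) < 1e-8 * np.linalg.norm(y)


def test_highpass_preserves_fast_oscillation():
    t = np.arange(300)
    y = np.sin(2 * np.pi * t / 10.0)
    out = fl.highpass(y, tr=1.0, cutoff=100.0)
    assert np.linalg.norm(out) / np.linalg.norm(y) > 0.99


def test_highpass_is_idempotent(rng):
    y = rng.standard_normal((200, 4))
    once = fl.highpass(y, tr=1.0)
    twice = fl.highpass(once, tr=1.0)
    assert np.allclose(once, twice, atol=1e-10)


def test_highpass_requires_reasonable_cutoff():
    with pytest.raises(ValueError):
        fl.highpass(np.zeros(10), tr=3.0, cutoff=5.0)


# ---------------------------------------------------------------- smoothing

def test_smoothing_leaves_constant_volume_unchanged():
    vol = VolumeMap(np.full((10, 10, 10), 7.0), default_affine(3.0))
    out = fl.smooth_volumes(vol, fwhm=5.0)
    assert np.allclose(out.data, 7.0)


def test_smoothing_impulse_has_requested_fwhm():
    data = np.zeros((41, 41, 41))
    data[20, 20, 20] = 1.0
    out = fl.smooth_volumes(data, fwhm=5.0, voxel_size=1.0)
    prof = out[:, 20, 20]
    half = prof.max() / 2
    above = np.where(prof >= half)[0]
    width = above[-1] - above[0] + 1  # mm, 1 mm voxels
    assert width == pytest.approx(5.0, abs=1.0)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)  # interior impulse conserved


def test_smoothing_rejects_negative_fwhm():
    with pytest.raises(ValueError):
        fl.smooth_volumes(np.zeros((4, 4, 4)), fwhm=-1.0, voxel_size=3.0)


# ---------------------------------------------------------------- GLM

def _simple_design(n_vol=120, tr=1.0, rng=None):
    ev = _events([5.0, 25.0, 50.0, 75.0], [1.0, -1.0, 2.0, 0.5],
                 [-0.2, -0.9, -0.4, -0.6])
    motion = sy.simulate_motion(n_vol, rng or np.random.default_rng(0))
    return fl.build_design(ev, motion, tr=tr, n_volumes=n_vol)


def test_data_equal_to_design_column_recovers_unit_beta():
    design = _simple_design()
    X = design.values
    k = design.columns.index("SV_mod")
    Y = X[:, [k]].copy()
    est = fl.fit_run_glm(Y, design, prewhiten=False)
    assert est.betas["SV_mod"][0] == pytest.approx(1.0, abs=1e-8)
    for name in ("trial_intercept", "iDE_mod"):
        assert est.betas[name][0] == pytest.approx(0.0, abs=1e-8)


def test_rank_deficient_design_raises_with_column_names():
    design = _simple_design()
    frame = design.frame.copy()
    frame["dup"] = frame["SV_mod"]
    bad = fl.DesignMatrix(frame=frame, tr=design.tr)
    with pytest.raises(ValueError, match="collinear"):
        fl.fit_run_glm(np.zeros((len(frame), 2)), bad)


def test_noiseless_roundtrip_recovers_weight_maps_exactly(loss_averse_fit):
    cfg = sy.TaskConfig(seed=11)
    gambles = sy.generate_gambles(cfg)
    trials = sy.simulate_choices(gambles, loss_averse_fit, np.random.default_rng(2))
    vals = bh.trial_values(loss_averse_fit, trials)
    ev = vals[vals["run"] == 1]
    maps = sy.make_gradient_maps(shape=(6, 6, 6), rng=np.random.default_rng(3))
    noise = sy.NoiseModel(sigma=0.0, drift_amplitude=0.0)
    rng = np.random.default_rng(4)
    bold, motion = sy.generate_bold(ev, maps, noise, cfg.tr, rng)
    design = fl.build_design(ev, motion, cfg.tr, bold.shape[3])
    est = fl.fit_run_glm(bold, design)
    for name, truth in (("SV_mod", maps.sv_weight_map), ("iDE_mod", maps.ide_weight_map),
                        ("trial_intercept", maps.intercept_map)):
        err = np.abs(est.betas[name] - truth.data.ravel()).max()
        assert err < 1e-6 * max(np.abs(truth.data).max(), 1.0)


def test_glm_z_type_one_error_is_calibrated(rng):
    """White-noise voxels: |Z| for the SV modulator exceeds 1.96 about 5% of the time."""
    design = _simple_design(n_vol=200)
    Y = rng.standard_normal((200, 4000))
    est = fl.fit_run_glm(Y, design, prewhiten=False)
    z = est.betas["SV_mod"] / np.sqrt(est.variances["SV_mod"])
    rate = np.mean(np.abs(z) > 1.96)
    assert rate == pytest.approx(0.05, abs=0.02)


def test_prewhitening_restores_variance_calibration(rng):
    """AR(1) noise breaks OLS variances; Cochrane-Orcutt largely repairs them.

    With only task + constant columns the repaired type-I rate is nominal;
    smooth nuisance regressors (motion random walks, derivatives) absorb part
    of the low-frequency noise and attenuate the residual-based AR estimate,
    leaving a small known anticonservative remainder.
    """
    design = _simple_design(n_vol=250)
    rho = 0.5
    eps = rng.standard_normal((250, 3000))
    Y = np.empty_like(eps)
    Y[0] = eps[0]
    for i in range(1, 250):
        Y[i] = rho * Y[i - 1] + np.sqrt(1 - rho ** 2) * eps[i]
    rate = lambda e: np.mean(np.abs(e.betas["SV_mod"] / np.sqrt(e.variances["SV_mod"])) > 1.96)
    est_naive = fl.fit_run_glm(Y, design, prewhiten=False)
    est_white = fl.fit_run_glm(Y, design, prewhiten=True)
    assert rate(est_naive) > 0.2           # grossly anticonservative without whitening
    assert rate(est_white) < 0.12          # most of the inflation removed
    slim = fl.DesignMatrix(
        frame=design.frame[["trial_intercept", "SV_mod", "iDE_mod", "constant"]].copy(),
        tr=design.tr)
    est_slim = fl.fit_run_glm(Y, slim, prewhiten=True)
    assert rate(est_slim) == pytest.approx(0.05, abs=0.03)


# ---------------------------------------------------------------- pooling

def _run_estimates(betas, variances):
    return fl.RunEstimates(
        betas={"SV_mod": np.array(betas)},
        variances={"SV_mod": np.array(variances)},
        dof=100, ar1_rho=np.zeros(len(betas)), grid_shape=(len(betas), 1, 1),
        affine=np.eye(4))


def test_inverse_variance_pooling_formula():
    runs = [_run_estimates([1.0], [1.0]), _run_estimates([3.0], [1.0])]
    pooled = fl.pool_fixed_effects(runs, regressors=("SV_mod",))
    assert pooled.betas["SV_mod"][0] == pytest.approx(2.0)
    assert pooled.variances["SV_mod"][0] == pytest.approx(0.5)
    assert pooled.z["SV_mod"][0] == pytest.approx(2.0 / np.sqrt(0.5))


def test_single_run_pooling_is_identity():
    runs = [_run_estimates([1.5, -2.0], [0.3, 0.7])]
    pooled = fl.pool_fixed_effects(runs, regressors=("SV_mod",))
    assert np.allclose(pooled.betas["SV_mod"], [1.5, -2.0])
    assert np.allclose(pooled.variances["SV_mod"], [0.3, 0.7])


def test_four_identical_runs_quarter_the_variance():
    runs = [_run_estimates([1.0], [0.8]) for _ in range(4)]
    pooled = fl.pool_fixed_effects(runs, regressors=("SV_mod",))
    assert pooled.variances["SV_mod"][0] == pytest.approx(0.2)
    # pooled variance never exceeds the smallest run variance
    assert pooled.variances["SV_mod"][0] <= 0.8


def test_zero_variance_voxel_raises():
    runs = [_run_estimates([1.0], [0.0])]
    with pytest.raises(ValueError, match="zero-variance"):
        fl.pool_fixed_effects(runs, regressors=("SV_mod",))
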