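"""Choice model, entropy measures, exclusions and behavioural validation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

from entrograd import behavior as bh
from entrograd.behavior import ParticipantFit

from conftest import simulate_trials


# ---------------------------------------------------------------- derived values

@pytest.mark.parametrize("bg, bl, gain, loss, expected", [
    (0.5, -1.0, 20, 10, 0.0),        # exact cancellation
    (1.0, -2.0, 16, 5, 6.0),         # loss-averse pattern beta_losses = -2 beta_gains
    (0.7, -1.3, 0, 0, 0.0),          # zero-stake gamble is worthless for any beta
])
def test_subjective_value_is_interceptless_linear_combination(bg, bl, gain, loss, expected):
    fit = ParticipantFit(bg, bl, intercept=5.0)  # intercept must not leak into SV
    assert bh.compute_sv(fit, gain, loss) == pytest.approx(expected, abs=1e-12)


def test_sv_accepts_gamble_objects():
    fit = ParticipantFit(1.0, -2.0, 0.0)
    assert bh.compute_sv(fit, bh.Gamble(gain=16, loss=5)) == pytest.approx(6.0)


def test_gamble_rejects_negative_or_nonfinite_stakes():
    with pytest.raises(ValueError):
        bh.Gamble(gain=-1.0, loss=2.0)
    with pytest.raises(ValueError):
        bh.Gamble(gain=np.nan, loss=2.0)


def test_p_accept_is_inverse_logit_of_sv_plus_intercept():
    fit = ParticipantFit(1.0, -1.0, 0.0)
    assert bh.compute_p_accept(fit, 0.0) == pytest.approx(0.5)
    assert bh.compute_p_accept(fit, 1.0) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)
    assert bh.compute_p_accept(fit, 50.0) == pytest.approx(1.0, abs=1e-12)
    sv = np.linspace(-5, 5, 101)
    assert np.all(np.diff(bh.compute_p_accept(fit, sv)) > 0)


def test_decision_entropy_examples():
    de, ide = bh.compute_ide(0.5)
    assert de == pytest.approx(1.0) and ide == pytest.approx(-1.0)
    for p in (0.0, 1.0):
        de, ide = bh.compute_ide(p)
        assert de == 0.0 and ide == 0.0
    # direct evaluation at p = logit^-1(1)
    _, ide = bh.compute_ide(0.7311)
    assert ide == pytest.approx(-0.8400, abs=1e-3)


def test_decision_entropy_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh.compute_ide(1.2)
    with pytest.raises(ValueError):
        bh.compute_ide(-0.1)


@pytest.mark.parametrize("p, expected", [(0.3, 0.7), (0.5, 0.5), (0.9, 0.9)])
def test_probability_correct_is_max_of_tails(p, expected):
    assert bh.compute_p_correct(p) == pytest.approx(expected)


@given(p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_entropy_symmetry_and_bounds(p):
    de, ide = bh.compute_ide(p)
    de_c, _ = bh.compute_ide(1.0 - p)
    assert de == pytest.approx(de_c, abs=1e-12)
    assert 0.0 <= de <= 1.0 and -1.0 <= ide <= 0.0


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_rank_correlations_are_unity_for_tie_free_participants(seed):
    """Monotone transforms force Spearman rho = 1 whenever SV has no ties."""
    r = np.random.default_rng(seed)
    fit = ParticipantFit(r.uniform(0.2, 1.0), r.uniform(-1.0, -0.2), r.normal(0, 0.5))
    df = pd.DataFrame({"gain": r.uniform(1, 8, 50), "loss": r.uniform(1, 8, 50)})
    vals = bh.trial_values(fit, df)
    assert stats.spearmanr(vals["sv"], vals["p_accept"]).statistic == pytest.approx(1.0)
    if not np.any(np.diff(np.sort(np.abs(vals["p_accept"] - 0.5))) == 0):
        assert stats.spearmanr(vals["ide"], vals["p_correct"]).statistic == pytest.approx(1.0)


# ---------------------------------------------------------------- model fitting

def _grid_search_oracle(df, bg_range, bl_range, b0_range, n_grid=21):
    """Coarse exact-likelihood maximiser, independent of the IRLS path."""
    g = df["gain"].to_numpy(); l = df["loss"].to_numpy(); y = df["accept"].to_numpy()
    best, best_ll = None, -np.inf
    for bg in np.linspace(*bg_range, n_grid):
        for bl in np.linspace(*bl_range, n_grid):
            for b0 in np.linspace(*b0_range, 7):
                eta = bg * g + bl * l + b0
                ll = np.sum(y * eta - np.logaddexp(0, eta))
                if ll > best_ll:
                    best, best_ll = (bg, bl, b0), ll
    return np.array(best), best_ll


def test_fit_recovers_known_coefficients_vs_grid_oracle(rng):
    df = simulate_trials(0.5, -1.0, 0.0, 10_000, rng)
    fit = bh.fit_choice_model(df)
    coef = fit.coefficients()
    # the stake coefficients are tightly identified; the intercept is the
    # weakly identified direction on an all-positive stake design
    assert np.all(np.abs(coef[:2] - [0.5, -1.0]) < 0.05)
    assert abs(coef[2]) < 0.1
    oracle, oracle_ll = _grid_search_oracle(df, (0.3, 0.7), (-1.2, -0.8), (-0.3, 0.3))
    assert np.all(np.abs(coef[:2] - oracle[:2]) < 0.03)  # within grid resolution
    # the fit's own likelihood cannot fall below the coarse-grid maximum
    eta = coef[0] * df["gain"] + coef[1] * df["loss"] + coef[2]
    ll = np.sum(df["accept"] * eta - np.logaddexp(0, eta))
    assert ll >= oracle_ll - 1e-6


def test_fit_matches_unpenalised_mle_when_well_identified(rng):
    df = simulate_trials(0.5, -0.8, 0.2, 4000, rng)
    import statsmodels.api as sm
    X = sm.add_constant(df[["gain", "loss"]].to_numpy())
    ref = sm.Logit(df["accept"].to_numpy(), X).fit(disp=0)
    fit = bh.fit_choice_model(df)
    # statsmodels orders [const, gain, loss]
    assert fit.beta_gains == pytest.approx(ref.params[1], abs=0.01)
    assert fit.beta_losses == pytest.approx(ref.params[2], abs=0.01)
    assert fit.intercept == pytest.approx(ref.params[0], abs=0.02)


def test_fit_no_signal_gives_near_zero_coefficients(rng):
    df = simulate_trials(0.0, 0.0, 0.0, 20_000, rng)
    fit = bh.fit_choice_model(df)
    assert np.all(np.abs(fit.coefficients()) < 0.1)
    assert not fit.separable


def test_perfectly_separable_data_is_flagged_and_finite(rng):
    g = rng.uniform(1, 8, 400); l = rng.uniform(1, 8, 400)
    df = pd.DataFrame({"gain": g, "loss": l, "accept": (g > l).astype(int)})
    fit = bh.fit_choice_model(df)
    assert fit.separable
    assert np.all(np.isfinite(fit.coefficients()))


def test_one_class_responses_are_separable_not_infinite(rng):
    df = pd.DataFrame({"gain": rng.uniform(1, 8, 50), "loss": rng.uniform(1, 8, 50),
                       "accept": np.ones(50, dtype=int)})
    fit = bh.fit_choice_model(df)
    assert fit.separable and np.all(np.isfinite(fit.coefficients()))
    assert bh.compute_p_accept(fit, bh.compute_sv(fit, 8.0, 1.0)) > 0.5


def test_all_missing_responses_raise():
    df = pd.DataFrame({"gain": [1.0, 2.0], "loss": [1.0, 2.0],
                       "response": ["NoResp", "NoResp"]})
    with pytest.raises(ValueError, match="missing"):
        bh.fit_choice_model(df)


def test_missing_responses_are_dropped_from_fit(rng):
    df = simulate_trials(0.5, -1.0, 0.0, 500, rng)
    df["response"] = np.where(df["accept"] == 1, "strongly_accept", "strongly_reject")
    df_aug = pd.concat([df, pd.DataFrame({"gain": [100.0] * 5, "loss": [0.0] * 5,
                                          "response": ["NoResp"] * 5})],
                       ignore_index=True)[["gain", "loss", "response"]]
    fit_full = bh.fit_choice_model(df[["gain", "loss", "response"]])
    fit_aug = bh.fit_choice_model(df_aug)
    assert fit_aug.n_trials == fit_full.n_trials
    assert fit_aug.coefficients() == pytest.approx(fit_full.coefficients())


def test_loss_aversion_ratio_recovered_within_ten_percent(rng):
    df = simulate_trials(0.6, -1.2, 0.1, 10_000, rng)
    fit = bh.fit_choice_model(df)
    assert fit.loss_aversion == pytest.approx(-2.0, rel=0.1)


# ---------------------------------------------------------------- exclusions

def _fits(gains, losses=None):
    losses = losses if losses is not None else [-1.0] * len(gains)
    return {f"s{i}": ParticipantFit(g, l, 0.0) for i, (g, l) in enumerate(zip(gains, losses))}


def test_coefficient_outlier_is_excluded():
    fits = _fits([1.0] * 9 + [10.0])
    table = bh.exclude_participants(fits)
    assert not table.loc["s9", "kept"]
    assert table["kept"][:9].all()


def test_identical_participants_are_all_kept():
    table = bh.exclude_participants(_fits([1.0] * 10))
    assert table["kept"].all()


def test_high_motion_participant_is_excluded():
    fits = _fits([1.0] * 10)
    motion = {f"s{i}": 0.1 for i in range(9)} | {"s9": 0.9}
    table = bh.exclude_participants(fits, motion)
    assert not table.loc["s9", "kept"]
    assert "motion" in table.loc["s9", "reasons"][0]


def test_low_motion_is_not_excluded_one_sided():
    fits = _fits([1.0] * 10)
    motion = {f"s{i}": 0.5 for i in range(9)} | {"s9": 0.0}  # unusually still
    assert bh.exclude_participants(fits, motion)["kept"].all()


def test_exclusion_needs_three_participants():
    with pytest.raises(ValueError):
        bh.exclude_participants(_fits([1.0, 2.0]))


# ---------------------------------------------------------------- validation

def _values_frame(fit, p_accepts, responses):
    de, ide = bh.compute_ide(np.asarray(p_accepts))
    return pd.DataFrame({
        "sv": stats.norm.ppf(np.asarray(p_accepts)),  # any monotone carrier
        "p_accept": p_accepts, "ide": ide,
        "p_correct": bh.compute_p_correct(np.asarray(p_accepts)),
        "response": responses,
    })


def test_validation_reports_unity_rho_for_tie_free_values():
    fit = ParticipantFit(0.5, -1.0, 0.0)
    frames = {}
    for pid in range(4):
        # distinct |p - 0.5| values, so both rank correlations are forced to 1
        p = [0.52, 0.61, 0.95, 0.07]
        resp = ["weakly_accept", "weakly_accept", "strongly_accept", "strongly_reject"]
        frames[f"s{pid}"] = _values_frame(fit, p, resp)
    report = bh.validate_ide(frames)
    assert report.sv_paccept_rho_mean == pytest.approx(1.0)
    assert report.ide_pcorrect_rho_mean == pytest.approx(1.0)


def test_validation_weak_strong_ordering_matches_entropy_values():
    fit = ParticipantFit(0.5, -1.0, 0.0)
    frames = {}
    for pid in range(4):
        p = [0.55, 0.95]
        resp = ["weakly_accept", "strongly_accept"]
        frames[f"s{pid}"] = _values_frame(fit, p, resp)
    report = bh.validate_ide(frames)
    # direct entropy evaluation: H(0.55) = 0.9928, H(0.95) = 0.2864
    assert report.weak_ide_mean == pytest.approx(-0.9928, abs=1e-4)
    assert report.strong_ide_mean == pytest.approx(-0.2864, abs=1e-4)
    assert report.weak_ide_mean < report.strong_ide_mean
    assert report.welch_t > 0 and report.welch_p < 0.05


def test_validation_warns_and_skips_welch_without_weak_responses():
    fit = ParticipantFit(0.5, -1.0, 0.0)
    frames = {"s0": _values_frame(fit, [0.95, 0.05], ["strongly_accept", "strongly_reject"]),
              "s1": _values_frame(fit, [0.9, 0.1], ["strongly_accept", "strongly_reject"])}
    with pytest.warns(UserWarning, match="Welch"):
        report = bh.validate_ide(frames)
    assert report.welch_t is None


def test_events_roundtrip(tmp_path):
    df = pd.DataFrame({"onset": [0.0, 10.0], "duration": [4.0, 4.0],
                       "gain": [10.0, 20.0], "loss": [5.0, 15.0],
                       "participant_response": ["weakly_accept", "NoResp"]})
    path = tmp_path / "events.tsv"
    df.to_csv(path, sep="\t", index=False)
    out = bh.read_events(path)
    assert out["accept"].tolist() == [1, pd.NA] or out["accept"].isna().iloc[1]
    assert out["accept"].iloc[0] == 1
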