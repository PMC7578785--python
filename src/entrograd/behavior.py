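"""Cognitive model of mixed-gamble choice and its derived quantities.

The behavioural model is a logistic regression of the accept/reject decision
on the gamble's gain and loss magnitudes,

    p_accept = logit^-1(beta_gains * gain + beta_losses * loss + intercept),

with the subjective value of a gamble defined as the intercept-free linear
predictor

    SV = beta_gains * gain + beta_losses * loss.

Decision (Shannon) entropy of the implied accept/reject distribution,

    DE = -[p * log2(p) + (1 - p) * log2(1 - p)],   p = p_accept,

is measured in bits; inverse decision entropy iDE = -DE is near 0 for
confident decisions and -1 bit at indifference (p = 0.5).  The subjective
probability of being correct is max(p_accept, 1 - p_accept).

Losses are stored as magnitudes; loss aversion is the ratio
beta_losses / beta_gains (typically around -2).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, xlogy

__all__ = [
    "RESPONSE_LEVELS",
    "WEAK_RESPONSES",
    "STRONG_RESPONSES",
    "MISSING_RESPONSE",
    "Gamble",
    "ParticipantFit",
    "ValidationReport",
    "accept_from_response",
    "fit_choice_model",
    "compute_sv",
    "compute_p_accept",
    "compute_ide",
    "compute_p_correct",
    "trial_values",
    "exclude_participants",
    "validate_ide",
    "read_events",
    "write_fit_json",
]

RESPONSE_LEVELS = ("strongly_reject", "weakly_reject", "weakly_accept", "strongly_accept")
WEAK_RESPONSES = ("weakly_reject", "weakly_accept")
STRONG_RESPONSES = ("strongly_reject", "strongly_accept")
ACCEPT_RESPONSES = ("weakly_accept", "strongly_accept")
MISSING_RESPONSE = "missing"

#: labels accepted in events files, normalised to the canonical snake_case form
_RESPONSE_ALIASES = {
    "strongly_reject": "strongly_reject",
    "weakly_reject": "weakly_reject",
    "weakly_accept": "weakly_accept",
    "strongly_accept": "strongly_accept",
    "noresp": MISSING_RESPONSE,
    "missing": MISSING_RESPONSE,
    "n/a": MISSING_RESPONSE,
}

# Weakly-informative Gaussian prior (ridge) on the stake coefficients.  The
# penalty is fixed (does not grow with n), so the estimator is the MLE
# asymptotically while near-separable small samples are kept on scale.
DEFAULT_RIDGE = 0.75
#: stronger ridge, applied to all coefficients, once separation is detected
#: and the unpenalised-direction fit has run away (keeps one-class data finite)
SEPARABLE_RIDGE = 2.0
#: coefficient magnitude beyond which a fit is treated as runaway
_RUNAWAY_COEF = 10.0


@dataclass(frozen=True)
class Gamble:
    """A 50/50 mixed gamble; ``loss`` is a magnitude (sign enters via beta_losses)."""

    gain: float
    loss: float

    def __post_init__(self):
        if not (np.isfinite(self.gain) and np.isfinite(self.loss)):
            raise ValueError("gain and loss must be finite")
        if self.gain < 0 or self.loss < 0:
            raise ValueError("gain and loss must be non-negative magnitudes")


@dataclass
class ParticipantFit:
    """Fitted (or generative) choice-model coefficients for one participant."""

    beta_gains: float
    beta_losses: float
    intercept: float
    converged: bool = True
    separable: bool = False
    n_trials: int = 0

    @property
    def loss_aversion(self) -> float:
        """beta_losses / beta_gains; undefined (nan) when beta_gains == 0."""
        if self.beta_gains == 0:
            return float("nan")
        return self.beta_losses / self.beta_gains

    def coefficients(self) -> np.ndarray:
        return np.array([self.beta_gains, self.beta_losses, self.intercept])


def accept_from_response(response: pd.Series | Sequence[str]) -> pd.Series:
    """Binary accept indicator; missing responses map to NA."""
    resp = pd.Series(response).astype(str).str.strip().str.lower()
    unknown = set(resp.unique()) - set(_RESPONSE_ALIASES)
    if unknown:
        raise ValueError(f"unknown response labels: {sorted(unknown)}")
    norm = resp.map(_RESPONSE_ALIASES)
    out = pd.Series(pd.NA, index=resp.index, dtype="Int64")
    out[norm.isin(ACCEPT_RESPONSES)] = 1
    out[norm.isin(("strongly_reject", "weakly_reject"))] = 0
    return out


def _penalised_irls(X: np.ndarray, y: np.ndarray, lam: np.ndarray,
                    max_iter: int = 200, tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Newton/IRLS maximiser of the ridge-penalised Bernoulli log-likelihood."""
    w = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ w, -35.0, 35.0)
        mu = expit(eta)
        wgt = np.maximum(mu * (1.0 - mu), 1e-12)
        hess = (X * wgt[:, None]).T @ X + np.diag(lam)
        grad = X.T @ (y - mu) - lam * w
        step = np.linalg.solve(hess, grad)
        w = w + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return w, converged


def _as_trials_frame(trials) -> pd.DataFrame:
    """Normalise the accepted trial representations into a DataFrame."""
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame([
            {"gain": t.gamble.gain if hasattr(t, "gamble") else t.gain,
             "loss": t.gamble.loss if hasattr(t, "gamble") else t.loss,
             **({"response": t.response} if hasattr(t, "response") else {})}
            for t in trials
        ])
    if "accept" not in df.columns:
        if "response" not in df.columns:
            raise ValueError("trials need either an 'accept' or a 'response' column")
        df["accept"] = accept_from_response(df["response"])
    return df


def fit_choice_model(trials, ridge: float = DEFAULT_RIDGE,
                     separable_ridge: float = SEPARABLE_RIDGE) -> ParticipantFit:
    """Fit the logistic choice model accept ~ gain + loss + intercept.

    Parameters
    ----------
    trials
        DataFrame with columns ``gain``, ``loss`` and either ``accept``
        (0/1, NA for missing) or ``response`` (four-level labels).  Missing
        responses are dropped before fitting.
    ridge
        L2 penalty on the two stake coefficients (the intercept is not
        penalised in the base fit).
    separable_ridge
        Penalty on all three coefficients for the fallback fit used when the
        data are one-class or the base fit runs away.

    Separable data (perfectly classifiable, including all-one-class data) are
    flagged ``separable=True``; the returned coefficients are always finite.
    """
    df = _as_trials_frame(trials)
    kept = df.dropna(subset=["accept"])
    if len(kept) == 0:
        raise ValueError("all responses missing; cannot fit choice model")
    y = kept["accept"].astype(float).to_numpy()
    X = np.column_stack([kept["gain"].to_numpy(float),
                         kept["loss"].to_numpy(float),
                         np.ones(len(kept))])
    if not np.isfinite(X).all():
        raise ValueError("non-finite gain/loss values")
    one_class = y.min() == y.max()
    if len(kept) < 2 and not one_class:
        raise ValueError("need at least 2 non-missing trials")

    separable = one_class
    if one_class:
        w, converged = _penalised_irls(X, y, np.full(3, separable_ridge))
    else:
        w, converged = _penalised_irls(X, y, np.array([ridge, ridge, 0.0]))
        # separation probe: a near-unpenalised fit has monotone likelihood on
        # separable data, so it either classifies perfectly or runs away
        w_probe, conv_probe = _penalised_irls(X, y, np.array([1e-6, 1e-6, 0.0]),
                                              max_iter=50)
        eta_probe = X @ w_probe
        perfectly_classified = bool(np.all((eta_probe > 0) == (y > 0.5)))
        probe_runaway = (not conv_probe) and np.any(np.abs(w_probe) > _RUNAWAY_COEF)
        runaway = (not converged) or np.any(np.abs(w) > _RUNAWAY_COEF)
        separable = perfectly_classified or probe_runaway or runaway
        if runaway:
            w, converged = _penalised_irls(X, y, np.full(3, separable_ridge))
    if not np.isfinite(w).all():  # pragma: no cover - ridge keeps this finite
        raise RuntimeError("choice-model fit produced non-finite coefficients")
    return ParticipantFit(beta_gains=float(w[0]), beta_losses=float(w[1]),
                          intercept=float(w[2]), converged=bool(converged),
                          separable=bool(separable), n_trials=int(len(kept)))


def _check_fit(fit: ParticipantFit) -> None:
    if not np.isfinite(fit.coefficients()).all():
        raise ValueError("fit has non-finite coefficients")


def compute_sv(fit: ParticipantFit, gain, loss=None):
    """Subjective value: beta_gains * gain + beta_losses * loss (no intercept)."""
    _check_fit(fit)
    if loss is None:  # a Gamble (or anything with .gain/.loss)
        gain, loss = gain.gain, gain.loss
    gain = np.asarray(gain, dtype=float)
    loss = np.asarray(loss, dtype=float)
    out = fit.beta_gains * gain + fit.beta_losses * loss
    return float(out) if out.ndim == 0 else out


def compute_p_accept(fit: ParticipantFit, sv):
    """Acceptance probability: inverse-logit of (SV + intercept)."""
    _check_fit(fit)
    out = expit(np.asarray(sv, dtype=float) + fit.intercept)
    return float(out) if out.ndim == 0 else out


def compute_ide(p_accept):
    """Decision entropy (bits) and its negative.

    Returns ``(de, ide)`` with de = binary Shannon entropy of p_accept and
    ide = -de.  The convention 0*log2(0) = 0 makes the endpoints exact.
    """
    p = np.asarray(p_accept, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_accept must lie in [0, 1]")
    # evaluate on min(p, 1-p) so that de(p) == de(1-p) exactly in floating point
    q = np.minimum(p, 1.0 - p)
    de = -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)) / np.log(2.0)
    de = np.clip(de, 0.0, 1.0)
    if de.ndim == 0:
        return float(de), float(-de)
    return de, -de


def compute_p_correct(p_accept):
    """Subjective probability of being correct: max(p, 1 - p)."""
    p = np.asarray(p_accept, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_accept must lie in [0, 1]")
    out = np.maximum(p, 1.0 - p)
    return float(out) if out.ndim == 0 else out


def trial_values(fit: ParticipantFit, trials) -> pd.DataFrame:
    """Per-trial derived quantities (sv, p_accept, p_reject, de, ide, p_correct)."""
    df = _as_trials_frame(trials) if not isinstance(trials, pd.DataFrame) else trials.copy()
    sv = compute_sv(fit, df["gain"].to_numpy(float), df["loss"].to_numpy(float))
    p = compute_p_accept(fit, sv)
    de, ide = compute_ide(p)
    df["sv"] = sv
    df["p_accept"] = p
    df["p_reject"] = 1.0 - p
    df["de"] = de
    df["ide"] = ide
    df["p_correct"] = compute_p_correct(p)
    return df


def exclude_participants(fits: Mapping[str, ParticipantFit],
                         motion: Mapping[str, float] | None = None,
                         sd_threshold: float = 2.3) -> pd.DataFrame:
    """Flag coefficient and motion outliers relative to the group.

    A participant is excluded when a gain or loss coefficient lies more than
    ``sd_threshold`` group standard deviations from the group mean (two-sided,
    SD computed over all participants including the candidate, ddof=1), or
    when the framewise-displacement summary exceeds the group mean plus
    ``sd_threshold`` SD (one-sided: only high movers are excluded).

    Returns a DataFrame indexed by participant with ``kept`` and ``reasons``.
    """
    ids = list(fits)
    if len(ids) < 3:
        raise ValueError("need at least 3 participants for group-based exclusion")
    reasons: dict[str, list[str]] = {pid: [] for pid in ids}
    coef = {"gain_coefficient": np.array([fits[p].beta_gains for p in ids]),
            "loss_coefficient": np.array([fits[p].beta_losses for p in ids])}
    for name, vals in coef.items():
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:  # degenerate: identical coefficients, no exclusions
            continue
        for pid, v in zip(ids, vals):
            if abs(v - mu) > sd_threshold * sd:
                reasons[pid].append(f"{name} outlier ({v:.3g} vs group {mu:.3g} +- {sd:.3g})")
    if motion is not None:
        vals = np.array([motion[p] for p in ids], dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd > 0:
            for pid, v in zip(ids, vals):
                if v > mu + sd_threshold * sd:
                    reasons[pid].append(f"high motion ({v:.3g} vs group {mu:.3g} + {sd_threshold}*{sd:.3g})")
    return pd.DataFrame({
        "participant": ids,
        "kept": [not reasons[p] for p in ids],
        "reasons": [list(reasons[p]) for p in ids],
    }).set_index("participant")


@dataclass
class ValidationReport:
    """Behavioural validation of the entropy measure across participants."""

    per_participant: pd.DataFrame
    sv_paccept_rho_mean: float
    sv_paccept_rho_sd: float
    sv_paccept_t: float
    sv_paccept_p: float
    ide_pcorrect_rho_mean: float
    ide_pcorrect_rho_sd: float
    ide_pcorrect_t: float
    ide_pcorrect_p: float
    weak_ide_mean: float | None = None
    weak_ide_sd: float | None = None
    strong_ide_mean: float | None = None
    strong_ide_sd: float | None = None
    welch_t: float | None = None
    welch_df: float | None = None
    welch_p: float | None = None


def validate_ide(values_by_participant: Mapping[str, pd.DataFrame]) -> ValidationReport:
    """Rank-correlation and weak/strong checks of the entropy measure.

    For each participant, Spearman correlations between SV and p_accept and
    between iDE and the probability of being correct are computed from the
    trialwise values (both are monotone transforms, so tie-free data give
    exactly 1).  Across participants the correlations are summarised with a
    one-sample t test against zero.  Mean iDE per response type feeds a
    two-sample Welch t test of strong vs weak responses (two observations per
    participant on each side, matching the four-level response scale).
    """
    rows = []
    weak_means: list[float] = []
    strong_means: list[float] = []
    for pid, df in values_by_participant.items():
        rho_sv = stats.spearmanr(df["sv"], df["p_accept"]).statistic
        rho_ide = stats.spearmanr(df["ide"], df["p_correct"]).statistic
        rows.append({"participant": pid, "rho_sv_paccept": rho_sv, "rho_ide_pcorrect": rho_ide})
        if "response" in df.columns:
            resp = df["response"].astype(str).str.strip().str.lower().map(_RESPONSE_ALIASES)
            for r in WEAK_RESPONSES:
                sel = df.loc[resp == r, "ide"]
                if len(sel):
                    weak_means.append(float(sel.mean()))
            for r in STRONG_RESPONSES:
                sel = df.loc[resp == r, "ide"]
                if len(sel):
                    strong_means.append(float(sel.mean()))
    per = pd.DataFrame(rows).set_index("participant")

    def _onesample(x: pd.Series):
        # identical correlations across participants (e.g. exactly 1.0) would
        # trip a catastrophic-cancellation warning inside the t test
        if x.std(ddof=1) < 1e-12:
            t = np.inf * np.sign(x.mean()) if x.mean() != 0 else 0.0
            return type("R", (), {"statistic": t, "pvalue": 0.0 if t != 0 else 1.0})
        return stats.ttest_1samp(x, 0.0)

    t_sv = _onesample(per["rho_sv_paccept"])
    t_ide = _onesample(per["rho_ide_pcorrect"])
    report = ValidationReport(
        per_participant=per,
        sv_paccept_rho_mean=float(per["rho_sv_paccept"].mean()),
        sv_paccept_rho_sd=float(per["rho_sv_paccept"].std(ddof=1)),
        sv_paccept_t=float(t_sv.statistic), sv_paccept_p=float(t_sv.pvalue),
        ide_pcorrect_rho_mean=float(per["rho_ide_pcorrect"].mean()),
        ide_pcorrect_rho_sd=float(per["rho_ide_pcorrect"].std(ddof=1)),
        ide_pcorrect_t=float(t_ide.statistic), ide_pcorrect_p=float(t_ide.pvalue),
    )
    if weak_means and strong_means:
        res = stats.ttest_ind(strong_means, weak_means, equal_var=False)
        report.weak_ide_mean = float(np.mean(weak_means))
        report.weak_ide_sd = float(np.std(weak_means, ddof=1)) if len(weak_means) > 1 else 0.0
        report.strong_ide_mean = float(np.mean(strong_means))
        report.strong_ide_sd = float(np.std(strong_means, ddof=1)) if len(strong_means) > 1 else 0.0
        report.welch_t = float(res.statistic)
        report.welch_df = float(res.df)
        report.welch_p = float(res.pvalue)
    else:
        warnings.warn("no weak or no strong responses anywhere; Welch test skipped")
    return report


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events TSV (onset, duration, gain, loss, participant_response)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "gain", "loss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns {sorted(missing)}")
    resp_col = "participant_response" if "participant_response" in df.columns else "response"
    if resp_col in df.columns:
        df["response"] = df[resp_col].astype(str)
        df["accept"] = accept_from_response(df["response"])
    return df


def write_fit_json(path, fit: ParticipantFit) -> None:
    d = asdict(fit)
    d["loss_aversion"] = fit.loss_aversion
    Path(path).write_text(json.dumps(d, indent=2))
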