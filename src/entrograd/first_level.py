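"""Per-run voxelwise GLM with parametric modulators.

Each run is modelled with three task regressors — a trial-onset boxcar
(full 4 s trial duration), and the same boxcar amplitude-modulated by
mean-centred SV and by mean-centred iDE — convolved with a canonical
double-gamma haemodynamic response, plus the temporal derivative of each
convolved task column, seven motion nuisance regressors and a constant.
No orthogonalisation is applied between regressors; the modulators are
mean-centred across the run's trials before convolution.

Drift is removed by projecting a discrete-cosine basis (plus an explicit
linear term) out of both data and design (100 s cutoff).  Serial
correlation is handled by per-voxel AR(1) Cochrane-Orcutt prewhitening;
runs are pooled within subject by inverse-variance (fixed-effects)
weighting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import VolumeMap

__all__ = [
    "TASK_COLUMNS",
    "MOTION_COLUMNS",
    "DesignMatrix",
    "RunEstimates",
    "SubjectEstimates",
    "hrf_double_gamma",
    "convolved_task_regressors",
    "build_design",
    "highpass",
    "smooth_volumes",
    "fit_run_glm",
    "pool_fixed_effects",
]

TASK_COLUMNS = ("trial_intercept", "SV_mod", "iDE_mod")
MOTION_COLUMNS = ("framewise_displacement",
                  "rot_x", "rot_y", "rot_z",
                  "trans_x", "trans_y", "trans_z")

#: microtime resolution (s) for boxcar construction before convolution
MICROTIME_DT = 0.1
#: support of the HRF kernel (s)
HRF_LENGTH = 32.0


def hrf_double_gamma(t, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), peak scaled to 1.

    Positive gamma lobe (peak near 5-6 s) minus a delayed undershoot gamma
    (trough near 15-16 s) scaled by 1/undershoot_ratio.
    """
    t = np.asarray(t, dtype=float)

    def _raw(tt):
        pos = stats.gamma.pdf(tt, peak_delay / peak_disp, scale=peak_disp)
        neg = stats.gamma.pdf(tt, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        return pos - neg / undershoot_ratio

    h = _raw(t)
    h[t < 0] = 0.0
    # normalise by the kernel's true peak so scaling is grid-independent
    peak = _raw(np.arange(0.0, peak_delay * 2, 0.001)).max()
    return h / peak


def convolved_task_regressors(events: pd.DataFrame, n_volumes: int, tr: float,
                              center_modulators: bool = True) -> tuple[pd.DataFrame, dict]:
    """HRF-convolved task columns sampled at the volume grid.

    ``events`` needs onset, duration, sv and ide columns (one row per trial;
    rows with missing responses should already be dropped).  SV and iDE
    amplitudes are mean-centred across the run's trials before convolution.
    Returns the three task columns and the centring metadata.
    """
    if len(events) == 0:
        raise ValueError("empty event list")
    onsets = events["onset"].to_numpy(float)
    durations = events["duration"].to_numpy(float)
    if np.any(durations <= 0):
        raise ValueError("event durations must be positive")
    run_length = n_volumes * tr
    if np.any(onsets + durations > run_length + MICROTIME_DT):
        raise ValueError("events extend past the end of the run")

    means = {"SV_mod": float(events["sv"].mean()), "iDE_mod": float(events["ide"].mean())}
    amplitudes = {
        "trial_intercept": np.ones(len(events)),
        "SV_mod": events["sv"].to_numpy(float) - (means["SV_mod"] if center_modulators else 0.0),
        "iDE_mod": events["ide"].to_numpy(float) - (means["iDE_mod"] if center_modulators else 0.0),
    }
    n_micro = int(np.ceil(run_length / MICROTIME_DT)) + 1
    kernel = hrf_double_gamma(np.arange(0.0, HRF_LENGTH, MICROTIME_DT))
    vol_idx = np.round(np.arange(n_volumes) * tr / MICROTIME_DT).astype(int)
    cols = {}
    for name, amp in amplitudes.items():
        u = np.zeros(n_micro)
        for onset, dur, a in zip(onsets, durations, amp):
            i0 = int(np.round(onset / MICROTIME_DT))
            i1 = int(np.round((onset + dur) / MICROTIME_DT))
            u[i0:i1] += a
        conv = np.convolve(u, kernel)[:n_micro] * MICROTIME_DT
        cols[name] = conv[vol_idx]
    return pd.DataFrame(cols), means


@dataclass
class DesignMatrix:
    """Time-by-regressor matrix with named columns and centring metadata."""

    frame: pd.DataFrame
    tr: float
    modulator_means: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)


def build_design(events: pd.DataFrame, motion: pd.DataFrame | None, tr: float,
                 n_volumes: int, derivatives: bool = True) -> DesignMatrix:
    """Assemble the run design matrix.

    Column order: the three convolved task regressors, their temporal
    derivatives (post-convolution central differences), seven motion
    confounds (unconvolved), constant last.  Onsets must be strictly
    increasing; pass ``motion=None`` to omit confounds.
    """
    if not np.all(np.diff(events["onset"].to_numpy(float)) > 0):
        raise ValueError("onsets must be strictly increasing within a run")
    task, means = convolved_task_regressors(events, n_volumes, tr)
    frame = task.copy()
    if derivatives:
        for name in TASK_COLUMNS:
            frame[f"{name}_derivative"] = np.gradient(task[name].to_numpy(), tr)
    if motion is not None:
        missing = set(MOTION_COLUMNS) - set(motion.columns)
        if missing:
            raise ValueError(f"motion table missing columns {sorted(missing)}")
        if len(motion) != n_volumes:
            raise ValueError("motion table length does not match n_volumes")
        for name in MOTION_COLUMNS:
            frame[name] = motion[name].to_numpy(float)
    frame["constant"] = 1.0
    if frame.columns.duplicated().any():
        raise ValueError("duplicate design column names")
    return DesignMatrix(frame=frame, tr=tr, modulator_means=means)


def _dct_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Constant + linear + discrete-cosine columns with period > cutoff."""
    t = np.arange(n)
    k_max = int(np.floor(2.0 * n * tr / cutoff))
    cols = [np.ones(n), t - t.mean()]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)))
    basis = np.column_stack(cols)
    # orthonormalise for a numerically clean projection
    q, _ = np.linalg.qr(basis)
    return q


def highpass(data: np.ndarray, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Remove slow drift by projecting out a cosine + trend basis.

    Applied identically to data and regressors (time along the first axis).
    The projection is idempotent; components with period above the cutoff
    (including any linear trend and the mean) are removed.
    """
    if cutoff <= 2.0 * tr:
        raise ValueError("cutoff must exceed 2*TR")
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    q = _dct_basis(arr.shape[0], tr, cutoff)
    out = arr - q @ (q.T @ arr)
    return out[:, 0] if squeeze else out


def smooth_volumes(data, fwhm: float = 5.0, voxel_size=None):
    """Per-volume 3-D Gaussian smoothing with the kernel given as FWHM in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if isinstance(data, VolumeMap):
        vs = data.voxel_size
        arr = data.data
    else:
        if voxel_size is None:
            raise ValueError("voxel_size required for bare arrays")
        vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        arr = np.asarray(data, float)
    if fwhm == 0:
        out = arr.copy()
    else:
        sigma_vox = (fwhm / 2.3548) / vs
        sigma = tuple(sigma_vox) + ((0.0,) if arr.ndim == 4 else ())
        out = ndimage.gaussian_filter(arr.astype(float), sigma=sigma)
    return data.like(out) if isinstance(data, VolumeMap) else out


@dataclass
class RunEstimates:
    """Voxelwise betas/variances for one run (arrays flattened over voxels)."""

    betas: dict
    variances: dict
    dof: int
    ar1_rho: np.ndarray
    grid_shape: tuple
    affine: np.ndarray

    def beta_map(self, name: str) -> VolumeMap:
        return VolumeMap(self.betas[name].reshape(self.grid_shape), self.affine)


@dataclass
class SubjectEstimates:
    """Fixed-effects pooled beta, variance and Z per regressor."""

    betas: dict
    variances: dict
    z: dict
    grid_shape: tuple
    affine: np.ndarray

    def z_map(self, name: str) -> VolumeMap:
        return VolumeMap(self.z[name].reshape(self.grid_shape), self.affine)

    def beta_map(self, name: str) -> VolumeMap:
        return VolumeMap(self.betas[name].reshape(self.grid_shape), self.affine)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design (collinear columns: {bad})")


def fit_run_glm(data, design: DesignMatrix, prewhiten: bool = True,
                rho_quantum: float = 0.01) -> RunEstimates:
    """Voxelwise least squares with AR(1) Cochrane-Orcutt prewhitening.

    ``data`` is a 4-D VolumeMap (x, y, z, t) or a (T, V) array.  The AR(1)
    coefficient is estimated per voxel from OLS residuals, quantised to
    ``rho_quantum`` so voxels sharing a coefficient are solved in one batch,
    and both data and design are transformed before the final fit.  Voxels
    with numerically zero residual variance skip prewhitening.
    """
    if isinstance(data, VolumeMap):
        grid_shape = data.grid_shape
        affine = data.affine
        Y = data.data.reshape(-1, data.shape[3]).T.astype(float)
    else:
        Y = np.asarray(data, dtype=float)
        grid_shape = (Y.shape[1], 1, 1)
        affine = np.eye(4)
    X = design.values
    names = design.columns
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data and design disagree on the number of volumes")
    _check_rank(X, names)
    T, p = X.shape
    dof = T - p

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    den = (resid ** 2).sum(axis=0)
    if prewhiten:
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 1e-10, num / np.maximum(den, 1e-300), 0.0)
        rho = np.clip(rho, 0.0, 0.95)
        rho = np.round(rho / rho_quantum) * rho_quantum
    else:
        rho = np.zeros(Y.shape[1])

    betas = np.empty_like(beta)
    variances = np.empty((p, Y.shape[1]))
    for r in np.unique(rho):
        sel = rho == r
        if r == 0.0:
            Xs, Ys = X, Y[:, sel]
        else:
            Xs = X.copy()
            Xs[1:] -= r * X[:-1]
            Xs[0] *= np.sqrt(1.0 - r ** 2)
            Ys = Y[:, sel].copy()
            Ys[1:] -= r * Y[:-1, sel]
            Ys[0] *= np.sqrt(1.0 - r ** 2)
        pinv_s = np.linalg.pinv(Xs)
        b = pinv_s @ Ys
        rss = ((Ys - Xs @ b) ** 2).sum(axis=0)
        sigma2 = rss / dof
        xtx_inv_diag = np.diag(np.linalg.inv(Xs.T @ Xs))
        betas[:, sel] = b
        variances[:, sel] = xtx_inv_diag[:, None] * sigma2[None, :]
    return RunEstimates(
        betas={n: betas[i] for i, n in enumerate(names)},
        variances={n: variances[i] for i, n in enumerate(names)},
        dof=dof, ar1_rho=rho, grid_shape=grid_shape, affine=affine)


def pool_fixed_effects(runs: list[RunEstimates],
                       regressors=TASK_COLUMNS) -> SubjectEstimates:
    """Inverse-variance (fixed-effects) pooling of run estimates.

    pooled_var = 1 / sum(1/v_i), pooled_beta = pooled_var * sum(b_i/v_i),
    Z = pooled_beta / sqrt(pooled_var).  Raises on zero-variance voxels
    (degenerate, e.g. noise-free simulations; inspect run betas directly).
    """
    if not runs:
        raise ValueError("need at least one run")
    shape0 = runs[0].grid_shape
    if any(r.grid_shape != shape0 for r in runs):
        raise ValueError("runs are on different grids")
    betas, variances, zs = {}, {}, {}
    for name in regressors:
        v = np.stack([r.variances[name] for r in runs])
        b = np.stack([r.betas[name] for r in runs])
        if np.any(v <= 0):
            raise ValueError(f"zero-variance voxel encountered for {name} (degenerate)")
        w = 1.0 / v
        pooled_var = 1.0 / w.sum(axis=0)
        pooled_beta = (w * b).sum(axis=0) * pooled_var
        betas[name] = pooled_beta
        variances[name] = pooled_var
        zs[name] = pooled_beta / np.sqrt(pooled_var)
    return SubjectEstimates(betas=betas, variances=variances, z=zs,
                            grid_shape=shape0, affine=runs[0].affine)
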