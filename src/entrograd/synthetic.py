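"""Synthetic mixed-gambles task and BOLD generator with known ground truth.

The generator emulates the study design end to end: orthogonal gain/loss
grids in two range conditions (equal range, or losses spanning half the
gains), Bernoulli choices from a logistic model with loss-averse
coefficients, a four-level response scale obtained by splitting each
accept/reject at a confidence threshold on the model's probability of
being correct, and 4-D BOLD runs in which each voxel's time series is the
HRF-convolved trial regressors weighted by spatially smooth intercept /
SV / iDE ground-truth maps, plus AR(1) noise, slow drift and a
motion-correlated nuisance option.

Because the BOLD signal is built with the same convolution code the
first-level GLM uses, noise-free simulations round-trip exactly: fitted
betas equal the generating weight maps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import behavior, first_level
from .behavior import ParticipantFit
from .volume import VolumeMap, default_affine

__all__ = [
    "TaskConfig",
    "NoiseModel",
    "GroundTruthMaps",
    "generate_gambles",
    "simulate_choices",
    "make_gradient_maps",
    "generate_bold",
    "simulate_motion",
    "draw_cohort_fits",
    "write_dataset",
]

#: confidence threshold on p_correct splitting strong from weak responses
DEFAULT_CONFIDENCE_THETA = 0.75


def _default_levels(condition: str) -> tuple[np.ndarray, np.ndarray]:
    if condition == "equal_indifference":
        # loss range half the gain range
        return np.arange(10.0, 41.0, 2.0), np.arange(5.0, 21.0, 1.0)
    if condition == "equal_range":
        return np.arange(5.0, 21.0, 1.0), np.arange(5.0, 21.0, 1.0)
    raise ValueError(f"unknown condition {condition!r}")


@dataclass
class TaskConfig:
    """Mixed-gambles schedule parameters.

    Gains and losses are crossed orthogonally; the default level sets give a
    16 x 16 grid whose 256 cells exactly fill the default 64 trials/run x 4
    runs without replacement.
    """

    condition: str = "equal_indifference"
    gain_levels: np.ndarray | None = None
    loss_levels: np.ndarray | None = None
    n_trials_per_run: int = 64
    n_runs: int = 4
    trial_duration: float = 4.0
    iti_range: tuple[float, float] = (2.0, 6.0)
    tr: float = 1.0
    seed: int = 0

    def __post_init__(self):
        gains, losses = _default_levels(self.condition)
        if self.gain_levels is None:
            self.gain_levels = gains
        if self.loss_levels is None:
            self.loss_levels = losses
        self.gain_levels = np.asarray(self.gain_levels, dtype=float)
        self.loss_levels = np.asarray(self.loss_levels, dtype=float)
        if self.gain_levels.size == 0 or self.loss_levels.size == 0:
            raise ValueError("gain/loss level lists must be non-empty")
        if self.condition == "equal_range":
            if not np.isclose(np.ptp(self.gain_levels), np.ptp(self.loss_levels)):
                raise ValueError("equal_range requires equal gain and loss spans")
        if self.condition == "equal_indifference":
            if not np.isclose(np.ptp(self.loss_levels), np.ptp(self.gain_levels) / 2):
                raise ValueError("equal_indifference requires the loss span to be half the gain span")


@dataclass
class NoiseModel:
    """Additive noise for the BOLD generator (signal units)."""

    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    motion_coupling: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass
class GroundTruthMaps:
    """Voxelwise generating weights for the three task regressors."""

    intercept_map: VolumeMap
    sv_weight_map: VolumeMap
    ide_weight_map: VolumeMap
    roi_masks: dict = field(default_factory=dict)
    mode: str = "aligned"

    def __post_init__(self):
        if not self.sv_weight_map.same_grid(self.ide_weight_map) or \
           not self.sv_weight_map.same_grid(self.intercept_map):
            raise ValueError("ground-truth maps must share grid and affine")


def generate_gambles(config: TaskConfig, rng: np.random.Generator | None = None,
                     allow_replacement: bool = False) -> pd.DataFrame:
    """Trial schedule drawn from the full gain x loss crossing.

    Trials are a seeded shuffle of the complete crossing (or a with-replacement
    draw when more trials than cells are requested and allowed).  Onsets follow
    a uniform inter-trial interval; columns: run (1-based), trial, onset,
    duration, gain, loss.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    G, L = np.meshgrid(config.gain_levels, config.loss_levels, indexing="ij")
    cells = np.column_stack([G.ravel(), L.ravel()])
    n_total = config.n_trials_per_run * config.n_runs
    if n_total > len(cells):
        if not allow_replacement:
            raise ValueError(
                f"{n_total} trials exceed the {len(cells)} unique gain/loss crossings; "
                "enable allow_replacement to sample with replacement")
        idx = rng.integers(0, len(cells), n_total)
    else:
        idx = rng.permutation(len(cells))[:n_total]
    chosen = cells[idx]
    rows = []
    for run in range(1, config.n_runs + 1):
        t = 0.0
        for j in range(config.n_trials_per_run):
            iti = rng.uniform(*config.iti_range)
            k = (run - 1) * config.n_trials_per_run + j
            rows.append({"run": run, "trial": j + 1, "onset": round(t, 3),
                         "duration": config.trial_duration,
                         "gain": chosen[k, 0], "loss": chosen[k, 1]})
            t += config.trial_duration + iti
    return pd.DataFrame(rows)


def simulate_choices(gambles: pd.DataFrame, true_fit: ParticipantFit,
                     rng: np.random.Generator,
                     theta: float = DEFAULT_CONFIDENCE_THETA) -> pd.DataFrame:
    """Bernoulli choices plus a four-level response from a confidence split.

    accept ~ Bernoulli(p_accept); the response is Strongly Accept/Reject when
    the model's probability of being correct reaches ``theta``, otherwise the
    Weak variant on the side of the sampled choice.
    """
    df = behavior.trial_values(true_fit, gambles.copy())
    accept = (rng.random(len(df)) < df["p_accept"].to_numpy()).astype(int)
    strong = df["p_correct"].to_numpy() >= theta
    labels = np.where(accept == 1,
                      np.where(strong, "strongly_accept", "weakly_accept"),
                      np.where(strong, "strongly_reject", "weakly_reject"))
    out = gambles.copy()
    out["accept"] = accept
    out["response"] = labels
    return out


def _smooth_unit_field(shape, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    # periodic smoothing keeps the field stationary on the grid torus, which
    # the joint-coding torus-translation null relies on
    f = rng.standard_normal(shape)
    if smoothness > 0:
        f = ndimage.gaussian_filter(f, smoothness, mode="wrap")
    return f / f.std()


def make_gradient_maps(shape=(20, 20, 20), axis: int = 2,
                       sv_amplitude: float = 0.25, ide_amplitude: float = 8.0,
                       intercept_amplitude: float = 4.0,
                       smoothness: float = 1.5, mode: str = "aligned",
                       voxel_size: float = 3.0,
                       rng: np.random.Generator | None = None) -> GroundTruthMaps:
    """Spatially smooth ground-truth weight maps.

    ``aligned`` builds both SV and iDE weights around one smooth field that
    transitions from jointly positive to jointly negative along ``axis``
    (sign agreement by construction); ``independent`` samples two unrelated
    smooth fields; ``opposed`` flips the iDE map's sign relative to aligned.
    Amplitudes are in signal units per unit of (centred) modulator, so the
    SV and iDE scales can differ to compensate for the very different ranges
    of the two modulators.
    """
    if len(shape) != 3:
        raise ValueError("shape must be 3-D")
    rng = np.random.default_rng(0) if rng is None else rng
    affine = default_affine(voxel_size, shape)
    grad = np.linspace(1.0, -1.0, shape[axis])
    grad = np.moveaxis(np.broadcast_to(grad, shape[:axis] + shape[axis + 1:] + (shape[axis],)),
                       -1, axis).copy()
    if mode in ("aligned", "opposed"):
        base = grad + 0.15 * _smooth_unit_field(shape, smoothness, rng)
        sv_w = sv_amplitude * (base + 0.05 * _smooth_unit_field(shape, smoothness, rng))
        ide_w = ide_amplitude * (base + 0.05 * _smooth_unit_field(shape, smoothness, rng))
        if mode == "opposed":
            ide_w = -ide_w
    elif mode == "independent":
        sv_w = sv_amplitude * _smooth_unit_field(shape, smoothness, rng)
        ide_w = ide_amplitude * _smooth_unit_field(shape, smoothness, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    intercept = np.full(shape, float(intercept_amplitude))
    maps = GroundTruthMaps(
        intercept_map=VolumeMap(intercept, affine),
        sv_weight_map=VolumeMap(sv_w, affine),
        ide_weight_map=VolumeMap(ide_w, affine),
        mode=mode,
    )
    maps.roi_masks = {
        "jointly_positive": VolumeMap(((sv_w > 0) & (ide_w > 0)).astype(float), affine),
        "jointly_negative": VolumeMap(((sv_w < 0) & (ide_w < 0)).astype(float), affine),
    }
    return maps


def simulate_motion(n_volumes: int, rng: np.random.Generator,
                    step_sd: float = 0.01, smooth_sigma: float = 5.0) -> pd.DataFrame:
    """Slow random-walk motion parameters and their framewise displacement.

    Three rotations (rad) and three translations (mm) as smoothed random
    walks; framewise displacement sums absolute parameter changes with
    rotations converted to mm on a 50 mm sphere.
    """
    walk = np.cumsum(rng.normal(0.0, step_sd, size=(n_volumes, 6)), axis=0)
    walk = ndimage.gaussian_filter1d(walk, smooth_sigma, axis=0)
    rot, trans = walk[:, :3] * 0.01, walk[:, 3:]
    d = np.vstack([np.zeros((1, 6)), np.diff(np.column_stack([rot * 50.0, trans]), axis=0)])
    fd = np.abs(d).sum(axis=1)
    return pd.DataFrame({
        "framewise_displacement": fd,
        "rot_x": rot[:, 0], "rot_y": rot[:, 1], "rot_z": rot[:, 2],
        "trans_x": trans[:, 0], "trans_y": trans[:, 1], "trans_z": trans[:, 2],
    })


def generate_bold(events: pd.DataFrame, maps: GroundTruthMaps, noise: NoiseModel,
                  tr: float, rng: np.random.Generator,
                  n_volumes: int | None = None, pad: float = 16.0,
                  baseline: float = 100.0,
                  motion: pd.DataFrame | None = None) -> tuple[VolumeMap, pd.DataFrame]:
    """One run of 4-D BOLD plus its motion confound table.

    Voxel time series = baseline
                      + intercept_map * conv(boxcar)
                      + sv_weight_map * conv(boxcar * centred SV)
                      + ide_weight_map * conv(boxcar * centred iDE)
                      + drift + motion coupling + stationary AR(1) noise,
    with the identical double-gamma convolution used by the first-level GLM.
    ``events`` must carry onset, duration, sv and ide for one run.
    """
    if n_volumes is None:
        end = float((events["onset"] + events["duration"]).max()) + pad
        n_volumes = int(np.ceil(end / tr))
    task, _ = first_level.convolved_task_regressors(events, n_volumes, tr)
    shape = maps.sv_weight_map.grid_shape
    V = int(np.prod(shape))
    weights = np.vstack([maps.intercept_map.data.ravel(),
                         maps.sv_weight_map.data.ravel(),
                         maps.ide_weight_map.data.ravel()])
    C = task[list(first_level.TASK_COLUMNS)].to_numpy()  # (T, 3)
    Y = baseline + C @ weights  # (T, V)
    if motion is None:
        motion = simulate_motion(n_volumes, rng)
    if noise.drift_amplitude > 0:
        t = np.arange(n_volumes) * tr
        slow = np.column_stack([t / t.max() - 0.5,
                                np.cos(np.pi * t / t.max()),
                                np.cos(2 * np.pi * t / t.max())])
        Y += slow @ (noise.drift_amplitude * rng.standard_normal((3, V)))
    if noise.motion_coupling > 0:
        params = motion[["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]].to_numpy()
        params = (params - params.mean(0)) / np.maximum(params.std(0), 1e-12)
        Y += noise.motion_coupling * params @ rng.standard_normal((6, V))
    if noise.sigma > 0:
        eps = rng.standard_normal((n_volumes, V)) * noise.sigma * np.sqrt(1.0 - noise.ar1_rho ** 2)
        ar = np.empty_like(eps)
        ar[0] = eps[0] / np.sqrt(1.0 - noise.ar1_rho ** 2)
        for i in range(1, n_volumes):
            ar[i] = noise.ar1_rho * ar[i - 1] + eps[i]
        Y += ar
    bold = VolumeMap(np.moveaxis(Y, 0, -1).reshape(shape + (n_volumes,)),
                     maps.sv_weight_map.affine)
    return bold, motion


def draw_cohort_fits(n_subjects: int, rng: np.random.Generator) -> list[ParticipantFit]:
    """Generative coefficients for a cohort: loss-averse with ratio near -2.

    beta_gains ~ U(0.08, 0.25) logit units per currency unit, loss aversion
    ratio ~ N(2, 0.3) truncated to [1.2, 3], intercept ~ N(0, 0.5).  On the
    default gain/loss grids these give acceptance probabilities spanning the
    unit interval without saturating.
    """
    fits = []
    for _ in range(n_subjects):
        bg = rng.uniform(0.08, 0.25)
        ratio = float(np.clip(rng.normal(2.0, 0.3), 1.2, 3.0))
        fits.append(ParticipantFit(beta_gains=bg, beta_losses=-ratio * bg,
                                   intercept=float(rng.normal(0.0, 0.5))))
    return fits


def write_dataset(root, subjects: dict, maps: GroundTruthMaps,
                  config: TaskConfig, manifest_extra: dict | None = None) -> None:
    """Write a BIDS-like tree: events/bold/confounds per run plus ground truth.

    ``subjects`` maps participant label -> dict with keys ``events`` (DataFrame
    including run, response), ``bold`` (dict run -> VolumeMap) and
    ``confounds`` (dict run -> DataFrame).
    """
    root = Path(root)
    for sub, payload in subjects.items():
        func = root / f"sub-{sub}" / "func"
        func.mkdir(parents=True, exist_ok=True)
        ev = payload["events"]
        for run in sorted(ev["run"].unique()):
            stem = f"sub-{sub}_task-gambles_run-{int(run):02d}"
            run_ev = ev[ev["run"] == run].copy()
            run_ev.rename(columns={"response": "participant_response"}) \
                  .to_csv(func / f"{stem}_events.tsv", sep="\t", index=False)
            if "bold" in payload:
                payload["bold"][run].save(func / f"{stem}_bold.nii.gz")
            if "confounds" in payload:
                payload["confounds"][run].to_csv(func / f"{stem}_confounds.tsv",
                                                 sep="\t", index=False)
    gt = root / "ground_truth"
    gt.mkdir(parents=True, exist_ok=True)
    maps.intercept_map.save(gt / "intercept_weight.nii.gz")
    maps.sv_weight_map.save(gt / "sv_weight.nii.gz")
    maps.ide_weight_map.save(gt / "ide_weight.nii.gz")
    for name, m in maps.roi_masks.items():
        m.save(gt / f"roi-{name}_mask.nii.gz")
    manifest = {"config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in asdict(config).items()},
                "maps_mode": maps.mode,
                "n_subjects": len(subjects)}
    if manifest_extra:
        manifest.update(manifest_extra)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
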