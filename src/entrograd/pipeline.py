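"""End-to-end orchestration: simulate -> behaviour -> GLM -> group -> joint coding.

A single :class:`RunConfig` (YAML-serialisable) fixes every parameter and
seed; identical configs give identical numerical outputs.  Stages can be
re-run in isolation from cached state, and every procedure that stands in
for the original tooling (AR(1) prewhitening, permutation cluster p values,
method-of-moments mixed effects) is named in the report's deviations list.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, first_level, group_level, joint_coding, synthetic
from .behavior import ParticipantFit
from .volume import VolumeMap

__all__ = ["RunConfig", "RunReport", "run_pipeline", "simulate_dataset"]

log = logging.getLogger("entrograd")

DEVIATIONS = [
    "serial correlation: per-voxel AR(1) Cochrane-Orcutt prewhitening "
    "(not a locally regularised autocorrelation estimator)",
    "high-pass: discrete cosine + trend projection applied to data and design "
    "(not a running-line detrend)",
    "group level: method-of-moments random effects with optional Huber "
    "deweighting (not Bayesian two-stage mixed effects)",
    "cluster correction: sign-flip permutation null of maximum cluster extent "
    "(not Gaussian-random-field theory)",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full synthetic run."""

    seed: int = 0
    n_subjects: int = 24
    # task
    condition: str = "equal_indifference"
    n_trials_per_run: int = 64
    n_runs: int = 4
    trial_duration: float = 4.0
    tr: float = 1.0
    confidence_theta: float = 0.75
    # ground-truth maps
    maps_mode: str = "aligned"
    grid_shape: tuple = (20, 20, 20)
    voxel_size: float = 3.0
    sv_amplitude: float = 0.25
    ide_amplitude: float = 8.0
    intercept_amplitude: float = 4.0
    smoothness: float = 1.5
    # noise
    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    motion_coupling: float = 0.0
    # analysis
    fwhm: float = 5.0
    highpass_cutoff: float = 100.0
    z_thresh: float = 2.3
    alpha: float = 0.05
    contrast_alpha: float = 0.01
    n_perm: int = 1000
    n_perm_contrast: int = 1000
    exclusion_sd: float = 2.3
    deweight: bool = True
    contingency_mode: str = "corrected"  # or "uncorrected"
    run_contrast: bool = True
    run_cluster_inference: bool = True
    # I/O
    dataset_root: str | None = None
    output_root: str | None = None

    def task_config(self) -> synthetic.TaskConfig:
        return synthetic.TaskConfig(
            condition=self.condition, n_trials_per_run=self.n_trials_per_run,
            n_runs=self.n_runs, trial_duration=self.trial_duration,
            tr=self.tr, seed=self.seed)

    def noise_model(self) -> synthetic.NoiseModel:
        return synthetic.NoiseModel(sigma=self.sigma, ar1_rho=self.ar1_rho,
                                    drift_amplitude=self.drift_amplitude,
                                    motion_coupling=self.motion_coupling)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunReport:
    """Collected outputs plus provenance for one pipeline run."""

    config: dict
    config_hash: str
    deviations: list = field(default_factory=lambda: list(DEVIATIONS))
    timings: dict = field(default_factory=dict)
    behaviour: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    cluster_tables: dict = field(default_factory=dict)
    contingency: dict = field(default_factory=dict)
    roi_overlap: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    contrast: dict = field(default_factory=dict)
    loss_aversion: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _seeds(config: RunConfig) -> dict:
    ss = np.random.SeedSequence(config.seed)
    names = ["maps", "subjects", "group", "contrast", "contingency"]
    children = ss.spawn(len(names))
    return dict(zip(names, children))


def simulate_cohort(config: RunConfig):
    """Ground-truth maps plus per-subject schedules, choices and true fits."""
    seeds = _seeds(config)
    maps = synthetic.make_gradient_maps(
        shape=tuple(config.grid_shape), mode=config.maps_mode,
        sv_amplitude=config.sv_amplitude, ide_amplitude=config.ide_amplitude,
        intercept_amplitude=config.intercept_amplitude,
        smoothness=config.smoothness, voxel_size=config.voxel_size,
        rng=np.random.default_rng(seeds["maps"]))
    task = config.task_config()
    sub_seeds = seeds["subjects"].spawn(config.n_subjects)
    cohort_rng = np.random.default_rng(seeds["subjects"])
    true_fits = synthetic.draw_cohort_fits(config.n_subjects, cohort_rng)
    subjects = {}
    for i, (true_fit, sseed) in enumerate(zip(true_fits, sub_seeds)):
        rng = np.random.default_rng(sseed)
        gambles = synthetic.generate_gambles(task, rng)
        trials = synthetic.simulate_choices(gambles, true_fit, rng,
                                            theta=config.confidence_theta)
        subjects[f"{i + 1:02d}"] = {"true_fit": true_fit, "trials": trials, "rng": rng}
    return maps, subjects


def _first_level_subject(trials_with_values: pd.DataFrame, maps, config: RunConfig,
                         rng: np.random.Generator):
    """Generate BOLD and fit the GLM run by run; returns pooled estimates + mean FD."""
    noise = config.noise_model()
    runs = []
    fd = []
    for run in sorted(trials_with_values["run"].unique()):
        ev = trials_with_values[trials_with_values["run"] == run]
        ev_kept = ev.dropna(subset=["accept"])
        bold, motion = synthetic.generate_bold(ev_kept, maps, noise, config.tr, rng)
        fd.append(float(motion["framewise_displacement"].mean()))
        smoothed = first_level.smooth_volumes(bold, fwhm=config.fwhm)
        design = first_level.build_design(ev_kept, motion, config.tr, bold.shape[3])
        Y = smoothed.data.reshape(-1, bold.shape[3]).T
        Yf = first_level.highpass(Y, config.tr, config.highpass_cutoff)
        Xf = design.frame.copy()
        filt_cols = [c for c in Xf.columns if c != "constant"]
        Xf[filt_cols] = first_level.highpass(Xf[filt_cols].to_numpy(), config.tr,
                                             config.highpass_cutoff)
        design_f = first_level.DesignMatrix(frame=Xf, tr=config.tr,
                                            modulator_means=design.modulator_means)
        est = first_level.fit_run_glm(Yf, design_f)
        est.grid_shape = maps.sv_weight_map.grid_shape
        est.affine = maps.sv_weight_map.affine
        runs.append(est)
    pooled = first_level.pool_fixed_effects(runs)
    return pooled, float(np.mean(fd))


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute behaviour -> first level -> group level -> joint coding."""
    t_start = time.time()
    report = RunReport(config=config.to_dict(), config_hash=config.config_hash())
    seeds = _seeds(config)
    timings = report.timings

    t0 = time.time()
    maps, subjects = simulate_cohort(config)
    timings["simulate"] = time.time() - t0

    # ---- behaviour ----------------------------------------------------
    t0 = time.time()
    fitted: dict[str, ParticipantFit] = {}
    values: dict[str, pd.DataFrame] = {}
    for pid, payload in subjects.items():
        fit = behavior.fit_choice_model(payload["trials"])
        fitted[pid] = fit
        values[pid] = behavior.trial_values(fit, payload["trials"])
    timings["behaviour_fit"] = time.time() - t0

    # ---- first level --------------------------------------------------
    t0 = time.time()
    pooled = {}
    motion_summary = {}
    for pid, payload in subjects.items():
        pooled[pid], motion_summary[pid] = _first_level_subject(
            values[pid], maps, config, payload["rng"])
        log.info("first level done for sub-%s", pid)
    timings["first_level"] = time.time() - t0

    exclusion_table = behavior.exclude_participants(fitted, motion_summary,
                                                    sd_threshold=config.exclusion_sd)
    kept = [pid for pid in fitted if exclusion_table.loc[pid, "kept"]]
    report.exclusions = {
        "kept": kept,
        "excluded": {pid: exclusion_table.loc[pid, "reasons"]
                     for pid in fitted if pid not in kept},
    }
    if not kept:
        raise RuntimeError("behaviour stage: all participants excluded: "
                           + json.dumps(report.exclusions["excluded"]))

    validation = behavior.validate_ide({pid: values[pid] for pid in kept})
    report.behaviour = {
        "n_kept": len(kept),
        "sv_paccept_rho_mean": validation.sv_paccept_rho_mean,
        "sv_paccept_rho_sd": validation.sv_paccept_rho_sd,
        "ide_pcorrect_rho_mean": validation.ide_pcorrect_rho_mean,
        "ide_pcorrect_rho_sd": validation.ide_pcorrect_rho_sd,
        "weak_ide_mean": validation.weak_ide_mean,
        "strong_ide_mean": validation.strong_ide_mean,
        "welch_t": validation.welch_t, "welch_df": validation.welch_df,
        "welch_p": validation.welch_p,
        "mean_loss_aversion": float(np.mean([fitted[p].loss_aversion for p in kept])),
    }

    # ---- group level ---------------------------------------------------
    t0 = time.time()
    grid_shape = maps.sv_weight_map.grid_shape
    affine = maps.sv_weight_map.affine
    stacks = {name: np.stack([pooled[p].betas[name] for p in kept])
              for name in first_level.TASK_COLUMNS}
    z_stacks = {name: np.stack([pooled[p].z[name] for p in kept])
                for name in first_level.TASK_COLUMNS}
    group = {name: group_level.group_onesample((stacks[name], grid_shape, affine),
                                               deweight=config.deweight)
             for name in first_level.TASK_COLUMNS}
    task_mask = group_level.task_active_mask(group["trial_intercept"], config.z_thresh)

    grng = np.random.default_rng(seeds["group"])
    clusters = {}
    if config.run_cluster_inference:
        for name in ("SV_mod", "iDE_mod"):
            for tail in ("pos", "neg"):
                clusters[f"{name}_{tail}"] = group_level.cluster_inference(
                    group[name], z_thresh=config.z_thresh, alpha=config.alpha,
                    n_perm=config.n_perm, tail=tail, rng=grng)
        for tail in ("pos", "neg"):
            clusters[f"conjunction_{tail}"] = group_level.conjunction(
                group["SV_mod"], group["iDE_mod"], z_thresh=config.z_thresh,
                alpha=config.alpha, n_perm=config.n_perm, tail=tail, rng=grng)
        report.cluster_tables = {k: v.table for k, v in clusters.items()}
    if config.run_contrast:
        contrast = group_level.contrast_sv_vs_ide(
            group_level.group_onesample((z_stacks["SV_mod"], grid_shape, affine)),
            group_level.group_onesample((z_stacks["iDE_mod"], grid_shape, affine)),
            mask=task_mask, n_perm=config.n_perm_contrast,
            alpha=config.contrast_alpha, z_thresh=config.z_thresh,
            rng=np.random.default_rng(seeds["contrast"]))
        report.contrast = {k: v.cluster.table for k, v in contrast.items()}
    timings["group_level"] = time.time() - t0

    # ---- joint coding --------------------------------------------------
    t0 = time.time()
    if config.contingency_mode == "corrected" and config.run_cluster_inference:
        sig = {f"{n}_{t}": clusters[f"{n}_{t}"].significant_mask.reshape(-1)
               for n in ("SV_mod", "iDE_mod") for t in ("pos", "neg")}
    else:
        sig = {}
        for n in ("SV_mod", "iDE_mod"):
            sig[f"{n}_pos"] = group[n].z >= config.z_thresh
            sig[f"{n}_neg"] = group[n].z <= -config.z_thresh
    try:
        contingency = joint_coding.sign_contingency(
            *(sig[k].reshape(grid_shape) for k in
              ("SV_mod_pos", "SV_mod_neg", "iDE_mod_pos", "iDE_mod_neg")),
            mask=task_mask.reshape(grid_shape),
            rng=np.random.default_rng(seeds["contingency"]))
        report.contingency = contingency.to_dict()
    except ValueError as err:
        report.contingency = {"error": str(err)}

    for name, roi in maps.roi_masks.items():
        pct = joint_coding.roi_overlap(sig["SV_mod_pos"], sig["SV_mod_neg"],
                                       sig["iDE_mod_pos"], sig["iDE_mod_neg"],
                                       roi.data)
        report.roi_overlap[name] = pct
        corr = joint_coding.map_correlation(group["SV_mod"].effect,
                                            group["iDE_mod"].effect,
                                            roi.data, region=name)
        report.correlations.append(asdict(corr))
    whole = joint_coding.map_correlation(group["SV_mod"].effect,
                                         group["iDE_mod"].effect,
                                         task_mask, region="task_active")
    report.correlations.append(asdict(whole))
    gradient = joint_coding.gradient_map(group["SV_mod"].effect,
                                         group["iDE_mod"].effect, task_mask)

    sv_z_by_sub = {pid: pooled[pid].z["SV_mod"] for pid in kept}
    la_table, la_rho = joint_coding.loss_aversion_voxel_ratio(
        sv_z_by_sub, fitted, mask=task_mask, z_thresh=config.z_thresh)
    report.loss_aversion = {"spearman_rho": la_rho,
                            "n_defined": int(la_table["ratio"].notna().sum())}
    timings["joint_coding"] = time.time() - t0
    timings["total"] = time.time() - t_start

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.save(outdir / "report.json")
        VolumeMap(gradient.reshape(grid_shape), affine).save(outdir / "gradient_map.nii.gz")
        for name in first_level.TASK_COLUMNS:
            group[name].z_map().save(outdir / f"group_{name}_z.nii.gz")
        for key, tab in report.cluster_tables.items():
            tab.to_csv(outdir / f"clusters_{key}.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")

    # expose arrays for downstream reuse / stage isolation
    report._state = {  # type: ignore[attr-defined]
        "maps": maps, "group": group, "task_mask": task_mask,
        "pooled": pooled, "fitted": fitted, "values": values,
        "kept": kept, "gradient": gradient, "clusters": clusters,
    }
    return report


def simulate_dataset(config: RunConfig, root) -> Path:
    """Write the synthetic cohort as a BIDS-like tree with ground truth."""
    maps, subjects = simulate_cohort(config)
    noise = config.noise_model()
    payloads = {}
    for pid, payload in subjects.items():
        fit = payload["true_fit"]
        trials = behavior.trial_values(fit, payload["trials"])
        bolds, confs = {}, {}
        for run in sorted(trials["run"].unique()):
            ev = trials[trials["run"] == run].dropna(subset=["accept"])
            bold, motion = synthetic.generate_bold(ev, maps, noise, config.tr,
                                                   payload["rng"])
            bolds[run], confs[run] = bold, motion
        payloads[pid] = {"events": payload["trials"], "bold": bolds, "confounds": confs}
    root = Path(root)
    synthetic.write_dataset(
        root, payloads, maps, config.task_config(),
        manifest_extra={
            "seed": config.seed,
            "true_coefficients": {pid: list(subjects[pid]["true_fit"].coefficients())
                                  for pid in subjects},
        })
    return root
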