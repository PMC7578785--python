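"""Across-participant inference: one-sample maps, clusters, conjunctions.

The group model is a one-sample random-effects test per voxel
(method-of-moments between-subject variance, optional one-round Huber
deweighting of outlying subjects), with the t statistic mapped through its
CDF to a standard-normal Z.  Cluster-level family-wise error is controlled
by a sign-flip permutation null of the maximum supra-threshold cluster
extent (26-neighbour connectivity); this replaces Gaussian-random-field
cluster p-values while preserving the contract of corrected cluster
inference.  Conjunctions use the minimum statistic: a voxel survives only
where both parent effects exceed the cluster-forming threshold.  The
SV-vs-iDE comparison is a paired sign-flip permutation test on subject
differences of Z maps, conjoined with the matching main effect and masked
by voxels whose absolute group effect favours the tested variable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import VolumeMap

__all__ = [
    "GroupMap",
    "ClusterResult",
    "group_onesample",
    "cluster_inference",
    "conjunction",
    "contrast_sv_vs_ide",
    "task_active_mask",
]

#: Huber tuning constant for the optional outlier deweighting round
HUBER_C = 1.345
_CONNECTIVITY = {26: np.ones((3, 3, 3), bool),
                 6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2)}
_Z_CAP = 37.0  # |Z| ceiling where the normal tail underflows


def _t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t statistics to standard-normal quantiles of equal tail mass."""
    t = np.asarray(t, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(sf, 1e-300, 1.0))
    return np.sign(t) * np.minimum(z, _Z_CAP)


@dataclass
class GroupMap:
    """One-sample group estimate; keeps the subject stack for permutations."""

    effect: np.ndarray          # (V,)
    var_between: np.ndarray     # (V,) between-subject variance of the mean's parent
    t: np.ndarray               # (V,)
    z: np.ndarray               # (V,)
    df: float
    n_subjects: int
    stack: np.ndarray           # (n, V) subject values
    mask: np.ndarray            # (V,) bool analysis mask
    grid_shape: tuple
    affine: np.ndarray
    weights: np.ndarray | None = None  # per-subject deweighting summary

    def z_map(self) -> VolumeMap:
        return VolumeMap(self.z.reshape(self.grid_shape), self.affine)


def _stack_from_maps(maps) -> tuple[np.ndarray, tuple, np.ndarray]:
    if isinstance(maps, np.ndarray):
        raise TypeError("pass a list of VolumeMap or (stack, shape, affine)")
    first = maps[0]
    if not all(m.same_grid(first) for m in maps):
        raise ValueError("subject maps are on different grids")
    stack = np.stack([m.data.ravel() for m in maps])
    return stack, first.grid_shape, first.affine


def group_onesample(subject_maps, mask: np.ndarray | None = None,
                    deweight: bool = False) -> GroupMap:
    """Voxelwise one-sample random-effects test across subjects.

    ``subject_maps`` is a list of 3-D VolumeMaps (or a tuple
    ``(stack, grid_shape, affine)`` with stack shaped (n, V)).  With
    ``deweight`` a single round of Huber reweighting (c = 1.345 on
    standardised residuals) shrinks the influence of outlying subjects;
    the t statistic then uses the effective sample size.
    """
    if isinstance(subject_maps, tuple) and len(subject_maps) == 3:
        stack, grid_shape, affine = subject_maps
        stack = np.asarray(stack, dtype=float)
    else:
        stack, grid_shape, affine = _stack_from_maps(subject_maps)
    n, V = stack.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if mask is None:
        mask = np.ones(V, dtype=bool)
    else:
        mask = np.asarray(mask).reshape(-1).astype(bool)

    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    weights = None
    if deweight:
        sd = np.sqrt(np.maximum(var, 1e-300))
        r = (stack - mean) / sd
        w = np.minimum(1.0, HUBER_C / np.maximum(np.abs(r), 1e-12))
        wsum = w.sum(axis=0)
        mean = (w * stack).sum(axis=0) / wsum
        n_eff = wsum ** 2 / (w ** 2).sum(axis=0)
        var = (w * (stack - mean) ** 2).sum(axis=0) / wsum * n_eff / np.maximum(n_eff - 1, 1e-6)
        df = np.maximum(n_eff - 1, 1.0)
        weights = w.mean(axis=1)  # per-subject average weight as a summary
    else:
        n_eff = np.full(V, float(n))
        df = np.full(V, float(n - 1))

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var / n_eff)
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    # piecewise t->z since deweighting gives per-voxel df
    z = np.zeros(V)
    for d in np.unique(np.round(df, 2)):
        sel = np.round(df, 2) == d
        z[sel] = _t_to_z(t[sel], float(d))
    z[~mask] = 0.0
    return GroupMap(effect=mean, var_between=var, t=t, z=z,
                    df=float(n - 1), n_subjects=n, stack=stack, mask=mask,
                    grid_shape=grid_shape, affine=affine, weights=weights)


@dataclass
class ClusterResult:
    """Supra-threshold clusters with permutation-corrected p values."""

    table: pd.DataFrame
    label_map: np.ndarray  # 3-D int labels matching table['index']
    sign: str
    z_thresh: float
    alpha: float
    n_perm: int

    @property
    def significant_mask(self) -> np.ndarray:
        """Boolean 3-D mask of voxels in clusters with p_corrected <= alpha."""
        keep = self.table.loc[self.table["p_corrected"] <= self.alpha, "index"]
        return np.isin(self.label_map, list(keep))


def _max_cluster_extents(binary_stack: np.ndarray, shape, structure) -> np.ndarray:
    """Max connected-component size for each binary map in a (k, V) stack."""
    out = np.zeros(binary_stack.shape[0], dtype=int)
    for i, b in enumerate(binary_stack):
        lab, nlab = ndimage.label(b.reshape(shape), structure=structure)
        if nlab:
            out[i] = np.bincount(lab.ravel())[1:].max()
    return out


def _cluster_table(z_map: np.ndarray, sig: np.ndarray, shape, affine,
                   structure, null_extents: np.ndarray, n_perm: int,
                   sign: str) -> tuple[pd.DataFrame, np.ndarray]:
    lab, nlab = ndimage.label(sig.reshape(shape), structure=structure)
    rows = []
    zz = z_map.reshape(shape)
    for idx in range(1, nlab + 1):
        where = np.argwhere(lab == idx)
        vals = zz[tuple(where.T)]
        peak = where[np.argmax(vals)]
        mm = (affine @ np.append(peak, 1.0))[:3]
        size = len(where)
        p_corr = (1 + int((null_extents >= size).sum())) / (n_perm + 1)
        rows.append({"index": idx, "n_voxels": size,
                     "peak_z": float(vals.max()),
                     "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                     "p_corrected": p_corr, "sign": sign})
    cols = ["index", "n_voxels", "peak_z", "x_mm", "y_mm", "z_mm", "p_corrected", "sign"]
    table = pd.DataFrame(rows, columns=cols).sort_values("n_voxels", ascending=False) \
        if rows else pd.DataFrame(columns=cols)
    return table, lab


def _sign_flip_t(stack: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps for each row of sign flips (vectorised over perms)."""
    n = stack.shape[0]
    sumsq = (stack ** 2).sum(axis=0)
    m = signs @ stack / n
    v = (sumsq - n * m ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(np.maximum(v, 1e-300) / n)
    return t


def cluster_inference(group: GroupMap, z_thresh: float = 2.3, alpha: float = 0.05,
                      n_perm: int = 1000, tail: str = "pos", connectivity: int = 26,
                      rng: np.random.Generator | None = None) -> ClusterResult:
    """Cluster-extent inference with a sign-flip permutation FWE null.

    Voxels with Z >= z_thresh (after negation for ``tail='neg'``) are grouped
    into 26-connected components; each component's corrected p is the
    permutation probability that the maximum null cluster extent reaches its
    size.  Permutation maps are plain one-sample t maps thresholded at the
    t value whose tail mass matches ``z_thresh``.
    """
    if not group.mask.any():
        raise ValueError("empty analysis mask")
    rng = np.random.default_rng(0) if rng is None else rng
    structure = _CONNECTIVITY[connectivity]
    flip = -1.0 if tail == "neg" else 1.0
    z = flip * group.z
    stack = flip * group.stack
    sig = (z >= z_thresh) & group.mask
    t_thresh = stats.t.isf(stats.norm.sf(z_thresh), group.df)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, group.n_subjects))
    null = np.zeros(n_perm, dtype=int)
    chunk = max(1, int(2e7 // stack.shape[1]))
    for lo in range(0, n_perm, chunk):
        t_null = _sign_flip_t(stack, signs[lo:lo + chunk])
        binary = (t_null >= t_thresh) & group.mask
        null[lo:lo + chunk] = _max_cluster_extents(binary, group.grid_shape, structure)
    table, lab = _cluster_table(z, sig, group.grid_shape, group.affine,
                                structure, null, n_perm, "positive" if flip > 0 else "negative")
    return ClusterResult(table=table, label_map=lab, sign="positive" if flip > 0 else "negative",
                         z_thresh=z_thresh, alpha=alpha, n_perm=n_perm)


def conjunction(map_a: GroupMap, map_b: GroupMap, z_thresh: float = 2.3,
                alpha: float = 0.05, n_perm: int = 1000, tail: str = "pos",
                connectivity: int = 26,
                rng: np.random.Generator | None = None) -> ClusterResult:
    """Minimum-statistic conjunction with permutation cluster correction.

    Z_conj = min(Z_a, Z_b) voxelwise, so a voxel survives only when both
    parents exceed the threshold.  The permutation null flips subject signs
    jointly in both stacks (paired subjects) and records the maximum extent
    where both permuted t maps cross the threshold.
    """
    if map_a.grid_shape != map_b.grid_shape or not np.allclose(map_a.affine, map_b.affine):
        raise ValueError("grid mismatch between conjunction inputs")
    if map_a.n_subjects != map_b.n_subjects:
        raise ValueError("conjunction expects paired subject stacks")
    rng = np.random.default_rng(0) if rng is None else rng
    structure = _CONNECTIVITY[connectivity]
    flip = -1.0 if tail == "neg" else 1.0
    mask = map_a.mask & map_b.mask
    z_conj = np.minimum(flip * map_a.z, flip * map_b.z)
    sig = (z_conj >= z_thresh) & mask
    t_thresh = stats.t.isf(stats.norm.sf(z_thresh), map_a.df)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, map_a.n_subjects))
    null = np.zeros(n_perm, dtype=int)
    chunk = max(1, int(1e7 // map_a.stack.shape[1]))
    for lo in range(0, n_perm, chunk):
        s = signs[lo:lo + chunk]
        ta = _sign_flip_t(flip * map_a.stack, s)
        tb = _sign_flip_t(flip * map_b.stack, s)
        binary = (ta >= t_thresh) & (tb >= t_thresh) & mask
        null[lo:lo + chunk] = _max_cluster_extents(binary, map_a.grid_shape, structure)
    label = "positive" if flip > 0 else "negative"
    table, lab = _cluster_table(z_conj, sig, map_a.grid_shape, map_a.affine,
                                structure, null, n_perm, label)
    return ClusterResult(table=table, label_map=lab, sign=label,
                         z_thresh=z_thresh, alpha=alpha, n_perm=n_perm)


@dataclass
class ContrastResult:
    """One direction of the paired SV-vs-iDE comparison."""

    cluster: ClusterResult
    z_perm: np.ndarray        # permutation-p-derived Z map (V,)
    p_uncorrected: np.ndarray
    direction: str


def contrast_sv_vs_ide(sv_maps, ide_maps, mask: np.ndarray | None = None,
                       n_perm: int = 5000, alpha: float = 0.01,
                       z_thresh: float = 2.3, connectivity: int = 26,
                       rng: np.random.Generator | None = None) -> dict:
    """Paired sign-flip contrast of subject Z maps, both directions at once.

    For each voxel the null flips the sign of each subject's iDE-minus-SV
    difference; one-sided permutation p values are converted to Z via the
    normal quantile (so the attainable Z saturates at the resolution set by
    ``1/(n_perm+1)``).  Each direction is conjoined (minimum statistic) with
    its main effect and masked by voxels whose absolute group Z favours the
    tested variable; surviving voxels are clustered, with corrected cluster p
    from the permutation null of maximum extent at the matching threshold.

    Returns ``{"ide_gt_sv": ContrastResult, "sv_gt_ide": ContrastResult}``;
    swapping the inputs exactly swaps the two results.
    """
    sv = sv_maps if isinstance(sv_maps, GroupMap) else group_onesample(sv_maps, mask=mask)
    ide = ide_maps if isinstance(ide_maps, GroupMap) else group_onesample(ide_maps, mask=mask)
    if sv.stack.shape != ide.stack.shape:
        raise ValueError("SV and iDE subject stacks must be paired (same subjects)")
    rng = np.random.default_rng(0) if rng is None else rng
    mask = (sv.mask & ide.mask) if mask is None else np.asarray(mask).reshape(-1).astype(bool)
    structure = _CONNECTIVITY[connectivity]
    d = ide.stack - sv.stack
    n, V = d.shape
    m = d.mean(axis=0)
    v = d.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = np.where(v > 0, m / np.sqrt(np.maximum(v, 1e-300) / n), 0.0)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    ge = np.zeros(V)   # count of null t >= observed t
    le = np.zeros(V)
    t_quant = stats.t.isf(alpha, n - 1)  # cluster-forming threshold for null maps
    null_hi = np.zeros(n_perm, dtype=int)
    null_lo = np.zeros(n_perm, dtype=int)
    chunk = max(1, int(2e7 // V))
    for lo_i in range(0, n_perm, chunk):
        t_null = _sign_flip_t(d, signs[lo_i:lo_i + chunk])
        ge[:] += (t_null >= t_obs).sum(axis=0)
        le[:] += (t_null <= t_obs).sum(axis=0)
        null_hi[lo_i:lo_i + chunk] = _max_cluster_extents((t_null >= t_quant) & mask,
                                                          sv.grid_shape, structure)
        null_lo[lo_i:lo_i + chunk] = _max_cluster_extents((-t_null >= t_quant) & mask,
                                                          sv.grid_shape, structure)
    p_ide = (1.0 + ge) / (n_perm + 1.0)   # H1: iDE > SV
    p_sv = (1.0 + le) / (n_perm + 1.0)    # H1: SV > iDE
    abs_ide = np.abs(ide.z) > np.abs(sv.z)

    out = {}
    for direction, p_unc, main, absmask, null in (
            ("ide_gt_sv", p_ide, ide, abs_ide, null_hi),
            ("sv_gt_ide", p_sv, sv, ~abs_ide, null_lo)):
        z_perm = stats.norm.isf(np.clip(p_unc, 1e-300, 1.0))
        z_conj = np.minimum(z_perm, main.z)
        sig = (p_unc <= alpha) & (main.z >= z_thresh) & absmask & mask
        table, lab = _cluster_table(z_conj, sig, sv.grid_shape, sv.affine,
                                    structure, null, n_perm, direction)
        cluster = ClusterResult(table=table, label_map=lab, sign=direction,
                                z_thresh=z_thresh, alpha=0.05, n_perm=n_perm)
        out[direction] = ContrastResult(cluster=cluster, z_perm=z_perm,
                                        p_uncorrected=p_unc, direction=direction)
    return out


def task_active_mask(group_intercept: GroupMap, z_thresh: float = 2.3) -> np.ndarray:
    """Binary mask of voxels responding to trial events regardless of modulation."""
    return (np.abs(group_intercept.z) >= z_thresh) & group_intercept.mask
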