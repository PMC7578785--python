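"""Headline joint-coding statistics for SV and iDE maps.

Where both variables have a corrected effect, voxels are classified by the
2x2 crossing of effect signs; a chi-square test (df = 1, no continuity
correction) asks whether same-sign pairings (+/+ and -/-) are
over-represented relative to the independence expectation formed from the
marginals.  Complementary continuous views: Pearson correlations between
the two group-level maps over a mask or ROI, a gradient map formed by
summing the two maps after independent z-scoring (near zero where effects
cancel, large where they agree), and a per-participant ratio of negative
to positive SV voxels that can be compared with behavioural loss aversion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import VolumeMap

__all__ = [
    "ContingencyResult",
    "MapCorrelation",
    "sign_contingency",
    "roi_overlap",
    "map_correlation",
    "gradient_map",
    "loss_aversion_voxel_ratio",
    "binarise_roi",
]


def _flat(x) -> np.ndarray:
    if isinstance(x, VolumeMap):
        return x.data.reshape(-1)
    return np.asarray(x).reshape(-1)


def _flat_bool(x) -> np.ndarray:
    return _flat(x).astype(bool)


@dataclass
class ContingencyResult:
    """2x2 sign contingency over jointly significant voxels.

    Rows index the SV sign (+, -), columns the iDE sign.  Percentages are of
    the classified total; expected percentages come from the product of the
    observed marginals (the independence model of the chi-square test).

    ``p`` is the asymptotic chi-square tail probability, which treats voxels
    as independent samples; for spatially smooth maps ``p_perm`` (a
    torus-translation permutation p that preserves each map's spatial
    autocorrelation) is the calibrated significance and should be preferred
    when present.
    """

    observed: np.ndarray
    observed_pct: np.ndarray
    expected: np.ndarray
    expected_pct: np.ndarray
    chi2: float
    df: int
    p: float
    n_voxels: int
    p_perm: float | None = None
    n_perm: int = 0

    @property
    def diagonal_pct(self) -> float:
        """Share of classified voxels with matching signs (+/+ or -/-)."""
        return float(self.observed_pct[0, 0] + self.observed_pct[1, 1])

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.tolist(),
            "observed_pct": np.round(self.observed_pct, 1).tolist(),
            "expected_pct": np.round(self.expected_pct, 1).tolist(),
            "chi2": self.chi2, "df": self.df, "p": self.p,
            "p_perm": self.p_perm, "n_perm": self.n_perm,
            "n_voxels": self.n_voxels, "diagonal_pct": round(self.diagonal_pct, 1),
        }


def contingency_from_counts(observed: np.ndarray) -> ContingencyResult:
    """Chi-square independence test for a 2x2 count table (df=1, uncorrected)."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("observed must be a non-negative 2x2 table")
    total = obs.sum()
    if total == 0:
        raise ValueError("no overlapping effects: the contingency table is empty")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / total
    if np.any(row == 0) or np.any(col == 0):
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        chi2, p = float(chi2), float(p)
    return ContingencyResult(
        observed=obs.astype(int), observed_pct=100.0 * obs / total,
        expected=expected, expected_pct=100.0 * expected / total,
        chi2=chi2, df=1, p=p, n_voxels=int(total))


def _contingency_chi2(sa: np.ndarray, sb: np.ndarray, joint: np.ndarray) -> float:
    """Raw chi-square of the 2x2 sign table; 0 when degenerate."""
    obs = np.array([
        [((sa > 0) & (sb > 0) & joint).sum(), ((sa > 0) & (sb < 0) & joint).sum()],
        [((sa < 0) & (sb > 0) & joint).sum(), ((sa < 0) & (sb < 0) & joint).sum()],
    ], dtype=float)
    total = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0
    exp = row @ col / total
    return float(((obs - exp) ** 2 / exp).sum())


def sign_contingency(sv_pos, sv_neg, ide_pos, ide_neg, mask=None,
                     n_perm: int = 499,
                     rng: np.random.Generator | None = None) -> ContingencyResult:
    """Classify voxels significant for BOTH variables by their sign pair.

    Inputs are binary maps of positively / negatively significant voxels per
    variable (within each variable the two sets must be disjoint), plus an
    optional restriction mask (typically the task-active mask).

    When the inputs carry a 3-D grid (VolumeMap or 3-D arrays) and
    ``n_perm > 0``, a torus-translation permutation p is computed by randomly
    circular-shifting one variable's sign structure relative to the other:
    this preserves the spatial autocorrelation of each map, so the test stays
    calibrated on smooth maps where the asymptotic chi-square (independent
    voxels) does not.
    """
    grid_shape = None
    for x in (sv_pos, sv_neg, ide_pos, ide_neg):
        arr = x.data if isinstance(x, VolumeMap) else np.asarray(x)
        if arr.ndim == 3:
            grid_shape = arr.shape
            break
    sp, sn = _flat_bool(sv_pos), _flat_bool(sv_neg)
    ip, ineg = _flat_bool(ide_pos), _flat_bool(ide_neg)
    if (sp & sn).any() or (ip & ineg).any():
        raise ValueError("positive and negative significance sets overlap")
    keep = np.ones_like(sp) if mask is None else _flat_bool(mask)
    joint = keep & (sp | sn) & (ip | ineg)
    obs = np.array([
        [(joint & sp & ip).sum(), (joint & sp & ineg).sum()],
        [(joint & sn & ip).sum(), (joint & sn & ineg).sum()],
    ], dtype=float)
    result = contingency_from_counts(obs)

    if grid_shape is not None and n_perm > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        sa = (sp.astype(int) - sn.astype(int)).reshape(grid_shape)
        sb = ((ip.astype(int) - ineg.astype(int)) * keep).reshape(grid_shape)
        ma = ((sp | sn) & keep).reshape(grid_shape)
        mb = ((ip | ineg) & keep).reshape(grid_shape)
        chi2_obs = _contingency_chi2(sa, sb, ma & mb)
        count = 0
        for _ in range(n_perm):
            shift = tuple(int(rng.integers(0, s)) for s in grid_shape)
            sbs = np.roll(sb, shift, axis=(0, 1, 2))
            mbs = np.roll(mb, shift, axis=(0, 1, 2))
            if _contingency_chi2(sa, sbs, ma & mbs) >= chi2_obs:
                count += 1
        result.p_perm = (1 + count) / (n_perm + 1)
        result.n_perm = n_perm
    return result


def roi_overlap(sv_pos, sv_neg, ide_pos, ide_neg, roi) -> float | None:
    """Percentage of jointly significant ROI voxels whose signs match.

    Returns None (undefined) when no ROI voxel is significant for both
    variables.
    """
    roi_mask = _flat_bool(roi)
    if not roi_mask.any():
        return None
    sp, sn = _flat_bool(sv_pos), _flat_bool(sv_neg)
    ip, ineg = _flat_bool(ide_pos), _flat_bool(ide_neg)
    joint = roi_mask & (sp | sn) & (ip | ineg)
    n = int(joint.sum())
    if n == 0:
        return None
    match = int((joint & ((sp & ip) | (sn & ineg))).sum())
    return 100.0 * match / n


@dataclass
class MapCorrelation:
    """Pearson correlation between two maps across masked voxels."""

    region: str
    n_voxels: int
    r: float
    p: float
    degenerate: bool = False


def map_correlation(map_a, map_b, mask, region: str = "whole_mask") -> MapCorrelation:
    """Pearson r between two group-level maps over the masked voxels."""
    a, b, m = _flat(map_a), _flat(map_b), _flat_bool(mask)
    n = int(m.sum())
    if n < 3:
        raise ValueError("need at least 3 masked voxels for a correlation")
    av, bv = a[m], b[m]
    if av.std() == 0 or bv.std() == 0:
        return MapCorrelation(region=region, n_voxels=n, r=float("nan"),
                              p=float("nan"), degenerate=True)
    res = stats.pearsonr(av, bv)
    return MapCorrelation(region=region, n_voxels=n,
                          r=float(res.statistic), p=float(res.pvalue))


def gradient_map(map_a, map_b, mask) -> np.ndarray:
    """Sum of the two maps after independent z-scoring across masked voxels.

    Values near zero mark cancellation, large magnitudes joint effects of a
    common sign.  Voxels outside the mask are NaN.
    """
    a, b, m = _flat(map_a), _flat(map_b), _flat_bool(mask)
    out = np.full(a.shape, np.nan)
    for v in (a, b):
        if v[m].std() == 0:
            raise ValueError("zero-variance map within mask; z-scoring undefined")
    za = (a[m] - a[m].mean()) / a[m].std()
    zb = (b[m] - b[m].mean()) / b[m].std()
    out[m] = za + zb
    shape = map_a.data.shape if isinstance(map_a, VolumeMap) else np.asarray(map_a).shape
    return out.reshape(shape)


def loss_aversion_voxel_ratio(sv_z_by_participant: dict, fits: dict,
                              mask=None, z_thresh: float = 2.3) -> tuple[pd.DataFrame, float]:
    """Ratio of negative to positive SV voxels per participant vs loss aversion.

    Counts voxels with Z <= -z_thresh and Z >= z_thresh in each participant's
    subject-level SV map; participants with no positive voxels have an
    undefined ratio and are excluded from the rank correlation with the
    behavioural |beta_losses/beta_gains|.
    """
    rows = []
    for pid, zmap in sv_z_by_participant.items():
        z = _flat(zmap)
        keep = np.ones_like(z, bool) if mask is None else _flat_bool(mask)
        n_neg = int((z[keep] <= -z_thresh).sum())
        n_pos = int((z[keep] >= z_thresh).sum())
        ratio = n_neg / n_pos if n_pos > 0 else np.nan
        rows.append({"participant": pid, "n_negative": n_neg, "n_positive": n_pos,
                     "ratio": ratio,
                     "loss_aversion": abs(fits[pid].loss_aversion)})
    df = pd.DataFrame(rows).set_index("participant")
    ok = df.dropna(subset=["ratio"])
    if len(ok) >= 3 and ok["ratio"].nunique() > 1 and ok["loss_aversion"].nunique() > 1:
        rho = float(stats.spearmanr(ok["ratio"], ok["loss_aversion"]).statistic)
    else:
        rho = float("nan")
    return df, rho


def binarise_roi(roi: VolumeMap, target: VolumeMap, threshold: float = 0.5) -> np.ndarray:
    """Resample a (possibly probabilistic) ROI to the analysis grid, binarised.

    Nearest-neighbour resampling through the two affines, then thresholding
    at ``threshold`` (default 50%).
    """
    inv = np.linalg.inv(roi.affine)
    idx = np.indices(target.grid_shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    src = (inv @ target.affine @ homog)[:3]
    src = np.round(src).astype(int)
    inside = np.all((src >= 0) & (src < np.array(roi.grid_shape)[:, None]), axis=0)
    out = np.zeros(idx.shape[1])
    out[inside] = roi.data[tuple(src[:, inside])]
    return (out >= threshold).reshape(target.grid_shape)
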