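"""Voxelwise 2x2 mixed ANOVA with Monte-Carlo cluster-extent correction.

The design has one between-subject factor (group, two levels) and one
within-subject factor (session: baseline vs follow-up), subject nested in
group.  For this balanced 2x2 design the interaction F is exactly the squared
two-sample t statistic on per-subject difference scores (follow-up minus
baseline), the group F is the squared two-sample t on per-subject means, and
the session F tests the pooled mean difference against the same within-subject
error — closed forms that match a general linear model with subject dummy
coding, and SPM's flexible factorial, for this design.

Family-wise error over the voxelwise map is controlled by a cluster-extent
threshold calibrated by Monte-Carlo simulation (AlphaSim-style): Gaussian
noise fields matched to the residual smoothness are thresholded at the voxel
p, and the (1 - alpha) quantile of the max-cluster-size null distribution
gives the minimum surviving extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .connectivity import ZConnectivityMap
from .geometry import voxel_sizes_mm, voxel_volume_mm3

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-sd Gaussian


@dataclass
class AnovaResult:
    """Voxelwise (or scalar) F statistics and p-values of the 2x2 mixed model."""

    F_interaction: np.ndarray
    F_group: np.ndarray
    F_time: np.ndarray
    p_interaction: np.ndarray
    p_group: np.ndarray
    p_time: np.ndarray
    df: tuple[int, int]


@dataclass
class InteractionResult:
    F_volume: np.ndarray
    p_volume: np.ndarray
    est_fwhm_mm: np.ndarray
    extent_threshold_voxels: int
    corrected_mask: np.ndarray
    cluster_table: "object"  # pandas.DataFrame: label, size_voxels, size_mm3, peak, peak_F
    df: tuple[int, int]
    voxel_F_threshold: float


def mixed_anova_2x2(
    baseline: np.ndarray, followup: np.ndarray, groups: np.ndarray
) -> AnovaResult:
    """Closed-form 2x2 mixed ANOVA via the difference-score identity.

    Parameters
    ----------
    baseline, followup : arrays of shape (n_subjects,) or (n_subjects, ...) —
        one value per subject (per voxel) and session.
    groups : (n_subjects,) labels with exactly two levels; at least two
        subjects per level.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape:
        raise ValueError("baseline and followup must have identical shapes")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two group levels are required")
    g1 = groups == levels[0]
    g2 = ~g1
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 2:
        raise ValueError("need at least two subjects per group")
    n = n1 + n2
    df = (1, n - 2)

    diffs = followup - baseline  # within-subject change
    means = 0.5 * (followup + baseline)  # subject means

    def _two_sample_f(values: np.ndarray) -> np.ndarray:
        m1 = values[g1].mean(axis=0)
        m2 = values[g2].mean(axis=0)
        ss = ((values[g1] - m1) ** 2).sum(axis=0) + ((values[g2] - m2) ** 2).sum(axis=0)
        pooled = ss / (n - 2)
        denom = pooled * (1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, (m1 - m2) ** 2 / denom, 0.0)
        return f

    f_inter = _two_sample_f(diffs)
    f_group = _two_sample_f(means)

    # Session effect: unweighted mean of group difference-means against the
    # pooled within-subject error (Type III for the balanced design).
    d1 = diffs[g1].mean(axis=0)
    d2 = diffs[g2].mean(axis=0)
    ss_within = ((diffs[g1] - d1) ** 2).sum(axis=0) + ((diffs[g2] - d2) ** 2).sum(axis=0)
    pooled = ss_within / (n - 2)
    denom = pooled * 0.25 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_time = np.where(denom > 0, (0.5 * (d1 + d2)) ** 2 / denom, 0.0)

    def _p(f: np.ndarray) -> np.ndarray:
        return stats.f.sf(f, *df)

    return AnovaResult(
        F_interaction=f_inter,
        F_group=f_group,
        F_time=f_time,
        p_interaction=_p(f_inter),
        p_group=_p(f_group),
        p_time=_p(f_time),
        df=df,
    )


def estimate_smoothness(
    residual_volumes: np.ndarray, mask: np.ndarray, affine: np.ndarray
) -> np.ndarray:
    """Per-axis smoothness (FWHM, mm) from the variance of neighbour differences.

    For a Gaussian-autocorrelated field, var(x_{i+1} - x_i) = 2 sigma^2 (1 - rho)
    with rho = exp(-delta^2 / (4 s^2)), so the smoothing-kernel sd s, and hence
    FWHM, follows from the ratio of difference variance to field variance.
    FWHM is floored at the voxel size (white noise).
    """
    vols = np.asarray(residual_volumes, dtype=float)
    if vols.ndim == 3:
        vols = vols[None]
    if vols.shape[0] < 2:
        raise ValueError("need at least two residual volumes")
    mask = np.asarray(mask, dtype=bool)
    vsize = voxel_sizes_mm(affine)

    masked = vols[:, mask]
    var = masked.var()
    if var <= 0:
        raise ValueError("residuals are constant; smoothness undefined")

    fwhm = np.empty(3)
    for ax in range(3):
        pair = mask & np.roll(mask, -1, axis=ax)
        # exclude wrap-around pairs
        sl = [slice(None)] * 3
        sl[ax] = slice(-1, None)
        pair[tuple(sl)] = False
        if not pair.any():
            fwhm[ax] = vsize[ax]
            continue
        d = np.roll(vols, -1, axis=ax + 1) - vols
        vdx = d[:, pair].var()
        ratio = vdx / (2.0 * var)
        if ratio >= 1.0 or ratio <= 0.0:
            fwhm[ax] = vsize[ax]
            continue
        s2 = -(vsize[ax] ** 2) / (4.0 * np.log(1.0 - ratio))
        fwhm[ax] = max(GAUSS_FWHM * np.sqrt(s2), vsize[ax])
    return fwhm


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[int(connectivity)]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def simulate_null_field(
    mask: np.ndarray, fwhm_mm: np.ndarray, affine: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One stationary Gaussian field at the requested smoothness, masked.

    Smoothing uses periodic boundaries so the field is stationary on the grid,
    then it is standardized to unit variance within the mask.
    """
    vsize = voxel_sizes_mm(affine)
    sigma_vox = np.maximum(np.asarray(fwhm_mm, dtype=float) / vsize, 1.0) / GAUSS_FWHM
    # FWHM equal to the voxel size means independent voxels: no smoothing.
    sigma_vox[np.asarray(fwhm_mm) <= vsize * (1 + 1e-9)] = 0.0
    field = rng.standard_normal(mask.shape)
    if sigma_vox.any():
        field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="wrap")
    vals = field[mask]
    return (field - vals.mean()) / vals.std()


def monte_carlo_extent_threshold(
    mask: np.ndarray,
    est_fwhm_mm: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.05,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 18,
    rng_seed: int = 0,
) -> int:
    """Minimum cluster extent (voxels) controlling family-wise error at alpha.

    Simulates smooth Gaussian noise on the masked grid, thresholds two-sided
    at ``voxel_p``, and records the maximum cluster size per iteration.  The
    returned threshold is the smallest integer k >= 1 whose empirical
    exceedance probability P(max cluster >= k) is at most alpha (the AlphaSim
    convention; one more than the ceiling of the (1 - alpha) quantile when
    that quantile's own exceedance overshoots alpha).  A cluster is declared
    significant when its size is >= the returned threshold, so the realized
    family-wise rate is the largest attainable value not exceeding alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_iter < 500:
        raise ValueError("need at least 500 Monte-Carlo iterations")
    rng = np.random.default_rng(rng_seed)
    zc = stats.norm.isf(voxel_p / 2.0)
    struct = _connectivity_structure(connectivity)
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        field = simulate_null_field(mask, est_fwhm_mm, affine, rng)
        supra = (np.abs(field) > zc) & mask
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=struct)
            max_sizes[i] = np.bincount(labels.ravel())[1:].max()
    counts = np.bincount(max_sizes)
    tail = counts[::-1].cumsum()[::-1]  # tail[k] = #{max >= k}
    ok = np.nonzero(tail <= alpha * n_iter)[0]
    k = int(ok[0]) if ok.size else int(max_sizes.max()) + 1
    return max(k, 1)


def label_clusters(
    stat_volume: np.ndarray,
    voxel_threshold: float,
    affine: np.ndarray,
    connectivity: int = 18,
    mask: np.ndarray | None = None,
):
    """Connected components of supra-threshold voxels as a cluster table.

    Returns ``(labels_volume, table)`` where the table has one row per cluster
    with its size in voxels and mm^3, peak voxel index, and peak statistic.
    """
    import pandas as pd

    stat = np.asarray(stat_volume, dtype=float)
    supra = stat >= voxel_threshold
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    struct = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(supra, structure=struct)
    vol = voxel_volume_mm3(affine)
    rows = []
    for lab in range(1, n_lab + 1):
        where = labels == lab
        size = int(where.sum())
        flat_peak = np.flatnonzero(where.ravel())[np.argmax(stat[where])]
        peak = tuple(int(x) for x in np.unravel_index(flat_peak, stat.shape))
        rows.append(
            {
                "label": lab,
                "size_voxels": size,
                "size_mm3": size * vol,
                "peak_voxel": peak,
                "peak_stat": float(stat[where].max()),
            }
        )
    table = pd.DataFrame(rows, columns=["label", "size_voxels", "size_mm3", "peak_voxel", "peak_stat"])
    return labels, table


def extract_mask_mean(zmap: ZConnectivityMap | np.ndarray, region_mask: np.ndarray) -> float:
    """Arithmetic mean of a z-volume over a region mask (same grid)."""
    vol = zmap.z_volume if isinstance(zmap, ZConnectivityMap) else np.asarray(zmap, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if vol.shape != region_mask.shape:
        raise ValueError("volume and region mask are on different grids")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    return float(vol[region_mask].mean())


def _stack_zmaps(zmaps: list[ZConnectivityMap]):
    """Pair baseline/follow-up maps per subject; exclude incomplete subjects."""
    by_subject: dict[str, dict[str, ZConnectivityMap]] = {}
    for zm in zmaps:
        by_subject.setdefault(zm.subject, {})[zm.timepoint] = zm
    subjects, base, follow, groups = [], [], [], []
    for subj in sorted(by_subject):
        sess = by_subject[subj]
        if "baseline" not in sess or "followup" not in sess:
            warnings.warn(f"subject {subj} is missing a session; excluded", stacklevel=3)
            continue
        subjects.append(subj)
        base.append(sess["baseline"].z_volume)
        follow.append(sess["followup"].z_volume)
        groups.append(sess["baseline"].group)
    if not subjects:
        raise ValueError("no subject has both sessions")
    return subjects, np.asarray(base), np.asarray(follow), np.asarray(groups)


def interaction_analysis(
    zmaps: list[ZConnectivityMap],
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.05,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 18,
    rng_seed: int = 0,
) -> InteractionResult:
    """Full interaction stage: voxelwise mixed ANOVA, smoothness estimation,
    Monte-Carlo extent threshold, and the corrected interaction mask.
    """
    mask = np.asarray(mask, dtype=bool)
    subjects, base, follow, groups = _stack_zmaps(zmaps)
    n_subj = len(subjects)
    flat_mask = mask.reshape(-1)
    res = mixed_anova_2x2(
        base.reshape(n_subj, -1)[:, flat_mask],
        follow.reshape(n_subj, -1)[:, flat_mask],
        groups,
    )
    shape = mask.shape
    f_vol = np.zeros(shape)
    p_vol = np.ones(shape)
    f_vol[mask] = res.F_interaction
    p_vol[mask] = res.p_interaction

    # Residual change maps (difference minus its group mean) carry the noise
    # smoothness the Monte-Carlo null must match.
    diffs = follow - base
    resid = diffs.copy()
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] -= diffs[sel].mean(axis=0)
    fwhm = estimate_smoothness(resid, mask, affine)

    extent = monte_carlo_extent_threshold(
        mask, fwhm, affine, voxel_p=voxel_p, alpha=alpha,
        n_iter=n_iter, connectivity=connectivity, rng_seed=rng_seed,
    )

    f_thresh = float(stats.f.isf(voxel_p, *res.df))
    labels, table = label_clusters(f_vol, f_thresh, affine, connectivity=connectivity, mask=mask)
    corrected = np.zeros(shape, dtype=bool)
    keep = table[table["size_voxels"] >= extent]
    for lab in keep["label"]:
        corrected |= labels == lab
    return InteractionResult(
        F_volume=f_vol,
        p_volume=p_vol,
        est_fwhm_mm=fwhm,
        extent_threshold_voxels=extent,
        corrected_mask=corrected,
        cluster_table=keep.reset_index(drop=True),
        df=res.df,
        voxel_F_threshold=f_thresh,
    )
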