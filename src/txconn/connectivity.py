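"""Seed-based functional connectivity: sphere seeds, nuisance regression, z-maps.

The seed region is a sphere in millimetre space (default: left angular gyrus,
MNI -45, -67, 38, radius 6 mm).  For each scan, voxel time series are
residualized against nuisance confounds (six motion parameters plus mean white
matter and CSF series in the intended use), the mean residual series over the
seed sphere is correlated with every voxel's residual series, and the Pearson
r is mapped through the Fisher transform z = atanh(r).  The collection of
these z-volumes across subjects and sessions feeds the group-by-time
interaction stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import grid_coordinates_mm

#: r is clipped to +/- (1 - R_CLIP) before atanh so z stays finite.
R_CLIP = 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed region in millimetre (MNI) space."""

    center_mni: tuple[float, float, float] = (-45.0, -67.0, 38.0)
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("seed radius must be positive")


@dataclass
class ZConnectivityMap:
    """Per subject/session voxelwise Fisher-z seed-connectivity volume."""

    subject: str
    timepoint: str  # "baseline" | "followup"
    group: str
    z_volume: np.ndarray  # 3D, finite everywhere
    affine: np.ndarray
    #: voxels whose series had zero variance; z was set to 0 there
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(self.z_volume.shape, dtype=bool)


def sphere_mask(seed: SeedSpec, shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """Boolean volume of voxels whose centres lie within the seed sphere.

    Raises ``ValueError`` if no voxel centre falls inside the sphere (seed
    outside the grid, or radius smaller than the voxel spacing allows).
    """
    coords = grid_coordinates_mm(shape, affine)
    d2 = ((coords - np.asarray(seed.center_mni)) ** 2).sum(axis=-1)
    mask = d2 <= float(seed.radius_mm) ** 2
    if not mask.any():
        raise ValueError(
            f"seed sphere at {seed.center_mni} (radius {seed.radius_mm} mm) "
            "contains no voxel centre on this grid"
        )
    return mask


def nuisance_regress(series: np.ndarray, confounds: np.ndarray | None = None) -> np.ndarray:
    """Residualize time series against confounds (an intercept is always added).

    Parameters
    ----------
    series : (T, V) array of voxel (or ROI) time series.
    confounds : (T, k) array or None.  Rank-deficient confound matrices are
        reduced by dropping collinear columns, with a warning.

    Returns residuals orthogonal to every retained confound column.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    t = series.shape[0]
    if np.isnan(series).any():
        raise ValueError("series contains missing values")
    design = np.ones((t, 1))
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != t:
            raise ValueError("confounds and series disagree on the time dimension")
        if np.isnan(confounds).any():
            raise ValueError("confounds contain missing values")
        design = np.column_stack([design, confounds])
    # Drop collinear columns via pivoted QR on the column-scaled design.
    scale = np.linalg.norm(design, axis=0)
    scale[scale == 0] = 1.0
    from scipy.linalg import qr

    _, r, piv = qr(design / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > max(design.shape) * np.finfo(float).eps * diag[0]).sum())
    if keep_rank < design.shape[1]:
        dropped = sorted(piv[keep_rank:])
        warnings.warn(
            f"confound matrix is rank deficient; dropping column(s) {dropped} "
            "(0 is the intercept)",
            stacklevel=2,
        )
        design = design[:, sorted(piv[:keep_rank])]
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher transform z = atanh(r) with r clipped to +/-(1 - 1e-7)."""
    r = np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP)
    return np.arctanh(r)


def seed_fc_zmap(
    image,  # CohortImage (kept untyped to avoid a circular import)
    seed: SeedSpec,
    confounds: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> ZConnectivityMap:
    """Voxelwise Fisher-z map of correlation with the mean seed-sphere series.

    Both the seed series and the voxel series are nuisance-regressed before
    the Pearson correlation.  Voxels with zero residual variance (e.g.
    out-of-brain padding) get z = 0 and are flagged rather than erroring, so
    every subject keeps a common grid.
    """
    data = np.asarray(image.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) BOLD array")
    shape, t = data.shape[:3], data.shape[3]
    if confounds is None and image.confounds is not None:
        confounds = np.asarray(image.confounds, dtype=float)
    n_conf = 0 if confounds is None else np.atleast_2d(confounds).shape[1]
    if t - n_conf - 1 < 20:
        raise ValueError("need at least 20 time points after confound regression")

    series = data.reshape(-1, t).T  # (T, V)
    resid = nuisance_regress(series, confounds)

    seed_vox = sphere_mask(seed, shape, image.affine).reshape(-1)
    seed_series = resid[:, seed_vox].mean(axis=1)
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed series has zero variance")

    v = resid - resid.mean(axis=0)
    v_norm = np.linalg.norm(v, axis=0)
    flagged = v_norm == 0
    v_norm_safe = np.where(flagged, 1.0, v_norm)
    r = (s @ v) / (s_norm * v_norm_safe)
    r[flagged] = 0.0
    z = fisher_z(r)
    z[flagged] = 0.0

    z_vol = np.asarray(z).reshape(shape)
    flag_vol = flagged.reshape(shape)
    if mask is not None:
        z_vol = np.where(mask, z_vol, 0.0)
    return ZConnectivityMap(
        subject=image.subject,
        timepoint=image.timepoint,
        group=image.group,
        z_volume=z_vol,
        affine=np.asarray(image.affine),
        flagged=flag_vol,
    )
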