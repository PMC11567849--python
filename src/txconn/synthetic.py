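"""Synthetic cohort, expression, and PPI generators with known ground truth.

These generators emulate the statistical structure the analysis chain
assumes, so every downstream stage is testable without any data download:

* a 2-group x 2-session BOLD cohort in which each voxel's series is a shared
  seed time course times a coupling weight plus spatially smoothed Gaussian
  noise — the seed-coupling weight inside planted clusters changes from
  baseline to follow-up by +d*sigma in one group and -d*sigma in the other
  (a pure group-by-time interaction whose functional-connectivity ground
  truth is analytic);
* a phenotype table whose five sleep scales share a latent sleep-quality
  factor separating the groups (so the first principal component recovers
  it), and whose four episodic-memory tests improve in proportion to each
  subject's planted connectivity change;
* an AHBA-style expression matrix (genes x samples at MNI coordinates, six
  donors) with spatially autocorrelated noise genes and a planted subset
  correlated with a supplied brain map at a target strength;
* an Erdos-Renyi STRING-dialect PPI background with an optional denser
  planted module.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .connectivity import SeedSpec, fisher_z, sphere_mask
from .geometry import default_affine, ellipsoid_mask, grid_coordinates_mm, voxel_to_mm
from .interaction import GAUSS_FWHM
from .transcriptomics import ExpressionDataset

CONFOUND_NAMES = [
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "wm_mean", "csf_mean",
]
SLEEP_SCALES = ["ISI", "AIS", "PSQI", "SRSS", "ESS"]
MEMORY_TESTS = ["AVLT_IR", "AVLT_SR", "AVLT_LR", "VR_DR"]

# population means / SDs of the synthetic scale totals (badness-scored)
_SCALE_LOC = {"ISI": (12, 5), "AIS": (8, 4), "PSQI": (9, 4), "SRSS": (28, 8), "ESS": (9, 4)}
_MEMORY_LOC = {"AVLT_IR": (16, 5), "AVLT_SR": (5, 3), "AVLT_LR": (4, 3), "VR_DR": (7, 4)}


@dataclass
class CohortImage:
    """One subject/session 4D BOLD array with its grid and confound series."""

    subject: str
    timepoint: str  # "baseline" | "followup"
    group: str
    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    confounds: np.ndarray  # (t, 8): six motion + WM + CSF means


@dataclass(frozen=True)
class PlantedCluster:
    """Spherical region whose seed coupling carries the interaction effect."""

    center_voxel: tuple[int, int, int]
    radius_mm: float = 7.5
    effect_size: float = 1.2  # d, in units of the noise SD
    sign: int = 1  # +1: coupling rises in group 1 (CI+LSQ)


@dataclass(frozen=True)
class SyntheticDesign:
    """Study-scale design of the synthetic rTMS cohort (2 groups x 2 sessions)."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_per_group: int = 23
    n_timepoints_series: int = 120
    seed_center_mni: tuple[float, float, float] = (-45.0, -67.0, 38.0)
    seed_radius_mm: float = 6.0
    planted_clusters: tuple[PlantedCluster, ...] = (
        PlantedCluster(center_voxel=(11, 11, 8), radius_mm=6.0),
    )
    noise_fwhm_mm: float = 6.0
    rng_seed: int = 0
    # generative nuisance parameters
    baseline_coupling: float = 0.2  # seed-coupling weight everywhere in the mask
    seed_region_coupling: float = 1.2  # coupling inside the seed sphere itself
    noise_sigma: float = 1.0
    coupling_jitter: float = 0.25  # between-subject SD of the effect, x d
    memory_coupling_r: float = 0.5  # corr(memory change, planted connectivity change)
    confound_leak: float = 0.1  # per-voxel confound contamination scale
    temporal_smooth: float = 0.75  # volumes; emulates band-limited series

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for cl in self.planted_clusters:
            if not np.isfinite(cl.effect_size):
                raise ValueError(f"non-finite effect size for cluster {cl.center_voxel}")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.grid_shape, self.voxel_size_mm, self.seed_center_mni)

    @property
    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape, margin=0)

    def cluster_mask(self, cluster: PlantedCluster) -> np.ndarray:
        centre_mm = voxel_to_mm(self.affine, np.asarray(cluster.center_voxel, dtype=float))
        coords = grid_coordinates_mm(self.grid_shape, self.affine)
        return ((coords - centre_mm) ** 2).sum(axis=-1) <= cluster.radius_mm**2

    def validate_clusters(self) -> None:
        mask = self.brain_mask
        seed_region = sphere_mask(
            SeedSpec(self.seed_center_mni, self.seed_radius_mm), self.grid_shape, self.affine
        )
        for cl in self.planted_clusters:
            cmask = self.cluster_mask(cl)
            if not cmask.any():
                raise ValueError(f"planted cluster at {cl.center_voxel} contains no voxel")
            if (cmask & ~mask).any():
                raise ValueError(
                    f"planted cluster at {cl.center_voxel} (radius {cl.radius_mm} mm) "
                    "extends outside the brain mask"
                )
            if (cmask & seed_region).any():
                raise ValueError(
                    f"planted cluster at {cl.center_voxel} overlaps the seed sphere; "
                    "the interaction ground truth requires them to be disjoint"
                )


@dataclass(frozen=True)
class ExpressionDesign:
    """Reduced-scale emulation of a normalized AHBA expression dataset."""

    n_genes: int = 2000
    n_samples: int = 300
    n_donors: int = 6
    n_planted_genes: int = 50
    planted_r: float = 0.8
    spatial_corr_length_mm: float = 5.0
    donor_offset_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_planted_genes < self.n_genes:
            raise ValueError("need 0 < n_planted_genes < n_genes")
        if not abs(self.planted_r) < 1:
            raise ValueError("|planted_r| must be < 1")


def _smooth_standardized(arr: np.ndarray, sigma) -> np.ndarray:
    out = ndimage.gaussian_filter(arr, sigma=sigma, mode="wrap")
    return (out - out.mean()) / out.std()


def analytic_coupling_z(w: np.ndarray | float, sigma: float = 1.0):
    """Expected Fisher z of a voxel with coupling weight w and noise SD sigma.

    With a unit-variance seed series, r = w / sqrt(w^2 + sigma^2).
    """
    w = np.asarray(w, dtype=float)
    return fisher_z(w / np.sqrt(w**2 + sigma**2))


def planted_change_map(design: SyntheticDesign) -> np.ndarray:
    """Expected cohort-mean (follow-up minus baseline) z volume.

    Group 1's coupling rises by d*sigma and group 2's falls by d*sigma, so the
    cohort mean change at a planted voxel is the average of the two analytic
    z-changes (nonzero only through the nonlinearity of atanh).
    """
    sig = design.noise_sigma
    out = np.zeros(design.grid_shape)
    z0 = analytic_coupling_z(design.baseline_coupling, sig)
    for cl in design.planted_clusters:
        d = cl.sign * cl.effect_size * sig
        up = analytic_coupling_z(design.baseline_coupling + d, sig) - z0
        dn = analytic_coupling_z(design.baseline_coupling - d, sig) - z0
        out[design.cluster_mask(cl)] = 0.5 * (up + dn)
    return out


def _make_confounds(rng: np.random.Generator, n_t: int) -> np.ndarray:
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_t, 6)), axis=0)
    tissue = rng.normal(0.0, 1.0, size=(n_t, 2))
    tissue = ndimage.gaussian_filter1d(tissue, sigma=1.5, axis=0, mode="nearest")
    return np.column_stack([motion, tissue])


def generate_cohort(design: SyntheticDesign) -> tuple[list[CohortImage], pd.DataFrame]:
    """Simulate the full 2 x 2 x n_per_group cohort and its phenotype table.

    Returns one :class:`CohortImage` per subject and session (baseline first)
    and a phenotype table with one row per subject and session carrying group,
    demographics, the five sleep-scale totals and the four memory tests.
    """
    design.validate_clusters()
    rng = np.random.default_rng(design.rng_seed)
    shape = design.grid_shape
    affine = design.affine
    mask = design.brain_mask
    n_t = design.n_timepoints_series
    sigma = design.noise_sigma
    # FWHM at or below the voxel size means spatially independent noise
    sigma_vox = (
        design.noise_fwhm_mm / design.voxel_size_mm / GAUSS_FWHM
        if design.noise_fwhm_mm > design.voxel_size_mm
        else 0.0
    )

    seed_region = sphere_mask(
        SeedSpec(design.seed_center_mni, design.seed_radius_mm), shape, affine
    )
    if (seed_region & ~mask).any():
        raise ValueError("seed sphere extends outside the brain mask")
    cluster_masks = [design.cluster_mask(cl) for cl in design.planted_clusters]

    groups = ["CI+LSQ", "CI+HSQ"]
    n = design.n_per_group
    subjects = [f"sub-{i + 1:02d}" for i in range(2 * n)]
    subj_group = {s: groups[i // n] for i, s in enumerate(subjects)}

    # per-subject effect heterogeneity (drives the memory correlation)
    deltas = {
        (s, ci): design.planted_clusters[ci].effect_size
        * (1.0 + design.coupling_jitter * rng.standard_normal())
        for s in subjects
        for ci in range(len(design.planted_clusters))
    }

    images: list[CohortImage] = []
    planted_change = np.zeros(len(subjects))  # analytic per-subject mean z change
    z0 = analytic_coupling_z(design.baseline_coupling, sigma)
    for si, subj in enumerate(subjects):
        gsign = 1.0 if subj_group[subj] == "CI+LSQ" else -1.0
        for timepoint in ("baseline", "followup"):
            w = np.where(mask, design.baseline_coupling, 0.0)
            w[seed_region] = design.seed_region_coupling
            if timepoint == "followup":
                for ci, cmask in enumerate(cluster_masks):
                    cl = design.planted_clusters[ci]
                    w[cmask] = design.baseline_coupling + gsign * cl.sign * deltas[(subj, ci)] * sigma
            seed_series = rng.standard_normal(n_t)
            seed_series = ndimage.gaussian_filter1d(seed_series, design.temporal_smooth, mode="wrap")
            seed_series = (seed_series - seed_series.mean()) / seed_series.std()
            noise = rng.standard_normal((*shape, n_t))
            noise = ndimage.gaussian_filter(
                noise, sigma=(sigma_vox, sigma_vox, sigma_vox, design.temporal_smooth), mode="wrap"
            )
            noise /= noise.std()
            data = w[..., None] * seed_series + sigma * noise
            confounds = _make_confounds(rng, n_t)
            c_std = (confounds - confounds.mean(axis=0)) / confounds.std(axis=0)
            leak = rng.normal(0.0, design.confound_leak, size=(c_std.shape[1], int(np.prod(shape))))
            data += (c_std @ leak).T.reshape(*shape, n_t)
            data[~mask] = 0.0
            images.append(
                CohortImage(
                    subject=subj,
                    timepoint=timepoint,
                    group=subj_group[subj],
                    data=data.astype(np.float32),
                    affine=affine,
                    confounds=confounds,
                )
            )
        # analytic mean z change over all planted voxels for this subject
        total, nvox = 0.0, 0
        for ci, cmask in enumerate(cluster_masks):
            cl = design.planted_clusters[ci]
            dw = gsign * cl.sign * deltas[(subj, ci)] * sigma
            dz = analytic_coupling_z(design.baseline_coupling + dw, sigma) - z0
            total += float(dz) * int(cmask.sum())
            nvox += int(cmask.sum())
        planted_change[si] = total / max(nvox, 1)

    phenotype = _make_phenotype(rng, design, subjects, subj_group, planted_change)
    return images, phenotype


def _make_phenotype(
    rng: np.random.Generator,
    design: SyntheticDesign,
    subjects: list[str],
    subj_group: dict[str, str],
    planted_change: np.ndarray,
) -> pd.DataFrame:
    n_subj = len(subjects)
    age = np.round(rng.normal(68, 6, n_subj)).astype(int)
    sex = rng.integers(0, 2, n_subj)
    education = np.clip(np.round(rng.normal(12, 3, n_subj)), 3, 22).astype(int)

    # latent sleep quality (higher = better); LSQ group sits lower
    quality = np.where(
        [subj_group[s] == "CI+LSQ" for s in subjects],
        rng.normal(-1.0, 0.6, n_subj),
        rng.normal(1.0, 0.6, n_subj),
    )
    sleep = {}
    for name in SLEEP_SCALES:
        mu, sd = _SCALE_LOC[name]
        raw = mu - quality * 0.8 * sd + rng.normal(0.0, 0.6 * sd, n_subj)
        sleep[name] = np.clip(np.round(raw), 0, None).astype(int)

    # Memory change correlates with the planted connectivity change.  The
    # coupling is defined on the within-group variation (between-subject
    # effect heterogeneity), so the association survives adjustment for
    # sleep-status group in downstream correlations.
    groups_arr = np.array([subj_group[s] for s in subjects])
    c = planted_change.copy()
    for g in np.unique(groups_arr):
        c[groups_arr == g] -= planted_change[groups_arr == g].mean()
    c_std = c / c.std() if c.std() > 0 else np.zeros_like(c)
    r = design.memory_coupling_r
    baseline_scores, change_scores = {}, {}
    for name in MEMORY_TESTS:
        mu, sd = _MEMORY_LOC[name]
        baseline_scores[name] = np.clip(np.round(rng.normal(mu, sd, n_subj)), 0, None).astype(int)
        noise = rng.standard_normal(n_subj)
        noise = (noise - noise.mean()) / noise.std()
        change = 0.6 * sd * (r * c_std + np.sqrt(1 - r**2) * noise) + 0.3 * sd
        change_scores[name] = np.round(change).astype(int)

    rows = []
    for i, subj in enumerate(subjects):
        for timepoint in ("baseline", "followup"):
            row = {
                "subject": subj,
                "group": subj_group[subj],
                "timepoint": timepoint,
                "age": age[i],
                "sex": int(sex[i]),
                "education": education[i],
            }
            for name in SLEEP_SCALES:
                row[name] = sleep[name][i]
            for name in MEMORY_TESTS:
                val = baseline_scores[name][i]
                if timepoint == "followup":
                    val = max(val + change_scores[name][i], 0)
                row[name] = int(val)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_expression(
    design: ExpressionDesign,
    target_map: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
) -> tuple[ExpressionDataset, np.ndarray]:
    """Simulate a normalized expression matrix over mask-constrained samples.

    Samples are placed at random mask-voxel centres with sub-voxel jitter.
    Planted genes are constructed to have cross-sample Pearson correlation
    ``planted_r`` with the target map's values at the sample locations (before
    donor offsets, which attenuate it slightly); the remaining genes are
    spatially autocorrelated noise obtained by Gaussian-kernel mixing over
    inter-sample distance.  Returns the dataset and a boolean planted-gene
    flag (ground truth for recovery tests).
    """
    if design.n_samples < 10:
        raise ValueError("need at least 10 samples for meaningful correlations")
    mask = np.asarray(mask, dtype=bool)
    target_map = np.asarray(target_map, dtype=float)
    if target_map.shape != mask.shape:
        raise ValueError("target map and mask are on different grids")
    rng = np.random.default_rng(design.rng_seed)

    vox_idx = np.argwhere(mask)
    pick = rng.choice(len(vox_idx), size=design.n_samples, replace=len(vox_idx) < design.n_samples)
    jitter = rng.uniform(-0.49, 0.49, size=(design.n_samples, 3))
    coords = voxel_to_mm(affine, vox_idx[pick] + jitter)
    target = target_map[tuple(vox_idx[pick].T)]
    t_std = target - target.mean()
    sd = t_std.std()
    if sd == 0:
        raise ValueError("target map is constant over the sampled voxels")
    t_std /= sd

    # spatially autocorrelated noise: Gaussian-kernel mixing by distance.
    # Mixing white noise with a kernel of width L/sqrt(2) yields a field whose
    # autocorrelation is Gaussian with length L (kernel self-convolution).
    dist = cdist(coords, coords)
    width = design.spatial_corr_length_mm / np.sqrt(2.0)
    kernel = np.exp(-(dist**2) / (2.0 * width**2))
    white = rng.standard_normal((design.n_genes, design.n_samples))
    noise = white @ kernel.T
    noise = (noise - noise.mean(axis=1, keepdims=True)) / noise.std(axis=1, keepdims=True)

    planted = np.zeros(design.n_genes, dtype=bool)
    planted[rng.choice(design.n_genes, size=design.n_planted_genes, replace=False)] = True
    expr = np.empty((design.n_genes, design.n_samples))
    r = design.planted_r
    for g in range(design.n_genes):
        if planted[g]:
            n_perp = noise[g] - (noise[g] @ t_std) / (t_std @ t_std) * t_std
            n_perp = (n_perp - n_perp.mean()) / n_perp.std()
            expr[g] = r * t_std + np.sqrt(1 - r**2) * n_perp
        else:
            expr[g] = noise[g]

    donors = rng.integers(0, design.n_donors, size=design.n_samples)
    donor_offset = rng.normal(0.0, design.donor_offset_sd, size=design.n_donors)
    expr += donor_offset[donors]
    expr += rng.normal(0.0, 1.0, size=(design.n_genes, 1))  # per-gene baseline level

    dataset = ExpressionDataset(
        genes=np.array([f"G{g:04d}" for g in range(design.n_genes)]),
        samples=np.array([f"S{s:04d}" for s in range(design.n_samples)]),
        donors=np.array([f"donor{d + 1}" for d in donors]),
        sample_mni=coords,
        expr=expr,
    )
    return dataset, planted


def generate_ppi_background(
    n_nodes: int,
    edge_prob: float,
    planted_module: tuple[list, float] | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Erdos-Renyi STRING-dialect edge table with an optional denser module.

    ``planted_module`` is ``(node subset, within_prob)``: pairs inside the
    subset get an extra chance of an edge so the module is denser than the
    background.  Scores are uniform on [0.4, 1.0] written in the integer
    dialect (x1000).  Node ids follow the synthetic gene naming (``G0000``…)
    so the table composes with the expression generator.
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be a probability")
    rng = np.random.default_rng(rng_seed)
    names = np.array([f"G{i:04d}" for i in range(n_nodes)])
    iu, ju = np.triu_indices(n_nodes, k=1)
    present = rng.random(iu.size) < edge_prob
    if planted_module is not None:
        subset, within_prob = planted_module
        if not 0 <= within_prob <= 1:
            raise ValueError("within_prob must be a probability")
        member = np.zeros(n_nodes, dtype=bool)
        idx = [int(s[1:]) if isinstance(s, str) else int(s) for s in subset]
        member[idx] = True
        inside = member[iu] & member[ju]
        present |= inside & (rng.random(iu.size) < within_prob)
    scores = np.round(rng.uniform(0.4, 1.0, size=int(present.sum())) * 1000).astype(int)
    return pd.DataFrame(
        {
            "node1": names[iu[present]],
            "node2": names[ju[present]],
            "combined_score": scores,
        }
    )
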