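"""Shared fixtures: small synthetic cohorts and expression sets.

Everything is generated at test time from the package's own generators;
session scope keeps the heavier cohorts to a single build.
"""

import numpy as np
import pytest
from scipy import ndimage

import txconn as tc
from txconn.geometry import default_affine, ellipsoid_mask
from txconn.interaction import GAUSS_FWHM


@pytest.fixture(scope="session")
def small_cohort():
    """14^3 cohort, 12 subjects/group, one planted cluster clear of the seed."""
    design = tc.SyntheticDesign(
        grid_shape=(14, 14, 14),
        n_per_group=12,
        n_timepoints_series=60,
        planted_clusters=(tc.PlantedCluster(center_voxel=(10, 10, 7), radius_mm=5.0, effect_size=1.5),),
        rng_seed=11,
    )
    images, phenotype = tc.generate_cohort(design)
    return design, images, phenotype


@pytest.fixture(scope="session")
def small_zmaps(small_cohort):
    design, images, _ = small_cohort
    seed = tc.SeedSpec(design.seed_center_mni, 6.0)
    return [tc.seed_fc_zmap(img, seed, mask=design.brain_mask) for img in images]


@pytest.fixture(scope="session")
def expression_world():
    """Brain-scale 40^3 sampling volume (120 mm extent, as the atlas samples
    the whole brain) + a connectivity-change map at the BOLD generator's
    6 mm noise smoothness."""
    shape = (40, 40, 40)
    affine = default_affine(shape, 3.0, (0.0, 0.0, 0.0))
    mask = ellipsoid_mask(shape)
    rng = np.random.default_rng(1000)
    sigma_vox = 6.0 / 3.0 / GAUSS_FWHM  # 6 mm FWHM, the BOLD noise smoothness
    target = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="wrap")
    return mask, affine, target


@pytest.fixture(scope="session")
def planted_expression(expression_world):
    mask, affine, target = expression_world
    dataset, planted = tc.generate_expression(
        tc.ExpressionDesign(rng_seed=7), target, mask, affine
    )
    values, kept = tc.regional_value_per_sample(target, affine, mask, dataset.sample_mni, radius_mm=6.0)
    assert kept.all()
    return dataset, planted, values
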