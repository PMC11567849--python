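"""Mask restriction, gene-wise association, FDR, and surrogate-map nulls."""

import numpy as np
import pytest

import txconn as tc
from txconn.geometry import default_affine, ellipsoid_mask, voxel_to_mm
from txconn.transcriptomics import (
    ExpressionDataset,
    assign_samples_to_mask,
    empirical_variogram,
    fdr_bh,
    genewise_correlation,
    permutation_count_test,
    regional_value_per_sample,
    spatial_surrogates,
    surrogate_significant_counts,
)


def _dataset(coords, expr=None, n_genes=3):
    coords = np.atleast_2d(np.asarray(coords, float))
    s = len(coords)
    if expr is None:
        expr = np.arange(n_genes * s, dtype=float).reshape(n_genes, s)
    return ExpressionDataset(
        genes=np.array([f"G{i}" for i in range(expr.shape[0])]),
        samples=np.array([f"S{i}" for i in range(s)]),
        donors=np.array(["d1"] * s),
        sample_mni=coords,
        expr=expr,
    )


class TestAssignSamples:
    shape = (8, 8, 8)
    affine = default_affine((8, 8, 8), 3.0, (0, 0, 0))

    def _mask(self, voxels):
        m = np.zeros(self.shape, bool)
        for v in voxels:
            m[v] = True
        return m

    def test_sample_at_voxel_centre_retained(self):
        mask = self._mask([(4, 4, 4)])
        ds = _dataset([voxel_to_mm(self.affine, np.array([4.0, 4, 4]))])
        assert assign_samples_to_mask(ds, mask, self.affine).tolist() == [True]

    def test_distant_sample_dropped_and_error_when_none_left(self):
        mask = self._mask([(4, 4, 4)])
        centre = voxel_to_mm(self.affine, np.array([4.0, 4, 4]))
        far = _dataset([centre + [10.0, 0, 0], centre])
        keep = assign_samples_to_mask(far, mask, self.affine, tolerance_mm=2.0)
        assert keep.tolist() == [False, True]
        with pytest.raises(ValueError, match="no expression sample"):
            assign_samples_to_mask(_dataset([centre + [50.0, 0, 0]]), mask, self.affine)

    def test_matches_brute_force_distances(self):
        mask = self._mask([(2, 2, 2), (5, 5, 5)])
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 21, size=(4, 3)) + self.affine[:3, 3]
        coords = np.vstack([coords, voxel_to_mm(self.affine, np.array([2.0, 2, 2])) + 1.0])
        ds = _dataset(coords, n_genes=2)
        keep = assign_samples_to_mask(ds, mask, self.affine, tolerance_mm=2.0)
        centres = np.array([voxel_to_mm(self.affine, np.array(v, float)) for v in [(2, 2, 2), (5, 5, 5)]])
        for i, xyz in enumerate(coords):
            vox = np.rint((xyz - self.affine[:3, 3]) / 3.0).astype(int)
            in_vox = tuple(vox) in {(2, 2, 2), (5, 5, 5)}
            near = np.linalg.norm(centres - xyz, axis=1).min() <= 2.0
            assert keep[i] == (in_vox or near)


class TestRegionalValue:
    shape = (10, 10, 10)
    affine = default_affine((10, 10, 10), 3.0, (0, 0, 0))
    mask = ellipsoid_mask((10, 10, 10))

    def test_constant_volume_gives_constant(self):
        vol = np.full(self.shape, 3.14)
        vals, kept = regional_value_per_sample(vol, self.affine, self.mask, [[0, 0, 0], [3, 0, -3]], 6.0)
        assert kept.all()
        np.testing.assert_allclose(vals, 3.14)

    def test_radius_zero_is_voxel_lookup(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal(self.shape)
        xyz = voxel_to_mm(self.affine, np.array([5.0, 4, 6]))
        vals, kept = regional_value_per_sample(vol, self.affine, self.mask, [xyz], 0.0)
        assert vals[0] == vol[5, 4, 6]

    def test_sphere_average_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal(self.shape)
        xyz = np.array([1.5, -2.0, 3.0])
        vals, _ = regional_value_per_sample(vol, self.affine, self.mask, [xyz], 6.0)
        acc = [
            vol[idx]
            for idx in np.ndindex(self.shape)
            if self.mask[idx]
            and np.linalg.norm(voxel_to_mm(self.affine, np.array(idx, float)) - xyz) <= 6.0
        ]
        assert vals[0] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_sample_outside_mask_dropped_with_warning(self):
        vol = np.zeros(self.shape)
        with pytest.warns(UserWarning, match="dropped"):
            vals, kept = regional_value_per_sample(
                vol, self.affine, self.mask, [[200.0, 0, 0], [0, 0, 0]], 3.0
            )
        assert kept.tolist() == [False, True]


class TestGenewiseCorrelation:
    def test_gene_equal_to_values_gives_r_one(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(20)
        expr = np.vstack([v, rng.standard_normal(20)])
        out = genewise_correlation(expr, v)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-12

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(15)
        expr = np.vstack([np.full(15, 2.0), v])
        out = genewise_correlation(expr, v)
        assert bool(out.loc[0, "excluded"]) and np.isnan(out.loc[0, "r"])
        assert not out.loc[1, "excluded"]

    def test_dimension_mismatch_and_min_samples(self):
        with pytest.raises(ValueError, match="disagree"):
            genewise_correlation(np.zeros((2, 10)), np.zeros(9))
        with pytest.raises(ValueError, match="at least 10"):
            genewise_correlation(np.zeros((2, 5)), np.zeros(5))

    def test_significant_set_invariant_to_gene_rescaling(self, planted_expression):
        dataset, planted, values = planted_expression
        out1 = genewise_correlation(dataset.expr, values)
        scale = np.linspace(0.5, 4.0, dataset.expr.shape[0])[:, None]
        out2 = genewise_correlation(dataset.expr * scale + 11.0, values)
        _, sig1 = fdr_bh(out1["p"].to_numpy())
        _, sig2 = fdr_bh(out2["p"].to_numpy())
        assert (sig1 == sig2).all()


class TestFdrBh:
    def test_hand_stepup_example(self):
        p = np.array([0.0001, 0.0004, 0.019, 0.095, 0.201])
        q, sig = fdr_bh(p, q_threshold=0.001)
        assert sig.tolist() == [True, True, False, False, False]
        assert q[0] == pytest.approx(0.0005)

    def test_all_ones_none_significant(self):
        _, sig = fdr_bh(np.ones(7), 0.001)
        assert not sig.any()

    def test_single_p_identity(self):
        q, sig = fdr_bh(np.array([0.0005]), 0.001)
        assert q[0] == pytest.approx(0.0005)
        assert sig.tolist() == [True]

    def test_q_at_least_p_and_empty_input(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q, _ = fdr_bh(p)
        assert (q >= p - 1e-15).all()
        q0, s0 = fdr_bh([])
        assert q0.size == 0 and s0.size == 0


class TestSpatialSurrogates:
    def test_zero_surrogates_empty(self):
        out = spatial_surrogates(np.arange(30.0), np.random.default_rng(0).normal(size=(30, 3)), 0)
        assert out.shape == (0, 30)

    def test_multiset_preserved(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal(40)
        coords = rng.uniform(0, 50, size=(40, 3))
        surr = spatial_surrogates(v, coords, 5, rng_seed=1)
        for s in surr:
            np.testing.assert_allclose(np.sort(s), np.sort(v))

    def test_degenerate_geometry_falls_back_to_shuffle(self):
        v = np.arange(25.0)
        coords = np.zeros((25, 3))
        with pytest.warns(UserWarning, match="coincide"):
            surr = spatial_surrogates(v, coords, 3, rng_seed=2)
        assert surr.shape == (3, 25)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="20 samples"):
            spatial_surrogates(np.arange(10.0), np.random.default_rng(0).normal(size=(10, 3)), 5)

    def test_variogram_match_within_tolerance(self, planted_expression):
        """Surrogate variograms track the original's within ~20% integrated
        absolute deviation on average."""
        _, _, values = planted_expression
        coords_ds = planted_expression[0].sample_mni
        surr = spatial_surrogates(values, coords_ds, 20, rng_seed=3)
        _, g_target = empirical_variogram(values, coords_ds)
        iads = []
        for s in surr:
            _, g = empirical_variogram(s, coords_ds)
            iads.append(np.nansum(np.abs(g - g_target)) / np.nansum(g_target))
        assert np.mean(iads) < 0.20
        assert np.max(iads) < 0.40

    def test_shuffle_null_smaller_than_variogram_null_on_smooth_data(self):
        """The spatially constrained null exists because plain shuffles are
        anti-conservative: on strongly autocorrelated data the variogram-
        matched surrogates yield systematically larger significant counts."""
        from scipy import ndimage
        from txconn.interaction import GAUSS_FWHM

        shape = (16, 16, 16)
        affine = default_affine(shape, 3.0, (0, 0, 0))
        mask = ellipsoid_mask(shape)
        rng = np.random.default_rng(7)
        target = ndimage.gaussian_filter(rng.standard_normal(shape), 12 / 3 / GAUSS_FWHM, mode="wrap")
        ds, _ = tc.generate_expression(
            tc.ExpressionDesign(n_genes=600, n_samples=150, spatial_corr_length_mm=12.0, rng_seed=8),
            target, mask, affine,
        )
        vals, _ = regional_value_per_sample(target, affine, mask, ds.sample_mni, 6.0)
        sv = spatial_surrogates(vals, ds.sample_mni, 60, rng_seed=9)
        sh = spatial_surrogates(vals, ds.sample_mni, 60, rng_seed=9, method="shuffle")
        cv = surrogate_significant_counts(ds.expr, sv, 0.01)
        cs = surrogate_significant_counts(ds.expr, sh, 0.01)
        assert cv.mean() > cs.mean() + 10


class TestPermutationCountTest:
    def test_add_one_estimator_extremes(self):
        counts = np.zeros(5000, dtype=int)
        null = permutation_count_test(100, counts)
        assert null.p_perm == pytest.approx(1 / 5001)
        assert null.p_perm < 0.001
        null_all = permutation_count_test(0, counts)
        assert null_all.p_perm == 1.0

    def test_median_count_gives_half(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(20, size=999)
        null = permutation_count_test(int(np.median(counts)), counts)
        assert null.p_perm == pytest.approx(0.5, abs=0.1)

    def test_too_few_surrogates_error(self):
        with pytest.raises(ValueError, match="100 surrogates"):
            permutation_count_test(1, np.zeros(50, int))


class TestNullCalibration:
    def test_uncorrected_count_nominal_and_bh_count_tiny(self, expression_world):
        """All-null generator against a spatially white imaging vector:
        E[#{p < t}] = m t for the uncorrected threshold, and the BH-selected
        count under the global null is far below m t.  (With a smooth imaging
        vector the rate is inflated — that regime is covered by the
        shuffle-vs-variogram comparison.)"""
        mask, affine, _ = expression_world
        white = np.random.default_rng(39).standard_normal(mask.shape)
        total_unc, total_bh, m, runs = 0, 0, 1500, 6
        for seed in range(runs):
            ds, _ = tc.generate_expression(
                tc.ExpressionDesign(n_genes=m, n_samples=250, n_planted_genes=1,
                                    planted_r=0.0, rng_seed=40 + seed),
                white, mask, affine,
            )
            vals, _ = regional_value_per_sample(white, affine, mask, ds.sample_mni, 0.0)
            out = genewise_correlation(ds.expr, vals)
            total_unc += int((out["p"] < 0.001).sum())
            _, sig = fdr_bh(out["p"].to_numpy(), 0.001)
            total_bh += int(sig.sum())
        expect = m * 0.001 * runs
        assert total_unc == pytest.approx(expect, abs=4 * np.sqrt(expect) + 4)
        assert total_bh <= total_unc

    def test_permutation_p_not_significant_under_null(self, expression_world):
        mask, affine, target = expression_world
        ds, _ = tc.generate_expression(
            tc.ExpressionDesign(n_genes=500, n_samples=200, n_planted_genes=1,
                                planted_r=0.0, rng_seed=50),
            target, mask, affine,
        )
        vals, _ = regional_value_per_sample(target, affine, mask, ds.sample_mni, 6.0)
        out = genewise_correlation(ds.expr, vals)
        _, sig = fdr_bh(out["p"].to_numpy(), 0.001)
        surr = spatial_surrogates(vals, ds.sample_mni, 120, rng_seed=51)
        counts = surrogate_significant_counts(ds.expr, surr, 0.001)
        null = permutation_count_test(int(sig.sum()), counts)
        assert null.p_perm > 0.05
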