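"""Covariance, DCCM, PCA, cosine content, free-energy landscapes, basins."""

import numpy as np
import pytest

from allostery import essential
from allostery.essential import (
    cosine_content,
    covariance,
    covariance_from_matrix,
    dccm,
    dccm_from_covariance,
    detect_basins,
    free_energy_landscape,
    map_difference,
    pca,
    porcupine_vectors,
    project,
)
from allostery.model import Ensemble
from conftest import make_sites, static_ensemble


def _gaussian_ensemble(rng, n_frames, site_std):
    """i.i.d. per-site anisotropic Gaussian fluctuations about a line."""
    n = len(site_std)
    base = np.arange(n)[:, None] * np.array([4.0, 0, 0])
    noise = rng.normal(size=(n_frames, n, 3)) * np.asarray(site_std)[None, :, None]
    return Ensemble(base[None] + noise, make_sites(base))


class TestCovariance:
    def test_static_frames_zero_matrix(self, square_model):
        cov = covariance(static_ensemble(square_model), align=False)
        np.testing.assert_allclose(cov.gamma, 0.0, atol=1e-14)

    def test_single_coordinate_fluctuation(self):
        model = make_sites([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        coords = np.tile(model.reference_coords, (1000, 1, 1))
        x = np.random.default_rng(0).normal(size=1000)
        coords[:, 1, 0] += x
        cov = covariance(Ensemble(coords, model), align=False)
        expected = np.zeros((9, 9))
        expected[3, 3] = x.var()
        np.testing.assert_allclose(cov.gamma, expected, atol=1e-12)

    def test_needs_two_frames(self, square_model):
        with pytest.raises(ValueError):
            covariance(static_ensemble(square_model, n_frames=1))

    def test_eigenvalues_descending_sum_to_trace(self, rng):
        ens = _gaussian_ensemble(rng, 500, [1.0, 0.5, 0.2, 0.1])
        cov = covariance(ens, align=False)
        assert np.all(np.diff(cov.eigenvalues) <= 1e-12)
        assert cov.eigenvalues.sum() == pytest.approx(np.trace(cov.gamma))

    def test_eigenvectors_orthonormal(self, rng):
        ens = _gaussian_ensemble(rng, 300, [1.0, 0.5, 0.2])
        cov = covariance(ens, align=False)
        np.testing.assert_allclose(
            cov.eigenvectors.T @ cov.eigenvectors, np.eye(9), atol=1e-10
        )


class TestDccm:
    def _tracking_cov(self, sign):
        # site 1 rigidly tracks (or mirrors) site 0 along x
        g = np.zeros((6, 6))
        g[0, 0] = g[3, 3] = 1.0
        g[0, 3] = g[3, 0] = sign
        return g

    def test_perfect_correlation(self):
        c = dccm_from_covariance(self._tracking_cov(+1.0))
        assert c[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        c = dccm_from_covariance(self._tracking_cov(-1.0))
        assert c[0, 1] == pytest.approx(-1.0)

    def test_orthogonal_motion_uncorrelated(self):
        g = np.zeros((6, 6))
        g[0, 0] = g[4, 4] = 1.0  # x motion at site 0, y at site 1, independent
        c = dccm_from_covariance(g)
        assert c[0, 1] == pytest.approx(0.0)

    def test_diagonal_exactly_one(self, rng):
        a = rng.normal(size=(12, 12))
        c = dccm_from_covariance(a @ a.T + np.eye(12))
        np.testing.assert_array_equal(np.diag(c), 1.0)

    def test_zero_fluctuation_site_named(self):
        g = np.zeros((6, 6))
        g[0, 0] = 1.0
        with pytest.raises(ValueError, match="site index 1"):
            dccm_from_covariance(g)


class TestMapDifference:
    def test_identical_maps_zero(self, rng):
        a = rng.normal(size=(5, 5))
        np.testing.assert_array_equal(map_difference(a, a), 0.0)

    def test_planted_symmetric_edit(self, rng):
        a = rng.normal(size=(10, 10))
        a = (a + a.T) / 2
        b = a.copy()
        b[5, 9] += 0.3
        b[9, 5] += 0.3
        d = map_difference(b, a)
        assert d[5, 9] == pytest.approx(0.3) and d[9, 5] == pytest.approx(0.3)
        assert np.abs(np.delete(d.ravel(), [5 * 10 + 9, 9 * 10 + 5])).max() == 0.0

    def test_antisymmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 4, 4))
        np.testing.assert_array_equal(map_difference(a, b), -map_difference(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            map_difference(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPca:
    def test_single_coordinate_gets_full_variance(self):
        g = np.zeros((6, 6))
        g[2, 2] = 4.0
        cov = covariance_from_matrix(g, np.zeros((2, 3)))
        modes = pca(cov, 3)
        assert modes[0]["variance_fraction"] == pytest.approx(1.0)

    def test_constructed_spectrum_recovered_from_sample(self, rng):
        # spectrum (4, 2, 1) planted along orthogonal directions at 3 sites
        n_frames = 20_000
        stds = np.sqrt([4.0, 2.0, 1.0])
        z = rng.normal(size=(n_frames, 3)) * stds
        coords = np.zeros((n_frames, 3, 3))
        for k in range(3):
            coords[:, k, k] = z[:, k]
        ens = Ensemble(coords + np.arange(3)[None, :, None] * 10, make_sites(np.zeros((3, 3))))
        cov = covariance(ens, align=False)
        fracs = [m["variance_fraction"] for m in pca(cov, 3)]
        np.testing.assert_allclose(fracs, np.array([4, 2, 1]) / 7.0, atol=0.02)

    def test_component_bounds_checked(self):
        cov = covariance_from_matrix(np.eye(6), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            pca(cov, 7)


class TestProjection:
    def test_variance_equals_eigenvalue(self, rng):
        ens = _gaussian_ensemble(rng, 2000, [1.0, 0.4, 0.1])
        cov = covariance(ens, align=False)
        p = project(ens, cov, 0)
        assert p.values.var() == pytest.approx(cov.eigenvalues[0], rel=1e-10)

    def test_static_ensemble_projects_to_zero(self, square_model):
        ens = static_ensemble(square_model)
        cov = covariance_from_matrix(np.eye(12), ens.coords[0])
        p = project(ens, cov, 0)
        np.testing.assert_allclose(p.values, 0.0, atol=1e-12)

    def test_two_basin_projection_separates_ground_truth(self, rng):
        from allostery.synth import sample_two_state

        ref_a = rng.normal(size=(8, 3)) * 6
        ref_b = ref_a + rng.normal(size=(8, 3)) * 1.5
        ens = sample_two_state(ref_a, ref_b, (0.5, 0.5), jitter=0.05,
                               n_frames=4000, seed=3, site_model=make_sites(ref_a))
        cov = covariance(ens, align=False)
        p = project(ens, cov, 0)
        labels = ens.metadata["basin_labels"]
        thr = 0.5 * (p.values[labels == 0].mean() + p.values[labels == 1].mean())
        side = p.values > thr
        acc = max(np.mean(side == labels), np.mean(side == (1 - labels)))
        assert acc >= 0.99

    def test_distinct_components_uncorrelated(self, rng):
        ens = _gaussian_ensemble(rng, 5000, [1.0, 0.4, 0.1])
        cov = covariance(ens, align=False)
        p1, p2 = project(ens, cov, 0), project(ens, cov, 1)
        corr = np.corrcoef(p1.values, p2.values)[0, 1]
        assert abs(corr) < 1e-8  # exactly orthogonal on the sample that built cov


class TestCosineContent:
    def test_pure_cosine_is_one(self):
        t = np.linspace(0, 1, 5000)
        assert cosine_content(np.cos(np.pi * t)) == pytest.approx(1.0, abs=1e-3)

    def test_orthogonal_sine_is_zero(self):
        t = np.linspace(0, 1, 5000)
        assert cosine_content(np.sin(np.pi * t)) == pytest.approx(0.0, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cosine_content(np.zeros(10))


class TestFreeEnergyLandscape:
    def test_uniform_samples_flat_surface(self, rng):
        x, y = rng.uniform(size=(2, 200_000))
        fel = free_energy_landscape(x, y, n_bins=10)
        assert not fel.mask.any()
        assert float(fel.free_energy.max()) < 0.25  # sampling noise only

    def test_minimum_is_exactly_zero(self, rng):
        fel = free_energy_landscape(rng.normal(size=3000), rng.normal(size=3000), 20)
        assert float(fel.free_energy.min()) == 0.0

    def test_empty_bins_masked(self):
        x = np.array([0.0, 0.1, 5.0])
        fel = free_energy_landscape(x, x, n_bins=5)
        assert fel.mask.sum() > 0

    def test_kT_scales_surface_globally(self, rng):
        x, y = rng.normal(size=(2, 5000))
        f1 = free_energy_landscape(x, y, 15, kT=1.0).free_energy
        f2 = free_energy_landscape(x, y, 15, kT=2.5).free_energy
        np.testing.assert_allclose(np.asarray(f2), 2.5 * np.asarray(f1), atol=1e-12)


class TestDetectBasins:
    def test_single_cluster_single_basin(self, rng):
        x, y = rng.normal(size=(2, 20_000))
        fel = free_energy_landscape(x, y, 25)
        basins = detect_basins(fel, depth_threshold=1.0)
        assert len(basins) == 1

    def test_two_clusters_found_at_centres(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 50_000), rng.normal(5, 0.5, 25_000)])
        y = np.concatenate([rng.normal(0, 0.5, 50_000), rng.normal(5, 0.5, 25_000)])
        fel = free_energy_landscape(x, y, 30)
        basins = detect_basins(fel, depth_threshold=1.0)
        assert len(basins) == 2
        assert basins[0]["free_energy"] == 0.0
        assert abs(basins[0]["x"]) < 0.5 and abs(basins[1]["x"] - 5) < 0.5

    def test_flat_surface_degenerate_single_basin(self):
        grid = np.ma.masked_array(np.zeros((4, 4)), mask=np.zeros((4, 4), bool))
        fel = essential.FreeEnergySurface(np.arange(5.0), np.arange(5.0), grid)
        basins = detect_basins(fel)
        assert len(basins) == 1 and basins[0]["degenerate"]

    def test_all_masked_rejected(self):
        grid = np.ma.masked_array(np.zeros((2, 2)), mask=np.ones((2, 2), bool))
        fel = essential.FreeEnergySurface(np.arange(3.0), np.arange(3.0), grid)
        with pytest.raises(ValueError):
            detect_basins(fel)


class TestPorcupine:
    def _cov_single_site_mode(self):
        g = np.zeros((9, 9))
        g[3, 3] = 4.0  # only site 1 moves, along x
        return covariance_from_matrix(g, np.arange(9, dtype=float).reshape(3, 3))

    def test_mode_moving_one_site_gives_one_arrow(self):
        arrows = porcupine_vectors(self._cov_single_site_mode(), 0, scale=2.0)
        assert len(arrows) == 1
        assert arrows[0]["site_index"] == 1
        assert arrows[0]["length"] == pytest.approx(2.0)

    def test_zero_scale_suppresses_all(self):
        assert porcupine_vectors(self._cov_single_site_mode(), 0, scale=0.0) == []

    def test_lengths_proportional_to_eigenvector_norm(self, rng):
        a = rng.normal(size=(9, 9))
        cov = covariance_from_matrix(a @ a.T, np.zeros((3, 3)))
        arrows = porcupine_vectors(cov, 0, scale=3.0)
        v = cov.eigenvectors[:, 0].reshape(3, 3)
        for arrow in arrows:
            assert arrow["length"] == pytest.approx(
                3.0 * np.linalg.norm(v[arrow["site_index"]])
            )
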