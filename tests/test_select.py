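"""Pearson screening and the three feature extractors."""

import numpy as np
import pytest
from scipy import stats

import leafspec as L


def _spectra_from_matrix(X, rng_ids="S"):
    grid = L.WavelengthGrid(350.0 + np.arange(X.shape[1]))
    return L.SpectraSet(sample_ids=[f"{rng_ids}{i}" for i in range(X.shape[0])],
                        reflectance=np.asarray(X, dtype=float), grid=grid)


def _targets_for(spectra, y):
    return L.TargetVector(sample_ids=list(spectra.sample_ids),
                          spad=np.asarray(y, dtype=float))


class TestPearsonProfile:
    def test_hand_oracle(self):
        s = _spectra_from_matrix(np.column_stack([[1, 2, 3, 4], [4, 3, 2, 1]]))
        t = _targets_for(s, [2, 4, 5, 9])
        profile = L.pearson_profile(s, t)
        np.testing.assert_allclose(profile.r[0], 11 / np.sqrt(130), atol=1e-12)
        np.testing.assert_allclose(profile.r[1], -11 / np.sqrt(130), atol=1e-12)

    def test_band_identical_to_target_gives_r_one(self):
        y = np.array([40.0, 43, 47, 50, 55])
        s = _spectra_from_matrix(np.column_stack([y / 100, y / 100]))
        profile = L.pearson_profile(s, _targets_for(s, y))
        np.testing.assert_allclose(profile.r, 1.0, atol=1e-12)

    def test_invariant_to_positive_affine_band_rescaling(self, rng):
        X = rng.uniform(0, 1, (15, 4))
        y = rng.uniform(35, 55, 15)
        s1 = _spectra_from_matrix(X)
        s2 = _spectra_from_matrix(2.7 * X + 0.3)
        r1 = L.pearson_profile(s1, _targets_for(s1, y)).r
        r2 = L.pearson_profile(s2, _targets_for(s2, y)).r
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_matches_brute_force_per_band(self, rng):
        X = rng.uniform(0, 1, (20, 15))
        y = rng.uniform(30, 60, 20)
        s = _spectra_from_matrix(X)
        profile = L.pearson_profile(s, _targets_for(s, y))
        expected = [stats.pearsonr(X[:, j], y).statistic for j in range(15)]
        np.testing.assert_allclose(profile.r, expected, atol=1e-12)

    def test_zero_variance_band_warns_and_sets_zero(self, rng):
        X = rng.uniform(0, 1, (12, 3))
        X[:, 1] = 0.5
        s = _spectra_from_matrix(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            profile = L.pearson_profile(s, _targets_for(s, rng.uniform(35, 55, 12)))
        assert profile.r[1] == 0.0

    def test_constant_target_rejected(self, rng):
        s = _spectra_from_matrix(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValueError, match="constant"):
            L.pearson_profile(s, _targets_for(s, np.full(10, 45.0)))


class TestThresholdMask:
    def test_magnitude_thresholding(self):
        grid = L.WavelengthGrid(np.array([500.0, 501, 502]))
        profile = L.CorrelationProfile(grid=grid, r=np.array([0.7, -0.65, 0.3]))
        mask = L.threshold_mask(profile, 0.6)
        np.testing.assert_array_equal(mask.selected, [True, True, False])
        np.testing.assert_array_equal(mask.wavelengths, [500.0, 501.0])

    def test_empty_mask_warns(self):
        grid = L.WavelengthGrid(np.array([500.0, 501]))
        profile = L.CorrelationProfile(grid=grid, r=np.zeros(2))
        with pytest.warns(UserWarning, match="no band"):
            mask = L.threshold_mask(profile)
        assert mask.n_selected == 0

    def test_threshold_range_checked(self):
        grid = L.WavelengthGrid(np.array([500.0, 501]))
        profile = L.CorrelationProfile(grid=grid, r=np.zeros(2))
        with pytest.raises(ValueError):
            L.threshold_mask(profile, 0.0)


def _full_mask(spectra):
    return L.BandMask(grid=spectra.grid,
                      selected=np.ones(spectra.n_bands, dtype=bool))


class TestBandSelectors:
    def test_fewer_masked_bands_than_k_keeps_all(self, tiny_spectra):
        spectra, targets = tiny_spectra
        mask = _full_mask(spectra)
        with pytest.warns(UserWarning, match="keeping all"):
            fs = L.gbt_importance_select(spectra, targets, mask, k=10, seed=0)
        assert fs.n_features == spectra.n_bands
        with pytest.warns(UserWarning, match="keeping all"):
            fs = L.rfe_select(spectra, targets, mask, k=10, seed=0)
        assert fs.n_features == spectra.n_bands

    def test_masked_count_equal_k_is_identity_selection(self, tiny_spectra):
        spectra, targets = tiny_spectra
        fs = L.rfe_select(spectra, targets, _full_mask(spectra),
                          k=spectra.n_bands, seed=0)
        np.testing.assert_array_equal(fs.selected_wavelengths,
                                      spectra.grid.wavelengths_nm)
        np.testing.assert_array_equal(fs.elimination_rank, 1)

    def test_empty_mask_is_an_error(self, tiny_spectra):
        spectra, targets = tiny_spectra
        empty = L.BandMask(grid=spectra.grid,
                           selected=np.zeros(spectra.n_bands, dtype=bool))
        for fn in (lambda: L.gbt_importance_select(spectra, targets, empty),
                   lambda: L.rfe_select(spectra, targets, empty),
                   lambda: L.pca_project(spectra, empty)):
            with pytest.raises(ValueError, match="empty band mask"):
                fn()

    def test_selections_are_subsets_of_mask(self, noise_only_dataset):
        spectra, targets, _ = noise_only_dataset
        # a tight screen keeps the problem small for one-band-per-step RFE
        mask = L.threshold_mask(L.pearson_profile(spectra, targets), 0.95)
        assert 10 < mask.n_selected < 120
        masked = set(mask.wavelengths)
        for fs in (L.gbt_importance_select(spectra, targets, mask, seed=1),
                   L.rfe_select(spectra, targets, mask, seed=1)):
            assert fs.n_features == 10
            assert set(fs.selected_wavelengths) <= masked
            assert np.all(np.diff(fs.selected_wavelengths) > 0)


class TestPCAProject:
    def _with_sample_covariance_eigs(self, eigs, n=20, seed=0):
        """Data whose ddof=1 sample covariance has exactly these eigenvalues."""
        rng = np.random.default_rng(seed)
        d = len(eigs)
        G = rng.normal(size=(n, d))
        G -= G.mean(axis=0)
        U, _, _ = np.linalg.svd(G, full_matrices=False)
        X = np.sqrt(n - 1) * U[:, :d] * np.sqrt(np.asarray(eigs))
        return _spectra_from_matrix(X - X.min() + 0.01)

    def test_two_orthogonal_directions_give_two_components(self):
        s = self._with_sample_covariance_eigs([4.0, 1.0])
        fs = L.pca_project(s, _full_mask(s), cum_var=0.99)
        assert fs.n_features == 2
        np.testing.assert_allclose(fs.explained_variance_ratio.sum(), 1.0, atol=1e-9)

    def test_eigenvalue_ratio_arithmetic(self):
        # ratios (0.8991, 0.0999, 0.0010): two components reach 0.9990 >= 0.99
        s = self._with_sample_covariance_eigs([9.0, 1.0, 0.01])
        fs = L.pca_project(s, _full_mask(s), cum_var=0.99)
        assert fs.n_features == 2
        np.testing.assert_allclose(fs.explained_variance_ratio,
                                   [9 / 10.01, 1 / 10.01], atol=1e-9)

    def test_scores_centered_and_transform_consistent(self, tiny_spectra):
        spectra, _ = tiny_spectra
        fs = L.pca_project(spectra, _full_mask(spectra), cum_var=0.99)
        np.testing.assert_allclose(fs.design_matrix.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fs.transform(spectra), fs.design_matrix, atol=1e-9)
        assert fs.selected_wavelengths.size == 0
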