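"""Splitting, scaling, metrics, leakage hygiene and the 27-cell grid."""

import numpy as np
import pytest

import leafspec as L


class TestSplit:
    def test_91_samples_split_63_28(self, default_dataset):
        spectra, targets, _ = default_dataset
        (tr_s, tr_t), (te_s, te_t) = L.split(spectra, targets, L.SplitSpec(seed=0))
        assert tr_s.n_samples == 63 and te_s.n_samples == 28
        assert len(tr_t) == 63 and len(te_t) == 28

    def test_partition_is_disjoint_and_complete(self, default_dataset):
        spectra, targets, _ = default_dataset
        (tr_s, _), (te_s, _) = L.split(spectra, targets, L.SplitSpec(seed=4))
        tr, te = set(tr_s.sample_ids), set(te_s.sample_ids)
        assert tr.isdisjoint(te)
        assert tr | te == set(spectra.sample_ids)

    def test_deterministic_under_seed(self, default_dataset):
        spectra, targets, _ = default_dataset
        a = L.split(spectra, targets, L.SplitSpec(seed=9))
        b = L.split(spectra, targets, L.SplitSpec(seed=9))
        assert a[0][0].sample_ids == b[0][0].sample_ids

    def test_too_few_samples_rejected(self, rng):
        grid = L.WavelengthGrid(np.array([500.0, 501]))
        s = L.SpectraSet(sample_ids=[f"S{i}" for i in range(5)],
                         reflectance=rng.uniform(0, 1, (5, 2)), grid=grid)
        t = L.TargetVector(sample_ids=list(s.sample_ids), spad=rng.uniform(40, 50, 5))
        with pytest.raises(ValueError, match="at least 10"):
            L.split(s, t)


class TestScaler:
    def test_min_max_mapping(self):
        scaler = L.fit_scaler(np.array([[2.0], [4.0], [6.0]]), np.array([40.0, 50.0]))
        np.testing.assert_allclose(scaler.transform(np.array([[2.0], [4.0], [6.0]])),
                                   [[0.0], [0.5], [1.0]], atol=1e-15)

    def test_invert_after_apply_is_identity(self, rng):
        X = rng.uniform(0, 1, (20, 3))
        y = rng.uniform(35, 55, 20)
        scaler = L.fit_scaler(X, y)
        np.testing.assert_allclose(scaler.invert_y(scaler.transform_y(y)), y,
                                   atol=1e-12)

    def test_out_of_range_test_values_pass_through_unclipped(self):
        scaler = L.fit_scaler(np.array([[2.0], [6.0]]), np.array([40.0, 50.0]))
        out = scaler.transform(np.array([[0.0], [8.0]]))
        np.testing.assert_allclose(out, [[-0.5], [1.5]], atol=1e-15)

    def test_constant_feature_maps_to_half_with_warning(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            scaler = L.fit_scaler(X, np.array([40.0, 50.0]))
        np.testing.assert_allclose(scaler.transform(X)[:, 1], 0.5)


class TestMetrics:
    def test_hand_oracle(self):
        res = L.metrics(np.array([40.0, 45, 50]), np.array([41.0, 44, 52]))
        np.testing.assert_allclose(res.rmse, np.sqrt(2), atol=1e-9)
        np.testing.assert_allclose(res.nrmse, np.sqrt(2) / 45, atol=1e-9)
        np.testing.assert_allclose(res.r2, 1 - 6 / 50, atol=1e-9)
        assert res.n_test == 3

    def test_perfect_and_mean_predictions(self, rng):
        y = rng.uniform(35, 55, 15)
        perfect = L.metrics(y, y)
        assert (perfect.r2, perfect.rmse, perfect.nrmse) == (1.0, 0.0, 0.0)
        at_mean = L.metrics(y, np.full_like(y, y.mean()))
        np.testing.assert_allclose(at_mean.r2, 0.0, atol=1e-12)

    def test_matches_brute_force_formulas(self, rng):
        y = rng.uniform(30, 60, 25)
        p = y + rng.normal(0, 2, 25)
        res = L.metrics(y, p)
        rmse = np.sqrt(np.mean((y - p) ** 2))
        np.testing.assert_allclose(res.rmse, rmse, atol=1e-12)
        np.testing.assert_allclose(res.nrmse, rmse / y.mean(), atol=1e-12)
        np.testing.assert_allclose(
            res.r2, 1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            L.metrics(np.array([1.0, 2]), np.array([1.0]))
        with pytest.raises(ValueError, match="zero"):
            L.metrics(np.array([-1.0, 1.0]), np.array([0.0, 0.0]))


class TestPipeline:
    def test_smoke_original_pca_svr(self, easy_dataset):
        spectra, targets, _ = easy_dataset
        res = L.run_combination(spectra, targets, "original", "pca", "svr",
                                master_seed=1)
        assert np.isfinite(res.r2) and res.nrmse >= 0
        assert res.n_test == 28

    def test_easy_recovery_regime_original_rfe_gabp(self, easy_dataset):
        """With corruption off, raw spectra + RFE + GA-BP recover SPAD well."""
        spectra, targets, _ = easy_dataset
        res = L.run_combination(spectra, targets, "original", "rfe", "gabp",
                                master_seed=7)
        assert res.r2 >= 0.9

    def test_stage_errors_carry_the_cell_name(self, default_dataset):
        spectra, targets, _ = default_dataset
        # default corruption leaves no raw band above the 0.6 screen
        with pytest.raises(ValueError, match=r"\[original/rfe/gabp\]"):
            L.run_combination(spectra, targets, "original", "rfe", "gabp",
                              master_seed=0)

    def test_no_leakage_from_test_rows(self, easy_dataset):
        """Removing a test row changes neither fitted state nor the other
        predictions: everything is fitted on the training split alone."""
        spectra, targets, _ = easy_dataset
        (tr_s, tr_t), (te_s, te_t) = L.split(spectra, targets, L.SplitSpec(seed=2))
        fit1 = L.fit_pipeline(tr_s, tr_t, "snv", "pca", "gabp",
                              selector_seed=3, model_seed=4)
        fit2 = L.fit_pipeline(tr_s, tr_t, "snv", "pca", "gabp",
                              selector_seed=3, model_seed=4)
        np.testing.assert_array_equal(fit1.mask.selected, fit2.mask.selected)
        np.testing.assert_array_equal(fit1.scaler.feat_min, fit2.scaler.feat_min)
        np.testing.assert_array_equal(fit1.model.W1, fit2.model.W1)
        pred_full = L.predict_pipeline(fit1, te_s)
        keep = np.arange(1, te_s.n_samples)  # drop the first test row
        pred_dropped = L.predict_pipeline(fit1, te_s.take(keep))
        np.testing.assert_array_equal(pred_dropped, pred_full[1:])


class TestGrid:
    def test_grid_has_27_cells_and_valid_metrics(self, default_dataset):
        spectra, targets, _ = default_dataset
        report = L.run_grid(spectra, targets, master_seed=3)
        assert len(report.table) == 27
        ok = report.table[report.table.status == "ok"]
        assert len(ok) > 0
        assert (ok.r2 <= 1.0).all()
        assert (ok.nrmse >= 0.0).all()
        # failed cells carry their error, not silence
        failed = report.table[report.table.status != "ok"]
        assert failed.r2.isna().all()
        assert report.best_cell is not None
        pr, se, mo = report.best_cell
        assert report.cell(pr, se, mo).r2 == report.table.r2.max()
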