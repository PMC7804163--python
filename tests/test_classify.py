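import numpy as np
import pytest
from dataclasses import replace

from drspipe import classify
from drspipe.classify import (
    PAPER_KERNELS,
    QUADRATIC,
    SVMConfig,
    auto_kernel_scale,
    compute_metrics,
    evaluate_cv,
    fold_assignment,
    kernel_comparison,
    kernel_value,
    train_svm,
    wavelength_range_experiment,
)
from drspipe.errors import ConfigError, NumericalError
from drspipe.preprocess import SpectraDataset

from _oracles import brute_force_auc, minmax_scale, qp_svm_decision


class TestKernelValue:
    def test_poly2_forced_arithmetic(self):
        cfg = SVMConfig("poly2", kernel_scale=1.0)
        assert kernel_value([1.0, 1.0], [1.0, 1.0], cfg) == pytest.approx(9.0)

    def test_gaussian_identical_points(self):
        for sigma in (0.5, 2.0, 8.0):
            cfg = SVMConfig("gaussian", gaussian_sigma=sigma)
            assert kernel_value([1.0, 2.0], [1.0, 2.0], cfg) == 1.0

    def test_gaussian_forced_arithmetic(self):
        cfg = SVMConfig("gaussian", gaussian_sigma=2.0)
        x1 = np.zeros(2)
        x2 = np.array([2.0, 2.0])  # squared distance 8 -> exp(-1)
        assert kernel_value(x1, x2, cfg) == pytest.approx(np.exp(-1.0),
                                                          rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=(2, 6))
        for cfg in (SVMConfig("poly3", kernel_scale=2.0),
                    SVMConfig("gaussian", gaussian_sigma=1.5)):
            assert kernel_value(x1, x2, cfg) == kernel_value(x2, x1, cfg)

    def test_length_mismatch_rejected(self):
        with pytest.raises(NumericalError):
            kernel_value([1.0], [1.0, 2.0], SVMConfig("linear",
                                                      kernel_scale=1.0))


class TestTrainSVM:
    def test_separable_1d_perfect_training_accuracy(self):
        X = np.array([[-10.0], [-9.0], [10.0], [9.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_svm(X, y, SVMConfig("linear", kernel_scale=1.0))
        np.testing.assert_array_equal(model.predict(X), y)

    def test_contradictory_points_give_half_accuracy(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([1, -1, 1, -1])
        model = train_svm(X, y, SVMConfig("linear", kernel_scale=1.0))
        assert np.mean(model.predict(X) == y) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(NumericalError):
            train_svm(np.zeros((3, 2)), np.ones(3),
                      SVMConfig("linear", kernel_scale=1.0))

    def test_dual_coefficients_bounded_by_C(self):
        rng = np.random.default_rng(1)
        X = minmax_scale(rng.normal(size=(30, 4)))
        y = np.where(rng.random(30) < 0.5, -1, 1)
        y[:2] = [-1, 1]
        model = train_svm(X, y, SVMConfig("poly2", kernel_scale=1.0))
        assert np.all(np.abs(model.dual_coef) <= 1.0 + 1e-9)

    @pytest.mark.parametrize("cfg", [
        SVMConfig("linear", kernel_scale=1.0),
        SVMConfig("poly2", kernel_scale=1.0),
        SVMConfig("gaussian", gaussian_sigma=2.0),
    ], ids=["linear", "poly2", "gaussian"])
    def test_matches_reference_qp(self, cfg):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = int(rng.integers(8, 21))
            X = minmax_scale(rng.normal(size=(n, 3)))
            y = np.where(rng.random(n) < 0.5, -1, 1)
            if len(np.unique(y)) < 2:
                y[0] = -y[0]
            model = train_svm(X, y, cfg, kernel_scale=1.0, tol=1e-10)
            ref = qp_svm_decision(
                lambda a, b: kernel_value(a, b, cfg, kernel_scale=1.0), X, y, X)
            np.testing.assert_allclose(model.decision_function(X), ref,
                                       atol=1e-6)


class TestAutoKernelScale:
    def test_two_rows_distance(self):
        X = np.array([[0.0, 0.0], [0.0, 4.0]])
        assert auto_kernel_scale(X) == pytest.approx(4.0)

    def test_identical_rows_fallback(self):
        assert auto_kernel_scale(np.ones((5, 3))) == 1.0

    def test_matches_exhaustive_median(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        dists = []
        for i in range(100):
            for j in range(i + 1, 100):
                dists.append(np.sqrt(((X[i] - X[j]) ** 2).sum()))
        assert auto_kernel_scale(X, seed=3) == pytest.approx(
            np.median(dists), rel=1e-12)

    def test_subsample_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1500, 3))
        assert auto_kernel_scale(X, seed=1) == auto_kernel_scale(X, seed=1)
        assert auto_kernel_scale(X, seed=1) != auto_kernel_scale(X, seed=2)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1] * 50 + [-1] * 50)
        scores = np.where(y == 1, 2.0, -2.0)
        m = compute_metrics(y, y, scores)
        assert (m.sensitivity, m.specificity, m.accuracy, m.auc) == \
            (100.0, 100.0, 100.0, 1.0)

    def test_pair_counting_example(self):
        y = np.array([1, 1, -1])
        scores = np.array([0.9, 0.3, 0.4])
        m = compute_metrics(y, np.sign(scores - 0.5).astype(int), scores)
        assert m.auc == pytest.approx(0.5)

    def test_auc_matches_brute_force(self):
        rng = np.random.default_rng(8)
        y = np.where(rng.random(200) < 0.5, -1, 1)
        y[:2] = [-1, 1]
        scores = np.round(rng.normal(size=200), 1)  # induce ties
        m = compute_metrics(y, np.sign(scores).astype(int), scores)
        assert m.auc == pytest.approx(brute_force_auc(y, scores), abs=0)

    def test_absent_class_flagged(self):
        y = np.array([1, 1, 1])
        m = compute_metrics(y, y, np.ones(3))
        assert np.isnan(m.specificity)
        assert "no negative samples" in m.flags


class TestFoldAssignment:
    def test_stratified_and_balanced(self):
        ids = np.arange(40)
        y = np.array([-1, 1] * 20)
        folds = fold_assignment(ids, y, 2, seed=0, iteration=0)
        for cls in (-1, 1):
            counts = np.bincount(folds[y == cls])
            assert abs(counts[0] - counts[1]) <= 1

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        ids = np.arange(20)
        y = np.array([-1, 1] * 10)
        folds = fold_assignment(ids, y, 2, seed=3, iteration=1)
        perm = rng.permutation(20)
        folds_p = fold_assignment(ids[perm], y[perm], 2, seed=3, iteration=1)
        np.testing.assert_array_equal(folds[perm], folds_p)

    def test_symmetric_under_label_swap(self):
        ids = np.arange(20)
        y = np.array([-1, 1] * 10)
        f1 = fold_assignment(ids, y, 2, seed=4, iteration=2)
        f2 = fold_assignment(ids, -y, 2, seed=4, iteration=2)
        np.testing.assert_array_equal(f1, f2)


class TestEvaluateCV:
    def test_separable_gives_perfect_metrics(self, separable_dataset):
        res = evaluate_cv(separable_dataset, QUADRATIC, n_iterations=10, seed=3)
        assert res.mean_accuracy == 100.0
        assert res.sd_accuracy == 0.0
        assert res.mean_auc == 1.0

    def test_permuted_labels_null_auc(self, separable_dataset):
        rng = np.random.default_rng(5)
        ds = replace(separable_dataset, y=rng.permutation(separable_dataset.y))
        res = evaluate_cv(ds, QUADRATIC, n_iterations=10, seed=3)
        assert 0.40 < res.mean_auc < 0.60

    def test_toy_dataset_matches_manual_rerun(self, toy_dataset):
        """Re-execute the recorded splits by hand and compare all metrics."""
        from sklearn.svm import SVC

        cfg = SVMConfig("poly2", kernel_scale=1.0)
        res = evaluate_cv(toy_dataset, cfg, n_iterations=3, seed=11)
        order = np.argsort(toy_dataset.ids, kind="stable")
        X_all = toy_dataset.X[order]
        y_all = toy_dataset.y[order]
        for it in range(3):
            ids_rec, folds = res.fold_assignments[it]
            scores = np.empty(12)
            preds = np.empty(12, dtype=int)
            for f in (0, 1):
                test = folds == f
                train = ~test
                Xtr = X_all[train]
                mx, mn = Xtr.max(0), Xtr.min(0)
                half = (mx - mn) / 2.0
                mid = (mx + mn) / 2.0
                half[half == 0] = np.inf
                svc = SVC(C=1.0, kernel="poly", degree=2, gamma=1.0, coef0=1.0,
                          tol=1e-6)
                svc.fit((Xtr - mid) / half, y_all[train])
                Xte = (X_all[test] - mid) / half
                scores[test] = svc.decision_function(Xte)
                preds[test] = svc.predict(Xte)
            pos = y_all == 1
            sens = 100.0 * np.sum(pos & (preds == 1)) / pos.sum()
            spec = 100.0 * np.sum(~pos & (preds == -1)) / (~pos).sum()
            acc = 100.0 * np.mean(preds == y_all)
            auc = brute_force_auc(y_all, scores)
            assert res.sensitivity[it] == pytest.approx(sens)
            assert res.specificity[it] == pytest.approx(spec)
            assert res.accuracy[it] == pytest.approx(acc)
            assert res.auc[it] == pytest.approx(auc)

    def test_label_swap_exchanges_sensitivity_specificity(self, toy_dataset):
        cfg = SVMConfig("poly2", kernel_scale=1.0)
        res = evaluate_cv(toy_dataset, cfg, n_iterations=4, seed=2)
        swapped = evaluate_cv(replace(toy_dataset, y=-toy_dataset.y), cfg,
                              n_iterations=4, seed=2)
        np.testing.assert_allclose(res.sensitivity, swapped.specificity)
        np.testing.assert_allclose(res.specificity, swapped.sensitivity)
        # labels and scores both negate, so the AUC is invariant
        np.testing.assert_allclose(res.auc, swapped.auc)

    def test_row_order_invariance(self, toy_dataset):
        rng = np.random.default_rng(9)
        perm = rng.permutation(toy_dataset.n_samples)
        shuffled = toy_dataset.select_rows(perm)
        cfg = SVMConfig("poly2", kernel_scale=1.0)
        r1 = evaluate_cv(toy_dataset, cfg, n_iterations=4, seed=6)
        r2 = evaluate_cv(shuffled, cfg, n_iterations=4, seed=6)
        np.testing.assert_array_equal(r1.accuracy, r2.accuracy)
        np.testing.assert_array_equal(r1.auc, r2.auc)

    def test_single_class_rejected(self, toy_dataset):
        ds = replace(toy_dataset, y=np.ones(12, dtype=int))
        with pytest.raises(NumericalError):
            evaluate_cv(ds, QUADRATIC, seed=0)

    def test_full_scale_mode_runs(self, toy_dataset):
        cfg = SVMConfig("poly2", kernel_scale=1.0)
        res = evaluate_cv(toy_dataset, cfg, n_iterations=2, seed=1,
                          scale_mode="full")
        assert res.accuracy.shape == (2,)
        with pytest.raises(ConfigError):
            evaluate_cv(toy_dataset, cfg, scale_mode="bogus")


class TestDrivers:
    def test_kernel_comparison_shape_and_determinism(self, separable_dataset):
        sub = separable_dataset.select_rows(np.arange(0, 200, 4))
        t1 = kernel_comparison(sub, n_iterations=2, seed=5)
        t2 = kernel_comparison(sub, n_iterations=2, seed=5)
        assert [r.name for r in t1.values()] == [
            "Linear", "Quadratic", "Cubic", "Fine Gaussian",
            "Medium Gaussian", "Coarse Gaussian"]
        for name in t1:
            assert t1[name].auc.shape == (2,)
            np.testing.assert_array_equal(t1[name].auc, t2[name].auc)
            assert np.all(t1[name].sensitivity >= 0)
            assert np.all(t1[name].sensitivity <= 100)

    def test_ceiling_quadratic_close_to_linear(self, separable_dataset):
        results = kernel_comparison(
            separable_dataset, configs=PAPER_KERNELS[:2], n_iterations=5,
            seed=7)
        lin, quad = results["Linear"], results["Quadratic"]
        assert abs(lin.mean_auc - quad.mean_auc) < 0.02

    def test_full_range_row_equals_direct_cv(self, separable_dataset):
        res = wavelength_range_experiment(
            separable_dataset,
            range_specs={"full": [(350, 1919)]}, n_iterations=3, seed=9)
        direct = evaluate_cv(separable_dataset, QUADRATIC, n_iterations=3,
                             seed=9)
        np.testing.assert_array_equal(res["full"].auc, direct.auc)
        np.testing.assert_array_equal(res["full"].accuracy, direct.accuracy)

    def test_uninformative_range_is_null(self):
        """Classes differing only in water content are invisible below 900 nm."""
        from drspipe import synth

        base = {"oxyhemoglobin": 0.006, "deoxyhemoglobin": 0.003,
                "collagen": 0.2, "lipid": 0.05}
        normal_m = synth.ChromophoreModel({**base, "water": 0.60},
                                          scattering_amplitude=14.0,
                                          scattering_power=1.2)
        tumor_m = synth.ChromophoreModel({**base, "water": 0.80},
                                         scattering_amplitude=14.0,
                                         scattering_power=1.2)
        normal = synth.ClassSpec(label=-1, chromophore_model=normal_m,
                                 per_site_jitter_sd=0.05, per_patient_sd=0.05,
                                 n_patients=8, sites_per_patient=10)
        tumor = replace(normal, label=+1, chromophore_model=tumor_m)
        ds, _ = synth.generate_dataset(normal, tumor, 630, noise_sd=0.02,
                                       seed=15, grid_step=4.0,
                                       return_bundles=False)
        res = wavelength_range_experiment(
            ds, range_specs={"vis": [(400.0, 600.0)],
                             "nir": [(1300.0, 1600.0)]},
            n_iterations=10, seed=3)
        # null band sized for n=160 (dataset-level AUC SE ~ 0.045)
        assert 0.40 < res["vis"].mean_auc < 0.60
        assert res["nir"].mean_auc > 0.9

    def test_results_table_layout(self, separable_dataset):
        sub = separable_dataset.select_rows(np.arange(0, 200, 10))
        results = kernel_comparison(sub, configs=PAPER_KERNELS[:1],
                                    n_iterations=2, seed=1)
        table = classify.results_table(results, "Type of SVM")
        assert list(table.columns) == ["sensitivity", "specificity",
                                       "accuracy", "auc"]
        assert "±" in table.iloc[0]["auc"]


def test_config_validation():
    with pytest.raises(ConfigError):
        SVMConfig("sigmoid")
    with pytest.raises(ConfigError):
        SVMConfig("gaussian")  # missing sigma
    with pytest.raises(ConfigError):
        SVMConfig("linear", C=0.0)
    with pytest.raises(ConfigError):
        SVMConfig("poly2", kernel_scale=-1.0)
    assert classify.config_by_name("quadratic").kernel == "poly2"
    assert classify.config_by_name("Fine-Gaussian").gaussian_sigma == 0.5
    with pytest.raises(ConfigError):
        classify.config_by_name("nope")
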