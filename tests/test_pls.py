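"""PLS core, BIC component selection, screening, subset search, reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oculopls.pls import (ModelingConfig, _bic_from_press, _fold_arrays,
                          bic_select_components, build_score_model,
                          complete_oculo_block, exhaustive_subset_search,
                          fit_pls, make_folds, predict,
                          predicted_age_analysis, r2_and_adjusted,
                          screen_features)
from oculopls._plskernel import cv_press, cv_press_numpy


class TestPLSCore:
    def test_perfect_single_feature_fit(self):
        x = np.linspace(-2, 3, 30).reshape(-1, 1)
        y = 2.0 * x.ravel()
        model = fit_pls(x, y, 1)
        np.testing.assert_allclose(model.training_predictions, y, atol=1e-10)
        r2, _ = r2_and_adjusted(y, model.training_predictions, 1)
        assert r2 == pytest.approx(1.0)

    def test_full_components_equal_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, p = 40, 5
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            model = fit_pls(X, y, p)
            Xa = np.column_stack([np.ones(n), X])
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            np.testing.assert_allclose(model.training_predictions, Xa @ beta,
                                       atol=1e-8)

    def test_first_weight_vector_proportional_to_covariances(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.normal(size=50)
        model = fit_pls(X, y, 3)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = Xs.T @ (y - y.mean())
        np.testing.assert_allclose(model.x_weights[:, 0],
                                   cov / np.linalg.norm(cov), atol=1e-12)

    def test_matches_sklearn_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=60)
        for k in (1, 3, 5):
            ours = fit_pls(X, y, k)
            ref = PLSRegression(n_components=k, scale=True).fit(X, y)
            np.testing.assert_allclose(ours.training_predictions,
                                       ref.predict(X).ravel(), atol=1e-8)

    def test_predict_reproduces_training_and_centering_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + rng.normal(size=30)
        model = fit_pls(X, y, 2)
        np.testing.assert_array_equal(predict(model, X),
                                      model.training_predictions)
        mean_row = X.mean(axis=0, keepdims=True)
        assert predict(model, mean_row)[0] == pytest.approx(model.y_mean)

    def test_shift_invariance_of_predictions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + rng.normal(size=40) * 0.2
        base = fit_pls(X, y, 2).training_predictions
        shifted = X.copy()
        shifted[:, 1] += 100.0  # standardization absorbs the shift
        np.testing.assert_allclose(fit_pls(shifted, y, 2).training_predictions,
                                   base, atol=1e-9)

    def test_error_conditions(self):
        X = np.random.default_rng(5).normal(size=(20, 3))
        y = X[:, 0]
        X_const = X.copy()
        X_const[:, 2] = 7.0
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X_const, y, 2)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, y, 4)
        with pytest.raises(ValueError, match="complete data"):
            fit_pls(np.where(X > 2, np.nan, X), y, 1)


class TestR2:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        assert r2_and_adjusted(y, y, 3) == (1.0, 1.0)

    def test_worked_adjustment(self):
        # R2=0.5, n=100, p=10 -> adjusted = 1 - 0.5*99/89
        rng = np.random.default_rng(6)
        y = rng.normal(size=100)
        sstot = np.sum((y - y.mean()) ** 2)
        resid_scale = np.sqrt(0.5 * sstot / 100)
        y_pred = y - np.sqrt(0.5) * (y - y.mean())  # leaves SSres = 0.5 SStot
        r2, adj = r2_and_adjusted(y, y_pred, 10)
        assert r2 == pytest.approx(0.5, abs=1e-12)
        assert adj == pytest.approx(1 - 0.5 * 99 / 89, abs=1e-12)

    def test_printed_pairing_of_r2_and_adjusted(self):
        # an R2 of 0.36 at n=204 adjusts to 0.33 when 9 predictors are used
        rng = np.random.default_rng(7)
        y = rng.normal(size=204)
        y_pred = y - np.sqrt(1 - 0.36) * (y - y.mean())
        r2, adj = r2_and_adjusted(y, y_pred, 9)
        assert r2 == pytest.approx(0.36, abs=1e-12)
        assert adj == pytest.approx(0.33, abs=0.005)

    def test_adjusted_never_exceeds_r2(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=30)
            y_pred = y + rng.normal(size=30)
            r2, adj = r2_and_adjusted(y, y_pred, rng.integers(1, 8))
            assert adj <= r2 + 1e-12


class TestBICSelection:
    def test_bic_arithmetic(self):
        bic = _bic_from_press(np.array([80.0, 50.0]), 100)
        assert bic[1] == pytest.approx(100 * np.log(0.5) + 3 * np.log(100),
                                       abs=1e-9)

    def test_recovers_two_latent_directions(self):
        """X lives in exactly two orthogonal latent directions of unequal
        variance and y loads on both, so two components are necessary and
        sufficient; BIC should find that."""
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(300, 2)) * np.array([4.0, 2.0])
            P = np.linalg.qr(rng.normal(size=(8, 2)))[0]
            X = T @ P.T
            y = T @ np.array([1.0, 2.0]) + rng.normal(size=300)
            k, _ = bic_select_components(X, y, max_components=5, seed=seed)
            hits += k == 2
        assert hits >= 12

    def test_pure_noise_prefers_one_component(self):
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 6))
            y = rng.normal(size=100)
            k, _ = bic_select_components(X, y, max_components=5, seed=seed)
            hits += k == 1
        assert hits >= 8

    def test_fold_partition_is_pure_function_of_inputs(self):
        a = make_folds(57, 10, 3)
        b = make_folds(57, 10, 3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        c = make_folds(57, 10, 4)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


class TestKernel:
    def test_jit_kernel_equals_numpy_twin(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(45, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=45)
        arrays = _fold_arrays(X, y, make_folds(45, 5, 0))
        for cols in ([0], [1, 4], [0, 2, 5, 6]):
            cidx = np.asarray(cols, dtype=np.int64)
            np.testing.assert_allclose(
                cv_press(*arrays, cidx, len(cols)),
                cv_press_numpy(*arrays, cidx, len(cols)), atol=1e-10)

    def test_kernel_press_matches_naive_per_fold_refits(self):
        rng = np.random.default_rng(10)
        n = 40
        X = rng.normal(size=(n, 5))
        y = X[:, 0] - X[:, 2] + 0.3 * rng.normal(size=n)
        folds = make_folds(n, 5, 1)
        arrays = _fold_arrays(X, y, folds)
        cols = np.array([0, 2, 3], dtype=np.int64)
        press = cv_press(*arrays, cols, 3)
        naive = np.zeros(3)
        for test_idx in folds:
            train = np.setdiff1d(np.arange(n), test_idx)
            for k in range(1, 4):
                m = fit_pls(X[np.ix_(train, cols)], y[train], k)
                pred = predict(m, X[np.ix_(test_idx, cols)])
                naive[k - 1] += np.sum((y[test_idx] - pred) ** 2)
        np.testing.assert_allclose(press, naive, atol=1e-9)


class TestScreening:
    def test_returns_all_when_fewer_than_requested(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.normal(size=(30, 6)),
                             columns=list("abcdef"))
        y = frame["a"] + 0.1 * rng.normal(size=30)
        names = screen_features(frame, y, n_top=20)
        assert len(names) == 6
        assert names[0] == "a"

    def test_planted_feature_ranked_first(self):
        rng = np.random.default_rng(12)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(rng.normal(size=(200, 30)),
                                 columns=[f"c{i:02d}" for i in range(30)])
            y = 3 * frame["c07"] + 0.5 * rng.normal(size=200)
            hits += screen_features(frame, y, n_top=5)[0] == "c07"
        assert hits >= 19

    def test_deterministic_tie_break_by_name(self):
        frame = pd.DataFrame({"b": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4]})
        y = np.array([1.0, 2, 3, 4])
        assert screen_features(frame, y, n_top=2) == ["a", "b"]


class TestSubsetSearch:
    def test_three_candidates_seven_subsets_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + 0.5 * X[:, 2] + 0.2 * rng.normal(size=50)
        model, trace = exhaustive_subset_search(X, y, ["f0", "f1", "f2"],
                                                n_folds=5, seed=0)
        assert trace.n_subsets_evaluated == 7

        # independent brute force via naive per-subset CV
        folds = make_folds(50, 5, 0)
        yte_all = np.concatenate([y[f] for f in folds])
        tss = sum(np.sum((y[f] - y[np.setdiff1d(np.arange(50), f)].mean())**2)
                  for f in folds)
        scored = []
        for size in (1, 2, 3):
            for combo in itertools.combinations(range(3), size):
                cols = np.asarray(combo)
                press_k = np.zeros(min(size, 10))
                for f in folds:
                    tr = np.setdiff1d(np.arange(50), f)
                    for k in range(1, len(press_k) + 1):
                        m = fit_pls(X[np.ix_(tr, cols)], y[tr], k)
                        pred = predict(m, X[np.ix_(f, cols)])
                        press_k[k - 1] += np.sum((y[f] - pred) ** 2)
                bic = _bic_from_press(press_k, 50)
                k_star = int(np.argmin(bic)) + 1
                cv_r2 = 1 - press_k[k_star - 1] / tss
                scored.append((cv_r2, size, tuple(f"f{i}" for i in combo)))
        top = max(s[0] for s in scored)
        best = min((s for s in scored if s[0] >= top - 0.002),
                   key=lambda s: (s[1], -s[0], s[2]))
        assert trace.best_subset == best[2]
        assert trace.best_criterion == pytest.approx(best[0], abs=1e-9)

    def test_single_candidate(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        model, trace = exhaustive_subset_search(X, y, ["only"], n_folds=5,
                                                seed=0)
        assert trace.n_subsets_evaluated == 1
        assert trace.best_subset == ("only",)

    def test_candidate_cap_enforced(self):
        X = np.random.default_rng(15).normal(size=(30, 5))
        with pytest.raises(ValueError, match="cap"):
            exhaustive_subset_search(X, X[:, 0], list("abcde"),
                                     max_candidates_cap=3)


class TestBuildScoreModel:
    def test_report_invariants_and_determinism(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        config = ModelingConfig(subset_cap=6, seed=5)
        completed, _ = complete_oculo_block(cohort, config)
        a = build_score_model(cohort, "SDMT", config=config,
                              completed=completed)
        b = build_score_model(cohort, "SDMT", config=config,
                              completed=completed)
        assert a.r2_adjusted <= a.r2_insample
        assert 1 <= len(a.selected_features) <= 6
        assert a.n_components <= len(a.selected_features)
        assert a.r2_insample == b.r2_insample
        assert a.selected_features == b.selected_features
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_include_age_adds_age_candidate(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        config = ModelingConfig(subset_cap=4, seed=2)
        completed, _ = complete_oculo_block(cohort, config)
        report = build_score_model(cohort, "SDMT", include_age=True,
                                   config=config, completed=completed)
        assert report.include_age
        # age is strongly coupled to SDMT in the generator, so the search
        # should retain it
        assert "age" in report.selected_features

    def test_outcome_with_too_few_rows_rejected(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        broken = cohort.frame.copy()
        broken.loc[broken.index[5:], "BAI"] = np.nan
        from oculopls.cohort import CohortTable
        small = CohortTable(broken, cohort.catalog)
        with pytest.raises(ValueError, match="BAI"):
            build_score_model(small, "BAI", config=ModelingConfig(seed=0))


class TestPredictedAge:
    def test_perfect_age_model_gives_identical_rhos(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        config = ModelingConfig(subset_cap=5, seed=1)
        completed, _ = complete_oculo_block(cohort, config)
        report = build_score_model(cohort, "Age", config=config,
                                   completed=completed)
        report.predictions["predicted"] = report.predictions["true"]
        table = predicted_age_analysis(cohort, report, ["SDMT", "TMTA"])
        for _, row in table.iterrows():
            assert row["rho_predicted_age"] == pytest.approx(
                row["rho_true_age"])

    def test_real_age_model_preserves_signs(self, hc_cohort_small):
        cohort, _, _ = hc_cohort_small
        config = ModelingConfig(subset_cap=8, seed=1)
        completed, _ = complete_oculo_block(cohort, config)
        report = build_score_model(cohort, "Age", config=config,
                                   completed=completed)
        table = predicted_age_analysis(cohort, report,
                                       ["SDMT", "TMTA", "HVLT"])
        strong = table[table["rho_true_age"].abs() > 0.2]
        assert (np.sign(strong["rho_predicted_age"])
                == np.sign(strong["rho_true_age"])).all()
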