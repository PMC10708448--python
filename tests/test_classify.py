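"""PLS/SVM binary learners, RMSEcv selection, and OVO soft voting."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hsisoa.classify import (
    REDUCED_GRID,
    SVMGrid,
    _pair_probability_matrix,
    binary_probability,
    ovo_train,
    pls_fit,
    pls_predict,
    predict,
    select_plsda,
    select_svm,
    soft_vote,
)
from hsisoa.preprocess import (
    SpectraTable,
    log_inverse,
    mean_center_apply,
    mean_center_fit,
    msc_apply,
    msc_fit,
)
from sklearn.cross_decomposition import PLSRegression


def _make_table(X, labels):
    n = len(labels)
    meta = pd.DataFrame(
        {
            "sample_id": [f"R1_s_{i:03d}" for i in range(n)],
            "treatment": labels,
            "soa": "x",
            "moa_group": "x",
            "dat": 1,
            "round": 1,
            "outlier": False,
        }
    )
    return SpectraTable(X=X, wavelengths=np.linspace(460, 975, X.shape[1]), meta=meta)


def _two_class_reflectance(rng, n_per=10, n_bands=25, gap=0.15):
    """Wide-margin reflectance-like data: class 1 has a bump in mid-spectrum."""
    base = 0.3 + 0.2 * rng.random(n_bands)
    X0 = base + 0.005 * rng.standard_normal((n_per, n_bands))
    bump = np.zeros(n_bands)
    bump[10:15] = gap
    X1 = base + bump + 0.005 * rng.standard_normal((n_per, n_bands))
    X = np.clip(np.vstack([X0, X1]), 0.01, 0.99)
    y = np.array([0] * n_per + [1] * n_per)
    return X, y


class TestPLS:
    def test_rank_one_exact_fit(self, rng):
        y = rng.random(12)
        X = np.column_stack([2.0 * y])
        model = pls_fit(X, y, n_lv=1)
        np.testing.assert_allclose(pls_predict(model, X), y, atol=1e-8)

    def test_full_rank_equals_least_squares_oracle(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        model = pls_fit(X, y, n_lv=4)
        Xc = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(pls_predict(model, X), Xc @ beta, atol=1e-8)

    def test_n_lv_exceeding_rank_raises(self, rng):
        X = np.tile(rng.standard_normal((10, 1)), (1, 3))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            pls_fit(X, rng.random(10), n_lv=2)

    def test_sample_order_invariance(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        perm = rng.permutation(15)
        a = pls_fit(X, y, 3)
        b = pls_fit(X[perm], y[perm], 3)
        test = rng.standard_normal((4, 6))
        np.testing.assert_allclose(pls_predict(a, test), pls_predict(b, test), atol=1e-10)


class TestSelectPLSDA:
    def test_single_informative_direction_selects_one_lv(self):
        picks = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            y = np.array([0] * 12 + [1] * 12)
            direction = g.standard_normal(10)
            X = np.outer(y - 0.5, direction) + 0.05 * g.standard_normal((24, 10))
            model = select_plsda(X, y, preprocess=False)
            picks.append(model.n_lv)
        assert np.mean(np.array(picks) == 1) >= 0.9

    def test_rmsecv_matches_brute_force_loo_oracle(self, rng):
        X, y = _two_class_reflectance(rng, n_per=6, n_bands=12)
        model = select_plsda(X, y)
        # independent oracle: explicit refit per fold using the public chain ops
        best = (None, np.inf)
        for n_lv in (1, 2, 3):
            errs = []
            for i in range(len(X)):
                tr = np.arange(len(X)) != i
                A = log_inverse(X)
                ref = msc_fit(A[tr])
                Ztr = msc_apply(A[tr], ref)
                zte = msc_apply(A[i][None, :], ref)
                mu = mean_center_fit(Ztr)
                pls = PLSRegression(n_components=n_lv, scale=False)
                pls.fit(mean_center_apply(Ztr, mu), y[tr].astype(float))
                pred = np.clip(pls.predict(mean_center_apply(zte, mu)).ravel()[0], 0, 1)
                errs.append((pred - y[i]) ** 2)
            rmse = float(np.sqrt(np.mean(errs)))
            if rmse < best[1] - 1e-12:
                best = (n_lv, rmse)
        assert model.n_lv == best[0]
        assert model.rmsecv == pytest.approx(best[1], abs=1e-10)

    def test_three_samples_still_runs(self, rng):
        X = 0.2 + 0.6 * rng.random((3, 8))
        y = np.array([0, 1, 1])
        model = select_plsda(X, y)
        assert model.n_lv == 1
        assert model.cv_probabilities.shape == (3,)


class TestSelectSVM:
    def test_grid_size_from_config(self):
        assert len(SVMGrid().candidates()) == 6 + 36
        assert len(REDUCED_GRID.candidates()) == 3 + 9

    def test_wide_margin_data_reaches_loo_accuracy_one(self, rng):
        X, y = _two_class_reflectance(rng)
        model = select_svm(X, y, grid=REDUCED_GRID)
        assert np.all((model.cv_probabilities > 0.5) == (y == 1))

    def test_tie_break_prefers_linear_then_small_c(self, rng):
        X, y = _two_class_reflectance(rng)
        model = select_svm(X, y, grid=REDUCED_GRID)
        # on cleanly separable data many candidates tie; the earliest wins
        assert model.kernel in ("linear", "rbf")
        rerun = select_svm(X, y, grid=REDUCED_GRID)
        assert (model.kernel, model.C, model.gamma) == (rerun.kernel, rerun.C, rerun.gamma)

    def test_single_class_raises(self, rng):
        X = rng.random((6, 5))
        with pytest.raises(ValueError, match="both classes"):
            select_svm(X, np.zeros(6, dtype=int), grid=REDUCED_GRID)

    def test_calibrated_probability_monotone_in_margin(self, rng):
        X, y = _two_class_reflectance(rng)
        model = select_svm(X, y, grid=REDUCED_GRID)
        grid_points = np.clip(
            0.3 + 0.2 * rng.random((40, X.shape[1])), 0.01, 0.99
        )
        from hsisoa.preprocess import preprocess_chain_apply

        Z = preprocess_chain_apply(grid_points, model.chain)
        f = model.svc.decision_function(Z)
        p = binary_probability(model, Z)
        order = np.argsort(f)
        assert np.all(np.diff(p[order]) >= -1e-12)


class TestBinaryProbability:
    def test_pls_probability_is_clipped_prediction(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20) * 2.0  # continuous, forces out-of-range preds
        model = pls_fit(X, y, 3)
        raw = pls_predict(model, X)
        p = binary_probability(model, X)
        np.testing.assert_allclose(p, np.clip(raw, 0.0, 1.0))
        assert raw.max() > 1.0 or raw.min() < 0.0  # clipping actually exercised


class TestSoftVote:
    def test_hand_worked_example(self):
        probs = {("A", "B"): 0.9, ("A", "C"): 0.8, ("B", "C"): 0.6}
        winner, averages = soft_vote(probs, class_order=["A", "B", "C"])
        assert averages["A"] == pytest.approx(0.85)
        assert averages["B"] == pytest.approx(0.35)
        assert averages["C"] == pytest.approx(0.30)
        assert winner == "A"

    def test_all_half_ties_to_first_in_order(self):
        probs = {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}
        winner, _ = soft_vote(probs, class_order=["B", "A", "C"])
        assert winner == "B"

    def test_two_class_case(self):
        winner, averages = soft_vote({("UTC", "Paraquat"): 0.3}, class_order=["UTC", "Paraquat"])
        assert winner == "Paraquat"
        assert averages == {"UTC": 0.3, "Paraquat": 0.7}


class TestOVO:
    def _study_table(self, rng, classes, n_per=6, n_bands=20):
        centers = {c: i for i, c in enumerate(classes)}
        rows, labels = [], []
        base = 0.3 + 0.2 * rng.random(n_bands)
        for c in classes:
            bump = np.zeros(n_bands)
            bump[2 * centers[c] : 2 * centers[c] + 2] = 0.2
            for _ in range(n_per):
                rows.append(np.clip(base + bump + 0.004 * rng.standard_normal(n_bands), 0.01, 0.99))
                labels.append(c)
        return _make_table(np.vstack(rows), labels)

    def test_nine_classes_make_36_models(self, rng):
        classes = ["UTC", "Atrazine", "Dinoseb", "Flumioxazin", "Paraquat",
                   "Glyphosate", "Glufosinate", "Chlorimuron", "Indaziflam"]
        table = self._study_table(rng, classes, n_per=3)
        ens = ovo_train(table, learner="plsda")
        assert len(ens.models) == 36
        appearances = {c: 0 for c in classes}
        for a, b in ens.models:
            appearances[a] += 1
            appearances[b] += 1
        assert all(v == 8 for v in appearances.values())

    def test_two_classes_single_model(self, rng):
        table = self._study_table(rng, ["UTC", "Paraquat"])
        ens = ovo_train(table, learner="plsda")
        assert len(ens.models) == 1

    def test_small_class_raises_with_name(self, rng):
        table = self._study_table(rng, ["UTC", "Paraquat"])
        keep = ~(table.meta["treatment"].eq("Paraquat") & (table.meta.index > 6))
        clipped = table.select(keep.to_numpy())
        with pytest.raises(ValueError, match="Paraquat"):
            ovo_train(clipped, learner="plsda")

    def test_training_rows_classified_perfectly_on_wide_margin_data(self, rng):
        table = self._study_table(rng, ["UTC", "Atrazine", "Paraquat"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = ovo_train(table, learner="svm", grid=REDUCED_GRID)
        labels, probs = predict(ens, table)
        assert (labels == table.meta["treatment"].to_numpy()).mean() == 1.0
        assert np.all((probs.values >= 0) & (probs.values <= 1))

    def test_duplicated_row_predicts_identically(self, rng):
        table = self._study_table(rng, ["UTC", "Atrazine"])
        ens = ovo_train(table, learner="plsda")
        row = table.X[3]
        labels, probs = predict(ens, np.vstack([row, row]))
        assert labels[0] == labels[1]
        np.testing.assert_array_equal(probs.iloc[0].values, probs.iloc[1].values)

    def test_predict_averages_match_manual_soft_vote(self, rng):
        """The vectorized ensemble prediction equals per-row soft_vote calls."""
        table = self._study_table(rng, ["UTC", "Atrazine", "Paraquat"])
        ens = ovo_train(table, learner="plsda")
        pair_probs = _pair_probability_matrix(ens, table.X[:4])
        labels, probs = predict(ens, table.X[:4])
        for i in range(4):
            row_probs = {pair: 1.0 - p[i] for pair, p in pair_probs.items()}
            winner, averages = soft_vote(row_probs, class_order=ens.classes)
            assert winner == labels[i]
            for c in ens.classes:
                assert probs.loc[i, c] == pytest.approx(averages[c], abs=1e-12)

    def test_unknown_learner_rejected(self, rng):
        table = self._study_table(rng, ["UTC", "Atrazine"])
        with pytest.raises(ValueError, match="learner"):
            ovo_train(table, learner="forest")

    @pytest.mark.parametrize("learner", ["plsda", "svm"])
    def test_saved_bundle_predicts_identically(self, rng, tmp_path, learner):
        """Serialized model bundles reproduce the original predictions exactly."""
        from hsisoa.classify import load_ensemble, save_ensemble

        table = self._study_table(rng, ["UTC", "Atrazine", "Paraquat"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = ovo_train(table, learner=learner, grid=REDUCED_GRID)
        save_ensemble(ens, str(tmp_path / "model"))
        back = load_ensemble(str(tmp_path / "model"))
        assert back.classes == ens.classes and len(back.models) == 3
        labels_a, probs_a = predict(ens, table)
        labels_b, probs_b = predict(back, table)
        np.testing.assert_array_equal(labels_a, labels_b)
        np.testing.assert_allclose(probs_a.values, probs_b.values, atol=1e-10)
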