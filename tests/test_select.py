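"""Sparse-logistic core: objective-level oracles, CV penalty selection,
bootstrap reliability, and baselines."""

import numpy as np
import pytest
from scipy import optimize

from mavenpy import (
    PhenotypeTable,
    RegionSignalMatrix,
    accuracy,
    baseline_comparison,
    bootstrap_lasso,
    fit_lasso,
    fit_lasso_cv,
    predict,
    refit_excluding,
    select_lambda_cv,
    synthetic,
)
from mavenpy import _glm
from mavenpy.errors import SingleClassError, UnknownRegionError, ValidationError
from mavenpy.select import _standardize


def make_dataset(n, betas, intercept=0.0, seed=0, n_noise=0):
    """Logistic data with known standardized-scale coefficients."""
    rng = np.random.default_rng(seed)
    p = len(betas) + n_noise
    X = rng.normal(size=(n, p))
    eta = intercept + X[:, : len(betas)] @ np.asarray(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    m = RegionSignalMatrix.from_arrays(
        [f"s{i:03d}" for i in range(n)], [f"r{j:02d}" for j in range(p)], X
    )
    t = PhenotypeTable.from_arrays(m.subjects, y)
    return m, t


class TestFitLasso:
    def test_huge_penalty_kills_all_slopes(self):
        m, y = make_dataset(40, [1.5, -1.0], seed=1)
        model = fit_lasso(m, y, 1e6)
        np.testing.assert_array_equal(model.coef, 0.0)
        phat = y.phenotype.mean()
        assert model.intercept == pytest.approx(np.log(phat / (1 - phat)), abs=1e-6)
        assert model.selected_regions == []

    def test_zero_penalty_matches_newton_mle_oracle(self):
        m, y = make_dataset(30, [1.0, -0.8], seed=2)
        model = fit_lasso(m, y, 0.0)
        # independent oracle: statsmodels Newton MLE on the standardized design
        import statsmodels.api as sm

        Xs, _, _ = _standardize(m.values)
        fit = sm.Logit(y.phenotype, sm.add_constant(Xs)).fit(disp=0, method="newton")
        assert model.intercept == pytest.approx(fit.params[0], abs=1e-4)
        np.testing.assert_allclose(model.coef, fit.params[1:], atol=1e-4)

    def test_mid_path_objective_matches_grid_polish_oracle(self):
        """Feature A has a real effect, B is noise; at a mid-path penalty the
        fit zeros B, keeps A positive, and attains the global optimum of the
        3-parameter objective within 1e-6."""
        m, y = make_dataset(40, [2.0], seed=3, n_noise=1)
        Xs, _, _ = _standardize(m.values)
        yy = y.phenotype.astype(float)
        lam = 0.5 * _glm.lambda_max(Xs, yy)
        model = fit_lasso(m, y, lam)
        assert model.coef[1] == 0.0
        assert model.coef[0] > 0.0
        want = grid_polish_oracle(Xs, yy, lam)
        got = _glm.logistic_objective(Xs, yy, model.intercept, model.coef, lam)
        assert got <= want + 1e-6

    def test_single_class_rejected(self):
        m, _ = make_dataset(20, [1.0], seed=4)
        y = PhenotypeTable.from_arrays(m.subjects, np.zeros(20, dtype=int))
        with pytest.raises(SingleClassError):
            fit_lasso(m, y, 0.1)

    def test_negative_penalty_rejected(self):
        m, y = make_dataset(20, [1.0], seed=4)
        with pytest.raises(ValidationError):
            fit_lasso(m, y, -0.1)

    def test_destandardized_prediction_equals_standardized(self):
        m, y = make_dataset(30, [1.2, -0.5], seed=5)
        model = fit_lasso(m, y, 0.02)
        Xraw = m.values
        b0_raw, b_raw = model.raw_coefficients()
        eta_raw = b0_raw + Xraw @ b_raw
        np.testing.assert_allclose(eta_raw, model.decision_function(Xraw), atol=1e-10)

    def test_matches_sklearn_saga_cross_check(self):
        """Independent solver route: sklearn's saga at tight tolerance
        reaches the same objective value."""
        from sklearn.linear_model import LogisticRegression

        m, y = make_dataset(50, [1.5, -1.0, 0.0], seed=6, n_noise=3)
        Xs, _, _ = _standardize(m.values)
        yy = y.phenotype.astype(float)
        lam = 0.05
        model = fit_lasso(m, y, lam)
        clf = LogisticRegression(
            solver="saga", l1_ratio=1.0, C=1 / (len(yy) * lam),
            max_iter=200_000, tol=1e-12,
        ).fit(Xs, yy)
        obj_mine = _glm.logistic_objective(Xs, yy, model.intercept, model.coef, lam)
        obj_sk = _glm.logistic_objective(Xs, yy, clf.intercept_[0], clf.coef_[0], lam)
        assert obj_mine == pytest.approx(obj_sk, abs=1e-8)


def grid_polish_oracle(Xs, yy, lam, span=4.0, steps=33):
    """Dense grid over (b0, b1, b2) followed by Nelder-Mead polish."""
    best, best_obj = None, np.inf
    grid = np.linspace(-span, span, steps)
    for b0 in grid:
        for b1 in grid:
            for b2 in grid:
                obj = _glm.logistic_objective(Xs, yy, b0, np.array([b1, b2]), lam)
                if obj < best_obj:
                    best, best_obj = (b0, b1, b2), obj
    res = optimize.minimize(
        lambda t: _glm.logistic_objective(Xs, yy, t[0], t[1:], lam),
        np.array(best),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    return min(best_obj, float(res.fun))


class TestSolutionPath:
    @pytest.mark.parametrize("seed", range(4))
    def test_kkt_optimality_at_every_path_point(self, seed):
        """Every point of the warm-started path satisfies the lasso KKT
        conditions: |score_j| <= lam for zeroed coordinates, score_j equal to
        -lam*sign(beta_j) for active ones, zero score for the intercept."""
        m, y = make_dataset(50, [2.0, -1.5, 1.0], seed=seed, n_noise=17)
        Xs, _, _ = _standardize(m.values)
        yy = y.phenotype.astype(float)
        grid = _glm.default_lambda_grid(Xs, yy, n_lambdas=30)
        b0s, betas = _glm.lasso_path(Xs, yy, grid)
        n = len(yy)
        for lam, b0, b in zip(grid, b0s, betas):
            prob = 1 / (1 + np.exp(-(b0 + Xs @ b)))
            score = Xs.T @ (yy - prob) / n  # negative objective gradient
            tol = 1e-5 * max(1.0, lam)
            assert abs((yy - prob).mean()) < tol
            zero = b == 0
            assert (np.abs(score[zero]) <= lam + tol).all()
            active = ~zero
            np.testing.assert_allclose(
                score[active], lam * np.sign(b[active]), atol=tol
            )

    def test_support_grows_from_empty_along_path(self):
        """At lambda_max the model is intercept-only; the support broadly
        grows as the penalty relaxes (occasional single-coefficient drop
        events are genuine lasso behavior, so only the trend is asserted)."""
        m, y = make_dataset(50, [2.0, -1.5, 1.0], seed=0, n_noise=17)
        Xs, _, _ = _standardize(m.values)
        yy = y.phenotype.astype(float)
        grid = _glm.default_lambda_grid(Xs, yy, n_lambdas=30)
        _, betas = _glm.lasso_path(Xs, yy, grid)
        nnz = (betas != 0).sum(axis=1)
        assert nnz[0] == 0
        assert nnz[-1] == nnz.max()
        assert (np.diff(nnz) >= -1).all()


class TestSelectLambdaCV:
    def test_pure_noise_yields_all_zero_model(self):
        rng = np.random.default_rng(10)
        m = RegionSignalMatrix.from_arrays(
            [f"s{i}" for i in range(50)],
            [f"r{j}" for j in range(30)],
            rng.normal(size=(50, 30)),
        )
        y = PhenotypeTable.from_arrays(m.subjects, rng.integers(0, 2, 50))
        model = fit_lasso_cv(m, y, seed=0)
        assert model.selected_regions == []

    def test_dominant_predictor_selected_across_seeds(self):
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            m, y = make_dataset(50, [3.0], seed=100 + s, n_noise=9)
            model = fit_lasso_cv(m, y, seed=s)
            hits += "r00" in model.selected_regions
        assert hits >= int(0.95 * n_rep)

    def test_grid_of_length_one(self):
        m, y = make_dataset(30, [1.0], seed=11)
        lam = select_lambda_cv(m, y, grid=np.array([0.07]), seed=0)
        assert lam == 0.07

    def test_minority_class_too_small_for_folds(self):
        m, _ = make_dataset(20, [1.0], seed=12)
        y = PhenotypeTable.from_arrays(
            m.subjects, np.array([1, 1, 1] + [0] * 17)
        )
        with pytest.raises(SingleClassError):
            select_lambda_cv(m, y, n_folds=5)

    def test_one_se_picks_larger_lambda_than_min(self):
        m, y = make_dataset(60, [1.5, -1.0], seed=13, n_noise=8)
        lam_min = select_lambda_cv(m, y, rule="min", seed=0)
        lam_1se = select_lambda_cv(m, y, rule="one_se", seed=0)
        assert lam_1se >= lam_min


class TestPredictAccuracy:
    def test_null_model_predicts_half(self):
        m, y = make_dataset(20, [1.0], seed=20)
        model = fit_lasso(m, y, 1e6)
        model.intercept = 0.0
        prob, cls = predict(model, m)
        np.testing.assert_array_equal(prob, 0.5)

    def test_unpenalized_training_accuracy_beats_threshold_oracle(self):
        """Training accuracy of the full-likelihood fit is at least that of
        the best single-feature threshold rule on the same data."""
        m, y = make_dataset(30, [1.8, 1.2], seed=21)
        model = fit_lasso(m, y, 0.0)
        acc = accuracy(model, m, y)
        assert acc >= exhaustive_threshold_oracle(m.values, y.phenotype)

    def test_permuted_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(22)
        accs = []
        for s in range(20):
            m, y = make_dataset(50, [2.0], seed=300 + s)
            perm = rng.permutation(50)
            y_perm = PhenotypeTable.from_arrays(
                m.subjects, y.phenotype[perm]
            )
            model = fit_lasso_cv(m, y_perm, seed=s)
            accs.append(accuracy(model, m, y_perm))
        # chance level is the majority-class rate; with n=50 per experiment
        # the mean over 20 experiments stays within a few percent of it
        base = np.mean(
            [max(np.bincount(make_dataset(50, [2.0], seed=300 + s)[1].phenotype)) / 50
             for s in range(20)]
        )
        assert abs(np.mean(accs) - base) < 0.08

    def test_missing_region_column(self):
        m, y = make_dataset(20, [1.0], seed=23)
        model = fit_lasso(m, y, 0.1)
        with pytest.raises(UnknownRegionError):
            predict(model, m.drop_regions(["r00"]))


def exhaustive_threshold_oracle(X, y):
    """Best training accuracy of any rule 1{x_j > t} or 1{x_j < t}."""
    best = max(np.mean(y == 0), np.mean(y == 1))
    for j in range(X.shape[1]):
        for t in np.unique(X[:, j]):
            for rule in ((X[:, j] > t), (X[:, j] < t)):
                best = max(best, np.mean(rule.astype(int) == y))
    return best


class TestRefitExcluding:
    def test_empty_drop_is_identity(self):
        m, y = make_dataset(40, [1.5, -1.0], seed=30, n_noise=3)
        a = fit_lasso_cv(m, y, seed=7)
        b = refit_excluding(m, y, [], seed=7)
        assert a.lam == b.lam
        np.testing.assert_allclose(b.coef, a.coef, atol=1e-12)

    def test_drop_all_but_one(self):
        m, y = make_dataset(40, [2.0], seed=31, n_noise=2)
        model = refit_excluding(m, y, ["r01", "r02"], lam=0.05)
        assert model.region_ids == ["r00"]
        assert set(model.selected_regions) <= {"r00"}

    def test_drop_everything_rejected(self):
        m, y = make_dataset(20, [1.0], seed=32)
        with pytest.raises(ValidationError):
            refit_excluding(m, y, m.regions)

    def test_proxy_promoted_when_causal_dropped(self):
        """With the causal region omitted, its r~0.8 proxy becomes the top
        selected region in most replicates."""
        promoted = 0
        n_rep = 15
        for s in range(n_rep):
            m, y, _ = synthetic.simulate_matrix(synthetic.default_config(seed=700 + s))
            model = refit_excluding(m, y, ["region_017"], seed=s)
            promoted += model.top_region == "region_042"
        assert promoted >= int(0.8 * n_rep)


class TestBootstrap:
    def test_same_seed_identical_reports(self):
        m, y, _ = synthetic.simulate_matrix(
            synthetic.default_config(seed=40, n_regions=40, causal_region=10, proxy_region=30)
        )
        r1 = bootstrap_lasso(m, y, n_models=8, seed=99)
        r2 = bootstrap_lasso(m, y, n_models=8, seed=99)
        assert r1.to_dict() == r2.to_dict()

    def test_accurate_flag_contract_and_count_bounds(self):
        m, y, _ = synthetic.simulate_matrix(
            synthetic.default_config(seed=41, n_regions=40, causal_region=10, proxy_region=30)
        )
        rep = bootstrap_lasso(m, y, n_models=12, seed=5)
        np.testing.assert_array_equal(
            rep.accurate, (rep.train_accuracy > 0.5) & (rep.test_accuracy > 0.5)
        )
        assert rep.positive_counts.max(initial=0) <= rep.n_accurate
        assert rep.negative_counts.max(initial=0) <= rep.n_accurate

    def test_planted_signs_top_frequency_tables(self):
        """A planted positive-effect region and a planted negative-effect
        region top the respective signed-frequency tables."""
        hits_pos = hits_neg = 0
        n_rep = 5
        for s in range(n_rep):
            cfg = synthetic.default_config(
                seed=800 + s, n_regions=60,
                causal_region=10, proxy_region=50,
                causal_effects={10: 3.0, 30: -3.0},
            )
            m, y, _ = synthetic.simulate_matrix(cfg)
            rep = bootstrap_lasso(m, y, n_models=30, seed=s)
            table = rep.frequency_table()
            top_pos = max(table, key=lambda d: d["positive"])
            top_neg = max(table, key=lambda d: d["negative"])
            hits_pos += top_pos["region_id"] == "region_010"
            hits_neg += top_neg["region_id"] == "region_030"
        assert hits_pos >= 4
        assert hits_neg >= 4

    def test_bad_train_fraction(self):
        m, y, _ = synthetic.simulate_matrix(
            synthetic.default_config(seed=42, n_regions=10, causal_region=2, proxy_region=7)
        )
        with pytest.raises(ValidationError):
            bootstrap_lasso(m, y, train_fraction=1.5)


class TestBaselines:
    def test_single_boot_shapes(self):
        m, y = make_dataset(40, [1.0], seed=50, n_noise=4)
        rep = baseline_comparison(m, y, "r00", n_boot=1, seed=0)
        assert set(rep.accuracies) == {"brain_average", "focal", "both"}
        assert all(len(v) == 1 for v in rep.accuracies.values())

    def test_focal_beats_brain_average_when_phenotype_is_focal_driven(self):
        wins = 0
        n_rep = 6
        for s in range(n_rep):
            m, y, _ = synthetic.simulate_matrix(
                synthetic.default_config(seed=900 + s, n_regions=60, causal_region=17, proxy_region=50, causal_effect=3.0)
            )
            rep = baseline_comparison(m, y, "region_017", n_boot=40, seed=s)
            focal_wins = rep.mean("focal") > rep.mean("brain_average")
            no_gain = rep.mean("both") <= rep.mean("focal") + rep.sem("focal")
            wins += focal_wins and no_gain
        assert wins >= 5

    def test_noise_phenotype_all_near_chance(self):
        rng = np.random.default_rng(51)
        m, _, _ = synthetic.simulate_matrix(
            synthetic.default_config(seed=52, n_regions=40, causal_region=10, proxy_region=30, causal_effects={})
        )
        y = PhenotypeTable.from_arrays(m.subjects, rng.integers(0, 2, 50))
        rep = baseline_comparison(m, y, "region_000", n_boot=60, seed=1)
        for name in rep.accuracies:
            assert abs(rep.mean(name) - 0.5) < 0.12

    def test_unknown_focal(self):
        m, y = make_dataset(20, [1.0], seed=53)
        with pytest.raises(UnknownRegionError):
            baseline_comparison(m, y, "nope")
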