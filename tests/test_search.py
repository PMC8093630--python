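import numpy as np
import pandas as pd
import pytest

import _oracles as oracle

from pcrad.search import (
    ExhaustiveSubsetSearch,
    FitResult,
    ModelSpec,
    VariableGroup,
    aggregate_coefficients,
    cv_scores,
    encode_dummies,
    evaluate_model,
    run_group_search,
    standard_groups,
    tune_hyperparameters,
)
from pcrad.synthetic import SyntheticConfig, OutcomeModel, generate_cohort

TABLE2_DUMMIES = ["Grade_3", "HER2", "Shape_I", "Shape_O", "Margin_I",
                  "IntEnh_E", "IntEnh_O", "Curve_III", "Type_MC", "Type_MF"]


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SyntheticConfig(seed=31))


class TestEncodeDummies:
    def test_reproduces_published_design_column_names(self, cohort):
        design, name_map = encode_dummies(cohort.drop(columns=["pCR"]))
        for d in TABLE2_DUMMIES:
            assert d in design.columns
        assert len(design.columns) == 21  # 11 continuous + 10 dummies

    def test_reference_levels_encode_to_zero(self):
        table = pd.DataFrame({"Grade": ["2", "2"], "Shape": ["R", "I"],
                              "HER2": ["Neg", "Pos"]})
        design, _ = encode_dummies(table)
        assert design["Grade_3"].tolist() == [0.0, 0.0]
        assert design.loc[0, ["Shape_I", "Shape_O"]].tolist() == [0.0, 0.0]
        assert design["HER2"].tolist() == [0.0, 1.0]

    def test_unseen_level_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            encode_dummies(pd.DataFrame({"Shape": ["I", "X"]}))

    def test_name_map_groups_dummies(self, cohort):
        _, name_map = encode_dummies(cohort.drop(columns=["pCR"]))
        assert name_map["Shape"] == ["Shape_I", "Shape_O"]
        assert name_map["Age"] == ["Age"]


class TestCvScores:
    def test_loo_scores_every_subject_once(self, cohort):
        design, nm = encode_dummies(cohort.drop(columns=["pCR"]))
        X = design[["Ki67", "ER"]].to_numpy()
        y = cohort["pCR"].to_numpy(float)
        scores = cv_scores(X, y, "logit", "loo", seed=0)
        assert scores.shape == (60,)
        assert np.all((scores > 0) & (scores < 1))

    def test_30fold_partition_deterministic(self, cohort):
        design, _ = encode_dummies(cohort.drop(columns=["pCR"]))
        X = design[["Ki67", "ER"]].to_numpy()
        y = cohort["pCR"].to_numpy(float)
        s1 = cv_scores(X, y, "logit", "30fold", seed=5)
        s2 = cv_scores(X, y, "logit", "30fold", seed=5)
        assert np.array_equal(s1, s2)
        s3 = cv_scores(X, y, "logit", "30fold", seed=6)
        assert not np.array_equal(s1, s3)

    def test_logit_matches_sklearn_per_fold_oracle(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 2))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0], dtype=float)
        ours = cv_scores(X, y, "logit", "loo", seed=0)
        for i in range(10):
            tr = np.arange(10) != i
            sc = StandardScaler().fit(X[tr])
            m = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10_000,
                                   tol=1e-12).fit(sc.transform(X[tr]), y[tr])
            ref = m.predict_proba(sc.transform(X[i : i + 1]))[0, 1]
            assert ours[i] == pytest.approx(ref, abs=1e-6)

    @pytest.mark.parametrize("classifier", ["svr", "rf"])
    def test_sklearn_classifiers_produce_scores(self, cohort, classifier):
        design, _ = encode_dummies(cohort.drop(columns=["pCR"]))
        X = design[["Ki67", "ER", "F2"]].to_numpy()
        y = cohort["pCR"].to_numpy(float)
        hyper = {"cost": 1.0} if classifier == "svr" else {"n_trees": 50}
        s = cv_scores(X, y, classifier, "30fold", seed=0, hyperparameters=hyper)
        assert s.shape == (60,)
        assert np.isfinite(s).all()


class TestTuneHyperparameters:
    def test_grid_of_one_and_duplicates(self, cohort):
        g = standard_groups()["Hist"]
        assert tune_hyperparameters(cohort, g, "svr", grid=[0.5]) == {"cost": 0.5}
        a = tune_hyperparameters(cohort, g, "rf", grid=[25, 25, 50])
        b = tune_hyperparameters(cohort, g, "rf", grid=[25, 50])
        assert a == b

    def test_logit_has_no_hyperparameters(self, cohort):
        assert tune_hyperparameters(cohort, standard_groups()["Hist"], "logit") == {}

    def test_argmax_recheck_on_small_grid(self, cohort):
        from pcrad import roc
        from pcrad.search import _design_for_subset

        g = standard_groups()["Hist"]
        grid = [10, 100]
        chosen = tune_hyperparameters(cohort, g, "rf", seed=0, grid=grid)["n_trees"]
        design, nm = encode_dummies(cohort.drop(columns=["pCR"]))
        X = _design_for_subset(design, nm, g.members)
        y = cohort["pCR"].to_numpy(float)
        aucs = {v: roc.auc(cv_scores(X, y, "rf", "loo", 0, {"n_trees": v}), y) for v in grid}
        assert aucs[chosen] == max(aucs.values())


class TestEvaluateModel:
    def test_auc_mean_definition_and_separating_covariate(self, cohort):
        table = cohort.copy()
        table["oracle_score"] = table["pCR"] * 2.0 + np.linspace(0, 1, 60)
        perf = evaluate_model(ModelSpec("logit", ("oracle_score",)), table, seed=0)
        assert perf.auc_mean == pytest.approx((perf.auc_loo + perf.auc_30fold) / 2)
        assert perf.auc_loo == 1.0

    def test_null_calibration(self):
        # outcome-independent random scores are calibrated at AUC 0.5; pooled
        # cross-validated scores of a refit null model are pessimistic (the
        # held-out subject is anti-predicted), so the CV estimate must not be
        # optimistic under the null
        from pcrad import roc

        raw_aucs, cv_aucs = [], []
        for seed in range(60):
            rng = np.random.default_rng(7000 + seed)
            y = np.array([1] * 13 + [0] * 27)
            raw_aucs.append(roc.auc(rng.normal(size=40), y))
            table = pd.DataFrame({"x": rng.normal(size=40), "pCR": y})
            cv_aucs.append(evaluate_model(ModelSpec("logit", ("x",)), table, seed=seed).auc_mean)
        assert np.mean(raw_aucs) == pytest.approx(0.5, abs=0.03)
        assert np.mean(cv_aucs) < 0.5


class TestGroupSearch:
    def test_three_covariates_give_seven_subsets(self, cohort):
        rep = run_group_search(cohort, VariableGroup("toy", ("Age", "Ki67", "ER")),
                               classifier="logit", seed=0)
        assert rep.n_evaluated == 7
        assert not rep.truncated
        subsets = {s.subset for s, _ in rep.models}
        assert len(subsets) == 7

    def test_always_included_covariate_has_frequency_one(self, cohort):
        table = cohort.copy()
        table["strong"] = table["pCR"] * 3.0 + np.random.default_rng(0).normal(0, 0.3, 60)
        # 4-covariate group: 8 of 15 subsets contain "strong", so all six best
        # models can (and must) include the separating covariate
        rep = run_group_search(table, VariableGroup("toy", ("strong", "Age", "ADC", "PET_SUV")),
                               classifier="logit", seed=0)
        assert rep.frequency["strong"] == 1.0

    def test_ranking_is_permutation_and_best6_is_head(self, cohort):
        rep = run_group_search(cohort, standard_groups()["Hist"], seed=0)
        assert rep.n_evaluated == 15
        aucs = [p.auc_mean for _, p in rep.models]
        assert aucs == sorted(aucs, reverse=True)
        assert rep.best6 == rep.models[:6]
        assert all(0 <= f <= 1 for f in rep.frequency.values())

    def test_subset_cap_samples_and_flags_truncation(self, cohort):
        rep = run_group_search(cohort, standard_groups()["Hist"], seed=0, subset_cap=5)
        assert rep.truncated and rep.n_evaluated == 5
        rep2 = run_group_search(cohort, standard_groups()["Hist"], seed=0, subset_cap=5)
        assert [s.subset for s, _ in rep.models] == [s.subset for s, _ in rep2.models]

    def test_bh_adjustment_spans_the_whole_run(self, cohort):
        rep = run_group_search(cohort, VariableGroup("toy", ("Age", "ADC", "PET_SUV")), seed=0)
        raw = [p.p_raw for _, p in rep.models]
        adj = [p.p_adj for _, p in rep.models]
        assert np.allclose(adj, oracle.bh_adjust(raw), atol=1e-12)

    def test_informative_covariates_beat_nulls_in_best6(self):
        wins = 0
        for seed in range(8):
            cfg = SyntheticConfig(
                n_responders=40, n_nonresponders=60,
                continuous_spec={f"x{i}": {"responder": (0, 1), "nonresponder": (0, 1)}
                                 for i in range(8)},
                categorical_spec={},
                outcome_model=OutcomeModel(0.0, {"x0": 1.5, "x1": -1.5}),
                seed=9000 + seed,
            )
            table = generate_cohort(cfg)
            rep = run_group_search(table, VariableGroup("toy", tuple(f"x{i}" for i in range(8))),
                                   classifier="logit", seed=seed)
            informative = np.mean([rep.frequency["x0"], rep.frequency["x1"]])
            null = np.mean([rep.frequency[f"x{i}"] for i in range(2, 8)])
            wins += informative > null
        assert wins >= 6

    def test_empty_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            VariableGroup("empty", ())


class TestAggregateCoefficients:
    def test_single_and_equal_fits(self):
        one = FitResult(("a",), np.array([2.0]), np.array([1.0]), True)
        assert aggregate_coefficients([one])["a"] == pytest.approx(2.0)
        two = [FitResult(("a",), np.array([1.0]), np.array([1.0]), True)] * 2
        assert aggregate_coefficients(two)["a"] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, rng):
        fits = []
        for _ in range(20):
            names = tuple(rng.choice(["a", "b", "c"], size=rng.integers(1, 4), replace=False))
            fits.append(FitResult(names, rng.normal(size=len(names)),
                                  rng.uniform(0.2, 2.0, len(names)), True))
        got = aggregate_coefficients(fits)
        for name in got:
            num = sum(f.coefficients[f.names.index(name)] / f.standard_errors[f.names.index(name)] ** 2
                      for f in fits if name in f.names)
            den = sum(1.0 / f.standard_errors[f.names.index(name)]
                      for f in fits if name in f.names)
            assert got[name] == pytest.approx(num / den, rel=1e-12)

    def test_inverse_variance_variant(self):
        fits = [FitResult(("a",), np.array([1.0]), np.array([0.5]), True),
                FitResult(("a",), np.array([3.0]), np.array([1.0]), True)]
        printed = aggregate_coefficients(fits, "printed")["a"]
        ivw = aggregate_coefficients(fits, "inverse_variance")["a"]
        assert ivw == pytest.approx((1 / 0.25 + 3 / 1) / (1 / 0.25 + 1 / 1))
        assert printed == pytest.approx((1 / 0.25 + 3 / 1) / (1 / 0.5 + 1 / 1))

    def test_unconverged_fits_ignored(self):
        fits = [FitResult(("a",), np.array([1.0]), np.array([1.0]), True),
                FitResult(("a",), np.array([50.0]), np.array([1.0]), False)]
        assert aggregate_coefficients(fits)["a"] == pytest.approx(1.0)


def test_full_logit_fit_standard_errors_match_statsmodels(rng):
    import statsmodels.api as sm

    from pcrad.search import full_logit_fit

    X = rng.standard_normal((80, 3))
    y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
    fit = full_logit_fit(X, y, ("a", "b", "c"))
    Xs = (X - X.mean(0)) / X.std(0)
    ref = sm.GLM(y, sm.add_constant(Xs), family=sm.families.Binomial()).fit()
    assert fit.converged
    assert np.allclose(fit.coefficients, ref.params[1:], atol=1e-6)
    assert np.allclose(fit.standard_errors, ref.bse[1:], atol=1e-5)
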