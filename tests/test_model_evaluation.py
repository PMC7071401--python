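"""Split plans, IRLS logistic regression, metrics and the evaluation loop."""

import numpy as np
import pytest

import pdprognosis as pp
from pdprognosis.model_evaluation import lr_predict_proba


# -- splits ----------------------------------------------------------------

def test_split_sizes_and_determinism():
    ids = [f"s{i}" for i in range(100)]
    y = np.array([1] * 30 + [0] * 70)
    plan = pp.make_splits(ids, y, pp.SplitPlan(n_splits=5, seed=3))
    for train, test in plan.splits:
        assert len(test) == 20 and len(train) == 80
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)
        positives = sum(y[ids.index(s)] for s in test)
        assert abs(positives - 6) <= 1  # proportional allocation
    again = pp.make_splits(ids, y, pp.SplitPlan(n_splits=5, seed=3))
    assert plan.splits == again.splits


def test_split_requires_both_classes():
    with pytest.raises(ValueError):
        pp.make_splits(list("abcdef"), np.zeros(6), pp.SplitPlan())


# -- logistic regression ---------------------------------------------------

def test_lr_symmetry_example():
    model = pp.train_logistic_regression(np.array([[-1.0], [1.0]]),
                                         np.array([0, 1]), l2=0.1)
    assert model.coef[0] > 0
    assert lr_predict_proba(model, np.array([[0.0]]))[0, 1] == pytest.approx(0.5, abs=1e-9)


def test_lr_matches_grid_search_oracle():
    """Coefficients agree with a brute-force grid over (intercept, slope)
    minimising the penalised cross-entropy on a 6-point toy set."""
    X = np.array([[-2.0], [-1.0], [0.5], [-0.5], [1.0], [2.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    l2 = 0.1
    model = pp.train_logistic_regression(X, y, l2=l2)

    def cost(b0, b1):
        p = 1 / (1 + np.exp(-(b0 + b1 * X[:, 0])))
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        return ce + l2 / 2 * b1**2
    grid = np.arange(-3, 3, 0.01)
    bb0, bb1 = min(((b0, b1) for b0 in grid for b1 in grid), key=lambda t: cost(*t))
    assert model.intercept == pytest.approx(bb0, abs=0.01)
    assert model.coef[0] == pytest.approx(bb1, abs=0.01)


def test_lr_matches_sklearn():
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 3))
    y = (X @ [1.0, -0.5, 0.2] + 0.3 * rng.standard_normal(200) > 0).astype(int)
    l2 = 0.05
    mine = pp.train_logistic_regression(X, y, l2=l2)
    ref = sklearn.LogisticRegression(C=1 / (l2 * len(y)), tol=1e-10, max_iter=5000).fit(X, y)
    assert np.allclose(mine.coef, ref.coef_[0], atol=1e-4)
    assert mine.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)


def test_lr_single_class_error():
    with pytest.raises(ValueError):
        pp.train_logistic_regression(np.ones((4, 1)), np.ones(4))


def test_lr_separable_data_capped():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    model = pp.train_logistic_regression(X, np.array([0, 0, 1, 1]), l2=0.0)
    assert model.n_iter <= 100
    assert model.coef[0] > 0


# -- metrics ---------------------------------------------------------------

def test_confusion_metrics_hand_counts():
    perfect = pp.confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
    assert (perfect["accuracy"], perfect["sensitivity"], perfect["specificity"]) == (1, 1, 1)
    wrong = pp.confusion_metrics([1, 0], [0, 1])
    assert (wrong["accuracy"], wrong["sensitivity"], wrong["specificity"]) == (0, 0, 0)
    m = pp.confusion_metrics([1, 1, 1, 0, 0], [1, 1, 0, 0, 0])
    assert m["accuracy"] == pytest.approx(0.8)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(1.0)
    assert (m["TP"], m["FN"], m["TN"], m["FP"]) == (2, 1, 2, 0)


def test_probability_tie_goes_to_positive_class():
    m = pp.confusion_metrics([1], np.array([[0.5, 0.5]]))
    assert m["TP"] == 1
    with pytest.raises(ValueError):
        pp.confusion_metrics([], [])


# -- end-to-end evaluation -------------------------------------------------

def test_models_share_identical_splits(default_cohort):
    table, outcomes, _ = default_cohort
    plan = pp.SplitPlan(n_splits=2, seed=5)
    spec = pp.ModelSpec(kind="autoencoder", pretrain_iters=30, softmax_iters=30,
                        finetune_iters=60)
    reports = pp.compare_models(table, outcomes, 2, "MoCA", plan=plan, ae_spec=spec)
    assert reports["autoencoder"].per_split[0]["n_test"] == reports["logistic"].per_split[0]["n_test"]
    # identical split hashes: per-split test sets coincide exactly
    work = pp.exclude_incomplete(table)
    labels = outcomes.categories["MoCA"].loc[work.patient_ids, 2].to_numpy(int)
    p1 = pp.make_splits(work.patient_ids, labels, pp.SplitPlan(n_splits=2, seed=5))
    p2 = pp.make_splits(work.patient_ids, labels, pp.SplitPlan(n_splits=2, seed=5))
    assert [hash(tuple(t)) for _, t in p1.splits] == [hash(tuple(t)) for _, t in p2.splits]


def test_strong_signal_beats_majority_rate(default_cohort):
    """With the default planted effects the autoencoder clears the
    majority-class rate by a wide margin out of sample."""
    table, outcomes, _ = default_cohort
    spec = pp.ModelSpec(kind="autoencoder", finetune_iters=600)
    report = pp.evaluate_pipeline(table, outcomes, 2, "MoCA", spec,
                                  pp.SplitPlan(n_splits=3, seed=2))
    work = pp.exclude_incomplete(table)
    y = outcomes.categories["MoCA"].loc[work.patient_ids, 2]
    majority = max(y.mean(), 1 - y.mean())
    assert report.mean("accuracy") >= majority + 0.10


def test_screening_refits_per_split(default_cohort):
    """Leakage guard: feature lists derive from each split's training rows
    (recomputing the screen on the training rows reproduces them)."""
    table, outcomes, _ = default_cohort
    spec = pp.ModelSpec(kind="logistic")
    plan = pp.SplitPlan(n_splits=2, seed=9)
    report = pp.evaluate_pipeline(table, outcomes, 1, "UPDRS", spec, plan, keep_models=True)
    work = pp.exclude_incomplete(table)
    work = work.subset(work.patient_ids)
    labels = outcomes.categories["UPDRS"].loc[work.subject_ids, 1].to_numpy(int)
    plan = pp.make_splits(work.subject_ids, labels, pp.SplitPlan(n_splits=2, seed=9))
    for fitted, (train_ids, _) in zip(report.fitted, plan.splits):
        sub = pp.impute_median(work.subset(train_ids), train_ids)
        y = outcomes.raw_scores["UPDRS"].loc[train_ids, 1].to_numpy(float)
        res = pp.select_features(sub, y, work.dbm_columns)
        expect = [r.feature for r in res if r.selected]
        got_dbm = [f for f in fitted.feature_names if f in work.dbm_columns]
        assert sorted(expect) == sorted(got_dbm)
        # scaler statistics recompute from training rows alone
        ref = pp.fit_scaler(sub, train_ids, mode="minmax")
        assert np.allclose(fitted.scaler.loc, ref.loc)
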