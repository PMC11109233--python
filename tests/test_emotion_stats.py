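"""Classical tests, the multinomial logit, bootstrap and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emodraw.emotion_stats import (
    SeparationError,
    bootstrap_fit,
    build_design_matrix,
    chisq_independence,
    classification_table,
    fit_multinomial_logit,
    nagelkerke_r2,
    oneway_anova,
)


# ---------------------------------------------------------------------------
# chi-square and ANOVA
# ---------------------------------------------------------------------------

def test_chisq_perfect_independence():
    stat, df, p = chisq_independence([[10, 10], [10, 10]])
    assert stat == 0.0
    assert df == 1
    assert p == pytest.approx(1.0)


def test_chisq_hand_computed_2x2():
    # expected all 12.5; sum (O-E)^2/E = 4 * (7.5^2/12.5) = 18
    stat, df, _ = chisq_independence([[20, 5], [5, 20]])
    assert stat == pytest.approx(18.0)
    assert df == 1


def test_chisq_matches_brute_force_on_4x4():
    rng = np.random.default_rng(9)
    table = rng.integers(1, 40, (4, 4)).astype(float)
    table += np.diag([50, 60, 55, 45])
    stat, df, p = chisq_independence(table)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())
    assert df == 9
    assert 0.0 <= p <= 1.0


def test_chisq_zero_marginal_rejected():
    with pytest.raises(ValueError):
        chisq_independence([[0, 0], [5, 5]])


def test_anova_identical_groups_give_zero_f():
    g = np.array([1.0, 2.0, 3.0])
    f, p = oneway_anova([g, g.copy(), g.copy()])
    assert f == pytest.approx(0.0)


def test_anova_constant_equal_groups_degenerate_convention():
    g = np.array([2.0, 2.0, 2.0])
    assert oneway_anova([g, g.copy()]) == (0.0, 1.0)


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(10)
    a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)
    f, pf = oneway_anova([a, b])
    t, pt = stats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t**2)
    assert pf == pytest.approx(pt)


# ---------------------------------------------------------------------------
# multinomial logit
# ---------------------------------------------------------------------------

def _binary_fixture():
    """Binary outcome/predictor with known 2x2 counts a,b,c,d."""
    a, b, c, d = 30, 10, 15, 45   # rows x=0/1, cols y=no/yes
    x = np.array([0] * (a + b) + [1] * (c + d), dtype=float)
    y = np.array(["no"] * a + ["yes"] * b + ["no"] * c + ["yes"] * d)
    return x.reshape(-1, 1), y, np.log((d * a) / (b * c))


def test_binary_slope_equals_log_odds_ratio():
    X, y, log_or = _binary_fixture()
    m = fit_multinomial_logit(pd.DataFrame(X, columns=["x"]), pd.Series(y),
                              reference="no")
    assert m.converged
    assert m.coefficients.loc["yes", "x"] == pytest.approx(log_or, abs=1e-6)


def test_null_data_gives_flat_model():
    rng = np.random.default_rng(11)
    X = pd.DataFrame({"x1": rng.normal(size=400), "x2": rng.normal(size=400)})
    y = pd.Series(rng.choice(["anger", "happiness", "sadness", "fear"], 400))
    m = fit_multinomial_logit(X, y)
    assert np.abs(m.coefficients[["x1", "x2"]].to_numpy()).max() < 0.5
    assert m.lr_chi2 < stats.chi2.ppf(0.999, m.lr_df)
    assert m.nagelkerke_r2 < 0.05


def test_predicted_probabilities_sum_to_one():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({"x": rng.normal(size=200)})
    y = pd.Series(np.where(rng.random(200) < 0.5, "happiness", "anger"))
    m = fit_multinomial_logit(X, y)
    P = m.predict_proba(X).to_numpy()
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12


def test_model_likelihood_at_least_null():
    rng = np.random.default_rng(13)
    X = pd.DataFrame({"x": rng.normal(size=150)})
    y = pd.Series(rng.choice(["anger", "fear"], 150))
    m = fit_multinomial_logit(X, y, reference="anger")
    assert m.log_likelihood >= m.null_log_likelihood - 1e-9


def test_nagelkerke_bounds_and_errors():
    assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0
    assert nagelkerke_r2(-100.0, 0.0, 50) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        nagelkerke_r2(-10.0, -20.0, 50)
    # worked value recomputed from the definition
    ll0, ll1, n = -120.0, -70.0, 100
    expected = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
    assert nagelkerke_r2(ll0, ll1, n) == pytest.approx(expected)


def _simulate_multinomial(n, seed, B_true):
    """Draw (X, y) from a known 3-class softmax model."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    X1 = np.column_stack([np.ones(n), X])
    eta = np.zeros((n, 3))
    eta[:, 1:] = X1 @ B_true.T
    P = np.exp(eta - eta.max(1, keepdims=True))
    P /= P.sum(1, keepdims=True)
    u = rng.random(n)
    y_idx = (u[:, None] > P.cumsum(1)).sum(1)
    classes = np.array(["a", "b", "c"])
    return pd.DataFrame(X, columns=["x1", "x2"]), pd.Series(classes[y_idx])


def test_parameter_recovery_within_three_standard_errors():
    B_true = np.array([[0.3, 1.0, -0.5], [-0.4, -0.8, 0.9]])
    X, y = _simulate_multinomial(2000, 14, B_true)
    m = fit_multinomial_logit(X, y, reference="a")
    assert m.converged
    se = m.coef_standard_errors()
    est = m.coefficients
    for i, cls in enumerate(["b", "c"]):
        for j, term in enumerate(["intercept", "x1", "x2"]):
            z = (est.loc[cls, term] - B_true[i, j]) / se.loc[cls, term]
            assert abs(z) < 3.0, (cls, term, z)


def test_agrees_with_statsmodels_mnlogit():
    """Independent cross-check of the Newton fit against statsmodels."""
    import statsmodels.api as sm

    B_true = np.array([[0.2, 0.7, -0.3], [-0.1, -0.5, 0.6]])
    X, y = _simulate_multinomial(400, 15, B_true)
    m = fit_multinomial_logit(X, y, reference="a")
    codes = pd.Categorical(y, categories=["a", "b", "c"]).codes
    sm_fit = sm.MNLogit(codes, sm.add_constant(X.to_numpy())).fit(disp=0)
    ours = m.coefficients.to_numpy()           # rows b, c
    theirs = np.asarray(sm_fit.params).T       # rows: outcome 1, 2
    assert np.allclose(ours, theirs, atol=1e-4)
    assert m.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)


def test_separation_detected():
    x = np.array([0.0] * 20 + [1.0] * 20)
    y = np.array(["a"] * 20 + ["b"] * 20)
    with pytest.raises(SeparationError):
        fit_multinomial_logit(pd.DataFrame({"x": x}), pd.Series(y), reference="a")


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_single_resample_degenerates_to_point_estimate():
    X, y, _ = _binary_fixture()
    Xf, ys = pd.DataFrame(X, columns=["x"]), pd.Series(y)
    m = fit_multinomial_logit(Xf, ys, reference="no")
    ci, failed = bootstrap_fit(Xf, ys, B=1, seed=0, reference="no")
    assert failed == 0
    assert ci.loc[("yes", "x"), "lower"] == pytest.approx(
        m.coefficients.loc["yes", "x"]
    )
    assert ci.loc[("yes", "x"), "lower"] == ci.loc[("yes", "x"), "upper"]


def test_bootstrap_reproducible_for_same_seed():
    rng = np.random.default_rng(16)
    X = pd.DataFrame({"x": rng.normal(size=120)})
    y = pd.Series(np.where(X["x"] + rng.normal(0, 1.5, 120) > 0, "b", "a"))
    ci1, _ = bootstrap_fit(X, y, B=25, seed=42, reference="a")
    ci2, _ = bootstrap_fit(X, y, B=25, seed=42, reference="a")
    pd.testing.assert_frame_equal(ci1, ci2)


def test_bootstrap_interval_excludes_zero_for_strong_effect():
    rng = np.random.default_rng(17)
    n = 150
    x = rng.normal(size=n)
    y = pd.Series(np.where(2.0 * x + rng.normal(0, 1, n) > 0, "b", "a"))
    X = pd.DataFrame({"x": x})
    ci, failed = bootstrap_fit(X, y, B=200, seed=3, reference="a")
    assert failed < 40
    assert ci.loc[("b", "x"), "lower"] > 0.0


# ---------------------------------------------------------------------------
# classification table and design matrix
# ---------------------------------------------------------------------------

def test_classification_table_perfect_predictor():
    from emodraw.emotion_stats import EmotionModel

    coef = pd.DataFrame([[0.0, 10.0]], index=pd.Index(["b"], name="emotion"),
                        columns=["intercept", "x"])
    model = EmotionModel(
        coefficients=coef, classes=("a", "b"), reference="a",
        feature_names=("x",), log_likelihood=0, null_log_likelihood=0,
        lr_chi2=0, lr_df=1, lr_pvalue=1, nagelkerke_r2=0, n_obs=80,
        converged=True, n_iter=0,
    )
    rng = np.random.default_rng(18)
    x = np.concatenate([rng.normal(-4, 0.3, 40), rng.normal(4, 0.3, 40)])
    X = pd.DataFrame({"x": x})
    y = pd.Series(["a"] * 40 + ["b"] * 40)
    tab = classification_table(model, X, y)
    assert tab.overall_percent == 100.0
    assert np.trace(tab.table.to_numpy()) == 80
    assert (tab.percent_correct == 100.0).all()


def test_classification_table_hand_counted_fixture():
    from emodraw.emotion_stats import EmotionModel

    # model with known coefficients: predicts "b" iff x > 0
    coef = pd.DataFrame([[0.0, 5.0]], index=pd.Index(["b"], name="emotion"),
                        columns=["intercept", "x"])
    model = EmotionModel(
        coefficients=coef, classes=("a", "b"), reference="a",
        feature_names=("x",), log_likelihood=0, null_log_likelihood=0,
        lr_chi2=0, lr_df=1, lr_pvalue=1, nagelkerke_r2=0, n_obs=8,
        converged=True, n_iter=0,
    )
    X = pd.DataFrame({"x": [-1, -1, -1, 1, 1, -1, 1, 1.0]})
    y = pd.Series(["a", "a", "a", "a", "b", "b", "b", "b"])
    tab = classification_table(model, X, y)
    # hand count: observed a -> predicted a 3, b 1; observed b -> a 1, b 3
    assert tab.table.loc["a", "a"] == 3
    assert tab.table.loc["a", "b"] == 1
    assert tab.table.loc["b", "a"] == 1
    assert tab.table.loc["b", "b"] == 3
    assert tab.overall_percent == pytest.approx(75.0)
    assert (tab.table.sum(axis=1).to_numpy() == np.array([4, 4])).all()


def test_chance_level_accuracy_on_balanced_null_data():
    rng = np.random.default_rng(19)
    n = 2000
    X = pd.DataFrame({"x": rng.normal(size=n)})
    y = pd.Series(np.tile(["anger", "happiness", "sadness", "fear"], n // 4))
    m = fit_multinomial_logit(X, y)
    tab = classification_table(m, X, y)
    assert abs(tab.overall_percent - 25.0) < 5.0


def test_build_design_matrix_dummies_and_constant_drop(small_cohort_features):
    feats = small_cohort_features
    X, y = build_design_matrix(feats)
    assert len(X) == len(feats)
    assert set(y.unique()) <= {"anger", "happiness", "sadness", "fear"}
    dummy_cols = [c for c in X.columns if c.startswith("color_")]
    present = feats["prominent_color"].unique()
    assert len(dummy_cols) <= max(len(present) - 1, 0) + 6
    for c in X.columns:
        assert X[c].nunique() > 1
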