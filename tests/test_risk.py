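"""Risk models: AUC, operating points, calibration, IDI, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcrisk.risk import (
    LinearRiskModel,
    LinearRiskScore,
    auc,
    bootstrap_compare,
    combined_model,
    evaluate_linear_score,
    fit_linear_score,
    idi,
    roc_operating_point,
)

#: the published five-gene RNA score (log10(normalised count + 1) scale)
RNA_MODEL = LinearRiskModel(
    feature_names=["RANBP17", "TRIM9", "ITGAM", "ELOVL2", "KCNJ10"],
    weights=np.array([0.593, 0.710, -0.903, -0.803, -0.815]),
    intercept=3.190,
    calibration=(0.0, 1.0),
    cutoff=0.507,
)

#: the published combined clinical + RNA score
COMBINED_MODEL = LinearRiskModel(
    feature_names=["bmi_ge_23", "ebv_ge_4000", "tnm_eq_4", "rna_score"],
    weights=np.array([-0.610, 0.042, 0.873, 0.405]),
    intercept=0.388,
    calibration=(0.0, 1.0),
    cutoff=0.714,
)


# ------------------------------------------------------------------ AUC


def _auc_bruteforce(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5
    assert auc([0.7, 0.85, 0.9, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_auc_matches_all_pairs_count(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 30)
    y = np.r_[np.ones(2), np.zeros(2), rng.integers(0, 2, n - 4)]
    s = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
    assert auc(s, y) == pytest.approx(_auc_bruteforce(s, y))


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        auc([1, 2], [1, 1])


# ------------------------------------------------------ operating point


def test_operating_point_perfect_split():
    cut = roc_operating_point([0, 0, 1, 1], [0, 0, 1, 1])
    assert cut == pytest.approx(0.5)


def _youden_bruteforce(s, y):
    s, y = np.asarray(s, float), np.asarray(y)
    best = -np.inf
    for t in np.concatenate([s - 1e-9, s + 1e-9, [s.min() - 1, s.max() + 1]]):
        pred = s > t
        j = (pred & (y == 1)).sum() / (y == 1).sum() - (pred & (y == 0)).sum() / (
            y == 0
        ).sum()
        best = max(best, j)
    return best


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_operating_point_maximises_youden_j(seed):
    rng = np.random.default_rng(seed)
    s = rng.choice(np.linspace(0, 1, 5), size=6)
    y = np.r_[1, 0, rng.integers(0, 2, 4)]
    cut = roc_operating_point(s, y)
    pred = s > cut
    j_at_cut = (pred & (y == 1)).sum() / (y == 1).sum() - (pred & (y == 0)).sum() / (
        y == 0
    ).sum()
    assert j_at_cut == pytest.approx(_youden_bruteforce(s, y))


# ------------------------------------------------- fitting & calibration


def test_calibrated_group_means_are_exactly_zero_and_one():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 3))
    y = rng.integers(0, 2, 60)
    y[:2], y[-2:] = 1, 0
    m = fit_linear_score(X, y)
    s = m.evaluate(X)
    assert abs(s[y == 0].mean()) < 1e-10
    assert abs(s[y == 1].mean() - 1.0) < 1e-10


def test_perfectly_separating_feature():
    y = np.r_[np.zeros(10), np.ones(10)]
    m = fit_linear_score(y.reshape(-1, 1), y)
    s = m.evaluate(y.reshape(-1, 1))
    assert auc(s, y) == 1.0
    assert s[y == 0].mean() == pytest.approx(0.0, abs=1e-12)
    assert s[y == 1].mean() == pytest.approx(1.0, abs=1e-12)


def test_refit_on_own_scores_is_affine_identity():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 2))
    y = rng.integers(0, 2, 80)
    y[:2], y[-2:] = 1, 0
    s1 = fit_linear_score(X, y).evaluate(X)
    s2 = fit_linear_score(s1.reshape(-1, 1), y).evaluate(s1.reshape(-1, 1))
    np.testing.assert_allclose(s1, s2, atol=1e-8)


def test_degenerate_fit_warns_and_returns_constant():
    X = np.ones((20, 1))
    y = np.r_[np.ones(10), np.zeros(10)]
    with pytest.warns(RuntimeWarning, match="degenerate"):
        m = fit_linear_score(X, y)
    assert np.ptp(m.evaluate(X)) == 0


def test_true_risk_recovered_at_large_n():
    rng = np.random.default_rng(6)
    n = 500
    true_w = np.array([1.0, -2.0, 0.5])
    X = rng.normal(size=(n, 3))
    risk = X @ true_w
    y = (risk > np.median(risk)).astype(int)
    s = fit_linear_score(X, y).evaluate(X)
    assert np.corrcoef(s, risk)[0, 1] > 0.99


# ---------------------------------------------------- published formulas


def test_rna_score_at_zero_expression_is_intercept():
    assert evaluate_linear_score(RNA_MODEL, np.zeros((1, 5)))[0] == pytest.approx(
        3.190
    )


def test_rna_score_at_unit_expression():
    # .593 + .710 - .903 - .803 - .815 + 3.190
    assert evaluate_linear_score(RNA_MODEL, np.ones((1, 5)))[0] == pytest.approx(
        1.972
    )


def test_combined_score_at_zero_inputs_is_intercept():
    assert COMBINED_MODEL.evaluate(np.zeros((1, 4)))[0] == pytest.approx(0.388)


def test_combined_score_all_indicators_and_unit_rna():
    # -.610 + .042 + .873 + .405 + .388
    assert COMBINED_MODEL.evaluate(np.ones((1, 4)))[0] == pytest.approx(1.098)


def test_model_json_roundtrip(tmp_path):
    path = tmp_path / "model.json"
    RNA_MODEL.to_json(path)
    back = LinearRiskModel.from_json(path)
    assert back.feature_names == RNA_MODEL.feature_names
    np.testing.assert_allclose(back.weights, RNA_MODEL.weights)
    assert back.cutoff == RNA_MODEL.cutoff


def test_missing_feature_raises():
    with pytest.raises(KeyError):
        RNA_MODEL.evaluate(pd.DataFrame({"RANBP17": [1.0]}))


def test_combined_model_rejects_nonbinary_indicators():
    with pytest.raises(ValueError, match="binary"):
        combined_model(np.full((10, 3), 0.5), np.zeros(10), [0, 1] * 5)


def test_combined_model_with_label_indicator_is_near_perfect():
    rng = np.random.default_rng(8)
    y = rng.integers(0, 2, 40)
    y[:2], y[-2:] = 1, 0
    clin = np.column_stack([y, rng.integers(0, 2, 40), rng.integers(0, 2, 40)])
    m = combined_model(clin, rng.normal(size=40), y)
    s = m.evaluate(np.column_stack([clin, rng.normal(size=40)]))
    assert auc(s, y) > 0.99


# ------------------------------------------------------------------ IDI


def test_idi_identical_predictions_zero():
    y = [0, 1, 0, 1]
    assert idi([0.1, 0.9, 0.2, 0.8], [0.1, 0.9, 0.2, 0.8], y) == 0.0


def test_idi_uninformative_to_perfect_is_one():
    y = np.array([0, 1, 0, 1])
    assert idi(np.full(4, 0.5), y.astype(float), y) == pytest.approx(1.0)


def test_idi_hand_example():
    y = [1, 1, 0, 0]
    old = [0.6, 0.4, 0.5, 0.5]
    new = [0.9, 0.7, 0.2, 0.4]
    assert idi(old, new, y) == pytest.approx(0.5)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_idi_antisymmetric(seed):
    rng = np.random.default_rng(seed)
    y = np.r_[1, 0, rng.integers(0, 2, 10)]
    a, b = rng.random(12), rng.random(12)
    assert idi(a, b, y) == pytest.approx(-idi(b, a, y))


# ------------------------------------------------------------ bootstrap


def _test_cohort_arrays(seed=0, n=70, informative_rna=True):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(23), np.zeros(47)].astype(int)
    logit = -0.5 + 1.2 * y
    clin = np.column_stack(
        [
            rng.binomial(1, 1 / (1 + np.exp(0.8 * y - 0.2))),
            rng.binomial(1, 1 / (1 + np.exp(-logit))),
            rng.binomial(1, 1 / (1 + np.exp(-logit + 0.5))),
        ]
    )
    rna = y + rng.normal(0, 0.8, n) if informative_rna else rng.normal(0, 1, n)
    return y, clin, rna


def test_bootstrap_deterministic_under_seed():
    y, clin, rna = _test_cohort_arrays()
    r1 = bootstrap_compare(y, clin, rna, n_reps=25, seed=5)
    r2 = bootstrap_compare(y, clin, rna, n_reps=25, seed=5)
    np.testing.assert_array_equal(r1.auc_combined, r2.auc_combined)
    assert r1.comparison_p == r2.comparison_p


def test_bootstrap_null_rna_adds_nothing():
    y, clin, rna = _test_cohort_arrays(seed=1, informative_rna=False)
    r = bootstrap_compare(y, clin, rna, n_reps=60, seed=2)
    assert abs(r.mean_auc_combined - r.mean_auc_clinical) < 0.05
    assert abs(r.mean_idi) < 0.05


def test_bootstrap_informative_rna_improves_auc():
    y, clin, rna = _test_cohort_arrays(seed=3)
    r = bootstrap_compare(y, clin, rna, n_reps=200, seed=4)
    assert r.mean_auc_combined > r.mean_auc_clinical
    assert r.comparison_p < 0.05
    assert r.mean_idi > 0


def test_bootstrap_averaged_model_is_calibrated():
    y, clin, rna = _test_cohort_arrays(seed=7)
    r = bootstrap_compare(y, clin, rna, n_reps=40, seed=8)
    s = r.averaged_model.evaluate(np.column_stack([clin, rna]))
    assert abs(s[y == 0].mean()) < 1e-10
    assert abs(s[y == 1].mean() - 1.0) < 1e-10


def test_summary_renders(study):
    cohorts, truth = study
    genes = sorted(truth.de_gene_signs)[:5]
    res = LinearRiskScore.from_cohort(cohorts[0], genes).fit()
    text = res.summary()
    assert "training AUC" in text and "intercept" in text
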