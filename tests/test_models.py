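import json
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pfasbind.metrics import q2_loo
from pfasbind.models import (
    DCVConfig,
    DiscriminantModel,
    GAConfig,
    RegressionModel,
    double_cross_validate,
    fit_lda,
    fit_mlr,
    fit_pls,
    ga_select,
    load_model,
    predict,
    pretreat,
    reference_eq1,
    reference_eq2,
    save_model,
)


# ---------------------------------------------------------------------------
# frozen reference models


def test_reference_discriminant_frozen_constants():
    m = reference_eq1()
    assert m.descriptor_names == ("Eig12_AEA_bo", "DECC", "X4A")
    assert m.coefficients == (33.651, 0.378, 30.405)
    assert m.intercept == -14.668
    assert m.score([[0.0, 0.0, 0.0]])[0] == pytest.approx(-14.668)
    # two calls return equal models
    assert reference_eq1() == reference_eq1()


def test_reference_discriminant_sign_convention():
    m = reference_eq1()
    # score far below the threshold -> high affinity; far above -> low
    assert m.predict([[0.0, 0.0, 0.0]])[0] == "H"  # score -14.668 < 0
    assert m.predict([[1.0, 1.0, 1.0]])[0] == "L"  # score ~49.8 > 0


def test_reference_regression_frozen_constants_and_linearity():
    m = reference_eq2()
    assert m.kind == "PLS" and m.n_latent == 3
    zero = m.predict([[0.0, 0.0, 0.0, 0.0]])[0]
    assert zero == pytest.approx(24.427)
    bumped_qed = m.predict([[0.0, 0.0, 0.0, 1.0]])[0]
    assert zero - bumped_qed == pytest.approx(4.388)
    bumped_pdi = m.predict([[0.1, 0.0, 0.0, 0.0]])[0]
    assert zero - bumped_pdi == pytest.approx(2.3551)


def test_model_json_round_trip(tmp_path):
    for m in (reference_eq1(), reference_eq2()):
        p = tmp_path / "model.json"
        save_model(m, p)
        assert load_model(p) == m
    # serialized form is plain JSON with named coefficients
    d = json.loads(reference_eq2().to_json())
    assert d["descriptor_names"] == ["PDI", "GATS8v", "MATS8m", "QED"]


def test_predict_aligns_named_columns_and_errors_on_missing():
    m = reference_eq2()
    df = pd.DataFrame(
        {"QED": [0.0], "MATS8m": [0.0], "GATS8v": [0.0], "PDI": [0.0]}
    )  # shuffled column order
    assert predict(m, df)[0] == pytest.approx(24.427)
    with pytest.raises(KeyError, match="QED"):
        predict(m, df.drop(columns=["QED"]))


# ---------------------------------------------------------------------------
# LDA


def test_lda_separates_well_separated_gaussians():
    rng = np.random.default_rng(0)
    X = np.r_[rng.normal(-5, 0.5, (50, 1)), rng.normal(5, 0.5, (50, 1))]
    y = np.array(["H"] * 50 + ["L"] * 50)
    m = fit_lda(X, y)
    assert (m.predict(X) == y).mean() == 1.0
    assert m.stats["wilks_lambda"] < 0.05


def test_lda_identical_means_lambda_near_one():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (80, 2))
    y = np.array(["H", "L"] * 40)
    m = fit_lda(X, y)
    assert m.stats["wilks_lambda"] > 0.9


def test_lda_label_flip_negates_direction():
    rng = np.random.default_rng(2)
    X = np.r_[rng.normal(-2, 1, (30, 2)), rng.normal(2, 1, (30, 2))]
    y = np.array(["H"] * 30 + ["L"] * 30)
    m1 = fit_lda(X, y, positive_class="H")
    m2 = fit_lda(X, y, positive_class="L")
    assert np.allclose(m1.coefficients, -np.array(m2.coefficients))
    assert m1.stats["wilks_lambda"] == pytest.approx(m2.stats["wilks_lambda"])


def test_lda_singular_scatter_suggests_pruning():
    X = np.ones((10, 2))
    X[:, 1] = X[:, 0]  # perfectly collinear, zero within-class scatter
    y = np.array(["H"] * 5 + ["L"] * 5)
    with pytest.raises(np.linalg.LinAlgError, match="prune"):
        fit_lda(X, y)


# ---------------------------------------------------------------------------
# MLR


def test_mlr_exact_fit_zero_residuals():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 3))
    y = 1.0 + X @ [2.0, -1.0, 0.5]
    m = fit_mlr(X, y)
    assert m.stats["rss"] == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(m.predict(X), y)


def test_mlr_duplicate_column_rank_error():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 2))
    X = np.column_stack([X, X[:, 0]])
    with pytest.raises(ValueError, match="rank"):
        fit_mlr(X, X[:, 0])


def test_mlr_parameter_recovery_at_low_noise():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 2))
    y = X @ [2.0, -3.0] + rng.normal(0, 0.01, 100)
    m = fit_mlr(X, y)
    assert abs(m.coefficients[0] - 2.0) < 0.05
    assert abs(m.coefficients[1] + 3.0) < 0.05


# ---------------------------------------------------------------------------
# PLS


def test_pls_full_rank_equals_mlr():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(25, 4))
    y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.3, 25)
    mlr = fit_mlr(X, y)
    pls = fit_pls(X, y, n_lv=4)
    assert np.allclose(pls.predict(X), mlr.predict(X), atol=1e-8)


def test_pls_single_lv_on_orthonormal_columns_proportional_to_covariance():
    rng = np.random.default_rng(7)
    M = rng.normal(size=(40, 3))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    X = Q  # orthonormal, zero-mean columns
    y = rng.normal(size=40)
    m = fit_pls(X, y, n_lv=1, scale=False)
    cov = X.T @ (y - y.mean())
    coef = np.array(m.coefficients)
    ratio = coef / cov
    assert np.allclose(ratio, ratio[0])


def test_pls_matches_sklearn_reference():
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(8)
    X = rng.normal(size=(22, 5))
    y = X @ [1, 0, -1, 2, 0.5] + rng.normal(0, 0.5, 22)
    for n_lv in (1, 2, 3):
        mine = fit_pls(X, y, n_lv=n_lv)
        ref = PLSRegression(n_components=n_lv, scale=True).fit(X, y)
        assert np.allclose(mine.predict(X), ref.predict(X).ravel(), atol=1e-8)


def test_pls_deterministic_and_lv_bounds():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(15, 3))
    y = rng.normal(size=15)
    assert fit_pls(X, y, 2) == fit_pls(X, y, 2)
    with pytest.raises(ValueError):
        fit_pls(X, y, 4)
    with pytest.raises(ValueError):
        fit_pls(X, y, 0)


# ---------------------------------------------------------------------------
# pretreatment


def test_pretreat_drops_constant_and_duplicate_columns():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(50, 3))
    X = np.column_stack([X, np.full(50, 2.0), X[:, 0]])
    res = pretreat(X)
    assert 3 in res.dropped  # constant
    assert (0 in res.dropped) != (4 in res.dropped)  # exactly one twin survives
    assert res.reduce(X).shape[1] == 3


def test_pretreat_keeps_independent_columns():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(200, 30))
    res = pretreat(X)
    assert len(res.kept) >= 0.95 * 30


def test_pretreat_prefers_column_more_correlated_with_response():
    rng = np.random.default_rng(12)
    base = rng.normal(size=100)
    X = np.column_stack([base + rng.normal(0, 0.01, 100), base])
    y = base  # column 1 is y itself
    res = pretreat(X, y)
    assert res.kept == [1]


# ---------------------------------------------------------------------------
# GA selection


def test_ga_finds_planted_signal_pair():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, 8))
        y = X[:, 1] + X[:, 2] + rng.normal(0, 0.1, 40)
        cfg = GAConfig(subset_size=2, population_size=20, generations=15, seed=seed)
        ranked = ga_select(X, y, kind="mlr", cfg=cfg)
        if ranked[0][0] == (1, 2):
            hits += 1
    assert hits >= 18  # >= 90% of seeded runs


def test_ga_pool_equals_subset_size_returns_single_subset():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    ranked = ga_select(X, y, cfg=GAConfig(subset_size=3))
    assert len(ranked) == 1 and ranked[0][0] == (0, 1, 2)


def test_ga_seed_reproducibility_and_infeasible_size():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(30, 10))
    y = X[:, 0] - X[:, 5] + rng.normal(0, 0.2, 30)
    cfg = GAConfig(subset_size=2, population_size=16, generations=10, seed=7)
    assert ga_select(X, y, cfg=cfg) == ga_select(X, y, cfg=cfg)
    with pytest.raises(ValueError, match="subset size"):
        ga_select(X, y, cfg=GAConfig(subset_size=11))


def test_ga_lda_fitness_uses_wilks_lambda():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(60, 6))
    y = np.array(["H"] * 30 + ["L"] * 30)
    X[:30, 3] += 4.0  # only column 3 separates
    ranked = ga_select(X, y, kind="lda",
                       cfg=GAConfig(subset_size=1, population_size=10, generations=10, seed=1))
    assert ranked[0][0] == (3,)


# ---------------------------------------------------------------------------
# double cross-validation


def test_dcv_enumerates_all_triples():
    rng = np.random.default_rng(16)
    X = rng.normal(size=(5, 1))
    y = rng.normal(size=5)
    res = double_cross_validate(X, y, DCVConfig(validation_size=3))
    assert res.n_splits_enumerated == math.comb(5, 3) == 10
    assert len(res.splits) == 10


def test_dcv_noiseless_linear_consensus_exact():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(10, 3))
    y = 2.0 + X @ [1.0, -1.0, 0.5]
    res = double_cross_validate(X, y, DCVConfig(validation_size=3))
    assert np.allclose(res.consensus, y, atol=1e-8)
    coefs = {tuple(np.round(s.model.coefficients, 10)) for s in res.splits}
    assert len(coefs) == 1  # every split recovers identical coefficients


def test_dcv_selected_coefficients_within_two_se():
    rng = np.random.default_rng(18)
    n, beta, sigma = 22, np.array([2.0, -3.0, 1.5, -1.0]), 0.3
    X = rng.normal(size=(n, 4))
    y = X @ beta + rng.normal(0, sigma, n)
    res = double_cross_validate(X, y, DCVConfig(validation_size=3, max_splits=200, seed=0))
    model = res.best.model
    # compare against the OLS standard errors on the winning split's training part
    Xt = np.delete(X, res.best.val_indices, axis=0)
    At = np.column_stack([np.ones(len(Xt)), Xt])
    se = sigma * np.sqrt(np.diag(np.linalg.inv(At.T @ At)))[1:]
    assert np.all(np.abs(np.array(model.coefficients) - beta) < 2.5 * se + 1e-9)


def test_dcv_validation_size_bounds_and_cap():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(6, 2))
    y = rng.normal(size=6)
    with pytest.raises(ValueError):
        double_cross_validate(X, y, DCVConfig(validation_size=6))
    res = double_cross_validate(X, y, DCVConfig(validation_size=3, max_splits=5, seed=1))
    assert len(res.splits) == 5
    res2 = double_cross_validate(X, y, DCVConfig(validation_size=3, max_splits=5, seed=1))
    assert [s.val_indices for s in res.splits] == [s.val_indices for s in res2.splits]


def test_q2_loo_hat_matrix_equals_naive_refit():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(22, 4))
    y = X @ [1, -1, 2, 0.5] + rng.normal(0, 0.5, 22)
    assert q2_loo(X, y) == pytest.approx(q2_loo(X, y, fit=fit_mlr), abs=1e-10)
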