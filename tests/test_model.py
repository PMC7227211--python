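"""Penalized model: design assembly, the lambda_se rule, solver
correctness against an independent proximal-gradient oracle, and
chromatin-only extraction."""

import numpy as np
import pandas as pd
import pytest

import chromlasso as cl
from chromlasso.matching import MatchedSet
from chromlasso.model import BACKGROUND_COLUMNS, _fit_path, _standardize


def _toy_inputs(n_cases=10, n_controls_per=100, reuse=False):
    cases = [f"case{i}" for i in range(n_cases)]
    controls = []
    matched = []
    for i, c in enumerate(cases):
        if reuse and i > 0:
            ctrl = [f"ctl{i - 1}_{j}" for j in range(n_controls_per)]
        else:
            ctrl = [f"ctl{i}_{j}" for j in range(n_controls_per)]
            controls.extend(ctrl)
        matched.append(MatchedSet(case_rsid=c, control_rsids=ctrl))
    rsids = cases + controls
    rng = np.random.default_rng(0)
    matrix = pd.DataFrame(rng.integers(0, 2, (len(rsids), 3)),
                          index=pd.Index(rsids, name="rsid"),
                          columns=["f1", "f2", "f3"])
    cov = pd.DataFrame({
        "rsid": rsids,
        "dist_to_gene": rng.integers(0, 10_000, len(rsids)),
        "n_proxies": rng.integers(0, 5, len(rsids)),
        "maf": rng.uniform(0.1, 0.5, len(rsids)),
    })
    return matched, matrix, cov


def test_design_row_count_and_penalty_factors():
    matched, matrix, cov = _toy_inputs()
    design = cl.assemble_design(matched, matrix, cov)
    assert design.X.shape[0] == 1010
    assert design.y.sum() == 10
    np.testing.assert_array_equal(
        design.penalty_factors, [1, 1, 1, 0, 0, 0])
    assert design.background_columns == BACKGROUND_COLUMNS
    assert list(design.X.columns[:3]) == ["f1", "f2", "f3"]


def test_reused_control_contributes_one_row():
    matched, matrix, cov = _toy_inputs(n_cases=2, reuse=True)
    design = cl.assemble_design(matched, matrix, cov)
    assert design.X.shape[0] == 2 + 100   # shared control block deduped


def test_missing_rsid_is_named():
    matched, matrix, cov = _toy_inputs(n_cases=2)
    with pytest.raises(KeyError, match="case0"):
        cl.assemble_design(matched, matrix.drop(index="case0"), cov)


def test_lambda_se_rule_on_toy_curve():
    """AUC {0.70, 0.74, 0.75} at lambdas {1.0, 0.5, 0.1} with SE 0.02 at
    the maximum: 0.74 >= 0.75 - 0.02, so lambda_se = 0.5."""
    lam_min, lam_se = cl.select_lambda_se(
        np.array([1.0, 0.5, 0.1]),
        np.array([0.70, 0.74, 0.75]),
        np.array([0.03, 0.025, 0.02]))
    assert lam_min == 0.1
    assert lam_se == 0.5


def test_all_zero_features_give_empty_model():
    matched, matrix, cov = _toy_inputs(n_cases=5, n_controls_per=40)
    matrix[:] = 0
    design = cl.assemble_design(matched, matrix, cov)
    path = cl.fit_lasso_cv(design, k_folds=3, seed=0, n_lambdas=20)
    assert (path.n_nonzero == 0).all()
    model = cl.extract_scoring_model(path)
    assert model.entries == {}


def _proximal_gradient_oracle(X, y, pf, lam, n_iter=300_000, tol=1e-12):
    """Independent minimizer of the same penalized objective:
    (1/n)*logistic loss + lam * sum(pf_j |beta_j|), FISTA on the
    standardized design with an unpenalized intercept column."""
    n, p = X.shape
    Xi = np.c_[np.ones(n), X]
    pfi = np.r_[0.0, pf]
    L = np.linalg.norm(Xi, 2) ** 2 / (4 * n)
    b = np.zeros(p + 1)
    v = b.copy()
    t = 1.0
    prev_obj = np.inf
    for it in range(n_iter):
        eta = Xi @ v
        prob = 1 / (1 + np.exp(-eta))
        grad = Xi.T @ (prob - y) / n
        b_new = v - grad / L
        thr = lam * pfi / L
        b_new = np.sign(b_new) * np.maximum(np.abs(b_new) - thr, 0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        v = b_new + (t - 1) / t_new * (b_new - b)
        b, t = b_new, t_new
        if it % 200 == 0:
            eta = np.clip(Xi @ b, -30, 30)
            obj = (np.mean(np.log1p(np.exp(eta)) - y * eta)
                   + lam * np.sum(pfi * np.abs(b)))
            if abs(prev_obj - obj) < tol:
                break
            prev_obj = obj
    return b[0], b[1:]


def test_solver_matches_proximal_gradient_oracle():
    """A feature present in 90% of cases and 5% of controls is active
    with beta > 0, and the coordinate-descent solution agrees with an
    independent FISTA minimizer of the same objective."""
    rng = np.random.default_rng(3)
    n_cases, n_controls = 200, 2000
    n = n_cases + n_controls
    y = np.r_[np.ones(n_cases), np.zeros(n_controls)]
    signal = np.r_[rng.random(n_cases) < 0.9,
                   rng.random(n_controls) < 0.05].astype(float)
    noise = (rng.random((n, 2)) < 0.1).astype(float)
    backg = rng.normal(size=(n, 2))
    X_raw = np.c_[signal, noise, backg]
    pf = np.array([1.0, 1.0, 1.0, 0.0, 0.0])

    def objective(b0, beta, lam):
        eta = np.clip(b0 + X @ beta, -30, 30)
        return (np.mean(np.log1p(np.exp(eta)) - y * eta)
                + lam * np.sum(pf * np.abs(beta)))

    X, _, _ = _standardize(X_raw)
    for lam in (0.05, 0.01, 0.002):
        coefs, b0s, ok = _fit_path(X, y, pf, np.array([lam]))
        assert ok
        b0_o, beta_o = _proximal_gradient_oracle(X, y, pf, lam)
        np.testing.assert_allclose(coefs[0], beta_o, atol=1e-3)
        np.testing.assert_allclose(b0s[0], b0_o, atol=1e-3)
        # both minimize the same convex objective to the same value
        assert objective(b0s[0], coefs[0], lam) <= \
            objective(b0_o, beta_o, lam) + 1e-7
        assert coefs[0][0] > 0          # planted feature active, positive


def test_signal_feature_active_at_lambda_se():
    rng = np.random.default_rng(4)
    n_cases, n_controls = 200, 2000
    rsids = [f"s{i}" for i in range(n_cases + n_controls)]
    y_sig = np.r_[rng.random(n_cases) < 0.9,
                  rng.random(n_controls) < 0.05].astype(int)
    matrix = pd.DataFrame({
        "sig": y_sig,
        "noise": (rng.random(n_cases + n_controls) < 0.1).astype(int),
    }, index=pd.Index(rsids, name="rsid"))
    cov = pd.DataFrame({
        "rsid": rsids,
        "dist_to_gene": rng.integers(0, 10_000, len(rsids)),
        "n_proxies": rng.integers(0, 5, len(rsids)),
        "maf": rng.uniform(0.1, 0.5, len(rsids)),
    })
    matched = [MatchedSet(case_rsid=rsids[i],
                          control_rsids=rsids[n_cases + i * 10:
                                              n_cases + (i + 1) * 10])
               for i in range(n_cases)]
    design = cl.assemble_design(matched, matrix, cov)
    path = cl.fit_lasso_cv(design, k_folds=5, seed=0, n_lambdas=40)
    model = cl.extract_scoring_model(path, "lambda_se")
    assert "sig" in model.entries and model.entries["sig"] > 0


def test_lambda_min_support_contains_lambda_se_support(small_fit):
    path = small_fit["path"]
    n_se = path.n_nonzero[path.index_of(path.lambda_se)]
    n_min = path.n_nonzero[path.index_of(path.lambda_min)]
    assert path.lambda_se >= path.lambda_min
    assert n_min >= n_se


def test_scoring_model_excludes_background(small_fit):
    model = small_fit["model"]
    assert not set(model.feature_ids) & set(BACKGROUND_COLUMNS)
    assert all(v != 0 for v in model.entries.values())
    assert set(model.background) == set(BACKGROUND_COLUMNS)


def test_fit_determinism(small_universe, small_matrix, small_covariates):
    u = small_universe
    matched, _ = cl.select_matched_controls(
        u.sentinels("rbc")[:25], small_covariates, ld_pairs=u.ld,
        n_controls=10, seed=2)
    design = cl.assemble_design(matched, small_matrix, small_covariates)
    p1 = cl.fit_lasso_cv(design, k_folds=4, seed=9)
    p2 = cl.fit_lasso_cv(design, k_folds=4, seed=9)
    assert p1.lambda_se == p2.lambda_se
    np.testing.assert_array_equal(p1.coefficients.to_numpy(),
                                  p2.coefficients.to_numpy())


def test_requesting_offgrid_lambda_errors(small_fit):
    with pytest.raises(ValueError, match="grid"):
        cl.extract_scoring_model(small_fit["path"], at=123.456)
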