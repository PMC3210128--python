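"""Sampler checks: exact special cases, hand-computed draws, enumeration oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from spikeslab.datatypes import ExpressionMatrix
from spikeslab.model import (
    DesignMatrix,
    InclusionPrior,
    PosteriorSamples,
    PriorConfig,
    SpikeSlabModel,
    build_design,
    compute_deviance,
    posterior_predict,
)


def make_design(X: np.ndarray, types=None, ids=None) -> DesignMatrix:
    n, p = X.shape
    ids = ids or [f"c{j}" for j in range(p)]
    frame = pd.DataFrame(X, index=[f"l{i}" for i in range(n)], columns=ids, dtype=float)
    return DesignMatrix(
        frame,
        np.asarray(types if types is not None else ["expression"] * p, dtype=object),
        pd.Series(0.0, index=frame.columns),
        pd.Series(1.0, index=frame.columns),
    )


def enumerate_posterior(X, y, pi, tau2, a0, b0, n_grid=400):
    """Exhaustive 2^p model enumeration with sigma^2 integrated numerically.

    For each model, alpha (N(0,1) prior) and the included coefficients
    (N(0, tau2)) are integrated analytically; the remaining 1-D integral
    over sigma^2 under its inverse-Gamma prior is done on a log grid.
    Returns (inclusion probabilities, posterior mean of I*beta).
    """
    n, p = X.shape
    log_s2 = np.linspace(np.log(np.var(y)) - 7, np.log(np.var(y)) + 7, n_grid)
    s2 = np.exp(log_s2)
    lp_s2 = a0 * np.log(b0) - math.lgamma(a0) - (a0 + 1) * log_s2 - b0 / s2 + log_s2
    models = list(itertools.product([0, 1], repeat=p))
    log_weights = np.empty(len(models))
    mean_beta = np.zeros((len(models), p))
    for mi, m in enumerate(models):
        idx = [j for j in range(p) if m[j]]
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in idx])
        V = np.diag([1.0] + [tau2] * len(idx))
        ZVZ = Z @ V @ Z.T
        lls = np.empty(n_grid)
        cond_beta = np.zeros((n_grid, len(idx)))
        for gi, s in enumerate(s2):
            lls[gi] = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=ZVZ + s * np.eye(n))
            prec = Z.T @ Z / s + np.linalg.inv(V)
            cond = np.linalg.solve(prec, Z.T @ y / s)
            cond_beta[gi] = cond[1:]
        integrand = lls + lp_s2
        mx = integrand.max()
        rel = np.exp(integrand - mx)
        norm = np.trapezoid(rel, log_s2)
        log_weights[mi] = mx + np.log(norm)
        k = len(idx)
        log_weights[mi] += k * np.log(pi) + (p - k) * np.log(1.0 - pi)
        if idx:
            post_beta = np.trapezoid(rel[:, None] * cond_beta, log_s2, axis=0) / norm
            mean_beta[mi, idx] = post_beta
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()
    pips = np.zeros(p)
    for wm, m in zip(w, models):
        pips += wm * np.asarray(m, dtype=float)
    return pips, w @ mean_beta


class TestBuildDesign:
    def test_sfp_only_columns_and_labels(self, ril_dataset):
        G, _, _, _ = ril_dataset
        sel = {"sfp": G.marker_ids[:10]}
        d = build_design(G=G, selection=sel)
        assert d.column_ids == G.marker_ids[:10]
        assert (d.col_types == "sfp").all()
        assert set(np.unique(d.values.to_numpy())) <= {0.0, 1.0}

    def test_joint_design_preserves_type_labels(self, ril_dataset):
        G, E, _, _ = ril_dataset
        sel = {"sfp": G.marker_ids[:5], "expression": E.gene_ids[:8]}
        d = build_design(G, E, sel)
        assert d.values.shape[1] == 13
        assert list(d.col_types) == ["sfp"] * 5 + ["expression"] * 8
        # expression columns standardized on the common lines
        expr = d.values.iloc[:, 5:]
        assert np.allclose(expr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(expr.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_missing_selection_id_errors_with_name(self, ril_dataset):
        G, E, _, _ = ril_dataset
        with pytest.raises(ValueError, match="no_such_gene"):
            build_design(G, E, {"expression": ["no_such_gene"]})

    def test_disjoint_lines_error(self, ril_dataset):
        G, E, _, _ = ril_dataset
        shifted = ExpressionMatrix(
            E.values.set_axis([f"x{i}" for i in range(len(E.line_ids))], axis=0))
        with pytest.raises(ValueError, match="no lines"):
            build_design(G, shifted, {"sfp": G.marker_ids[:2]})

    def test_apply_to_reuses_training_standardization(self, ril_dataset):
        G, E, _, _ = ril_dataset
        train = E.line_ids[:150]
        sub = ExpressionMatrix(E.values.loc[train])
        d = build_design(E=sub, selection={"expression": E.gene_ids[:3]})
        held = d.apply_to(E=E, lines=E.line_ids[150:])
        gene = E.gene_ids[0]
        mu = E.values.loc[train, gene].mean()
        sd = E.values.loc[train, gene].std(ddof=0)
        expected = (E.values.loc[E.line_ids[150:], gene] - mu) / sd
        assert np.allclose(held.values[gene], expected)


class TestSamplerSpecialCases:
    def test_always_out_collapses_to_shrunk_intercept(self):
        rng = np.random.default_rng(0)
        n = 100
        y = pd.Series(2.0 + rng.normal(size=n), index=[f"l{i}" for i in range(n)])
        d = make_design(rng.normal(size=(n, 1)))
        priors = PriorConfig(by_type={"expression": InclusionPrior("always_out")})
        res = SpikeSlabModel(y, d, priors).fit(iterations=2000, burn_in=500, chains=1, seed=1)
        pred = res.predict()
        assert np.allclose(pred, pred.iloc[0])  # constant predictions
        assert res.pip.iloc[0] == 0.0
        # alpha posterior mean ~= sample mean shrunk by the N(0,1) prior
        s2 = res.sigma2_mean
        expected = y.mean() * (n / s2) / (n / s2 + 1.0)
        assert res.intercept == pytest.approx(expected, abs=0.08)

    def test_always_in_matches_conjugate_linear_regression(self):
        # with fixed tau2 and a tight sigma^2 prior the posterior mean of
        # beta has the ridge-like closed form (Z'Z/s2 + Vinv)^-1 Z'y/s2
        rng = np.random.default_rng(1)
        n, p, s2 = 120, 4, 0.8
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 0.0, 0.3])
        y_arr = 0.5 + X @ beta + rng.normal(scale=np.sqrt(s2), size=n)
        d = make_design(X)
        priors = PriorConfig(
            by_type={"expression": InclusionPrior("always_in", tau2=1.0)},
            sigma2_shape=5000.0, sigma2_scale=5000.0 * s2,
        )
        y = pd.Series(y_arr, index=d.line_ids)
        res = SpikeSlabModel(y, d, priors).fit(iterations=6000, burn_in=1000, chains=2, seed=2)
        Z = np.column_stack([np.ones(n), X])
        Vinv = np.diag([1.0] + [1.0] * p)
        closed = np.linalg.solve(Z.T @ Z / s2 + Vinv, Z.T @ y_arr / s2)
        assert res.intercept == pytest.approx(closed[0], abs=0.05)
        assert np.allclose(res.params.to_numpy(), closed[1:], atol=0.05)
        assert (res.pip == 1.0).all()

    def test_pip_and_mean_beta_match_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        n, p = 40, 3
        X = rng.normal(size=(n, p))
        y_arr = 1.0 * X[:, 0] + rng.normal(size=n)
        pi, tau2, a0, b0 = 0.5, 1.0, 0.01, 0.01
        pips, mean_beta = enumerate_posterior(X, y_arr, pi, tau2, a0, b0)
        d = make_design(X)
        priors = PriorConfig(
            by_type={"expression": InclusionPrior("fixed_prob", pi=pi, tau2=tau2)},
            sigma2_shape=a0, sigma2_scale=b0,
        )
        y = pd.Series(y_arr, index=d.line_ids)
        res = SpikeSlabModel(y, d, priors).fit(
            iterations=20000, burn_in=4000, thin=1, chains=2, seed=3)
        assert np.abs(res.pip.to_numpy() - pips).max() < 0.03
        assert np.abs(res.params.to_numpy() - mean_beta).max() < 0.03

    def test_two_seeds_agree_on_inclusion_probabilities(self):
        rng = np.random.default_rng(5)
        n, p = 150, 10
        X = rng.normal(size=(n, p))
        y_arr = X[:, 0] - 0.8 * X[:, 1] + rng.normal(size=n)
        d = make_design(X)
        priors = PriorConfig(by_type={"expression": InclusionPrior("fixed_prob", pi=0.2)})
        y = pd.Series(y_arr, index=d.line_ids)
        m = SpikeSlabModel(y, d, priors)
        pip_a = m.fit(iterations=8000, burn_in=2000, chains=1, seed=11).pip
        pip_b = m.fit(iterations=8000, burn_in=2000, chains=1, seed=12).pip
        assert np.abs(pip_a - pip_b).max() < 0.03

    def test_same_seed_reproducible(self, ril_dataset, fitted_results):
        G, E, y, _ = ril_dataset
        m = fitted_results.model
        again = m.fit(iterations=3000, burn_in=1000, thin=2, chains=2, seed=21)
        assert np.array_equal(again.samples.beta, fitted_results.samples.beta)

    def test_input_validation(self, toy_design):
        y = pd.Series(np.ones(6), index=toy_design.line_ids)
        with pytest.raises(ValueError, match="zero variance"):
            SpikeSlabModel(y, toy_design)
        y2 = pd.Series(np.arange(6.0), index=toy_design.line_ids)
        model = SpikeSlabModel(y2, toy_design)
        with pytest.raises(ValueError, match="exceed"):
            model.fit(iterations=100, burn_in=100, seed=1)
        with pytest.raises(ValueError, match="seed"):
            model.fit(iterations=100, burn_in=10)


class TestPriorSampling:
    def test_fixed_shrinkage_prior_model_size(self, ril_dataset):
        G, _, y, _ = ril_dataset
        d = build_design(G=G, selection={"sfp": G.marker_ids[:50]})
        priors = PriorConfig(by_type={"sfp": InclusionPrior("fixed_prob", pi=0.1)})
        m = SpikeSlabModel(y, d, priors)
        prior = m.sample_prior(draws=20000, seed=4)
        assert prior.effective_model_size == pytest.approx(5.0, abs=0.15)

    def test_uniform_prior_expects_half_the_columns(self, ril_dataset):
        G, _, y, _ = ril_dataset
        d = build_design(G=G, selection={"sfp": G.marker_ids[:40]})
        priors = PriorConfig(by_type={"sfp": InclusionPrior("uniform_prob")})
        prior = SpikeSlabModel(y, d, priors).sample_prior(draws=40000, seed=5)
        assert prior.effective_model_size == pytest.approx(20.0, rel=0.02)


def hand_samples(alpha, beta, ind, sigma2, ids, types):
    d = len(alpha)
    T = len(set(types))
    return PosteriorSamples(
        column_ids=ids, column_types=np.asarray(types, dtype=object),
        alpha=np.asarray(alpha, float), beta=np.asarray(beta, float),
        indicator=np.asarray(ind, np.int8), sigma2=np.asarray(sigma2, float),
        pi=np.full((d, T), 0.5), tau2=np.ones((d, T)),
        type_labels=sorted(set(types)), chain=np.zeros(d, int),
    )


class TestPredictionAndDeviance:
    def test_prediction_equals_hand_average_of_three_draws(self, toy_design):
        s = hand_samples(
            alpha=[1.0, 2.0, 3.0],
            beta=[[1.0, 0.5], [2.0, -1.0], [0.5, 4.0]],
            ind=[[1, 1], [0, 1], [1, 0]],
            sigma2=[1.0, 1.0, 1.0],
            ids=toy_design.column_ids, types=list(toy_design.col_types),
        )
        X = toy_design.matrix()
        rows = [1.0 + X[:, 0] + 0.5 * X[:, 1], 2.0 - X[:, 1], 3.0 + 0.5 * X[:, 0]]
        expected = np.mean(rows, axis=0)
        assert np.allclose(posterior_predict(s, toy_design), expected)

    def test_all_excluded_draws_predict_the_intercept(self, toy_design):
        s = hand_samples([1.5, 1.5], np.ones((2, 2)), np.zeros((2, 2)), [1.0, 1.0],
                         toy_design.column_ids, list(toy_design.col_types))
        assert np.allclose(posterior_predict(s, toy_design), 1.5)

    def test_column_mismatch_rejected(self, toy_design):
        s = hand_samples([0.0], [[0.0, 0.0]], [[0, 0]], [1.0],
                         ["other", "cols"], ["sfp", "expression"])
        with pytest.raises(ValueError, match="columns"):
            posterior_predict(s, toy_design)

    def test_perfect_fit_unit_variance_deviance(self, toy_design):
        # mu = y exactly, sigma2 = 1 -> deviance = n log(2 pi)
        X = toy_design.matrix()
        y = pd.Series(2.0 + X[:, 0] - X[:, 1], index=toy_design.line_ids)
        s = hand_samples([2.0], [[1.0, -1.0]], [[1, 1]], [1.0],
                         toy_design.column_ids, list(toy_design.col_types))
        n = len(y)
        assert compute_deviance(s, toy_design, y) == pytest.approx(n * np.log(2 * np.pi))

    def test_single_draw_matches_hand_likelihood(self, toy_design):
        X = toy_design.matrix()
        y = pd.Series(np.arange(6.0), index=toy_design.line_ids)
        alpha, beta, s2 = 0.5, np.array([1.0, 2.0]), 1.7
        mu = alpha + X @ beta
        hand = np.sum(np.log(2 * np.pi * s2) + (y.to_numpy() - mu) ** 2 / s2)
        s = hand_samples([alpha], [beta], [[1, 1]], [s2],
                         toy_design.column_ids, list(toy_design.col_types))
        assert compute_deviance(s, toy_design, y) == pytest.approx(hand)

    def test_adding_true_predictors_lowers_deviance(self, ril_dataset):
        G, E, y, truth = ril_dataset
        planted = list(truth.marker_effects)
        priors = PriorConfig.non_indicator()
        d_small = build_design(G=G, selection={"sfp": planted[:1]})
        d_full = build_design(G=G, selection={"sfp": planted})
        dev_small = SpikeSlabModel(y, d_small, priors).fit(
            iterations=1500, burn_in=500, chains=1, seed=6).deviance()
        dev_full = SpikeSlabModel(y, d_full, priors).fit(
            iterations=1500, burn_in=500, chains=1, seed=6).deviance()
        assert dev_full < dev_small

    def test_in_sample_predictions_used_for_goodness_of_fit(self, fitted_results):
        direct = posterior_predict(fitted_results.samples, fitted_results.model.design)
        pd.testing.assert_series_equal(fitted_results.fittedvalues, direct)

    def test_summary_renders(self, fitted_results):
        text = fitted_results.summary()
        assert "Effective model size" in text and "pip" in text
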