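"""Panel GVAR core: moments, likelihoods, estimation, networks, fit indices."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize, stats

from clpn import (
    PGVARParameters,
    NetworkSet,
    PanelDataset,
    PanelGVAR,
    StructureMasks,
    fiml_loglik,
    fit_indices,
    fit_saturated,
    implied_moments,
    networks_from_params,
    simulate,
    stationary_covariance,
    structure_search,
)
from clpn.cohort import random_sparse_scenario
from clpn.model import (
    _fiml_loglik_moments,
    masks_at_penalty,
    moment_estimate,
)


def _params(p=2, b=0.0, kz=1.0, kb=1.0):
    return PGVARParameters(
        mu=np.zeros(p),
        B=np.eye(p) * b,
        K_zeta=np.eye(p) * kz,
        K_B=np.eye(p) * kb,
    )


# -- stationary covariance --------------------------------------------------


def test_stationary_no_dynamics():
    S = np.array([[2.0, 0.3], [0.3, 1.0]])
    assert np.allclose(stationary_covariance(np.zeros((2, 2)), S), S)


def test_stationary_scalar_closed_form():
    S0 = stationary_covariance(np.array([[0.5]]), np.array([[0.75]]))
    assert S0[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_stationary_matches_fixed_point_oracle(rng):
    for _ in range(3):
        B = rng.normal(scale=0.2, size=(4, 4))
        A = rng.normal(size=(4, 4))
        Sz = A @ A.T + np.eye(4)
        S0 = stationary_covariance(B, Sz)
        # brute-force fixed-point iteration written independently
        S = Sz.copy()
        for _ in range(2000):
            S = B @ S @ B.T + Sz
        assert np.max(np.abs(S0 - S)) < 1e-10


def test_stationary_nonstationary_errors():
    with pytest.raises(ValueError, match="non-stationary"):
        stationary_covariance(np.eye(2) * 1.05, np.eye(2))


# -- implied moments --------------------------------------------------------


def test_implied_moments_exchangeable_when_b_zero():
    params = _params(p=2, b=0.0, kz=2.0, kb=4.0)
    _, cov = implied_moments(params, 3)
    Sigma_B = np.eye(2) / 4.0
    Sigma_zeta = np.eye(2) / 2.0
    for s in range(3):
        for t in range(3):
            blk = cov[2 * s : 2 * s + 2, 2 * t : 2 * t + 2]
            want = Sigma_B + (Sigma_zeta if s == t else 0.0)
            assert np.allclose(blk, want)


def test_implied_moments_scalar_hand_computation():
    params = PGVARParameters(
        mu=[0.0], B=[[0.5]], K_zeta=[[1.0 / 0.75]], K_B=[[1.0]]
    )
    mean, cov = implied_moments(params, 2)
    assert np.allclose(mean, [0.0, 0.0])
    assert np.allclose(cov, [[2.0, 1.5], [1.5, 2.0]], atol=1e-12)


# -- FIML -------------------------------------------------------------------


def test_fiml_equals_stacked_mvn_on_complete_data(rng):
    params = _params(p=2, b=0.3)
    data = PanelDataset(
        values=rng.normal(size=(5, 3, 2)), mask=np.ones((5, 3, 2), bool)
    )
    mean, cov = implied_moments(params, 3)
    want = stats.multivariate_normal(mean, cov).logpdf(
        data.values.reshape(5, -1)
    ).sum()
    assert fiml_loglik(params, data) == pytest.approx(want, abs=1e-9)


def test_fiml_univariate_reduction():
    params = PGVARParameters(mu=[1.5], B=[[0.4]], K_zeta=[[2.0]], K_B=[[1.0]])
    values = np.full((1, 2, 1), np.nan)
    values[0, 0, 0] = 2.2
    mask = np.zeros((1, 2, 1), bool)
    mask[0, 0, 0] = True
    data = PanelDataset(values=values, mask=mask)
    _, cov = implied_moments(params, 2)
    want = stats.norm(1.5, np.sqrt(cov[0, 0])).logpdf(2.2)
    assert fiml_loglik(params, data) == pytest.approx(want, abs=1e-12)


def test_fiml_matches_bruteforce_marginalization(rng):
    params = _params(p=2, b=0.25)
    values = rng.normal(size=(6, 3, 2))
    mask = rng.random((6, 3, 2)) > 0.3
    mask[mask.sum(axis=(1, 2)) == 0] = True
    data = PanelDataset(values=values, mask=mask)
    mean, cov = implied_moments(params, 3)
    want = 0.0
    vals2, mask2 = data.stacked()
    for i in range(6):
        obs = mask2[i]
        want += stats.multivariate_normal(
            mean[obs], cov[np.ix_(obs, obs)]
        ).logpdf(vals2[i, obs])
    assert fiml_loglik(params, data) == pytest.approx(want, abs=1e-8)


def test_fiml_singular_covariance_names_person():
    data = PanelDataset(values=np.ones((2, 2, 1)), mask=np.ones((2, 2, 1), bool))
    singular = np.ones((2, 2))
    with pytest.raises(Exception, match="person"):
        _fiml_loglik_moments(np.zeros(2), singular, data)


# -- saturated fit ----------------------------------------------------------


def test_saturated_complete_closed_form(rng):
    values = rng.normal(size=(20, 2, 2))
    data = PanelDataset(values=values, mask=np.ones((20, 2, 2), bool))
    mean, cov, ll = fit_saturated(data)
    flat = values.reshape(20, -1)
    assert np.allclose(mean, flat.mean(axis=0))
    assert np.allclose(cov, np.cov(flat.T, bias=True))
    assert ll == pytest.approx(_fiml_loglik_moments(mean, cov, data), abs=1e-9)


def test_saturated_warns_rank_deficient(rng):
    values = rng.normal(size=(3, 2, 2))  # 3 persons < 4 coordinates
    data = PanelDataset(values=values, mask=np.ones((3, 2, 2), bool))
    with pytest.warns(UserWarning, match="rank-deficient"):
        with pytest.raises(Exception, match="not invertible"):
            fit_saturated(data)


def test_saturated_em_matches_numeric_oracle(rng):
    # six persons, one node, two waves, one missing cell: compare the EM
    # optimum against direct numeric maximization of the observed loglik
    values = np.array(
        [
            [[0.4], [1.0]],
            [[0.9], [np.nan]],
            [[-0.2], [0.5]],
            [[1.1], [0.2]],
            [[0.3], [0.9]],
            [[-0.5], [0.1]],
        ]
    )
    mask = ~np.isnan(values)
    data = PanelDataset(values=values, mask=mask)
    mean, cov, ll = fit_saturated(data)

    def neg_ll(theta):
        m = theta[:2]
        L = np.array([[np.exp(theta[2]), 0.0], [theta[3], np.exp(theta[4])]])
        return -_fiml_loglik_moments(m, L @ L.T, data)

    res = optimize.minimize(
        neg_ll, np.array([0.3, 0.7, -0.5, 0.0, -0.5]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    assert ll == pytest.approx(-res.fun, abs=1e-6)
    m_hat = res.x[:2]
    assert np.allclose(mean, m_hat, atol=1e-4)


def test_likelihood_nesting(fitted, sparse_data):
    assert fitted.saturated_loglik >= fitted.log_likelihood - 1e-6
    # a masked submodel can never beat the dense fit
    p = sparse_data.n_nodes
    sub = PanelGVAR(sparse_data, structure=StructureMasks.empty(p)).fit(
        compute_se=False
    )
    assert fitted.log_likelihood >= sub.log_likelihood - 1e-6


# -- networks ---------------------------------------------------------------


def test_partial_correlation_two_node_identity():
    params = PGVARParameters(
        mu=np.zeros(2),
        B=np.zeros((2, 2)),
        K_zeta=np.array([[1.0, -0.5], [-0.5, 1.0]]),
        K_B=np.eye(2),
    )
    nets = networks_from_params(params)
    assert nets.contemporaneous[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert np.allclose(nets.between, 0.0)


def test_partial_correlation_residualization_oracle(rng):
    A = rng.normal(size=(3, 3))
    K = A @ A.T + 3 * np.eye(3)
    params = PGVARParameters(
        mu=np.zeros(3), B=np.zeros((3, 3)), K_zeta=K, K_B=np.eye(3)
    )
    nets = networks_from_params(params)
    # oracle: correlate residuals after regressing out the third variable,
    # using the population covariance inv(K)
    S = np.linalg.inv(K)
    for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        bi = S[i, k] / S[k, k]
        bj = S[j, k] / S[k, k]
        cij = S[i, j] - bi * S[k, j]
        vii = S[i, i] - bi * S[k, i]
        vjj = S[j, j] - bj * S[k, j]
        want = cij / np.sqrt(vii * vjj)
        assert nets.contemporaneous[i, j] == pytest.approx(want, abs=1e-10)


def test_planted_partial_round_trip():
    rho = 0.37
    K = np.array([[1.0, -rho, 0.0], [-rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    params = PGVARParameters(
        mu=np.zeros(3), B=np.zeros((3, 3)), K_zeta=K, K_B=np.eye(3)
    )
    nets = networks_from_params(params)
    assert nets.contemporaneous[0, 1] == pytest.approx(rho, abs=1e-12)


def test_temporal_standardization_flags():
    params = PGVARParameters(
        mu=np.zeros(2),
        B=np.array([[0.5, 0.2], [0.0, 0.3]]),
        K_zeta=np.eye(2),
        K_B=np.eye(2),
    )
    S0 = stationary_covariance(params.B, np.eye(2))
    s = np.sqrt(np.diag(S0))
    stat = networks_from_params(params, "stationary")
    resid = networks_from_params(params, "residual")
    assert stat.temporal[0, 1] == pytest.approx(0.2 * s[1] / s[0])
    assert resid.temporal[0, 1] == pytest.approx(0.2 * s[1] / 1.0)
    with pytest.raises(ValueError):
        networks_from_params(params, "pearson")


def test_network_set_invariants():
    with pytest.raises(ValueError, match="symmetric"):
        NetworkSet(
            temporal=np.zeros((2, 2)),
            contemporaneous=np.array([[0.0, 0.5], [0.2, 0.0]]),
            between=np.zeros((2, 2)),
        )
    with pytest.raises(ValueError, match=r"\(-1, 1\)"):
        NetworkSet(
            temporal=np.zeros((2, 2)),
            contemporaneous=np.array([[0.0, 1.5], [1.5, 0.0]]),
            between=np.zeros((2, 2)),
        )


# -- fit indices ------------------------------------------------------------


def test_fit_indices_saturated_is_perfect():
    fi = fit_indices(-100.0, 5, -100.0, -400.0, 20, 500)
    assert fi.chi_square == 0.0
    assert fi.cfi == 1.0
    assert fi.rmsea == 0.0


def test_fit_indices_worked_example():
    # chi2_M = 50 (df 40), chi2_B = 500 (df 60), n = 1000
    fi = fit_indices(-25.0, 40, 0.0, -250.0, 60, 1000)
    assert fi.chi_square == pytest.approx(50.0)
    assert fi.cfi == pytest.approx(1.0 - 10.0 / 440.0, abs=1e-12)
    want_tli = ((500 / 60) - (50 / 40)) / ((500 / 60) - 1.0)
    assert fi.tli == pytest.approx(want_tli, abs=1e-12)
    assert fi.rmsea == pytest.approx(np.sqrt(10.0 / (40 * 1000)), abs=1e-12)


def test_fit_indices_central_chi_square_boundary():
    fi = fit_indices(-20.0, 40, 0.0, -250.0, 60, 1000)  # chi2_M = df_M = 40
    assert fi.rmsea == 0.0
    assert fi.tli >= 1.0 - 1e-12


def test_fit_indices_baseline_clamp_warns():
    with pytest.warns(UserWarning, match="clamped"):
        fi = fit_indices(-30.0, 10, 0.0, -5.0, 60, 100)
    assert 0.0 <= fi.cfi <= 1.0


def test_rmsea_ci_brackets_point_estimate():
    fi = fit_indices(-50.0, 20, 0.0, -500.0, 60, 300)
    assert fi.rmsea_ci90_low <= fi.rmsea + 1e-12
    assert fi.rmsea_ci90_high >= fi.rmsea - 1e-12


# -- estimation -------------------------------------------------------------


def test_masked_fit_respects_zeros(sparse_data):
    p = sparse_data.n_nodes
    masks = StructureMasks.empty(p)
    res = PanelGVAR(sparse_data, structure=masks).fit(compute_se=False)
    offdiag = ~np.eye(p, dtype=bool)
    assert np.all(res.params.B[offdiag] == 0.0)
    assert np.all(res.params.K_zeta[offdiag] == 0.0)
    assert np.all(res.params.K_B[offdiag] == 0.0)


def test_fit_deterministic(sparse_data):
    r1 = PanelGVAR(sparse_data).fit(compute_se=False)
    r2 = PanelGVAR(sparse_data).fit(compute_se=False)
    assert np.array_equal(r1.theta, r2.theta)


def test_fit_results_shape(fitted, sparse_data):
    p = sparse_data.n_nodes
    assert fitted.networks.temporal.shape == (p, p)
    assert fitted.converged
    assert 0.0 <= fitted.fit_indices.cfi <= 1.0
    assert fitted.fit_indices.chi_square >= 0.0
    pv = fitted.edge_pvalues()
    assert ("temporal", 0, 1) in pv
    assert all(0.0 <= v <= 1.0 for v in pv.values())
    assert "Panel GVAR results" in fitted.summary()


def test_direct_fiml_agrees_with_twostage_on_complete_data():
    sc = dataclasses.replace(
        random_sparse_scenario(5, n_nodes=3, n_waves=4, seed=9), n_persons=400
    )
    data = simulate(sc)
    two = PanelGVAR(data).fit(method="twostage", compute_se=False)
    direct = PanelGVAR(data).fit(method="direct", compute_se=False)
    # complete data: both maximize the same likelihood
    assert direct.log_likelihood == pytest.approx(
        two.log_likelihood, abs=0.05
    )
    assert np.allclose(direct.params.B, two.params.B, atol=0.02)


def test_equivariance_under_node_permutation(sparse_data):
    perm = np.array([2, 0, 3, 1, 4])
    permuted = PanelDataset(
        values=sparse_data.values[:, :, perm],
        mask=sparse_data.mask[:, :, perm],
        nodes=[sparse_data.nodes[j] for j in perm],
    )
    mean1, cov1, _ = fit_saturated(sparse_data)
    est1 = moment_estimate(mean1, cov1, sparse_data.n_waves, 5)
    mean2, cov2, _ = fit_saturated(permuted)
    est2 = moment_estimate(mean2, cov2, sparse_data.n_waves, 5)
    nets1 = networks_from_params(est1)
    nets2 = networks_from_params(est2)
    assert np.allclose(
        nets2.temporal, nets1.temporal[np.ix_(perm, perm)], atol=1e-8
    )
    assert np.allclose(
        nets2.contemporaneous, nets1.contemporaneous[np.ix_(perm, perm)], atol=1e-8
    )


def test_moment_estimator_consistency():
    sc = dataclasses.replace(
        random_sparse_scenario(5, n_nodes=4, n_waves=5, seed=21), n_persons=20000
    )
    data = simulate(sc)
    mean, cov, _ = fit_saturated(data)
    est = moment_estimate(mean, cov, 5, 4)
    assert np.max(np.abs(est.B - sc.params.B)) < 0.05
    assert np.max(np.abs(est.sigma_B - sc.params.sigma_B)) < 0.05


# -- structure path ---------------------------------------------------------


def test_penalty_path_endpoints(sparse_data):
    mean, cov, _ = fit_saturated(sparse_data)
    est = moment_estimate(mean, cov, sparse_data.n_waves, sparse_data.n_nodes)
    p = sparse_data.n_nodes
    sparse_end = masks_at_penalty(est, 10.0)
    assert np.array_equal(sparse_end.b_mask, np.eye(p, dtype=bool))
    assert np.array_equal(sparse_end.kzeta_mask, np.eye(p, dtype=bool))
    dense_end = masks_at_penalty(est, 0.0)
    assert dense_end.b_mask.all()
    assert dense_end.kzeta_mask.all()


def test_structure_search_returns_masks_and_refit(sparse_data):
    masks, res = structure_search(sparse_data, n_models=20, compute_se=False)
    p = sparse_data.n_nodes
    assert masks.b_mask.shape == (p, p)
    assert np.diag(masks.b_mask).all()
    # refit honors the mask
    assert np.all(res.params.B[~masks.b_mask] == 0.0)


def test_parameters_validate():
    with pytest.raises(ValueError, match="non-stationary"):
        _params(b=1.2).validate()
    with pytest.raises(ValueError, match="positive definite"):
        PGVARParameters(
            mu=np.zeros(2),
            B=np.zeros((2, 2)),
            K_zeta=np.array([[1.0, 2.0], [2.0, 1.0]]),
            K_B=np.eye(2),
        ).validate()
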