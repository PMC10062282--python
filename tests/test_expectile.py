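import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import expectmon as em
from expectmon.expectile import GridSearchConfig

POLISHED = GridSearchConfig(polish=True)


# ---------------------------------------------------------------------------
# loss calculus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tau,x,expected",
    [(0.3, 0.0, 0.0), (0.5, 2.0, 2.0), (0.25, -2.0, 3.0)],
)
def test_rho_examples(tau, x, expected):
    assert em.rho(tau, x) == pytest.approx(expected)


@pytest.mark.parametrize(
    "tau,x,expected",
    [(0.5, -3.0, -3.0), (0.5, 0.0, 0.0), (0.5, 7.0, 7.0), (0.25, -2.0, -3.0)],
)
def test_g_examples(tau, x, expected):
    assert em.g(tau, x) == pytest.approx(expected)


@pytest.mark.parametrize(
    "tau,x,expected",
    [(0.5, -5.0, 1.0), (0.5, 3.0, 1.0), (0.1, -1.0, 1.8), (0.3, 0.0, 0.6)],
)
def test_h_examples(tau, x, expected):
    # x = 0 sits on the x >= 0 branch by convention
    assert em.h(tau, x) == pytest.approx(expected)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    tau=st.floats(0.01, 0.99),
    x=st.floats(-50.0, 50.0, allow_nan=False),
)
def test_rho_reflection_symmetry(tau, x):
    assert em.rho(tau, x) == pytest.approx(em.rho(1.0 - tau, -x), rel=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    tau=st.floats(0.05, 0.95),
    x=st.floats(-20.0, 20.0).filter(lambda v: abs(v) > 1e-3),
)
def test_g_is_derivative_of_rho(tau, x):
    delta = 1e-7 * max(1.0, abs(x))
    fd = (em.rho(tau, x + delta) - em.rho(tau, x - delta)) / (2.0 * delta)
    assert fd == pytest.approx(em.g(tau, x), rel=1e-5, abs=1e-8)


@pytest.mark.parametrize("fn", [em.rho, em.g, em.h])
@pytest.mark.parametrize("tau", [0.0, 1.0, -0.2, 1.3])
def test_loss_rejects_tau_outside_unit_interval(fn, tau):
    with pytest.raises(ValueError):
        fn(tau, 1.0)


# ---------------------------------------------------------------------------
# tau-hat and the score variance
# ---------------------------------------------------------------------------

def test_tau_hat_examples():
    assert em.tau_hat([1.0, -1.0]) == pytest.approx(0.5)
    assert em.tau_hat([3.0, -1.0]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        em.tau_hat([5.0, 5.0])
    with pytest.raises(ValueError):
        em.tau_hat([-1.0, -2.0])


def test_tau_hat_matches_bisection_root():
    # the closed form must equal a numeric root of the monotone moment equation
    rng = np.random.default_rng(42)
    for _ in range(100):
        r = rng.standard_normal(rng.integers(5, 60)) + rng.uniform(-0.5, 0.5)
        if not ((r > 0).any() and (r < 0).any()):
            continue
        moment = lambda tau: float(np.mean(em.g(tau, r)))
        root = optimize.brentq(moment, 1e-12, 1.0 - 1e-12, xtol=1e-14)
        closed = em.tau_hat(r)
        assert closed == pytest.approx(root, abs=1e-10)
        assert abs(moment(closed)) < 1e-10


def test_var_g_examples():
    assert em.var_g([1.0, -1.0], 0.5) == pytest.approx(2.0)
    assert em.var_g([0.0, 0.0, 0.0], 0.3) == 0.0
    r = np.array([0.4, -1.2, 2.0, -0.3])
    assert em.var_g(3.0 * r, 0.2) == pytest.approx(9.0 * em.var_g(r, 0.2))
    with pytest.raises(ValueError):
        em.var_g([1.0], 0.5)


# ---------------------------------------------------------------------------
# J matrix and its Cholesky inverse square root
# ---------------------------------------------------------------------------

def test_J_matrix_linear_is_scaled_crossproduct():
    model = em.linear_model()
    x = np.array([0.0, 1.0, 2.0, 4.0])
    D = np.column_stack([np.ones(4), x])
    J = em.J_matrix(model, x, [0.3, -0.7], var_g_value=1.7)
    assert np.allclose(J, 1.7 * D.T @ D / 4)


def test_J_matrix_intercept_only_and_zero_variance():
    model = em.constant_model()
    x = np.zeros(3)
    assert em.J_matrix(model, x, [1.0], 2.0) == pytest.approx(np.array([[2.0]]))
    assert np.allclose(em.J_matrix(model, x, [1.0], 0.0), 0.0)


def test_inv_sqrt_cholesky():
    assert np.allclose(em.inv_sqrt_cholesky(np.eye(3)), np.eye(3))
    assert np.allclose(em.inv_sqrt_cholesky(np.diag([4.0, 9.0])), np.diag([0.5, 1.0 / 3.0]))
    rng = np.random.default_rng(1)
    A = rng.standard_normal((4, 4))
    J = A @ A.T + 0.5 * np.eye(4)
    M = em.inv_sqrt_cholesky(J)
    assert np.allclose(M @ J @ M.T, np.eye(4), atol=1e-8)
    assert np.allclose(M, np.tril(M))  # lower-triangular
    with pytest.raises(Exception):
        em.inv_sqrt_cholesky(np.array([[1.0, 0.0], [0.0, -1.0]]))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_linear_interpolates_two_points():
    fit = em.fit_expectile(em.linear_model(), [0.0, 1.0], [1.0, 3.0], 0.5, search=POLISHED)
    assert fit.beta_hat == pytest.approx([1.0, 2.0], abs=1e-5)
    assert np.allclose(fit.residuals, 0.0, atol=1e-5)
    assert fit.objective == pytest.approx(0.0, abs=1e-10)


def test_fit_mean_expectile_of_bernoulli_sample():
    # the 0.5-expectile is the mean: [0,0,0,1] -> 1/4
    fit = em.fit_expectile(
        em.constant_model(), np.zeros(4), [0.0, 0.0, 0.0, 1.0], 0.5, search=POLISHED
    )
    assert fit.beta_hat[0] == pytest.approx(0.25, abs=1e-6)


def test_fit_linear_half_expectile_matches_least_squares():
    rng = np.random.default_rng(8)
    x = rng.uniform(-2, 3, 40)
    y = 1.5 - 0.8 * x + rng.standard_normal(40)
    fit = em.fit_expectile(em.linear_model(), x, y, 0.5, search=POLISHED)
    D = np.column_stack([np.ones_like(x), x])
    beta_ls = np.linalg.solve(D.T @ D, D.T @ y)  # normal equations oracle
    assert np.allclose(fit.beta_hat, beta_ls, atol=1e-5)


@pytest.mark.parametrize("tau", [0.1, 0.35, 0.5, 0.8])
def test_intercept_only_fit_equals_scalar_expectile(tau):
    rng = np.random.default_rng(13)
    y = rng.standard_normal(60) + 0.4
    fit = em.fit_expectile(em.constant_model(), np.zeros_like(y), y, tau, search=POLISHED)
    # independent scalar root-finder: the tau-expectile zeroes E g_tau(y - c)
    root = optimize.brentq(
        lambda c: float(np.mean(em.g(tau, y - c))), y.min() - 1, y.max() + 1, xtol=1e-12
    )
    assert fit.beta_hat[0] == pytest.approx(root, abs=1e-6)


def test_fit_populates_consistent_plugins(gompertz_data):
    fit = gompertz_data.fit
    # residual identity and the J = var_g * V factorisation
    assert np.array_equal(
        fit.residuals, gompertz_data.y - fit.model.predict(gompertz_data.x, fit.beta_hat)
    )
    assert fit.var_g == pytest.approx(em.var_g(fit.residuals, fit.tau))
    assert np.allclose(fit.J_m, fit.var_g * fit.V_m)
    assert np.allclose(fit.J_m, fit.J_m.T)
    assert np.allclose(fit.J_inv_sqrt @ fit.J_m @ fit.J_inv_sqrt.T, np.eye(2), atol=1e-8)
    assert fit.objective <= np.sum(em.rho(fit.tau, fit.residuals)) + 1e-9


def test_estimated_tau_zeroes_the_moment():
    rng = np.random.default_rng(9)
    model = em.gompertz2_model()
    x = rng.uniform(0, 1, 150)
    y = model.predict(x.reshape(-1, 1), [10.0, 5.0]) + 1.0 + rng.standard_normal(150)
    fit = em.fit_expectile_estimated_tau(model, x, y)
    assert fit.tau_estimated
    assert 0.0 < fit.tau < 0.5  # positively skewed errors push the index low
    assert abs(np.mean(em.g(fit.tau, fit.residuals))) < 1e-8


def test_fit_input_validation():
    model = em.gompertz2_model()
    with pytest.raises(ValueError):
        em.fit_expectile(model, [0.5], [1.0], 0.5)  # m < p
    with pytest.raises(ValueError):
        em.fit_expectile(model, [0.1, 0.5, 0.9], [1.0, np.nan, 0.5], 0.5)
    with pytest.raises(ValueError):
        em.fit_expectile(model, [0.1, 0.5], [1.0, 2.0], 1.5)
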