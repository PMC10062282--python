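"""Expectile loss calculus and nonlinear expectile estimation.

The tau-expectile of a distribution is the minimiser of the asymmetrically
weighted squared loss

    rho_tau(x) = |tau - 1{x < 0}| x^2 ,

so tau = 1/2 recovers the mean and ordinary (nonlinear) least squares.
Estimation minimises the empirical rho_tau-risk of ``y - f(x, beta)`` over
a compact parameter box by an iterative grid search: a coarse grid over the
full box is refined around the incumbent with a geometrically shrinking
span.  The objective need not be convex in beta, which is why a global
search (rather than a single local solver) is the default; an optional
derivative-based polish can tighten the final point.

The module also provides the plug-in quantities needed by the sequential
monitoring statistic: the implicit expectile-index estimate tau-hat that
zeroes the empirical moment (1/m) sum g_tau(residual_i), the score variance
S^2 = (1/(m-1)) sum g_tau(residual_i)^2, the matrix
J_m = S^2 * (1/m) sum grad_f grad_f^T, and the inverse of its lower
Cholesky factor.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy import linalg, optimize

from .models import ModelSpec, as_design

Array = np.ndarray

__all__ = [
    "rho",
    "g",
    "h",
    "GridSearchConfig",
    "ExpectileFit",
    "fit_expectile",
    "fit_expectile_estimated_tau",
    "tau_hat",
    "var_g",
    "J_matrix",
    "inv_sqrt_cholesky",
    "AsymptoticApprox",
    "asymptotic_approx",
    "linearization_remainder",
]


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    return tau


def rho(tau: float, x) -> Array | float:
    """Expectile loss |tau - 1{x < 0}| x^2 (elementwise)."""
    tau = _check_tau(tau)
    x = np.asarray(x, dtype=float)
    w = np.where(x < 0, 1.0 - tau, tau)
    out = w * x * x
    return out if out.ndim else float(out)


def g(tau: float, x) -> Array | float:
    """First derivative of the expectile loss.

    ``g(tau, x) = 2 tau x`` for x >= 0 and ``2 (1-tau) x`` for x < 0;
    at tau = 1/2 this is the identity.  x = 0 belongs to the x >= 0 branch.
    """
    tau = _check_tau(tau)
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 2.0 * tau * x, 2.0 * (1.0 - tau) * x)
    return out if out.ndim else float(out)


def h(tau: float, x) -> Array | float:
    """Second derivative of the expectile loss: 2 tau (x >= 0) or 2 (1-tau)."""
    tau = _check_tau(tau)
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 2.0 * tau, 2.0 * (1.0 - tau))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Plug-in quantities
# ---------------------------------------------------------------------------

def tau_hat(residuals: Array) -> float:
    """Expectile index solving (1/m) sum g_tau(residual_i) = 0.

    The moment is linear in tau, so the root is available in closed form:
    with A = sum of nonnegative residuals and B = sum of negative residuals,
    tau = -B / (A - B).  Requires residuals of both signs, otherwise no
    root exists inside (0, 1).
    """
    r = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals contain non-finite values")
    A = float(r[r >= 0].sum())
    B = float(r[r < 0].sum())
    if A <= 0.0 or B >= 0.0:
        raise ValueError("tau-hat requires residuals of both signs")
    return -B / (A - B)


def var_g(residuals: Array, tau: float) -> float:
    """Sample variance proxy S^2 = (1/(m-1)) sum g_tau(residual_i)^2."""
    tau = _check_tau(tau)
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two residuals")
    gv = np.asarray(g(tau, r))
    return float(gv @ gv) / (r.size - 1)


def J_matrix(model: ModelSpec, X: Array, beta: Array, var_g_value: float) -> Array:
    """J = var_g * (1/m) sum grad_f(x_i, beta) grad_f(x_i, beta)^T."""
    if var_g_value < 0:
        raise ValueError("var_g must be nonnegative")
    G = model.predict_grad(X, beta)
    m = G.shape[0]
    return var_g_value * (G.T @ G) / m


def inv_sqrt_cholesky(J: Array, ridge: bool = True) -> Array:
    """Inverse of the lower Cholesky factor of a symmetric PD matrix.

    Returns M = L^{-1} where J = L L^T, so that M J M^T = I.  If the
    factorisation fails and ``ridge`` is set, a single diagonal ridge of
    1e-10 * trace(J)/p is added before retrying; a second failure raises.
    """
    J = np.asarray(J, dtype=float)
    p = J.shape[0]
    try:
        L = linalg.cholesky(J, lower=True)
    except linalg.LinAlgError:
        if not ridge:
            raise
        bump = 1e-10 * np.trace(J) / p
        if bump <= 0:
            raise linalg.LinAlgError("J is not positive definite and has no mass to ridge")
        try:
            L = linalg.cholesky(J + bump * np.eye(p), lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError("J is not positive definite even after ridge") from exc
    return linalg.solve_triangular(L, np.eye(p), lower=True)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GridSearchConfig:
    """Settings of the iterative grid search.

    n_stages refinement passes are made with n_points per dimension; each
    pass is centred on the incumbent with the span shrunk by ``shrink``
    relative to the previous full width and clipped to the parameter box.
    The search stops early once every per-coordinate step falls below
    ``step_tol`` times the box width.  ``polish`` runs a bounded
    quasi-Newton refinement (L-BFGS-B on the smooth expectile risk with its
    analytic gradient) from the grid incumbent.
    """

    n_stages: int = 3
    n_points: int = 41
    shrink: float = 0.12
    step_tol: float = 1e-3
    polish: bool = False

    def __post_init__(self):
        if self.n_stages < 1 or self.n_points < 2:
            raise ValueError("need at least one stage and two grid points")
        if not 0.0 < self.shrink < 1.0:
            raise ValueError("shrink must lie in (0, 1)")


@dataclasses.dataclass
class ExpectileFit:
    """A fitted expectile regression with its monitoring plug-ins."""

    model: ModelSpec
    beta_hat: Array
    tau: float
    residuals: Array
    var_g: float
    V_m: Array
    J_m: Array
    # None when J_m is singular (e.g. an exactly interpolating fit);
    # monitoring then raises, estimation results remain usable.
    J_inv_sqrt: Optional[Array]
    objective: float
    m: int
    tau_estimated: bool = False
    search: GridSearchConfig = dataclasses.field(default_factory=GridSearchConfig)

    def predict(self, X: Array) -> Array:
        return self.model.predict(X, self.beta_hat)

    def score_terms(self, X: Array, Y: Array) -> Array:
        """Per-observation monitoring scores grad_f(x, beta_hat) g_tau(residual)."""
        X = as_design(X, self.model.q)
        Y = np.asarray(Y, dtype=float).reshape(-1)
        resid = Y - self.predict(X)
        return self.model.predict_grad(X, self.beta_hat) * np.asarray(g(self.tau, resid))[:, None]


def _objective_grid(model: ModelSpec, X: Array, Y: Array, tau: float, B: Array) -> Array:
    R = Y[None, :] - model.predict_batch(X, B)
    W = np.where(R < 0, 1.0 - tau, tau)
    return np.einsum("ij,ij,ij->i", W, R, R)


def _grid_search(model: ModelSpec, X: Array, Y: Array, tau: float, cfg: GridSearchConfig):
    lo, hi = model.box_lower, model.box_upper
    width = hi - lo
    center = 0.5 * (lo + hi)
    best_obj = math.inf
    for stage in range(cfg.n_stages):
        span = width * (cfg.shrink ** stage)
        step = span / (cfg.n_points - 1)
        axes = [
            np.linspace(
                max(lo[j], center[j] - span[j] / 2.0),
                min(hi[j], center[j] + span[j] / 2.0),
                cfg.n_points,
            )
            for j in range(model.p)
        ]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, model.p)
        obj = _objective_grid(model, X, Y, tau, grid)
        i = int(np.argmin(obj))  # first index wins ties
        center, best_obj = grid[i], float(obj[i])
        if np.all(step < cfg.step_tol * width):
            break  # resolution target reached; further stages are pointless
    if cfg.polish:
        def fun_jac(b):
            resid = Y - model.predict(X, b)
            w = np.where(resid < 0, 1.0 - tau, tau)
            grad = -model.predict_grad(X, b).T @ np.asarray(g(tau, resid))
            return float(w @ (resid * resid)), grad

        res = optimize.minimize(
            fun_jac, center, jac=True, method="L-BFGS-B", bounds=list(model.param_box)
        )
        if res.fun <= best_obj:
            center, best_obj = res.x, float(res.fun)
    return center, best_obj


def _finalize(model, X, Y, beta, tau, objective, cfg, tau_estimated) -> ExpectileFit:
    resid = Y - model.predict(X, beta)
    s2 = var_g(resid, tau)
    G = model.predict_grad(X, beta)
    m = G.shape[0]
    V = (G.T @ G) / m
    J = s2 * V
    try:
        J_inv_sqrt = inv_sqrt_cholesky(J)
    except linalg.LinAlgError:
        J_inv_sqrt = None
    return ExpectileFit(
        model=model,
        beta_hat=np.asarray(beta, dtype=float),
        tau=tau,
        residuals=resid,
        var_g=s2,
        V_m=V,
        J_m=J,
        J_inv_sqrt=J_inv_sqrt,
        objective=objective,
        m=m,
        tau_estimated=tau_estimated,
        search=cfg,
    )


def fit_expectile(
    model: ModelSpec,
    X: Array,
    Y: Array,
    tau: float = 0.5,
    search: Optional[GridSearchConfig] = None,
) -> ExpectileFit:
    """Fit beta by minimising the empirical expectile risk over the box.

    Parameters
    ----------
    model
        The regression function, its gradient and its parameter box.
    X, Y
        Historical design ((m, q) or 1-d for q = 1) and responses.
    tau
        Expectile index in (0, 1); 1/2 gives nonlinear least squares.
    search
        Grid-search settings; defaults to :class:`GridSearchConfig`.
    """
    tau = _check_tau(tau)
    cfg = search or GridSearchConfig()
    X = as_design(X, model.q)
    Y = np.asarray(Y, dtype=float).reshape(-1)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y disagree on the number of observations")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    if X.shape[0] < model.p:
        raise ValueError(f"need at least p={model.p} observations, got {X.shape[0]}")
    beta, obj = _grid_search(model, X, Y, tau, cfg)
    return _finalize(model, X, Y, beta, tau, obj, cfg, tau_estimated=False)


def fit_expectile_estimated_tau(
    model: ModelSpec,
    X: Array,
    Y: Array,
    search: Optional[GridSearchConfig] = None,
    tau0: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> ExpectileFit:
    """Fit beta and the expectile index jointly.

    The index that zeroes the empirical moment depends on the residuals,
    which depend on the fit; the coupled system is solved by alternating
    ``fit(tau) -> residuals -> tau_hat`` from ``tau0`` until the index
    moves by less than ``tol``.  The returned fit carries the exact
    moment-zeroing index of its final residuals, so the Remark-style
    moment condition holds to machine precision.
    """
    cfg = search or GridSearchConfig()
    tau = _check_tau(tau0)
    fit = None
    for _ in range(max_iter):
        fit = fit_expectile(model, X, Y, tau, cfg)
        tau_new = tau_hat(fit.residuals)
        done = abs(tau_new - tau) < tol
        tau = tau_new
        if done:
            break
    assert fit is not None
    # re-express the final fit at the exact moment-zeroing index
    final = _finalize(model, X, Y, fit.beta_hat, tau, fit.objective, cfg, tau_estimated=True)
    return final


# ---------------------------------------------------------------------------
# Asymptotic linearization helpers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AsymptoticApprox:
    """Population quantities of the estimator's first-order expansion."""

    E_h: float
    V0: Array
    Omega: Array


def asymptotic_approx(model: ModelSpec, X: Array, beta0: Array, E_h: float) -> AsymptoticApprox:
    """Omega = E[h_tau(eps)] * V(beta0), with V approximated by the design average."""
    G = model.predict_grad(X, beta0)
    V0 = (G.T @ G) / G.shape[0]
    return AsymptoticApprox(E_h=float(E_h), V0=V0, Omega=float(E_h) * V0)


def linearization_remainder(
    model: ModelSpec,
    X: Array,
    eps: Array,
    beta_hat: Array,
    beta0: Array,
    tau: float,
    E_h: float,
) -> float:
    """Euclidean norm of beta_hat - beta0 - Omega^{-1} (1/m) sum grad_f g_tau(eps).

    The expansion predicts this remainder to vanish faster than m^{-1/2};
    multiplying by sqrt(m) therefore gives a quantity that should shrink
    with the sample size.
    """
    approx = asymptotic_approx(model, X, beta0, E_h)
    G = model.predict_grad(X, beta0)
    score = G.T @ np.asarray(g(tau, np.asarray(eps, dtype=float))) / G.shape[0]
    lin = np.linalg.solve(approx.Omega, score)
    r = np.asarray(beta_hat, dtype=float) - np.asarray(beta0, dtype=float) - lin
    return float(np.linalg.norm(r))
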