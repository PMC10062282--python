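"""Parametric regression functions f(x, beta) with analytic gradients.

A :class:`ModelSpec` bundles everything the estimation and monitoring code
needs to know about a regression function: how to evaluate it, how to
differentiate it with respect to the parameter vector, and a compact
parameter box over which the (possibly non-convex) expectile risk is
searched.  Built-in models cover the straight line, the intercept-only
model, and the two- and three-parameter Gompertz growth curves used for
cumulative epidemic counts.

User models plug in through the same contract: ``evaluator(X, beta)``
returns the fitted values for a whole design matrix at once, and
``gradient(X, beta)`` the ``(m, p)`` matrix of partial derivatives.  When
no analytic gradient is available, :func:`numeric_gradient` provides a
central-difference fallback.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np

Array = np.ndarray

__all__ = [
    "ModelSpec",
    "eval_model",
    "grad_model",
    "numeric_gradient",
    "get_model",
    "constant_model",
    "linear_model",
    "gompertz2_model",
    "gompertz3_model",
    "MODEL_NAMES",
]


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A parametric regression function with gradient and parameter box.

    Parameters
    ----------
    name
        Identifier used in serialized fits and on the command line.
    p
        Dimension of the parameter vector ``beta``.
    q
        Dimension of the covariate vector ``x``.
    param_box
        ``p`` pairs ``(lower, upper)`` of finite bounds — the compact set
        over which the expectile risk is minimised.
    evaluator
        ``(X, beta) -> y_hat`` mapping an ``(m, q)`` design and a
        ``p``-vector to the ``m``-vector of fitted values.
    gradient
        ``(X, beta) -> (m, p)`` matrix of partial derivatives of ``f``
        with respect to ``beta``.
    batch_evaluator
        Optional vectorised ``(X, B) -> (n, m)`` evaluation over a whole
        ``(n, p)`` block of candidate parameters; used to make the grid
        search fast.  Falls back to looping over ``evaluator``.
    """

    name: str
    p: int
    q: int
    param_box: tuple[tuple[float, float], ...]
    evaluator: Callable[[Array, Array], Array]
    gradient: Callable[[Array, Array], Array]
    hessian_available: bool = False
    batch_evaluator: Optional[Callable[[Array, Array], Array]] = None

    def __post_init__(self) -> None:
        if self.p < 1 or self.q < 1:
            raise ValueError("p and q must be positive integers")
        if len(self.param_box) != self.p:
            raise ValueError("param_box must contain one (lower, upper) pair per parameter")
        for lo, hi in self.param_box:
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("parameter box bounds must be finite")
            if not lo < hi:
                raise ValueError(f"degenerate parameter box: [{lo}, {hi}]")

    def with_box(self, param_box) -> "ModelSpec":
        """Return a copy of this model with a different parameter box."""
        return dataclasses.replace(self, param_box=tuple(map(tuple, param_box)))

    # -- convenience -------------------------------------------------
    @property
    def box_lower(self) -> Array:
        return np.array([lo for lo, _ in self.param_box], dtype=float)

    @property
    def box_upper(self) -> Array:
        return np.array([hi for _, hi in self.param_box], dtype=float)

    def predict(self, X: Array, beta: Array) -> Array:
        """Evaluate f row-wise on a design matrix (validated)."""
        X = as_design(X, self.q)
        beta = _check_beta(self, beta)
        out = np.asarray(self.evaluator(X, beta), dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValueError("model evaluation produced non-finite values")
        return out

    def predict_grad(self, X: Array, beta: Array) -> Array:
        """Gradient of f w.r.t. beta, one row per observation: (m, p)."""
        X = as_design(X, self.q)
        beta = _check_beta(self, beta)
        G = np.asarray(self.gradient(X, beta), dtype=float)
        if G.shape != (X.shape[0], self.p):
            raise ValueError(
                f"gradient returned shape {G.shape}, expected {(X.shape[0], self.p)}"
            )
        return G

    def predict_batch(self, X: Array, B: Array) -> Array:
        """Evaluate f for a block of parameter vectors: (n_beta, m)."""
        X = as_design(X, self.q)
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if self.batch_evaluator is not None:
            return np.asarray(self.batch_evaluator(X, B), dtype=float)
        return np.stack([np.asarray(self.evaluator(X, b), dtype=float) for b in B])


def as_design(X: Array, q: int) -> Array:
    """Coerce covariates to an (m, q) float design matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 0:
        X = X.reshape(1, 1)
    elif X.ndim == 1:
        # a single observation if it matches q > 1, otherwise m scalar covariates
        X = X.reshape(1, -1) if (q > 1 and X.size == q) else X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[1] != q:
        raise ValueError(f"design has shape {X.shape}, expected (m, {q})")
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values")
    return X


def _check_beta(model: ModelSpec, beta: Array) -> Array:
    beta = np.asarray(beta, dtype=float).reshape(-1)
    if beta.shape != (model.p,):
        raise ValueError(f"beta has length {beta.size}, expected {model.p}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite values")
    return beta


def eval_model(model: ModelSpec, x: Array, beta: Array) -> float:
    """Evaluate f(x, beta) at a single covariate vector."""
    return float(model.predict(np.asarray(x, dtype=float).reshape(1, -1), beta)[0])


def grad_model(model: ModelSpec, x: Array, beta: Array) -> Array:
    """Analytic gradient of f at a single covariate vector (p-vector)."""
    return model.predict_grad(np.asarray(x, dtype=float).reshape(1, -1), beta)[0]


def numeric_gradient(model: ModelSpec, x: Array, beta: Array, step: float = 1e-6) -> Array:
    """Central finite-difference approximation of the parameter gradient.

    Supports user models that only supply an evaluator.  The error is
    O(step^2) for twice-differentiable f.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    beta = _check_beta(model, beta)
    out = np.empty(model.p)
    for j in range(model.p):
        bp, bm = beta.copy(), beta.copy()
        bp[j] += step
        bm[j] -= step
        out[j] = (eval_model(model, x, bp) - eval_model(model, x, bm)) / (2.0 * step)
    return out


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

def constant_model(box: tuple[float, float] = (-100.0, 100.0)) -> ModelSpec:
    """Intercept-only model f(x, beta) = beta_1 (the scalar expectile)."""

    def ev(X, b):
        return np.full(X.shape[0], b[0])

    def gr(X, b):
        return np.ones((X.shape[0], 1))

    def bev(X, B):
        return np.repeat(B[:, :1], X.shape[0], axis=1)

    return ModelSpec("constant", 1, 1, (tuple(box),), ev, gr, True, bev)


def linear_model(box: tuple[tuple[float, float], ...] = ((-100.0, 100.0), (-100.0, 100.0))) -> ModelSpec:
    """Simple line f(x, beta) = beta_1 + beta_2 * x."""

    def ev(X, b):
        return b[0] + b[1] * X[:, 0]

    def gr(X, b):
        return np.column_stack([np.ones(X.shape[0]), X[:, 0]])

    def bev(X, B):
        return B[:, 0][:, None] + B[:, 1][:, None] * X[:, 0][None, :]

    return ModelSpec("linear", 2, 1, tuple(map(tuple, box)), ev, gr, True, bev)


def gompertz2_model(box: tuple[tuple[float, float], ...] = ((0.1, 30.0), (0.5, 15.0))) -> ModelSpec:
    """Two-parameter Gompertz curve f(x, beta) = exp(-beta_1 e^{-beta_2 x}).

    A unit-saturation sigmoid used for cumulative growth phenomena; the
    gradient is (-f e^{-beta_2 x}, f beta_1 x e^{-beta_2 x}).
    """

    def ev(X, b):
        return np.exp(-b[0] * np.exp(-b[1] * X[:, 0]))

    def gr(X, b):
        x = X[:, 0]
        e = np.exp(-b[1] * x)
        f = np.exp(-b[0] * e)
        return np.column_stack([-f * e, f * b[0] * x * e])

    def bev(X, B):
        x = X[:, 0][None, :]
        return np.exp(-B[:, 0][:, None] * np.exp(-B[:, 1][:, None] * x))

    return ModelSpec("gompertz2", 2, 1, tuple(map(tuple, box)), ev, gr, True, bev)


def gompertz3_model(
    k_upper: float = 1000.0,
    box: Optional[tuple[tuple[float, float], ...]] = None,
) -> ModelSpec:
    """Three-parameter Gompertz curve f(x, beta) = K exp(-beta_1 e^{-beta_2 x}).

    ``beta = (beta_1, beta_2, K)`` where K is the saturation level (e.g. the
    eventual cumulative case count of an epidemic wave).  ``k_upper`` should
    comfortably exceed the plausible saturation — a common rule of thumb is
    ten times the largest observed response.
    """
    if box is None:
        box = ((0.1, 30.0), (0.001, 15.0), (1.0, float(k_upper)))

    def ev(X, b):
        return b[2] * np.exp(-b[0] * np.exp(-b[1] * X[:, 0]))

    def gr(X, b):
        x = X[:, 0]
        e = np.exp(-b[1] * x)
        core = np.exp(-b[0] * e)
        f = b[2] * core
        return np.column_stack([-f * e, f * b[0] * x * e, core])

    def bev(X, B):
        x = X[:, 0][None, :]
        return B[:, 2][:, None] * np.exp(-B[:, 0][:, None] * np.exp(-B[:, 1][:, None] * x))

    return ModelSpec("gompertz3", 3, 1, tuple(map(tuple, box)), ev, gr, True, bev)


_REGISTRY: dict[str, Callable[..., ModelSpec]] = {
    "constant": constant_model,
    "linear": linear_model,
    "gompertz2": gompertz2_model,
    "gompertz3": gompertz3_model,
}

MODEL_NAMES = tuple(_REGISTRY)


def get_model(name: str, **kwargs) -> ModelSpec:
    """Look a built-in model up by name (see :data:`MODEL_NAMES`)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}") from None
    return factory(**kwargs)
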