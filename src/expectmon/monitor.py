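"""Sequential CUSUM-type detector over a stream of new observations.

After a model has been fitted on m historical observations, each incoming
observation (x, y) contributes a score ``grad_f(x, beta_hat) g_tau(y -
f(x, beta_hat))``.  The detector tracks the cumulative score vector,
whitens it with the inverse Cholesky factor of J_m, and normalises by the
boundary function

    z(m, k, gamma) = sqrt(m) (1 + k/m) (k / (k + m))^gamma ,

for gamma in [0, 1/2).  Monitoring stops at the first online index whose
normalised sup-norm statistic exceeds the critical value; under the null
of no parameter change the running supremum converges to the law of
sup_{0<t<L} ||W_p(t)||_inf / t^gamma, whose quantiles the
:mod:`expectmon.limit` module simulates.

All plug-ins (tau, the score variance and J_m) are computed from the
historical data only and stay frozen while monitoring — the detector is
strictly one-pass and can be attached to a live stream.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .expectile import ExpectileFit, g

Array = np.ndarray

__all__ = [
    "z_norm",
    "MonitorState",
    "DetectionResult",
    "new_monitor",
    "detector_step",
    "run_monitor",
    "statistic_path",
]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not 0.0 <= gamma < 0.5:
        raise ValueError(f"gamma must lie in [0, 1/2), got {gamma}")
    return gamma


def z_norm(m: int, k, gamma: float):
    """Boundary function sqrt(m) (1 + k/m) (k/(k+m))^gamma (vectorised in k)."""
    gamma = _check_gamma(gamma)
    if m < 1:
        raise ValueError("m must be a positive integer")
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    out = math.sqrt(m) * (1.0 + k / m) * (k / (k + m)) ** gamma
    return out if out.ndim else float(out)


@dataclasses.dataclass
class MonitorState:
    """Running state of the one-pass detector."""

    fit: ExpectileFit
    gamma: float
    threshold: float
    m: int
    k: int = 0
    cumsum: Array = None  # type: ignore[assignment]
    stat_path: list = dataclasses.field(default_factory=list)
    stopped_at: Optional[int] = None

    def __post_init__(self):
        if self.cumsum is None:
            self.cumsum = np.zeros(self.fit.model.p)


def new_monitor(fit: ExpectileFit, gamma: float, threshold: float) -> MonitorState:
    """Initialise a detector from a frozen historical fit."""
    if fit.J_inv_sqrt is None:
        raise ValueError(
            "fit has a singular J matrix (e.g. zero residual variance); "
            "monitoring is undefined without a positive-definite normalizer"
        )
    return MonitorState(fit=fit, gamma=_check_gamma(gamma), threshold=float(threshold), m=fit.m)


def detector_step(state: MonitorState, x, y: float) -> Tuple[MonitorState, float]:
    """Consume one online observation and return the updated statistic.

    The cumulative score vector is updated in place; the returned value is
    ``||J^{-1/2} cumsum||_inf / z(m, k, gamma)`` for the new k.  Identical,
    to floating-point roundoff, to recomputing the whole sum from scratch.
    """
    y = float(y)
    if not np.isfinite(y):
        raise ValueError("non-finite response")
    fit = state.fit
    x_arr = np.asarray(x, dtype=float).reshape(1, -1)
    resid = y - fit.predict(x_arr)[0]
    grad = fit.model.predict_grad(x_arr, fit.beta_hat)[0]
    state.cumsum = state.cumsum + grad * g(fit.tau, resid)
    state.k += 1
    stat = float(
        np.abs(fit.J_inv_sqrt @ state.cumsum).max() / z_norm(state.m, state.k, state.gamma)
    )
    state.stat_path.append(stat)
    if state.stopped_at is None and stat > state.threshold:
        state.stopped_at = state.k
    return state, stat


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    """Outcome of a monitoring run.

    ``k_hat`` is the stopping time in online indexing (1..horizon), or
    ``math.inf`` when the statistic never exceeded the threshold; the
    absolute index of the last pre-change regime is then ``m + k_hat``.
    """

    detected: bool
    k_hat: float  # int or math.inf
    absolute_index: Optional[int]
    max_stat: float
    stat_path: Array
    threshold: float


def run_monitor(
    fit: ExpectileFit,
    stream: Iterable[Tuple[Sequence[float], float]],
    gamma: float,
    threshold: float,
    horizon: Optional[int] = None,
) -> DetectionResult:
    """Monitor a stream of (x, y) pairs until detection or exhaustion.

    The stream is consumed lazily and strictly once; monitoring stops at
    the first exceedance (or after ``horizon`` observations).
    """
    if horizon is not None and horizon < 1:
        raise ValueError("horizon must be a positive integer")
    state = new_monitor(fit, gamma, threshold)
    seen = 0
    for x, y in stream:
        state, _ = detector_step(state, x, y)
        seen += 1
        if state.stopped_at is not None:
            break
        if horizon is not None and seen >= horizon:
            break
    if seen == 0:
        raise ValueError("empty online stream")
    path = np.asarray(state.stat_path)
    detected = state.stopped_at is not None
    k_hat = state.stopped_at if detected else math.inf
    return DetectionResult(
        detected=detected,
        k_hat=k_hat,
        absolute_index=(fit.m + state.stopped_at) if detected else None,
        max_stat=float(path.max()),
        stat_path=path,
        threshold=float(threshold),
    )


def statistic_path(fit: ExpectileFit, X: Array, Y: Array, gamma: float) -> Array:
    """Whole statistic path for a batch of online data, vectorised.

    Equivalent to running :func:`detector_step` over the rows of (X, Y)
    without stopping; used by the simulation drivers where the online
    block is available up front.
    """
    gamma = _check_gamma(gamma)
    if fit.J_inv_sqrt is None:
        raise ValueError("fit has a singular J matrix; cannot form the statistic")
    scores = fit.score_terms(X, Y)  # (T, p)
    S = fit.J_inv_sqrt @ np.cumsum(scores, axis=0).T  # (p, T)
    k = np.arange(1, scores.shape[0] + 1)
    return np.abs(S).max(axis=0) / z_norm(fit.m, k, gamma)
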