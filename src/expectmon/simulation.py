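"""Synthetic data generation and Monte-Carlo level/power experiments.

The study design mirrors a standard finite-sample assessment of a
sequential changepoint test on a Gompertz growth curve: historical data of
size m are generated from ``f(x, beta0) + eps`` with ``beta0 = (10, 5)``
and covariates in (0, 1); an online block of T_m further observations
follows either the same parameter (level experiments) or switches to
``beta1`` at a changepoint (power experiments).  Three error laws are
covered — standard normal, normal with mean and variance one (asymmetric
about zero, so the moment-zeroing expectile index is far from 1/2), and a
zero-mean unit-variance Laplace — and three horizon rules: a fixed short
horizon of 10, T_m = floor(m/2), and the long T_m = floor(m ln m), the
first two treated as closed-end monitoring with T = T_m/m and the last as
open-end.

Changepoint placement follows the convention that ``k0`` counts the
unchanged online observations: ``immediate`` means every online
observation is already generated under ``beta1`` and ``midpoint`` puts the
first changed observation at floor(T_m/2) + 1.  For midpoint experiments,
exceedances in the first half of the online block are discarded as false
alarms and only detections in the second half count, and the detection
location is summarised by (k_hat - 1)/(T_m - 1) in [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np

from .expectile import (
    ExpectileFit,
    GridSearchConfig,
    fit_expectile,
    fit_expectile_estimated_tau,
)
from .limit import L_of_T, critical_value
from .models import ModelSpec
from .monitor import statistic_path

Array = np.ndarray

__all__ = [
    "ErrorDist",
    "SimDesign",
    "SimResult",
    "gen_dataset",
    "run_level_experiment",
    "run_power_experiment",
]


@dataclasses.dataclass(frozen=True)
class ErrorDist:
    """An i.i.d. error law specified by family, mean and variance."""

    family: str = "gaussian"
    mean: float = 0.0
    variance: float = 1.0

    def __post_init__(self):
        if self.family not in ("gaussian", "laplace"):
            raise ValueError("family must be 'gaussian' or 'laplace'")
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")

    def sample(self, rng: np.random.Generator, n: int) -> Array:
        if self.variance == 0.0:
            return np.full(n, self.mean)
        if self.family == "gaussian":
            return self.mean + math.sqrt(self.variance) * rng.standard_normal(n)
        # unit-variance Laplace has scale 1/sqrt(2)
        return rng.laplace(self.mean, math.sqrt(self.variance / 2.0), n)


_HORIZON_RULES = ("fixed10", "half_m", "m_log_m")
_K0_RULES = ("none", "immediate", "midpoint")


@dataclasses.dataclass(frozen=True)
class SimDesign:
    """One Monte-Carlo experiment cell.

    ``tau`` is either a fixed expectile index or the string ``"estimate"``
    for per-replication estimation of the moment-zeroing index.  The
    monitoring threshold is simulated once per design from the limit law
    (closed-end for the fixed10/half_m horizons, open-end for m_log_m)
    unless ``threshold`` overrides it.
    """

    model: ModelSpec
    beta0: tuple
    m: int
    horizon_rule: str = "fixed10"
    k0_rule: str = "none"
    beta1: Optional[tuple] = None
    dist: ErrorDist = dataclasses.field(default_factory=ErrorDist)
    tau: Union[float, str] = 0.5
    gamma: float = 0.1
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0
    design: str = "uniform"  # or "equispaced"
    search: Optional[GridSearchConfig] = None
    threshold: Optional[float] = None
    cv_paths: int = 100_000
    cv_grid: int = 10_000

    def __post_init__(self):
        if self.horizon_rule not in _HORIZON_RULES:
            raise ValueError(f"horizon_rule must be one of {_HORIZON_RULES}")
        if self.k0_rule not in _K0_RULES:
            raise ValueError(f"k0_rule must be one of {_K0_RULES}")
        if (self.beta1 is not None) != (self.k0_rule != "none"):
            raise ValueError("beta1 must be given exactly when k0_rule is not 'none'")
        if self.design not in ("uniform", "equispaced"):
            raise ValueError("design must be 'uniform' or 'equispaced'")
        if len(self.beta0) != self.model.p:
            raise ValueError("beta0 has the wrong length for the model")
        if self.m < self.model.p:
            raise ValueError("m must be at least the parameter dimension")

    @property
    def T_m(self) -> int:
        if self.horizon_rule == "fixed10":
            return 10
        if self.horizon_rule == "half_m":
            return self.m // 2
        return int(self.m * math.log(self.m))

    @property
    def open_end(self) -> bool:
        return self.horizon_rule == "m_log_m"

    @property
    def k0(self) -> int:
        """Number of unchanged online observations."""
        if self.k0_rule == "none":
            return self.T_m
        if self.k0_rule == "immediate":
            return 0
        return self.T_m // 2

    def limit_L(self) -> float:
        if self.open_end:
            return L_of_T(None, closed_end=False)
        return L_of_T(self.T_m / self.m, closed_end=True)

    def resolve_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return critical_value(
            p=self.model.p,
            gamma=self.gamma,
            L=self.limit_L(),
            alpha=self.alpha,
            n_paths=self.cv_paths,
            n_grid=self.cv_grid,
            seed=self.seed,
        )


def _draw_x(rng: np.random.Generator, n: int, design: str) -> Array:
    if design == "equispaced":
        return (np.arange(1, n + 1) / (n + 1)).reshape(-1, 1)
    return rng.uniform(0.0, 1.0, n).reshape(-1, 1)


def gen_dataset(design: SimDesign, rep_seed) -> tuple[Array, Array, Array, Array]:
    """Generate one replication: (X_hist, Y_hist, X_online, Y_online).

    Online observations with index <= design.k0 use beta0; strictly later
    ones use beta1.  Identical ``rep_seed`` reproduces identical arrays.
    """
    rng = np.random.default_rng(rep_seed)
    beta0 = np.asarray(design.beta0, dtype=float)
    X_hist = _draw_x(rng, design.m, design.design)
    Y_hist = design.model.predict(X_hist, beta0) + design.dist.sample(rng, design.m)
    T = design.T_m
    X_onl = _draw_x(rng, T, design.design)
    mu = design.model.predict(X_onl, beta0)
    if design.k0_rule != "none" and design.k0 < T:
        beta1 = np.asarray(design.beta1, dtype=float)
        changed = np.arange(1, T + 1) > design.k0
        mu = np.where(changed, design.model.predict(X_onl, beta1), mu)
    Y_onl = mu + design.dist.sample(rng, T)
    return X_hist, Y_hist, X_onl, Y_onl


@dataclasses.dataclass(frozen=True)
class SimResult:
    """Monte-Carlo summary of one experiment cell."""

    rejection_rate: float
    est_mean: Array
    est_sd: Array
    tau_mean: float
    mean_location: Optional[float]
    median_location: Optional[float]
    n_valid: int
    threshold: float


def _fit_rep(design: SimDesign, X: Array, Y: Array) -> ExpectileFit:
    if design.tau == "estimate":
        return fit_expectile_estimated_tau(design.model, X, Y, search=design.search)
    return fit_expectile(design.model, X, Y, float(design.tau), search=design.search)


def _rep_seed(design: SimDesign, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([design.seed, rep])


def run_level_experiment(design: SimDesign) -> SimResult:
    """Empirical size of the test under the no-change null."""
    if design.k0_rule != "none":
        raise ValueError("level experiments require k0_rule='none'")
    threshold = design.resolve_threshold()
    betas = np.empty((design.n_reps, design.model.p))
    taus = np.empty(design.n_reps)
    rejections = 0
    for rep in range(design.n_reps):
        Xh, Yh, Xo, Yo = gen_dataset(design, _rep_seed(design, rep))
        fit = _fit_rep(design, Xh, Yh)
        betas[rep] = fit.beta_hat
        taus[rep] = fit.tau
        stats = statistic_path(fit, Xo, Yo, design.gamma)
        rejections += bool(np.any(stats > threshold))
    return SimResult(
        rejection_rate=rejections / design.n_reps,
        est_mean=betas.mean(axis=0),
        est_sd=betas.std(axis=0, ddof=1),
        tau_mean=float(taus.mean()),
        mean_location=None,
        median_location=None,
        n_valid=design.n_reps,
        threshold=threshold,
    )


def run_power_experiment(design: SimDesign) -> SimResult:
    """Empirical power and detection-location summaries under a changepoint.

    With the midpoint rule, exceedances at k <= floor(T_m/2) are discarded
    as false alarms; a replication counts as a detection only if the
    statistic exceeds the threshold at some later k, and the location
    indicator (k_hat - 1)/(T_m - 1) is computed over those detections.
    """
    if design.k0_rule == "none":
        raise ValueError("power experiments require a changepoint rule")
    threshold = design.resolve_threshold()
    T = design.T_m
    first_valid_k = (T // 2) + 1 if design.k0_rule == "midpoint" else 1
    betas = np.empty((design.n_reps, design.model.p))
    taus = np.empty(design.n_reps)
    rejections = 0
    locations = []
    for rep in range(design.n_reps):
        Xh, Yh, Xo, Yo = gen_dataset(design, _rep_seed(design, rep))
        fit = _fit_rep(design, Xh, Yh)
        betas[rep] = fit.beta_hat
        taus[rep] = fit.tau
        stats = statistic_path(fit, Xo, Yo, design.gamma)
        exceed = np.flatnonzero(stats[first_valid_k - 1 :] > threshold)
        if exceed.size:
            rejections += 1
            k_hat = first_valid_k + int(exceed[0])
            locations.append((k_hat - 1) / (T - 1) if T > 1 else 0.0)
    return SimResult(
        rejection_rate=rejections / design.n_reps,
        est_mean=betas.mean(axis=0),
        est_sd=betas.std(axis=0, ddof=1),
        tau_mean=float(taus.mean()),
        mean_location=float(np.mean(locations)) if locations else None,
        median_location=float(np.median(locations)) if locations else None,
        n_valid=design.n_reps,
        threshold=threshold,
    )
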