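"""Monte-Carlo critical values of the weighted Wiener-supremum limit law.

Under the no-change null the monitoring statistic converges to

    sup_{0 < t < L} ||W_p(t)||_inf / t^gamma ,

where W_p is a p-dimensional standard Wiener process, gamma in [0, 1/2)
is the boundary exponent, and the range endpoint is L = 1 for open-end
monitoring and L = T/(1+T) for a closed-end horizon with T =
lim T_m / m.  No closed form is known for gamma > 0, so quantiles are
simulated: Wiener paths are generated as cumulative sums of Gaussian
increments on an equispaced grid of (0, 1], and closed-end ranges are
obtained from the exact Brownian-scaling identity

    sup_{0<t<L} ||W(t)||_inf / t^gamma  =d  L^{1/2-gamma} sup_{0<t<1} ...

rather than by re-simulation, which removes grid-resolution asymmetries
between the two procedures.

For p = 1 and gamma = 0 an analytic check is available through the
reflection series P(sup_{[0,1]} |W| <= b) = (4/pi) sum_k (-1)^k
(2k+1)^{-1} exp(-pi^2 (2k+1)^2 / (8 b^2)); its 95% point is ~2.2414.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from pathlib import Path
from typing import Optional

import numpy as np

Array = np.ndarray

__all__ = [
    "LimitSpec",
    "L_of_T",
    "simulate_sup",
    "critical_value",
    "sup_abs_wiener_cdf",
    "default_cache_dir",
]

_CHUNK_BUDGET = 20_000_000  # floats per simulation chunk


def default_cache_dir() -> Path:
    env = os.environ.get("EXPECTMON_CACHE_DIR")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "expectmon"


def L_of_T(T: Optional[float], closed_end: bool) -> float:
    """Range endpoint of the limit law: 1 open-end, T/(1+T) closed-end."""
    if not closed_end:
        return 1.0
    if T is None or not math.isfinite(T) or T <= 0:
        raise ValueError("closed-end monitoring needs a finite horizon ratio T > 0")
    return T / (1.0 + T)


@dataclasses.dataclass(frozen=True)
class LimitSpec:
    """Configuration of one limit-law simulation."""

    p: int
    gamma: float
    L: float = 1.0
    n_grid: int = 10_000
    n_paths: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        if not 0.0 <= self.gamma < 0.5:
            raise ValueError("gamma must lie in [0, 1/2)")
        if not 0.0 < self.L <= 1.0:
            raise ValueError("L must lie in (0, 1]")
        if self.n_grid < 100 or self.n_paths < 1000:
            raise ValueError("need n_grid >= 100 and n_paths >= 1000 for quantile estimation")


# In-memory cache of unit-range sup samples, keyed by everything but L.
_BASE_CACHE: dict[tuple, Array] = {}
_BASE_CACHE_MAX = 6


def _base_sup_samples(p: int, gamma: float, n_grid: int, n_paths: int, seed: int) -> Array:
    key = (p, gamma, n_grid, n_paths, seed)
    hit = _BASE_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_grid + 1) / n_grid
    weight = t ** (-gamma)
    sd = 1.0 / math.sqrt(n_grid)
    out = np.empty(n_paths)
    chunk = max(1, _CHUNK_BUDGET // (p * n_grid))
    done = 0
    while done < n_paths:
        nb = min(chunk, n_paths - done)
        increments = rng.standard_normal((nb, p, n_grid))
        increments *= sd
        W = np.cumsum(increments, axis=2)
        np.abs(W, out=W)
        sup = (W.max(axis=1) * weight[None, :]).max(axis=1)
        out[done : done + nb] = sup
        done += nb
    if len(_BASE_CACHE) >= _BASE_CACHE_MAX:
        _BASE_CACHE.pop(next(iter(_BASE_CACHE)))
    _BASE_CACHE[key] = out
    return out


def simulate_sup(spec: LimitSpec) -> Array:
    """Monte-Carlo samples of sup_{0<t<L} ||W_p(t)||_inf / t^gamma.

    Samples are simulated on the unit range and rescaled by
    L^{1/2 - gamma}, which is exact in distribution.
    """
    base = _base_sup_samples(spec.p, spec.gamma, spec.n_grid, spec.n_paths, spec.seed)
    return base * spec.L ** (0.5 - spec.gamma)


def critical_value(
    p: int,
    gamma: float,
    L: float = 1.0,
    alpha: float = 0.05,
    n_paths: int = 100_000,
    n_grid: int = 10_000,
    seed: int = 0,
    cache_dir: Optional[Path] = None,
    use_cache: bool = True,
) -> float:
    """(1 - alpha)-quantile of the limit law, simulated.

    Quantiles are cached on disk (best-effort) keyed by the full
    configuration, with L rounded to 1e-4; ``cache_dir=None`` uses
    :func:`default_cache_dir` and ``use_cache=False`` disables the disk
    table entirely.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    spec = LimitSpec(p=p, gamma=gamma, L=L, n_grid=n_grid, n_paths=n_paths, seed=seed)
    key = f"p{p}_g{gamma:.6g}_L{round(L, 4):.4f}_a{alpha:.6g}_n{n_paths}_grid{n_grid}_s{seed}"
    cache_file = None
    table: dict = {}
    if use_cache:
        cache_dir = default_cache_dir() if cache_dir is None else Path(cache_dir)
        cache_file = cache_dir / "critical_values.json"
        try:
            table = json.loads(cache_file.read_text())
            if key in table:
                return float(table[key])
        except (OSError, ValueError):
            table = {}
    value = float(np.quantile(simulate_sup(spec), 1.0 - alpha))
    if cache_file is not None:
        try:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            table[key] = value
            cache_file.write_text(json.dumps(table, indent=0, sort_keys=True))
        except OSError:
            pass  # caching is best-effort
    return value


def sup_abs_wiener_cdf(b: float, terms: int = 200) -> float:
    """P(sup_{0<=t<=1} |W(t)| <= b) via the reflection series (p=1, gamma=0)."""
    if b <= 0:
        return 0.0
    k = np.arange(terms)
    series = (-1.0) ** k / (2 * k + 1) * np.exp(-(math.pi**2) * (2 * k + 1) ** 2 / (8 * b * b))
    return float(4.0 / math.pi * series.sum())
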