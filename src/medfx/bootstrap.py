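"""Percentile and bias-corrected bootstrap intervals for mediation effect sizes.

Case resampling: draw n observations with replacement, refit the mediation
regressions, recompute the effect size; repeat B times.  The percentile
interval takes the alpha/2 and 1-alpha/2 order statistics of the resampled
estimates.  The bias-corrected interval first measures where the full-sample
estimate sits in the bootstrap distribution (z0) and shifts the two quantile
levels to Phi(2 z0 + z_{alpha/2}) and Phi(2 z0 + z_{1-alpha/2}).

Quantiles use the ceiling-rule order statistic (index ceil(q*B), 1-based, no
interpolation) so every interval endpoint is a realised draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from ._batch import batched_single_paths, batched_two_paths
from .effects import MEASURES, effect_size_arrays
from .model import MediationDataset, fit_paths

__all__ = [
    "BootstrapDraws",
    "IntervalEstimate",
    "resample_estimates",
    "bootstrap_all_measures",
    "percentile_interval",
    "bias_corrected_interval",
]

#: Accepted short aliases for the four effect-size estimators.
ESTIMATOR_ALIASES = {
    "abps": "ab_ps",
    "abfs": "ab_fs",
    "prop": "proportion",
    "ratio": "ratio",
    **{m: m for m in MEASURES},
}

_MAX_REDRAW_ROUNDS = 50


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval with its nominal level and construction method."""

    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.defined and self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.lower) or math.isnan(self.upper))

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


@dataclass(frozen=True)
class BootstrapDraws:
    """B resampled estimates of one effect-size functional.

    ``values`` has length B with NaN marking resamples on which the estimator
    was undefined (e.g. a proportion with zero total effect); ``n_undefined``
    counts them.  ``n_redrawn`` counts resamples that were regenerated because
    their design matrix was rank deficient.
    """

    values: np.ndarray
    observed: float
    B: int
    n_undefined: int
    n_redrawn: int = 0
    estimator: str = ""

    def __post_init__(self):
        if self.B < 100:
            raise ValueError("use at least B = 100 bootstrap resamples")
        if len(self.values) != self.B:
            raise ValueError("values must have length B")

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


def _resample_paths(data: MediationDataset, B: int, rng: np.random.Generator):
    """Batched path estimates over B case resamples; redraws rank-deficient ones."""
    n = data.n
    idx = rng.integers(0, n, size=(B, n))

    def fit(idx_arr):
        xb = data.x[idx_arr]
        yb = data.y[idx_arr]
        if data.n_mediators == 1:
            return batched_single_paths(xb, data.mediators[0][idx_arr], yb)
        return batched_two_paths(
            xb, data.mediators[0][idx_arr], data.mediators[1][idx_arr], yb
        )

    res = fit(idx)
    n_redrawn = 0
    rounds = 0
    while not res["ok"].all():
        bad = ~res["ok"]
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise RuntimeError(
                f"{bad.sum()} resamples remained rank deficient after "
                f"{_MAX_REDRAW_ROUNDS} redraw rounds; the data admit too few "
                "estimable resamples (e.g. a nearly constant X)"
            )
        n_redrawn += int(bad.sum())
        sub = fit(rng.integers(0, n, size=(int(bad.sum()), n)))
        for k, v in res.items():
            v[bad] = sub[k]
    return res, n_redrawn


def _observed_effects(data: MediationDataset) -> dict:
    paths = fit_paths(data)
    arrs = effect_size_arrays(paths.indirect, paths.c_prime, paths.s_x, paths.s_y)
    return {m: float(arrs[m]) for m in MEASURES}


def bootstrap_all_measures(
    data: MediationDataset, B: int = 1000, seed=0
) -> dict[str, BootstrapDraws]:
    """Bootstrap draws for all four effect sizes from one shared set of resamples.

    Sharing resamples across measures mirrors how a simulation would compute
    every effect size from the same refitted model, and is several times
    cheaper than bootstrapping each measure separately.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res, n_redrawn = _resample_paths(data, B, rng)
    if data.n_mediators == 1:
        indirect = res["a"] * res["b"]
    else:
        indirect = res["a1"] * res["b1"] + res["a2"] * res["b2"]
    arrs = effect_size_arrays(indirect, res["c_prime"], res["s_x"], res["s_y"])
    observed = _observed_effects(data)
    return {
        m: BootstrapDraws(
            values=arrs[m],
            observed=observed[m],
            B=B,
            n_undefined=int(np.isnan(arrs[m]).sum()),
            n_redrawn=n_redrawn,
            estimator=m,
        )
        for m in MEASURES
    }


def resample_estimates(
    data: MediationDataset,
    estimator: str | Callable[[MediationDataset], float],
    B: int = 1000,
    seed=0,
) -> BootstrapDraws:
    """B case-resampled estimates of one effect-size functional.

    ``estimator`` is either one of the built-in names (``"ab_ps"``/"abps",
    ``"ab_fs"``/"abfs", ``"proportion"``/"prop", ``"ratio"``) — computed on
    the fast vectorised path — or an arbitrary callable mapping a
    :class:`MediationDataset` to a float (NaN for undefined).
    """
    if B < 100:
        raise ValueError("use at least B = 100 bootstrap resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(estimator, str):
        key = ESTIMATOR_ALIASES.get(estimator)
        if key is None:
            raise ValueError(f"unknown estimator {estimator!r}")
        return bootstrap_all_measures(data, B=B, seed=rng)[key]

    n = data.n
    values = np.empty(B)
    n_redrawn = 0
    for i in range(B):
        for attempt in range(_MAX_REDRAW_ROUNDS + 1):
            idx = rng.integers(0, n, size=n)
            sub = MediationDataset(
                x=data.x[idx],
                mediators=tuple(m[idx] for m in data.mediators),
                y=data.y[idx],
                x_type=data.x_type,
            )
            try:
                values[i] = estimator(sub)
                break
            except np.linalg.LinAlgError:
                n_redrawn += 1
        else:
            raise RuntimeError(
                f"resample {i} stayed rank deficient after {_MAX_REDRAW_ROUNDS} redraws"
            )
    return BootstrapDraws(
        values=values,
        observed=float(estimator(data)),
        B=B,
        n_undefined=int(np.isnan(values).sum()),
        n_redrawn=n_redrawn,
        estimator=getattr(estimator, "__name__", "custom"),
    )


def order_statistic(sorted_vals: np.ndarray, q: float) -> float:
    """Ceiling-rule order statistic: the ceil(q*B)-th smallest value (1-based).

    A tiny tolerance keeps q*B values that are integers up to floating-point
    error (e.g. 0.975 * 1000) from spilling into the next order statistic.
    """
    B = len(sorted_vals)
    idx = min(max(math.ceil(q * B - 1e-9), 1), B)
    return float(sorted_vals[idx - 1])


def _defined_sorted(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return np.sort(v[~np.isnan(v)])


def percentile_interval(draws, level: float = 0.95, method: str = "percentile") -> IntervalEstimate:
    """Percentile interval from the alpha/2 and 1-alpha/2 order statistics.

    ``draws`` may be a :class:`BootstrapDraws` or a plain array.  Undefined
    (NaN) draws are excluded; if fewer than ceil(level * B) defined draws
    remain the interval itself is undefined (NaN bounds).
    """
    values = draws.values if isinstance(draws, BootstrapDraws) else draws
    v = _defined_sorted(values)
    if len(v) < math.ceil(level * len(np.asarray(values))):
        return IntervalEstimate(math.nan, math.nan, level, method)
    alpha = 1.0 - level
    return IntervalEstimate(
        lower=order_statistic(v, alpha / 2),
        upper=order_statistic(v, 1 - alpha / 2),
        level=level,
        method=method,
    )


def bias_corrected_interval(
    draws, level: float = 0.95, observed: float | None = None
) -> IntervalEstimate:
    """Bias-corrected percentile interval.

    z0 = Phi^-1(p_below) where p_below is the fraction of defined draws below
    the observed estimate (ties counted half).  The interval endpoints are the
    order statistics at the adjusted levels Phi(2 z0 + z_{alpha/2}) and
    Phi(2 z0 + z_{1-alpha/2}).  A degenerate p_below of 0 or 1 is clamped to
    1/(B+1) or B/(B+1) with a warning.

    ``draws`` is a :class:`BootstrapDraws`, or a plain array of draws with the
    full-sample estimate passed as ``observed``.
    """
    if isinstance(draws, BootstrapDraws):
        values, observed = draws.values, draws.observed
    else:
        if observed is None:
            raise ValueError("observed is required when draws is a plain array")
        values = np.asarray(draws, dtype=float)
    if not math.isfinite(observed):
        raise ValueError("observed estimate must be finite for bias correction")
    v = _defined_sorted(values)
    B = len(values)
    if len(v) < math.ceil(level * B):
        return IntervalEstimate(math.nan, math.nan, level, "bias_corrected")
    nb = len(v)
    p_below = (np.sum(v < observed) + 0.5 * np.sum(v == observed)) / nb
    if p_below <= 0.0 or p_below >= 1.0:
        clamped = 1.0 / (nb + 1) if p_below <= 0.0 else nb / (nb + 1.0)
        warnings.warn(
            f"all bootstrap draws on one side of the observed estimate; "
            f"clamping p_below from {p_below} to {clamped}",
            RuntimeWarning,
            stacklevel=2,
        )
        p_below = clamped
    z0 = norm.ppf(p_below)
    alpha = 1.0 - level
    q_lo = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    q_hi = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    return IntervalEstimate(
        lower=order_statistic(v, q_lo),
        upper=order_statistic(v, q_hi),
        level=level,
        method="bias_corrected",
    )
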