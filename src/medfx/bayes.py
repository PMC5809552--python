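"""Bayesian estimation of the mediation regressions by conjugate Gibbs sampling.

Each regression equation (Y~X, Y~X+mediators, M_j~X) is a normal linear model
whose parameters are a priori independent of the other equations', and the
likelihood factors across equations, so each is sampled as an independent
two-block Gibbs chain:

* coefficients | variance  ~ multivariate normal with precision
  X'X / sigma^2 + tau0 I (precision-weighted least squares; the whole
  coefficient vector is drawn jointly, which removes within-equation
  autocorrelation),
* variance | coefficients ~ inverse gamma(shape0 + n/2, rate0 + RSS/2).

Default priors are diffuse: normal(0, precision 1e-3) on every coefficient
(intercepts included) and inverse gamma(0.01, 0.01) on every residual
variance.  Posterior draws of the path coefficients are mapped through the
effect-size formulas with the *sample* s_X and s_Y held fixed, matching the
standardizers the frequentist estimator uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bootstrap import IntervalEstimate, order_statistic
from .effects import MEASURES, effect_size_arrays
from .model import MediationDataset, RankDeficientError

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "gibbs_mediation",
    "effect_size_draws",
    "posterior_point",
    "equal_tail_interval",
    "hpd_interval",
    "split_rhat",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for every regression coefficient and residual variance.

    coef ~ Normal(coef_mean, precision=coef_precision) independently;
    sigma^2 ~ InverseGamma(var_shape, var_inverse_scale)  (inverse scale is
    the rate parameter of the reciprocal's gamma distribution).
    """

    coef_mean: float = 0.0
    coef_precision: float = 1e-3
    var_shape: float = 0.01
    var_inverse_scale: float = 0.01

    def __post_init__(self):
        for name in ("coef_precision", "var_shape", "var_inverse_scale"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        if not math.isfinite(self.coef_mean):
            raise ValueError("coef_mean must be finite")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained Gibbs draws for every equation of a mediation model.

    ``coef[eq]`` has shape (ndraws, p) with the intercept in column 0;
    ``sigma2[eq]`` has shape (ndraws,).  ``slopes`` exposes the named path
    coefficients (a, b, c, c_prime, ... ) as 1-D arrays.
    """

    coef: dict = field(default_factory=dict)
    sigma2: dict = field(default_factory=dict)
    slopes: dict = field(default_factory=dict)
    n_mediators: int = 1
    n_iter: int = 0
    burn_in: int = 0
    seed: int | None = None
    s_x: float = 1.0
    s_y: float = 1.0

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.burn_in


def _gibbs_equation(
    X: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-block Gibbs chain for one normal linear regression.

    Returns (coef draws (n_iter, p), sigma2 draws (n_iter,)).
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    if np.linalg.matrix_rank(XtX) < p:
        raise RankDeficientError("design matrix is rank deficient")
    prior_prec = priors.coef_precision * np.eye(p)
    prior_mean_term = priors.coef_precision * priors.coef_mean * np.ones(p)
    shape_post = priors.var_shape + n / 2.0

    # start the variance chain at the method-of-moments residual variance
    beta_ols = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta_ols
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-12)

    coef_out = np.empty((n_iter, p))
    sig_out = np.empty(n_iter)
    for it in range(n_iter):
        prec = XtX / sigma2 + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / sigma2 + prior_mean_term)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        resid = y - X @ beta
        rate_post = priors.var_inverse_scale + float(resid @ resid) / 2.0
        sigma2 = 1.0 / rng.gamma(shape_post, 1.0 / rate_post)
        if not (np.isfinite(beta).all() and np.isfinite(sigma2) and sigma2 > 0):
            raise FloatingPointError(f"non-finite Gibbs draw at iteration {it}")
        coef_out[it] = beta
        sig_out[it] = sigma2
    return coef_out, sig_out


def gibbs_mediation(
    data: MediationDataset,
    priors: PriorSpec = PriorSpec(),
    n_iter: int = 11000,
    burn_in: int = 1000,
    seed: int = 0,
) -> PosteriorDraws:
    """Gibbs chains for every equation of the mediation model.

    Deterministic given ``seed``.  Draws before ``burn_in`` are discarded.
    """
    if not 0 <= burn_in < n_iter:
        raise ValueError("need 0 <= burn_in < n_iter")
    rng = np.random.default_rng(seed)
    one = np.ones(data.n)
    if data.n_mediators == 1:
        m = data.mediators[0]
        eqs = {
            "y~x": (np.column_stack([one, data.x]), data.y),
            "y~x+m": (np.column_stack([one, data.x, m]), data.y),
            "m~x": (np.column_stack([one, data.x]), m),
        }
        slope_map = {
            "a": ("m~x", 1),
            "b": ("y~x+m", 2),
            "c": ("y~x", 1),
            "c_prime": ("y~x+m", 1),
        }
    else:
        m1, m2 = data.mediators
        eqs = {
            "y~x": (np.column_stack([one, data.x]), data.y),
            "y~x+m1+m2": (np.column_stack([one, data.x, m1, m2]), data.y),
            "m1~x": (np.column_stack([one, data.x]), m1),
            "m2~x": (np.column_stack([one, data.x]), m2),
        }
        slope_map = {
            "a1": ("m1~x", 1),
            "b1": ("y~x+m1+m2", 2),
            "a2": ("m2~x", 1),
            "b2": ("y~x+m1+m2", 3),
            "c": ("y~x", 1),
            "c_prime": ("y~x+m1+m2", 1),
        }
    coef, sigma2 = {}, {}
    for eq, (X, y) in eqs.items():
        cdraws, sdraws = _gibbs_equation(X, y, priors, n_iter, rng)
        coef[eq] = cdraws[burn_in:]
        sigma2[eq] = sdraws[burn_in:]
    slopes = {name: coef[eq][:, col] for name, (eq, col) in slope_map.items()}
    return PosteriorDraws(
        coef=coef,
        sigma2=sigma2,
        slopes=slopes,
        n_mediators=data.n_mediators,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        s_x=float(np.std(data.x, ddof=1)),
        s_y=float(np.std(data.y, ddof=1)),
    )


def effect_size_draws(
    post: PosteriorDraws, s_x: float | None = None, s_y: float | None = None
) -> dict[str, np.ndarray]:
    """Per-iteration effect sizes from retained posterior draws.

    The standardizers default to the sample SDs captured at fit time and are
    held fixed across draws.  Returns a dict keyed by measure name plus
    ``"indirect"``; NaN marks iterations where a measure is undefined.
    """
    if post.n_retained < 1:
        raise ValueError("no retained draws")
    s_x = post.s_x if s_x is None else s_x
    s_y = post.s_y if s_y is None else s_y
    if post.n_mediators == 1:
        indirect = post.slopes["a"] * post.slopes["b"]
    else:
        indirect = (
            post.slopes["a1"] * post.slopes["b1"]
            + post.slopes["a2"] * post.slopes["b2"]
        )
    out = effect_size_arrays(indirect, post.slopes["c_prime"], s_x, s_y)
    out["indirect"] = indirect
    return out


def posterior_point(draws: np.ndarray, which: str = "median") -> float:
    """Mean or median of the defined (non-NaN) draws; NaN if none are defined."""
    if which not in ("mean", "median"):
        raise ValueError("which must be 'mean' or 'median'")
    v = np.asarray(draws, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return math.nan
    return float(np.mean(v) if which == "mean" else np.median(v))


def equal_tail_interval(draws: np.ndarray, level: float = 0.95) -> IntervalEstimate:
    """Equal-tail credibility interval: alpha/2 and 1-alpha/2 posterior quantiles.

    Uses the same ceiling-rule order statistics as the percentile bootstrap.
    """
    from .bootstrap import percentile_interval

    est = percentile_interval(np.asarray(draws, dtype=float), level, method="equal_tail")
    return est


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> IntervalEstimate:
    """Highest-posterior-density interval from sorted draws.

    Among all contiguous windows of ceil(level * ndraws) sorted draws the
    narrowest is returned (ties broken toward the lowest lower bound), so no
    value outside the interval has higher estimated density than any inside.
    """
    v = np.asarray(draws, dtype=float)
    total = len(v)
    v = np.sort(v[~np.isnan(v)])
    k = math.ceil(level * total)
    if len(v) < k or k < 1:
        return IntervalEstimate(math.nan, math.nan, level, "hpd")
    widths = v[k - 1 :] - v[: len(v) - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return IntervalEstimate(float(v[i]), float(v[i + k - 1]), level, "hpd")


def split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar chain.

    The chain is split in half and the usual between/within variance ratio is
    computed; values near 1 indicate the two halves agree.
    """
    v = np.asarray(chain, dtype=float)
    v = v[~np.isnan(v)]
    half = len(v) // 2
    if half < 2:
        return math.nan
    parts = np.stack([v[:half], v[half : 2 * half]])
    m = half
    within = parts.var(axis=1, ddof=1).mean()
    between = m * parts.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else math.inf
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))
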