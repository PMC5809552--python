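"""Monte Carlo evaluation harness for the four effect-size measures.

Data are generated under the linear mediation model with unit-variance X
(continuous) or Bernoulli 0/1 X, unit residual variances, independent
mediator residuals, and zero intercepts.  Three study types mirror the
estimator evaluations:

* point study   — OLS point estimates: bias, relative bias, SD, standardized bias;
* interval study — percentile / bias-corrected bootstrap intervals: power or
  Type I error, coverage, mean width, imbalance, Bradley classification;
* Bayesian study — relative bias of posterior mean/median and coverage of
  equal-tail and HPD credibility intervals on the problematic n = 50 cells.

Every replication draws its randomness from a seed stream derived from
(master seed, condition index, replication index), so any cell can be rerun
in isolation; replications whose design is rank deficient (possible with
binary X at small n) are regenerated from the next substream and counted.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import conditions as cond_lists
from ._batch import batched_single_paths, batched_two_paths
from .bayes import (
    PriorSpec,
    effect_size_draws,
    equal_tail_interval,
    gibbs_mediation,
    hpd_interval,
    posterior_point,
    split_rhat,
)
from .bootstrap import bias_corrected_interval, bootstrap_all_measures, percentile_interval
from .effects import MEASURES, EffectSizeSet, effect_size_arrays, effect_sizes
from .model import (
    MediationDataset,
    SimulationCondition,
    fit_paths,
    population_moments,
)

__all__ = [
    "generate_dataset",
    "true_effect_sizes",
    "point_metrics",
    "interval_metrics",
    "bradley_assess",
    "run_point_study",
    "run_interval_study",
    "run_bayes_study",
    "RELATIVE_BIAS_FLAG",
]

#: Relative-bias values above this magnitude are flagged as problematic.
RELATIVE_BIAS_FLAG = 0.05

_BRADLEY = {"type1": (0.025, 0.075), "coverage": (0.925, 0.975)}
_MAX_REGEN = 100


# ---------------------------------------------------------------------------
# data generation and estimands

def _rng_for(seed: int, cond_idx: int, rep_idx: int, attempt: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), cond_idx, rep_idx, attempt))
    )


def _draw_arrays(cond: SimulationCondition, rng: np.random.Generator):
    n, p = cond.n, cond.paths
    if cond.x_type == "continuous":
        x = rng.standard_normal(n)
    else:
        x = rng.binomial(1, cond.binary_p, size=n).astype(float)
    if cond.n_mediators == 1:
        m = p["a"] * x + rng.standard_normal(n)
        y = p["c_prime"] * x + p["b"] * m + rng.standard_normal(n)
        return x, (m,), y
    m1 = p["a1"] * x + rng.standard_normal(n)
    m2 = p["a2"] * x + rng.standard_normal(n)
    y = p["c_prime"] * x + p["b1"] * m1 + p["b2"] * m2 + rng.standard_normal(n)
    return x, (m1, m2), y


def generate_dataset(cond: SimulationCondition, seed=0) -> MediationDataset:
    """One dataset under the generating model; deterministic given ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, meds, y = _draw_arrays(cond, rng)
    return MediationDataset(x=x, mediators=meds, y=y, x_type=cond.x_type)


def true_effect_sizes(cond: SimulationCondition) -> EffectSizeSet:
    """Population effect sizes (the estimands) for a simulation condition."""
    return effect_sizes(population_moments(cond))


# ---------------------------------------------------------------------------
# metric computations

def point_metrics(estimates, truth: float) -> dict:
    """Bias, relative bias, SD and standardized bias of replicate estimates.

    NaN estimates (undefined replicates) are excluded.  Relative bias is
    undefined at truth 0 (or undefined truth); standardized bias is undefined
    when the replicate SD is 0.
    """
    v = np.asarray(estimates, dtype=float)
    defined = v[~np.isnan(v)]
    if len(defined) < 2:
        return {
            "bias": math.nan,
            "relative_bias": math.nan,
            "sd": math.nan,
            "standardized_bias": math.nan,
            "reps_used": len(defined),
            "reps_undefined": len(v) - len(defined),
        }
    bias = float(np.mean(defined)) - truth if not math.isnan(truth) else math.nan
    sd = float(np.std(defined, ddof=1))
    rel = bias / truth if truth not in (0.0,) and not math.isnan(truth) else math.nan
    std_bias = bias / sd if sd > 0 and not math.isnan(bias) else math.nan
    return {
        "bias": bias,
        "relative_bias": rel,
        "sd": sd,
        "standardized_bias": std_bias,
        "reps_used": len(defined),
        "reps_undefined": len(v) - len(defined),
    }


def interval_metrics(lowers, uppers, truth: float) -> dict:
    """Power/Type I, coverage, mean width and imbalance of replicate intervals.

    The zero-exclusion rate is labelled Type I error when the true effect
    size is 0 and power otherwise; with an undefined truth the rate is still
    reported but coverage and imbalance are undefined.
    """
    lo = np.asarray(lowers, dtype=float)
    hi = np.asarray(uppers, dtype=float)
    ok = ~(np.isnan(lo) | np.isnan(hi))
    n_def = int(ok.sum())
    out = {
        "reps_used": n_def,
        "reps_undefined": int(len(lo) - n_def),
        "rate_excl_zero": math.nan,
        "rate_kind": "n/a",
        "coverage": math.nan,
        "width_mean": math.nan,
        "imbalance": math.nan,
    }
    if n_def == 0:
        return out
    lo, hi = lo[ok], hi[ok]
    out["rate_excl_zero"] = float(np.mean((lo > 0.0) | (hi < 0.0)))
    out["width_mean"] = float(np.mean(hi - lo))
    if math.isnan(truth):
        return out
    out["rate_kind"] = "type1" if truth == 0.0 else "power"
    miss_left = float(np.mean(truth < lo))  # truth left of (below) the interval
    miss_right = float(np.mean(truth > hi))
    out["coverage"] = 1.0 - miss_left - miss_right
    # disparity between misses with the truth right of the interval vs left of it
    out["imbalance"] = miss_right - miss_left
    return out


def bradley_assess(rate: float, kind: str) -> str:
    """Classify a Type I error rate or coverage against the robustness band.

    Type I error is acceptable in [0.025, 0.075]; coverage in [0.925, 0.975]
    (bounds inclusive).  Returns "below", "within" or "above".
    """
    if kind not in _BRADLEY:
        raise ValueError("kind must be 'type1' or 'coverage'")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a proportion")
    lo, hi = _BRADLEY[kind]
    if rate < lo:
        return "below"
    if rate > hi:
        return "above"
    return "within"


# ---------------------------------------------------------------------------
# study runners

def _condition_id(cond: SimulationCondition) -> str:
    paths = ",".join(f"{k}={v:g}" for k, v in sorted(cond.paths.items()))
    model = "single" if cond.n_mediators == 1 else "two"
    return f"{model}|{cond.x_type}|n={cond.n}|{paths}"


def _batched_fit(cond, xb, meds, yb):
    if cond.n_mediators == 1:
        return batched_single_paths(xb, meds[0], yb)
    return batched_two_paths(xb, meds[0], meds[1], yb)


def _generate_replicates(cond: SimulationCondition, reps: int, cond_idx: int, seed: int):
    """(reps, n) arrays of generated data with rank-deficient reps regenerated."""
    xb = np.empty((reps, cond.n))
    mb = [np.empty((reps, cond.n)) for _ in range(cond.n_mediators)]
    yb = np.empty((reps, cond.n))
    n_regen = 0
    for r in range(reps):
        for attempt in range(_MAX_REGEN):
            x, meds, y = _draw_arrays(cond, _rng_for(seed, cond_idx, r, attempt))
            # a constant X (possible for binary X at small n) cannot be fitted
            if np.ptp(x) > 0:
                break
            n_regen += 1
        else:
            raise RuntimeError(f"could not generate estimable data for {cond}")
        xb[r] = x
        yb[r] = y
        for j, m in enumerate(meds):
            mb[j][r] = m
    return xb, mb, yb, n_regen


def run_point_study(
    grid: Sequence[SimulationCondition],
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Point-estimate study: one row per condition x effect-size measure."""
    if reps < 2:
        raise ValueError("need at least 2 replications")
    records = []
    for ci, cond in enumerate(grid):
        xb, mb, yb, n_regen = _generate_replicates(cond, reps, ci, seed)
        fit = _batched_fit(cond, xb, mb, yb)
        bad = ~fit["ok"]
        attempt_base = 1
        while bad.any():
            if attempt_base > _MAX_REGEN:
                raise RuntimeError(f"persistent rank deficiency in {cond}")
            n_regen += int(bad.sum())
            for r in np.flatnonzero(bad):
                x, meds, y = _draw_arrays(
                    cond, _rng_for(seed, ci, int(r), _MAX_REGEN + attempt_base)
                )
                xb[r] = x
                yb[r] = y
                for j, m in enumerate(meds):
                    mb[j][r] = m
            fit = _batched_fit(cond, xb, mb, yb)
            bad = ~fit["ok"]
            attempt_base += 1
        if cond.n_mediators == 1:
            indirect = fit["a"] * fit["b"]
        else:
            indirect = fit["a1"] * fit["b1"] + fit["a2"] * fit["b2"]
        est = effect_size_arrays(indirect, fit["c_prime"], fit["s_x"], fit["s_y"])
        truth = true_effect_sizes(cond)
        for m in MEASURES:
            rec = {
                "condition": _condition_id(cond),
                "n": cond.n,
                "x_type": cond.x_type,
                "estimator": m,
                "truth": truth[m],
                "mean_estimate": float(np.nanmean(est[m])) if (~np.isnan(est[m])).any() else math.nan,
                **point_metrics(est[m], truth[m]),
                "reps_regenerated": n_regen,
            }
            rec["relative_bias_flagged"] = (
                abs(rec["relative_bias"]) > RELATIVE_BIAS_FLAG
                if not math.isnan(rec["relative_bias"])
                else False
            )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def run_interval_study(
    grid: Sequence[SimulationCondition],
    reps: int = 1000,
    B: int = 1000,
    methods: Iterable[str] = ("percentile", "bias_corrected"),
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-interval study: one row per condition x measure x method."""
    if reps < 2:
        raise ValueError("need at least 2 replications")
    if B < 100:
        raise ValueError("need at least B = 100 bootstrap resamples")
    methods = tuple(methods)
    records = []
    for ci, cond in enumerate(grid):
        truth = true_effect_sizes(cond)
        bounds = {
            (m, meth): (np.full(reps, np.nan), np.full(reps, np.nan))
            for m in MEASURES
            for meth in methods
        }
        n_regen = 0
        with warnings.catch_warnings():
            # clamped bias corrections on degenerate resample sets are
            # expected in null cells; they are aggregated, not printed
            warnings.simplefilter("ignore", RuntimeWarning)
            for r in range(reps):
                for attempt in range(_MAX_REGEN):
                    rng = _rng_for(seed, ci, r, attempt)
                    data = generate_dataset(cond, rng)
                    if np.ptp(data.x) > 0:
                        break
                    n_regen += 1
                else:
                    raise RuntimeError(f"could not generate estimable data for {cond}")
                draws = bootstrap_all_measures(data, B=B, seed=rng)
                for m in MEASURES:
                    for meth in methods:
                        if meth == "percentile":
                            iv = percentile_interval(draws[m], level)
                        elif meth == "bias_corrected":
                            iv = bias_corrected_interval(draws[m], level)
                        else:
                            raise ValueError(f"unknown method {meth!r}")
                        bounds[(m, meth)][0][r] = iv.lower
                        bounds[(m, meth)][1][r] = iv.upper
        for m in MEASURES:
            for meth in methods:
                lo, hi = bounds[(m, meth)]
                met = interval_metrics(lo, hi, truth[m])
                rec = {
                    "condition": _condition_id(cond),
                    "n": cond.n,
                    "x_type": cond.x_type,
                    "estimator": m,
                    "method": meth,
                    "truth": truth[m],
                    "level": level,
                    "B": B,
                    **met,
                    "reps_regenerated": n_regen,
                }
                rec["bradley_type1"] = (
                    bradley_assess(met["rate_excl_zero"], "type1")
                    if met["rate_kind"] == "type1"
                    else "n/a"
                )
                rec["bradley_coverage"] = (
                    bradley_assess(met["coverage"], "coverage")
                    if not math.isnan(met["coverage"])
                    else "n/a"
                )
                records.append(rec)
    return pd.DataFrame.from_records(records)


def run_bayes_study(
    conditions: Sequence[SimulationCondition] | None = None,
    reps: int = 1000,
    seed: int = 0,
    model: str = "single",
    x_type: str | None = None,
    priors: PriorSpec = PriorSpec(),
    n_iter: int = 2500,
    burn_in: int = 500,
    level: float = 0.95,
    rhat_threshold: float = 1.1,
) -> pd.DataFrame:
    """Bayesian study: relative bias of posterior mean/median and interval coverage.

    Defaults to the problematic n = 50 cells (17 single-mediator or 21
    two-mediator conditions across both X types).  Returns one row per
    condition x measure with posterior-summary relative biases, the
    frequentist relative bias for comparison, and equal-tail/HPD coverage.
    """
    if reps < 2:
        raise ValueError("need at least 2 replications")
    if conditions is None:
        conditions = cond_lists.bayes_study_conditions(model, x_type)
    records = []
    for ci, cond in enumerate(conditions):
        truth = true_effect_sizes(cond)
        summaries = {
            (m, s): np.full(reps, np.nan)
            for m in MEASURES
            for s in ("mean", "median", "freq")
        }
        bounds = {
            (m, t): (np.full(reps, np.nan), np.full(reps, np.nan))
            for m in MEASURES
            for t in ("equal_tail", "hpd")
        }
        n_regen = 0
        n_nonconverged = 0
        for r in range(reps):
            for attempt in range(_MAX_REGEN):
                rng = _rng_for(seed, ci, r, attempt)
                data = generate_dataset(cond, rng)
                if np.ptp(data.x) > 0:
                    break
                n_regen += 1
            else:
                raise RuntimeError(f"could not generate estimable data for {cond}")
            chain_seed = int(rng.integers(0, 2**31 - 1))
            post = gibbs_mediation(
                data, priors=priors, n_iter=n_iter, burn_in=burn_in, seed=chain_seed
            )
            es = effect_size_draws(post)
            if split_rhat(es["indirect"]) > rhat_threshold:
                n_nonconverged += 1
            freq = effect_sizes(fit_paths(data))
            for m in MEASURES:
                summaries[(m, "mean")][r] = posterior_point(es[m], "mean")
                summaries[(m, "median")][r] = posterior_point(es[m], "median")
                summaries[(m, "freq")][r] = freq[m]
                et = equal_tail_interval(es[m], level)
                hp = hpd_interval(es[m], level)
                bounds[(m, "equal_tail")][0][r] = et.lower
                bounds[(m, "equal_tail")][1][r] = et.upper
                bounds[(m, "hpd")][0][r] = hp.lower
                bounds[(m, "hpd")][1][r] = hp.upper
        for m in MEASURES:
            rec = {
                "condition": _condition_id(cond),
                "n": cond.n,
                "x_type": cond.x_type,
                "estimator": m,
                "truth": truth[m],
                "reps": reps,
                "reps_regenerated": n_regen,
                "n_nonconverged": n_nonconverged,
            }
            for s in ("mean", "median", "freq"):
                pm = point_metrics(summaries[(m, s)], truth[m])
                rec[f"relative_bias_{s}"] = pm["relative_bias"]
                rec[f"bias_{s}"] = pm["bias"]
            for t in ("equal_tail", "hpd"):
                lo, hi = bounds[(m, t)]
                met = interval_metrics(lo, hi, truth[m])
                rec[f"coverage_{t}"] = met["coverage"]
                rec[f"width_{t}"] = met["width_mean"]
                rec[f"bradley_{t}"] = (
                    bradley_assess(met["coverage"], "coverage")
                    if not math.isnan(met["coverage"])
                    else "n/a"
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)
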