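"""Linear mediation models: data containers, OLS estimation, population moments.

The single-mediator model is the classic three-equation system

    Y = i1 + c X + e1          (total effect)
    Y = i2 + c' X + b M + e2   (direct effect + mediator slope)
    M = i3 + a X + e3          (action path)

and the parallel two-mediator model adds a second mediator predicted by X,
with Y regressed on X, M1 and M2 jointly.  All equations are estimated by
ordinary least squares with an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediationDataset",
    "PathEstimates",
    "SimulationCondition",
    "RankDeficientError",
    "fit_single_mediator",
    "fit_two_mediator",
    "fit_paths",
    "population_moments",
    "read_dataset",
    "write_path_estimates",
]

XType = Literal["continuous", "binary"]


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when a regression design matrix is not of full column rank."""


@dataclass(frozen=True)
class MediationDataset:
    """Observed data for a single- or parallel two-mediator model.

    Parameters
    ----------
    x : array of shape (n,)
        Independent variable; continuous or 0/1 coded binary.
    mediators : tuple of 1 or 2 arrays of shape (n,)
        Mediator variables M (or M1, M2).
    y : array of shape (n,)
        Dependent variable.
    x_type : {"continuous", "binary"}
        Declared type of X; a binary X may take at most two distinct values.
    """

    x: np.ndarray
    mediators: tuple[np.ndarray, ...]
    y: np.ndarray
    x_type: XType = "continuous"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        meds = tuple(np.asarray(m, dtype=float) for m in self.mediators)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "mediators", meds)
        if len(meds) not in (1, 2):
            raise ValueError("mediators must contain 1 or 2 vectors")
        n = x.shape[0]
        if any(m.shape != (n,) for m in meds) or y.shape != (n,):
            raise ValueError("x, mediators and y must all have the same length")
        min_n = 4 if len(meds) == 1 else 5
        if n < min_n:
            raise ValueError(f"need at least {min_n} observations, got {n}")
        if self.x_type == "binary" and np.unique(x).size > 2:
            raise ValueError("binary x may take at most 2 distinct values")
        if self.x_type not in ("continuous", "binary"):
            raise ValueError(f"unknown x_type {self.x_type!r}")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def n_mediators(self) -> int:
        return len(self.mediators)


@dataclass(frozen=True)
class PathEstimates:
    """Path coefficients of a fitted (or population) mediation model.

    For a single mediator the slopes are ``a``, ``b``; for two mediators
    ``a1``, ``b1``, ``a2``, ``b2``.  ``c`` is the total-effect slope and
    ``c_prime`` the direct effect.  ``residual_variances`` holds one entry per
    regression equation, keyed ``"y~x"``, ``"y~x+m"`` (or ``"y~x+m1+m2"``),
    ``"m~x"`` (or ``"m1~x"``, ``"m2~x"``).  ``s_x`` and ``s_y`` are standard
    deviations of X and Y (sample SDs with an n-1 denominator when fitted;
    population SDs when produced by :func:`population_moments`).
    """

    n_mediators: int
    c: float
    c_prime: float
    s_x: float
    s_y: float
    a: float | None = None
    b: float | None = None
    a1: float | None = None
    b1: float | None = None
    a2: float | None = None
    b2: float | None = None
    intercepts: dict = field(default_factory=dict)
    residual_variances: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_mediators == 1:
            if self.a is None or self.b is None:
                raise ValueError("single-mediator estimates need a and b")
            if any(v is not None for v in (self.a1, self.b1, self.a2, self.b2)):
                raise ValueError("a1/b1/a2/b2 must be absent for 1 mediator")
        elif self.n_mediators == 2:
            if any(v is None for v in (self.a1, self.b1, self.a2, self.b2)):
                raise ValueError("two-mediator estimates need a1, b1, a2, b2")
            if self.a is not None or self.b is not None:
                raise ValueError("a/b must be absent for 2 mediators")
        else:
            raise ValueError("n_mediators must be 1 or 2")
        if not (self.s_x > 0 and self.s_y > 0):
            raise ValueError("s_x and s_y must be positive")
        if any(v <= 0 for v in self.residual_variances.values()):
            raise ValueError("residual variances must be positive")

    @property
    def indirect(self) -> float:
        """Indirect effect: ab, or a1*b1 + a2*b2."""
        if self.n_mediators == 1:
            return self.a * self.b
        return self.a1 * self.b1 + self.a2 * self.b2


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of a simulation design: sample size, population paths, X type.

    ``paths`` maps path names to population values: keys ``a``, ``b``,
    ``c_prime`` for a single mediator, or ``a1``, ``b1``, ``a2``, ``b2``,
    ``c_prime`` for two.  X has variance 1 when continuous, or is Bernoulli
    with success probability ``binary_p`` (0/1 coded) when binary.  Residual
    variances of the mediators and Y are 1 and intercepts are 0.
    """

    n: int
    paths: dict
    x_type: XType = "continuous"
    binary_p: float = 0.5

    _SINGLE_KEYS = frozenset({"a", "b", "c_prime"})
    _TWO_KEYS = frozenset({"a1", "b1", "a2", "b2", "c_prime"})

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("simulation conditions use n >= 10")
        keys = frozenset(self.paths)
        if keys not in (self._SINGLE_KEYS, self._TWO_KEYS):
            raise ValueError(f"unrecognised path keys {sorted(keys)}")
        if not all(np.isfinite(v) for v in self.paths.values()):
            raise ValueError("path values must be finite")
        if not 0.0 < self.binary_p < 1.0:
            raise ValueError("binary_p must be in (0, 1)")

    @property
    def n_mediators(self) -> int:
        return 1 if frozenset(self.paths) == self._SINGLE_KEYS else 2

    @property
    def var_x(self) -> float:
        return 1.0 if self.x_type == "continuous" else self.binary_p * (1.0 - self.binary_p)


def _ols(design_cols: Sequence[np.ndarray], y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS with intercept.  Returns (coefs, residual_variance).

    ``coefs[0]`` is the intercept, followed by one slope per design column.
    The residual variance is the unbiased estimate RSS / (n - p).
    """
    n = y.shape[0]
    X = np.column_stack([np.ones(n), *design_cols])
    p = X.shape[1]
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise RankDeficientError(
            f"design matrix with {p} columns has rank {rank}"
        )
    resid = y - X @ coefs
    dof = n - p
    if dof <= 0:
        raise RankDeficientError("no residual degrees of freedom")
    return coefs, float(resid @ resid) / dof


def fit_single_mediator(data: MediationDataset) -> PathEstimates:
    """Fit the three single-mediator regressions by OLS.

    Raises
    ------
    RankDeficientError
        If any design matrix is rank deficient (e.g. constant X).
    """
    if data.n_mediators != 1:
        raise ValueError("dataset has two mediators; use fit_two_mediator")
    m = data.mediators[0]
    tot, v_tot = _ols([data.x], data.y)
    dir_, v_dir = _ols([data.x, m], data.y)
    act, v_act = _ols([data.x], m)
    return PathEstimates(
        n_mediators=1,
        a=float(act[1]),
        b=float(dir_[2]),
        c=float(tot[1]),
        c_prime=float(dir_[1]),
        s_x=float(np.std(data.x, ddof=1)),
        s_y=float(np.std(data.y, ddof=1)),
        intercepts={"y~x": float(tot[0]), "y~x+m": float(dir_[0]), "m~x": float(act[0])},
        residual_variances={"y~x": v_tot, "y~x+m": v_dir, "m~x": v_act},
    )


def fit_two_mediator(data: MediationDataset) -> PathEstimates:
    """Fit the four parallel two-mediator regressions by OLS."""
    if data.n_mediators != 2:
        raise ValueError("dataset has one mediator; use fit_single_mediator")
    m1, m2 = data.mediators
    tot, v_tot = _ols([data.x], data.y)
    dir_, v_dir = _ols([data.x, m1, m2], data.y)
    act1, v_a1 = _ols([data.x], m1)
    act2, v_a2 = _ols([data.x], m2)
    return PathEstimates(
        n_mediators=2,
        a1=float(act1[1]),
        b1=float(dir_[2]),
        a2=float(act2[1]),
        b2=float(dir_[3]),
        c=float(tot[1]),
        c_prime=float(dir_[1]),
        s_x=float(np.std(data.x, ddof=1)),
        s_y=float(np.std(data.y, ddof=1)),
        intercepts={
            "y~x": float(tot[0]),
            "y~x+m1+m2": float(dir_[0]),
            "m1~x": float(act1[0]),
            "m2~x": float(act2[0]),
        },
        residual_variances={
            "y~x": v_tot,
            "y~x+m1+m2": v_dir,
            "m1~x": v_a1,
            "m2~x": v_a2,
        },
    )


def fit_paths(data: MediationDataset) -> PathEstimates:
    """Dispatch to the single- or two-mediator OLS fit."""
    if data.n_mediators == 1:
        return fit_single_mediator(data)
    return fit_two_mediator(data)


def population_moments(cond: SimulationCondition) -> PathEstimates:
    """Population path values and model-implied SDs of X and Y for a condition.

    Under the generating model (unit residual variances, independent mediator
    residuals, Var(X) = 1 continuous or p(1-p) binary):

        Var(Y) = (indirect + c')^2 Var(X) + sum(b_j^2) + 1

    These population SDs feed the "true" effect sizes used as estimands for
    bias and coverage.
    """
    p = cond.paths
    var_x = cond.var_x
    if cond.n_mediators == 1:
        indirect = p["a"] * p["b"]
        sum_b2 = p["b"] ** 2
        kwargs = dict(a=p["a"], b=p["b"])
        rv = {"y~x+m": 1.0, "m~x": 1.0}
    else:
        indirect = p["a1"] * p["b1"] + p["a2"] * p["b2"]
        sum_b2 = p["b1"] ** 2 + p["b2"] ** 2
        kwargs = dict(a1=p["a1"], b1=p["b1"], a2=p["a2"], b2=p["b2"])
        rv = {"y~x+m1+m2": 1.0, "m1~x": 1.0, "m2~x": 1.0}
    c = indirect + p["c_prime"]
    var_y = c**2 * var_x + sum_b2 + 1.0
    return PathEstimates(
        n_mediators=cond.n_mediators,
        c=c,
        c_prime=p["c_prime"],
        s_x=float(np.sqrt(var_x)),
        s_y=float(np.sqrt(var_y)),
        residual_variances=rv,
        **kwargs,
    )


def read_dataset(path, x_type: XType = "continuous") -> MediationDataset:
    """Read a delimited text file with header columns x, m (or m1, m2), y.

    The delimiter (comma or tab) is inferred by pandas.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if {"x", "m", "y"} <= cols:
        meds = (df["m"].to_numpy(float),)
    elif {"x", "m1", "m2", "y"} <= cols:
        meds = (df["m1"].to_numpy(float), df["m2"].to_numpy(float))
    else:
        raise ValueError(
            "expected columns x, m, y or x, m1, m2, y; found " + ", ".join(sorted(cols))
        )
    return MediationDataset(
        x=df["x"].to_numpy(float), mediators=meds, y=df["y"].to_numpy(float), x_type=x_type
    )


def write_path_estimates(paths: PathEstimates, path) -> None:
    """Write fitted coefficients as CSV, one row per equation term."""
    rows = []
    slopes = (
        {"a": paths.a, "b": paths.b}
        if paths.n_mediators == 1
        else {"a1": paths.a1, "b1": paths.b1, "a2": paths.a2, "b2": paths.b2}
    )
    for name, value in {**slopes, "c": paths.c, "c_prime": paths.c_prime}.items():
        rows.append({"term": name, "kind": "slope", "value": value})
    for eq, v in paths.intercepts.items():
        rows.append({"term": f"intercept[{eq}]", "kind": "intercept", "value": v})
    for eq, v in paths.residual_variances.items():
        rows.append({"term": f"resid_var[{eq}]", "kind": "variance", "value": v})
    rows.append({"term": "s_x", "kind": "sd", "value": paths.s_x})
    rows.append({"term": "s_y", "kind": "sd", "value": paths.s_y})
    pd.DataFrame(rows).to_csv(path, index=False)
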