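"""The four effect-size measures for the indirect effect.

Given path coefficients and the SDs of X and Y:

* partially standardized, ``ab_ps = indirect / s_Y``
* fully standardized,     ``ab_fs = indirect * s_X / s_Y``
* proportion mediated,    ``indirect / (indirect + c')``
* ratio mediated,         ``indirect / c'``

The proportion is undefined when the total effect is zero, and the ratio is
undefined when the direct effect c' is zero.  Undefinedness is a *value*
(NaN plus a flag), never an exception: simulation grids include complete-
mediation cells and the harness must keep running through them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PathEstimates

__all__ = [
    "MEASURES",
    "EffectSizeSet",
    "indirect_effect",
    "partially_standardized",
    "fully_standardized",
    "proportion_mediated",
    "ratio_mediated",
    "effect_sizes",
    "effect_size_arrays",
]

#: Canonical ordering of the four measures in tables and outputs.
MEASURES = ("ab_ps", "ab_fs", "proportion", "ratio")


@dataclass(frozen=True)
class EffectSizeSet:
    """The four effect sizes plus the raw indirect effect.

    Undefined measures are stored as NaN; ``defined`` reports per-measure
    definedness.  No clamping is applied: the proportion may leave [0, 1]
    under inconsistent mediation and the ratio may be arbitrarily large.
    """

    indirect: float
    ab_ps: float
    ab_fs: float
    proportion: float
    ratio: float

    def __getitem__(self, measure: str) -> float:
        if measure not in MEASURES and measure != "indirect":
            raise KeyError(measure)
        return getattr(self, measure)

    @property
    def defined(self) -> dict:
        return {m: not math.isnan(getattr(self, m)) for m in MEASURES}


def indirect_effect(paths: PathEstimates) -> float:
    """ab for one mediator, a1*b1 + a2*b2 for two."""
    return paths.indirect


def partially_standardized(indirect: float, s_y: float) -> float:
    """Indirect effect in SD units of Y: indirect / s_y."""
    if not s_y > 0:
        raise ValueError("s_y must be positive")
    return indirect / s_y


def fully_standardized(indirect: float, s_x: float, s_y: float) -> float:
    """Indirect effect in SD units of both X and Y: indirect * s_x / s_y."""
    if not (s_x > 0 and s_y > 0):
        raise ValueError("s_x and s_y must be positive")
    return indirect * s_x / s_y


def proportion_mediated(indirect: float, c_prime: float) -> float:
    """indirect / (indirect + c'); NaN when the total effect is zero."""
    total = indirect + c_prime
    if total == 0.0:
        return math.nan
    return indirect / total


def ratio_mediated(indirect: float, c_prime: float) -> float:
    """indirect / c'; NaN when the direct effect is zero."""
    if c_prime == 0.0:
        return math.nan
    return indirect / c_prime


def effect_sizes(
    paths: PathEstimates, s_x: float | None = None, s_y: float | None = None
) -> EffectSizeSet:
    """All four measures from a set of path estimates.

    ``s_x``/``s_y`` default to the SDs stored on ``paths`` (sample SDs for
    fitted paths, population SDs for population moments).
    """
    s_x = paths.s_x if s_x is None else s_x
    s_y = paths.s_y if s_y is None else s_y
    ind = paths.indirect
    return EffectSizeSet(
        indirect=ind,
        ab_ps=partially_standardized(ind, s_y),
        ab_fs=fully_standardized(ind, s_x, s_y),
        proportion=proportion_mediated(ind, paths.c_prime),
        ratio=ratio_mediated(ind, paths.c_prime),
    )


def effect_size_arrays(indirect, c_prime, s_x, s_y) -> dict:
    """Vectorised effect sizes for arrays of path draws.

    All inputs broadcast; returns a dict keyed by :data:`MEASURES` with NaN
    marking undefined entries.  This is the shared kernel of the bootstrap
    and the posterior-draw transformations.
    """
    indirect = np.asarray(indirect, dtype=float)
    c_prime = np.asarray(c_prime, dtype=float)
    total = indirect + c_prime
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {
            "ab_ps": indirect / s_y,
            "ab_fs": indirect * s_x / s_y,
            "proportion": np.where(total != 0.0, indirect / np.where(total != 0.0, total, 1.0), np.nan),
            "ratio": np.where(c_prime != 0.0, indirect / np.where(c_prime != 0.0, c_prime, 1.0), np.nan),
        }
    return out
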