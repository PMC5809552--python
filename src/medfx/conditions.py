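"""Simulation design grids and the problematic-relative-bias condition lists.

Path values correspond to approximately zero, small (2% of variance), medium
(13%) and large (26%) effects: {0, 0.14, 0.39, 0.59} for the single-mediator
paths and {0, 0.101, 0.314, 0.577} (with c' in {0, 0.131, 0.400, 0.740}) for
the two-mediator model, where only cells with a1 = b1 and a2 = b2 are used.

``BAYES_SINGLE`` / ``BAYES_TWO`` list, per X type, the parameter combinations
at n = 50 for which frequentist point estimates showed excessive relative
bias (|relative bias| > 0.05) — the cells on which the Bayesian study runs:
6 continuous + 11 binary single-mediator cells, and 11 continuous + 10 binary
two-mediator cells.
"""

from __future__ import annotations

from itertools import product

from .model import SimulationCondition

__all__ = [
    "SINGLE_PATH_VALUES",
    "TWO_PATH_VALUES",
    "TWO_CPRIME_VALUES",
    "single_mediator_grid",
    "two_mediator_grid",
    "bayes_study_conditions",
    "BAYES_SINGLE",
    "BAYES_TWO",
]

SINGLE_PATH_VALUES = (0.0, 0.14, 0.39, 0.59)
TWO_PATH_VALUES = (0.0, 0.101, 0.314, 0.577)
TWO_CPRIME_VALUES = (0.0, 0.131, 0.400, 0.740)

#: Sample-size grids: point study vs interval study, single- vs two-mediator.
SINGLE_POINT_NS = (10, 50, 100, 500, 1000)
SINGLE_INTERVAL_NS = (50, 100, 500, 1000)
TWO_NS = (10, 50, 100, 500)

# (a, b) pairs per direct-effect value, single-mediator model, n = 50.
BAYES_SINGLE = {
    "continuous": [
        (0.14, 0.14, 0.0),
        (0.14, 0.39, 0.14),
        (0.14, 0.14, 0.39),
        (0.14, 0.59, 0.39),
        (0.39, 0.39, 0.39),
        (0.14, 0.59, 0.59),
    ],
    "binary": [
        (0.14, 0.39, 0.0),
        (0.39, 0.39, 0.0),
        (0.14, 0.14, 0.14),
        (0.14, 0.39, 0.14),
        (0.14, 0.59, 0.14),
        (0.39, 0.14, 0.14),
        (0.14, 0.39, 0.39),
        (0.39, 0.14, 0.39),
        (0.59, 0.14, 0.39),
        (0.14, 0.39, 0.59),
        (0.39, 0.59, 0.59),
    ],
}

# (a1 = b1, a2 = b2, c') triples, two-mediator model, n = 50.
BAYES_TWO = {
    "continuous": [
        (0.0, 0.101, 0.0),
        (0.101, 0.0, 0.0),
        (0.101, 0.101, 0.0),
        (0.0, 0.314, 0.131),
        (0.101, 0.0, 0.131),
        (0.0, 0.101, 0.400),
        (0.101, 0.0, 0.400),
        (0.0, 0.101, 0.740),
        (0.101, 0.0, 0.740),
        (0.101, 0.101, 0.740),
        (0.314, 0.101, 0.740),
    ],
    "binary": [
        (0.0, 0.101, 0.0),
        (0.101, 0.0, 0.0),
        (0.314, 0.101, 0.0),
        (0.101, 0.0, 0.131),
        (0.0, 0.101, 0.400),
        (0.101, 0.0, 0.400),
        (0.101, 0.101, 0.400),
        (0.0, 0.101, 0.740),
        (0.101, 0.0, 0.740),
        (0.101, 0.101, 0.740),
    ],
}


def single_mediator_grid(
    x_type: str = "continuous", ns=SINGLE_POINT_NS
) -> list[SimulationCondition]:
    """Full factorial grid over n and the a, b, c' path values.

    With the default five sample sizes this is the 5 x 4^3 = 320-cell point
    study; pass ``ns=SINGLE_INTERVAL_NS`` for the interval study's four
    sample sizes.
    """
    return [
        SimulationCondition(n=n, paths={"a": a, "b": b, "c_prime": cp}, x_type=x_type)
        for n, a, b, cp in product(
            ns, SINGLE_PATH_VALUES, SINGLE_PATH_VALUES, SINGLE_PATH_VALUES
        )
    ]


def two_mediator_grid(x_type: str = "continuous", ns=TWO_NS) -> list[SimulationCondition]:
    """Constrained two-mediator grid (a1 = b1, a2 = b2): 4 x 4^2 x 4 = 256 cells."""
    return [
        SimulationCondition(
            n=n,
            paths={"a1": p1, "b1": p1, "a2": p2, "b2": p2, "c_prime": cp},
            x_type=x_type,
        )
        for n, p1, p2, cp in product(ns, TWO_PATH_VALUES, TWO_PATH_VALUES, TWO_CPRIME_VALUES)
    ]


def bayes_study_conditions(model: str, x_type: str | None = None, n: int = 50):
    """Default Bayesian-study conditions (the excessive-relative-bias cells).

    ``model`` is "single" or "two"; with ``x_type=None`` both X types are
    returned (17 single-mediator or 21 two-mediator conditions in total).
    """
    table = {"single": BAYES_SINGLE, "two": BAYES_TWO}[model]
    x_types = [x_type] if x_type else ["continuous", "binary"]
    out = []
    for xt in x_types:
        for row in table[xt]:
            if model == "single":
                a, b, cp = row
                paths = {"a": a, "b": b, "c_prime": cp}
            else:
                p1, p2, cp = row
                paths = {"a1": p1, "b1": p1, "a2": p2, "b2": p2, "c_prime": cp}
            out.append(SimulationCondition(n=n, paths=paths, x_type=xt))
    return out
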