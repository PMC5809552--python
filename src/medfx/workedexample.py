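"""Worked examples from a steroid-use prevention trial (n = 1315).

The raw data are not distributed; the published regression coefficients are
the inputs.  X is binary (treatment vs control), so only the partially
standardized effect, the proportion mediated and the ratio mediated are
reported (the fully standardized effect is not meaningful for a binary X).

Single-mediator model (mediator: team as an information source):
    a = 0.549, b = 0.174, c = 0.318, c' = 0.234, s_Y = 1.217
Two-mediator model (adds perceived severity of steroid use):
    a1 = 0.549, b1 = 0.165, a2 = 0.440, b2 = 0.092, c = 0.318, c' = 0.188

Interval estimates and posterior summaries published alongside these point
estimates required the raw individual-level data and are therefore not
recomputed here.
"""

from __future__ import annotations

from .effects import partially_standardized, proportion_mediated, ratio_mediated

__all__ = ["worked_example", "EXAMPLE_COEFFICIENTS"]

EXAMPLE_COEFFICIENTS = {
    "table3": {"a": 0.549, "b": 0.174, "c": 0.318, "c_prime": 0.234, "s_y": 1.217},
    "table4": {
        "a1": 0.549,
        "b1": 0.165,
        "a2": 0.440,
        "b2": 0.092,
        "c": 0.318,
        "c_prime": 0.188,
        "s_y": 1.217,
    },
}


def worked_example(which: str = "table3") -> dict:
    """Effect-size point estimates from the published coefficients.

    ``which`` selects the single-mediator ("table3") or two-mediator
    ("table4") example.  Returns a dict with the inputs and the computed
    ``indirect``, ``ab_ps``, ``proportion`` and ``ratio``.
    """
    if which not in EXAMPLE_COEFFICIENTS:
        raise ValueError("which must be 'table3' or 'table4'")
    coef = EXAMPLE_COEFFICIENTS[which]
    if which == "table3":
        indirect = coef["a"] * coef["b"]
    else:
        indirect = coef["a1"] * coef["b1"] + coef["a2"] * coef["b2"]
    return {
        "inputs": dict(coef),
        "indirect": indirect,
        "ab_ps": partially_standardized(indirect, coef["s_y"]),
        "proportion": proportion_mediated(indirect, coef["c_prime"]),
        "ratio": ratio_mediated(indirect, coef["c_prime"]),
    }
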