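"""Effect sizes from published trial coefficients (no raw data needed).

Recomputes the point estimates of a steroid-use prevention trial's mediation
analysis from its published regression coefficients, for the single-mediator
and the parallel two-mediator model.
"""

from medfx import worked_example

for which, label in [("table3", "single mediator"), ("table4", "two mediators")]:
    res = worked_example(which)
    print(f"\n{label} (published coefficients: {res['inputs']})")
    print(f"  indirect effect        : {res['indirect']:.3f}")
    print(f"  partially standardized : {res['ab_ps']:.3f}")
    print(f"  proportion mediated    : {res['proportion']:.3f}")
    print(f"  ratio mediated         : {res['ratio']:.3f}")

print(
    "\nReading: the treatment raises the outcome by ~0.08 SD (single mediator)"
    "\nor ~0.11 SD (two mediators) through the mediator(s); roughly 29% / 41%"
    "\nof the total effect is carried by the mediators."
)
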