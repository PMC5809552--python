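"""A small Monte Carlo study of estimator quality.

Runs the point-estimate study on a few single-mediator cells and the
bootstrap-interval study on one null cell, printing bias/efficiency metrics
and Type I error with its robustness classification.  Replication counts are
kept small so the script finishes in seconds; scale `reps` up for precision.
"""

import pandas as pd

from medfx import SimulationCondition, run_interval_study, run_point_study

pd.set_option("display.width", 160)

grid = [
    SimulationCondition(n=n, paths={"a": 0.39, "b": 0.39, "c_prime": cp})
    for n in (50, 500)
    for cp in (0.0, 0.39)
]
point = run_point_study(grid, reps=200, seed=0)
print("point-estimate metrics (bias / relative bias / SD):")
print(
    point[["condition", "estimator", "truth", "bias", "relative_bias", "sd"]]
    .round(4)
    .to_string(index=False)
)

null = SimulationCondition(n=100, paths={"a": 0.0, "b": 0.39, "c_prime": 0.39})
intervals = run_interval_study([null], reps=100, B=500, seed=0)
print("\ninterval metrics at a null cell (true indirect effect = 0):")
print(
    intervals[["estimator", "method", "rate_excl_zero", "rate_kind", "coverage",
               "width_mean", "bradley_type1"]]
    .round(3)
    .to_string(index=False)
)
print(
    "\nReading: 'rate_excl_zero' is the empirical Type I error here; 'within'"
    "\nmeans it falls in the 0.025-0.075 robustness band. The standardized"
    "\nmeasures shrink in SD as n grows; proportion/ratio stay unstable."
)
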