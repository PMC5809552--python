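"""Bayesian effect sizes: Gibbs sampling, posterior summaries, HPD intervals.

Fits a two-mediator model with diffuse priors and summarises the posterior
distribution of each effect-size measure by its mean, median, equal-tail and
highest-posterior-density interval.
"""

from medfx import (
    MEASURES,
    SimulationCondition,
    effect_size_draws,
    equal_tail_interval,
    generate_dataset,
    gibbs_mediation,
    hpd_interval,
    posterior_point,
)

cond = SimulationCondition(
    n=150, paths={"a1": 0.314, "b1": 0.314, "a2": 0.101, "b2": 0.101, "c_prime": 0.4}
)
data = generate_dataset(cond, seed=3)

post = gibbs_mediation(data, n_iter=11000, burn_in=1000, seed=4)
es = effect_size_draws(post)

for m in MEASURES:
    et = equal_tail_interval(es[m], 0.95)
    hp = hpd_interval(es[m], 0.95)
    print(
        f"{m:<11} mean {posterior_point(es[m], 'mean'):7.3f}  "
        f"median {posterior_point(es[m], 'median'):7.3f}  "
        f"equal-tail [{et.lower:7.3f}, {et.upper:7.3f}]  "
        f"HPD [{hp.lower:7.3f}, {hp.upper:7.3f}]"
    )
print(
    "\nReading: the HPD interval is never wider than the equal-tail interval;"
    "\nfor skewed measures (ratio mediated) the posterior median is the more"
    "\nstable point summary than the mean."
)
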