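"""OLS fitting, data containers and population moments."""

import numpy as np
import pytest

from medfx.model import (
    MediationDataset,
    RankDeficientError,
    SimulationCondition,
    fit_single_mediator,
    fit_two_mediator,
    population_moments,
    read_dataset,
    write_path_estimates,
)
from medfx.simulate import generate_dataset


def test_noiseless_single_mediator_recovered_exactly():
    # mediator residual pattern orthogonal to [1, x] so a is recovered exactly;
    # y is an exact linear combination of x and m
    x = np.array([-3.0, -1, 1, 3])
    e = np.array([1.0, -1, -1, 1])
    m = 0.5 * x + e
    y = 0.2 * x + 0.3 * m
    p = fit_single_mediator(MediationDataset(x=x, mediators=(m,), y=y))
    assert p.a == pytest.approx(0.5, abs=1e-12)
    assert p.b == pytest.approx(0.3, abs=1e-12)
    assert p.c_prime == pytest.approx(0.2, abs=1e-12)
    assert p.c == pytest.approx(0.2 + 0.5 * 0.3, abs=1e-12)


def test_noiseless_two_mediator_recovered_exactly():
    x = np.array([-5.0, -3, -1, 1, 3, 5])
    e1 = np.array([1.0, -1, 0, 0, -1, 1])
    e2 = np.array([1.0, 0, -1, -1, 0, 1])
    m1 = 0.3 * x + e1
    m2 = 0.1 * x + e2
    y = 0.4 * x + 0.3 * m1 + 0.1 * m2
    p = fit_two_mediator(MediationDataset(x=x, mediators=(m1, m2), y=y))
    assert (p.a1, p.b1) == (pytest.approx(0.3), pytest.approx(0.3))
    assert (p.a2, p.b2) == (pytest.approx(0.1), pytest.approx(0.1))
    assert p.c_prime == pytest.approx(0.4)
    assert p.c == pytest.approx(0.4 + 0.09 + 0.01)


def test_four_point_dataset_matches_hand_solved_normal_equations(handcrafted_4pt):
    p = fit_single_mediator(handcrafted_4pt)
    assert p.a == pytest.approx(1 / 5)
    assert p.c == pytest.approx(3 / 5)
    assert p.c_prime == pytest.approx(2 / 3)
    assert p.b == pytest.approx(-1 / 3)


def test_fit_agrees_with_statsmodels(single_dataset):
    sm = pytest.importorskip("statsmodels.api")
    p = fit_single_mediator(single_dataset)
    X = sm.add_constant(
        np.column_stack([single_dataset.x, single_dataset.mediators[0]])
    )
    fit = sm.OLS(single_dataset.y, X).fit()
    assert p.c_prime == pytest.approx(fit.params[1], rel=1e-10)
    assert p.b == pytest.approx(fit.params[2], rel=1e-10)
    assert p.residual_variances["y~x+m"] == pytest.approx(fit.scale, rel=1e-10)


def test_large_sample_slopes_near_population_values():
    cond = SimulationCondition(n=1_000_000, paths={"a": 0.39, "b": 0.39, "c_prime": 0.39})
    p = fit_single_mediator(generate_dataset(cond, seed=5))
    for got, want in ((p.a, 0.39), (p.b, 0.39), (p.c_prime, 0.39)):
        assert got == pytest.approx(want, abs=0.01)


def test_large_sample_two_mediator_slopes():
    cond = SimulationCondition(
        n=1_000_000,
        paths={"a1": 0.314, "b1": 0.314, "a2": 0.314, "b2": 0.314, "c_prime": 0.4},
    )
    p = fit_two_mediator(generate_dataset(cond, seed=6))
    for got, want in ((p.a1, 0.314), (p.b1, 0.314), (p.a2, 0.314), (p.b2, 0.314), (p.c_prime, 0.4)):
        assert got == pytest.approx(want, abs=0.01)


def test_duplicate_mediators_raise_rank_error():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    m = rng.standard_normal(50)
    data = MediationDataset(x=x, mediators=(m, m.copy()), y=rng.standard_normal(50))
    with pytest.raises(RankDeficientError):
        fit_two_mediator(data)


def test_constant_x_raises_rank_error():
    rng = np.random.default_rng(0)
    data = MediationDataset(
        x=np.ones(20),
        mediators=(rng.standard_normal(20),),
        y=rng.standard_normal(20),
        x_type="binary",
    )
    with pytest.raises(RankDeficientError):
        fit_single_mediator(data)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ols_identity_total_equals_direct_plus_indirect(seed):
    """c = c' + sum(a_j b_j) holds to 1e-10 for any full-rank dataset."""
    cond1 = SimulationCondition(n=60, paths={"a": 0.14, "b": 0.59, "c_prime": 0.39})
    p = fit_single_mediator(generate_dataset(cond1, seed=seed))
    assert abs(p.c - (p.c_prime + p.a * p.b)) < 1e-10
    cond2 = SimulationCondition(
        n=60, paths={"a1": 0.1, "b1": 0.3, "a2": 0.5, "b2": 0.2, "c_prime": 0.131}
    )
    q = fit_two_mediator(generate_dataset(cond2, seed=seed))
    assert abs(q.c - (q.c_prime + q.a1 * q.b1 + q.a2 * q.b2)) < 1e-10


def test_fit_invariant_to_row_order(single_dataset):
    p1 = fit_single_mediator(single_dataset)
    perm = np.random.default_rng(3).permutation(single_dataset.n)
    shuffled = MediationDataset(
        x=single_dataset.x[perm],
        mediators=(single_dataset.mediators[0][perm],),
        y=single_dataset.y[perm],
    )
    p2 = fit_single_mediator(shuffled)
    assert p1.a == pytest.approx(p2.a)
    assert p1.b == pytest.approx(p2.b)
    assert p1.c_prime == pytest.approx(p2.c_prime)
    assert p1.s_y == pytest.approx(p2.s_y)


def test_dataset_validation_errors():
    with pytest.raises(ValueError):
        MediationDataset(x=np.ones(3), mediators=(np.ones(3),), y=np.ones(3))
    with pytest.raises(ValueError):
        MediationDataset(x=np.ones(5), mediators=(np.ones(4),), y=np.ones(5))
    with pytest.raises(ValueError):
        MediationDataset(
            x=np.array([0.0, 1, 2, 0, 1]),
            mediators=(np.ones(5),),
            y=np.ones(5),
            x_type="binary",
        )


def test_population_moments_null_condition():
    cond = SimulationCondition(n=100, paths={"a": 0.0, "b": 0.0, "c_prime": 0.0})
    pm = population_moments(cond)
    assert pm.s_y == pytest.approx(1.0)
    assert pm.s_x == pytest.approx(1.0)


def test_population_moments_closed_form_medium_paths():
    # Var(Y) = (ab + c')^2 + b^2 + 1 = 0.5421^2 + 0.1521 + 1 = 1.44597...
    cond = SimulationCondition(n=100, paths={"a": 0.39, "b": 0.39, "c_prime": 0.39})
    pm = population_moments(cond)
    assert pm.s_y == pytest.approx(np.sqrt(0.5421**2 + 0.39**2 + 1), rel=1e-12)
    assert pm.s_y == pytest.approx(1.2025, abs=5e-5)


def test_population_moments_binary_x():
    cond = SimulationCondition(
        n=100, paths={"a": 0.39, "b": 0.39, "c_prime": 0.39}, x_type="binary"
    )
    pm = population_moments(cond)
    assert pm.s_x == pytest.approx(0.5)
    assert pm.s_y**2 == pytest.approx(0.25 * 0.5421**2 + 0.1521 + 1, rel=1e-10)


def test_read_dataset_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"x": [0.0, 1, 0, 1, 0], "m1": range(5), "m2": [2.0, 1, 4, 3, 5],
                       "y": [1.0, 3, 2, 5, 4]})
    path = tmp_path / "d.csv"
    df.to_csv(path, index=False)
    data = read_dataset(path, x_type="binary")
    assert data.n_mediators == 2
    np.testing.assert_allclose(data.mediators[1], df["m2"])


def test_write_path_estimates(tmp_path, single_dataset):
    import pandas as pd

    p = fit_single_mediator(single_dataset)
    out = tmp_path / "coefs.csv"
    write_path_estimates(p, out)
    back = pd.read_csv(out)
    assert back.set_index("term").loc["a", "value"] == pytest.approx(p.a)
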