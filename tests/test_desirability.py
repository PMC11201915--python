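"""Desirability transforms, geometric-mean combination, and the optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combifit import (
    DesirabilityGoal,
    InputError,
    desirability_score,
    fit_quadratic,
    overall_desirability,
    optimize,
    pairwise_cv,
)
from combifit.desirability import default_goals_from_fits
from combifit.synthetic import (
    OPTIMUM_BP,
    OPTIMUM_TM,
    generate_ccd_response_table,
)

TARGET_GOAL = DesirabilityGoal("viability", "target", target=50.0, low=0.0, high=100.0)


@pytest.fixture(scope="module")
def noiseless_fits(design, noiseless_config):
    table = generate_ccd_response_table(noiseless_config, design)
    return [
        fit_quadratic(table, design, cell_line=name)
        for name in sorted(noiseless_config.surface_coeffs)
    ]


@pytest.mark.parametrize(
    "y,expected",
    [
        (50.0, 1.0),                    # on target
        (0.0, 0.0),                     # at the lower bound
        (100.0, 0.0),                   # at the upper bound
        (53.3, (100 - 53.3) / 50.0),    # linear ramp above target: 0.934
        (25.0, 0.5),
        (-5.0, 0.0),                    # outside the acceptable band
        (105.0, 0.0),
    ],
)
def test_target_desirability_values(y, expected):
    assert desirability_score(y, TARGET_GOAL) == pytest.approx(expected, abs=1e-12)


def test_one_sided_goals():
    g_max = DesirabilityGoal("r", "maximize", low=0.0, high=100.0)
    g_min = DesirabilityGoal("r", "minimize", low=0.0, high=100.0)
    assert desirability_score(100.0, g_max) == 1.0
    assert desirability_score(0.0, g_max) == 0.0
    assert desirability_score(25.0, g_max) == pytest.approx(0.25)
    assert desirability_score(25.0, g_min) == pytest.approx(0.75)


def test_weight_exponents_curve_the_ramp():
    g = DesirabilityGoal("r", "target", target=50.0, low=0.0, high=100.0, s=2.0, t=0.5)
    assert desirability_score(25.0, g) == pytest.approx(0.25)   # (0.5)^2
    assert desirability_score(75.0, g) == pytest.approx(np.sqrt(0.5))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"kind": "nonsense"},
        {"kind": "target", "target": None},
        {"kind": "target", "target": 150.0},   # target outside [low, high]
        {"kind": "target", "target": 50.0, "s": 0.0},
        {"kind": "target", "target": 50.0, "low": 100.0, "high": 0.0},
    ],
)
def test_invalid_goals_raise(kwargs):
    kwargs.setdefault("low", 0.0)
    kwargs.setdefault("high", 100.0)
    with pytest.raises(InputError):
        DesirabilityGoal("r", **kwargs)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([1.0, 1.0], 1.0),
        ([1.0, 0.0], 0.0),
        ([0.25, 1.0], 0.5),
        ([0.5, 0.5, 0.5], 0.5),
    ],
)
def test_overall_desirability_values(values, expected):
    assert overall_desirability(values) == pytest.approx(expected, abs=1e-12)


def test_overall_desirability_empty_raises():
    with pytest.raises(InputError):
        overall_desirability([])


@settings(derandomize=True, max_examples=100)
@given(
    d=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=5),
    c=st.floats(min_value=1e-3, max_value=1.0),
)
def test_geometric_mean_identities(d, c):
    """Order invariance and homogeneity: D(c*d) = c * D(d)."""
    D = overall_desirability(d)
    assert overall_desirability(list(reversed(d))) == pytest.approx(D, rel=1e-9)
    assert overall_desirability([c * x for x in d]) == pytest.approx(c * D, rel=1e-9)


def test_optimizer_finds_forced_interior_optimum(noiseless_fits):
    """Both noiseless surfaces cross 50% at one interior point: the
    optimizer must return it as rank 1 with D = 1."""
    goals = default_goals_from_fits(noiseless_fits, target=50.0)
    sols = optimize(noiseless_fits, goals, k=5)
    top = sols[0]
    assert top.rank == 1
    assert top.D == pytest.approx(1.0, abs=1e-9)
    assert top.tm == pytest.approx(OPTIMUM_TM, abs=1e-4)
    assert top.bp == pytest.approx(OPTIMUM_BP, abs=1e-3)
    for v in top.predicted.values():
        assert v == pytest.approx(50.0, abs=1e-7)
    # ranking is monotone non-increasing in D, solutions are distinct
    Ds = [s.D for s in sols]
    assert all(a >= b for a, b in zip(Ds, Ds[1:]))
    pts = [(round(s.tm, 1), round(s.bp, 1)) for s in sols]
    assert len(set(pts)) == len(pts)


def test_optimizer_matches_dense_grid_oracle(noiseless_fits):
    goals = default_goals_from_fits(noiseless_fits, target=50.0)
    best = optimize(noiseless_fits, goals, k=1)[0].D
    (tlo, thi), (blo, bhi) = noiseless_fits[0].region
    tm, bp = np.meshgrid(
        np.linspace(tlo, thi, 500), np.linspace(blo, bhi, 500), indexing="ij"
    )
    from combifit.desirability import _evaluate_D

    grid_best = float(np.max(_evaluate_D(noiseless_fits, goals, tm, bp)))
    assert best >= grid_best - 1e-9


def test_solution_d_consistency(noiseless_fits):
    goals = default_goals_from_fits(noiseless_fits, target=50.0)
    for s in optimize(noiseless_fits, goals, k=3):
        assert s.D == pytest.approx(
            float(np.prod(list(s.d_i.values())) ** (1.0 / len(s.d_i))), abs=1e-12
        )


def test_unattainable_goals_return_empty_with_warning(noiseless_fits):
    goals = [
        DesirabilityGoal(f.response_name, "target", target=2.0, low=0.0, high=4.0)
        for f in noiseless_fits
    ]
    with pytest.warns(UserWarning):
        sols = optimize(noiseless_fits, goals, k=5)
    assert sols == []


def test_goal_count_mismatch_raises(noiseless_fits):
    with pytest.raises(InputError):
        optimize(noiseless_fits, [TARGET_GOAL], k=1)


def test_pairwise_cv_closed_form():
    # CV of a pair reduces to 100 * |a - b| / (sqrt(2) * mean)
    assert pairwise_cv(50.0, 47.6) == pytest.approx(
        100.0 * abs(50.0 - 47.6) / np.sqrt(2.0) / 48.8, rel=1e-12
    )
    with pytest.raises(InputError):
        pairwise_cv(1.0, -1.0)
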