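"""Chou-Talalay combination-index properties and classification."""

import numpy as np
import pandas as pd
import pytest

from combifit import (
    CombinationMeasurement,
    FitError,
    InputError,
    ci_fa_curve,
    classify_ci,
    combination_index,
    dose_for_effect,
    fit_median_effect,
)
from combifit.synergy import is_nontoxic
from combifit.synthetic import (
    GeneratorConfig,
    generate_combination_table,
    generate_single_agent_table,
    median_effect_fa,
)


def exact_fit(m=2.0, dm=80.0):
    doses = np.array([dm / 2, dm, dm * 2])
    fa = median_effect_fa(doses, m, dm)
    table = pd.DataFrame(
        {
            "agent": "TM",
            "cell_line": "A549",
            "concentration_ug_ml": doses,
            "replicate": 1,
            "viability_pct": 100.0 * (1.0 - fa),
        }
    )
    return fit_median_effect(table)


def test_sham_self_combination_is_additive():
    """Splitting Dx(fa) of one agent into two 'partners' must give CI = 1."""
    fit = exact_fit()
    fa = 0.6                     # viability 40%
    dx = dose_for_effect(fit, fa)
    res = combination_index(
        CombinationMeasurement(0.3 * dx, 0.7 * dx, 40.0), fit, fit
    )
    assert res.ci == pytest.approx(1.0, abs=1e-9)
    assert res.classification == "additive"


def test_single_agent_limit():
    fit = exact_fit()
    dx = dose_for_effect(fit, 0.5)
    res = combination_index(CombinationMeasurement(dx, 0.0, 50.0), fit, fit)
    assert res.ci == pytest.approx(1.0, abs=1e-9)


def test_ci_homogeneous_in_doses():
    fit = exact_fit()
    m1 = CombinationMeasurement(20.0, 100.0, 40.0)
    m2 = CombinationMeasurement(40.0, 200.0, 40.0)
    ci1 = combination_index(m1, fit, fit).ci
    ci2 = combination_index(m2, fit, fit).ci
    assert ci2 == pytest.approx(2.0 * ci1, rel=1e-12)


def test_ci_strictly_decreasing_in_fa_at_fixed_doses():
    fit = exact_fit()
    viabilities = [80.0, 60.0, 40.0, 20.0]  # increasing fa
    cis = [
        combination_index(CombinationMeasurement(30.0, 50.0, v), fit, fit).ci
        for v in viabilities
    ]
    assert all(a > b for a, b in zip(cis, cis[1:]))


@pytest.mark.parametrize(
    "ci,expected",
    [
        (0.9499999, "synergy"),
        (0.95, "additive"),
        (1.0, "additive"),
        (1.05, "additive"),
        (1.0500001, "antagonism"),
    ],
)
def test_classification_boundaries_respect_tolerance(ci, expected):
    assert classify_ci(ci, tol=0.05) == expected


def test_nontoxic_partner_term_is_dropped_and_flagged():
    fit = exact_fit()
    meas = CombinationMeasurement(40.0, 300.0, 50.0)
    res = combination_index(meas, fit, None)
    assert res.partner_nontoxic
    assert res.dx2 is None
    assert res.ci == pytest.approx(40.0 / fit.dm, rel=1e-9)


def test_primary_agent_must_be_usable():
    bad = fit_median_effect(
        pd.DataFrame(
            {
                "agent": "TM",
                "cell_line": "A549",
                "concentration_ug_ml": [10.0, 50.0, 100.0],
                "replicate": 1,
                "viability_pct": [40.0, 60.0, 80.0],  # inverted: slope < 0
            }
        )
    )
    with pytest.raises(FitError):
        combination_index(CombinationMeasurement(10.0, 10.0, 50.0), bad)


def test_measurement_validation():
    with pytest.raises(InputError):
        CombinationMeasurement(0.0, 0.0, 50.0)
    with pytest.raises(InputError):
        CombinationMeasurement(-1.0, 10.0, 50.0)


def test_ci_fa_curve_sorted_and_deterministic():
    fit = exact_fit()
    meas = [
        CombinationMeasurement(30.0, 100.0, 70.0),
        CombinationMeasurement(30.0, 100.0, 30.0),
        CombinationMeasurement(30.0, 100.0, 50.0),
        CombinationMeasurement(30.0, 100.0, 50.0),  # duplicate
    ]
    curve = ci_fa_curve(meas, fit, partner_nontoxic=True)
    fas = [r.fa for r in curve]
    assert fas == sorted(fas)
    dup = [r.ci for r in curve if r.fa == pytest.approx(0.5)]
    assert dup[0] == dup[1]
    with pytest.raises(InputError):
        ci_fa_curve([], fit)


def test_seeded_synergy_scenario_all_ci_below_one():
    """The ground-truth combination surface is more cytotoxic than the TM
    single-agent model predicts, so every tested combination scores CI < 1
    (the qualitative synergy finding this chain is built to detect)."""
    gen = GeneratorConfig(seed=11, noise_cv=0.05)
    for line in ("A549", "NCI-H292"):
        single = generate_single_agent_table(gen, "TM", line)
        fit_tm = fit_median_effect(single)
        points = [(50.0, 250.0), (50.0, 300.0), (50.0, 350.0), (50.0, 400.0),
                  (48.5, 241.7)]
        combo = generate_combination_table(gen, points, line)
        means = (
            combo.groupby(["tm_ug_ml", "bp_ug_ml"])["viability_pct"].mean().reset_index()
        )
        meas = [
            CombinationMeasurement(r.tm_ug_ml, r.bp_ug_ml, r.viability_pct)
            for r in means.itertuples()
        ]
        curve = ci_fa_curve(meas, fit_tm, partner_nontoxic=True)
        assert all(r.ci < 1.0 for r in curve)
        assert all(r.classification == "synergy" for r in curve)


def test_bp_is_flagged_nontoxic():
    gen = GeneratorConfig(seed=5, noise_cv=0.05)
    bp = generate_single_agent_table(gen, "BP", "A549")
    fit_bp = fit_median_effect(bp)
    assert is_nontoxic(fit_bp, bp)
    tm = generate_single_agent_table(gen, "TM", "A549")
    fit_tm = fit_median_effect(tm)
    assert not is_nontoxic(fit_tm, tm)
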