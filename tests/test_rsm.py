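"""CCD construction and quadratic surface fitting with ANOVA diagnostics."""

import numpy as np
import pandas as pd
import pytest

from combifit import DesignError, FitError, RangeError, build_ccd, fit_quadratic
from combifit.pipeline import BP_LEVELS, TM_LEVELS
from combifit.rsm import evaluate_quadratic
from combifit.synthetic import GeneratorConfig, generate_ccd_response_table

from helpers_oracles import normal_equations_quadratic


def test_ccd_structure(design):
    assert design.n_runs == 14                       # 4 factorial + 4 axial + 6 center
    assert design.alpha == 2.0
    assert design.centers == (30.0, 300.0)
    np.testing.assert_allclose(design.coded.mean(axis=0), 0.0, atol=1e-12)
    (tlo, thi), (blo, bhi) = design.natural_ranges
    assert (tlo, thi) == (10.0, 50.0)
    assert (blo, bhi) == (200.0, 400.0)
    # axial points land exactly on the extreme stated levels
    assert set(design.natural[:, 0]) == {10.0, 20.0, 30.0, 40.0, 50.0}
    assert set(design.natural[:, 1]) == {200.0, 250.0, 300.0, 350.0, 400.0}


@pytest.mark.parametrize(
    "levels_tm,levels_bp,n_center",
    [
        ([10, 20, 35, 40, 50], BP_LEVELS, 6),     # non-uniform spacing
        ([10, 20, 30, 40], BP_LEVELS, 6),         # wrong level count
        (TM_LEVELS, [400, 350, 300, 250, 200], 6),  # decreasing
        (TM_LEVELS, BP_LEVELS, 0),                # no center points
    ],
)
def test_invalid_designs_raise(levels_tm, levels_bp, n_center):
    with pytest.raises(DesignError):
        build_ccd(levels_tm, levels_bp, n_center=n_center)


def test_noiseless_fit_recovers_surface_coefficients(design, noiseless_config):
    """A quadratic fit interpolates a quadratic truth exactly."""
    table = generate_ccd_response_table(noiseless_config, design)
    for name, beta_true in noiseless_config.surface_coeffs.items():
        fit = fit_quadratic(table, design, cell_line=name)
        np.testing.assert_allclose(fit.beta, beta_true, rtol=0, atol=1e-8)
        assert fit.anova.ss_residual == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_normal_equations_oracle(design, noisy_config):
    table = generate_ccd_response_table(noisy_config, design)
    sub = table[table["cell_line"] == "A549"]
    fit = fit_quadratic(table, design, cell_line="A549")
    x1, x2 = design.code(sub["tm_ug_ml"].to_numpy(), sub["bp_ug_ml"].to_numpy())
    oracle = normal_equations_quadratic(x1, x2, sub["viability_pct"].to_numpy())
    np.testing.assert_allclose(fit.beta_coded, oracle, rtol=1e-9)


def test_anova_identity_and_nonnegative_components(design, noisy_config):
    table = generate_ccd_response_table(noisy_config, design)
    fit = fit_quadratic(table, design, cell_line="A549")
    a = fit.anova
    # SS_total = SS_model + SS_lof + SS_pe, with SS computed independently
    sub = table[table["cell_line"] == "A549"]
    y = sub["viability_pct"].to_numpy()
    yhat = fit.predict(sub["tm_ug_ml"].to_numpy(), sub["bp_ug_ml"].to_numpy())
    ss_model_indep = float(np.sum((yhat - y.mean()) ** 2))
    assert a.ss_model == pytest.approx(ss_model_indep, rel=1e-8)
    assert a.ss_total == pytest.approx(
        a.ss_model + a.ss_lack_of_fit + a.ss_pure_error, rel=1e-8
    )
    assert a.ss_residual == pytest.approx(
        a.ss_lack_of_fit + a.ss_pure_error, rel=1e-10
    )
    assert min(a.ss_lack_of_fit, a.ss_pure_error) >= 0
    assert min(a.df_model, a.df_residual, a.df_lack_of_fit, a.df_pure_error) >= 0
    assert a.df_total == a.df_model + a.df_residual
    assert fit.adj_r2 <= fit.r2
    assert np.isfinite(fit.adeq_precision) and fit.adeq_precision > 0
    assert fit.cv_pct > 0


def test_coded_and_natural_predictions_agree_at_design_points(design, noisy_config):
    table = generate_ccd_response_table(noisy_config, design)
    fit = fit_quadratic(table, design, cell_line="NCI-H292")
    nat = fit.predict(design.natural[:, 0], design.natural[:, 1])
    cod = fit.predict_coded(design.coded[:, 0], design.coded[:, 1])
    np.testing.assert_allclose(nat, cod, rtol=1e-10)


def test_dropping_interaction_cannot_decrease_residual_ss(design, noisy_config):
    table = generate_ccd_response_table(noisy_config, design)
    sub = table[table["cell_line"] == "A549"]
    x1, x2 = design.code(sub["tm_ug_ml"].to_numpy(), sub["bp_ug_ml"].to_numpy())
    y = sub["viability_pct"].to_numpy()
    X_full = np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])
    ss_full = np.linalg.lstsq(X_full, y, rcond=None)[1][0] if X_full.shape[1] < len(y) else 0
    ss_red = np.linalg.lstsq(X_full[:, :5], y, rcond=None)[1][0]
    assert ss_red >= ss_full - 1e-10


def test_coefficient_estimates_unbiased_under_replicate_noise(design):
    """Mean coded-coefficient bias over 500 noisy repeats is < 2% of the
    largest non-intercept coefficient (OLS unbiasedness at assay noise)."""
    truth_fit = fit_quadratic(
        generate_ccd_response_table(GeneratorConfig(seed=0, noise_cv=0.0), design),
        design,
        cell_line="A549",
    )
    g_true = truth_fit.beta_coded
    acc = np.zeros(6)
    for seed in range(500):
        cfg = GeneratorConfig(seed=seed, noise_cv=0.05)
        table = generate_ccd_response_table(cfg, design)
        acc += fit_quadratic(table, design, cell_line="A549").beta_coded
    bias = acc / 500 - g_true
    scale = np.max(np.abs(g_true[1:]))
    assert np.all(np.abs(bias) < 0.02 * scale)


def test_rank_deficient_design_names_aliased_term(design):
    # all points on the line bp = 10 * tm: x2 is aliased with x1
    tm = np.repeat([10.0, 20.0, 30.0, 40.0, 50.0, 25.0], 2)
    table = pd.DataFrame(
        {
            "cell_line": "A549",
            "tm_ug_ml": tm,
            "bp_ug_ml": 10.0 * tm,
            "viability_pct": 100.0 - tm,
        }
    )
    with pytest.raises(FitError, match="x2"):
        fit_quadratic(table, design)


def test_too_few_design_points_raise(design, noiseless_config):
    table = generate_ccd_response_table(noiseless_config, design)
    small = table[table["cell_line"] == "A549"].head(5)
    with pytest.raises(FitError):
        fit_quadratic(small, design)


def test_predict_extrapolation_policy(design, noisy_config):
    table = generate_ccd_response_table(noisy_config, design)
    fit = fit_quadratic(table, design, cell_line="A549")
    fit.predict(30.0, 300.0)  # interior: silent
    with pytest.warns(UserWarning):
        fit.predict(50.5, 300.0)  # within 5% of the span beyond the edge
    with pytest.raises(RangeError):
        fit.predict(60.0, 300.0)  # gross extrapolation


def test_constant_surface_predicts_constant(design):
    runs = design.to_frame()
    table = pd.DataFrame(
        {
            "cell_line": "A549",
            "tm_ug_ml": runs["tm_ug_ml"],
            "bp_ug_ml": runs["bp_ug_ml"],
            "viability_pct": 100.0,
        }
    )
    fit = fit_quadratic(table, design)
    assert fit.predict(30.0, 300.0) == pytest.approx(100.0, abs=1e-9)
    assert fit.predict(45.0, 220.0) == pytest.approx(100.0, abs=1e-9)


def test_evaluate_quadratic_matches_manual():
    beta = (1.0, 2.0, -3.0, 0.5, -0.25, 0.1)
    assert evaluate_quadratic(beta, 2.0, 4.0) == pytest.approx(
        1 + 4 - 12 + 0.5 * 4 - 0.25 * 16 + 0.1 * 8
    )
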