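"""Median-effect dose-response fitting.

The median-effect equation (Chou) unifies dose-effect relationships as

    fa / fu = (D / Dm)**m

where ``fa`` is the fraction of cells affected at dose ``D``, ``fu = 1 - fa``
the fraction unaffected, ``Dm`` the median-effect dose (the dose producing a
50% effect, i.e. the EC50 when the effect is loss of viability) and ``m`` a
unitless slope describing the sigmoidicity of the curve.  Taking log10 of
both sides linearizes the model,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

so ``m`` and ``Dm`` are obtained by ordinary least squares of the logit of
``fa`` on log-dose.  Base-10 logarithms are used throughout, following the
convention of the CI-model software this mirrors.

Viability percentages are converted to fractions affected with
:func:`fraction_affected`, which clamps to the open interval
``(EPS, 1 - EPS)`` so the logit stays finite.  Points sitting *at* the clamp
(viability at or beyond 0% or 100%) carry no dose-response information and
are excluded from the regression to avoid leverage artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, InputError

__all__ = [
    "EPS",
    "MedianEffectFit",
    "fraction_affected",
    "fit_median_effect",
    "dose_for_effect",
    "validate_dose_response_table",
]

#: Clamp half-width for the viability -> fraction-affected transform.
EPS = 1e-4

#: Column schema of a single-agent dose-response table.
DOSE_RESPONSE_COLUMNS = (
    "agent",
    "cell_line",
    "concentration_ug_ml",
    "replicate",
    "viability_pct",
)


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of a linearized median-effect fit.

    Attributes
    ----------
    agent, cell_line
        Labels carried through from the input table (may be empty).
    m
        Unitless median-effect slope.
    dm
        Median-effect dose in ug/mL; equals the EC50 for viability data.
    r2
        Coefficient of determination of the linearized (logit vs log-dose)
        regression, clipped to [0, 1].
    n_points
        Number of replicate-averaged concentration points used.
    usable
        True when the fitted slope is positive and at least two usable
        points entered the regression.  Unusable fits mark agents with no
        measurable dose response (e.g. a non-toxic partner).
    """

    m: float
    dm: float
    r2: float
    n_points: int
    usable: bool
    agent: str = ""
    cell_line: str = ""


def fraction_affected(viability: float | np.ndarray, eps: float = EPS):
    """Convert percent viability to the fraction affected ``fa``.

    ``fa = 1 - viability/100`` clamped to ``(eps, 1 - eps)``; clamping is
    part of the contract so that logit transforms downstream remain finite.
    """
    v = np.asarray(viability, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("viability values must be finite")
    fa = np.clip(1.0 - v / 100.0, eps, 1.0 - eps)
    return float(fa) if fa.ndim == 0 else fa


def validate_dose_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a single-agent dose-response table."""
    missing = set(DOSE_RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"dose-response table missing columns: {sorted(missing)}")
    conc = table["concentration_ug_ml"].to_numpy(dtype=float)
    if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
        raise InputError("concentrations must be positive and finite")
    if not np.all(np.isfinite(table["viability_pct"].to_numpy(dtype=float))):
        raise InputError("viability values must be finite")
    if table["concentration_ug_ml"].nunique() < 2:
        raise InputError("need at least 2 distinct concentrations")
    return table


def fit_median_effect(
    table: pd.DataFrame,
    *,
    agent: str | None = None,
    cell_line: str | None = None,
    eps: float = EPS,
) -> MedianEffectFit:
    """Fit the median-effect model to a replicated dose-response table.

    Replicates are averaged per concentration before the logit transform
    (matching mean +/- SD reporting of plate assays); points whose mean
    viability falls at the clamp boundary are excluded as uninformative.

    Parameters
    ----------
    table
        DataFrame with columns ``agent, cell_line, concentration_ug_ml,
        replicate, viability_pct``.  If *agent* / *cell_line* are given the
        table is filtered first.
    """
    df = table
    if agent is not None:
        df = df[df["agent"] == agent]
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    if df.empty:
        raise InputError("no rows match the requested agent/cell line")
    validate_dose_response_table(df)

    agent_label = str(df["agent"].iloc[0])
    line_label = str(df["cell_line"].iloc[0])

    means = (
        df.groupby("concentration_ug_ml", sort=True)["viability_pct"]
        .mean()
        .reset_index()
    )
    fa = fraction_affected(means["viability_pct"].to_numpy(), eps=eps)
    # Clamped points (viability >= 100% or <= 0%) carry no information.
    usable_mask = (fa > eps) & (fa < 1.0 - eps)
    dose = means["concentration_ug_ml"].to_numpy()[usable_mask]
    fa = fa[usable_mask]

    if len(dose) < 2:
        raise FitError(
            f"median-effect fit for {agent_label}/{line_label}: "
            f"fewer than 2 usable points after clamping"
        )
    x = np.log10(dose)
    if np.ptp(x) == 0:
        raise FitError("zero variance in log-dose: need >= 2 distinct doses")
    y = np.log10(fa / (1.0 - fa))

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    r2 = float(np.clip(res.rsquared, 0.0, 1.0)) if len(x) > 2 else 1.0
    if len(x) == 2:
        r2 = 1.0

    usable = bool(slope > 0)
    dm = float(10.0 ** (-intercept / slope)) if usable else float("nan")
    return MedianEffectFit(
        m=float(slope),
        dm=dm,
        r2=r2,
        n_points=int(len(x)),
        usable=usable,
        agent=agent_label,
        cell_line=line_label,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Back-calculate the dose ``Dx`` producing fraction affected *fa*.

    ``Dx = Dm * (fa / (1 - fa))**(1/m)``.  Requires a usable fit; an
    unusable fit signals an agent without a dose response (handled by the
    synergy module as the non-toxic-partner case).
    """
    if not fit.usable:
        raise FitError(
            f"fit for {fit.agent or 'agent'} is unusable (no positive slope); "
            "cannot back-calculate a dose"
        )
    if not 0.0 < fa < 1.0:
        raise InputError("fa must lie strictly between 0 and 1")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def fit_summary(fits: list[MedianEffectFit]) -> pd.DataFrame:
    """Tabulate fits as ``agent,cell_line,m,Dm,r2,usable`` (one row each)."""
    return pd.DataFrame(
        [
            {
                "agent": f.agent,
                "cell_line": f.cell_line,
                "m": f.m,
                "Dm": f.dm,
                "r2": f.r2,
                "n_points": f.n_points,
                "usable": f.usable,
            }
            for f in fits
        ]
    )
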