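"""Chou-Talalay combination-index scoring.

For a combination dose pair (d1, d2) producing fraction affected ``fa``,
the combination index is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where ``Dxi(fa)`` is the dose of agent *i* alone that would produce the
same effect level, back-calculated from its median-effect fit.  CI < 1
indicates synergy, CI = 1 additivity and CI > 1 antagonism; classification
uses a configurable additivity tolerance (default 0.05) because CI is a
continuous score, not a sharp statistic.

Each combination is evaluated at its own fa (non-constant-ratio analysis);
the study design here -- a fixed primary-agent dose with a varying partner
plus a single optimized pair -- is not a fixed-ratio dilution series.

When the partner agent has no usable dose-response (no measurable
cytotoxicity over its tested range), its ``d2/Dx2`` term is dropped and the
result flagged ``partner_nontoxic``: the classical ``Dx2 -> infinity``
limit, under which CI < 1 still indicates that the partner potentiates the
primary agent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import MedianEffectFit, dose_for_effect, fraction_affected
from .errors import FitError, InputError

__all__ = [
    "CombinationMeasurement",
    "CIResult",
    "combination_index",
    "ci_fa_curve",
    "classify_ci",
    "is_nontoxic",
]

#: Default half-width of the additive band around CI = 1.
ADDITIVITY_TOL = 0.05


@dataclass(frozen=True)
class CombinationMeasurement:
    """One combination exposure: doses (ug/mL) and observed % viability."""

    d1: float
    d2: float
    viability: float

    def __post_init__(self):
        if self.d1 < 0 or self.d2 < 0:
            raise InputError("doses must be non-negative")
        if self.d1 == 0 and self.d2 == 0:
            raise InputError("at least one dose must be positive")

    @property
    def fa(self) -> float:
        """Fraction affected, via the clamped viability transform."""
        return fraction_affected(self.viability)


@dataclass(frozen=True)
class CIResult:
    """Combination index for one measurement."""

    measurement: CombinationMeasurement
    fa: float
    dx1: float
    dx2: float | None
    ci: float
    classification: str
    partner_nontoxic: bool


def classify_ci(ci: float, tol: float = ADDITIVITY_TOL) -> str:
    """Classify a CI value as synergy / additive / antagonism within *tol*."""
    if ci < 1.0 - tol:
        return "synergy"
    if ci > 1.0 + tol:
        return "antagonism"
    return "additive"


def is_nontoxic(
    fit: MedianEffectFit, table: pd.DataFrame | None = None, max_fa: float = 0.2
) -> bool:
    """Decide whether an agent is effectively non-toxic over its tested range.

    True when the median-effect fit is unusable, or when *table* is given
    and the largest replicate-mean fraction affected stays below *max_fa*.
    """
    if not fit.usable:
        return True
    if table is None:
        return False
    means = table.groupby("concentration_ug_ml")["viability_pct"].mean()
    return float(np.max(fraction_affected(means.to_numpy()))) < max_fa


def combination_index(
    meas: CombinationMeasurement,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit | None = None,
    *,
    partner_nontoxic: bool | None = None,
    tol: float = ADDITIVITY_TOL,
) -> CIResult:
    """Compute the combination index for one measurement.

    *fit1* (the primary, cytotoxic agent) must be usable.  *fit2* may be
    omitted or unusable, or the partner may be declared non-toxic
    explicitly via *partner_nontoxic*; in that case the partner's dose term
    is dropped from CI and the result is flagged.
    """
    if not fit1.usable:
        raise FitError(
            "primary agent has no usable dose-response; CI is undefined"
        )
    if partner_nontoxic is None:
        partner_nontoxic = fit2 is None or not fit2.usable

    fa = meas.fa
    dx1 = dose_for_effect(fit1, fa)
    ci = meas.d1 / dx1
    dx2 = None
    if not partner_nontoxic:
        dx2 = dose_for_effect(fit2, fa)
        ci += meas.d2 / dx2
    return CIResult(
        measurement=meas,
        fa=fa,
        dx1=dx1,
        dx2=dx2,
        ci=float(ci),
        classification=classify_ci(float(ci), tol=tol),
        partner_nontoxic=bool(partner_nontoxic),
    )


def ci_fa_curve(
    measurements,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit | None = None,
    *,
    partner_nontoxic: bool | None = None,
    tol: float = ADDITIVITY_TOL,
) -> list[CIResult]:
    """Combination indices for a set of measurements, sorted by fa ascending."""
    measurements = list(measurements)
    if not measurements:
        raise InputError("need at least one combination measurement")
    results = [
        combination_index(
            m, fit1, fit2, partner_nontoxic=partner_nontoxic, tol=tol
        )
        for m in measurements
    ]
    return sorted(results, key=lambda r: r.fa)


def ci_table(results: list[CIResult]) -> pd.DataFrame:
    """Tabulate CI results in the standard CSV dialect."""
    return pd.DataFrame(
        [
            {
                "tm_ug_ml": r.measurement.d1,
                "bp_ug_ml": r.measurement.d2,
                "fa": r.fa,
                "dx1": r.dx1,
                "dx2": np.nan if r.dx2 is None else r.dx2,
                "ci": r.ci,
                "classification": r.classification,
                "partner_nontoxic": r.partner_nontoxic,
            }
            for r in results
        ]
    )
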