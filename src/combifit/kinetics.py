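"""Blank-corrected compound-consumption kinetics from decay time courses.

The measured signal (UPLC peak area or concentration, any proportional
unit) is regressed linearly on time.  With slope ``sigma_abs`` and
intercept ``abs0`` (the regression estimate of the initial signal), the
molar consumption rate is

    sigma_cc = -sigma_abs * N0 / abs0        [nmol/h]

where ``N0`` is the initial amount of compound (nmol) in the dosed medium.
Because slope and intercept scale together, sigma_cc is invariant to the
signal's unit -- only the fractional decay rate and N0 matter.

The cell-attributable consumption activity subtracts the abiotic blank
(compound incubated without cells) and normalizes to the initial compound
mass:

    activity = (sigma_cc_sample - sigma_cc_blank) / cc_mass   [nmol/h/ug]

A negative activity (blank decaying faster than the sample) is reported
with a warning rather than floored: it is an informative QC signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, InputError

__all__ = ["ConsumptionResult", "consumption_rate", "cc_activity"]

#: Column schema of a time-course table.
TIME_COURSE_COLUMNS = ("condition", "time_h", "concentration_nmol_ml", "replicate")


@dataclass(frozen=True)
class ConsumptionResult:
    """Linear-decay fit and derived consumption rate for one condition.

    ``sigma_abs`` is the raw signal slope (signal/h, negative for decay),
    ``abs0`` the regression intercept at t = 0, ``n0`` the initial compound
    amount (nmol) and ``sigma_cc`` the molar consumption rate (nmol/h,
    positive = net consumption).  ``r2`` is the goodness of the linear fit.
    """

    condition: str
    sigma_abs: float
    abs0: float
    n0: float
    sigma_cc: float
    r2: float
    n_points: int


def consumption_rate(
    table: pd.DataFrame, n0: float, *, use_replicate_means: bool = False
) -> ConsumptionResult:
    """Estimate the molar consumption rate from a decay time course.

    By default the regression uses every replicate point (correct
    pure-error weighting for replicated series); set
    *use_replicate_means* to average replicates per time point first.

    Requires >= 3 distinct time points and ``n0 > 0``; a non-positive
    regression intercept leaves the rate undefined and raises
    :class:`FitError`.
    """
    for col in ("condition", "time_h", "concentration_nmol_ml"):
        if col not in table.columns:
            raise InputError(f"time-course table missing column {col!r}")
    if n0 <= 0:
        raise InputError("n0 must be positive")

    df = table
    if use_replicate_means:
        df = (
            df.groupby(["condition", "time_h"], sort=True)["concentration_nmol_ml"]
            .mean()
            .reset_index()
        )
    t = df["time_h"].to_numpy(dtype=float)
    c = df["concentration_nmol_ml"].to_numpy(dtype=float)
    if np.unique(t).size < 3:
        raise InputError("need at least 3 distinct time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
        raise InputError("times and concentrations must be finite")

    res = sm.OLS(c, sm.add_constant(t)).fit()
    abs0, sigma_abs = res.params
    if abs0 <= 0:
        raise FitError(
            "regression intercept (initial signal) is non-positive; "
            "consumption rate is undefined"
        )
    sigma_cc = -sigma_abs * n0 / abs0
    r2 = float(np.clip(res.rsquared, 0.0, 1.0)) if np.ptp(c) > 0 else 1.0
    condition = str(df["condition"].iloc[0])
    return ConsumptionResult(
        condition=condition,
        sigma_abs=float(sigma_abs),
        abs0=float(abs0),
        n0=float(n0),
        sigma_cc=float(sigma_cc),
        r2=r2,
        n_points=int(len(t)),
    )


def cc_activity(
    sample: ConsumptionResult, blank: ConsumptionResult, cc_mass: float
) -> float:
    """Blank-corrected, mass-normalized consumption activity (nmol/h/ug).

    ``(sigma_cc_sample - sigma_cc_blank) / cc_mass`` with *cc_mass* the
    initial compound mass (ug) in the dosed medium.
    """
    if cc_mass <= 0:
        raise InputError("cc_mass must be positive")
    activity = (sample.sigma_cc - blank.sigma_cc) / cc_mass
    if activity < 0:
        warnings.warn(
            f"negative consumption activity for {sample.condition!r}: blank "
            "decays faster than the sample (check the blank series)",
            stacklevel=2,
        )
    return float(activity)


def activity_table(
    results: dict[str, ConsumptionResult],
    blank_condition: str,
    cc_mass: float,
) -> pd.DataFrame:
    """Summary CSV rows: per-condition sigma_cc, blank-corrected activity, r2."""
    if blank_condition not in results:
        raise InputError(f"blank condition {blank_condition!r} missing from results")
    blank = results[blank_condition]
    rows = []
    for name, res in results.items():
        activity = (
            np.nan if name == blank_condition else cc_activity(res, blank, cc_mass)
        )
        rows.append(
            {
                "condition": name,
                "sigma_cc_nmol_h": res.sigma_cc,
                "cc_activity_nmol_h_ug": activity,
                "r2": res.r2,
            }
        )
    return pd.DataFrame(rows)
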