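"""Central composite design construction and quadratic response-surface fitting.

A two-factor central composite design (CCD) combines a 2**2 factorial, four
axial ("star") points at coded distance +/-alpha on each axis, and replicated
center points.  Here the factors are the concentrations of two agents and
each is tested at five uniformly spaced levels; with uniform spacing the
axial points sit at twice the factorial half-range, so the coded axial
distance is alpha = 2 (a face-on-grid CCD rather than the rotatable
alpha = sqrt(2), which cannot land on a uniform five-level grid).

The fitted model is the full quadratic

    Y = b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2

with Y the response (percent cell viability).  Fitting is performed in coded
units for conditioning and the coefficients are reported in both coded and
natural (ug/mL) units.  Diagnostics follow the usual design-of-experiments
ANOVA: the residual sum of squares is split into lack of fit (model
inadequacy across distinct design points) and pure error (replicate-only
variation), and the fit reports adjusted R^2, the coefficient of variation,
and "adequate precision" -- the predicted-response range at the design
points divided by the average prediction standard deviation,
(max yhat - min yhat) / sqrt(p * MSE / n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, FitError, InputError, RangeError

__all__ = [
    "CCDDesign",
    "RSMFit",
    "AnovaTable",
    "build_ccd",
    "fit_quadratic",
    "evaluate_quadratic",
]

#: Term order of the quadratic coefficient vector.
TERM_NAMES = ("intercept", "x1", "x2", "x1^2", "x2^2", "x1*x2")

#: Column schema of a combination design/response table.
COMBINATION_COLUMNS = ("cell_line", "run", "tm_ug_ml", "bp_ug_ml", "viability_pct")


def evaluate_quadratic(beta, x1, x2):
    """Evaluate ``b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2``.

    *beta* is ordered ``(b0, b1, b2, b11, b22, b12)``; *x1*, *x2* may be
    scalars or broadcastable arrays.
    """
    b0, b1, b2, b11, b22, b12 = beta
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    out = b0 + b1 * x1 + b2 * x2 + b11 * x1**2 + b22 * x2**2 + b12 * x1 * x2
    return float(out) if out.ndim == 0 else out


def _model_matrix(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2]
    )


@dataclass(frozen=True)
class CCDDesign:
    """A two-factor central composite design.

    ``coded`` holds runs x 2 coded levels in {-alpha, -1, 0, +1, +alpha};
    ``natural`` the corresponding concentrations in ug/mL.  The affine map
    between the two is ``natural = center + step * coded``.
    """

    factor_names: tuple[str, str]
    coded: np.ndarray
    natural: np.ndarray
    centers: tuple[float, float]
    steps: tuple[float, float]
    n_center: int
    alpha: float

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def natural_ranges(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(min, max) natural level per factor."""
        lo = self.natural.min(axis=0)
        hi = self.natural.max(axis=0)
        return (float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))

    def to_frame(self) -> pd.DataFrame:
        f1, f2 = self.factor_names
        return pd.DataFrame(
            {
                "run": np.arange(1, self.n_runs + 1),
                f"{f1.lower()}_coded": self.coded[:, 0],
                f"{f2.lower()}_coded": self.coded[:, 1],
                f"{f1.lower()}_ug_ml": self.natural[:, 0],
                f"{f2.lower()}_ug_ml": self.natural[:, 1],
            }
        )

    def code(self, nat1, nat2):
        """Map natural concentrations to coded units."""
        return (
            (np.asarray(nat1, dtype=float) - self.centers[0]) / self.steps[0],
            (np.asarray(nat2, dtype=float) - self.centers[1]) / self.steps[1],
        )


def build_ccd(
    levels_tm,
    levels_bp,
    n_center: int = 6,
    factor_names: tuple[str, str] = ("TM", "BP"),
) -> CCDDesign:
    """Build the CCD from two five-level uniformly spaced concentration lists.

    Factorial points use levels 2 and 4, axial points levels 1 and 5 and the
    center (level 3) is replicated *n_center* times, for ``8 + n_center``
    runs in total.  With the default six center replicates this yields the
    classic 14-run two-factor layout.
    """
    levels = []
    for name, lv in zip(factor_names, (levels_tm, levels_bp)):
        lv = np.asarray(lv, dtype=float)
        if lv.shape != (5,):
            raise DesignError(f"{name}: exactly 5 levels required, got {lv.shape}")
        if np.any(np.diff(lv) <= 0):
            raise DesignError(f"{name}: levels must be strictly increasing")
        spacings = np.diff(lv)
        if not np.allclose(spacings, spacings[0], rtol=1e-9, atol=0.0):
            raise DesignError(
                f"{name}: levels must be uniformly spaced (got spacings {spacings})"
            )
        levels.append(lv)
    if n_center < 1:
        raise DesignError("n_center must be >= 1")

    alpha = 2.0
    coded_rows = (
        [(-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0)]
        + [(-alpha, 0.0), (alpha, 0.0), (0.0, -alpha), (0.0, alpha)]
        + [(0.0, 0.0)] * n_center
    )
    coded = np.array(coded_rows)
    centers = (float(levels[0][2]), float(levels[1][2]))
    steps = (float(levels[0][1] - levels[0][0]), float(levels[1][1] - levels[1][0]))
    natural = np.column_stack(
        [centers[0] + steps[0] * coded[:, 0], centers[1] + steps[1] * coded[:, 1]]
    )
    return CCDDesign(
        factor_names=tuple(factor_names),
        coded=coded,
        natural=natural,
        centers=centers,
        steps=steps,
        n_center=int(n_center),
        alpha=alpha,
    )


@dataclass(frozen=True)
class AnovaTable:
    """Sums of squares / degrees of freedom for the response-surface ANOVA."""

    ss_total: float
    ss_model: float
    ss_residual: float
    ss_lack_of_fit: float
    ss_pure_error: float
    df_total: int
    df_model: int
    df_residual: int
    df_lack_of_fit: int
    df_pure_error: int
    f_lack_of_fit: float
    p_lack_of_fit: float


@dataclass(frozen=True)
class RSMFit:
    """A fitted quadratic response surface with Design-Expert-style diagnostics."""

    response_name: str
    beta: np.ndarray          # natural units, (b0, b1, b2, b11, b22, b12)
    beta_coded: np.ndarray    # same terms, coded units
    anova: AnovaTable
    r2: float
    adj_r2: float
    adeq_precision: float
    cv_pct: float
    n_obs: int
    centers: tuple[float, float]
    steps: tuple[float, float]
    region: tuple[tuple[float, float], tuple[float, float]]
    factor_names: tuple[str, str] = ("TM", "BP")

    def predict(self, tm, bp, *, check_region: bool = True):
        """Predict percent viability at concentrations ``(tm, bp)`` in ug/mL.

        Mild extrapolation (within 5% of the region span beyond an edge)
        triggers a warning; anything further raises :class:`RangeError`.
        """
        tm_a = np.asarray(tm, dtype=float)
        bp_a = np.asarray(bp, dtype=float)
        if check_region:
            for val, (lo, hi), name in (
                (tm_a, self.region[0], self.factor_names[0]),
                (bp_a, self.region[1], self.factor_names[1]),
            ):
                span = hi - lo
                if np.any(val < lo - 0.05 * span) or np.any(val > hi + 0.05 * span):
                    raise RangeError(
                        f"{name} concentration outside the design region "
                        f"[{lo}, {hi}] ug/mL by more than 5% of the span"
                    )
                if np.any(val < lo) or np.any(val > hi):
                    warnings.warn(
                        f"{name} concentration mildly outside the design region "
                        f"[{lo}, {hi}] ug/mL; prediction is an extrapolation",
                        stacklevel=2,
                    )
        return evaluate_quadratic(self.beta, tm_a, bp_a)

    def predict_coded(self, x1, x2):
        """Predict from coded factor levels (no region check)."""
        return evaluate_quadratic(self.beta_coded, x1, x2)


def _coded_to_natural(g: np.ndarray, centers, steps) -> np.ndarray:
    """Re-express coded-unit quadratic coefficients in natural units."""
    g0, g1, g2, g11, g22, g12 = g
    c1, c2 = centers
    s1, s2 = steps
    b11 = g11 / s1**2
    b22 = g22 / s2**2
    b12 = g12 / (s1 * s2)
    b1 = g1 / s1 - 2.0 * g11 * c1 / s1**2 - g12 * c2 / (s1 * s2)
    b2 = g2 / s2 - 2.0 * g22 * c2 / s2**2 - g12 * c1 / (s1 * s2)
    b0 = (
        g0
        - g1 * c1 / s1
        - g2 * c2 / s2
        + g11 * c1**2 / s1**2
        + g22 * c2**2 / s2**2
        + g12 * c1 * c2 / (s1 * s2)
    )
    return np.array([b0, b1, b2, b11, b22, b12])


def _check_full_rank(X: np.ndarray) -> None:
    """Raise FitError naming the first aliased term if X is rank-deficient."""
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise FitError(
                f"model matrix is rank-deficient: term '{TERM_NAMES[j]}' is "
                "aliased with preceding terms"
            )
        rank = new_rank


def fit_quadratic(
    table: pd.DataFrame,
    design: CCDDesign | None = None,
    *,
    response_name: str = "",
    cell_line: str | None = None,
) -> RSMFit:
    """Fit the full quadratic surface to a combination design/response table.

    Parameters
    ----------
    table
        DataFrame with columns ``tm_ug_ml, bp_ug_ml, viability_pct`` (and
        optionally ``cell_line`` to filter on).
    design
        The CCD the data came from; provides the coding map and the region.
        When omitted, coding is derived from the data range assuming the
        axial points span twice the factorial half-range.

    At least six distinct design points are required to identify the six
    coefficients, and at least two replicated points to estimate pure error.
    """
    df = table
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
        if df.empty:
            raise InputError(f"no rows for cell line {cell_line!r}")
        response_name = response_name or cell_line
    for col in ("tm_ug_ml", "bp_ug_ml", "viability_pct"):
        if col not in df.columns:
            raise InputError(f"combination table missing column {col!r}")

    tm = df["tm_ug_ml"].to_numpy(dtype=float)
    bp = df["bp_ug_ml"].to_numpy(dtype=float)
    y = df["viability_pct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputError("responses must be finite")

    points = df.groupby(["tm_ug_ml", "bp_ug_ml"], sort=True)
    if points.ngroups < 6:
        raise FitError(
            f"need >= 6 distinct design points to fit 6 coefficients, "
            f"got {points.ngroups}"
        )
    replicated = points.size()[points.size() >= 2]
    if replicated.empty or replicated.sum() - len(replicated) < 1:
        raise FitError("need >= 2 replicate runs at some design point for pure error")

    if design is not None:
        centers, steps = design.centers, design.steps
        region = design.natural_ranges
    else:
        centers = (float((tm.min() + tm.max()) / 2), float((bp.min() + bp.max()) / 2))
        steps = (float((tm.max() - tm.min()) / 4), float((bp.max() - bp.min()) / 4))
        region = ((float(tm.min()), float(tm.max())), (float(bp.min()), float(bp.max())))
    x1 = (tm - centers[0]) / steps[0]
    x2 = (bp - centers[1]) / steps[1]

    X = _model_matrix(x1, x2)
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()
    g = np.asarray(res.params)
    beta = _coded_to_natural(g, centers, steps)

    n = len(y)
    p = X.shape[1]
    yhat = X @ g
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_residual = float(np.sum((y - yhat) ** 2))
    ss_model = ss_total - ss_residual
    # Pure error: replicate variation within identical (tm, bp) settings.
    ss_pe = float(points["viability_pct"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    df_pe = int((points.size() - 1).sum())
    ss_lof = max(ss_residual - ss_pe, 0.0)
    df_resid = n - p
    df_lof = df_resid - df_pe
    if df_lof > 0 and df_pe > 0 and ss_pe > 0:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof, p_lof = float("nan"), float("nan")
    anova = AnovaTable(
        ss_total=ss_total,
        ss_model=ss_model,
        ss_residual=ss_residual,
        ss_lack_of_fit=ss_lof,
        ss_pure_error=ss_pe,
        df_total=n - 1,
        df_model=p - 1,
        df_residual=df_resid,
        df_lack_of_fit=df_lof,
        df_pure_error=df_pe,
        f_lack_of_fit=float(f_lof),
        p_lack_of_fit=p_lof,
    )

    r2 = 1.0 - ss_residual / ss_total if ss_total > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else float("nan")
    mse = ss_residual / df_resid if df_resid > 0 else float("nan")
    pred_range = float(yhat.max() - yhat.min())
    avg_pred_sd = float(np.sqrt(p * mse / n)) if mse > 0 else 0.0
    adeq = pred_range / avg_pred_sd if avg_pred_sd > 0 else float("inf")
    cv_pct = 100.0 * float(np.sqrt(mse)) / float(y.mean()) if mse >= 0 else float("nan")

    return RSMFit(
        response_name=response_name,
        beta=beta,
        beta_coded=g,
        anova=anova,
        r2=float(r2),
        adj_r2=float(adj_r2),
        adeq_precision=float(adeq),
        cv_pct=float(cv_pct),
        n_obs=n,
        centers=centers,
        steps=steps,
        region=region,
        factor_names=design.factor_names if design is not None else ("TM", "BP"),
    )


def fit_summary(fits: list[RSMFit]) -> pd.DataFrame:
    """Coefficients and diagnostics, one row per fitted response."""
    rows = []
    for f in fits:
        row = {"response": f.response_name}
        for name, b_nat, b_cod in zip(TERM_NAMES, f.beta, f.beta_coded):
            row[f"beta[{name}]"] = b_nat
            row[f"beta_coded[{name}]"] = b_cod
        row.update(
            r2=f.r2,
            adj_r2=f.adj_r2,
            adeq_precision=f.adeq_precision,
            cv_pct=f.cv_pct,
            f_lack_of_fit=f.anova.f_lack_of_fit,
            p_lack_of_fit=f.anova.p_lack_of_fit,
        )
        rows.append(row)
    return pd.DataFrame(rows)
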