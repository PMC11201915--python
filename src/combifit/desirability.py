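"""Derringer-Suich desirability optimization over fitted response surfaces.

Each predicted response ``y`` is mapped to a dimensionless desirability
``d in [0, 1]`` by a piecewise power ramp.  For a *target* goal with lower
bound L, target T and upper bound U:

    d = ((y - L)/(T - L))**s   for L <= y <= T
    d = ((U - y)/(U - T))**t   for T <  y <= U
    d = 0                      outside [L, U]

(*maximize* and *minimize* goals use the corresponding one-sided ramps).
The overall desirability of a candidate setting is the geometric mean
``D = (d1 * d2 * ... * dn)**(1/n)``; D = 1 only when every response sits
exactly on its goal, and any fully undesirable response annihilates D.

The optimizer searches the concentration region with a dense grid pass,
polishes each grid-local optimum with Nelder-Mead, and -- when every goal
is a target goal -- refines the best candidates by solving the response
equations ``y_i(tm, bp) = T_i`` directly, so an attainable joint target is
hit to machine precision (D = 1 exactly).  Ties are broken toward the
lower total concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize as sp_optimize

from .errors import InputError
from .rsm import RSMFit, evaluate_quadratic

__all__ = [
    "DesirabilityGoal",
    "DesirabilitySolution",
    "desirability_score",
    "overall_desirability",
    "optimize",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response: target / maximize / minimize with bounds.

    For a *target* goal the acceptable band is [low, high] with the target
    strictly inside; *maximize* ramps up from low to high, *minimize* ramps
    down.  ``s`` and ``t`` are the ramp exponents (1 = linear).
    """

    response_name: str
    kind: str = "target"
    target: float | None = None
    low: float = 0.0
    high: float = 100.0
    s: float = 1.0
    t: float = 1.0

    def __post_init__(self):
        if self.kind not in ("target", "maximize", "minimize"):
            raise InputError(f"unknown goal kind {self.kind!r}")
        if self.s <= 0 or self.t <= 0:
            raise InputError("weights s, t must be positive")
        if not self.low < self.high:
            raise InputError("goal requires low < high")
        if self.kind == "target":
            if self.target is None:
                raise InputError("target goal requires a target value")
            if not self.low < self.target < self.high:
                raise InputError("target must lie strictly between low and high")


def desirability_score(y, goal: DesirabilityGoal):
    """Per-response desirability of predicted value(s) *y* under *goal*."""
    y = np.asarray(y, dtype=float)
    L, U = goal.low, goal.high
    if goal.kind == "target":
        T = goal.target
        # ramps may see negative bases outside [L, U]; those are masked below
        with np.errstate(invalid="ignore"):
            d = np.where(
                y <= T,
                np.clip((y - L) / (T - L), 0.0, None) ** goal.s,
                np.clip((U - y) / (U - T), 0.0, None) ** goal.t,
            )
        d = np.where((y < L) | (y > U), 0.0, d)
    elif goal.kind == "maximize":
        d = np.clip((y - L) / (U - L), 0.0, 1.0) ** goal.s
    else:  # minimize
        d = np.clip((U - y) / (U - L), 0.0, 1.0) ** goal.t
    d = np.clip(d, 0.0, 1.0)
    return float(d) if d.ndim == 0 else d


def overall_desirability(d_values) -> float | np.ndarray:
    """Geometric mean of per-response desirabilities.

    Computed in log space for numerical symmetry; exact zeros propagate
    (any fully undesirable response gives D = 0).
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0 or d.shape[0] == 0:
        raise InputError("need at least one desirability value")
    if np.any((d < 0) | (d > 1)):
        raise InputError("desirability values must lie in [0, 1]")
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        out = np.exp(np.mean(np.log(d), axis=0))
    out = np.where(np.any(d == 0.0, axis=0), 0.0, out) if d.ndim > 1 else (
        0.0 if np.any(d == 0.0) else out
    )
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DesirabilitySolution:
    """A ranked candidate combination with its desirability breakdown."""

    rank: int
    tm: float
    bp: float
    predicted: dict[str, float]
    d_i: dict[str, float]
    D: float


def default_goals_from_fits(
    fits: list[RSMFit],
    target: float = 50.0,
    region=None,
    n_grid: int = 201,
) -> list[DesirabilityGoal]:
    """Target goals with data-driven bounds.

    L and U default to the min/max predicted response over the region for
    each fit (the convention of DOE optimization software when the analyst
    supplies only a target); the target is the viability at the EC50, 50%.
    """
    goals = []
    for fit in fits:
        (tlo, thi), (blo, bhi) = region if region is not None else fit.region
        tm_g, bp_g = np.meshgrid(
            np.linspace(tlo, thi, n_grid), np.linspace(blo, bhi, n_grid)
        )
        y = evaluate_quadratic(fit.beta, tm_g, bp_g)
        lo, hi = float(np.min(y)), float(np.max(y))
        if not lo < target < hi:
            # widen just enough for a valid band; optimizer will report d=0
            lo, hi = min(lo, target - 1.0), max(hi, target + 1.0)
        goals.append(
            DesirabilityGoal(
                response_name=fit.response_name,
                kind="target",
                target=target,
                low=lo,
                high=hi,
            )
        )
    return goals


def _evaluate_D(fits, goals, tm, bp):
    """Vectorized D over arrays of (tm, bp), no region checks."""
    ds = [
        desirability_score(evaluate_quadratic(fit.beta, tm, bp), goal)
        for fit, goal in zip(fits, goals)
    ]
    return overall_desirability(np.stack([np.asarray(d, dtype=float) for d in ds]))


def optimize(
    fits: list[RSMFit],
    goals: list[DesirabilityGoal],
    region=None,
    k: int = 5,
    n_grid: int = 201,
    dedup_frac: float = 0.005,
) -> list[DesirabilitySolution]:
    """Find the *k* best local optima of the overall desirability D.

    Search strategy: evaluate D on an ``n_grid x n_grid`` lattice over the
    concentration region, keep every grid-local maximum, polish each with
    bounded Nelder-Mead, then (for all-target goals) attempt an exact joint
    target solve from the best candidates.  Results are deduplicated at
    *dedup_frac* of the region span per axis and ranked by D descending,
    ties broken toward the lower total concentration (pharmacological
    parsimony and deterministic output).
    """
    if len(fits) != len(goals):
        raise InputError("need exactly one goal per fitted response")
    if region is None:
        region = fits[0].region
    (tlo, thi), (blo, bhi) = region

    tm_ax = np.linspace(tlo, thi, n_grid)
    bp_ax = np.linspace(blo, bhi, n_grid)
    tm_g, bp_g = np.meshgrid(tm_ax, bp_ax, indexing="ij")
    D_grid = _evaluate_D(fits, goals, tm_g, bp_g)

    if float(np.max(D_grid)) == 0.0:
        warnings.warn(
            "overall desirability is zero everywhere in the region; "
            "no acceptable combination exists under these goals",
            stacklevel=2,
        )
        return []

    local_max = (D_grid == ndimage.maximum_filter(D_grid, size=3)) & (D_grid > 0)
    idx = np.argwhere(local_max)
    order = np.argsort(D_grid[local_max])[::-1][:30]
    seeds = [(tm_g[i, j], bp_g[i, j]) for i, j in idx[order]]

    def neg_D(xy):
        return -_evaluate_D(fits, goals, np.array(xy[0]), np.array(xy[1]))

    candidates = []
    for tm0, bp0 in seeds:
        res = sp_optimize.minimize(
            neg_D,
            x0=[tm0, bp0],
            method="Nelder-Mead",
            bounds=[(tlo, thi), (blo, bhi)],
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        tm1, bp1 = float(res.x[0]), float(res.x[1])
        candidates.append((tm1, bp1, float(-res.fun)))

    # Exact joint-target refinement: if every goal is a target goal the
    # optimum D = 1 lies where all responses equal their targets; solve
    # that square system directly from the best polished points.
    if all(g.kind == "target" for g in goals) and len(fits) == 2:
        targets = np.array([g.target for g in goals])

        def residual(xy):
            return np.array(
                [
                    evaluate_quadratic(fit.beta, xy[0], xy[1]) - t
                    for fit, t in zip(fits, targets)
                ]
            )

        for tm0, bp0, D0 in sorted(candidates, key=lambda c: -c[2])[:5]:
            sol, info, ier, _ = sp_optimize.fsolve(
                residual, x0=[tm0, bp0], full_output=True, xtol=1e-13
            )
            if ier != 1:
                continue
            tm1, bp1 = float(sol[0]), float(sol[1])
            if tlo <= tm1 <= thi and blo <= bp1 <= bhi:
                D1 = float(_evaluate_D(fits, goals, np.array(tm1), np.array(bp1)))
                if D1 >= D0:
                    candidates.append((tm1, bp1, D1))

    # Deduplicate at dedup_frac of the span; ties go to lower TM + BP.
    tol_tm = dedup_frac * (thi - tlo)
    tol_bp = dedup_frac * (bhi - blo)
    candidates.sort(key=lambda c: (-round(c[2], 12), c[0] + c[1]))
    kept: list[tuple[float, float, float]] = []
    for tm1, bp1, D1 in candidates:
        if any(abs(tm1 - t) <= tol_tm and abs(bp1 - b) <= tol_bp for t, b, _ in kept):
            continue
        kept.append((tm1, bp1, D1))
        if len(kept) >= k:
            break

    solutions = []
    for rank, (tm1, bp1, _) in enumerate(kept, start=1):
        predicted = {
            fit.response_name: float(evaluate_quadratic(fit.beta, tm1, bp1))
            for fit in fits
        }
        d_i = {
            fit.response_name: float(
                desirability_score(predicted[fit.response_name], goal)
            )
            for fit, goal in zip(fits, goals)
        }
        D = overall_desirability(list(d_i.values()))
        solutions.append(
            DesirabilitySolution(rank=rank, tm=tm1, bp=bp1, predicted=predicted, d_i=d_i, D=D)
        )
    return solutions


def solutions_table(solutions: list[DesirabilitySolution]) -> pd.DataFrame:
    """Ranked-solutions table mirroring the published validation layout."""
    rows = []
    for s in solutions:
        row = {"rank": s.rank, "desirability": s.D, "tm_ug_ml": s.tm, "bp_ug_ml": s.bp}
        for name, val in s.predicted.items():
            row[f"pred_{name}_pct"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_cv(a: float, b: float) -> float:
    """Coefficient of variation (%) of a predicted/observed value pair.

    ``100 * SD / mean`` with the sample SD (ddof=1) of the two values; the
    agreement metric used to validate predicted against experimental
    viabilities.
    """
    arr = np.array([a, b], dtype=float)
    m = arr.mean()
    if m == 0:
        raise InputError("pairwise CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / m)
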