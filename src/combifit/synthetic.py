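"""Synthetic assay-data generator.

Emulates the three kinds of raw data the analysis chain consumes, with the
statistical structure the downstream estimators assume:

* single-agent neutral-red viability curves following the median-effect
  equation ``fa = (D/Dm)^m / (1 + (D/Dm)^m)``, with a cytotoxic turmeric
  extract (TM) on two lung-cancer lines (EC50 77.8 and 92.0 ug/mL), a
  resistant normal fibroblast line, and a near-flat black-pepper extract
  (BP) curve (<= ~8% effect at the highest tested concentration);
* a ground-truth quadratic combination-response surface over the CCD
  region (TM 10-50, BP 200-400 ug/mL), anchored so both cell-line
  responses cross 50% viability at the same interior point
  (48.5, 241.7 ug/mL) -- the configuration the desirability workflow is
  designed to find;
* linear-in-time curcumin decay signals with and without cells (blank).

Replicate noise is multiplicative Gaussian on the mean (assay CVs scale
with signal); viability is clipped to [0, 120] to mimic plate-reader
behaviour.  All generators are deterministic functions of the config seed:
each output table draws from its own substream keyed by the table's labels,
so regenerating any one table in isolation reproduces it bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .rsm import CCDDesign, evaluate_quadratic

__all__ = [
    "CellLineParams",
    "DecayProfile",
    "GeneratorConfig",
    "generate_single_agent_table",
    "generate_ccd_response_table",
    "generate_time_course",
]

# Molar mass of curcumin (g/mol) and its content in the turmeric extract
# (ug curcumin per mg extract, from the component analysis of the extract).
CURCUMIN_MW = 368.38
CURCUMIN_CONTENT_UG_PER_MG = 26.7

#: TM concentration (ug/mL) of the optimal combination; anchor of the
#: ground-truth surfaces and basis of the kinetics dosing.
OPTIMUM_TM = 48.5
#: BP concentration (ug/mL) of the optimal combination.
OPTIMUM_BP = 241.7

#: Initial curcumin amount per mL of dosing medium at the optimal TM dose.
CURCUMIN_MASS_UG_PER_ML = OPTIMUM_TM * CURCUMIN_CONTENT_UG_PER_MG / 1000.0
CURCUMIN_N0_NMOL_PER_ML = CURCUMIN_MASS_UG_PER_ML / CURCUMIN_MW * 1000.0

#: Default single-agent dose panels (ug/mL).
TM_DOSES = (10.0, 25.0, 50.0, 75.0, 100.0, 150.0)
BP_DOSES = (50.0, 100.0, 200.0, 300.0, 400.0)

#: Default time-course sampling times (h).
TIME_POINTS = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class CellLineParams:
    """Median-effect ground truth for one cell line: slope m and Dm (ug/mL)."""

    name: str
    m: float
    dm: float


@dataclass(frozen=True)
class DecayProfile:
    """Linear decay of the curcumin signal: value(t) = initial - slope * t."""

    initial_nmol: float
    slope_nmol_per_h: float


def _anchored_surface(b1, b2, b11, b22, b12, anchor=(OPTIMUM_TM, OPTIMUM_BP), value=50.0):
    """Quadratic coefficients whose surface passes exactly through *value* at *anchor*."""
    tm, bp = anchor
    b0 = value - (b1 * tm + b2 * bp + b11 * tm * tm + b22 * bp * bp + b12 * tm * bp)
    return (b0, b1, b2, b11, b22, b12)


def _default_cell_lines():
    # TM slopes are a free choice (the assays report mean +/- SD only);
    # m = 2 gives curves of typical steepness for crude-extract cytotoxicity.
    # The normal fibroblast line only responds near the top tested dose.
    return (
        CellLineParams("A549", m=2.0, dm=77.8),
        CellLineParams("NCI-H292", m=2.0, dm=92.0),
        CellLineParams("MRC-5", m=4.0, dm=250.0),
    )


def _default_surfaces():
    # Viability decreases in both concentrations with a synergistic
    # (negative) interaction; both surfaces cross 50% at the anchor point.
    # The A549 response is driven mainly by TM with accelerating potency
    # (negative TM curvature: steepest near the anchor), the NCI-H292
    # response mainly by the BP-potentiation axis.  The two 50%-viability
    # contours therefore cross transversally and only once inside the
    # design region, keeping the joint-target point well identified when
    # the surfaces are re-fitted from noisy runs.
    return {
        "A549": _anchored_surface(-0.35, -0.012, -0.012, -1.0e-5, -0.0008),
        "NCI-H292": _anchored_surface(-0.06, -0.13, -0.0006, -1.2e-4, -0.0004),
    }


def _default_decay():
    # Fractional decay rates per hour: abiotic blank 0.5%/h; cells consume
    # curcumin faster alone (5.5%/h) than under the BP combination
    # (2.65%/h), reproducing the slowed-consumption ordering.
    n0 = CURCUMIN_N0_NMOL_PER_ML
    return {
        "bTM": DecayProfile(n0, 0.005 * n0),
        "TM": DecayProfile(n0, 0.055 * n0),
        "TMBP": DecayProfile(n0, 0.0265 * n0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and noise model for all synthetic tables.

    Attributes
    ----------
    seed
        Master RNG seed; the same seed yields bit-identical tables.
    cell_lines
        Median-effect parameters of the TM response per cell line.
    bp_max_effect
        Fraction affected by BP at 400 ug/mL (linear in dose below that);
        kept small because BP is essentially non-toxic alone.
    surface_coeffs
        Ground-truth quadratic combination surface per response, ordered
        ``(b0, b1, b2, b11, b22, b12)`` in natural (ug/mL) units.
    noise_cv
        Coefficient of variation of multiplicative replicate noise.
    decay
        Linear time-course decay per condition (bTM / TM / TMBP).
    replicates
        Replicates per condition (>= 1; assays are typically run in 3).
    """

    seed: int = 0
    cell_lines: tuple[CellLineParams, ...] = field(default_factory=_default_cell_lines)
    bp_max_effect: float = 0.08
    surface_coeffs: dict[str, tuple] = field(default_factory=_default_surfaces)
    noise_cv: float = 0.05
    decay: dict[str, DecayProfile] = field(default_factory=_default_decay)
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        if not 0.0 <= self.bp_max_effect <= 0.5:
            raise InputError("bp_max_effect must be a small fraction in [0, 0.5]")
        for cl in self.cell_lines:
            if cl.m <= 0 or cl.dm <= 0:
                raise InputError(f"cell line {cl.name}: m and Dm must be positive")

    def cell_line(self, name: str) -> CellLineParams:
        for cl in self.cell_lines:
            if cl.name == name:
                return cl
        raise InputError(f"unknown cell line {name!r}")


def _rng(config: GeneratorConfig, *labels: str) -> np.random.Generator:
    """Substream keyed by stable hashes of the table labels."""
    keys = [zlib.crc32(lbl.encode()) for lbl in labels]
    return np.random.default_rng([int(config.seed)] + keys)


def median_effect_fa(dose, m: float, dm: float):
    """Ground-truth fraction affected ``(D/Dm)^m / (1 + (D/Dm)^m)``."""
    r = (np.asarray(dose, dtype=float) / dm) ** m
    return r / (1.0 + r)


def _apply_noise(mean: np.ndarray, n_rep: int, cv: float, rng, lo=0.0, hi=120.0):
    """Replicate rows as mean * (1 + eps), eps ~ N(0, cv), clipped to [lo, hi]."""
    eps = rng.normal(0.0, cv, size=(n_rep, mean.size)) if cv > 0 else np.zeros(
        (n_rep, mean.size)
    )
    vals = mean[None, :] * (1.0 + eps)
    return np.clip(vals, lo, hi)


def generate_single_agent_table(
    config: GeneratorConfig,
    agent: str,
    cell_line: str,
    doses=None,
) -> pd.DataFrame:
    """Generate a replicated single-agent viability table.

    Mean viability is ``100 * (1 - fa(D))`` with ``fa`` from the
    median-effect equation for TM, or a small linear-in-dose effect for BP.
    Columns: ``agent, cell_line, concentration_ug_ml, replicate,
    viability_pct``.
    """
    if doses is None:
        doses = TM_DOSES if agent == "TM" else BP_DOSES
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses <= 0):
        raise InputError("doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise InputError("doses must be strictly increasing")

    if agent == "BP":
        fa = config.bp_max_effect * doses / 400.0
    else:
        cl = config.cell_line(cell_line)
        fa = median_effect_fa(doses, cl.m, cl.dm)
    mean_viab = 100.0 * (1.0 - fa)

    rng = _rng(config, "single_agent", agent, cell_line)
    vals = _apply_noise(mean_viab, config.replicates, config.noise_cv, rng)
    rows = []
    for rep in range(config.replicates):
        for d, v in zip(doses, vals[rep]):
            rows.append((agent, cell_line, d, rep + 1, v))
    return pd.DataFrame(
        rows,
        columns=["agent", "cell_line", "concentration_ug_ml", "replicate", "viability_pct"],
    )


def generate_ccd_response_table(config: GeneratorConfig, design: CCDDesign) -> pd.DataFrame:
    """Generate replicated combination responses on the ground-truth surfaces.

    Each design run is measured ``config.replicates`` times (assays are run
    in triplicate); center-run and within-run replicates together provide
    the pure-error degrees of freedom.  Columns: ``cell_line, run,
    tm_ug_ml, bp_ug_ml, replicate, viability_pct``.
    """
    rows = []
    for response, beta in config.surface_coeffs.items():
        mean = evaluate_quadratic(beta, design.natural[:, 0], design.natural[:, 1])
        mean = np.asarray(mean, dtype=float)
        rng = _rng(config, "ccd", response)
        vals = _apply_noise(mean, config.replicates, config.noise_cv, rng)
        for rep in range(config.replicates):
            for run, (tm, bp), v in zip(
                range(1, design.n_runs + 1), design.natural, vals[rep]
            ):
                rows.append((response, run, tm, bp, rep + 1, v))
    return pd.DataFrame(
        rows,
        columns=["cell_line", "run", "tm_ug_ml", "bp_ug_ml", "replicate", "viability_pct"],
    )


def generate_combination_table(
    config: GeneratorConfig, points, cell_line: str
) -> pd.DataFrame:
    """Replicated viability measurements at arbitrary (TM, BP) points.

    Used for the synergy experiment at and around the selected optimum.
    Columns match the single-agent dialect with two concentration columns:
    ``cell_line, tm_ug_ml, bp_ug_ml, replicate, viability_pct``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    beta = config.surface_coeffs[cell_line]
    mean = np.asarray(
        evaluate_quadratic(beta, pts[:, 0], pts[:, 1]), dtype=float
    ).reshape(-1)
    rng = _rng(config, "combination", cell_line)
    vals = _apply_noise(mean, config.replicates, config.noise_cv, rng)
    rows = []
    for rep in range(config.replicates):
        for (tm, bp), v in zip(pts, vals[rep]):
            rows.append((cell_line, tm, bp, rep + 1, v))
    return pd.DataFrame(
        rows, columns=["cell_line", "tm_ug_ml", "bp_ug_ml", "replicate", "viability_pct"]
    )


def generate_time_course(
    config: GeneratorConfig, condition: str, times=None
) -> pd.DataFrame:
    """Generate a replicated linear decay time course for one condition.

    ``concentration(t) = initial - slope * t`` with multiplicative replicate
    noise, floored at 0.  Columns: ``condition, time_h,
    concentration_nmol_ml, replicate``.
    """
    if times is None:
        times = TIME_POINTS
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InputError("times must be non-empty")
    if np.any(times < 0):
        raise InputError("times must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    if condition not in config.decay:
        raise InputError(f"no decay profile for condition {condition!r}")

    prof = config.decay[condition]
    mean = prof.initial_nmol - prof.slope_nmol_per_h * times
    rng = _rng(config, "time_course", condition)
    vals = _apply_noise(mean, config.replicates, config.noise_cv, rng, lo=0.0, hi=np.inf)
    rows = []
    for rep in range(config.replicates):
        for t, c in zip(times, vals[rep]):
            rows.append((condition, t, c, rep + 1))
    return pd.DataFrame(
        rows, columns=["condition", "time_h", "concentration_nmol_ml", "replicate"]
    )
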