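"""End-to-end orchestration of the combination-modelling chain.

``run_pipeline`` executes the full study workflow: (synthetic) data
generation -> single-agent median-effect fits -> CCD construction and
quadratic surface fits -> desirability optimization of the combination ->
combination-index scoring at the tested combinations -> consumption
kinetics.  Every stage writes a CSV whose first line records the seed and
config hash, and a run manifest records versions and per-file checksums,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputError
from . import dose_response as dr
from . import desirability as ds
from . import kinetics as kin
from . import rsm
from . import synergy
from . import synthetic as syn

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

#: The five uniformly spaced concentration levels per factor (ug/mL).
TM_LEVELS = (10.0, 20.0, 30.0, 40.0, 50.0)
BP_LEVELS = (200.0, 250.0, 300.0, 350.0, 400.0)

#: Combinations tested alongside the optimum: fixed TM with varying BP.
PREVIOUS_COMBINATIONS = ((50.0, 250.0), (50.0, 300.0), (50.0, 350.0), (50.0, 400.0))

CANCER_LINES = ("A549", "NCI-H292")
TIME_COURSE_CONDITIONS = ("bTM", "TM", "TMBP")


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    With all input paths ``None`` the pipeline runs in synthetic mode and
    generates its own data from *seed*.  Paths, when given, must exist.
    """

    seed: int = 0
    out_dir: str = "combifit_out"
    single_agent_csv: str | None = None
    ccd_csv: str | None = None
    combination_csv: str | None = None
    timecourse_csv: str | None = None
    target_viability: float = 50.0
    n_solutions: int = 5
    ci_tol: float = synergy.ADDITIVITY_TOL
    noise_cv: float = 0.05
    replicates: int = 3
    plot: bool = False

    @property
    def synthetic(self) -> bool:
        return all(
            p is None
            for p in (
                self.single_agent_csv,
                self.ccd_csv,
                self.combination_csv,
                self.timecourse_csv,
            )
        )

    def validate(self) -> None:
        for name in ("single_agent_csv", "ccd_csv", "combination_csv", "timecourse_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"{name}: file not found: {p}")
        if not self.synthetic:
            missing = [
                n
                for n in ("single_agent_csv", "ccd_csv", "combination_csv", "timecourse_csv")
                if getattr(self, n) is None
            ]
            if missing:
                raise InputError(
                    f"mixed input mode: provide all input CSVs or none; missing {missing}"
                )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs land and
        whether figures are drawn do not affect the computed results)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload.pop("plot")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """Objects and file paths produced by a pipeline run."""

    config: PipelineConfig
    out_dir: Path
    dose_fits: dict[tuple[str, str], dr.MedianEffectFit]
    rsm_fits: dict[str, rsm.RSMFit]
    solutions: list[ds.DesirabilitySolution]
    ci_results: dict[str, list[synergy.CIResult]]
    consumption: dict[str, kin.ConsumptionResult]
    activities: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def optimum(self) -> ds.DesirabilitySolution | None:
        return self.solutions[0] if self.solutions else None


def _write_csv(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# combifit v{__version__} seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_stage_csv(path: str | Path) -> pd.DataFrame:
    """Read a stage CSV, skipping the seed/config header comment."""
    return pd.read_csv(path, comment="#")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage and write the report bundle to *out_dir*."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    files: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        _write_csv(df, path, config.seed, chash)
        files[name] = path

    gen = syn.GeneratorConfig(
        seed=config.seed, noise_cv=config.noise_cv, replicates=config.replicates
    )
    design = rsm.build_ccd(TM_LEVELS, BP_LEVELS, n_center=6)

    # -- stage 1: inputs -------------------------------------------------
    try:
        if config.synthetic:
            single = pd.concat(
                [
                    syn.generate_single_agent_table(gen, agent, line)
                    for agent in ("TM", "BP")
                    for line in ("A549", "NCI-H292", "MRC-5")
                ],
                ignore_index=True,
            )
            ccd_table = syn.generate_ccd_response_table(gen, design)
            timecourse = pd.concat(
                [
                    syn.generate_time_course(gen, cond)
                    for cond in TIME_COURSE_CONDITIONS
                ],
                ignore_index=True,
            )
        else:
            single = read_stage_csv(config.single_agent_csv)
            ccd_table = read_stage_csv(config.ccd_csv)
            timecourse = read_stage_csv(config.timecourse_csv)
        save("single_agent", single)
        save("ccd_responses", ccd_table)
        save("time_course", timecourse)
        save("design", design.to_frame())
    except Exception as exc:
        raise type(exc)(f"[stage: inputs] {exc}") from exc

    # -- stage 2: single-agent median-effect fits ------------------------
    try:
        dose_fits: dict[tuple[str, str], dr.MedianEffectFit] = {}
        for agent in sorted(single["agent"].unique()):
            for line in sorted(single[single["agent"] == agent]["cell_line"].unique()):
                try:
                    fit = dr.fit_median_effect(single, agent=agent, cell_line=line)
                except dr.FitError:
                    if agent == "TM" and line in CANCER_LINES:
                        raise  # the primary agent must have a dose-response
                    # effectively flat curve: record an unusable fit
                    fit = dr.MedianEffectFit(
                        m=float("nan"), dm=float("nan"), r2=float("nan"),
                        n_points=0, usable=False, agent=agent, cell_line=line,
                    )
                dose_fits[(agent, line)] = fit
        save("dose_response_fits", dr.fit_summary(list(dose_fits.values())))
    except Exception as exc:
        raise type(exc)(f"[stage: fit-dose] {exc}") from exc

    # -- stage 3: response-surface fits ----------------------------------
    try:
        responses = sorted(ccd_table["cell_line"].unique())
        rsm_fits = {
            name: rsm.fit_quadratic(ccd_table, design, cell_line=name)
            for name in responses
        }
        save("rsm_fits", rsm.fit_summary(list(rsm_fits.values())))
    except Exception as exc:
        raise type(exc)(f"[stage: fit-rsm] {exc}") from exc

    # -- stage 4: desirability optimization ------------------------------
    try:
        fits = [rsm_fits[name] for name in responses]
        goals = ds.default_goals_from_fits(fits, target=config.target_viability)
        solutions = ds.optimize(fits, goals, k=config.n_solutions)
        save("desirability_solutions", ds.solutions_table(solutions))
    except Exception as exc:
        raise type(exc)(f"[stage: optimize] {exc}") from exc

    # -- stage 5: combination index at the tested combinations ----------
    try:
        if config.synthetic:
            points = list(PREVIOUS_COMBINATIONS)
            if solutions:
                points.append((solutions[0].tm, solutions[0].bp))
            combo = pd.concat(
                [
                    syn.generate_combination_table(gen, points, line)
                    for line in CANCER_LINES
                    if line in gen.surface_coeffs
                ],
                ignore_index=True,
            )
        else:
            combo = read_stage_csv(config.combination_csv)
        save("combination_viability", combo)

        ci_results: dict[str, list[synergy.CIResult]] = {}
        ci_frames = []
        for line in sorted(combo["cell_line"].unique()):
            fit_tm = dose_fits[("TM", line)]
            fit_bp = dose_fits.get(("BP", line))
            bp_table = single[(single["agent"] == "BP") & (single["cell_line"] == line)]
            nontoxic = fit_bp is None or synergy.is_nontoxic(
                fit_bp, bp_table if not bp_table.empty else None
            )
            sub = combo[combo["cell_line"] == line]
            means = (
                sub.groupby(["tm_ug_ml", "bp_ug_ml"], sort=True)["viability_pct"]
                .mean()
                .reset_index()
            )
            meas = [
                synergy.CombinationMeasurement(r.tm_ug_ml, r.bp_ug_ml, r.viability_pct)
                for r in means.itertuples()
            ]
            results = synergy.ci_fa_curve(
                meas, fit_tm, fit_bp, partner_nontoxic=nontoxic, tol=config.ci_tol
            )
            ci_results[line] = results
            frame = synergy.ci_table(results)
            frame.insert(0, "cell_line", line)
            ci_frames.append(frame)
        save("combination_index", pd.concat(ci_frames, ignore_index=True))
    except Exception as exc:
        raise type(exc)(f"[stage: ci] {exc}") from exc

    # -- stage 6: consumption kinetics -----------------------------------
    try:
        n0 = syn.CURCUMIN_N0_NMOL_PER_ML
        cc_mass = syn.CURCUMIN_MASS_UG_PER_ML
        consumption = {
            cond: kin.consumption_rate(
                timecourse[timecourse["condition"] == cond], n0=n0
            )
            for cond in sorted(timecourse["condition"].unique())
        }
        activities = kin.activity_table(consumption, "bTM", cc_mass)
        save("consumption_kinetics", activities)
    except Exception as exc:
        raise type(exc)(f"[stage: kinetics] {exc}") from exc

    if config.plot:
        try:
            from . import plots

            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            plots.dose_response_plot(single, plot_dir / "dose_response.png")
            plots.surface_plot(fits, plot_dir / "response_surfaces.png")
            all_ci = [r for rs in ci_results.values() for r in rs]
            plots.ci_fa_plot(all_ci, plot_dir / "ci_fa.png")
            plots.time_course_plot(timecourse, plot_dir / "time_course.png")
        except Exception as exc:
            raise type(exc)(f"[stage: plots] {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": chash,
        "versions": {
            "combifit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path

    return PipelineResult(
        config=config,
        out_dir=out,
        dose_fits=dose_fits,
        rsm_fits=rsm_fits,
        solutions=solutions,
        ci_results=ci_results,
        consumption=consumption,
        activities=activities,
        files=files,
        manifest=manifest,
    )
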