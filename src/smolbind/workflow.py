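"""Configuration, orchestration and reporting.

A single YAML file drives every analysis. :func:`validate_config` parses
it against a strict schema (unknown keys rejected, defaults filled);
:func:`run_pipeline` dispatches to the analysis modules in a fixed order
with all randomness derived from the single top-level seed, and writes
machine-readable tables plus a JSON report. Identical (config, inputs)
give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import afm as afm_mod
from . import binding as bind_mod
from . import tirfm as tirfm_mod
from ._errors import ConfigError, InputError
from ._util import derive_seed
from .simulate import (
    BindingSimConfig,
    ForceConfig,
    MovieConfig,
    read_movie_tiff,
    simulate_binding_series,
    simulate_force_curves,
    simulate_photobleach_trace,
    simulate_tirfm_movie,
    write_movie_tiff,
)
from .stepfit import StepModel

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class TirfmSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: condition label -> list of TIFF stack paths (one stack per cell)
    stacks: dict[str, list[str]]
    frame_interval: float = Field(0.1, gt=0)
    k_frames: int = Field(10, ge=1)
    threshold_sd: float = Field(5.0, gt=0)
    smooth_sigma: float = Field(1.0, ge=0)
    min_separation: float = Field(5.0, gt=0)
    penalty_mult: float = Field(2.0, gt=0)
    min_step_sd: float = Field(3.0, gt=0)
    zero_tol_sd: float = Field(2.0, gt=0)
    dim_sd: float = Field(4.0, gt=0)
    min_size: int = Field(2, ge=1)
    max_steps: int = Field(5, ge=1)


class AfmSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: CSV with columns file, condition, experiment
    manifest: str
    spring_constant: Optional[float] = Field(None, gt=0)
    n_sigma: float = Field(4.0, gt=0)
    d_min: float = Field(10.0, ge=0)
    median_kernel: int = Field(5, ge=1)
    gap: int = Field(3, ge=1)
    min_curves_per_experiment: int = Field(50, ge=1)
    probability_alternative: Literal["two-sided", "greater", "less"] = "greater"


class BindSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["steady_state", "competition"]
    input: str  # CSV: concentration, response
    free_slope: bool = False


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    modality: Literal["movie", "traces", "forces", "binding"]
    n_traces: int = Field(100, ge=1)  # traces modality
    #: passed through to the matching generator config (seed filled in)
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated top-level run configuration."""

    model_config = ConfigDict(extra="forbid")

    analysis: Literal["tirfm", "afm", "bind", "simulate"]
    seed: int
    out_dir: str = "smolbind_out"
    tirfm: Optional[TirfmSection] = None
    afm: Optional[AfmSection] = None
    bind: Optional[BindSection] = None
    simulate: Optional[SimulateSection] = None

    def section(self):
        sec = getattr(self, self.analysis)
        if sec is None:
            raise ConfigError(f"config lacks the {self.analysis!r} section")
        return sec

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    analysis: str
    seed: int
    config_hash: str
    version: str
    results: dict
    warnings: list = dc_field(default_factory=list)
    outputs: list = dc_field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "analysis": self.analysis,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "results": self.results,
            "warnings": self.warnings,
            "outputs": [str(o) for o in self.outputs],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected (named in the error); defaults are filled;
    referenced input paths must exist.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from exc

    sec = cfg.section()
    missing = []
    if cfg.analysis == "tirfm":
        for paths in sec.stacks.values():
            missing += [s for s in paths if not Path(s).exists()]
    elif cfg.analysis == "afm":
        if not Path(sec.manifest).exists():
            missing.append(sec.manifest)
    elif cfg.analysis == "bind":
        if not Path(sec.input).exists():
            missing.append(sec.input)
    if missing:
        raise ConfigError(f"referenced input paths do not exist: {missing}")
    return cfg


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------

def _run_tirfm(cfg: RunConfig, out: Path, report: RunReport) -> None:
    sec: TirfmSection = cfg.tirfm  # type: ignore[assignment]
    det = tirfm_mod.DetectionParams(
        k_frames=sec.k_frames, threshold_sd=sec.threshold_sd,
        smooth_sigma=sec.smooth_sigma, min_separation=sec.min_separation,
    )
    step_kw = dict(
        penalty_mult=sec.penalty_mult, min_step_sd=sec.min_step_sd,
        zero_tol_sd=sec.zero_tol_sd, dim_sd=sec.dim_sd,
        min_size=sec.min_size, max_steps=sec.max_steps,
    )
    spot_rows, tallies = [], []
    for condition, stack_paths in sec.stacks.items():
        for cell_idx, spath in enumerate(stack_paths):
            stack = read_movie_tiff(spath)
            spots = tirfm_mod.detect_spots(stack, det)
            classes = []
            for spot_idx, spot in enumerate(spots):
                trace = tirfm_mod.extract_trace(stack, spot, sec.frame_interval)
                fit = StepModel(trace, **step_kw).fit()
                cls = tirfm_mod.classify_stoichiometry(fit)
                classes.append(cls)
                spot_rows.append(
                    {
                        "condition": condition, "cell": cell_idx,
                        "spot": spot_idx, "row": spot.row, "col": spot.col,
                        "n_steps": fit.n_steps, "accepted": fit.accepted,
                        "rejection_reason": fit.rejection_reason,
                        "classification": cls,
                    }
                )
            try:
                tally = tirfm_mod.tally_stoichiometry(classes, condition)
                tallies.append(tally)
            except InputError as exc:
                report.warnings.append(
                    f"{condition}/cell{cell_idx}: {exc}"
                )
    spot_df = pd.DataFrame(spot_rows)
    spot_df.to_csv(out / "spots.csv", index=False)
    tally_df = pd.concat([t.to_frame() for t in tallies], ignore_index=True)
    tally_df.to_csv(out / "tallies.csv", index=False)
    report.outputs += [out / "spots.csv", out / "tallies.csv"]
    report.results["tallies"] = tally_df.to_dict(orient="records")

    by_cond: dict[str, list[float]] = {}
    for t in tallies:
        by_cond.setdefault(t.condition, []).append(t.pct_two)
    if len(by_cond) >= 2 and all(len(v) >= 2 for v in by_cond.values()):
        comp = tirfm_mod.compare_dimer_fractions(by_cond)
        (out / "statistics.txt").write_text(comp.summary() + "\n")
        report.outputs.append(out / "statistics.txt")
        report.results["anova"] = {
            "F": comp.f_statistic, "p": comp.pvalue,
            "pairwise": comp.comparisons.to_dict(orient="records"),
        }


def _run_afm(cfg: RunConfig, out: Path, report: RunReport) -> None:
    sec: AfmSection = cfg.afm  # type: ignore[assignment]
    manifest = pd.read_csv(sec.manifest)
    for col in ("file", "condition", "experiment"):
        if col not in manifest.columns:
            raise InputError(f"manifest lacks column {col!r}")
    params = afm_mod.RuptureParams(
        n_sigma=sec.n_sigma, d_min=sec.d_min,
        median_kernel=sec.median_kernel, gap=sec.gap,
    )
    base = Path(sec.manifest).parent
    event_rows = []
    forces: dict[str, list[float]] = {}
    flags: dict[str, dict[str, list[bool]]] = {}
    for rec in manifest.itertuples(index=False):
        fpath = Path(rec.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        for curve in afm_mod.read_force_curves(fpath, sec.spring_constant):
            curve.condition = str(rec.condition)
            corrected = afm_mod.correct_baseline(curve)
            events = afm_mod.detect_ruptures(corrected, params)
            has_specific = any(e.specific for e in events)
            flags.setdefault(str(rec.condition), {}).setdefault(
                str(rec.experiment), []
            ).append(has_specific)
            for e in events:
                event_rows.append(
                    {
                        "condition": rec.condition, "experiment": rec.experiment,
                        "curve_id": curve.curve_id, "force_pN": e.force,
                        "separation_nm": e.separation,
                        "distance_from_contact_nm": e.distance_from_contact,
                        "specific": e.specific,
                    }
                )
                if e.specific:
                    forces.setdefault(str(rec.condition), []).append(e.force)
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    report.outputs.append(out / "events.csv")

    prob_rows, hist_results = [], {}
    probabilities = {}
    for condition, per_exp in flags.items():
        bp = afm_mod.binding_probability(
            per_exp, condition, min_curves=sec.min_curves_per_experiment
        )
        probabilities[condition] = bp
        prob_rows += bp.per_experiment.assign(condition=condition).to_dict(
            orient="records"
        )
        if not bp.single_molecule_regime:
            report.warnings.append(
                f"{condition}: binding probability {bp.probability:.1f}% >= 30%; "
                "single-molecule regime not guaranteed"
            )
        cond_forces = forces.get(condition, [])
        if len(cond_forces) >= 30:
            hfit = afm_mod.fit_force_histogram(cond_forces)
            hist_results[condition] = {
                "peak_pN": hfit.peak, "sd_pN": hfit.sd,
                "n_forces": hfit.n_forces, "r2": hfit.goodness,
                "good_fit": hfit.good_fit,
            }
            if not hfit.good_fit:
                report.warnings.append(
                    f"{condition}: rupture-force histogram poorly described "
                    "by a single Gaussian"
                )
        else:
            report.warnings.append(
                f"{condition}: only {len(cond_forces)} specific forces; "
                "histogram fit skipped"
            )
    pd.DataFrame(prob_rows).to_csv(out / "binding_probability.csv", index=False)
    report.outputs.append(out / "binding_probability.csv")
    report.results["binding_probability"] = {
        c: {"probability_pct": bp.probability, "sem_pct": bp.sem,
            "n_total": bp.n_total,
            "single_molecule_regime": bp.single_molecule_regime}
        for c, bp in probabilities.items()
    }
    report.results["force_histograms"] = hist_results

    conds = sorted(flags)
    if len(conds) == 2:
        a, b = conds
        tests = {}
        if len(forces.get(a, [])) >= 2 and len(forces.get(b, [])) >= 2:
            res_f = afm_mod.compare_forces(forces[a], forces[b], "two-sided")
            tests["forces"] = {"U": res_f.statistic, "p": res_f.pvalue,
                               "method": res_f.method}
        pa = probabilities[a].per_experiment["probability_pct"].tolist()
        pb = probabilities[b].per_experiment["probability_pct"].tolist()
        if len(pa) >= 2 and len(pb) >= 2:
            res_p = afm_mod.compare_forces(pa, pb, sec.probability_alternative)
            tests["binding_probability"] = {
                "U": res_p.statistic, "p": res_p.pvalue, "method": res_p.method,
                "alternative": sec.probability_alternative,
            }
        report.results["tests"] = tests


def _run_bind(cfg: RunConfig, out: Path, report: RunReport) -> None:
    sec: BindSection = cfg.bind  # type: ignore[assignment]
    df = pd.read_csv(sec.input)
    if sec.mode == "steady_state":
        res = bind_mod.SingleSiteBindingModel.from_dataframe(df).fit()
        report.results["fit"] = {
            "mode": "steady_state", "KD_uM": res.kd, "KD_se": res.kd_se,
            "Rmax": res.rmax, "Rmax_se": res.rmax_se, "rss": res.rss,
            "converged": res.converged, "saturated": res.saturated,
        }
    else:
        resp_col = "pct_specific" if "pct_specific" in df.columns else "response"
        res = bind_mod.CompetitionBindingModel.from_dataframe(
            df, resp=resp_col, free_slope=sec.free_slope
        ).fit()
        report.results["fit"] = {
            "mode": "competition", "logIC50": res.log_ic50,
            "logIC50_se": res.log_ic50_se, "hill_slope": res.hill_slope,
            "rss": res.rss, "converged": res.converged,
            "out_of_range": res.out_of_range,
            "no_dose_dependence": res.no_dose_dependence,
        }
        if res.no_dose_dependence:
            report.warnings.append("no detectable dose dependence")
    (out / "fit_summary.txt").write_text(res.summary() + "\n")
    report.outputs.append(out / "fit_summary.txt")


def _run_simulate(cfg: RunConfig, out: Path, report: RunReport) -> None:
    sec: SimulateSection = cfg.simulate  # type: ignore[assignment]
    seed = derive_seed(cfg.seed, 10)
    params = dict(sec.params)
    params.setdefault("seed", seed)
    if sec.modality == "movie":
        mcfg = MovieConfig(**params)
        stack, truth = simulate_tirfm_movie(mcfg)
        write_movie_tiff(out / "movie.tif", stack)
        truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
        report.outputs += [out / "movie.tif", out / "ground_truth.csv"]
        report.results["movie"] = {"n_spots": int(mcfg.n_spots),
                                   "n_frames": int(mcfg.n_frames)}
    elif sec.modality == "traces":
        mcfg = MovieConfig(**params)
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(sec.n_traces):
            k = int(rng.choice([1, 2, 3], p=mcfg.fractions))
            trace, bf = simulate_photobleach_trace(k, mcfg, rng)
            rows.append(
                {"trace": i, "n_fluorophores": k,
                 "bleach_frames": ";".join(map(str, bf.tolist())),
                 "values": ";".join(f"{v:.3f}" for v in trace.values)}
            )
        pd.DataFrame(rows).to_csv(out / "traces.csv", index=False)
        report.outputs.append(out / "traces.csv")
        report.results["traces"] = {"n_traces": sec.n_traces}
    elif sec.modality == "forces":
        fcfg = ForceConfig(**params)
        curves, truth = simulate_force_curves(fcfg)
        cdir = out / "curves"
        cdir.mkdir(exist_ok=True)
        manifest_rows = []
        for curve in curves:
            fname = cdir / f"{curve.curve_id}.txt"
            afm_mod.write_force_curve(fname, curve)
            manifest_rows.append(
                {"file": str(fname.relative_to(out)), "condition": "simulated",
                 "experiment": "sim"}
            )
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
        report.outputs += [out / "manifest.csv", out / "ground_truth.csv"]
        report.results["forces"] = {"n_curves": fcfg.n_curves}
    else:
        bcfg = BindingSimConfig(**params)
        series = simulate_binding_series(bcfg)
        series.to_frame().to_csv(out / "binding_series.csv", index=False)
        report.outputs.append(out / "binding_series.csv")
        report.results["binding"] = {"mode": bcfg.mode,
                                     "n_doses": int(series.concentrations.size)}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the configured analysis; write outputs and return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        analysis=config.analysis,
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        results={},
    )
    runner = {
        "tirfm": _run_tirfm, "afm": _run_afm,
        "bind": _run_bind, "simulate": _run_simulate,
    }[config.analysis]
    try:
        runner(config, out, report)
    except Exception as exc:
        logger.error("pipeline failed in %s stage: %s", config.analysis, exc)
        raise
    (out / "report.json").write_text(report.to_json() + "\n")
    report.outputs.append(out / "report.json")
    for w in report.warnings:
        logger.warning("%s", w)
    return report
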