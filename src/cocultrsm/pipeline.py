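"""End-to-end orchestration: design -> data -> fit -> ANOVA -> optimize.

A validated :class:`PipelineConfig` drives the whole workflow the study
followed: build (or read) a central composite design, simulate (or read)
response tables, fit each response by stepwise polynomial regression,
validate by ANOVA, locate the single-response optimum of the first
response, and run desirability-based multiresponse optimization across
all responses.  All artifacts are plain text (CSV / JSON) plus a short
human-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import synthetic
from .doe import (
    DesignTable,
    FactorSpec,
    generate_ccd,
    read_design,
    rotatable_alpha,
    write_design,
)
from .errors import CocultRsmError
from .models import (
    AnovaTable,
    PolynomialModel,
    anova,
    backward_eliminate,
    build_terms,
    forward_select,
)
from .optimize import (
    DesirabilityGoal,
    OptimizationResult,
    Region,
    export_surface_grid,
    maximize_desirability,
    maximize_response,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("cocultrsm")


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    center: float
    step: float = Field(gt=0)
    alpha: float = Field(default_factory=lambda: rotatable_alpha(3), gt=0)
    units: str = ""

    def to_spec(self) -> FactorSpec:
        return FactorSpec(**self.model_dump())


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    factorial_reps: int = Field(default=2, ge=0)
    axial_reps: int = Field(default=2, ge=0)
    center_reps: int = Field(default=6, ge=0)
    alpha: float | None = Field(default=None, gt=0)
    n_blocks: int = Field(default=1, ge=1)


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = Field(default="forward", pattern="^(forward|backward)$")
    alpha_enter: float = Field(default=0.10, gt=0, le=1)
    alpha_remove: float = Field(default=0.10, gt=0, le=1)
    max_degree: int = Field(default=3, ge=1, le=3)
    block_effect: bool = False


class RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = Field(default="cube", pattern="^(cube|sphere)$")
    bound: float = Field(default=1.0, gt=0)

    def to_region(self) -> Region:
        return Region(kind=self.kind, bound=self.bound)


class GoalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    response: str
    y_min: float | None = None   # default: observed response minimum
    y_max: float | None = None   # default: observed response maximum
    r: float = Field(default=1.0, gt=0)
    w: float = Field(default=1.0, gt=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_sd: dict[str, float] = {"mbe": 2.3, "od": 0.5}
    block_offsets: dict[int, float] = {}


class PipelineConfig(BaseModel):
    """Validated configuration for :func:`run_pipeline`; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "results"
    factors: list[FactorConfig] = Field(
        default_factory=lambda: [
            FactorConfig(name=f.name, center=f.center, step=f.step,
                         alpha=f.alpha, units=f.units)
            for f in synthetic.default_factors()
        ]
    )
    design: DesignConfig = DesignConfig()
    design_file: str | None = None     # read instead of generate
    responses_file: str | None = None  # read instead of simulate
    simulate: bool = True
    simulation: SimulationConfig = SimulationConfig()
    responses: list[str] = ["mbe", "od"]
    selection: SelectionConfig = SelectionConfig()
    region: RegionConfig = RegionConfig()
    goals: list[GoalConfig] | None = None
    n_restarts: int = Field(default=50, ge=1)
    grid_resolution: int = Field(default=41, ge=2)

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not self.responses:
            raise ValueError("at least one response required")
        if not self.simulate and self.responses_file is None:
            raise ValueError("responses_file required when simulate is off")
        return self


def load_config(path) -> PipelineConfig:
    return PipelineConfig.model_validate(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    design: DesignTable
    responses: pd.DataFrame
    models: dict[str, PolynomialModel]
    anovas: dict[str, AnovaTable]
    optimum: OptimizationResult
    desirability: OptimizationResult | None
    outdir: Path


def _fit_one(cfg: PipelineConfig, design: DesignTable, y, name: str) -> PolynomialModel:
    pool = build_terms(design.k, cfg.selection.max_degree)
    if cfg.selection.method == "forward":
        m = forward_select(
            design, y, pool, alpha_enter=cfg.selection.alpha_enter,
            block_effect=cfg.selection.block_effect,
        )
    else:
        m = backward_eliminate(
            design, y, pool, alpha_remove=cfg.selection.alpha_remove,
            block_effect=cfg.selection.block_effect,
        )
    m.response_name = name
    return m


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and serialize all artifacts under ``config.outdir``.

    Stage failures propagate as package exceptions annotated with the stage
    name; nothing is written until the configuration has validated.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    factors = [f.to_spec() for f in config.factors]
    stage = "design"
    try:
        if config.design_file:
            design = read_design(config.design_file)
        else:
            design = generate_ccd(
                k=len(factors),
                factorial_reps=config.design.factorial_reps,
                axial_reps=config.design.axial_reps,
                center_reps=config.design.center_reps,
                alpha=config.design.alpha,
                n_blocks=config.design.n_blocks,
                seed=config.seed,
                factors=factors,
            )
        write_design(outdir / "design.csv", design)
        log.info("design: %d runs, %d factors, seed %d", len(design), design.k,
                 config.seed)

        stage = "data"
        if config.simulate:
            truth = synthetic.GroundTruth(
                noise_sd=dict(config.simulation.noise_sd),
                block_offsets=dict(config.simulation.block_offsets),
            )
            responses = synthetic.simulate_responses(design, truth, seed=config.seed)
        else:
            responses = pd.read_csv(config.responses_file)
            responses = responses.sort_values("run_id").reset_index(drop=True)
        for r in config.responses:
            if r not in responses.columns:
                raise CocultRsmError(f"response column {r!r} missing from data")
        responses.to_csv(outdir / "responses.csv", index=False)

        stage = "fit"
        models: dict[str, PolynomialModel] = {}
        anovas: dict[str, AnovaTable] = {}
        for name in config.responses:
            y = responses[name].to_numpy()
            m = _fit_one(config, design, y, name)
            models[name] = m
            (outdir / f"model_{name}.json").write_text(json.dumps(m.to_dict(), indent=2))
            log.info("fit %s: %d terms, R2=%.3f, R2_pred=%s", name, len(m.terms),
                     m.fit_stats.r2, f"{m.fit_stats.r2_pred:.3f}" if m.fit_stats.r2_pred
                     is not None else "n/a")
            stage = "anova"
            tab = anova(m, design, y)
            anovas[name] = tab
            tab.to_frame().to_csv(outdir / f"anova_{name}.csv", index=False)
            stage = "fit"

        stage = "surface"
        names = [f.name for f in factors]
        primary = models[config.responses[0]]
        for fixed_i in range(design.k):
            if design.k != 3:
                break
            grid = export_surface_grid(
                primary, {fixed_i: 0.0}, grid_resolution=config.grid_resolution,
                bound=config.region.bound, factor_names=names,
            )
            grid.to_csv(outdir / f"surface_{primary.response_name}_fix{names[fixed_i]}.csv",
                        index=False)

        stage = "optimize"
        region = config.region.to_region()
        optimum = maximize_response(
            primary, region, n_restarts=config.n_restarts, seed=config.seed,
            factors=factors,
        )
        log.info("optimum %s: %.3f at %s", primary.response_name,
                 optimum.predicted[primary.response_name],
                 np.round(optimum.coded_point, 3))

        stage = "desirability"
        desirability = None
        if len(config.responses) >= 2:
            goal_cfgs = config.goals or [
                GoalConfig(response=r) for r in config.responses
            ]
            goals = []
            for g in goal_cfgs:
                obs = responses[g.response]
                goals.append(
                    DesirabilityGoal(
                        response_name=g.response,
                        y_min=g.y_min if g.y_min is not None else float(obs.min()),
                        y_max=g.y_max if g.y_max is not None else float(obs.max()),
                        r=g.r,
                        w=g.w,
                    )
                )
            desirability = maximize_desirability(
                [models[g.response_name] for g in goals], goals, region,
                n_restarts=config.n_restarts, seed=config.seed, factors=factors,
            )
            log.info("desirability D=%.3f at %s", desirability.d_global,
                     np.round(desirability.coded_point, 3))

        stage = "report"
        _write_results_json(outdir, config, optimum, desirability)
        _write_report(outdir, config, design, models, anovas, optimum, desirability,
                      names)
    except CocultRsmError as exc:
        raise CocultRsmError(
            f"pipeline stage {stage!r} failed: {exc} "
            f"(check the {stage} section of the config)"
        ) from exc

    return PipelineResult(design, responses, models, anovas, optimum, desirability,
                          outdir)


def _opt_to_dict(opt: OptimizationResult) -> dict:
    d = {
        "coded_point": [float(v) for v in opt.coded_point],
        "predicted": {k: float(v) for k, v in opt.predicted.items()},
        "n_restarts_converged": opt.n_restarts_converged,
    }
    if opt.natural_point is not None:
        d["natural_point"] = [float(v) for v in opt.natural_point]
    if opt.d_global is not None:
        d["d_values"] = {k: float(v) for k, v in opt.d_values.items()}
        d["d_global"] = float(opt.d_global)
        d["degenerate"] = opt.degenerate
    return d


def _write_results_json(outdir, config, optimum, desirability) -> None:
    payload = {"seed": config.seed, "single_response": _opt_to_dict(optimum)}
    if desirability is not None:
        payload["desirability"] = _opt_to_dict(desirability)
    (outdir / "optimization.json").write_text(json.dumps(payload, indent=2))


def _write_report(outdir, config, design, models, anovas, optimum, desirability,
                  names) -> None:
    lines = ["coculture response-surface optimization report", "=" * 48, ""]
    lines.append(f"seed: {config.seed}")
    lines.append(f"design: {len(design)} runs, {design.k} factors, "
                 f"{len({p.block for p in design.points})} block(s)")
    for name, m in models.items():
        s = m.fit_stats
        lines.append("")
        lines.append(f"response {name}: {len(m.terms)} terms "
                     f"(R2={s.r2:.3f}, R2_adj={s.r2_adj:.3f}, "
                     f"R2_pred={s.r2_pred:.3f})" if s.r2_pred is not None else
                     f"response {name}: {len(m.terms)} terms (R2={s.r2:.3f})")
        eq = " ".join(
            f"{c:+.4g}{('·' + t.label(names)) if not t.is_intercept else ''}"
            for t, c in zip(m.terms, m.coefficients)
        )
        lines.append(f"  {name} = {eq}")
        tab = anovas[name]
        if "lack_of_fit" in tab:
            lof = tab["lack_of_fit"]
            lines.append(f"  lack of fit: F={lof.f:.3g} p={lof.p:.3f} "
                         f"(df {lof.df} vs pure-error df {tab['pure_error'].df})")
    first = config.responses[0]
    lines.append("")
    lines.append(f"single-response optimum ({first}): "
                 f"{optimum.predicted[first]:.2f} at coded "
                 f"{np.round(optimum.coded_point, 3).tolist()}")
    if optimum.natural_point is not None:
        nat = ", ".join(f"{n}={v:.3g}" for n, v in zip(names, optimum.natural_point))
        lines.append(f"  natural units: {nat}")
    if desirability is not None:
        lines.append(f"multiresponse optimum: D={desirability.d_global:.3f} at coded "
                     f"{np.round(desirability.coded_point, 3).tolist()}")
        for r, v in desirability.predicted.items():
            lines.append(f"  {r}: predicted {v:.2f} (d={desirability.d_values[r]:.3f})")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
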