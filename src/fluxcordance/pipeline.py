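"""End-to-end two-condition pipeline with reproducible configuration.

Stages: load -> (reduce) -> map expression -> LAD fit per condition ->
alternative-optima FVA + sampling -> flux-sums (compartmental and pooled)
-> dual Mann-Whitney differential reports -> optional scenario comparison
when extra constraint sets are configured. Every stage writes its outputs
into the run directory; a JSON manifest records versions, seeds, z* per
condition, tolerances and sampler diagnostics, so a run is reproducible
bit-for-bit from its config (modulo LP solver version).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .expression import (
    DEFAULT_SIGMA_FLOOR,
    ExpressionMatrix,
    reaction_data_from_expression,
    read_expression_tsv,
)
from .fit import FitConstraints, RatioConstraint, solve_lad
from .fluxsum import flux_sums
from .model import MetabolicModel, load_model, reduce_model
from .optima import OptimalSpace, check_sample, fva_over_optima, sample_optima
from .stats import DEFAULT_ALPHA, differential_flux_report, differential_fluxsum_report, scenario_shift

__all__ = ["RunConfig", "run_pipeline", "report_summary", "run_condition"]


@dataclass
class SamplerConfig:
    n: int = 20_000
    seed: int = 0
    warmup: int = 1000
    thin: int = 10
    opt_tol: float = 1e-6


@dataclass
class StatsConfig:
    alpha: float = DEFAULT_ALPHA
    exclude: list[str] = field(default_factory=list)
    binarize: str = "two"


@dataclass
class RunConfig:
    model_path: str
    expr_a_path: str
    expr_b_path: str
    out_dir: str
    dialect: str = "auto"
    reduce: bool = True
    label_a: str = "A"
    label_b: str = "B"
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    lam: float = 0.0
    constraints: FitConstraints = field(default_factory=FitConstraints)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    #: extra named constraint scenarios to compare against the base run
    scenarios: dict[str, FitConstraints] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        def parse_constraints(block: dict) -> FitConstraints:
            ratios = [RatioConstraint(**rc) for rc in block.pop("ratio_constraints", [])]
            return FitConstraints(ratio_constraints=ratios, **block)

        kwargs = dict(doc)
        if "constraints" in kwargs:
            kwargs["constraints"] = parse_constraints(dict(kwargs["constraints"]))
        if "sampler" in kwargs:
            kwargs["sampler"] = SamplerConfig(**kwargs["sampler"])
        if "stats" in kwargs:
            kwargs["stats"] = StatsConfig(**kwargs["stats"])
        if "scenarios" in kwargs:
            kwargs["scenarios"] = {
                name: parse_constraints(dict(block))
                for name, block in kwargs["scenarios"].items()
            }
        return cls(**kwargs)

    def validate(self) -> None:
        for p in (self.model_path, self.expr_a_path, self.expr_b_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def run_condition(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    constraints: FitConstraints,
    sampler: SamplerConfig,
    seed: int,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    lam: float = 0.0,
):
    """Fit one condition and sample its alternative optima.

    Returns (space, sample, flux range, reaction data).
    """
    data = reaction_data_from_expression(model, expr, sigma_floor=sigma_floor)
    fit = solve_lad(model, data, constraints, lam)
    if fit.status != "optimal":
        raise RuntimeError(f"LAD fit ended {fit.status}")
    space = OptimalSpace(model=model, data=data, fit=fit, opt_tol=sampler.opt_tol)
    fva = fva_over_optima(space)
    sample = sample_optima(space, n=sampler.n, seed=seed, warmup=sampler.warmup, thin=sampler.thin)
    return space, sample, fva, data


def _differential_outputs(model, sample_a, sample_b, alpha):
    rep_flux = differential_flux_report(sample_a, sample_b, alpha)
    fs = {}
    reps = {"flux": rep_flux}
    for mode in ("compartmental", "pooled"):
        fs_a = flux_sums(sample_a, model, mode)
        fs_b = flux_sums(sample_b, model, mode)
        reps[f"fluxsum_{mode}"] = differential_fluxsum_report(fs_a, fs_b, alpha)
        fs[mode] = (fs_a, fs_b)
    return reps, fs


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full two-condition analysis; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fluxcordance",
        "solver": "scipy.optimize.linprog(method='highs')",
        "stages": [],
        "seeds": {"A": config.sampler.seed, "B": config.sampler.seed + 1},
        "config": _config_dict(config),
    }
    stage = "load_model"
    try:
        t0 = time.time()
        model = load_model(config.model_path, config.dialect)
        if config.reduce:
            stage = "reduce_model"
            model = reduce_model(model)
        manifest["model"] = {
            "name": model.name,
            "n_reactions": model.n_reactions,
            "n_metabolites": model.n_metabolites,
        }
        manifest["stages"].append({"stage": "model", "wall_s": round(time.time() - t0, 3)})

        stage = "expression"
        expr_a = read_expression_tsv(config.expr_a_path)
        expr_b = read_expression_tsv(config.expr_b_path)

        results = {}
        for label, expr, seed in (
            (config.label_a, expr_a, config.sampler.seed),
            (config.label_b, expr_b, config.sampler.seed + 1),
        ):
            stage = f"fit_and_sample_{label}"
            t0 = time.time()
            space, sample, fva, data = run_condition(
                model, expr, config.constraints, config.sampler, seed,
                config.sigma_floor, config.lam,
            )
            diag = check_sample(space, sample)
            results[label] = (space, sample, fva, data)
            fva.to_frame().to_csv(out / f"fva_{label}.tsv", sep="\t", index_label="reaction_id")
            np.savez_compressed(out / f"sample_{label}.npz", values=sample.values)
            manifest["stages"].append(
                {"stage": stage, "wall_s": round(time.time() - t0, 3),
                 "z_star": results[label][0].z_star, "diagnostics": diag}
            )
            manifest.setdefault("z_star", {})[label] = results[label][0].z_star

        stage = "reaction_data"
        (_, sample_a, _, data_a) = results[config.label_a]
        (_, sample_b, _, data_b) = results[config.label_b]
        tbl = data_a.table.join(data_b.table, lsuffix=f"_{config.label_a}", rsuffix=f"_{config.label_b}")
        tbl.to_csv(out / "reaction_data.tsv", sep="\t", index_label="reaction_id")

        stage = "differential_reports"
        t0 = time.time()
        reps, _ = _differential_outputs(model, sample_a, sample_b, config.stats.alpha)
        reps["flux"].to_tsv(out / "diff_flux.tsv")
        reps["fluxsum_compartmental"].to_tsv(out / "diff_fluxsum_compartmental.tsv")
        reps["fluxsum_pooled"].to_tsv(out / "diff_fluxsum_pooled.tsv")
        manifest["stages"].append({"stage": stage, "wall_s": round(time.time() - t0, 3)})

        if config.scenarios:
            stage = "scenario_comparison"
            shifts = {}
            for name, cons in config.scenarios.items():
                t0 = time.time()
                sc_results = {}
                for label, expr, seed in (
                    (config.label_a, expr_a, config.sampler.seed),
                    (config.label_b, expr_b, config.sampler.seed + 1),
                ):
                    _, s, _, _ = run_condition(
                        model, expr, cons, config.sampler, seed,
                        config.sigma_floor, config.lam,
                    )
                    sc_results[label] = s
                sc_reps, _ = _differential_outputs(
                    model, sc_results[config.label_a], sc_results[config.label_b],
                    config.stats.alpha,
                )
                sc_reps["flux"].to_tsv(out / f"diff_flux_{name}.tsv")
                shift = scenario_shift(
                    reps["flux"], sc_reps["flux"],
                    which=config.stats.binarize, exclude=config.stats.exclude,
                )
                shifts[name] = {
                    "hamming": shift["hamming"],
                    "n_items": shift["n_items"],
                    "fraction": shift["fraction"],
                }
                manifest["stages"].append(
                    {"stage": f"scenario_{name}", "wall_s": round(time.time() - t0, 3)}
                )
            (out / "scenario_shift.json").write_text(json.dumps(shifts, indent=1))
            manifest["scenario_shift"] = shifts
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _config_dict(config: RunConfig) -> dict:
    doc = asdict(config)
    return doc


def report_summary(run_dir: Union[str, Path], top: int = 10) -> str:
    """Human-readable summary of a completed run directory."""
    import pandas as pd

    run_dir = Path(run_dir)
    if (run_dir / "FAILED").exists():
        raise RuntimeError(
            f"run {run_dir} failed; see {run_dir / 'FAILED'} for the stage log"
        )
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"run: {run_dir}",
        f"model: {manifest['model']['name']} "
        f"({manifest['model']['n_reactions']} reactions, "
        f"{manifest['model']['n_metabolites']} metabolites)",
        f"z*: " + ", ".join(f"{k}={v:.6g}" for k, v in manifest.get("z_star", {}).items()),
    ]
    for st in manifest["stages"]:
        if "diagnostics" in st:
            d = st["diagnostics"]
            lines.append(
                f"sampler {st['stage']}: residual {d['max_steady_state_residual']:.2e}, "
                f"bound viol {d['max_bound_violation']:.2e}, "
                f"obj excess {d['max_objective_excess']:.2e}, "
                f"outside FVA {d['fraction_outside_fva']:.3f}"
            )
    flux = pd.read_csv(run_dir / "diff_flux.tsv", sep="\t", index_col=0)
    sig = flux[flux["significant"]].sort_values("p_two")
    if sig.empty:
        lines.append("no differential reactions at the configured alpha")
    else:
        lines.append(f"differential reactions ({len(sig)}):")
        for rid, row in sig.head(top).iterrows():
            lines.append(
                f"  {rid}: mean_A={row['mean_A']:.4g} mean_B={row['mean_B']:.4g} "
                f"p_two={row['p_two']:.3g} {row['direction']}"
            )
    if "scenario_shift" in manifest:
        for name, s in manifest["scenario_shift"].items():
            lines.append(
                f"scenario {name}: {s['hamming']}/{s['n_items']} reactions changed "
                f"test status ({100 * s['fraction']:.2f}%)"
            )
    return "\n".join(lines)
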