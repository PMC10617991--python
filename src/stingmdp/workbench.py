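"""Command-line workbench: configuration, orchestration and table output.

Every verb is a thin wrapper over the library; outputs are CSV/JSON tables
plus a run manifest (config echo, seeds, output paths) so that a full run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .agent_simulator import RandomPolicy, cohort_frame, matched_random_policy, simulate_cohort
from .behavior_fit import fit_increasing_cost, goodness_of_fit
from .defense_solver import defense_closed_form, defense_closed_form_increasing_cost
from .model_spec import (
    DefenseConfig,
    PredationMDP,
    RewardSpec,
    defense_config_from_config,
    load_config,
    predation_mdp_from_config,
)
from .predation_solver import (
    asymptotic_policy,
    policy_monotonicity_report,
    solve_with_increasing_cost,
    value_iteration,
)
from .synthetic_data import GeneratorSpec, generate_behavior_dataset

log = logging.getLogger("stingmdp")
logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")


@dataclass
class RunManifest:
    """Record of one workbench run: config, seeds, outputs, flags."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    version: str = __version__
    started_utc: str = ""
    wall_seconds: float = 0.0

    def write(self, outdir: Path) -> Path:
        path = outdir / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def _out(path: Path, manifest: RunManifest) -> Path:
    manifest.outputs.append(str(path))
    return path


def _write_policy(outdir, name, mdp, solutions, manifest):
    frames = [sol.to_frame(mdp) for sol in solutions]
    path = _out(outdir / name, manifest)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


@click.group()
def cli():
    """Optimal-control models of sea-anemone stinging."""


def _common(outdir: str) -> Path:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


@cli.command("solve-predation")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "outdir", default="out", show_default=True)
@click.option("--reward", default=None, help="override reward form (atan_example/cos_example)")
def solve_predation_cmd(config_path, outdir, reward):
    """Solve the predatory MDP by value iteration and the asymptotic relation."""
    t0 = time.time()
    cfg = load_config(config_path) if config_path else {}
    if reward:
        cfg.setdefault("reward", {})["form"] = reward
    mdp = predation_mdp_from_config(cfg)
    out = _common(outdir)
    manifest = RunManifest("solve-predation", cfg, cfg.get("seed"))
    log.info("solve-predation: value iteration (n_states=%d)", mdp.n_states)
    vi = value_iteration(mdp)
    asym = asymptotic_policy(mdp)
    _write_policy(out, "policy.csv", mdp, [vi, asym], manifest)
    solver_info = {
        "iterations": vi.iterations,
        "residual": vi.final_residual,
        "converged": vi.converged,
        "monotonicity": policy_monotonicity_report(vi),
        "config": cfg,
    }
    _out(out / "solver.json", manifest).write_text(json.dumps(solver_info, indent=2))
    manifest.wall_seconds = time.time() - t0
    manifest.write(out)
    log.info("solve-predation: wrote %s", out / "policy.csv")


@cli.command("solve-defense")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "outdir", default="out", show_default=True)
def solve_defense_cmd(config_path, outdir):
    """Solve the defensive two-state problem in closed form."""
    t0 = time.time()
    cfg = load_config(config_path) if config_path else {}
    dcfg = defense_config_from_config(cfg)
    out = _common(outdir)
    manifest = RunManifest("solve-defense", cfg, cfg.get("seed"))
    sol = defense_closed_form_increasing_cost(dcfg)
    path = _out(out / "defense_policy.csv", manifest)
    sol.to_frame(dcfg.starvation_grid()).to_csv(path, index=False)
    consts = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in sol.constants.items()}
    _out(out / "defense_constants.json", manifest).write_text(json.dumps(consts, indent=2))
    manifest.wall_seconds = time.time() - t0
    manifest.write(out)
    log.info("solve-defense: wrote %s", path)


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--policy", "policy_kind", type=click.Choice(["optimal", "random", "matched-random"]), default="optimal", show_default=True)
@click.option("--agents", default=200, show_default=True)
@click.option("--events", default=500, show_default=True)
@click.option("--s0", default=0.9, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "outdir", default="out", show_default=True)
def simulate_cmd(config_path, policy_kind, agents, events, s0, seed, outdir):
    """Simulate an agent cohort through the predatory MDP."""
    t0 = time.time()
    cfg = load_config(config_path) if config_path else {}
    mdp = predation_mdp_from_config(cfg)
    out = _common(outdir)
    manifest = RunManifest("simulate", cfg, seed, flags={"policy": policy_kind})
    if policy_kind == "optimal":
        policy = value_iteration(mdp).a_star
    elif policy_kind == "random":
        policy = RandomPolicy()
    else:
        opt = simulate_cohort(mdp, value_iteration(mdp).a_star, s0, agents, events, seed)
        policy = matched_random_policy(opt)
        manifest.flags["matched_bounds"] = [policy.a_min, policy.a_max]
    summary = simulate_cohort(mdp, policy, s0, agents, events, seed)
    path = _out(out / "trajectories.csv", manifest)
    cohort_frame(summary, mdp).to_csv(path, index=False)
    slim = {k: v for k, v in summary.items() if k != "trajectories"}
    _out(out / "cohort_summary.json", manifest).write_text(json.dumps(slim, indent=2))
    manifest.wall_seconds = time.time() - t0
    manifest.write(out)
    log.info("simulate: %s cohort, median events to absorption = %s",
             policy_kind, slim["median_events_to_absorption"])


@cli.command("generate")
@click.option("--profile", type=click.Choice(["increasing_predatory", "flat_defensive", "slightly_decreasing_defensive"]), default="slightly_decreasing_defensive", show_default=True)
@click.option("--animals", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "outdir", default="out", show_default=True)
def generate_cmd(profile, animals, seed, outdir):
    """Generate a synthetic behavioral discharge dataset."""
    out = _common(outdir)
    manifest = RunManifest("generate", {"profile": profile, "animals": animals}, seed)
    spec = GeneratorSpec(species_profile=profile, n_animals=animals, seed=seed)
    dataset, truth = generate_behavior_dataset(spec)
    path = _out(out / "behavior.csv", manifest)
    dataset.to_csv(path)
    _out(out / "truth.json", manifest).write_text(json.dumps(truth, indent=2))
    manifest.write(out)
    log.info("generate: wrote %s (%s)", path, profile)


@cli.command("fit")
@click.option("--data", "data_path", type=click.Path(exists=True), required=True)
@click.option("--model", type=click.Choice(["predation", "defense"]), default="defense", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--s-last", default=0.5, show_default=True)
@click.option("--out", "outdir", default="out", show_default=True)
def fit_cmd(data_path, model, config_path, s_last, outdir):
    """Fit the starvation-dependent cost to a behavioral dataset."""
    from .behavior_fit import BehaviorDataset

    t0 = time.time()
    cfg = load_config(config_path) if config_path else {}
    base = predation_mdp_from_config(cfg) if model == "predation" else defense_config_from_config(cfg)
    out = _common(outdir)
    manifest = RunManifest("fit", cfg, cfg.get("seed"), flags={"model": model, "data": data_path})
    dataset = BehaviorDataset.read_csv(data_path)
    fit = fit_increasing_cost(dataset, model, base, s_last=s_last)
    report = goodness_of_fit(fit, dataset)
    _out(out / "fit_result.json", manifest).write_text(json.dumps(report, indent=2))
    curve = pd.DataFrame(
        {"s": fit.s_values, "model_action": fit.fitted_curve / fit.scale_lambda,
         "fitted_fraction": fit.fitted_curve, "observed_fraction": fit.extras["observed"]}
    )
    _out(out / "fit_curve.csv", manifest)
    curve.to_csv(out / "fit_curve.csv", index=False)
    manifest.wall_seconds = time.time() - t0
    manifest.write(out)
    log.info("fit: c0(s) = %.3f + %.3f s, lambda = %.3f", report["c0_base"], report["slope"], report["scale_lambda"])


def run_figure2_pipeline(config: dict | None = None, outdir: str | Path = "out", seed: int = 0) -> RunManifest:
    """End-to-end reproduction of the model panels as tables.

    Solves the predatory MDP for both example rewards (numeric and
    asymptotic), the defensive problem for constant and increasing costs,
    simulates optimal/random/matched-random cohorts, generates a synthetic
    defensive dataset and fits the cost to it.  Deterministic given the
    seed.
    """
    t0 = time.time()
    cfg = dict(config or {})
    out = _common(str(outdir))
    manifest = RunManifest("reproduce-fig2", cfg, seed)
    stage = "predation-policies"
    try:
        mdp_by_reward = {}
        for form in ("atan_example", "cos_example"):
            c = {**cfg, "reward": {**cfg.get("reward", {}), "form": form}}
            mdp = predation_mdp_from_config(c)
            mdp_by_reward[form] = mdp
            vi = value_iteration(mdp)
            asym = asymptotic_policy(mdp)
            _write_policy(out, f"predation_policy_{form}.csv", mdp, [vi, asym], manifest)

        stage = "steep-cost-check"
        steep_cfg = {**cfg, "cost": {"form": "linear_increasing", "c0_base": cfg.get("cost", {}).get("c0_base", 1.0), "slope": cfg.get("cost", {}).get("steep_slope", 40.0)}}
        steep = solve_with_increasing_cost(predation_mdp_from_config(steep_cfg))
        manifest.flags["steep_cost_monotonicity"] = steep.extras["monotonicity"]

        stage = "defense-policies"
        dcfg = defense_config_from_config(cfg)
        const = defense_closed_form(dcfg if dcfg.cost.form == "constant" else defense_config_from_config({**cfg, "cost": {"form": "constant", "c0_base": 1.0}}))
        inc_cfg = defense_config_from_config({**cfg, "cost": {"form": "linear_increasing", "c0_base": 1.0, "slope": cfg.get("cost", {}).get("slope", 0.4)}})
        inc = defense_closed_form_increasing_cost(inc_cfg)
        grid = inc_cfg.starvation_grid()
        frame = pd.concat([
            const.to_frame(grid).assign(cost="constant"),
            inc.to_frame(grid).assign(cost="linear_increasing"),
        ], ignore_index=True)
        path = _out(out / "defense_policy.csv", manifest)
        frame.to_csv(path, index=False)

        stage = "cohort-simulations"
        seeds = np.random.SeedSequence(seed).spawn(4)
        summaries = {}
        mdp = mdp_by_reward["cos_example"]
        opt_policy = value_iteration(mdp).a_star
        for name, policy, ss in (
            ("optimal_cos", opt_policy, seeds[0]),
            ("optimal_atan", value_iteration(mdp_by_reward["atan_example"]).a_star, seeds[1]),
            ("random", RandomPolicy(), seeds[2]),
        ):
            use_mdp = mdp_by_reward["atan_example"] if name.endswith("atan") else mdp
            summ = simulate_cohort(use_mdp, policy, 0.9, 200, 500, int(ss.generate_state(1)[0] % 2**31))
            summaries[name] = {k: v for k, v in summ.items() if k != "trajectories"}
        matched = matched_random_policy(summaries["optimal_cos"]["mean_action"])
        summ = simulate_cohort(mdp, matched, 0.9, 200, 500, int(seeds[3].generate_state(1)[0] % 2**31))
        summaries["matched_random"] = {k: v for k, v in summ.items() if k != "trajectories"}
        summaries["matched_random"]["bounds"] = [matched.a_min, matched.a_max]
        _out(out / "cohort_summary.json", manifest).write_text(json.dumps(summaries, indent=2))

        stage = "synthetic-fit"
        spec = GeneratorSpec(seed=seed)
        dataset, truth = generate_behavior_dataset(spec)
        dpath = _out(out / "behavior.csv", manifest)
        dataset.to_csv(dpath)
        _out(out / "truth.json", manifest).write_text(json.dumps(truth, indent=2))
        fit = fit_increasing_cost(dataset, "defense", defense_config_from_config(cfg))
        report = goodness_of_fit(fit, dataset)
        _out(out / "fit_result.json", manifest).write_text(json.dumps(report, indent=2))
    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"figure-2 pipeline failed at stage {stage!r}: {exc}") from exc
    manifest.wall_seconds = time.time() - t0
    manifest.write(out)
    return manifest


@cli.command("reproduce-fig2")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "outdir", default="out", show_default=True)
def reproduce_fig2_cmd(config_path, seed, outdir):
    """Reproduce all model panels (policies, cohorts, fit) as tables."""
    cfg = load_config(config_path) if config_path else {}
    manifest = run_figure2_pipeline(cfg, outdir, seed)
    log.info("reproduce-fig2: %d outputs in %.1f s", len(manifest.outputs), manifest.wall_seconds)
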